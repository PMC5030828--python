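"""Descriptive attributes for clustering: structural bits + MW + logP.

Structural features are named SMARTS substructure patterns organized in
lists (a MACCS-key-like list, and two functional-group lists in the spirit
of the FP3/FP4 fingerprint definitions).  Each compound gets one 0/1 column
per pattern (namespaced ``listname:key``) plus two numeric columns, ``mw``
(g/mol) and ``logp`` (Crippen atom-contribution estimate).  Duplicate
patterns occurring in more than one list are kept as separate namespaced
columns; constant columns are retained but flagged uninformative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureEntry:
    key: str
    smarts: str
    description: str = ""
    min_count: int = 0  # bit is 1 iff #matches > min_count


@dataclass
class FeatureList:
    """An ordered, named list of SMARTS substructure features."""

    name: str
    entries: list[FeatureEntry]

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            if e.key in seen:
                raise ValueError(f"duplicate feature key {e.key!r} in list {self.name!r}")
            seen.add(e.key)
            if Chem.MolFromSmarts(e.smarts) is None:
                raise ValueError(
                    f"unparseable SMARTS for {self.name}:{e.key}: {e.smarts!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureList":
        """Load a list from YAML: ``name: ...`` and
        ``features: [{key, smarts, description}, ...]``."""
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        entries = [
            FeatureEntry(key=str(f["key"]), smarts=str(f["smarts"]),
                         description=str(f.get("description", "")))
            for f in doc["features"]
        ]
        return cls(name=str(doc["name"]), entries=entries)


def maccs_feature_list() -> FeatureList:
    """MACCS-key-like structural list from RDKit's key definitions.

    Keys whose definition is not expressible as a single SMARTS (RDKit marks
    them ``'?'``) are omitted, so the list is slightly shorter than 166.
    """
    from rdkit.Chem import MACCSkeys

    entries = []
    for idx in sorted(MACCSkeys.smartsPatts):
        smarts, count = MACCSkeys.smartsPatts[idx]
        if smarts == "?":
            continue
        entries.append(FeatureEntry(
            key=f"k{idx}", smarts=smarts,
            description=f"MACCS-like key {idx}", min_count=count))
    return FeatureList(name="maccs", entries=entries)


def load_default_feature_lists() -> list[FeatureList]:
    """The bundled default lists: MACCS-like + fp3-like + fp4-like."""
    lists = [maccs_feature_list()]
    pkg = resources.files("toxclust") / "patterns"
    for fname in ("fp3_like.yaml", "fp4_like.yaml"):
        with resources.as_file(pkg / fname) as p:
            lists.append(FeatureList.from_yaml(p))
    return lists


def match_pattern(smiles: str, pattern: str) -> int:
    """1 iff the SMARTS *pattern* has at least one match in the molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    patt = Chem.MolFromSmarts(pattern)
    if patt is None:
        raise ValueError(f"unparseable SMARTS: {pattern!r}")
    return int(mol.HasSubstructMatch(patt))


@dataclass
class FeatureMatrix:
    """Per-compound feature values plus per-column metadata.

    ``values``: DataFrame indexed by compound_id; structural columns are 0/1,
    ``mw`` and ``logp`` numeric.  ``metadata[col]`` holds ``kind``
    ("binary"/"numeric"), ``description`` and ``uninformative`` (constant
    column flag).
    """

    values: pd.DataFrame
    metadata: dict[str, dict] = field(default_factory=dict)

    @property
    def binary_columns(self) -> list[str]:
        return [c for c in self.values.columns
                if self.metadata[c]["kind"] == "binary"]

    @property
    def numeric_columns(self) -> list[str]:
        return [c for c in self.values.columns
                if self.metadata[c]["kind"] == "numeric"]

    def to_csv(self, path: str | Path, metadata_path: str | Path | None = None):
        self.values.to_csv(path, index_label="compound_id")
        if metadata_path is not None:
            import json
            with open(metadata_path, "w", encoding="utf-8") as fh:
                json.dump(self.metadata, fh, indent=1)


def build_feature_matrix(
    compounds: pd.DataFrame,
    feature_lists: list[FeatureList] | None = None,
    skip_bad: bool = False,
) -> FeatureMatrix:
    """Compute the full descriptive matrix for a compound table.

    One row per compound; one 0/1 column per namespaced pattern plus ``mw``
    and ``logp``.  Unparseable compounds raise by default (ids listed);
    with ``skip_bad=True`` they are dropped with a warning.
    """
    if feature_lists is None:
        feature_lists = load_default_feature_lists()

    columns: list[str] = []
    patterns: list[tuple[Chem.Mol, int]] = []
    meta: dict[str, dict] = {}
    seen_cols = set()
    for fl in feature_lists:
        for e in fl.entries:
            col = f"{fl.name}:{e.key}"
            if col in seen_cols:
                raise ValueError(f"duplicate namespaced feature column {col!r}")
            seen_cols.add(col)
            columns.append(col)
            patterns.append((Chem.MolFromSmarts(e.smarts), e.min_count))
            meta[col] = {"kind": "binary", "description": e.description,
                         "uninformative": False}

    mols, ids, bad = [], [], []
    for _, row in compounds.iterrows():
        mol = Chem.MolFromSmiles(row["smiles"])
        if mol is None:
            bad.append(str(row["compound_id"]))
            continue
        mols.append(mol)
        ids.append(row["compound_id"])
    if bad:
        if not skip_bad:
            raise ValueError(f"unparseable compound(s): {', '.join(bad)}")
        logger.warning("skipping unparseable compound(s): %s", ", ".join(bad))

    bits = np.zeros((len(mols), len(columns)), dtype=np.int8)
    for i, mol in enumerate(mols):
        for j, (patt, min_count) in enumerate(patterns):
            if min_count == 0:
                bits[i, j] = mol.HasSubstructMatch(patt)
            else:
                bits[i, j] = len(mol.GetSubstructMatches(patt)) > min_count

    values = pd.DataFrame(bits, index=pd.Index(ids, name="compound_id"),
                          columns=columns, dtype=float)

    kept = compounds[compounds["compound_id"].isin(ids)].set_index("compound_id")
    values["mw"] = kept["mw"].reindex(values.index).astype(float)
    values["logp"] = kept["logp"].reindex(values.index).astype(float)
    meta["mw"] = {"kind": "numeric", "description": "molecular weight [g/mol]",
                  "uninformative": False}
    meta["logp"] = {"kind": "numeric",
                    "description": "logP (Crippen atom-contribution estimate)",
                    "uninformative": False}
    if not np.isfinite(values[["mw", "logp"]].to_numpy()).all():
        raise ValueError("non-finite mw/logp values in compound table")

    if len(values):
        for col in values.columns:
            if values[col].nunique() <= 1:
                meta[col]["uninformative"] = True

    return FeatureMatrix(values=values, metadata=meta)
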