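"""Compound and study ingest, inclusion filters, and endpoint aggregation.

The study table holds one organ-effect finding per row, each with a LOEL
(lowest observed effect level) in mg/kg bw/day.  Records are filtered to
reliable rat studies of subacute (28-32 d) or subchronic (84-99 d) duration
with substance purity >= 90%, then organ-effect findings are mapped through a
user-supplied glossary onto aggregated endpoints (e.g. every liver finding
onto "liver").  Within a (compound, endpoint, duration class) cell the lowest
LOEL over all contributing studies is kept, converted to mmol/kg bw/day using
the compound's molecular weight.  Endpoints observed for fewer than a
prevalence cutoff (default 5%) of compounds are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

DURATION_CLASSES = ("subacute", "subchronic")

STUDY_COLUMNS = [
    "compound_id", "species", "route", "duration_days", "reliability",
    "purity_pct", "organ", "effect", "loel_mg_per_kg",
]


# ---------------------------------------------------------------------------
# compounds

def _mol_from_smiles(smiles: str):
    if not isinstance(smiles, str) or not smiles.strip():
        return None
    return Chem.MolFromSmiles(smiles)


def read_compounds(path: str | Path, format: str = "smiles_table") -> pd.DataFrame:
    """Read a compound table from a ``.smi`` file or an SDF.

    Returns a DataFrame with columns ``compound_id, smiles, mw, logp``;
    molecular weight (g/mol) and logP (Crippen atom-contribution estimate)
    are computed for records lacking them.  Unparseable entries are logged
    and collected in ``df.attrs["rejected"]`` rather than silently dropped.

    Raises
    ------
    FileNotFoundError
        if *path* does not exist.
    ValueError
        on an unrecognized *format* or duplicate compound ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"compound file not found: {path}")
    if format == "smiles_table":
        rows, rejected = _read_smiles_table(path)
    elif format == "sdf":
        rows, rejected = _read_sdf(path)
    else:
        raise ValueError(f"unrecognized compound format: {format!r}")

    if not rows:
        logger.warning("compound file %s yielded no parseable structures", path)
    df = pd.DataFrame(rows, columns=["compound_id", "smiles", "mw", "logp"])
    dupes = df["compound_id"][df["compound_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate compound_id(s): {', '.join(map(str, dupes))}")
    df.attrs["rejected"] = rejected
    for entry in rejected:
        logger.warning("rejected compound entry: %s", entry)
    return df


def _read_smiles_table(path: Path):
    rows, rejected = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            mol = _mol_from_smiles(smiles)
            if mol is None:
                rejected.append(f"line {lineno}: unparseable SMILES {smiles!r}")
                continue
            rows.append(_compound_row(cid, smiles, mol))
    return rows, rejected


def _read_sdf(path: Path, id_tag: str = "compound_id"):
    rows, rejected = [], []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            rejected.append(f"SDF record {i}: unparseable structure")
            continue
        if mol.HasProp(id_tag):
            cid = mol.GetProp(id_tag)
        elif mol.HasProp("_Name") and mol.GetProp("_Name"):
            cid = mol.GetProp("_Name")
        else:
            cid = f"record{i}"
        rows.append(_compound_row(cid, Chem.MolToSmiles(mol), mol))
    return rows, rejected


def _compound_row(cid, smiles, mol):
    return {
        "compound_id": str(cid),
        "smiles": smiles,
        "mw": float(Descriptors.MolWt(mol)),
        "logp": float(Crippen.MolLogP(mol)),
    }


# ---------------------------------------------------------------------------
# studies

def read_studies(path: str | Path) -> pd.DataFrame:
    """Read the study CSV (UTF-8, comma separated, header required).

    One organ-effect finding per row; columns as in :data:`STUDY_COLUMNS`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"study file not found: {path}")
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"study table missing column(s): {', '.join(missing)}")
    return df


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusion criteria for study records.

    Defaults encode the curation rules of the underlying data model: rat
    studies by oral or inhalation route, guideline-reliability A or B,
    subacute 28-32 days or subchronic 84-99 days, purity >= 90%.
    """

    species_allowed: frozenset[str] = frozenset({"rat"})
    routes_allowed: frozenset[str] = frozenset({"oral", "inhalation"})
    subacute_window: tuple[int, int] = (28, 32)
    subchronic_window: tuple[int, int] = (84, 99)
    min_purity_pct: float = 90.0
    reliability_allowed: frozenset[str] = frozenset({"A", "B"})

    def __post_init__(self):
        lo1, hi1 = self.subacute_window
        lo2, hi2 = self.subchronic_window
        if not (lo1 <= hi1 < lo2 <= hi2):
            raise ValueError("duration windows must be ordered and non-overlapping")
        if not 0 < self.min_purity_pct <= 100:
            raise ValueError("min_purity_pct must be in (0, 100]")

    def duration_class(self, days: float) -> str | None:
        if self.subacute_window[0] <= days <= self.subacute_window[1]:
            return "subacute"
        if self.subchronic_window[0] <= days <= self.subchronic_window[1]:
            return "subchronic"
        return None


def filter_studies(
    studies: pd.DataFrame, criteria: FilterCriteria = FilterCriteria()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply inclusion criteria; label survivors with their duration class.

    Returns ``(kept, report)`` where *kept* carries an added
    ``duration_class`` column and *report* counts rejections per reason.
    Filtering is total: no record raises, every record is kept or counted.
    """
    report = {"species": 0, "route": 0, "reliability": 0, "purity": 0, "duration": 0}
    keep = np.ones(len(studies), dtype=bool)
    dclass = []

    species_bad = ~studies["species"].isin(criteria.species_allowed)
    route_bad = ~studies["route"].isin(criteria.routes_allowed)
    rel_bad = ~studies["reliability"].isin(criteria.reliability_allowed)
    purity_bad = studies["purity_pct"] < criteria.min_purity_pct

    for i, (_, row) in enumerate(studies.iterrows()):
        if species_bad.iloc[i]:
            report["species"] += 1
            keep[i] = False
        elif route_bad.iloc[i]:
            report["route"] += 1
            keep[i] = False
        elif rel_bad.iloc[i]:
            report["reliability"] += 1
            keep[i] = False
        elif purity_bad.iloc[i]:
            report["purity"] += 1
            keep[i] = False
        else:
            dc = criteria.duration_class(row["duration_days"])
            if dc is None:
                report["duration"] += 1
                keep[i] = False
            else:
                dclass.append(dc)
                continue
        dclass.append(None)

    kept = studies.loc[keep].copy()
    kept["duration_class"] = [d for d, k in zip(dclass, keep) if k]
    return kept.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# glossary and endpoint aggregation

@dataclass
class EndpointGlossary:
    """Maps (organ, effect) pairs onto aggregated endpoint names."""

    mapping: Mapping[tuple[str, str], str]
    prevalence_cutoff: float = 0.05

    def __post_init__(self):
        if not 0 <= self.prevalence_cutoff < 1:
            raise ValueError("prevalence_cutoff must be in [0, 1)")

    @property
    def endpoints(self) -> list[str]:
        seen: dict[str, None] = {}
        for ep in self.mapping.values():
            seen.setdefault(ep, None)
        return list(seen)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EndpointGlossary":
        """Load from YAML: ``endpoints: {name: [[organ, effect], ...]}``
        plus optional ``prevalence_cutoff``."""
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        mapping: dict[tuple[str, str], str] = {}
        for endpoint, pairs in doc["endpoints"].items():
            for organ, effect in pairs:
                key = (str(organ), str(effect))
                if key in mapping and mapping[key] != endpoint:
                    raise ValueError(
                        f"organ-effect pair {key} mapped to both "
                        f"{mapping[key]!r} and {endpoint!r}"
                    )
                mapping[key] = endpoint
        return cls(mapping=mapping,
                   prevalence_cutoff=float(doc.get("prevalence_cutoff", 0.05)))

    def to_yaml(self, path: str | Path) -> None:
        doc: dict = {"prevalence_cutoff": self.prevalence_cutoff, "endpoints": {}}
        for (organ, effect), ep in self.mapping.items():
            doc["endpoints"].setdefault(ep, []).append([organ, effect])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


MISSING_REASONS = ("no_finding", "not_investigated", "no_information")


@dataclass
class EndpointLoelMatrix:
    """Compounds x endpoints LOEL matrix in mmol/kg bw/day.

    ``loel`` has a (endpoint, duration_class) column MultiIndex with NaN for
    missing cells; ``reasons`` holds one of :data:`MISSING_REASONS` wherever
    ``loel`` is missing (and "" where observed).
    """

    loel: pd.DataFrame
    reasons: pd.DataFrame
    dropped_endpoints: list[str] = field(default_factory=list)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.loel.index)

    @property
    def endpoints(self) -> list[str]:
        return list(self.loel.columns.get_level_values(0).unique())

    def observed(self) -> pd.DataFrame:
        return self.loel.notna()

    def to_csv(self, path: str | Path) -> None:
        """Write one row per compound, one column per endpoint x duration,
        with ``NA:<reason>`` sentinels for missing cells."""
        out = self.loel.copy().astype(object)
        for col in out.columns:
            na = out[col].isna()
            out.loc[na, col] = "NA:" + self.reasons.loc[na, col]
        out.columns = [f"{ep}|{dc}" for ep, dc in out.columns]
        out.to_csv(path, index_label="compound_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "EndpointLoelMatrix":
        raw = pd.read_csv(path, index_col="compound_id", dtype=str)
        cols = pd.MultiIndex.from_tuples(
            [tuple(c.split("|", 1)) for c in raw.columns],
            names=["endpoint", "duration_class"])
        loel = pd.DataFrame(index=raw.index, columns=cols, dtype=float)
        reasons = pd.DataFrame("", index=raw.index, columns=cols, dtype=object)
        for i, c in enumerate(raw.columns):
            vals = raw.iloc[:, i]
            isna = vals.str.startswith("NA:")
            loel.iloc[:, i] = pd.to_numeric(vals.mask(isna), errors="coerce")
            reasons.iloc[:, i] = vals.where(isna, "").str.replace("NA:", "", regex=False)
        return cls(loel=loel, reasons=reasons)


def aggregate_endpoints(
    studies: pd.DataFrame,
    glossary: EndpointGlossary,
    compounds: pd.DataFrame,
    on_unknown_pair: str = "drop",
) -> EndpointLoelMatrix:
    """Aggregate filtered organ-effect findings into the endpoint matrix.

    Per (compound, endpoint, duration class) cell the minimum LOEL over all
    contributing records is stored, converted from mg/kg to mmol/kg bw/day
    with the compound's molecular weight.  Endpoints observed for fewer than
    ``glossary.prevalence_cutoff`` of compounds are removed (logged).

    Missing cells carry a derived reason: ``not_investigated`` when the
    compound has no study of that duration class at all, ``no_finding`` when
    it has studies of the class but none mapping to the endpoint, and
    ``no_information`` when the compound has no kept studies whatsoever.

    Parameters
    ----------
    on_unknown_pair : {"drop", "error"}
        What to do with organ-effect pairs absent from the glossary.
    """
    if on_unknown_pair not in ("drop", "error"):
        raise ValueError("on_unknown_pair must be 'drop' or 'error'")
    if "duration_class" not in studies.columns:
        raise ValueError("studies must be filtered first (no duration_class column)")

    mw = compounds.set_index("compound_id")["mw"]
    endpoints = glossary.endpoints
    cols = pd.MultiIndex.from_product(
        [endpoints, list(DURATION_CLASSES)], names=["endpoint", "duration_class"])
    loel = pd.DataFrame(np.nan, index=list(compounds["compound_id"]),
                        columns=cols, dtype=float)
    loel.index.name = "compound_id"

    for _, row in studies.iterrows():
        cid = row["compound_id"]
        if cid not in loel.index:
            logger.warning("study for unknown compound %s dropped", cid)
            continue
        key = (row["organ"], row["effect"])
        endpoint = glossary.mapping.get(key)
        if endpoint is None:
            if on_unknown_pair == "error":
                raise KeyError(f"organ-effect pair {key} not in glossary")
            logger.warning("organ-effect pair %s not in glossary; dropped", key)
            continue
        mmol = float(row["loel_mg_per_kg"]) / float(mw[cid])
        col = (endpoint, row["duration_class"])
        prev = loel.at[cid, col]
        if np.isnan(prev) or mmol < prev:
            loel.at[cid, col] = mmol

    # prevalence filter: endpoint must be observed (any duration) for a
    # sufficient fraction of compounds
    n = len(loel)
    dropped: list[str] = []
    if n:
        for ep in endpoints:
            frac = loel[ep].notna().any(axis=1).mean()
            if frac < glossary.prevalence_cutoff:
                dropped.append(ep)
    if dropped:
        logger.info("endpoints below prevalence cutoff removed: %s",
                    ", ".join(dropped))
        loel = loel.drop(columns=dropped, level=0)

    # missingness reasons
    has_any = studies.groupby("compound_id").size()
    has_class = studies.groupby(["compound_id", "duration_class"]).size()
    reasons = pd.DataFrame("", index=loel.index, columns=loel.columns, dtype=object)
    for cid in loel.index:
        if cid not in has_any.index:
            reason_by_class = {dc: "no_information" for dc in DURATION_CLASSES}
        else:
            reason_by_class = {
                dc: ("no_finding" if (cid, dc) in has_class.index
                     else "not_investigated")
                for dc in DURATION_CLASSES
            }
        for col in loel.columns:
            if np.isnan(loel.at[cid, col]):
                reasons.at[cid, col] = reason_by_class[col[1]]

    return EndpointLoelMatrix(loel=loel, reasons=reasons, dropped_endpoints=dropped)
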