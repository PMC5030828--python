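"""Synthetic compound/study generator with the pipeline's assumed structure.

The confidential repeated-dose data this kind of analysis runs on cannot be
redistributed, so the generator emulates their statistical shape: latent
clusters of compounds sharing a structural scaffold (so cluster members
share fingerprint bits), per-cluster endpoint potency profiles with
log-normal LOELs whose high/low modes straddle the discretization band,
~82% missing cells, ~49% high-potency among observed, and study records
back-generated inside the subacute/subchronic duration windows with purity
>= 90% so the full ingest path is exercised.  Everything is reproducible
from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from toxclust.chemdata import EndpointGlossary

# Scaffold families: name -> function(variant index) -> SMILES.  Chosen to
# overlap chemotypes this kind of dataset actually contains (nitroaromatics,
# glycols/alcohols, azoles, haloaromatics, anilines, ketones).
_CHAINS = ["", "C", "CC", "CCC", "CCCC", "CCCCC", "CC(C)", "CCCCCC"]


def _nitroaromatic(i):
    r = _CHAINS[i % len(_CHAINS)]
    core = f"{r}c1ccc([N+](=O)[O-])cc1" if r else "O=[N+]([O-])c1ccccc1"
    return core


def _glycol_ether(i):
    k = i % 4
    cap = ["", "C", "CC", ""][i % 4]
    body = "OCC" + "OCC" * k + "O"
    return (cap + body) if cap else body


def _azole(i):
    variants = ["c1cnc[nH]1", "Cn1ccnc1", "CCn1ccnc1", "CCCn1ccnc1",
                "Cc1ncc[nH]1", "c1cn[nH]c1", "Cn1cncn1", "CCCCn1ccnc1"]
    return variants[i % len(variants)]


def _chloroaromatic(i):
    r = _CHAINS[i % len(_CHAINS)]
    return f"{r}c1ccc(Cl)cc1" if r else "Clc1ccccc1"


def _alcohol(i):
    variants = ["CO", "CCO", "CCCO", "CCCCO", "CC(C)O", "CC(C)(C)O",
                "CCCCCO", "CC(O)CO"]
    return variants[i % len(variants)]


def _aniline(i):
    r = _CHAINS[i % len(_CHAINS)]
    return f"{r}c1ccc(N)cc1" if r else "Nc1ccccc1"


def _ketone(i):
    r = _CHAINS[i % len(_CHAINS)]
    return f"CC(=O)C{r}" if r else "CC(C)=O"


def _thioether(i):
    variants = ["CSC", "CCSC", "CCSCC", "CSCCO", "CCCSC", "CCSCCO",
                "CSCCS", "CCCCSC"]
    return variants[i % len(variants)]


SCAFFOLD_FAMILIES = {
    "nitroaromatic": _nitroaromatic,
    "glycol_ether": _glycol_ether,
    "azole": _azole,
    "chloroaromatic": _chloroaromatic,
    "alcohol": _alcohol,
    "aniline": _aniline,
    "ketone": _ketone,
    "thioether": _thioether,
}

_ENDPOINT_POOL = ["liver", "kidney", "spleen", "rbc", "cns", "thyroid",
                  "male_repro", "body_weight", "lung", "adrenal",
                  "thymus", "heart"]

_EFFECTS = ["degeneration", "weight_change", "histopathology"]


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the generator; defaults emulate the reference data shape.

    ``missing_fraction`` 0.82 and ``observed_high_fraction`` 0.49 mirror the
    published dataset statistics; ``effect_separation`` is the log10-dose
    gap between the high- and low-potency modes (centered on the
    discretization band), ``subchronic_share`` the probability a study is
    subchronic rather than subacute.
    """

    n_compounds: int = 300
    n_endpoints: int = 8
    n_latent_clusters: int = 4
    feature_signal: tuple[str, ...] | None = None  # scaffold family per cluster
    effect_separation: float = 2.0
    loel_sigma: float = 0.25
    missing_fraction: float = 0.82
    observed_high_fraction: float = 0.49
    subchronic_share: float = 0.3
    missing_mode: str = "random"  # or "block"
    seed: int = 0

    def __post_init__(self):
        for name in ("missing_fraction", "observed_high_fraction",
                     "subchronic_share"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_latent_clusters < 1:
            raise ValueError("n_latent_clusters must be >= 1")
        if self.n_endpoints < 1 or self.n_endpoints > len(_ENDPOINT_POOL):
            raise ValueError(
                f"n_endpoints must be in [1, {len(_ENDPOINT_POOL)}]")
        if self.missing_mode not in ("random", "block"):
            raise ValueError("missing_mode must be 'random' or 'block'")


@dataclass
class SynthDataset:
    compounds: pd.DataFrame
    studies: pd.DataFrame
    glossary: EndpointGlossary
    true_clusters: pd.Series
    true_potency: pd.DataFrame
    true_loel_mmol: pd.DataFrame
    params: SynthParams

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the .smi/CSV/YAML files chemdata reads, plus ground truth."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "compounds": outdir / "compounds.smi",
            "studies": outdir / "studies.csv",
            "glossary": outdir / "glossary.yaml",
            "true_clusters": outdir / "true_clusters.csv",
            "true_potency": outdir / "true_potency.csv",
        }
        with open(paths["compounds"], "w", encoding="utf-8") as fh:
            for _, row in self.compounds.iterrows():
                fh.write(f"{row['smiles']}\t{row['compound_id']}\n")
        self.studies.to_csv(paths["studies"], index=False)
        self.glossary.to_yaml(paths["glossary"])
        self.true_clusters.rename("cluster").to_csv(
            paths["true_clusters"], index_label="compound_id")
        self.true_potency.to_csv(paths["true_potency"],
                                 index_label="compound_id")
        return paths


def default_glossary(endpoints: list[str],
                     prevalence_cutoff: float = 0.05) -> EndpointGlossary:
    mapping = {(ep, eff): ep for ep in endpoints for eff in _EFFECTS}
    return EndpointGlossary(mapping=mapping,
                            prevalence_cutoff=prevalence_cutoff)


def generate_dataset(params: SynthParams = SynthParams()) -> SynthDataset:
    """Generate compounds, studies and ground truth from the seed.

    Cluster profiles (which endpoints are high-potency) are drawn with
    P(high) = ``observed_high_fraction`` and forced distinct across
    clusters; LOELs are log-normal around the profile's mode.  Study
    records carry one organ-effect finding per row (sometimes a second,
    higher finding, so the lowest-LOEL aggregation rule is exercised).
    """
    rng = np.random.default_rng(params.seed)
    k = params.n_latent_clusters
    families = (list(params.feature_signal) if params.feature_signal
                else list(SCAFFOLD_FAMILIES)[:k])
    if len(families) != k:
        raise ValueError("need one scaffold family per latent cluster")
    unknown = [f for f in families if f not in SCAFFOLD_FAMILIES]
    if unknown:
        raise ValueError(
            f"infeasible signature assignment; unknown scaffold families: "
            f"{', '.join(unknown)}")

    endpoints = _ENDPOINT_POOL[: params.n_endpoints]
    m = len(endpoints)

    # distinct per-cluster potency profiles
    profiles = np.zeros((k, m), dtype=int)
    seen: set[tuple] = set()
    for c in range(k):
        for _ in range(1000):
            prof = (rng.random(m) < params.observed_high_fraction).astype(int)
            if tuple(prof) not in seen:
                break
        seen.add(tuple(prof))
        profiles[c] = prof

    labels = rng.integers(0, k, size=params.n_compounds)
    width = len(str(params.n_compounds))
    ids = [f"C{i:0{width}d}" for i in range(params.n_compounds)]

    rows = []
    for i, cid in enumerate(ids):
        fam = families[labels[i]]
        smiles = SCAFFOLD_FAMILIES[fam](int(rng.integers(0, 8)))
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # scaffold builders only emit valid SMILES
            raise RuntimeError(f"internal scaffold error for {smiles!r}")
        rows.append({"compound_id": cid, "smiles": smiles,
                     "mw": float(Descriptors.MolWt(mol)),
                     "logp": float(Crippen.MolLogP(mol))})
    compounds = pd.DataFrame(rows)

    center = 0.5 * (np.log10(1.5) + np.log10(2.0))
    half = params.effect_separation / 2.0
    log_loel = np.where(profiles[labels] == 1, center - half, center + half)
    log_loel = log_loel + rng.normal(0, params.loel_sigma,
                                     size=(params.n_compounds, m))
    true_loel = pd.DataFrame(10.0 ** log_loel, index=pd.Index(ids, name="compound_id"),
                             columns=endpoints)
    true_potency = pd.DataFrame(profiles[labels], index=true_loel.index,
                                columns=endpoints)

    if params.missing_mode == "random":
        observed = rng.random((params.n_compounds, m)) >= params.missing_fraction
    else:
        # block-missing: per-compound observation propensity (whole endpoint
        # panels uninvestigated for some compounds)
        a = 0.5
        mf = min(max(params.missing_fraction, 1e-9), 1 - 1e-9)
        b = a * mf / (1 - mf)
        q = rng.beta(a, b, size=params.n_compounds)
        observed = rng.random((params.n_compounds, m)) < q[:, None]

    glossary = default_glossary(endpoints)
    effect_lists = {ep: [eff for (o, eff) in glossary.mapping if o == ep]
                    for ep in endpoints}

    mw = compounds.set_index("compound_id")["mw"]
    study_rows = []
    for i, cid in enumerate(ids):
        for j, ep in enumerate(endpoints):
            if not observed[i, j]:
                continue
            subchronic = rng.random() < params.subchronic_share
            if subchronic:
                duration = int(rng.integers(84, 100))
                loel_mmol = true_loel.iat[i, j] / 2.0
            else:
                duration = int(rng.integers(28, 33))
                loel_mmol = true_loel.iat[i, j]
            effects = effect_lists[ep]
            eff = effects[int(rng.integers(0, len(effects)))]
            purity = float(np.round(rng.uniform(90.0, 100.0), 1))
            reliability = "A" if rng.random() < 0.7 else "B"
            base = {"compound_id": cid, "species": "rat", "route": "oral",
                    "duration_days": duration, "reliability": reliability,
                    "purity_pct": purity}
            study_rows.append({**base, "organ": ep, "effect": eff,
                               "loel_mg_per_kg": float(loel_mmol * mw[cid])})
            if rng.random() < 0.3 and len(effects) > 1:
                # a second, less sensitive finding in the same organ
                eff2 = [e for e in effects if e != eff][0]
                factor = float(rng.uniform(1.5, 4.0))
                study_rows.append({**base, "organ": ep, "effect": eff2,
                                   "loel_mg_per_kg":
                                       float(loel_mmol * mw[cid] * factor)})
    studies = pd.DataFrame(study_rows, columns=[
        "compound_id", "species", "route", "duration_days", "reliability",
        "purity_pct", "organ", "effect", "loel_mg_per_kg"])

    return SynthDataset(
        compounds=compounds, studies=studies, glossary=glossary,
        true_clusters=pd.Series(labels, index=true_loel.index, name="cluster"),
        true_potency=true_potency, true_loel_mmol=true_loel, params=params)
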