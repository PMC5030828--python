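"""End-to-end orchestration: ingest -> features -> potency -> imputation ->
tree -> cluster statistics, with a run manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd
import yaml

import toxclust
from toxclust import chemdata, clusterstats, features as feat, imputation, pct, potency

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for a full model build."""

    compounds_path: str
    studies_path: str
    glossary_path: str
    output_dir: str
    compound_format: str = "smiles_table"
    feature_list_paths: list[str] = field(default_factory=list)  # empty -> defaults
    criteria: chemdata.FilterCriteria = field(default_factory=chemdata.FilterCriteria)
    discretization: potency.DiscretizationParams = field(
        default_factory=potency.DiscretizationParams)
    ecc: imputation.ECCParams = field(default_factory=imputation.ECCParams)
    pct_params: pct.PCTParams = field(default_factory=pct.PCTParams)
    enrichment_endpoint: str | None = None
    enrichment_correction: str = "holm"
    readacross_max_ratio: float = 5.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update(overrides)
        kwargs = {}
        for key in ("compounds_path", "studies_path", "glossary_path",
                    "output_dir", "compound_format", "feature_list_paths",
                    "enrichment_endpoint", "enrichment_correction",
                    "readacross_max_ratio", "seed"):
            if key in doc:
                kwargs[key] = doc[key]
        if "discretization" in doc:
            kwargs["discretization"] = potency.DiscretizationParams(**doc["discretization"])
        if "ecc" in doc:
            kwargs["ecc"] = imputation.ECCParams(**doc["ecc"])
        if "pct" in doc:
            kwargs["pct_params"] = pct.PCTParams(**doc["pct"])
        if "criteria" in doc:
            kwargs["criteria"] = chemdata.FilterCriteria(**{
                k: (frozenset(v) if isinstance(v, list) else
                    tuple(v) if k.endswith("_window") else v)
                for k, v in doc["criteria"].items()})
        return cls(**kwargs)


@dataclass
class ModelBundle:
    tree: pct.PCTree
    potency_observed: potency.PotencyMatrix
    potency_completed: potency.PotencyMatrix
    loel_matrix: chemdata.EndpointLoelMatrix
    feature_matrix: feat.FeatureMatrix
    summaries: list
    imputation_report: dict
    filter_report: dict
    manifest: dict


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build(config: RunConfig) -> ModelBundle:
    """Run the full pipeline and write the model bundle to the output dir.

    Writes ``model.json``, ``tree.dot``, ``clusters.csv``, ``summaries.csv``,
    ``imputation_report.json`` and ``manifest.json`` (plus
    ``enrichment.csv`` when an enrichment endpoint is configured).
    Deterministic: same config + seed gives an identical model digest.
    """
    for label, p in (("compounds", config.compounds_path),
                     ("studies", config.studies_path),
                     ("glossary", config.glossary_path)):
        if not Path(p).exists():
            raise FileNotFoundError(f"{label} file not found: {p}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage chemdata: reading inputs")
    compounds = chemdata.read_compounds(config.compounds_path,
                                        format=config.compound_format)
    studies = chemdata.read_studies(config.studies_path)
    glossary = chemdata.EndpointGlossary.from_yaml(config.glossary_path)
    kept, filter_report = chemdata.filter_studies(studies, config.criteria)
    loel_matrix = chemdata.aggregate_endpoints(kept, glossary, compounds)

    logger.info("stage features")
    if config.feature_list_paths:
        lists = [feat.FeatureList.from_yaml(p) for p in config.feature_list_paths]
    else:
        lists = feat.load_default_feature_lists()
    fmatrix = feat.build_feature_matrix(compounds, lists)

    logger.info("stage potency")
    observed_potency = potency.discretize(loel_matrix, config.discretization)

    logger.info("stage imputation")
    ecc = imputation.ECCParams(
        n_chains=config.ecc.n_chains, bag_fraction=config.ecc.bag_fraction,
        vote_threshold=config.ecc.vote_threshold,
        seed=config.seed if config.ecc.seed == 0 else config.ecc.seed,
        base_learner=config.ecc.base_learner)
    completed, imp_report = imputation.impute_missing(observed_potency, fmatrix, ecc)

    logger.info("stage pct")
    tree = pct.induce_tree(fmatrix, completed, config.pct_params)

    logger.info("stage clusterstats")
    summaries = clusterstats.summarize_clusters(
        tree, completed, fmatrix, loel_matrix,
        subchronic_factor=config.discretization.subchronic_factor)

    tree.to_json(outdir / "model.json")
    tree.to_dot(outdir / "tree.dot")
    clusters = pd.DataFrame(
        [(cid, m) for cid, members in tree.leaf_memberships().items()
         for m in members], columns=["cluster_id", "compound_id"])
    clusters.to_csv(outdir / "clusters.csv", index=False)
    clusterstats.summaries_table(summaries).to_csv(
        outdir / "summaries.csv", index=False)
    loel_matrix.to_csv(outdir / "endpoint_matrix.csv")
    with open(outdir / "imputation_report.json", "w", encoding="utf-8") as fh:
        json.dump(imp_report, fh, indent=1)

    if config.enrichment_endpoint is not None:
        ep = config.enrichment_endpoint
        masked = completed.calls.where(completed.observed)
        activity = masked[ep] == 1.0
        bits = fmatrix.values.loc[:, fmatrix.binary_columns]
        rows = clusterstats.enrichment(bits, activity,
                                       correction=config.enrichment_correction)
        clusterstats.enrichment_table(rows).to_csv(
            outdir / "enrichment.csv", index=False)

    manifest = {
        "package_version": toxclust.__version__,
        "seed": config.seed,
        "inputs": {
            "compounds": _sha256(config.compounds_path),
            "studies": _sha256(config.studies_path),
            "glossary": _sha256(config.glossary_path),
        },
        "filter_report": filter_report,
        "n_compounds": len(compounds),
        "n_endpoints": len(loel_matrix.endpoints),
        "n_clusters": len(tree.leaves()),
        "model_digest": hashlib.sha256(
            tree.to_json().encode()).hexdigest(),
        "params": {
            "discretization": asdict(config.discretization),
            "pct": asdict(config.pct_params),
            "ecc": {"n_chains": ecc.n_chains, "bag_fraction": ecc.bag_fraction,
                    "vote_threshold": ecc.vote_threshold, "seed": ecc.seed},
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return ModelBundle(tree=tree, potency_observed=observed_potency,
                       potency_completed=completed, loel_matrix=loel_matrix,
                       feature_matrix=fmatrix, summaries=summaries,
                       imputation_report=imp_report,
                       filter_report=filter_report, manifest=manifest)


def assign_compounds(
    model_dir: str | Path,
    query_compounds: pd.DataFrame,
    feature_lists: list | None = None,
    summaries: pd.DataFrame | None = None,
    readacross_max_ratio: float = 5.0,
) -> pd.DataFrame:
    """Assign query compounds to the clusters of a built model.

    Returns one row per query with its cluster id, per-endpoint prediction,
    decision path, and -- for clusters whose LOEL gm/min ratio is within the
    read-across bound -- the cluster geometric-mean LOEL together with a
    note that an additional assessment factor of 5 is advised.  Unparseable
    queries produce an error row; the run continues.
    """
    model_dir = Path(model_dir)
    tree = pct.PCTree.from_json(model_dir / "model.json")
    if summaries is None and (model_dir / "summaries.csv").exists():
        summaries = pd.read_csv(model_dir / "summaries.csv")
    if feature_lists is None:
        feature_lists = feat.load_default_feature_lists()

    out_rows = []
    for _, row in query_compounds.iterrows():
        cid = row["compound_id"]
        try:
            fm = feat.build_feature_matrix(pd.DataFrame([row]), feature_lists)
            res = pct.assign(tree, fm.values.iloc[0])
        except (ValueError, KeyError) as exc:
            out_rows.append({"compound_id": cid, "error": str(exc)})
            continue
        rec = {
            "compound_id": cid, "cluster_id": res.cluster_id,
            "decision_path": " -> ".join(res.path) if res.path else "(root)",
            "error": "",
        }
        for ep, v in res.prediction.items():
            rec[f"pred_{ep}"] = "high" if v else "low"
        if summaries is not None and len(summaries):
            srow = summaries[summaries["cluster_id"] == res.cluster_id]
            if len(srow):
                ratio = float(srow["ratio_gm_lower"].iloc[0])
                if pd.notna(ratio) and ratio <= readacross_max_ratio:
                    rec["readacross_loel_gm_mmol"] = float(
                        srow["loel_gm_mmol"].iloc[0])
                    rec["readacross_note"] = (
                        "read-across candidate cluster (gm/min ratio "
                        f"{ratio:.2g} <= {readacross_max_ratio:g}); apply an "
                        "additional assessment factor of 5 to the cluster "
                        "geometric-mean LOEL")
        out_rows.append(rec)
    return pd.DataFrame(out_rows)
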