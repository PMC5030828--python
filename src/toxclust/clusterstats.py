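"""Post-clustering analytics, computed on observed (non-imputed) data only.

Covers the per-compound "toxic value" (sum of endpoint grades: 0 missing,
1 low potency, 2 high potency), cluster LOEL summaries (geometric mean,
range, geometric-mean/minimum ratio), selection of quantitative
read-across candidates (ratio <= 5), cluster category grading from
structural/toxicological similarity, 2x2 chi-square feature enrichment with
Holm (or plain Bonferroni) correction, and Spearman correlation between
endpoint LOEL profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from toxclust.features import FeatureMatrix
from toxclust.potency import PotencyMatrix


@dataclass
class ClusterSummary:
    cluster_id: int
    n_members: int
    activity_fraction: dict[str, float]      # per-endpoint observed high fraction
    loel_gm: float
    loel_min: float
    loel_max: float
    ratio_gm_lower: float
    ratio_max_min: float
    structural_similarity_pct: float | None = None
    toxicological_similarity_pct: float | None = None
    category: str = "unassessed"
    members: list[str] = field(default_factory=list)


def toxic_value(potency_row, observed_mask=None) -> int:
    """Sum of endpoint grades for one compound.

    Grades: missing (for whatever reason, incl. imputed) 0, low potency 1,
    high potency 2.  ``potency_row`` holds 1/0/NaN per endpoint;
    ``observed_mask`` (optional) zeroes out non-observed cells.
    """
    row = np.asarray(pd.Series(potency_row).to_numpy(), dtype=float)
    if observed_mask is not None:
        mask = np.asarray(pd.Series(observed_mask).to_numpy(), dtype=bool)
        row = np.where(mask, row, np.nan)
    grades = np.where(np.isnan(row), 0.0, row + 1.0)
    return int(grades.sum())


def toxic_values(potency: PotencyMatrix) -> pd.Series:
    """Toxic value per compound, counting only observed cells."""
    vals = {cid: toxic_value(potency.calls.loc[cid], potency.observed.loc[cid])
            for cid in potency.compound_ids}
    return pd.Series(vals, name="toxic_value")


def loel_summary(loels) -> tuple[float, float, float, float]:
    """(geometric mean, min, max, gm/min ratio) of a cluster's LOELs."""
    vals = np.asarray(list(loels), dtype=float)
    if vals.size == 0:
        raise ValueError("empty LOEL list")
    if np.any(vals <= 0):
        raise ValueError("LOELs must be positive")
    gm = float(np.exp(np.mean(np.log(vals))))
    lo, hi = float(vals.min()), float(vals.max())
    return gm, lo, hi, gm / lo


def select_readacross_candidates(summaries, max_ratio: float = 5.0):
    """Clusters usable for quantitative read-across.

    Keeps summaries with ``ratio_gm_lower <= max_ratio`` (a boundary ratio
    is kept), sorted ascending by ratio.
    """
    kept = [s for s in summaries if s.ratio_gm_lower <= max_ratio]
    return sorted(kept, key=lambda s: s.ratio_gm_lower)


def categorize_cluster(structural_similarity_pct: float,
                       toxicological_similarity_pct: float) -> str:
    """Category grade from structural/toxicological similarity percentages.

    100/100 -> "1"; 100 structural with tox in [75, 100) -> "2"; 100
    structural with tox < 75 -> "3"; structural below 100 -> "unassessed".
    """
    s, t = structural_similarity_pct, toxicological_similarity_pct
    if not (0 <= s <= 100 and 0 <= t <= 100):
        raise ValueError("similarity percentages must be in [0, 100]")
    if s < 100:
        return "unassessed"
    if t == 100:
        return "1"
    if t >= 75:
        return "2"
    return "3"


@dataclass
class EnrichmentRow:
    feature: str
    a: int  # active, feature present
    b: int  # active, feature absent
    c: int  # inactive, feature present
    d: int  # inactive, feature absent
    p_raw: float
    p_adjusted: float
    method: str


def chi2_2x2_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Pearson chi-square p-value (1 df, no continuity
    correction) for a 2x2 table; 1.0 for degenerate margins."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def enrichment(
    feature_bits: pd.DataFrame,
    activity: pd.Series,
    features_to_test: list[str] | None = None,
    correction: str = "holm",
) -> list[EnrichmentRow]:
    """Which structural features are over-represented among active compounds.

    Builds, per feature, the 2x2 table of activity x feature presence and
    computes a two-sided Pearson chi-square without continuity correction;
    p-values are adjusted over the tested set by Holm step-down (default)
    or plain Bonferroni.  Rows come back sorted by raw p-value.
    """
    if correction not in ("holm", "bonferroni"):
        raise ValueError("correction must be 'holm' or 'bonferroni'")
    activity = activity.astype(bool).reindex(feature_bits.index)
    n_active = int(activity.sum())
    n_inactive = int((~activity).sum())
    if n_active < 1 or n_inactive < 1:
        raise ValueError("need at least one active and one inactive compound")
    if features_to_test is None:
        features_to_test = list(feature_bits.columns)
    missing = [f for f in features_to_test if f not in feature_bits.columns]
    if missing:
        raise KeyError(f"feature(s) absent from matrix: {', '.join(missing)}")

    rows = []
    for feat in features_to_test:
        present = feature_bits[feat] >= 0.5
        a = int((present & activity).sum())
        c = int((present & ~activity).sum())
        b, d = n_active - a, n_inactive - c
        rows.append((feat, a, b, c, d, chi2_2x2_p(a, b, c, d)))

    praw = [r[5] for r in rows]
    _, padj, _, _ = multipletests(praw, method=correction)
    out = [EnrichmentRow(feature=f, a=a, b=b, c=c, d=d, p_raw=p, p_adjusted=q,
                         method=correction)
           for (f, a, b, c, d, p), q in zip(rows, padj)]
    return sorted(out, key=lambda r: r.p_raw)


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature": r.feature, "active_with": r.a, "active_without": r.b,
        "inactive_with": r.c, "inactive_without": r.d,
        "pct_active_with": 100 * r.a / (r.a + r.b),
        "pct_inactive_with": 100 * r.c / (r.c + r.d),
        "p_raw": r.p_raw, "p_adjusted": r.p_adjusted, "method": r.method,
    } for r in rows])


def endpoint_correlation(
    loel_columns: pd.DataFrame,
    log_transform: bool = True,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pairwise Spearman correlation of endpoint LOEL columns.

    Uses compounds observed for both endpoints of a pair; pairs with fewer
    than ``min_pairs`` complete observations are reported as NaN.  The log
    transform is a no-op for a rank correlation but applied for parity with
    the reported analysis.
    """
    cols = list(loel_columns.columns)
    data = loel_columns.astype(float)
    if log_transform:
        data = np.log(data)
    out = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    for i, ci in enumerate(cols):
        for cj in cols[i:]:
            x, y = data[ci], data[cj]
            ok = x.notna() & y.notna()
            if int(ok.sum()) < min_pairs:
                continue
            rho = stats.spearmanr(x[ok], y[ok]).statistic
            out.loc[ci, cj] = out.loc[cj, ci] = float(rho)
    return out


# ---------------------------------------------------------------------------
# cluster summaries over a fitted tree

def compound_loels(loel_matrix, subchronic_factor: float = 2.0) -> pd.Series:
    """Representative LOEL per compound (mmol/kg, subacute scale).

    Geometric mean of the compound's observed endpoint LOELs, with
    subchronic values multiplied by ``subchronic_factor`` to align duration
    classes.  NaN for compounds with no observed LOEL.
    """
    sub = loel_matrix.loel.xs("subacute", axis=1, level=1)
    chron = loel_matrix.loel.xs("subchronic", axis=1, level=1) * subchronic_factor
    both = pd.concat([sub, chron], axis=1)
    logs = np.log(both)
    return np.exp(logs.mean(axis=1)).rename("loel_mmol")


def structural_similarity_pct(feature_bits: pd.DataFrame) -> float:
    """Proxy: % of members equal to the cluster's modal bit signature."""
    if len(feature_bits) == 0:
        raise ValueError("empty cluster")
    modal = (feature_bits.mean(axis=0) >= 0.5).astype(float)
    match = (feature_bits >= 0.5).eq(modal >= 0.5, axis=1).all(axis=1)
    return float(100.0 * match.mean())


def toxicological_similarity_pct(calls: pd.DataFrame,
                                 observed: pd.DataFrame) -> float:
    """Proxy: % of members whose observed calls agree with the cluster's
    modal observed endpoint profile (endpoints without any observation in
    the cluster, or in the member, are not compared)."""
    if len(calls) == 0:
        raise ValueError("empty cluster")
    masked = calls.where(observed)
    modal = masked.mean(axis=0)  # NaN where never observed in cluster
    ok = []
    for cid in calls.index:
        row = masked.loc[cid]
        comparable = row.notna() & modal.notna()
        if not comparable.any():
            ok.append(True)
            continue
        ok.append(bool((row[comparable].round() ==
                        (modal[comparable] >= 0.5).astype(float)).all()))
    return float(100.0 * np.mean(ok))


def summarize_clusters(
    tree,
    potency: PotencyMatrix,
    features: FeatureMatrix,
    loel_matrix=None,
    subchronic_factor: float = 2.0,
) -> list[ClusterSummary]:
    """One :class:`ClusterSummary` per leaf, from observed data only.

    LOEL statistics use the representative per-compound LOELs from
    ``loel_matrix`` (members without an observed LOEL are excluded from
    them); similarity percentages are the documented operational proxies,
    and the category follows the 100%-structural grading rule.
    """
    per_compound = (compound_loels(loel_matrix, subchronic_factor)
                    if loel_matrix is not None else None)
    masked = potency.calls.where(potency.observed)
    summaries = []
    for leaf in tree.leaves():
        members = leaf.members
        sub = masked.loc[members]
        activity = {ep: (float(sub[ep].mean()) if sub[ep].notna().any()
                         else float("nan"))
                    for ep in potency.endpoints}
        if per_compound is not None:
            vals = per_compound.reindex(members).dropna()
        else:
            vals = pd.Series(dtype=float)
        if len(vals):
            gm, lo, hi, ratio = loel_summary(vals)
            ratio_max_min = hi / lo
        else:
            gm = lo = hi = ratio = ratio_max_min = float("nan")
        spct = structural_similarity_pct(
            features.values.loc[members, features.binary_columns])
        tpct = toxicological_similarity_pct(potency.calls.loc[members],
                                            potency.observed.loc[members])
        summaries.append(ClusterSummary(
            cluster_id=leaf.cluster_id, n_members=len(members),
            activity_fraction=activity, loel_gm=gm, loel_min=lo, loel_max=hi,
            ratio_gm_lower=ratio, ratio_max_min=ratio_max_min,
            structural_similarity_pct=spct, toxicological_similarity_pct=tpct,
            category=categorize_cluster(spct, tpct), members=list(members)))
    return summaries


def summaries_table(summaries: list[ClusterSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cluster_id": s.cluster_id, "n_members": s.n_members,
        "loel_gm_mmol": s.loel_gm, "loel_min_mmol": s.loel_min,
        "loel_max_mmol": s.loel_max, "ratio_gm_lower": s.ratio_gm_lower,
        "ratio_max_min": s.ratio_max_min,
        "structural_similarity_pct": s.structural_similarity_pct,
        "toxicological_similarity_pct": s.toxicological_similarity_pct,
        "category": s.category,
    } for s in summaries])
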