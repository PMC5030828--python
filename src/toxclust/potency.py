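"""Molar conversion and high/low potency discretization of LOELs.

Doses in mg/kg bw/day are converted to mmol/kg bw/day with the molecular
weight.  Each endpoint then gets its own high/low threshold, found by a
deterministic one-dimensional two-means clustering on log10 doses and
clamped into a fixed band (default 1.5-2.0 mmol/kg for subacute studies).
A compound at or below the threshold is high-potency.  Subchronic LOELs are
compared against the subacute threshold divided by a duration factor
(default 2, the conventional subchronic-to-subacute assessment factor).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from toxclust.chemdata import EndpointLoelMatrix

logger = logging.getLogger(__name__)

HIGH, LOW = 1.0, 0.0


@dataclass(frozen=True)
class DiscretizationParams:
    """Bounds and duration adjustment for the potency threshold.

    threshold_lo / threshold_hi : mmol/kg bw/day
        Band into which the per-endpoint subacute threshold is clamped.
    subchronic_factor : float
        Subchronic threshold = subacute threshold / factor.
    per_endpoint : bool
        Detect one threshold per endpoint (else one global threshold).
    """

    threshold_lo: float = 1.5
    threshold_hi: float = 2.0
    subchronic_factor: float = 2.0
    per_endpoint: bool = True

    def __post_init__(self):
        if not 0 < self.threshold_lo < self.threshold_hi:
            raise ValueError("need 0 < threshold_lo < threshold_hi")
        if self.subchronic_factor <= 0:
            raise ValueError("subchronic_factor must be > 0")


def to_mmol(dose_mg_per_kg: float, mw_g_per_mol: float) -> float:
    """Convert a dose in mg/kg bw/day to mmol/kg bw/day."""
    if dose_mg_per_kg <= 0 or mw_g_per_mol <= 0:
        raise ValueError("dose and molecular weight must be positive")
    return dose_mg_per_kg / mw_g_per_mol


def find_threshold(values, params: DiscretizationParams = DiscretizationParams()) -> float:
    """Data-adaptive potency threshold for one endpoint.

    Runs deterministic two-means on log10(values) with centers initialized
    at the 25th/75th percentiles, takes the midpoint between the converged
    group means (in log space), back-transforms, and clamps the result into
    ``[threshold_lo, threshold_hi]``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot detect a threshold from an empty sample")
    if np.any(values <= 0):
        raise ValueError("LOEL values must be positive")
    lo, hi = params.threshold_lo, params.threshold_hi
    if values.size == 1:
        warnings.warn("single LOEL value; threshold is the clamped value")
        return float(np.clip(values[0], lo, hi))

    x = np.log10(values)
    c1, c2 = np.percentile(x, 25.0), np.percentile(x, 75.0)
    if c1 == c2:
        return float(np.clip(10.0 ** c1, lo, hi))
    for _ in range(200):
        # assign to the nearer center; ties go to the lower center
        lower = np.abs(x - c1) <= np.abs(x - c2)
        if lower.all() or (~lower).all():
            break
        n1, n2 = x[lower].mean(), x[~lower].mean()
        if n1 == c1 and n2 == c2:
            break
        c1, c2 = n1, n2
    mid = 0.5 * (c1 + c2)
    return float(np.clip(10.0 ** mid, lo, hi))


@dataclass
class PotencyMatrix:
    """Compounds x endpoints high/low potency calls.

    ``calls`` holds 1.0 (high), 0.0 (low) or NaN (missing); ``observed``
    marks experimentally derived cells, ``imputed`` the cells filled by
    imputation (all False before imputation); ``thresholds`` records the
    subacute threshold used per endpoint (mmol/kg bw/day).
    """

    calls: pd.DataFrame
    observed: pd.DataFrame
    thresholds: pd.Series
    imputed: pd.DataFrame | None = None

    def __post_init__(self):
        if self.imputed is None:
            self.imputed = pd.DataFrame(False, index=self.calls.index,
                                        columns=self.calls.columns)

    @property
    def endpoints(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.calls.index)

    def is_complete(self) -> bool:
        return not self.calls.isna().any().any()

    def copy(self) -> "PotencyMatrix":
        return PotencyMatrix(calls=self.calls.copy(), observed=self.observed.copy(),
                             thresholds=self.thresholds.copy(),
                             imputed=self.imputed.copy())

    def to_csv(self, path) -> None:
        """Export calls as {1, 0, NA} (1 = high potency)."""
        out = self.calls.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
        out.to_csv(path, index_label="compound_id")


def discretize(
    matrix: EndpointLoelMatrix,
    params: DiscretizationParams = DiscretizationParams(),
) -> PotencyMatrix:
    """Discretize an endpoint LOEL matrix into high/low potency calls.

    Per endpoint the subacute threshold ``t`` comes from
    :func:`find_threshold` on that endpoint's observed subacute values
    (default band midpoint, with a warning, when there are none).  A
    subacute LOEL <= t is high; a subchronic LOEL is compared against
    ``t / subchronic_factor``.  A compound with both duration classes is
    high if either class says high (conservative merge).  Missing stays
    missing.
    """
    endpoints = matrix.endpoints
    if not endpoints:
        raise ValueError("endpoint matrix has no endpoints")
    default_t = float(np.sqrt(params.threshold_lo * params.threshold_hi))

    global_t = None
    if not params.per_endpoint:
        allsub = matrix.loel.xs("subacute", axis=1, level=1).to_numpy().ravel()
        allsub = allsub[~np.isnan(allsub)]
        global_t = find_threshold(allsub, params) if allsub.size else default_t

    calls = pd.DataFrame(np.nan, index=matrix.loel.index, columns=endpoints,
                         dtype=float)
    thresholds = pd.Series(index=endpoints, dtype=float, name="subacute_threshold")
    for ep in endpoints:
        sub = matrix.loel[(ep, "subacute")]
        chron = matrix.loel[(ep, "subchronic")]
        if global_t is not None:
            t = global_t
        else:
            obs = sub.dropna().to_numpy()
            if obs.size == 0:
                warnings.warn(
                    f"endpoint {ep!r} has no observed subacute values; "
                    f"threshold defaults to band midpoint {default_t:.3g}")
                t = default_t
            else:
                t = find_threshold(obs, params)
        thresholds[ep] = t
        t_chron = t / params.subchronic_factor
        high = (sub <= t) | (chron <= t_chron)
        low = ((sub > t) | (chron > t_chron)) & ~high
        calls.loc[high.fillna(False), ep] = HIGH
        calls.loc[low.fillna(False), ep] = LOW

    observed = calls.notna()
    return PotencyMatrix(calls=calls, observed=observed, thresholds=thresholds)
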