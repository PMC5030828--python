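"""Multi-label imputation of missing potency calls.

An Ensemble of Classifier Chains (ECC) fills the missing cells of the
potency matrix so the clustering tree receives a complete target matrix.
Each chain draws a random endpoint order and a bootstrap sample of
compounds, then fits one binary base learner per endpoint on the structural
features + MW + logP augmented with the chain's earlier endpoint values
(observed where available, else the chain's own prediction).  The final
call per missing cell is a probability-mean vote across chains.  Imputed
cells stay flagged and are excluded from all downstream summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from toxclust.features import FeatureMatrix
from toxclust.potency import PotencyMatrix

logger = logging.getLogger(__name__)


def default_base_learner(random_state: int) -> DecisionTreeClassifier:
    """Depth-limited decision tree emitting class probabilities."""
    return DecisionTreeClassifier(max_depth=6, random_state=random_state)


@dataclass(frozen=True)
class ECCParams:
    """Configuration of the classifier-chain ensemble.

    n_chains : chains in the ensemble (each with its own endpoint order).
    bag_fraction : fraction of compounds bootstrap-sampled per chain
        (with replacement).
    base_learner : factory ``random_state -> classifier`` with
        fit/predict_proba; default is a depth-limited decision tree.
    vote_threshold : mean high-probability at or above which the vote is
        "high".
    seed : fixes all randomness (label orders, bags, learners).
    """

    n_chains: int = 10
    bag_fraction: float = 0.67
    vote_threshold: float = 0.5
    seed: int = 0
    base_learner: Callable[[int], object] = default_base_learner

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag_fraction must be in (0, 1]")
        if not 0 < self.vote_threshold < 1:
            raise ValueError("vote_threshold must be in (0, 1)")


def run_chain(
    X: np.ndarray,
    Y: np.ndarray,
    order: np.ndarray,
    bag: np.ndarray,
    tree_seeds: np.ndarray,
    base_learner: Callable[[int], object] = default_base_learner,
) -> np.ndarray:
    """Fit and apply a single classifier chain.

    ``Y`` is the n x m potency array with NaN for missing cells; ``order``
    the endpoint order; ``bag`` the training row indices; ``tree_seeds``
    one learner seed per endpoint (in chain order).  Returns an n x m array
    of P(high) for every cell.

    Missing predecessor labels within the training rows are filled with the
    endpoint's observed majority class; at prediction time predecessors use
    the observed value where available, else the chain's own hard call.
    """
    n, m = Y.shape
    proba = np.full((n, m), np.nan)
    hard = np.full((n, m), np.nan)  # chain's running hard calls
    majority = _observed_majorities(Y)

    pred_cols: list[int] = []
    for pos, j in enumerate(order):
        X_aug_train = _augment(X, Y, hard, pred_cols, majority, rows=bag,
                               training=True)
        X_aug_all = _augment(X, Y, hard, pred_cols, majority, rows=None,
                             training=False)
        y_bag = Y[bag, j]
        fit_rows = ~np.isnan(y_bag)
        classes = np.unique(y_bag[fit_rows])
        if classes.size == 0:
            p = np.full(n, float(majority[j]))
        elif classes.size == 1:
            warnings.warn(f"endpoint column {j} has a single observed class "
                          "in this bag; constant prediction")
            p = np.full(n, float(classes[0]))
        else:
            clf = base_learner(int(tree_seeds[pos]))
            clf.fit(X_aug_train[fit_rows], y_bag[fit_rows])
            hi = int(np.where(clf.classes_ == 1.0)[0][0])
            p = clf.predict_proba(X_aug_all)[:, hi]
        proba[:, j] = p
        hard[:, j] = (p >= 0.5).astype(float)
        pred_cols.append(j)
    return proba


def _observed_majorities(Y: np.ndarray) -> np.ndarray:
    m = Y.shape[1]
    out = np.zeros(m)
    for j in range(m):
        col = Y[:, j]
        obs = col[~np.isnan(col)]
        # ties go to high (conservative)
        out[j] = 1.0 if obs.size and obs.mean() >= 0.5 else 0.0
    return out


def _augment(X, Y, hard, pred_cols, majority, rows, training):
    base = X if rows is None else X[rows]
    if not pred_cols:
        return base
    cols = []
    for j in pred_cols:
        obs = Y[:, j] if rows is None else Y[rows, j]
        if training:
            fill = np.full(obs.shape, majority[j])
        else:
            fill = hard[:, j] if rows is None else hard[rows, j]
        cols.append(np.where(np.isnan(obs), fill, obs))
    return np.column_stack([base] + cols)


def impute_missing(
    potency: PotencyMatrix,
    features: FeatureMatrix,
    params: ECCParams = ECCParams(),
) -> tuple[PotencyMatrix, dict]:
    """Fill every missing potency cell with a high/low call.

    Returns ``(completed, report)``; observed cells are unchanged, the
    completed matrix's ``imputed`` mask marks exactly the formerly missing
    cells, and *report* records per-endpoint imputed counts and per-chain
    endpoint orders.  Fully reproducible from ``params.seed``.
    """
    if not features.values.index.equals(potency.calls.index):
        if set(features.values.index) != set(potency.calls.index):
            raise ValueError("feature and potency row sets differ")
        features = FeatureMatrix(
            values=features.values.reindex(potency.calls.index),
            metadata=features.metadata)
    if features.values.shape[1] == 0:
        raise ValueError("empty feature matrix")
    for ep in potency.endpoints:
        if not potency.observed[ep].any():
            raise ValueError(f"endpoint {ep!r} has no observed cells")

    completed = potency.copy()
    missing = potency.calls.isna()
    report: dict = {
        "n_chains": params.n_chains,
        "bag_fraction": params.bag_fraction,
        "vote_threshold": params.vote_threshold,
        "seed": params.seed,
        "chain_orders": [],
        "imputed_per_endpoint": {
            ep: int(missing[ep].sum()) for ep in potency.endpoints},
    }
    if not missing.any().any():
        return completed, report

    X = features.values.to_numpy(dtype=float)
    Y = potency.calls.to_numpy(dtype=float)
    n, m = Y.shape
    rng = np.random.default_rng(params.seed)
    bag_size = max(1, int(round(params.bag_fraction * n)))

    proba_sum = np.zeros((n, m))
    for _ in range(params.n_chains):
        order = rng.permutation(m)
        bag = rng.choice(n, size=bag_size, replace=True)
        tree_seeds = rng.integers(0, 2**31 - 1, size=m)
        proba_sum += run_chain(X, Y, order, bag, tree_seeds,
                               params.base_learner)
        report["chain_orders"].append([potency.endpoints[j] for j in order])

    votes = proba_sum / params.n_chains
    fill = (votes >= params.vote_threshold).astype(float)
    calls = completed.calls.to_numpy()
    calls[missing.to_numpy()] = fill[missing.to_numpy()]
    completed.calls = pd.DataFrame(calls, index=potency.calls.index,
                                   columns=potency.calls.columns)
    completed.imputed = missing.copy()
    return completed, report
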