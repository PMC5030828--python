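"""Predictive clustering tree (PCT) induction and cluster assignment.

A PCT is a binary decision tree over descriptive attributes (structural
bits, MW, logP) whose splits are chosen to minimize the variance of the
multi-endpoint potency targets, so every leaf is a cluster of compounds
with a homogeneous toxicity profile.  Induction is standard top-down: at
each node all admissible tests are scored by the variance reduction they
induce, the best is kept only if an F-test finds the reduction significant
(default alpha 0.125), and leaves must hold at least ``min_leaf`` (default
3) compounds.  No pruning, no ensembling; the procedure is deterministic.

Variance of a cluster is ``(1/n) * sum_i ||y_i - ybar||^2`` over the 0/1
target rows, which equals the sum of squared pairwise distances up to the
fixed factor ``2n``; the normalization is fixed throughout.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from toxclust.features import FeatureMatrix


@dataclass(frozen=True)
class PCTParams:
    """Induction settings: leaf size, stopping test, optional depth cap."""

    min_leaf: int = 3
    f_test_alpha: float = 0.125
    max_depth: int | None = None

    def __post_init__(self):
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if not 0 < self.f_test_alpha < 1:
            raise ValueError("f_test_alpha must be in (0, 1)")


@dataclass(frozen=True)
class SplitTest:
    """One node test: bit presence, or numeric-attribute <= threshold."""

    feature: str
    kind: str  # "binary_presence" | "numeric_threshold"
    threshold: float | None = None

    def __post_init__(self):
        if self.kind not in ("binary_presence", "numeric_threshold"):
            raise ValueError(f"unknown split kind {self.kind!r}")
        if self.kind == "numeric_threshold" and (
                self.threshold is None or not np.isfinite(self.threshold)):
            raise ValueError("numeric split needs a finite threshold")

    def goes_yes(self, value: float) -> bool:
        if self.kind == "binary_presence":
            return value >= 0.5
        return value <= self.threshold

    def describe(self, branch_yes: bool = True) -> str:
        if self.kind == "binary_presence":
            return f"{self.feature} {'present' if branch_yes else 'absent'}"
        op = "<=" if branch_yes else ">"
        return f"{self.feature} {op} {self.threshold:.6g}"


@dataclass
class PCTNode:
    node_id: int
    test: SplitTest | None = None
    yes: "PCTNode | None" = None
    no: "PCTNode | None" = None
    cluster_id: int | None = None
    members: list[str] = field(default_factory=list)
    prediction: dict[str, int] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.test is None


@dataclass
class PCTree:
    root: PCTNode
    params: PCTParams
    endpoints: list[str]
    feature_columns: list[str]
    training_digest: str = ""

    def leaves(self) -> list[PCTNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.no, node.yes])
        return sorted(out, key=lambda l: l.cluster_id)

    def leaf_memberships(self) -> dict[int, list[str]]:
        return {l.cluster_id: list(l.members) for l in self.leaves()}

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "params": {"min_leaf": self.params.min_leaf,
                       "f_test_alpha": self.params.f_test_alpha,
                       "max_depth": self.params.max_depth},
            "endpoints": self.endpoints,
            "feature_columns": self.feature_columns,
            "training_digest": self.training_digest,
            "root": _node_to_dict(self.root),
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PCTree":
        import os
        if isinstance(source, os.PathLike) or (
                isinstance(source, str) and not source.lstrip().startswith("{")):
            with open(source, encoding="utf-8") as fh:
                doc = json.load(fh)
        else:
            doc = json.loads(source)
        params = PCTParams(**doc["params"])
        return cls(root=_node_from_dict(doc["root"]), params=params,
                   endpoints=doc["endpoints"],
                   feature_columns=doc["feature_columns"],
                   training_digest=doc.get("training_digest", ""))

    def to_dot(self, path=None) -> str:
        """Graphviz DOT rendering: test labels on internal nodes, cluster
        id / size / prediction summary on leaves."""
        lines = ["digraph pct {", '  node [shape=box, fontname="Helvetica"];']
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                hot = [ep for ep, v in node.prediction.items() if v == 1]
                label = (f"cluster {node.cluster_id}\\nn={len(node.members)}"
                         f"\\nhigh: {', '.join(hot) if hot else 'none'}")
                lines.append(f'  n{node.node_id} [label="{label}", '
                             'style=filled, fillcolor=lightgrey];')
            else:
                lines.append(f'  n{node.node_id} [label="{node.test.describe()}?"];')
                lines.append(f'  n{node.node_id} -> n{node.yes.node_id} [label="yes"];')
                lines.append(f'  n{node.node_id} -> n{node.no.node_id} [label="no"];')
                stack.extend([node.no, node.yes])
        lines.append("}")
        text = "\n".join(lines)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def _node_to_dict(node: PCTNode) -> dict:
    if node.is_leaf:
        return {"node_id": node.node_id, "cluster_id": node.cluster_id,
                "members": node.members, "prediction": node.prediction}
    return {"node_id": node.node_id,
            "test": {"feature": node.test.feature, "kind": node.test.kind,
                     "threshold": node.test.threshold},
            "yes": _node_to_dict(node.yes), "no": _node_to_dict(node.no)}


def _node_from_dict(doc: dict) -> PCTNode:
    if "test" in doc:
        t = doc["test"]
        return PCTNode(node_id=doc["node_id"],
                       test=SplitTest(feature=t["feature"], kind=t["kind"],
                                      threshold=t["threshold"]),
                       yes=_node_from_dict(doc["yes"]),
                       no=_node_from_dict(doc["no"]))
    return PCTNode(node_id=doc["node_id"], cluster_id=doc["cluster_id"],
                   members=list(doc["members"]),
                   prediction={k: int(v) for k, v in doc["prediction"].items()})


# ---------------------------------------------------------------------------
# scoring primitives

def cluster_variance(target_rows) -> float:
    """Target-space variance of a set of 0/1 endpoint rows:
    ``(1/n) * sum_i ||y_i - ybar||^2``."""
    Y = np.asarray(target_rows, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] == 0:
        raise ValueError("variance of an empty set is undefined")
    return float(((Y - Y.mean(axis=0)) ** 2).sum() / Y.shape[0])


def variance_reduction(parent_rows, partition) -> float:
    """Var(parent) minus the size-weighted mean of the part variances."""
    Y = np.asarray(parent_rows, dtype=float)
    n = Y.shape[0]
    sizes = sum(len(p) for p in partition)
    if sizes != n:
        raise ValueError("partition does not cover the parent")
    if any(len(p) == 0 for p in partition):
        raise ValueError("degenerate partition with an empty side")
    pooled = sum(len(p) / n * cluster_variance(Y[list(p)]) for p in partition)
    return cluster_variance(Y) - pooled


def f_test_accept(var_parent: float, pooled_child_var: float, n: int,
                  alpha: float) -> bool:
    """Significance gate for a split.

    ``F = var_parent / pooled_child_var`` is referred to an F distribution
    with (n-1, n-2) degrees of freedom; the split is accepted iff the
    upper-tail probability is <= alpha.  A perfect split (pooled 0 with
    positive parent variance) is always accepted; a zero-variance parent
    never is.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if var_parent < 0 or pooled_child_var < 0:
        raise ValueError("variances must be nonnegative")
    if var_parent == 0:
        return False
    if pooled_child_var == 0:
        return True
    F = var_parent / pooled_child_var
    p = float(stats.f.sf(F, n - 1, n - 2))
    return p <= alpha


# ---------------------------------------------------------------------------
# induction

def _score_binary_splits(Xb: np.ndarray, Y: np.ndarray, min_leaf: int):
    """Variance reduction for every binary column at once.

    For 0/1 targets ``sum ||y||^2`` over a child equals the sum of its
    per-endpoint sums, so pooled variance needs only the column-group sums
    ``S1 = Xb.T @ Y``.  Returns (reductions, n_yes); inadmissible columns
    (a side smaller than min_leaf) get -inf.
    """
    n = Y.shape[0]
    tot = Y.sum(axis=0)
    S1 = Xb.T @ Y                       # (F, m) sums on the yes side
    n1 = Xb.sum(axis=0)
    n0 = n - n1
    S0 = tot[None, :] - S1
    sq_tot = float(tot.sum())           # sum of y^2 over everything (0/1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = (sq_tot
                  - np.where(n1 > 0, (S1 ** 2).sum(axis=1) / n1, 0.0)
                  - np.where(n0 > 0, (S0 ** 2).sum(axis=1) / n0, 0.0)) / n
    var_parent = (sq_tot - float((tot ** 2).sum()) / n) / n
    red = var_parent - pooled
    red[(n1 < min_leaf) | (n0 < min_leaf)] = -np.inf
    return red, n1


def _best_numeric_split(x: np.ndarray, Y: np.ndarray, min_leaf: int):
    """Best midpoint threshold for one numeric column via prefix sums.

    Returns (reduction, threshold) or (-inf, None).
    """
    n = Y.shape[0]
    order = np.argsort(x, kind="stable")
    xs, Ys = x[order], Y[order]
    tot = Ys.sum(axis=0)
    sq_tot = float((Ys ** 2).sum())
    var_parent = (sq_tot - float((tot ** 2).sum()) / n) / n
    csum = np.cumsum(Ys, axis=0)
    best_red, best_thr = -np.inf, None
    for i in range(n - 1):
        if xs[i] == xs[i + 1]:
            continue
        n1 = i + 1
        n0 = n - n1
        if n1 < min_leaf or n0 < min_leaf:
            continue
        S1 = csum[i]
        S0 = tot - S1
        pooled = (sq_tot - float((S1 ** 2).sum()) / n1
                  - float((S0 ** 2).sum()) / n0) / n
        red = var_parent - pooled
        thr = 0.5 * (xs[i] + xs[i + 1])
        if red > best_red:
            best_red, best_thr = red, thr
    return best_red, best_thr


def induce_tree(
    features: FeatureMatrix,
    targets,
    params: PCTParams = PCTParams(),
) -> PCTree:
    """Top-down induction of the predictive clustering tree.

    ``targets`` is a complete compounds x endpoints 0/1 DataFrame (or a
    completed :class:`~toxclust.potency.PotencyMatrix`).  At every node all
    binary-presence tests and all midpoint thresholds on numeric columns
    are enumerated; tests leaving a side below ``min_leaf`` are discarded;
    the maximal variance reduction wins (ties: lowest column index, then
    lowest threshold) and is kept only if the F-test accepts it.
    Deterministic and invariant to row order.
    """
    from toxclust.potency import PotencyMatrix

    if isinstance(targets, PotencyMatrix):
        targets = targets.calls
    if targets.isna().any().any():
        raise ValueError("targets must be complete (impute first)")

    # canonical row order for determinism under row permutation
    order = np.argsort(np.asarray(targets.index, dtype=object), kind="stable")
    targets = targets.iloc[order]
    fvals = features.values.reindex(targets.index)
    if fvals.isna().any().any():
        raise ValueError("feature rows missing for some compounds")

    bin_cols = [c for c in fvals.columns if features.metadata[c]["kind"] == "binary"]
    num_cols = [c for c in fvals.columns if features.metadata[c]["kind"] == "numeric"]
    col_order = list(fvals.columns)
    Xb = fvals[bin_cols].to_numpy(dtype=float) if bin_cols else np.zeros((len(fvals), 0))
    Xn = fvals[num_cols].to_numpy(dtype=float) if num_cols else np.zeros((len(fvals), 0))
    Y = targets.to_numpy(dtype=float)
    ids = list(targets.index)
    endpoints = list(targets.columns)

    digest = hashlib.sha256()
    digest.update(np.ascontiguousarray(Y).tobytes())
    digest.update(",".join(map(str, ids)).encode())

    counter = {"node": 0, "cluster": 0}
    if len(ids) < params.min_leaf:
        warnings.warn("fewer compounds than min_leaf; single-leaf tree")

    def make_leaf(idx: np.ndarray) -> PCTNode:
        pred = {ep: int(round(Y[idx, j].mean())) for j, ep in enumerate(endpoints)}
        node = PCTNode(node_id=counter["node"], cluster_id=counter["cluster"],
                       members=[ids[i] for i in idx], prediction=pred)
        counter["node"] += 1
        counter["cluster"] += 1
        return node

    def choose_split(idx: np.ndarray):
        """Best admissible test at a node, or None."""
        Yn = Y[idx]
        best = None  # (reduction, col_pos, threshold, test)

        def better(red, pos, thr):
            if best is None:
                return True
            b_red, b_pos, b_thr = best[0], best[1], best[2]
            if red != b_red:
                return red > b_red
            if pos != b_pos:
                return pos < b_pos
            return (thr if thr is not None else -np.inf) < \
                   (b_thr if b_thr is not None else -np.inf)

        if Xb.shape[1]:
            red, _ = _score_binary_splits(Xb[idx], Yn, params.min_leaf)
            j = int(np.argmax(red))  # first max = lowest binary column index
            if np.isfinite(red[j]) and red[j] > 0:
                col = bin_cols[j]
                best = (red[j], col_order.index(col), None,
                        SplitTest(feature=col, kind="binary_presence"))
        for k, col in enumerate(num_cols):
            red, thr = _best_numeric_split(Xn[idx, k], Yn, params.min_leaf)
            if not np.isfinite(red) or red <= 0:
                continue
            if better(red, col_order.index(col), thr):
                best = (red, col_order.index(col), thr,
                        SplitTest(feature=col, kind="numeric_threshold",
                                  threshold=thr))
        return best

    def grow(idx: np.ndarray, depth: int) -> PCTNode:
        n = idx.size
        if n < 2 * params.min_leaf:
            return make_leaf(idx)
        if params.max_depth is not None and depth >= params.max_depth:
            return make_leaf(idx)
        var_parent = cluster_variance(Y[idx])
        if var_parent == 0:
            return make_leaf(idx)
        best = choose_split(idx)
        if best is None:
            return make_leaf(idx)
        red, _, _, test = best
        pooled = var_parent - red
        if not f_test_accept(var_parent, max(pooled, 0.0), n, params.f_test_alpha):
            return make_leaf(idx)
        if test.kind == "binary_presence":
            yes_mask = Xb[idx, bin_cols.index(test.feature)] >= 0.5
        else:
            yes_mask = Xn[idx, num_cols.index(test.feature)] <= test.threshold
        node = PCTNode(node_id=counter["node"], test=test)
        counter["node"] += 1
        node.yes = grow(idx[yes_mask], depth + 1)
        node.no = grow(idx[~yes_mask], depth + 1)
        return node

    root = grow(np.arange(len(ids)), 0)
    return PCTree(root=root, params=params, endpoints=endpoints,
                  feature_columns=col_order,
                  training_digest=digest.hexdigest()[:16])


# ---------------------------------------------------------------------------
# assignment

@dataclass
class Assignment:
    cluster_id: int
    prediction: dict[str, int]
    path: list[str]


def assign(tree: PCTree, feature_row) -> Assignment:
    """Route one compound's feature row from root to leaf.

    ``feature_row`` is a mapping/Series with every column the tree tests.
    Returns the leaf's cluster id, its endpoint predictions and the
    readable decision path.
    """
    node = tree.root
    path: list[str] = []
    while not node.is_leaf:
        feat = node.test.feature
        try:
            value = feature_row[feat]
        except (KeyError, IndexError):
            raise KeyError(f"feature row lacks tested column {feat!r}")
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise KeyError(f"feature row lacks tested column {feat!r}")
        yes = node.test.goes_yes(float(value))
        path.append(node.test.describe(branch_yes=yes))
        node = node.yes if yes else node.no
    return Assignment(cluster_id=node.cluster_id,
                      prediction=dict(node.prediction), path=path)


def split_leaf_by_feature(tree: PCTree, cluster_id: int, feature: str,
                          features: FeatureMatrix, targets) -> PCTree:
    """Manual expert refinement: split one leaf on a named binary feature.

    Never applied automatically; provided for post-hoc refinement of a
    mixed cluster.  Renumbers cluster ids afterwards.
    """
    from toxclust.potency import PotencyMatrix
    if isinstance(targets, PotencyMatrix):
        targets = targets.calls
    leaf = next((l for l in tree.leaves() if l.cluster_id == cluster_id), None)
    if leaf is None:
        raise KeyError(f"no leaf with cluster id {cluster_id}")
    vals = features.values.loc[leaf.members, feature]
    yes_ids = [m for m, v in vals.items() if v >= 0.5]
    no_ids = [m for m in leaf.members if m not in set(yes_ids)]
    if not yes_ids or not no_ids:
        raise ValueError(f"feature {feature!r} does not split cluster {cluster_id}")

    def pred(ids):
        sub = targets.loc[ids]
        return {ep: int(round(sub[ep].mean())) for ep in targets.columns}

    max_node = _max_node_id(tree.root)
    leaf.test = SplitTest(feature=feature, kind="binary_presence")
    leaf.yes = PCTNode(node_id=max_node + 1, members=yes_ids, prediction=pred(yes_ids))
    leaf.no = PCTNode(node_id=max_node + 2, members=no_ids, prediction=pred(no_ids))
    leaf.members, leaf.prediction, leaf.cluster_id = [], {}, None
    _renumber_clusters(tree.root)
    return tree


def _max_node_id(node: PCTNode) -> int:
    if node.is_leaf:
        return node.node_id
    return max(node.node_id, _max_node_id(node.yes), _max_node_id(node.no))


def _renumber_clusters(root: PCTNode) -> None:
    counter = [0]

    def walk(node):
        if node.is_leaf:
            node.cluster_id = counter[0]
            counter[0] += 1
        else:
            walk(node.yes)
            walk(node.no)

    walk(root)
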