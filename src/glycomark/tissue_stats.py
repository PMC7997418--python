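"""Tissue-level statistics for H-score tables.

Paired Wilcoxon signed-rank comparisons between tissue components (with
Bonferroni adjustment), Kruskal-Wallis group comparisons, the
Jonckheere-Terpstra ordered-trend test across histologic grades (normal
approximation with tie-corrected variance, or exact permutation for small
cohorts), an ordinary least-squares linear trend fit, and a small CART-style
recursive partitioner used to discover H-score cut-offs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# ---------------------------------------------------------------------------
# paired component comparisons
# ---------------------------------------------------------------------------

def paired_component_tests(scores: pd.DataFrame, pairs: list[tuple[str, str]],
                           zero_method: str = "wilcox",
                           ) -> pd.DataFrame:
    """Wilcoxon signed-rank tests between tissue components, Bonferroni-adjusted.

    ``scores`` is a sample x component H-score table; only samples with
    both components assessed enter a pair's test.  Zero differences are
    dropped (Wilcoxon's original treatment).  The exact null distribution
    is used for n <= 25 nonzero differences without ties, the normal
    approximation with tie correction otherwise.  Adjusted p = min(1, m*p)
    with m = number of pairs.  Pairs with fewer than 2 nonzero differences
    are flagged undefined.
    """
    m = len(pairs)
    rows = []
    for a, b in pairs:
        sub = scores[[a, b]].dropna()
        d = sub[a].to_numpy(dtype=float) - sub[b].to_numpy(dtype=float)
        nz = d[d != 0]
        if nz.size < 2:
            rows.append((a, b, len(sub), int(nz.size), np.nan, np.nan, False))
            continue
        has_ties = np.unique(np.abs(nz)).size < nz.size
        method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
        res = stats.wilcoxon(d, zero_method=zero_method, method=method,
                             correction=False)
        p = float(res.pvalue)
        rows.append((a, b, len(sub), int(nz.size), p, min(1.0, m * p), True))
    return pd.DataFrame(rows, columns=["component_a", "component_b", "n_pairs",
                                       "n_nonzero", "p_value", "p_adjusted",
                                       "defined"])


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Degenerate all-identical data returns (0, 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra ordered trend test
# ---------------------------------------------------------------------------

@dataclass
class TrendTestResult:
    statistic: float
    p_value: float
    method: str                 # "normal_approx" or "permutation"
    alternative: str
    n_groups: int
    group_sizes: tuple[int, ...]
    mean_null: float = field(default=np.nan)
    sd_null: float = field(default=np.nan)


def _jt_statistic(groups: list[np.ndarray]) -> float:
    """J-T statistic: over ordered group pairs i<j, count pairs with
    x_i < x_j, ties counted one half."""
    s = 0.0
    for i, j in itertools.combinations(range(len(groups)), 2):
        a, b = groups[i][:, None], groups[j][None, :]
        s += float((a < b).sum()) + 0.5 * float((a == b).sum())
    return s


def _jt_null_moments(groups: list[np.ndarray]) -> tuple[float, float]:
    """Null mean and tie-corrected variance of the J-T statistic."""
    n_i = np.array([g.size for g in groups], dtype=float)
    N = n_i.sum()
    pooled = np.concatenate(groups)
    _, t = np.unique(pooled, return_counts=True)
    t = t.astype(float)
    mean = (N ** 2 - (n_i ** 2).sum()) / 4.0
    term1 = (N * (N - 1) * (2 * N + 5)
             - (n_i * (n_i - 1) * (2 * n_i + 5)).sum()
             - (t * (t - 1) * (2 * t + 5)).sum()) / 72.0
    term2 = ((n_i * (n_i - 1) * (n_i - 2)).sum()
             * (t * (t - 1) * (t - 2)).sum()) / (36.0 * N * (N - 1) * (N - 2))
    term3 = ((n_i * (n_i - 1)).sum() * (t * (t - 1)).sum()) / (8.0 * N * (N - 1))
    return float(mean), float(term1 + term2 + term3)


def jonckheere_terpstra(groups: list, alternative: str = "increasing",
                        method: str = "auto", exact_n_max: int = 12,
                        ) -> TrendTestResult:
    """Jonckheere-Terpstra trend test for >= 3 ordered groups.

    ``alternative`` is "increasing", "decreasing" or "two-sided" with
    respect to the stated group order.  ``method`` "normal" uses the
    tie-corrected normal approximation; "permutation" enumerates every
    assignment of the pooled observations to the group sizes; "auto" picks
    permutation when the total sample size is at most ``exact_n_max``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("Jonckheere-Terpstra needs >= 3 ordered groups; "
                         "use a rank-sum test for 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    if alternative not in ("increasing", "decreasing", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    sizes = tuple(int(g.size) for g in groups)
    N = sum(sizes)
    if method == "auto":
        method = "permutation" if N <= exact_n_max else "normal"
    S = _jt_statistic(groups)
    mean, var = _jt_null_moments(groups)

    if method == "permutation":
        p = _jt_permutation_p(groups, S, alternative)
        return TrendTestResult(statistic=S, p_value=p, method="permutation",
                               alternative=alternative, n_groups=len(groups),
                               group_sizes=sizes, mean_null=mean,
                               sd_null=float(np.sqrt(var)))
    if var <= 0:
        p = 1.0
    else:
        # continuity correction: the statistic moves in unit steps
        sd = np.sqrt(var)
        if alternative == "increasing":
            p = float(stats.norm.sf((S - mean - 0.5) / sd))
        elif alternative == "decreasing":
            p = float(stats.norm.cdf((S - mean + 0.5) / sd))
        else:
            p = float(2.0 * stats.norm.sf((max(abs(S - mean) - 0.5, 0.0)) / sd))
    return TrendTestResult(statistic=S, p_value=min(1.0, p),
                           method="normal_approx", alternative=alternative,
                           n_groups=len(groups), group_sizes=sizes,
                           mean_null=mean, sd_null=float(np.sqrt(max(var, 0.0))))


def _jt_permutation_p(groups: list[np.ndarray], observed: float,
                      alternative: str) -> float:
    """Exact permutation p-value by enumerating all assignments of the
    pooled observations into the ordered group sizes."""
    pooled = np.concatenate(groups)
    sizes = [g.size for g in groups]
    idx_all = tuple(range(pooled.size))
    tol = 1e-9

    def assignments(remaining: tuple, sizes_left: list[int]):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in set(combo))
            for tail in assignments(rest, sizes_left[1:]):
                yield [combo] + tail

    count_ge = count_le = total = 0
    for assign in assignments(idx_all, sizes):
        gs = [pooled[list(c)] for c in assign]
        s = _jt_statistic(gs)
        total += 1
        if s >= observed - tol:
            count_ge += 1
        if s <= observed + tol:
            count_le += 1
    if alternative == "increasing":
        return count_ge / total
    if alternative == "decreasing":
        return count_le / total
    return min(1.0, 2.0 * min(count_ge, count_le) / total)


# ---------------------------------------------------------------------------
# linear trend across grades
# ---------------------------------------------------------------------------

def fit_linear_trend(h_scores, grades) -> dict:
    """OLS of H-score on numeric histologic grade.

    Returns slope, intercept, r_squared and the overall-F p-value (for a
    single regressor this equals the slope's two-sided t-test p).
    """
    h = np.asarray(h_scores, dtype=float)
    g = np.asarray(grades, dtype=float)
    if h.size != g.size:
        raise ValueError("h_scores and grades must have equal length")
    if np.unique(g).size < 3:
        raise ValueError("need >= 3 distinct grade values for a trend fit")
    res = stats.linregress(g, h)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue ** 2),
        "p_value": float(res.pvalue),
        "n": int(h.size),
    }


# ---------------------------------------------------------------------------
# recursive partitioning (CART, Gini impurity)
# ---------------------------------------------------------------------------

@dataclass
class PartitionNode:
    """One node of the partition tree.  Internal nodes split on
    ``feature <= threshold`` (left) vs ``> threshold`` (right)."""

    depth: int
    n: int
    class_counts: dict
    prediction: object
    feature: object = None
    threshold: float | None = None
    left: "PartitionNode | None" = None
    right: "PartitionNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class PartitionTree:
    root: PartitionNode
    feature_names: list
    classes: list

    def predict_one(self, x: dict) -> object:
        node = self.root
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.prediction

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.array([self.predict_one(row._asdict() if hasattr(row, "_asdict")
                                          else dict(row))
                         for row in X.to_dict("records")], dtype=object)

    @property
    def depth(self) -> int:
        def d(node):
            if node.is_leaf:
                return 0
            return 1 + max(d(node.left), d(node.right))
        return d(self.root)

    def describe(self) -> str:
        lines: list[str] = []

        def walk(node, indent):
            pad = "  " * indent
            if node.is_leaf:
                lines.append(f"{pad}predict {node.prediction} "
                             f"(n={node.n}, counts={node.class_counts})")
            else:
                lines.append(f"{pad}if {node.feature} <= {node.threshold:g}:")
                walk(node.left, indent + 1)
                lines.append(f"{pad}else:  # {node.feature} > {node.threshold:g}")
                walk(node.right, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p ** 2).sum())


def best_split(X: pd.DataFrame, y: np.ndarray, min_leaf: int = 1,
               ) -> tuple[object, float, float] | None:
    """Exhaustive best (feature, threshold) split minimizing weighted Gini.

    Candidate thresholds are midpoints between consecutive distinct sorted
    feature values.  Ties break on feature order then smaller threshold.
    Returns (feature, threshold, weighted_gini) or None if no valid split.
    """
    classes, y_idx = np.unique(y, return_inverse=True)
    n = len(y)
    best = None
    for feat in X.columns:
        v = X[feat].to_numpy(dtype=float)
        distinct = np.unique(v)
        for lo, hi in zip(distinct[:-1], distinct[1:]):
            thr = (lo + hi) / 2.0
            mask = v <= thr
            nl = int(mask.sum())
            if nl < min_leaf or n - nl < min_leaf:
                continue
            cl = np.bincount(y_idx[mask], minlength=classes.size)
            cr = np.bincount(y_idx[~mask], minlength=classes.size)
            g = (nl * _gini(cl) + (n - nl) * _gini(cr)) / n
            if best is None or g < best[2] - 1e-12:
                best = (feat, thr, g)
    return best


def recursive_partition(X: pd.DataFrame, y, min_leaf: int = 1,
                        max_depth: int = 5) -> PartitionTree:
    """Greedy CART on numeric features with Gini impurity.

    Growth stops at pure nodes, ``min_leaf``, ``max_depth``, or when no
    split reduces impurity.
    """
    if len(X) == 0:
        raise ValueError("empty input")
    y = np.asarray(y)
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2 and max_depth > 0:
        # single-class input: root leaf
        pass

    def counts_of(yy):
        return {c: int((yy == c).sum()) for c in classes}

    def majority(yy):
        cts = counts_of(yy)
        return max(classes, key=lambda c: (cts[c],))

    def grow(Xn, yn, depth):
        cts = counts_of(yn)
        node = PartitionNode(depth=depth, n=len(yn), class_counts=cts,
                             prediction=majority(yn))
        if depth >= max_depth or np.unique(yn).size == 1 or len(yn) < 2 * min_leaf:
            return node
        split = best_split(Xn, yn, min_leaf=min_leaf)
        if split is None:
            return node
        feat, thr, g = split
        parent_g = _gini(np.array(list(cts.values()), dtype=float))
        if g >= parent_g - 1e-12:
            return node
        mask = Xn[feat].to_numpy(dtype=float) <= thr
        node.feature, node.threshold = feat, float(thr)
        node.left = grow(Xn[mask], yn[mask], depth + 1)
        node.right = grow(Xn[~mask], yn[~mask], depth + 1)
        return node

    root = grow(X.reset_index(drop=True), y, 0)
    return PartitionTree(root=root, feature_names=list(X.columns),
                         classes=classes)
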