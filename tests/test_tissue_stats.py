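"""Nonparametric tissue statistics and recursive partitioning."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glycomark.tissue_stats import (TrendTestResult, best_split,
                                    fit_linear_trend, jonckheere_terpstra,
                                    kruskal_wallis, paired_component_tests,
                                    recursive_partition)

# ---------------------------------------------------------------------------
# Wilcoxon signed-rank pairs
# ---------------------------------------------------------------------------

def _score_frame(a, b, names=("cancer", "vein")):
    return pd.DataFrame({names[0]: a, names[1]: b})


def test_wilcoxon_identical_vectors_flagged_undefined():
    df = _score_frame([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    out = paired_component_tests(df, [("cancer", "vein")])
    assert not out.iloc[0]["defined"]
    assert np.isnan(out.iloc[0]["p_value"])


def test_wilcoxon_bonferroni_multiplies_by_pair_count(rng):
    df = pd.DataFrame({
        "cancer": rng.normal(10, 1, 12),
        "artery": rng.normal(8, 1, 12),
        "vein": rng.normal(9, 1, 12),
    })
    pairs = [("cancer", "artery"), ("cancer", "vein"), ("artery", "vein")]
    out = paired_component_tests(df, pairs)
    for _, row in out.iterrows():
        assert row["p_adjusted"] == pytest.approx(min(1.0, 3 * row["p_value"]))


def _wilcoxon_exact_enumeration(d):
    """Exhaustive sign-flip null distribution of the signed-rank statistic;
    two-sided p as twice the smaller tail (scipy's exact convention)."""
    d = np.asarray(d, dtype=float)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    t_obs = ranks[d > 0].sum()
    n = len(d)
    stats_all = [np.sum(ranks[np.array(signs, dtype=bool)])
                 for signs in itertools.product([0, 1], repeat=n)]
    stats_all = np.array(stats_all)
    p_le = np.mean(stats_all <= t_obs)
    p_ge = np.mean(stats_all >= t_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


@pytest.mark.parametrize("seed", range(5))
def test_wilcoxon_matches_sign_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 9))
    d = rng.normal(0.3, 1.0, n)
    df = _score_frame(d, np.zeros(n))
    out = paired_component_tests(df, [("cancer", "vein")])
    assert out.iloc[0]["p_value"] == pytest.approx(
        _wilcoxon_exact_enumeration(d), abs=1e-12)


def test_wilcoxon_drops_incomplete_pairs():
    df = _score_frame([1.0, 2.0, np.nan, 5.0, 1.0, 9.0, 4.0],
                      [0.5, 1.0, 3.0, 1.0, 0.2, 2.0, 1.0])
    out = paired_component_tests(df, [("cancer", "vein")])
    assert out.iloc[0]["n_pairs"] == 6


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def test_kruskal_separated_groups_significant():
    groups = [list(range(10 * i, 10 * i + 8)) for i in range(3)]
    H, p = kruskal_wallis(groups)
    assert p < 0.001


def test_kruskal_degenerate_identical():
    assert kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]]) == (0.0, 1.0)


def test_kruskal_two_groups_equals_ranksum(rng):
    """For two groups, the Kruskal-Wallis chi-square p equals the two-sided
    normal-approximation rank-sum p (no continuity correction)."""
    from scipy import stats as ss
    a, b = rng.normal(0, 1, 9), rng.normal(0.8, 1, 7)
    _, p_kw = kruskal_wallis([a, b])
    p_rs = ss.mannwhitneyu(a, b, alternative="two-sided",
                           use_continuity=False, method="asymptotic").pvalue
    assert p_kw == pytest.approx(float(p_rs), abs=1e-10)


def test_kruskal_rejects_empty_group():
    with pytest.raises(ValueError):
        kruskal_wallis([[1.0], []])


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra
# ---------------------------------------------------------------------------

def test_jt_maximum_for_strictly_increasing_groups():
    groups = [[1, 2, 3], [10, 11, 12, 13], [20, 21]]
    res = jonckheere_terpstra(groups, method="normal")
    n = [3, 4, 2]
    s_max = n[0] * n[1] + n[0] * n[2] + n[1] * n[2]
    assert res.statistic == s_max
    assert res.p_value < 0.05


def test_jt_all_ties_gives_half_maximum():
    groups = [[7.0, 7.0], [7.0, 7.0, 7.0], [7.0, 7.0]]
    res = jonckheere_terpstra(groups, method="normal")
    s_max = 2 * 3 + 2 * 2 + 3 * 2
    assert res.statistic == s_max / 2.0


def test_jt_reversal_maps_statistic_to_complement(rng):
    groups = [rng.normal(i, 1, n) for i, n in zip((0, 1, 2), (4, 5, 3))]
    s_max = 4 * 5 + 4 * 3 + 5 * 3
    fwd = jonckheere_terpstra(groups, method="normal").statistic
    rev = jonckheere_terpstra(groups[::-1], method="normal").statistic
    assert fwd + rev == pytest.approx(s_max)


@given(st.integers(0, 1000))
def test_jt_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    groups = [rng.normal(0, 1, 4), rng.normal(0.5, 1, 4), rng.normal(1, 1, 4)]
    s1 = jonckheere_terpstra(groups, method="normal").statistic
    s2 = jonckheere_terpstra([np.exp(g) for g in groups],
                             method="normal").statistic
    assert s1 == s2


@pytest.mark.parametrize("seed", range(4))
def test_jt_permutation_close_to_normal_approximation(seed):
    rng = np.random.default_rng(seed)
    groups = [rng.normal(0.4 * i, 1, 3) for i in range(3)]
    exact = jonckheere_terpstra(groups, method="permutation")
    approx = jonckheere_terpstra(groups, method="normal")
    assert exact.method == "permutation"
    assert abs(exact.p_value - approx.p_value) <= 0.02


def test_jt_auto_picks_permutation_for_small_n(rng):
    groups = [rng.normal(0, 1, 3) for _ in range(3)]
    assert jonckheere_terpstra(groups).method == "permutation"
    big = [rng.normal(0, 1, 10) for _ in range(3)]
    assert jonckheere_terpstra(big).method == "normal_approx"


def test_jt_requires_three_groups():
    with pytest.raises(ValueError, match="rank-sum"):
        jonckheere_terpstra([[1, 2], [3, 4]])


def test_jt_decreasing_alternative_detects_downtrend():
    groups = [[20, 21, 22], [10, 11, 12], [1, 2, 3]]
    res = jonckheere_terpstra(groups, alternative="decreasing",
                              method="normal")
    assert res.p_value < 0.05


# ---------------------------------------------------------------------------
# linear trend
# ---------------------------------------------------------------------------

def test_linear_trend_perfect_line():
    grades = [1, 1, 2, 2, 3, 3]
    h = [10, 10, 20, 20, 30, 30]
    res = fit_linear_trend(h, grades)
    assert res["slope"] == pytest.approx(10.0)
    assert res["r_squared"] == pytest.approx(1.0)
    assert res["p_value"] < 1e-6


def test_linear_trend_null_p_uniformish():
    rng = np.random.default_rng(3)
    ps = []
    grades = np.repeat([1, 2, 3], [7, 14, 11])
    for _ in range(300):
        ps.append(fit_linear_trend(rng.normal(100, 30, 32), grades)["p_value"])
    assert 0.01 < np.mean(np.array(ps) < 0.05) < 0.11


def test_linear_trend_recovers_generator_slope():
    from glycomark.synthetic import HistoConfig, gen_histology_dataset
    from glycomark.histoscore import score_assessments
    cfg = HistoConfig(seed=8, grade_trend_slope={"DSA": 60.0})
    table, _ = gen_histology_dataset(cfg)
    scored = score_assessments(table)
    sub = scored[(scored["ligand"] == "DSA") & (scored["component"] == "cancer")
                 & scored["grade"].notna()]
    res = fit_linear_trend(sub["h_score"], sub["grade"].astype(float))
    assert 20.0 < res["slope"] < 100.0
    assert res["p_value"] < 0.05


def test_linear_trend_needs_three_grades():
    with pytest.raises(ValueError):
        fit_linear_trend([1, 2, 3, 4], [1, 1, 2, 2])


# ---------------------------------------------------------------------------
# recursive partitioning
# ---------------------------------------------------------------------------

def test_partition_gap_midpoint_threshold():
    X = pd.DataFrame({"c7": [20, 40, 55, 60, 75, 90, 120, 200]})
    y = np.array(["like", "like", "like", "like", "hsa", "hsa", "hsa", "hsa"])
    tree = recursive_partition(X, y, max_depth=3)
    assert tree.root.feature == "c7"
    assert tree.root.threshold == pytest.approx(67.5)
    assert tree.depth == 1  # split is pure, no further growth


def test_partition_pure_input_is_leaf():
    X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    tree = recursive_partition(X, np.array(["x", "x", "x"]))
    assert tree.root.is_leaf
    assert tree.root.prediction == "x"


def test_partition_empty_rejected():
    with pytest.raises(ValueError):
        recursive_partition(pd.DataFrame({"a": []}), np.array([]))


def _exhaustive_root(X, y):
    """Independent exhaustive search over every feature/midpoint pair."""
    best = None
    y = np.asarray(y)
    classes = np.unique(y)
    for feat in X.columns:
        v = X[feat].to_numpy(dtype=float)
        for thr in (np.unique(v)[:-1] + np.unique(v)[1:]) / 2.0:
            left, right = y[v <= thr], y[v > thr]
            g = 0.0
            for part in (left, right):
                counts = np.array([(part == c).sum() for c in classes])
                if counts.sum():
                    p = counts / counts.sum()
                    g += counts.sum() * (1 - (p ** 2).sum())
            g /= len(y)
            if best is None or g < best[2] - 1e-12:
                best = (feat, thr, g)
    return best


@pytest.mark.parametrize("seed", range(5))
def test_partition_root_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"f1": rng.normal(0, 1, 30), "f2": rng.normal(0, 1, 30)})
    y = np.where(X["f1"] + 0.5 * rng.normal(size=30) > 0, "a", "b")
    feat, thr, g = _exhaustive_root(X, y)
    got = best_split(X, y)
    assert got[0] == feat
    assert got[1] == pytest.approx(thr)
    assert got[2] == pytest.approx(g)


def test_partition_root_matches_sklearn(rng):
    """Cross-check the root split against sklearn's CART on separable data."""
    from sklearn.tree import DecisionTreeClassifier
    X = pd.DataFrame({"f1": rng.normal(0, 1, 40), "f2": rng.normal(0, 1, 40)})
    y = np.where(X["f2"] > 0.3, "a", "b")
    tree = recursive_partition(X, y, max_depth=1)
    clf = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
    assert tree.root.feature == X.columns[clf.tree_.feature[0]]
    # sklearn stores thresholds in float32 precision
    assert tree.root.threshold == pytest.approx(clf.tree_.threshold[0],
                                                abs=1e-5)


def test_partition_permuted_labels_chance_accuracy():
    rng = np.random.default_rng(12)
    X = pd.DataFrame({"f1": rng.normal(0, 1, 60), "f2": rng.normal(0, 1, 60)})
    y = np.array(["a", "b"] * 30)
    perm = rng.permutation(y)
    tree = recursive_partition(X, perm, min_leaf=5, max_depth=2)
    acc = float(np.mean(tree.predict(X) == perm))
    assert acc < 0.80  # far from separable; near-chance resubstitution


def test_partition_describe_and_predict_roundtrip():
    X = pd.DataFrame({"c7": [10.0, 20.0, 100.0, 200.0],
                      "dsa": [50.0, 60.0, 200.0, 250.0]})
    y = np.array(["like", "like", "hsa", "hsa"])
    tree = recursive_partition(X, y, max_depth=2)
    assert set(tree.predict(X)) == {"like", "hsa"}
    text = tree.describe()
    assert "if" in text and "predict" in text
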