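"""Search-result filtering, spike-in normalization, sPLS-DA and candidate
selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glycomark.discovery import (build_feature_matrix, combine_candidates,
                                 compute_normalization_factors,
                                 filter_search_results,
                                 group_binding_difference,
                                 normalize_intensities, select_candidates,
                                 splsda_fit, stability_selection)
from glycomark.synthetic import SyntheticConfig, gen_discovery_dataset

# ---------------------------------------------------------------------------
# search-result filtering
# ---------------------------------------------------------------------------

def _rows(records):
    return pd.DataFrame(records, columns=[
        "protein", "peptide", "protein_score", "peptide_score", "spi_pct",
        "missed_cleavages", "intensity"])


def test_filter_multi_vs_single_peptide_rules():
    rows = _rows([
        # multi-peptide protein: passes at the lenient thresholds
        ("A", "a1", 16.0, 7.0, 65.0, 2, 100.0),
        ("A", "a2", 16.0, 8.0, 70.0, 0, 100.0),
        # single-peptide protein with peptide score 14: removed
        ("B", "b1", 40.0, 14.0, 90.0, 0, 100.0),
        # single-peptide protein meeting the strict rule: kept
        ("C", "c1", 40.0, 16.0, 85.0, 1, 100.0),
        # single-peptide protein with 2 missed cleavages: removed
        ("D", "d1", 40.0, 20.0, 95.0, 2, 100.0),
    ])
    kept, report = filter_search_results(rows)
    assert set(kept["protein"]) == {"A", "C"}
    assert report["n_in"] == 5 and report["n_removed"] == 2
    assert report["n_single_peptide"] == 3


def test_filter_empty_table():
    kept, report = filter_search_results(_rows([]))
    assert kept.empty
    assert report == {"n_in": 0, "n_kept": 0, "n_removed": 0,
                      "n_single_peptide": 0}


# ---------------------------------------------------------------------------
# ovalbumin normalization
# ---------------------------------------------------------------------------

def _ova_table(intensities_by_sample, n_peps=4, lectin="DSA"):
    rows = []
    for sid, scale in intensities_by_sample.items():
        for j in range(n_peps):
            rows.append((sid, "g", lectin, "OVAL", f"OVAL_pep{j}",
                         scale * (j + 1) * 100.0))
        rows.append((sid, "g", lectin, "P1", "P1_pep1", scale * 500.0))
    return pd.DataFrame(rows, columns=["sample_id", "group", "lectin",
                                       "protein", "peptide", "intensity"])


def test_normalization_factor_flat_cohort_is_one():
    table = _ova_table({"s1": 1.0, "s2": 1.0, "s3": 1.0})
    fac = compute_normalization_factors(table)
    assert np.allclose(fac["factor"], 1.0)
    assert fac["valid"].all()


def test_normalization_factor_doubled_sample():
    table = _ova_table({"s1": 1.0, "s2": 1.0, "s3": 1.0, "s4": 2.0})
    fac = compute_normalization_factors(table).set_index("sample_id")
    # every ovalbumin peptide mean is (1+1+1+2)/4 = 1.25x base
    assert fac.loc["s4", "factor"] == pytest.approx(2.0 / 1.25)
    assert fac.loc["s1", "factor"] == pytest.approx(1.0 / 1.25)
    # normalization removes the 2x loading difference entirely
    norm = normalize_intensities(table, fac.reset_index())
    p1 = norm[norm["protein"] == "P1"].set_index("sample_id")["intensity"]
    assert p1["s4"] / p1["s1"] == pytest.approx(1.0)


def test_normalization_too_few_ovalbumin_peptides_flagged():
    table = _ova_table({"s1": 1.0, "s2": 1.0}, n_peps=3)
    fac = compute_normalization_factors(table)
    assert not fac["valid"].any()
    norm = normalize_intensities(table, fac)
    assert norm.empty


@given(c=st.floats(0.1, 10.0))
def test_normalization_equivariance(c):
    """Scaling one pulldown by c scales its factor by c and leaves the
    normalized table unchanged."""
    base = _ova_table({"s1": 1.0, "s2": 1.0, "s3": 1.5})
    scaled = base.copy()
    mask = scaled["sample_id"] == "s2"
    scaled.loc[mask, "intensity"] *= c
    fac0 = compute_normalization_factors(base)
    fac1 = compute_normalization_factors(scaled)
    f0 = fac0.set_index("sample_id")["factor"]
    f1 = fac1.set_index("sample_id")["factor"]
    # the cohort mean moves too; the s2 factor relative to others scales by c
    assert (f1["s2"] / f1["s1"]) == pytest.approx(c * f0["s2"] / f0["s1"],
                                                  rel=1e-9)
    # the normalized tables agree up to one global constant (the per-peptide
    # cross-sample reference mean absorbs the rescaling); the sample-to-sample
    # structure is unchanged
    n0 = normalize_intensities(base, fac0)
    n1 = normalize_intensities(scaled, fac1)
    merged = n0.merge(n1, on=["sample_id", "peptide"], suffixes=("_0", "_1"))
    ratios = merged["intensity_1"] / merged["intensity_0"]
    assert np.allclose(ratios, ratios.iloc[0])


# ---------------------------------------------------------------------------
# sparse PLS-DA
# ---------------------------------------------------------------------------

def _two_class_data(rng, n=20, p=10, sep_feature=0, sep=4.0):
    y = np.repeat(["a", "b"], n // 2)
    X = rng.normal(size=(n, p))
    X[y == "b", sep_feature] += sep
    return X, y


def test_splsda_single_separating_feature_gets_unit_weight(rng):
    X, y = _two_class_data(rng, sep=6.0)
    fit = splsda_fit(X, y, n_components=1, keep_per_component=1)
    assert fit.selected.sum() == 1
    assert fit.selected_features == [0]
    assert abs(fit.weights[0, 0]) == pytest.approx(1.0)


def test_splsda_sample_order_invariance(rng):
    X, y = _two_class_data(rng)
    fit1 = splsda_fit(X, y, n_components=2)
    perm = rng.permutation(len(y))
    fit2 = splsda_fit(X[perm], y[perm], n_components=2)
    assert np.allclose(fit1.weights, fit2.weights, atol=1e-10)


def test_splsda_zero_variance_feature_named(rng):
    X, y = _two_class_data(rng)
    X[:, 3] = 7.0
    with pytest.raises(ValueError, match="3"):
        splsda_fit(X, y)


def test_splsda_too_many_components_rejected(rng):
    X, y = _two_class_data(rng, n=6, p=3)
    with pytest.raises(ValueError, match="rank"):
        splsda_fit(X, y, n_components=5)


def test_splsda_dense_first_component_matches_pls_oracle(rng):
    """With sparsity disabled the first weight vector equals dense PLS-DA
    (sklearn PLSRegression) up to sign, |delta| < 1e-6."""
    from sklearn.cross_decomposition import PLSRegression

    for _ in range(5):
        X, y = _two_class_data(rng)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        fit = splsda_fit(X, y, n_components=1)
        pls = PLSRegression(n_components=1, scale=False).fit(
            Xs, (y == "b").astype(float))
        w_ref = pls.x_weights_[:, 0]
        w = fit.weights[:, 0]
        if np.dot(w, w_ref) < 0:
            w_ref = -w_ref
        assert np.max(np.abs(w - w_ref)) < 1e-6


# ---------------------------------------------------------------------------
# stability selection
# ---------------------------------------------------------------------------

def _stab_frame(rng, n=24, p=15, sep=4.0):
    X, y = _two_class_data(rng, n=n, p=p, sep=sep)
    return pd.DataFrame(X, index=[f"s{i}" for i in range(n)]), y


def test_stability_single_iteration_is_binary(rng):
    X, y = _stab_frame(rng)
    out = stability_selection(X, y, n_iter=1, keep=3, seed=1)
    assert set(out["stability"]).issubset({0.0, 1.0})


def test_stability_seeded_repeat_identical(rng):
    X, y = _stab_frame(rng)
    a = stability_selection(X, y, n_iter=20, keep=3, seed=5)
    b = stability_selection(X, y, n_iter=20, keep=3, seed=5)
    pd.testing.assert_frame_equal(a, b)


def test_stability_strong_feature_dominates(rng):
    X, y = _stab_frame(rng, n=30, p=30, sep=4.0)
    out = stability_selection(X, y, n_iter=100, keep=5, seed=2)
    assert out.set_index("feature").loc[0, "stability"] > 0.9
    assert out.iloc[0]["feature"] == 0  # ranked first


def test_stability_monotone_in_effect_size(rng):
    """Stability of the planted feature does not decrease over a 3-point
    effect-size grid."""
    stabs = []
    for sep in (0.0, 1.5, 4.0):
        X, y = _stab_frame(np.random.default_rng(77), n=30, p=20, sep=sep)
        out = stability_selection(X, y, n_iter=60, keep=4, seed=3)
        stabs.append(float(out.set_index("feature").loc[0, "stability"]))
    assert stabs[0] <= stabs[1] + 0.05 <= stabs[2] + 0.10
    assert stabs[2] >= stabs[0]


def test_stability_subsample_too_small(rng):
    X, y = _stab_frame(rng, n=6)
    with pytest.raises(ValueError, match="subsample"):
        stability_selection(X, y, n_iter=5, subsample_frac=0.5, keep=2)


def test_select_candidates_threshold_strict():
    df = pd.DataFrame({"feature": list("abc"), "stability": [0.9, 0.6, 0.2],
                       "max_abs_weight": [1.0, 0.5, 0.1],
                       "rank": [1, 2, 3]})
    out = select_candidates(df, top_n=100, min_stability=0.6)
    assert list(out["feature"]) == ["a"]  # 0.6 itself is excluded


# ---------------------------------------------------------------------------
# group-binding difference
# ---------------------------------------------------------------------------

def _detection(counts_a, counts_b, n=10):
    det = np.zeros((2 * n, len(counts_a)), dtype=bool)
    for j, (ca, cb) in enumerate(zip(counts_a, counts_b)):
        det[:ca, j] = True
        det[n:n + cb, j] = True
    labels = ["g1"] * n + ["g2"] * n
    return pd.DataFrame(det, index=[f"s{i}" for i in range(2 * n)]), labels


@pytest.mark.parametrize("ca,cb,flag", [
    (7, 3, True),    # 0.7 > 0.6 and 0.3 < 0.4
    (6, 3, False),   # 0.6 is not "more than 60%"
    (10, 10, False),
    (3, 7, True),    # symmetric direction
    (7, 4, False),   # 0.4 is not "less than 40%"
])
def test_group_binding_predicate(ca, cb, flag):
    det, labels = _detection([ca], [cb])
    out = group_binding_difference(det, labels)
    assert bool(out["flagged"].iloc[0]) is flag


def test_group_binding_matches_bruteforce_grid():
    """The implementation agrees with direct evaluation of the predicate on
    every 11x11 detection-count grid at n=10 per group."""
    counts = [(a, b) for a in range(11) for b in range(11)]
    det, labels = _detection([a for a, _ in counts], [b for _, b in counts])
    out = group_binding_difference(det, labels)
    expected = [((a / 10 > 0.6) and (b / 10 < 0.4))
                or ((b / 10 > 0.6) and (a / 10 < 0.4)) for a, b in counts]
    assert list(out["flagged"]) == expected


def test_group_binding_empty_group_rejected():
    det, _ = _detection([5], [5])
    with pytest.raises(ValueError):
        group_binding_difference(det, ["g1"] * len(det))


# ---------------------------------------------------------------------------
# candidate union
# ---------------------------------------------------------------------------

def test_combine_candidates_union_and_origin():
    spl = pd.DataFrame({"feature": [("DSA", "P1"), ("DSA", "P2"),
                                    ("WGA", "P3")]})
    gb = pd.DataFrame({"feature": [("DSA", "P2"), ("SNA", "P9")],
                       "flagged": [True, True]})
    out = combine_candidates(spl, gb)
    assert len(out) == 4
    origin = dict(zip(out["feature"], out["origin"]))
    assert origin[("DSA", "P2")] == "both"
    assert origin[("DSA", "P1")] == "splsda"
    assert origin[("SNA", "P9")] == "group_binding"


def test_planted_candidates_recovered_end_to_end():
    """Planted fold-change and presence/absence glycoforms all appear in
    the combined candidate list on synthetic discovery data."""
    cfg = SyntheticConfig(
        n_per_group=12, n_lectins=4, n_proteins=20, seed=42,
        lectin_names=("DSA", "WGA", "PSA", "SNA"),
        planted_up=[("P001", "DSA", 3.0), ("P002", "WGA", 2.5)],
        planted_down=[("P003", "DSA", 1 / 3.0)],
        presence_effects=[("P004", "PSA", 0.1, 0.95)],
        noise_log2_sd=0.3, missing_rate=0.05)
    table, truth = gen_discovery_dataset(cfg)
    fac = compute_normalization_factors(table)
    norm = normalize_intensities(table, fac)
    X, detected, labels = build_feature_matrix(norm)
    stab = stability_selection(X.fillna(X.mean()), labels, n_iter=60,
                               keep=8, seed=1)
    sel = select_candidates(stab, top_n=100, min_stability=0.6)
    gb = group_binding_difference(detected, labels)
    combined = combine_candidates(sel, gb)
    got = set(combined["feature"])
    planted = {("DSA", "P001"), ("WGA", "P002"), ("DSA", "P003"),
               ("PSA", "P004")}
    assert planted <= got
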