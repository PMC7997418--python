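"""Candidate glycoform selection from per-lectin pulldown intensity tables.

The discovery arm takes long-form peptide intensities (sample x lectin x
protein x peptide), filters search results on quality scores, normalizes
each pulldown by its ovalbumin spike-in, and selects candidate
(lectin, protein) glycoforms two ways:

* sparse PLS-DA with stability selection — the fraction of class-stratified
  subsample refits in which a glycoform is selected is its stability score;
  the top 100 candidates with stability > 0.6 are retained; and
* a group-binding-difference screen — glycoforms detected in more than 60%
  of one class but less than 40% of the other.

The union of both lists, keyed by (lectin, protein), is the candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ANALYSIS_DEFAULTS
from .synthetic import OVALBUMIN

# ---------------------------------------------------------------------------
# search-result filtering
# ---------------------------------------------------------------------------

def filter_search_results(rows: pd.DataFrame,
                          protein_score_min: float = 15.0,
                          peptide_score_min: float = 6.0,
                          spi_min: float = 60.0,
                          single_peptide_score_min: float = 15.0,
                          single_peptide_spi_min: float = 80.0,
                          single_peptide_max_mc: int = 1,
                          ) -> tuple[pd.DataFrame, dict]:
    """Apply search-engine quality filtering to identification rows.

    Proteins identified by several peptides pass at protein score > 15,
    peptide score > 6 and %SPI > 60; single-peptide proteins are held to the
    stricter peptide score > 15, %SPI > 80 and at most one missed cleavage.
    Multiplicity is counted per identification run (per sample x lectin when
    those columns are present).  All inequalities strict.
    """
    required = {"protein", "peptide", "protein_score", "peptide_score",
                "spi_pct", "missed_cleavages"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"search-result table missing columns: {sorted(missing)}")
    report = {"n_in": int(len(rows))}
    if rows.empty:
        report.update(n_kept=0, n_removed=0, n_single_peptide=0)
        return rows.copy(), report

    group_cols = [c for c in ("sample_id", "lectin") if c in rows.columns]
    n_pep = rows.groupby(group_cols + ["protein"])["peptide"].transform("nunique")
    multi = n_pep > 1
    keep_multi = (multi
                  & (rows["protein_score"] > protein_score_min)
                  & (rows["peptide_score"] > peptide_score_min)
                  & (rows["spi_pct"] > spi_min))
    keep_single = (~multi
                   & (rows["peptide_score"] > single_peptide_score_min)
                   & (rows["spi_pct"] > single_peptide_spi_min)
                   & (rows["missed_cleavages"] <= single_peptide_max_mc))
    kept = rows[keep_multi | keep_single].copy()
    report.update(n_kept=int(len(kept)), n_removed=int(len(rows) - len(kept)),
                  n_single_peptide=int((~multi).sum()))
    return kept, report


# ---------------------------------------------------------------------------
# ovalbumin spike-in normalization
# ---------------------------------------------------------------------------

def compute_normalization_factors(table: pd.DataFrame,
                                  ovalbumin_id: str = OVALBUMIN,
                                  min_peptides: int = 4) -> pd.DataFrame:
    """Per-pulldown normalization factors from the ovalbumin spike-in.

    For each lectin, every ovalbumin peptide intensity is divided by that
    peptide's mean over all samples of the lectin; a pulldown's factor is
    the mean of these ratios over its detected ovalbumin peptides.  A
    pulldown with fewer than ``min_peptides`` detected ovalbumin peptides
    is flagged invalid and must be excluded downstream.

    Returns a DataFrame with columns sample_id, lectin, factor,
    n_ovalbumin_peptides, valid.
    """
    ova = table[table["protein"] == ovalbumin_id]
    if ova.empty:
        raise ValueError(f"no ovalbumin ({ovalbumin_id!r}) peptides in table")
    ova = ova.copy()
    peptide_mean = ova.groupby(["lectin", "peptide"])["intensity"].transform("mean")
    ova["ratio"] = ova["intensity"] / peptide_mean
    fac = (ova.groupby(["sample_id", "lectin"])
           .agg(factor=("ratio", "mean"),
                n_ovalbumin_peptides=("peptide", "nunique"))
           .reset_index())
    # every pulldown present in the table gets a row, valid or not
    cells = table[["sample_id", "lectin"]].drop_duplicates()
    fac = cells.merge(fac, on=["sample_id", "lectin"], how="left")
    fac["n_ovalbumin_peptides"] = fac["n_ovalbumin_peptides"].fillna(0).astype(int)
    fac["valid"] = fac["n_ovalbumin_peptides"] >= min_peptides
    return fac.sort_values(["sample_id", "lectin"]).reset_index(drop=True)


def normalize_intensities(table: pd.DataFrame, factors: pd.DataFrame,
                          drop_invalid: bool = True) -> pd.DataFrame:
    """Divide every intensity of a pulldown by its normalization factor.

    Pulldowns flagged invalid are dropped (default) or left unscaled.
    """
    merged = table.merge(factors[["sample_id", "lectin", "factor", "valid"]],
                         on=["sample_id", "lectin"], how="left")
    if drop_invalid:
        merged = merged[merged["valid"].fillna(False)]
    out = merged.copy()
    out["intensity"] = out["intensity"] / out["factor"]
    return out.drop(columns=["factor", "valid"]).reset_index(drop=True)


def build_feature_matrix(table: pd.DataFrame, ovalbumin_id: str = OVALBUMIN,
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Pivot a long intensity table to sample x (lectin, protein) features.

    A glycoform's value is the mean log2 intensity over its detected
    peptides; nondetected glycoforms are NaN.  Returns
    ``(X, detected, labels)`` where ``detected`` is the boolean detection
    matrix and ``labels`` maps sample_id to group.
    """
    t = table[table["protein"] != ovalbumin_id].copy()
    t["log2_intensity"] = np.log2(t["intensity"])
    X = t.pivot_table(index="sample_id", columns=["lectin", "protein"],
                      values="log2_intensity", aggfunc="mean")
    labels = (t.drop_duplicates("sample_id").set_index("sample_id")["group"]
              .reindex(X.index))
    detected = X.notna()
    return X, detected, labels


# ---------------------------------------------------------------------------
# sparse PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class SplsdaFit:
    """Result of a sparse PLS-DA fit.

    ``weights`` are the per-component sparse x-weight vectors (unit norm),
    ``scores`` the latent sample scores, ``selected`` the per-feature
    boolean selection mask (nonzero weight in any component).
    """

    feature_names: list
    weights: np.ndarray          # p x K
    scores: np.ndarray           # n x K
    selected: np.ndarray         # p, bool
    keep_per_component: list[int] = field(default_factory=list)

    @property
    def selected_features(self) -> list:
        return [f for f, s in zip(self.feature_names, self.selected) if s]

    def max_abs_weight(self) -> np.ndarray:
        return np.abs(self.weights).max(axis=1)


def _soft_threshold_topk(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold ``w`` so exactly the top-``keep`` |w| survive."""
    if keep >= w.size:
        return w.copy()
    absw = np.abs(w)
    lam = np.sort(absw)[::-1][keep]  # largest discarded |w|
    out = np.sign(w) * np.maximum(absw - lam, 0.0)
    return out


def splsda_fit(X: np.ndarray | pd.DataFrame, y, n_components: int = 2,
               keep_per_component: int | list[int] | None = None) -> SplsdaFit:
    """Sparse PLS-DA for a two-class response.

    Features are mean-centred and scaled to unit variance; the class labels
    are one-hot coded and centred.  Each latent component's x-weight vector
    is the dominant left singular vector of the current cross-covariance
    X'Y, soft-thresholded to retain ``keep_per_component`` features and
    renormalized to unit norm; X and Y are deflated on the component score
    before the next component.  With the sparsity disabled
    (``keep_per_component=None``), the first component coincides with dense
    PLS-DA.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        feature_names = list(range(Xv.shape[1]))
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    n, p = Xv.shape
    if n != y.size:
        raise ValueError("X and y have incompatible shapes")

    sd = Xv.std(axis=0, ddof=1)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        raise ValueError(
            f"zero-variance feature(s): {[feature_names[i] for i in zero_var[:5]]}")
    Xc = (Xv - Xv.mean(axis=0)) / sd
    rank = np.linalg.matrix_rank(Xc)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")

    Y = np.column_stack([(y == c).astype(float) for c in classes])
    Yc = Y - Y.mean(axis=0)

    if keep_per_component is None:
        keeps = [p] * n_components
    elif np.isscalar(keep_per_component):
        keeps = [int(keep_per_component)] * n_components
    else:
        keeps = [int(k) for k in keep_per_component]
        if len(keeps) != n_components:
            raise ValueError("keep_per_component list must have n_components entries")
    for k in keeps:
        if not 1 <= k <= p:
            raise ValueError(f"keep_per_component must be in [1, {p}], got {k}")

    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    for k in range(n_components):
        M = Xc.T @ Yc
        u, s, vt = np.linalg.svd(M, full_matrices=False)
        w = u[:, 0]
        w = _soft_threshold_topk(w, keeps[k])
        nrm = np.linalg.norm(w)
        if nrm == 0:
            raise ValueError(f"component {k + 1}: all weights thresholded to zero")
        w = w / nrm
        # sign convention: largest-|w| entry positive (order invariance)
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        t = Xc @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError(f"component {k + 1} has zero score variance")
        p_load = Xc.T @ t / tt
        c_load = Yc.T @ t / tt
        Xc = Xc - np.outer(t, p_load)
        Yc = Yc - np.outer(t, c_load)
        W[:, k] = w
        T[:, k] = t

    selected = np.abs(W).sum(axis=1) > 0
    return SplsdaFit(feature_names=feature_names, weights=W, scores=T,
                     selected=selected, keep_per_component=keeps)


def stability_selection(X: pd.DataFrame, y, n_iter: int = 100,
                        subsample_frac: float = 0.8, keep: int = 10,
                        n_components: int = 2, seed: int = 0,
                        min_per_class: int = 3) -> pd.DataFrame:
    """Stability scores from repeated sparse PLS-DA on stratified subsamples.

    Each iteration draws ``subsample_frac`` of every class without
    replacement, refits sparse PLS-DA (features constant within the
    subsample are excluded from that refit — they carry no discriminant
    signal there), and records the selected feature set.  A feature's
    stability is the fraction of refits selecting it.

    Returns a DataFrame ranked by (stability desc, |weight| on the full fit
    desc, feature key), with columns feature, lectin, protein, stability,
    max_abs_weight, rank.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0.0 < subsample_frac <= 1.0:
        raise ValueError("subsample_frac must be in (0, 1]")
    y = pd.Series(np.asarray(y), index=X.index)
    classes = y.unique()
    if classes.size != 2:
        raise ValueError("stability selection needs exactly 2 classes")
    idx_by_class = {c: np.asarray(X.index[y == c]) for c in classes}
    take = {c: int(round(subsample_frac * len(idx_by_class[c]))) for c in classes}
    if any(t < min_per_class for t in take.values()):
        raise ValueError(
            f"subsample too small: would draw {take} per class "
            f"(need >= {min_per_class} each)")

    rng = np.random.default_rng(seed)
    counts = pd.Series(0.0, index=X.columns)
    for _ in range(n_iter):
        rows = np.concatenate([
            rng.choice(idx_by_class[c], size=take[c], replace=False)
            for c in classes])
        Xs = X.loc[rows]
        sd = Xs.std(axis=0, ddof=1)
        usable = sd[sd > 0].index
        fit = splsda_fit(Xs[usable], y.loc[rows], n_components=n_components,
                         keep_per_component=min(keep, len(usable)))
        counts.loc[[f for f in fit.selected_features]] += 1.0

    stability = counts / n_iter
    full_sd = X.std(axis=0, ddof=1)
    full_usable = full_sd[full_sd > 0].index
    full_fit = splsda_fit(X[full_usable], y, n_components=n_components,
                          keep_per_component=min(keep, len(full_usable)))
    maxw = pd.Series(0.0, index=X.columns)
    maxw.loc[list(full_usable)] = full_fit.max_abs_weight()

    out = pd.DataFrame({
        "feature": list(X.columns),
        "stability": stability.to_numpy(),
        "max_abs_weight": maxw.to_numpy(),
    })
    if isinstance(X.columns, pd.MultiIndex) and X.columns.nlevels == 2:
        out["lectin"] = [f[0] for f in out["feature"]]
        out["protein"] = [f[1] for f in out["feature"]]
    out["_key"] = out["feature"].astype(str)
    out = out.sort_values(["stability", "max_abs_weight", "_key"],
                          ascending=[False, False, True], kind="stable")
    out = out.drop(columns="_key").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def select_candidates(stability_df: pd.DataFrame, top_n: int = 100,
                      min_stability: float = 0.6) -> pd.DataFrame:
    """Export the top-``top_n`` candidates and keep those with stability
    strictly above ``min_stability``."""
    top = stability_df.nsmallest(top_n, "rank")
    return top[top["stability"] > min_stability].reset_index(drop=True)


# ---------------------------------------------------------------------------
# group-binding difference
# ---------------------------------------------------------------------------

def group_binding_difference(detected: pd.DataFrame, labels,
                             high: float = 0.6, low: float = 0.4,
                             ) -> pd.DataFrame:
    """Flag glycoforms bound in more than ``high`` of one class but less
    than ``low`` of the other (both inequalities strict, either direction).

    ``detected`` is a boolean sample x feature matrix; ``labels`` assigns
    each sample to one of exactly two groups, each non-empty.
    """
    labels = pd.Series(np.asarray(labels), index=detected.index)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    n1 = int((labels == groups[0]).sum())
    n2 = int((labels == groups[1]).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must contain at least one sample")
    f1 = detected[labels == groups[0]].mean(axis=0)
    f2 = detected[labels == groups[1]].mean(axis=0)
    flagged = ((f1 > high) & (f2 < low)) | ((f2 > high) & (f1 < low))
    out = pd.DataFrame({
        "feature": list(detected.columns),
        f"frac_detected_{groups[0]}": f1.to_numpy(),
        f"frac_detected_{groups[1]}": f2.to_numpy(),
        "flagged": flagged.to_numpy(),
    })
    if isinstance(detected.columns, pd.MultiIndex) and detected.columns.nlevels == 2:
        out["lectin"] = [f[0] for f in out["feature"]]
        out["protein"] = [f[1] for f in out["feature"]]
    return out


def combine_candidates(splsda_candidates: pd.DataFrame,
                       group_binding: pd.DataFrame) -> pd.DataFrame:
    """Union of the two candidate lists keyed by (lectin, protein).

    ``group_binding`` rows are restricted to flagged glycoforms.  Features
    present in both lists get origin ``both``.
    """
    a = {tuple(f) if not isinstance(f, str) else f
         for f in splsda_candidates["feature"]}
    gb = group_binding[group_binding["flagged"]]
    b = {tuple(f) if not isinstance(f, str) else f for f in gb["feature"]}
    rows = []
    for f in sorted(a | b, key=str):
        origin = "both" if f in a and f in b else ("splsda" if f in a
                                                  else "group_binding")
        rows.append((f, origin))
    out = pd.DataFrame(rows, columns=["feature", "origin"])
    if len(out) and isinstance(out["feature"].iloc[0], tuple):
        out["lectin"] = [f[0] for f in out["feature"]]
        out["protein"] = [f[1] for f in out["feature"]]
    return out
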