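"""Scheduled-MRM method construction, qualification QC, and volcano stats.

Method construction selects, per protein, up to five library peptides with
peptide score > 10 and %SPI >= 70, keeps only y-series products heavier
than the precursor (top five by library intensity rank), computes the
collision energy as ``CE = 0.036 * m/z - 4.8``, and schedules retention-time
windows so the instrument cycle time is shared among concurrent transitions
(dwell = cycle time / concurrency).

Qualification QC applies, in order: (i) drop peptides with cross-sample
median intensity < 500; (ii) drop peptides not detected in at least 90% of
the samples of any one group; (iii) log2-transform, compute each sample's
dilution factor (median peptide log2 intensity) and drop samples more than
1 log2 unit from the cohort median; (iv) within each protein drop peptides
correlating < 0.6 (Pearson) with the mean profile of their sibling
peptides; (v) impute nondetections as 1 (log2 = 0); (vi) subtract the
dilution factor; (vii) average peptides into protein log2 intensities with
equal weight.  Differential statistics then call each glycoform up / down /
ns at 1.5-fold and p < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ANALYSIS_DEFAULTS

# ---------------------------------------------------------------------------
# method construction
# ---------------------------------------------------------------------------

def collision_energy(precursor_mz: float, slope: float = 0.036,
                     intercept: float = -4.8) -> float:
    """Linear collision-energy ramp ``CE = slope * m/z + intercept`` (V),
    floored at 0."""
    if precursor_mz <= 0:
        raise ValueError(f"precursor_mz must be positive, got {precursor_mz}")
    return max(0.0, slope * precursor_mz + intercept)


@dataclass(frozen=True)
class MrmTransition:
    protein: str
    peptide: str
    precursor_mz: float
    product_mz: float
    collision_energy: float
    rt_start: float
    rt_end: float
    dwell_ms: float


def build_mrm_method(library: pd.DataFrame, cycle_time_s: float = 1.0,
                     max_transitions: int = 200, rt_window_min: float = 2.0,
                     peptide_score_min: float = 10.0, spi_min: float = 70.0,
                     max_peptides_per_protein: int = 5,
                     max_products_per_peptide: int = 5,
                     min_dwell_ms: float = 5.0,
                     ) -> tuple[pd.DataFrame, dict]:
    """Build a scheduled transition list from a spectral-library table.

    ``library`` has one row per candidate product ion with columns protein,
    peptide, peptide_score, spi_pct, precursor_mz, retention_time,
    ion_series, product_mz, rank_intensity.  Eligible peptides (score > 10,
    %SPI >= 70) are capped at five per protein (best scores first); only
    y-series products with product m/z above the precursor survive, the top
    five by intensity rank per peptide.  Each transition is scheduled in a
    retention-time window of width ``rt_window_min`` centred on the library
    retention time; its dwell is the cycle time divided by the maximum
    number of transitions concurrent anywhere in its window.  If the
    concurrency anywhere exceeds ``max_transitions`` (or would push dwell
    below ``min_dwell_ms``), lowest-priority transitions are dropped.

    Returns ``(transitions, summary)``.
    """
    required = {"protein", "peptide", "peptide_score", "spi_pct",
                "precursor_mz", "retention_time", "ion_series", "product_mz",
                "rank_intensity"}
    missing = required - set(library.columns)
    if missing:
        raise ValueError(f"library missing columns: {sorted(missing)}")
    if library.empty:
        raise ValueError("empty spectral library")

    lib = library[(library["peptide_score"] > peptide_score_min)
                  & (library["spi_pct"] >= spi_min)].copy()
    # cap peptides per protein, best scores first
    pep = (lib.drop_duplicates(["protein", "peptide"])
           [["protein", "peptide", "peptide_score"]]
           .sort_values(["protein", "peptide_score", "peptide"],
                        ascending=[True, False, True], kind="stable"))
    pep["pep_rank"] = pep.groupby("protein").cumcount()
    keep_peps = set(map(tuple, pep[pep["pep_rank"] < max_peptides_per_protein]
                        [["protein", "peptide"]].to_numpy()))
    mask = np.fromiter(((p, q) in keep_peps
                        for p, q in zip(lib["protein"], lib["peptide"])),
                       dtype=bool, count=len(lib))
    lib = lib[mask]
    # y ions heavier than the precursor only
    lib = lib[(lib["ion_series"] == "y")
              & (lib["product_mz"] > lib["precursor_mz"])]
    # top products per peptide by library intensity rank (1 = most intense)
    lib = lib.sort_values(["protein", "peptide", "rank_intensity"],
                          kind="stable")
    lib["prod_rank"] = lib.groupby(["protein", "peptide"]).cumcount()
    lib = lib[lib["prod_rank"] < max_products_per_peptide]
    if lib.empty:
        raise ValueError("no eligible transitions after library filtering")

    half = rt_window_min / 2.0
    trans = lib.copy().reset_index(drop=True)
    trans["rt_start"] = trans["retention_time"] - half
    trans["rt_end"] = trans["retention_time"] + half
    # priority: better peptide score first, then stronger product
    trans = trans.sort_values(["peptide_score", "rank_intensity", "protein",
                               "peptide", "product_mz"],
                              ascending=[False, True, True, True, True],
                              kind="stable").reset_index(drop=True)

    n_dropped_cap = 0
    max_conc_allowed = min(max_transitions,
                           int(math.floor(cycle_time_s * 1000.0 / min_dwell_ms)))
    while True:
        starts = trans["rt_start"].to_numpy()
        ends = trans["rt_end"].to_numpy()
        # continuous-time concurrency peaks at some window start
        conc_at = np.array([((starts <= t) & (ends >= t)).sum() for t in starts])
        if len(conc_at) == 0:
            raise ValueError("transition cap dropped every transition")
        peak = int(conc_at.max())
        if peak <= max_conc_allowed:
            break
        t_star = starts[int(conc_at.argmax())]
        active = trans.index[(starts <= t_star) & (ends >= t_star)]
        drop_idx = active[-1]  # rows sorted by priority; last = lowest
        trans = trans.drop(index=drop_idx)
        n_dropped_cap += 1
    trans = trans.reset_index(drop=True)
    conc = _max_concurrency(trans)
    trans["dwell_ms"] = cycle_time_s * 1000.0 / conc

    trans["collision_energy"] = [collision_energy(mz)
                                 for mz in trans["precursor_mz"]]
    out = trans[["protein", "peptide", "precursor_mz", "product_mz",
                 "collision_energy", "rt_start", "rt_end", "dwell_ms"]].copy()
    out = out.sort_values(["protein", "peptide", "product_mz"],
                          kind="stable").reset_index(drop=True)
    summary = {
        "n_transitions": int(len(out)),
        "n_proteins": int(out["protein"].nunique()),
        "n_peptides": int(out["peptide"].nunique()),
        "max_concurrency": int(conc.max()),
        "dwell_ms_min": float(out["dwell_ms"].min()),
        "dwell_ms_max": float(out["dwell_ms"].max()),
        "n_dropped_by_cap": int(n_dropped_cap),
    }
    return out, summary


def _max_concurrency(trans: pd.DataFrame) -> pd.Series:
    """For each transition, the max number of co-scheduled transitions at
    any retention-time point inside its window (itself included)."""
    starts = trans["rt_start"].to_numpy()
    ends = trans["rt_end"].to_numpy()
    out = np.empty(len(trans), dtype=float)
    for i in range(len(trans)):
        overlap = (starts <= ends[i]) & (ends >= starts[i])
        # concurrency peaks at some window boundary inside [start_i, end_i]
        pts = np.concatenate([starts[overlap], ends[overlap]])
        pts = pts[(pts >= starts[i]) & (pts <= ends[i])]
        best = 1
        for t in pts:
            best = max(best, int(((starts <= t) & (ends >= t)).sum()))
        out[i] = best
    return pd.Series(out, index=trans.index)


# ---------------------------------------------------------------------------
# qualification QC cascade
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Per-step bookkeeping through the QC cascade.

    ``steps`` rows carry (step, description, records_in, records_removed)
    counted in peptide features; sample removals are listed separately with
    reasons; ``dilution_factors`` maps sample_id -> median log2 intensity.
    """

    steps: list[dict] = field(default_factory=list)
    samples_removed: list[dict] = field(default_factory=list)
    dilution_factors: dict[str, float] = field(default_factory=dict)

    def add(self, step: str, description: str, records_in: int,
            records_removed: int) -> None:
        self.steps.append({"step": step, "description": description,
                           "records_in": int(records_in),
                           "records_removed": int(records_removed)})

    def check_consistent(self) -> None:
        """Raise unless records_in of step k+1 equals records_in minus
        records_removed of step k."""
        for prev, nxt in zip(self.steps, self.steps[1:]):
            expect = prev["records_in"] - prev["records_removed"]
            if nxt["records_in"] != expect:
                raise AssertionError(
                    f"report inconsistent: step {nxt['step']} starts with "
                    f"{nxt['records_in']} records, expected {expect} after "
                    f"step {prev['step']}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def qc_filter_pipeline(table: pd.DataFrame,
                       median_floor: float = 500.0,
                       detection_frac_min: float = 0.9,
                       dilution_tolerance: float = 1.0,
                       correlation_min: float = 0.6,
                       impute_value: float = 1.0,
                       ) -> tuple[pd.DataFrame, FilterReport]:
    """Seven-step qualification QC on a long-form peptide intensity table.

    ``table`` columns: sample_id, group, lectin, protein, peptide,
    intensity.  A peptide feature is the (lectin, protein, peptide) triple;
    "detected" means present in the table with intensity > 0.  Returns the
    sample x (lectin, protein) protein log2-intensity matrix and the
    step-by-step :class:`FilterReport`.
    """
    required = {"sample_id", "group", "lectin", "protein", "peptide",
                "intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    groups = table.drop_duplicates("sample_id").groupby("group").size()
    if len(groups) < 2 or (groups < 2).any():
        raise ValueError("need at least 2 groups with at least 2 samples each")

    report = FilterReport()
    t = table[table["intensity"] > 0]
    wide = t.pivot_table(index=["lectin", "protein", "peptide"],
                         columns="sample_id", values="intensity",
                         aggfunc="mean")
    sample_group = (table.drop_duplicates("sample_id")
                    .set_index("sample_id")["group"])
    wide = wide.reindex(columns=sample_group.index)

    # (i) cross-sample median (nondetections count as 0) >= floor
    n0 = len(wide)
    med = wide.fillna(0.0).median(axis=1)
    keep = med >= median_floor
    report.add("i", f"median intensity across samples < {median_floor:g}",
               n0, int((~keep).sum()))
    wide = wide[keep]

    # (ii) detected in >= detection_frac_min of the samples of any group
    n1 = len(wide)
    det_ok = pd.Series(False, index=wide.index)
    for g in sample_group.unique():
        cols = sample_group.index[sample_group == g]
        det_ok |= wide[cols].notna().mean(axis=1) >= detection_frac_min
    report.add("ii", f"not detected in >= {detection_frac_min:.0%} of any group",
               n1, int((~det_ok).sum()))
    wide = wide[det_ok]
    if wide.empty:
        raise ValueError("no peptides survive detection filtering")

    # (iii) log2; per-sample dilution factor; +/- tolerance screen
    log2w = np.log2(wide)
    dil = log2w.median(axis=0)
    cohort = float(dil.median())
    off = (dil - cohort).abs() > dilution_tolerance
    for sid in dil.index[off]:
        report.samples_removed.append({
            "sample_id": sid,
            "reason": f"dilution factor {dil[sid]:.3f} departs from cohort "
                      f"median {cohort:.3f} by more than {dilution_tolerance:g}",
        })
    report.dilution_factors = {s: float(v) for s, v in dil.items()}
    report.add("iii", f"sample dilution factor beyond +/-{dilution_tolerance:g} log2",
               len(log2w), 0)
    keep_samples = dil.index[~off]
    if len(keep_samples) == 0:
        raise ValueError(
            "dilution screen removed every sample; dilution dispersion of the "
            "cohort exceeds the tolerance")
    log2w = log2w[keep_samples]
    dil = dil[keep_samples]
    sample_group = sample_group[keep_samples]

    # (iv) within-protein peptide coherence vs mean sibling profile
    n3 = len(log2w)
    drop: list[tuple] = []
    for (lect, prot), sub in log2w.groupby(level=["lectin", "protein"]):
        if len(sub) < 2:
            continue
        for key in sub.index:
            others = sub.drop(index=key)
            ref = others.mean(axis=0)
            x = log2w.loc[key]
            mask = x.notna() & ref.notna()
            if mask.sum() < 3:
                continue  # too few shared samples to assess
            xs, rs = x[mask], ref[mask]
            if xs.std(ddof=0) == 0 or rs.std(ddof=0) == 0:
                continue  # flat profile: coherence not assessable, keep
            if float(np.corrcoef(xs, rs)[0, 1]) < correlation_min:
                drop.append(key)
    report.add("iv", f"peptide correlation with sibling mean < {correlation_min:g}",
               n3, len(drop))
    log2w = log2w.drop(index=drop)

    # (v) impute nondetections
    log2w = log2w.fillna(np.log2(impute_value))
    report.add("v", f"impute missing as {impute_value:g} "
                    f"(log2 = {np.log2(impute_value):g})", len(log2w), 0)

    # (vi) dilution-factor normalization
    log2w = log2w.sub(dil, axis=1)
    report.add("vi", "subtract per-sample dilution factor", len(log2w), 0)

    # (vii) protein roll-up, equal peptide weight
    protein = log2w.groupby(level=["lectin", "protein"]).mean().T
    report.add("vii", "protein intensity = unweighted mean of peptide log2",
               len(log2w), 0)
    protein.index.name = "sample_id"
    report.check_consistent()
    return protein, report


# ---------------------------------------------------------------------------
# differential statistics / volcano classification
# ---------------------------------------------------------------------------

def differential_stats(protein_matrix: pd.DataFrame, labels,
                       group_a: str, group_b: str, test: str = "welch",
                       fold_threshold: float = 1.5, alpha: float = 0.05,
                       ) -> pd.DataFrame:
    """Per-glycoform log2 fold-change (A minus B) and two-sample p-value.

    ``protein_matrix`` is samples x (lectin, protein) on the log2 scale.
    ``test`` is ``"welch"`` (Welch's t) or ``"mannwhitney"``.  Calls:
    up if log2FC >= log2(fold_threshold) and p < alpha; down if
    log2FC <= -log2(fold_threshold) and p < alpha; otherwise ns.
    """
    labels = pd.Series(np.asarray(labels), index=protein_matrix.index)
    a_idx = labels.index[labels == group_a]
    b_idx = labels.index[labels == group_b]
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise ValueError(f"each contrasted group needs >= 2 samples; got "
                         f"{len(a_idx)} ({group_a}) and {len(b_idx)} ({group_b})")
    if test not in ("welch", "mannwhitney"):
        raise ValueError(f"unknown test {test!r}")
    lfc_thresh = np.log2(fold_threshold)

    rows = []
    for feat in protein_matrix.columns:
        a = protein_matrix.loc[a_idx, feat].to_numpy(dtype=float)
        b = protein_matrix.loc[b_idx, feat].to_numpy(dtype=float)
        lfc = float(a.mean() - b.mean())
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and a[0] == b[0]:
            p = 1.0
        elif test == "welch":
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        if np.isnan(p):
            p = 1.0
        if lfc >= lfc_thresh and p < alpha:
            call = "up"
        elif lfc <= -lfc_thresh and p < alpha:
            call = "down"
        else:
            call = "ns"
        lect, prot = (feat if isinstance(feat, tuple) else ("", feat))
        rows.append((lect, prot, lfc, p, call))
    return pd.DataFrame(rows, columns=["lectin", "protein", "log2_fc",
                                       "p_value", "call"])
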