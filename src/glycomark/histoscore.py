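"""Semi-quantitative H-score computation and the C7/DSA diagnostic rule.

The H-score combines the intensity level of a lectin/immunohistochemical
reaction (0-3) with the proportion of cells at each level:
``H = sum(level * percent_at_level)`` over levels 1-3, giving a 0-300
scale.  Scores are binned into four overall intensity classes, control
slides are monitored by batch coefficient of variation, and the fixed
two-threshold rule classifies a sample as hemangiosarcoma (HSA) when the
complement C7 H-score exceeds 67.5 and then the DSA lectin H-score exceeds
145; otherwise HSA-like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LEVELS = (0, 1, 2, 3)
H_MAX = 300.0

#: Default four-class bin upper edges: 0 -> none, (0,100] mild,
#: (100,200] moderate, (200,300] high.
DEFAULT_CLASS_BINS: tuple[float, float, float] = (100.0, 200.0, 300.0)
CLASS_NAMES = ("none", "mild", "moderate", "high")


def h_score(pct_at_level, *, atol: float = 0.01) -> float:
    """H-score from a level -> percent-of-cells mapping.

    ``pct_at_level`` maps levels 0-3 to percentages; entries may be omitted
    (treated as 0).  Percentages must be nonnegative and sum to 100 within
    ``atol``.  Returns ``sum(level * pct)`` over levels 1-3, in [0, 300].
    """
    pct = {int(k): float(v) for k, v in dict(pct_at_level).items()}
    unknown = set(pct) - set(LEVELS)
    if unknown:
        raise ValueError(f"unknown intensity levels: {sorted(unknown)}")
    if any(v < 0 for v in pct.values()):
        raise ValueError("percentages must be nonnegative")
    total = sum(pct.values())
    if abs(total - 100.0) > atol:
        raise ValueError(f"percentages sum to {total:g}, expected 100")
    return float(sum(level * pct.get(level, 0.0) for level in (1, 2, 3)))


def overall_class(h: float, bins: tuple[float, float, float] = DEFAULT_CLASS_BINS,
                  ) -> str:
    """Four-class overall intensity: 0 -> none; then mild / moderate / high
    on (0, b1], (b1, b2], (b2, 300]."""
    if not 0.0 <= h <= H_MAX:
        raise ValueError(f"H-score must be in [0, {H_MAX:g}], got {h}")
    if not (0 < bins[0] < bins[1] < bins[2] == H_MAX):
        raise ValueError(f"class bins must satisfy 0 < b1 < b2 < b3 = {H_MAX:g}")
    if h == 0:
        return CLASS_NAMES[0]
    for name, edge in zip(CLASS_NAMES[1:], bins):
        if h <= edge:
            return name
    raise AssertionError("unreachable")


def batch_cv(scores) -> float:
    """Batch coefficient of variation (%) of a control-slide H-score series:
    100 * sample SD / mean.  Requires >= 2 batches and a positive mean."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size < 2:
        raise ValueError("batch CV needs at least 2 batches")
    mean = scores.mean()
    if mean <= 0:
        raise ValueError("batch CV undefined for non-positive mean")
    return float(100.0 * scores.std(ddof=1) / mean)


@dataclass(frozen=True)
class ControlSeries:
    """Control-slide H-scores for one ligand across experimental batches."""
    ligand: str
    scores: tuple[float, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores))

    @property
    def sd(self) -> float:
        return float(np.std(self.scores, ddof=1))

    @property
    def cv_pct(self) -> float:
        return batch_cv(self.scores)


def classify_c7_dsa(h_c7: float, h_dsa: float, c7_cutoff: float = 67.5,
                    dsa_cutoff: float = 145.0) -> str:
    """Nested two-threshold diagnostic rule.

    If the C7 H-score exceeds ``c7_cutoff`` (strictly) and then the DSA
    H-score exceeds ``dsa_cutoff`` (strictly), the sample is called HSA;
    any other outcome is HSA-like.
    """
    for name, h in (("C7", h_c7), ("DSA", h_dsa)):
        if not 0.0 <= h <= H_MAX:
            raise ValueError(f"{name} H-score must be in [0, {H_MAX:g}], got {h}")
    if h_c7 > c7_cutoff and h_dsa > dsa_cutoff:
        return "HSA"
    return "HSA-like"


def classify_c7_dsa_path(h_c7: float, h_dsa: float, c7_cutoff: float = 67.5,
                         dsa_cutoff: float = 145.0) -> tuple[str, str]:
    """Classification plus the rule path taken (for audit tables)."""
    label = classify_c7_dsa(h_c7, h_dsa, c7_cutoff, dsa_cutoff)
    if h_c7 <= c7_cutoff:
        path = f"C7<= {c7_cutoff:g}"
    elif h_dsa <= dsa_cutoff:
        path = f"C7>{c7_cutoff:g}; DSA<={dsa_cutoff:g}"
    else:
        path = f"C7>{c7_cutoff:g}; DSA>{dsa_cutoff:g}"
    return label, path


# ---------------------------------------------------------------------------
# tabular surface
# ---------------------------------------------------------------------------

PCT_COLS = ["pct_level0", "pct_level1", "pct_level2", "pct_level3"]


def score_assessments(table: pd.DataFrame,
                      bins: tuple[float, float, float] = DEFAULT_CLASS_BINS,
                      ) -> pd.DataFrame:
    """Add ``h_score`` and ``overall_class`` columns to an assessment table.

    ``table`` holds one row per sample x ligand x component with the four
    percent columns ``pct_level0`` .. ``pct_level3``.
    """
    missing = set(PCT_COLS) - set(table.columns)
    if missing:
        raise ValueError(f"assessment table missing columns: {sorted(missing)}")
    out = table.copy()
    scores = []
    for row in out[PCT_COLS].itertuples(index=False):
        scores.append(h_score(dict(zip(LEVELS, row))))
    out["h_score"] = scores
    out["overall_class"] = [overall_class(h, bins) for h in out["h_score"]]
    return out


def classify_samples(scored: pd.DataFrame, component: str = "cancer",
                     c7_ligand: str = "C7", dsa_ligand: str = "DSA",
                     c7_cutoff: float = 67.5, dsa_cutoff: float = 145.0,
                     ) -> pd.DataFrame:
    """Apply the C7 -> DSA rule per sample using one tissue component.

    ``scored`` is the output of :func:`score_assessments`.  Returns one row
    per sample with both H-scores, the call, and the rule path.
    """
    sub = scored[scored["component"] == component]
    wide = sub.pivot_table(index="sample_id", columns="ligand",
                           values="h_score", aggfunc="mean")
    for lig in (c7_ligand, dsa_ligand):
        if lig not in wide.columns:
            raise ValueError(f"no {lig} assessments for component {component!r}")
    rows = []
    for sid, r in wide.iterrows():
        label, path = classify_c7_dsa_path(r[c7_ligand], r[dsa_ligand],
                                           c7_cutoff, dsa_cutoff)
        rows.append((sid, float(r[c7_ligand]), float(r[dsa_ligand]), label, path))
    return pd.DataFrame(rows, columns=["sample_id", "h_c7", "h_dsa",
                                       "call", "rule_path"])
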