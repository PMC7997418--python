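"""Pipeline configuration and the analysis thresholds used throughout.

Every numeric default below is a working constant of the published analysis
workflow this package implements (candidate-selection stability cut-off,
group-binding fractions, MRM QC thresholds, volcano thresholds, and the
C7/DSA H-score diagnostic cut-offs).  They are collected in one place so a
run is fully described by a single serializable :class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Frozen table of the analysis constants (used by tests and documentation).
ANALYSIS_DEFAULTS: dict[str, float | int] = {
    # discovery: search-result filtering
    "protein_score_min": 15.0,
    "peptide_score_min": 6.0,
    "spi_min": 60.0,
    "single_peptide_score_min": 15.0,
    "single_peptide_spi_min": 80.0,
    "single_peptide_max_missed_cleavages": 1,
    # discovery: spike-in normalization
    "min_ovalbumin_peptides": 4,
    # discovery: candidate selection
    "stability_min": 0.6,
    "top_n_candidates": 100,
    "binding_high_frac": 0.6,
    "binding_low_frac": 0.4,
    # database merge
    "min_sequence_length": 30,
    "identity_high": 97.5,
    "identity_low": 95.0,
    "evalue_high": 1e-180,
    "evalue_low": 1e-150,
    "coverage_high": 0.95,
    "merge_min_score": 3,
    # MRM method construction
    "library_peptide_score_min": 10.0,
    "library_spi_min": 70.0,
    "max_peptides_per_protein": 5,
    "max_products_per_peptide": 5,
    "max_transitions": 200,
    "ce_slope": 0.036,
    "ce_intercept": -4.8,
    "cycle_time_s": 1.0,
    "min_dwell_ms": 5.0,
    # MRM qualification QC cascade
    "median_intensity_floor": 500.0,
    "detection_frac_min": 0.9,
    "dilution_tolerance_log2": 1.0,
    "peptide_correlation_min": 0.6,
    "impute_value": 1.0,
    # differential statistics / volcano
    "fold_change_threshold": 1.5,
    "alpha": 0.05,
    # tissue diagnostic rule
    "c7_cutoff": 67.5,
    "dsa_cutoff": 145.0,
    "h_score_max": 300.0,
}

#: Database source priority for duplicate resolution (highest first).
SOURCE_PRIORITY: tuple[str, ...] = (
    "SwissProt",
    "Ensembl",
    "NCBI",
    "TrEMBL",
    "GENESCAN",
)


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run.

    Attributes mirror :data:`ANALYSIS_DEFAULTS`, plus the run seed and the
    input/output locations used by the command-line stages.
    """

    seed: int = 0
    outdir: str = "glycomark_out"
    inputs: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=lambda: dict(ANALYSIS_DEFAULTS))

    def __post_init__(self) -> None:
        unknown = set(self.thresholds) - set(ANALYSIS_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        merged = dict(ANALYSIS_DEFAULTS)
        merged.update(self.thresholds)
        self.thresholds = merged
        self._validate()

    def _validate(self) -> None:
        t = self.thresholds
        for key in ("stability_min", "binding_high_frac", "binding_low_frac",
                    "detection_frac_min", "alpha"):
            if not 0.0 <= t[key] <= 1.0:
                raise ValueError(f"{key} must be in [0, 1], got {t[key]}")
        if not 0.0 <= t["c7_cutoff"] <= t["h_score_max"]:
            raise ValueError("c7_cutoff outside the H-score range")
        if not 0.0 <= t["dsa_cutoff"] <= t["h_score_max"]:
            raise ValueError("dsa_cutoff outside the H-score range")
        if t["fold_change_threshold"] <= 0:
            raise ValueError("fold_change_threshold must be positive")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        return cls.from_dict(json.loads(s))
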