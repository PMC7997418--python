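import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_qc_table() -> pd.DataFrame:
    """Hand-constructed 8-peptide / 3-protein / 6-sample QC cascade input.

    Designed so each cascade step removes exactly one known record:
    ``plow`` fails the median-500 floor, ``prare`` the 90% detection rule,
    sample s6 (a 4x over-loaded injection) the dilution screen, and ``p1u``
    (whose profile anti-tracks its siblings) the peptide-coherence filter.
    All intensities are powers of two so every log2 quantity is exact.
    """
    s6x = 4.0
    peptides = {
        # protein, peptide, per-sample base intensity (s1..s5); s6 = 4x pattern
        ("P1", "p1a"): [1024, 2048, 1024, 2048, 1024, 2048 * s6x],
        ("P1", "p1b"): [2048, 4096, 2048, 4096, 2048, 4096 * s6x],
        ("P1", "p1u"): [2048, 1024, 2048, 2048, 1024, 2048 * s6x],
        ("P2", "p2a"): [1024, 1024, 1024, 1024, 1024, 1024 * s6x],
        ("P2", "p2b"): [4096, 4096, 4096, 4096, 4096, 4096 * s6x],
        ("P3", "p3a"): [512, 512, 512, 512, 512, 512 * s6x],
        ("P2", "plow"): [256, 128, 256, 128, 256, 256 * s6x],
        ("P3", "prare"): [1024, 1024, None, 1024, 1024, None],
    }
    samples = [f"s{i}" for i in range(1, 7)]
    groups = dict(zip(samples, ["A", "A", "A", "B", "B", "B"]))
    rows = []
    for (prot, pep), values in peptides.items():
        for sid, v in zip(samples, values):
            if v is None:
                continue
            rows.append((sid, groups[sid], "DSA", prot, pep, float(v)))
    return pd.DataFrame(rows, columns=["sample_id", "group", "lectin",
                                       "protein", "peptide", "intensity"])


@pytest.fixture(scope="session")
def toy_qc_expected() -> dict:
    """Hand-executed expectations for :func:`toy_qc_table` (all arithmetic
    done on paper: log2 of powers of two, medians of 6 values, Pearson r
    of +/-0.5-step profiles)."""
    return {
        "removed_per_step": {"i": 1, "ii": 1, "iii": 0, "iv": 1, "v": 0,
                             "vi": 0, "vii": 0},
        "records_in_first": 8,
        "samples_removed": ["s6"],
        "dilution_factors": {"s1": 10.5, "s2": 10.5, "s3": 10.5,
                             "s4": 11.0, "s5": 10.0, "s6": 13.0},
        "protein_matrix": pd.DataFrame(
            {
                ("DSA", "P1"): [0.0, 1.0, 0.0, 0.5, 0.5],
                ("DSA", "P2"): [0.5, 0.5, 0.5, 0.0, 1.0],
                ("DSA", "P3"): [-1.5, -1.5, -1.5, -2.0, -1.0],
            },
            index=pd.Index(["s1", "s2", "s3", "s4", "s5"], name="sample_id"),
        ),
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
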