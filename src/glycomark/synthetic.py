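"""Seeded generators for every table the pipeline consumes.

The generators emulate the structure of a lectin magnetic bead array (LeMBA)
glycoproteomics study of canine hemangiosarcoma (HSA):

* discovery-phase per-lectin peptide-intensity tables (normal vs HSA serum,
  with chicken-ovalbumin spike-in peptides in every pulldown),
* three-group MRM qualification intensity tables (normal / HSA / HSA-like),
* spectral-library candidate tables for scheduled-MRM method construction,
* cross-database sequence metadata plus reciprocal-best-hit tabular output,
* tissue lectin/immunohistochemistry assessments as intensity-level
  proportion vectors (the raw inputs of H-score computation).

Intensities follow a log-normal model: normal on the log2 scale with
multiplicative group effects, per-sample (or per-pulldown) dilution offsets,
and residual noise.  Nondetection is missing-at-random at a baseline rate
plus configurable group-specific presence/absence patterns.  Every generator
is deterministic under a fixed seed and returns a truth record listing the
planted signal so downstream recovery can be audited.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OVALBUMIN = "OVAL"

#: The 20 discovery-phase lectins of the LeMBA panel.
LECTIN_PANEL: tuple[str, ...] = (
    "AAL", "BPL", "ConA", "DSA", "ECA", "EPHA", "GNL", "HAA", "HPA", "JAC",
    "LPHA", "MAA", "NPL", "PSA", "SBA", "SNA", "STL", "UEA", "WFA", "WGA",
)

#: The seven shortlisted lectins carried into the MRM validation phase.
MRM_LECTINS: tuple[str, ...] = ("AAL", "DSA", "LPHA", "NPL", "PSA", "SNA", "WGA")

TISSUE_COMPONENTS: tuple[str, ...] = (
    "cancer", "arterial_endothelium", "venous_endothelium",
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Configuration of the serum intensity-table generators.

    Planted effects are ``(protein, lectin, fold_change)`` triples applied
    multiplicatively to the disease group; presence effects are
    ``(protein, lectin, detect_frac_group1, detect_frac_group2)``.
    """

    n_per_group: int = 10
    n_lectins: int = 4
    n_proteins: int = 30
    peptides_per_protein: int = 3
    n_ovalbumin_peptides: int = 5
    planted_up: list[tuple[str, str, float]] = field(default_factory=list)
    planted_down: list[tuple[str, str, float]] = field(default_factory=list)
    presence_effects: list[tuple[str, str, float, float]] = field(default_factory=list)
    dilution_log2_sd: float = 0.25
    biological_log2_sd: float = 0.5
    noise_log2_sd: float = 0.5
    missing_rate: float = 0.1
    base_log2_mean: float = 14.0
    base_log2_sd: float = 1.5
    group_sizes: tuple[int, int, int] | None = None
    lectin_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_per_group", "n_lectins", "n_proteins",
                     "peptides_per_protein", "n_ovalbumin_peptides"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.n_ovalbumin_peptides < 4:
            raise ValueError(
                "n_ovalbumin_peptides must be >= 4 (spike-in normalization "
                f"requires at least 4 peptides), got {self.n_ovalbumin_peptides}")
        if self.lectin_names is not None:
            if len(self.lectin_names) != self.n_lectins:
                raise ValueError("lectin_names must have n_lectins entries")
        elif self.n_lectins > len(LECTIN_PANEL):
            raise ValueError(f"n_lectins must be <= {len(LECTIN_PANEL)}")
        for label, planted in (("planted_up", self.planted_up),
                               ("planted_down", self.planted_down)):
            for prot, lect, fold in planted:
                if fold <= 0:
                    raise ValueError(f"{label}: fold-change must be > 0, got "
                                     f"{fold} for ({prot}, {lect})")
        for prot, lect, f1, f2 in self.presence_effects:
            if not (0.0 <= f1 <= 1.0 and 0.0 <= f2 <= 1.0):
                raise ValueError("presence_effects: detection fractions must be "
                                 f"in [0, 1], got ({f1}, {f2}) for ({prot}, {lect})")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"missing_rate must be in [0, 1], got {self.missing_rate}")
        for name in ("dilution_log2_sd", "biological_log2_sd", "noise_log2_sd",
                     "base_log2_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.group_sizes is not None:
            if len(self.group_sizes) != 3 or any(
                    (not isinstance(n, (int, np.integer))) or n < 0
                    for n in self.group_sizes):
                raise ValueError("group_sizes must be three non-negative integers")
            if self.group_sizes[0] <= 0 or self.group_sizes[1] <= 0:
                raise ValueError("group_sizes: normal and HSA groups must be non-empty")

    @property
    def lectins(self) -> list[str]:
        if self.lectin_names is not None:
            return list(self.lectin_names)
        return list(LECTIN_PANEL[: self.n_lectins])

    @property
    def proteins(self) -> list[str]:
        return [f"P{i:03d}" for i in range(1, self.n_proteins + 1)]


@dataclass
class HistoConfig:
    """Configuration of the tissue lectin/immunohistochemistry generator.

    ``cancer_loc``/``cancer_scale`` give, per ligand and disease class, the
    H-score location and scale of the cancer component; endothelium
    components are drawn from class-independent locations (normal vascular
    endothelium is unaffected by the presence of the tumor).
    ``grade_trend_slope`` shifts the cancer-component H-score by that many
    units per histologic grade step (grades 1-3, centred at 2) per ligand.
    """

    n_hsa: int = 32
    n_hsa_like: int = 6
    ligands: tuple[str, ...] = ("C7", "DSA")
    components: tuple[str, ...] = TISSUE_COMPONENTS
    cancer_loc: dict = field(default_factory=lambda: {
        ("C7", "HSA"): 210.0, ("C7", "HSA-like"): 40.0,
        ("DSA", "HSA"): 235.0, ("DSA", "HSA-like"): 60.0,
    })
    cancer_scale: dict = field(default_factory=lambda: {
        ("C7", "HSA"): 35.0, ("C7", "HSA-like"): 22.0,
        ("DSA", "HSA"): 30.0, ("DSA", "HSA-like"): 25.0,
    })
    endo_loc: dict = field(default_factory=lambda: {
        ("C7", "arterial_endothelium"): 90.0,
        ("C7", "venous_endothelium"): 150.0,
        ("DSA", "arterial_endothelium"): 80.0,
        ("DSA", "venous_endothelium"): 200.0,
    })
    endo_scale: float = 40.0
    grade_counts: tuple[int, int, int] = (7, 14, 11)
    grade_trend_slope: dict | float = 0.0
    growth_patterns: tuple[str, ...] = ("typical", "solid", "cavernous", "mixed")
    growth_weights: tuple[float, ...] = (10.0, 7.0, 2.0, 13.0)
    dirichlet_concentration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hsa <= 0 or self.n_hsa_like <= 0:
            raise ValueError("n_hsa and n_hsa_like must be positive")
        if sum(self.grade_counts) != self.n_hsa:
            raise ValueError(
                f"grade_counts {self.grade_counts} must sum to n_hsa={self.n_hsa}")
        for lig in self.ligands:
            for cls in ("HSA", "HSA-like"):
                if (lig, cls) not in self.cancer_loc:
                    raise ValueError(f"cancer_loc missing entry for ({lig}, {cls})")
                if (lig, cls) not in self.cancer_scale:
                    raise ValueError(f"cancer_scale missing entry for ({lig}, {cls})")
        if len(self.growth_weights) != len(self.growth_patterns):
            raise ValueError("growth_weights must match growth_patterns")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")

    def slope_for(self, ligand: str) -> float:
        if isinstance(self.grade_trend_slope, dict):
            return float(self.grade_trend_slope.get(ligand, 0.0))
        return float(self.grade_trend_slope)


# ---------------------------------------------------------------------------
# serum intensity tables
# ---------------------------------------------------------------------------

def _planted_map(cfg: SyntheticConfig) -> dict[tuple[str, str], float]:
    """Map (protein, lectin) -> log2 fold-change applied to the HSA group."""
    out: dict[tuple[str, str], float] = {}
    for prot, lect, fold in cfg.planted_up:
        out[(prot, lect)] = np.log2(fold)
    for prot, lect, fold in cfg.planted_down:
        key = (prot, lect)
        lfc = np.log2(fold)
        # planted_down entries may be stated as the fold > 1 to divide by
        out[key] = -abs(lfc) if fold > 1 else lfc
    return out


def _intensity_table(cfg: SyntheticConfig, groups: list[str],
                     group_sizes: list[int], *,
                     dilution_per_lectin: bool) -> tuple[pd.DataFrame, dict]:
    rng = np.random.default_rng(cfg.seed)
    lectins, proteins = cfg.lectins, cfg.proteins
    planted = _planted_map(cfg)
    presence = {(p, l): (f1, f2) for p, l, f1, f2 in cfg.presence_effects}

    samples, sample_group = [], {}
    for g, n in zip(groups, group_sizes):
        for i in range(1, n + 1):
            sid = f"{g}_{i:03d}"
            samples.append(sid)
            sample_group[sid] = g

    peptides = {p: [f"{p}_pep{j}" for j in range(1, cfg.peptides_per_protein + 1)]
                for p in proteins}
    ova_peps = [f"{OVALBUMIN}_pep{j}" for j in range(1, cfg.n_ovalbumin_peptides + 1)]

    # per (lectin, protein, peptide) base abundance on the log2 scale
    base: dict[tuple[str, str], float] = {}
    for lect in lectins:
        for prot in proteins:
            for pep in peptides[prot]:
                base[(lect, pep)] = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd)
        for pep in ova_peps:
            base[(lect, pep)] = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd)

    if dilution_per_lectin:
        dilution = {(s, l): rng.normal(0.0, cfg.dilution_log2_sd)
                    for s in samples for l in lectins}
    else:
        per_sample = {s: rng.normal(0.0, cfg.dilution_log2_sd) for s in samples}
        dilution = {(s, l): per_sample[s] for s in samples for l in lectins}

    rows = []
    for sid in samples:
        grp = sample_group[sid]
        diseased = grp == "HSA"
        for lect in lectins:
            d = dilution[(sid, lect)]
            for prot in proteins:
                f1f2 = presence.get((prot, lect))
                if f1f2 is not None:
                    frac = f1f2[1] if diseased else f1f2[0]
                    if rng.random() >= frac:
                        continue  # the whole glycoform is absent in this run
                effect = planted.get((prot, lect), 0.0) if diseased else 0.0
                # biological glycoform abundance of this serum sample,
                # shared by all peptides of the (lectin, protein) pair
                bio = rng.normal(0.0, cfg.biological_log2_sd)
                for pep in peptides[prot]:
                    if cfg.missing_rate and rng.random() < cfg.missing_rate:
                        continue
                    log2_i = (base[(lect, pep)] + effect + bio + d
                              + rng.normal(0.0, cfg.noise_log2_sd))
                    rows.append((sid, grp, lect, prot, pep, float(2.0 ** log2_i)))
            # ovalbumin spike-in: present in every sample x lectin
            for pep in ova_peps:
                log2_i = (base[(lect, pep)] + d
                          + rng.normal(0.0, cfg.noise_log2_sd))
                rows.append((sid, grp, lect, OVALBUMIN, pep, float(2.0 ** log2_i)))

    table = pd.DataFrame(rows, columns=[
        "sample_id", "group", "lectin", "protein", "peptide", "intensity"])
    truth = {
        "groups": {g: n for g, n in zip(groups, group_sizes)},
        "planted_up": [[p, l, f] for p, l, f in cfg.planted_up],
        "planted_down": [[p, l, f] for p, l, f in cfg.planted_down],
        "presence_effects": [[p, l, f1, f2]
                             for p, l, f1, f2 in cfg.presence_effects],
        "dilution_log2": {f"{s}|{l}": dilution[(s, l)]
                          for s in samples for l in lectins},
        "ovalbumin_peptides": ova_peps,
    }
    return table, truth


def gen_discovery_dataset(cfg: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Two-group (normal vs HSA) per-lectin pulldown intensity table.

    Dilution offsets are drawn per sample x lectin (each pulldown is a
    separate bead assay), which is exactly the variation the ovalbumin
    spike-in normalization is designed to remove.
    """
    return _intensity_table(cfg, ["normal", "HSA"],
                            [cfg.n_per_group, cfg.n_per_group],
                            dilution_per_lectin=True)


def gen_mrm_dataset(cfg: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Three-group (normal / HSA / HSA-like) MRM qualification table.

    Dilution offsets are drawn once per serum sample and shared across
    lectins, matching the per-sample dilution-factor normalization of the
    qualification QC cascade.  Planted fold-changes apply to the HSA group.
    """
    sizes = cfg.group_sizes if cfg.group_sizes is not None else (
        cfg.n_per_group, cfg.n_per_group, cfg.n_per_group)
    groups = ["normal", "HSA", "HSA-like"]
    use = [(g, n) for g, n in zip(groups, sizes) if n > 0]
    return _intensity_table(cfg, [g for g, _ in use], [n for _, n in use],
                            dilution_per_lectin=False)


def default_mrm_config(seed: int = 0) -> SyntheticConfig:
    """Study-condition defaults for the qualification arm.

    Group sizes 30 normal / 55 HSA / 33 HSA-like; a 58-protein candidate
    panel across the seven shortlisted lectins; residual (technical) noise
    0.3 log2 per peptide on top of a 0.35 log2 between-sample biological
    spread shared by sibling peptides; six up- and six down-regulated
    glycoforms planted at 2-3.5-fold (validated candidates sit clear of
    the 1.5-fold screen, not on it).  Scheduled MRM of pre-qualified
    peptides is treated as complete (missing_rate 0); presence-type
    absence remains configurable.
    """
    up_folds = [2.0, 2.2, 2.5, 2.8, 3.0, 3.5]
    down_folds = [2.0, 2.2, 2.5, 2.8, 3.0, 3.5]
    lectins = MRM_LECTINS
    planted_up = [(f"P{i:03d}", lectins[i % 7], f)
                  for i, f in zip(range(1, 7), up_folds)]
    planted_down = [(f"P{i:03d}", lectins[i % 7], 1.0 / f)
                    for i, f in zip(range(7, 13), down_folds)]
    return SyntheticConfig(
        n_per_group=30,
        n_lectins=7,
        n_proteins=58,
        peptides_per_protein=3,
        n_ovalbumin_peptides=5,
        planted_up=planted_up,
        planted_down=planted_down,
        dilution_log2_sd=0.25,
        biological_log2_sd=0.35,
        noise_log2_sd=0.3,
        missing_rate=0.0,
        group_sizes=(30, 55, 33),
        lectin_names=MRM_LECTINS,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# spectral library (MRM method-construction input)
# ---------------------------------------------------------------------------

def gen_spectral_library(cfg: SyntheticConfig, *, peptides_per_protein: int = 8,
                         products_per_peptide: int = 8) -> pd.DataFrame:
    """Spectral-library candidate table: one row per candidate transition.

    Columns: protein, peptide, peptide_score, spi_pct, precursor_mz,
    retention_time, ion_series, product_mz, rank_intensity.  Peptide scores
    and %SPI straddle the method-construction eligibility thresholds, ion
    series mix y/b, and product m/z fall on both sides of the precursor so
    every selection rule is exercised.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    for prot in cfg.proteins:
        for j in range(1, peptides_per_protein + 1):
            pep = f"{prot}_lib{j}"
            score = float(rng.uniform(4.0, 25.0))
            spi = float(rng.uniform(50.0, 100.0))
            prec = float(rng.uniform(400.0, 1000.0))
            rt = float(rng.uniform(4.0, 24.0))
            order = rng.permutation(products_per_peptide) + 1
            for k in range(products_per_peptide):
                series = "y" if rng.random() < 0.7 else "b"
                prod = float(prec * rng.uniform(0.5, 1.8))
                rows.append((prot, pep, score, spi, prec, rt, series, prod,
                             int(order[k])))
    return pd.DataFrame(rows, columns=[
        "protein", "peptide", "peptide_score", "spi_pct", "precursor_mz",
        "retention_time", "ion_series", "product_mz", "rank_intensity"])


# ---------------------------------------------------------------------------
# tissue assessments
# ---------------------------------------------------------------------------

def _proportions_for_hscore(rng: np.random.Generator, target_h: float,
                            concentration: float) -> np.ndarray:
    """Percent-at-level vector (levels 0..3) with H-score near ``target_h``.

    The level distribution is a Dirichlet jitter around Binomial(3, q)
    weights with q = target_h / 300, so the expected H-score equals the
    target while individual assessments spread over adjacent levels the way
    a manual reading does.  Degenerate targets (0 or 300) are exact.
    """
    q = min(max(target_h / 300.0, 0.0), 1.0)
    weights = np.array([(1 - q) ** 3,
                        3 * q * (1 - q) ** 2,
                        3 * q ** 2 * (1 - q),
                        q ** 3])
    alive = weights > 0
    if alive.sum() == 1:
        p = np.zeros(4)
        p[np.argmax(weights)] = 1.0
    else:
        p = np.zeros(4)
        p[alive] = rng.dirichlet(concentration * weights[alive])
    return p * 100.0


def gen_histology_dataset(cfg: HistoConfig) -> tuple[pd.DataFrame, dict]:
    """Tissue assessment table: intensity-level proportions per record.

    One row per sample x ligand x component with percent-of-cells columns
    ``pct_level0`` .. ``pct_level3`` (summing to 100), the disease class,
    and for HSA samples a histologic grade (1-3) and growth pattern.
    """
    rng = np.random.default_rng(cfg.seed)
    grades = np.repeat([1, 2, 3], cfg.grade_counts)
    rng.shuffle(grades)
    gw = np.asarray(cfg.growth_weights, dtype=float)
    patterns = rng.choice(cfg.growth_patterns, size=cfg.n_hsa, p=gw / gw.sum())

    records = []
    meta = []
    for i in range(cfg.n_hsa):
        meta.append((f"HSA_{i + 1:03d}", "HSA", int(grades[i]), str(patterns[i])))
    for i in range(cfg.n_hsa_like):
        meta.append((f"HSAlike_{i + 1:03d}", "HSA-like", None, None))

    for sid, cls, grade, pattern in meta:
        for lig in cfg.ligands:
            for comp in cfg.components:
                if comp == "cancer":
                    loc = cfg.cancer_loc[(lig, cls)]
                    scale = cfg.cancer_scale[(lig, cls)]
                    if cls == "HSA" and grade is not None:
                        loc = loc + cfg.slope_for(lig) * (grade - 2)
                else:
                    loc = cfg.endo_loc.get((lig, comp), 100.0)
                    scale = cfg.endo_scale
                target = float(np.clip(rng.normal(loc, scale), 0.0, 300.0)) \
                    if scale > 0 else float(np.clip(loc, 0.0, 300.0))
                p = _proportions_for_hscore(rng, target, cfg.dirichlet_concentration)
                records.append((sid, cls, grade, pattern, lig, comp,
                                *[float(x) for x in p]))

    table = pd.DataFrame(records, columns=[
        "sample_id", "disease_class", "grade", "growth_pattern", "ligand",
        "component", "pct_level0", "pct_level1", "pct_level2", "pct_level3"])
    truth = {
        "n_hsa": cfg.n_hsa,
        "n_hsa_like": cfg.n_hsa_like,
        "grade_counts": list(cfg.grade_counts),
        "cancer_loc": {f"{l}|{c}": v for (l, c), v in cfg.cancer_loc.items()},
        "grade_trend_slope": (cfg.grade_trend_slope
                              if not isinstance(cfg.grade_trend_slope, dict)
                              else dict(cfg.grade_trend_slope)),
    }
    return table, truth


# ---------------------------------------------------------------------------
# database-merge fixture
# ---------------------------------------------------------------------------

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def gen_blast_fixture(n_entries: int, overlap_frac: float = 0.3, seed: int = 0,
                      *, n_short: int = 0,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Sequence metadata plus reciprocal-best-hit tabular output.

    Returns ``(entries, hits, truth)``.  ``entries`` has columns accession,
    source, length, sequence.  A fraction ``overlap_frac`` of entries get a
    twin deposited under a different source database, linked by a strong
    RBH hit (high identity, tiny e-value, high coverage); background hits
    between unrelated entries are weak.  ``n_short`` entries are generated
    shorter than 30 residues and flagged in the truth record.  Length ties
    between twins are planted for half of the duplicate pairs so the
    source-priority tie-break is exercised.
    """
    if n_entries <= 0:
        raise ValueError("n_entries must be positive")
    if not 0.0 <= overlap_frac <= 1.0:
        raise ValueError("overlap_frac must be in [0, 1]")
    if n_short > n_entries:
        raise ValueError("n_short cannot exceed n_entries")
    rng = np.random.default_rng(seed)
    sources = ["SwissProt", "Ensembl", "NCBI", "TrEMBL", "GENESCAN"]

    entries, hits = [], []
    truth_dups, truth_short = [], []
    n_dup = int(round(n_entries * overlap_frac))
    for i in range(n_entries):
        acc = f"ACC{i:04d}"
        if i < n_short:
            length = int(rng.integers(10, 30))
            truth_short.append(acc)
        else:
            length = int(rng.integers(60, 600))
        src = sources[int(rng.integers(0, len(sources)))]
        seq = "".join(rng.choice(_AA, size=length))
        entries.append((acc, src, length, seq))
        if i < n_dup:
            # deposit a twin under a different source
            twin_src = sources[(sources.index(src) + 1 +
                                int(rng.integers(0, len(sources) - 1)))
                               % len(sources)]
            tie = i % 2 == 0
            twin_len = length if tie else max(10, length + int(rng.integers(-20, 21)))
            twin_acc = f"ACC{i:04d}D"
            twin_seq = seq if tie else "".join(rng.choice(_AA, size=twin_len))
            entries.append((twin_acc, twin_src, twin_len, twin_seq))
            truth_dups.append([acc, twin_acc])
            hits.append((acc, twin_acc, float(rng.uniform(98.0, 100.0)),
                         float(10.0 ** rng.uniform(-250.0, -190.0)),
                         float(rng.uniform(0.96, 1.0))))

    # weak background hits between unrelated entries
    accs = [e[0] for e in entries]
    n_bg = min(len(accs), 2 * n_entries)
    for _ in range(n_bg):
        a, b = rng.choice(len(accs), size=2, replace=False)
        hits.append((accs[a], accs[b], float(rng.uniform(30.0, 90.0)),
                     float(10.0 ** rng.uniform(-40.0, -1.0)),
                     float(rng.uniform(0.1, 0.8))))

    entries_df = pd.DataFrame(entries, columns=["accession", "source", "length",
                                                "sequence"])
    hits_df = pd.DataFrame(hits, columns=["query", "subject", "identity_pct",
                                          "evalue", "coverage"])
    truth = {"duplicate_pairs": truth_dups, "short_entries": truth_short,
             "n_entries": n_entries, "overlap_frac": overlap_frac}
    return entries_df, hits_df, truth


# ---------------------------------------------------------------------------
# search-result fixture (discovery filtering input)
# ---------------------------------------------------------------------------

def attach_search_scores(table: pd.DataFrame, seed: int = 0,
                         *, frac_failing: float = 0.15) -> pd.DataFrame:
    """Decorate an intensity table with search-engine quality columns.

    Adds protein_score, peptide_score, spi_pct and missed_cleavages so the
    search-result filter has realistic pass/fail structure: a fraction
    ``frac_failing`` of peptides receive sub-threshold scores.
    """
    rng = np.random.default_rng(seed + 17)
    peptides = sorted(table["peptide"].unique())
    fail = {p: rng.random() < frac_failing for p in peptides}
    pep_score = {p: (rng.uniform(1.0, 6.0) if fail[p]
                     else rng.uniform(8.0, 25.0)) for p in peptides}
    spi = {p: (rng.uniform(20.0, 60.0) if fail[p]
               else rng.uniform(65.0, 100.0)) for p in peptides}
    mc = {p: int(rng.integers(0, 3)) for p in peptides}
    out = table.copy()
    out["peptide_score"] = out["peptide"].map(pep_score)
    out["spi_pct"] = out["peptide"].map(spi)
    out["missed_cleavages"] = out["peptide"].map(mc)
    prot_score = {pr: rng.uniform(16.0, 60.0) for pr in table["protein"].unique()}
    out["protein_score"] = out["protein"].map(prot_score)
    return out
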