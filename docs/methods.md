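# Methods

This note documents the models, defaults, and numerical choices behind
`glycomark`, and what the synthetic cohorts do and do not demonstrate.

## Synthetic data model

Serum intensity tables follow a log-normal model. On the log₂ scale, the
intensity of peptide *p* of glycoform (lectin ℓ, protein g) in sample *s*
is

    log2 I = b(ℓ,g,p) + β(ℓ,g)·1[s ∈ HSA] + u(s,ℓ,g) + d(s or s,ℓ) + ε

where *b* is a per-peptide base abundance (N(14, 1.5²) by default),
β = log₂ of the planted fold-change, *u* ~ N(0, `biological_log2_sd`²) is
the sample's biological glycoform abundance **shared by sibling peptides**,
*d* ~ N(0, `dilution_log2_sd`²) is a dilution/loading offset, and ε is
residual technical noise (`noise_log2_sd`). Nondetection is
missing-at-random at `missing_rate`, plus configurable group-specific
presence/absence patterns applied at the glycoform level. Ovalbumin
spike-in peptides are present in every pulldown, carry the dilution offset,
and have no group effect — exactly the structure that spike-in
normalization is designed to exploit.

The biological component matters: without it, sibling peptides correlate
only through the shared dilution offset (Pearson r ≈ 0.4 under the default
dispersions) and the QC cascade's coherence filter would discard nearly all
peptides. Serum protein abundances genuinely vary several-fold between
subjects; the shared component is what the correlation filter detects.

Dilution offsets are drawn per pulldown (sample × lectin) in the discovery
arm, where normalization is per pulldown, and once per serum sample in the
MRM arm, where the QC cascade computes one dilution factor per sample.

**Qualification-arm defaults** (`default_mrm_config`): 30 normal / 55 HSA /
33 HSA-like samples; 58 proteins × 7 lectins × 3 peptides; biological
spread 0.35 log₂, dilution 0.25 log₂, residual noise 0.3 log₂;
`missing_rate = 0` (scheduled MRM of pre-qualified peptides is essentially
complete; absence in such data is presence-type, which remains available
through `presence_effects`). Six up- and six down-regulated glycoforms are
planted at 2.0–3.5-fold. All planted effects clear the 1.5-fold calling
threshold by a margin: an effect planted exactly at the threshold would be
called in only half of replicates by construction, which describes the
estimator, not the pipeline. At these settings the protein-level SD is
≈ 0.42 log₂, so 2-fold is near the smallest effect a 30/55 design
validates reliably — consistent with a screen that reports candidates well
beyond its fold cut-off.

Tissue assessments are generated as intensity-level proportion vectors,
not as final H-scores, so the scoring operation itself is exercised. A
target H-score is drawn per (ligand, class) from a normal location/scale
model; the level distribution is a Dirichlet jitter around Binomial(3, q)
weights with q = H/300, giving the target in expectation while individual
readings spread over adjacent levels like manual scoring does. Defaults
place the cancer-component C7 scores at 210 ± 35 (HSA) vs 40 ± 22
(HSA-like) and DSA at 235 ± 30 vs 60 ± 25: both markers separate the
classes across the fixed 67.5 / 145 cut-offs, and a minority of HSA-like
samples exceed the C7 gate, so distinguishing the classes genuinely
requires both markers — the structure under which a two-threshold rule is
discoverable by recursive partitioning. Endothelium components use
class-independent locations (venous > arterial for DSA and C7), reflecting
that normal vascular endothelium is unaffected by the tumor's presence.

### What the generators do not emulate

No mass spectra, chromatograms, retention-time drift, or images; no
peptide-specific ionization interference; missingness is not
intensity-dependent (no left-censoring); H-score readings have no
inter-observer component. Passing recovery tests therefore shows the
pipeline is correct and well-calibrated under its stated model, not that
the thresholds are optimal for any particular instrument or pathologist.

## Database merge

Reciprocal-best-hit pairs are scored +2/+1 for identity > 97.5/> 95%,
+2/+1 for e-value < 1E-180/< 1E-150, +1 for coverage > 0.95 (all strict;
boundary values score the lower tier), giving 0–5. Pairs at or above a
configurable cut-off (default 3 — the workflow this implements does not
state the value used, so it is prominent in the configuration) are
clustered by transitive closure; the representative is the longest
sequence, then the strongest linking score, then the source priority
SwissProt > Ensembl > NCBI > TrEMBL > GENESCAN, then the accession string.
Hits naming unknown accessions are ignored, which makes the merge
idempotent; representative selection is invariant to input order.

## Discovery

Search-result filtering: multi-peptide proteins at protein score > 15,
peptide score > 6, %SPI > 60; single-peptide proteins at peptide score
> 15, %SPI > 80, ≤ 1 missed cleavage. Peptide multiplicity is counted per
identification run.

Normalization factors are per pulldown; a pulldown with < 4 detected
ovalbumin peptides is flagged invalid and excluded. Because the per-peptide
reference is the cross-sample mean, rescaling one pulldown rescales the
reference too: factors are equivariant in ratio and normalized tables in
relative structure (tests assert exactly this form).

Sparse PLS-DA uses mean-centred, unit-variance features and a centred
one-hot response; per component, the weight vector is the dominant left
singular vector of XᵀY, soft-thresholded so the top-k absolute weights
survive, unit-normalized with a deterministic sign convention, followed by
regression deflation of X and Y. With sparsity disabled the first
component coincides with dense PLS-DA (asserted against an independent
dense implementation at 1e-6).

Stability selection: 100 iterations of 80% class-stratified subsampling by
default (the resampling protocol is not fully specified in the published
workflow; these are common choices and fully configurable). Features that
are constant within a subsample are excluded from that refit — they carry
no discriminant information there and would otherwise abort the fit. Tie
order in the ranked export is stability desc, |weight| on the full-data
fit desc, then the feature key. "Detected" for the group-binding screen
means present with positive intensity after search-result filtering,
before model-fitting imputation (nondetections are imputed with the
feature mean for the standardized sPLS-DA fit only).

## MRM

The dwell of each transition is the cycle time divided by the maximum
number of transitions co-scheduled anywhere in its retention-time window;
summing dwells at any instant therefore never exceeds the cycle time. The
200-transition cap is enforced as a concurrency cap per scheduled window
(a method can monitor more transitions in total than it runs
concurrently); when exceeded — or when dwell would drop below the
configurable 5 ms floor — the lowest-priority transitions (worst peptide
score, weakest product rank) at the busiest instant are dropped, with the
count logged.

QC cascade order is fixed and load-bearing; a test asserts the dilution
screen precedes imputation, since imputing first would drag sparse
samples' medians to 0 and misclassify them as dilution outliers. Details:

* Step (i) computes the cross-sample median with nondetections as 0, so a
  peptide seen brightly in a few samples cannot pass on those alone.
* The dilution screen as literally printed ("Log2 > 1 or Log2 < 1") would
  remove every sample; it is implemented as |median log₂ − cohort median|
  > 1, the only reading consistent with calling the quantity a dilution
  factor.
* Step (iv) correlates each peptide against the leave-one-out mean profile
  of its sibling peptides (pairwise-complete samples; at least 3 shared).
  Removal is one-pass and simultaneous. Singletons, and peptides whose
  reference profile has zero variance, cannot be assessed and are kept.
* The default two-sample test is Welch's t on protein log₂ intensities
  (the source workflow names no test); Mann–Whitney is available by flag.
  No multiple-testing correction is applied by default, matching the raw
  p < 0.05 calling rule; Benjamini–Hochberg can be layered on externally.

## Tissue statistics

Wilcoxon signed-rank drops zero differences (Wilcoxon's original
treatment), uses the exact distribution for ≤ 25 nonzero differences
without ties and the tie-corrected normal approximation otherwise;
Bonferroni adjustment multiplies by the number of component pairs. The
Jonckheere–Terpstra statistic counts concordant cross-group pairs with
ties as ½; p-values come from the tie-corrected normal approximation with
a 0.5 continuity correction (the statistic moves in unit steps), or from
full enumeration of all group assignments when the total n ≤ 12. Grade is
treated as numeric 1/2/3 in the OLS trend fit, whose overall-F p equals
the slope t-test p for a single regressor.

Recursive partitioning is plain CART: greedy binary splits minimizing
weighted Gini impurity over midpoints between consecutive distinct feature
values, stopping at pure nodes, `min_leaf`, or `max_depth`. Ties break on
feature order then smaller threshold. Cost-complexity pruning is omitted —
depth and leaf-size caps suffice at the scale of two markers and a few
dozen samples. The fixed C7 → DSA rule is a nested tree (C7 gate first);
for classification this is identical to the conjunctive reading since both
cut-offs must be exceeded.

The four-class overall-intensity bins default to 0 / (0,100] / (100,200] /
(200,300] — the exact published bin boundaries are not available in the
text this implements, so symmetric defaults are used and exposed in the
configuration.

## Problem sizes in the shipped checks

The test suite exercises the qualification recovery claim at the full
30/55(/33) design over 20 seeds, null calibration of the trend tests with
2000 replicates at the grade design (7, 14, 11), and exact-oracle
comparisons at enumeration-friendly sizes (sign enumeration n ≤ 8,
permutation n ≤ 12, 30-record partition instances). The whole suite runs
in about 1.5 minutes on one CPU.

## Known limitations

* The published candidate counts (82 sPLS-DA, 64 group-binding) and tissue
  p-values are not reproduction targets: the underlying cohorts are not
  deposited, and those quantities depend on them.
* The stability-score definition follows the common selection-frequency
  interpretation; the original in-house tool's exact resampling scheme is
  not public.
* The dilution screen, detection definition, and correlation reference are
  disambiguated choices (documented above) where the source description is
  ambiguous; each is configurable.
* `merge_databases` resolves conflicting clusters deterministically but
  does not attempt sequence-level verification of duplicates.
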