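# Methods

This note documents the models implemented in `photoxl`, the defaults and
why, what the synthetic generators do and do not emulate, and the numerical
conventions. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Crosslinking kinetics (ET₅₀)

**Model.** Photo-crosslinked yield of a protein after irradiation time *t*
is treated as a saturating first-order process, y(t) = plateau·(1 − e^(−kt)).
The reported statistic is not a nonlinear fit of k but the field's
operational estimator: replicate intensities are averaged per time point
(arithmetic mean of finite values), the averaged series is divided by its
maximum, and points with t ≤ t_max — t_max being the earliest time achieving
the maximal relative intensity among positive times — are fitted by OLS of
relative intensity on ln t. Then **ET₅₀ = ln 2 / slope** (seconds). "log" is
the natural log throughout; any common base cancels only if the time
transform and the formula use the same base, and ln is the declared choice.

**Background handling.** The unirradiated (t = 0) sample cannot enter an
ln t fit and is used exclusively to remove crosslink-independent background:
proteins with relative intensity strictly greater than 0.5 at t = 0 are
dropped (missing at t = 0 counts as 0; exactly 0.5 is kept). Before
normalization, samples are median-centered so the glycoprotein reference
medians agree across samples; the common target is the geometric mean of the
per-sample reference medians (symmetric in sample order, scale-preserving).
An empty reference list falls back to all-protein centering with a warning.

**Fit conventions.** Minimum 3 points for a fit (a 2-point fit is an exact
line with no error estimate); earliest time on t_max ties includes the
fewest post-plateau points; slope ≤ 0 and too-few-points are reported as
status codes, never as fabricated ET₅₀ values. Replicates are averaged
before normalization and fitting — one curve per protein per source.

**Identifiability ceiling (known limitation).** For saturating curves the
shape of y as a function of ln t is independent of k (the rise always spans
the same ln-width, merely shifted by −ln k). After max-normalization, the
fitted log-time slope therefore discriminates rates only through the
position of the empirical maximum, and the estimated ET₅₀ varies by well
under one second across two decades of true k on a {1..64} s log grid. The
estimator is exactly monotone in 1/k for noiseless curves in the mid-rise
regime (k ∈ 10^[−2, −1.3] s⁻¹; the suite's monotonicity property test), but
with 20% CV noise and 3 replicates, replicate noise relocates the empirical
maximum across near-equal plateau points and the rank correlation between
estimated ET₅₀ and 1/k saturates around 0.6–0.7 (≈0.83–0.88 at 10% CV) —
the rate-recovery acceptance test documents this ceiling by asserting the
stricter 0.8 and failing honestly. Users wanting true rate constants from
time courses should fit the saturating model directly (nonlinear fitting is
deliberately out of scope for the reported statistic).

**Group comparisons.** Each annotation group's ET₅₀ values are compared to
the full set of recovered proteins (group members included — the inclusive
reading of "all") by a two-sided Wilcoxon rank-sum (Mann–Whitney) test with
Bonferroni–Holm step-down adjustment across groups; per-group mean and sd
are reported. Groups with fewer than 2 defined ET₅₀s are skipped with a
warning.

## Preprocessing

* **Identification filters** apply in the fixed order reverse → contaminant
  → peptides → precursors → spectral counts, so removal reports are
  deterministic. Contaminant/reverse detection is a prefix test (`CON_`,
  `REV_`) on any accession of the group, plus the MaxQuant marker columns.
  Thresholds: minimum peptides, minimum quantified precursors (distinct
  precursor ids with ≥ 1 non-missing run value in the pr_matrix), and
  minimum of the per-protein maximum spectral count across runs. A threshold
  active without its evidence column is a configuration error, not a silent
  pass.
* **Zero is missing.** Both supported dialects emit 0/blank for absence;
  readers convert to NaN because log transforms and imputation need an
  explicit missing state. The matrix writer emits 0 for missing, making
  write → read bit-identical (numeric cells are parsed with a correctly
  rounded float conversion).
* **Imputation** is per sample on natural-log intensities: missing entries
  are drawn from Normal(μ − downshift·σ, (width·σ)²) with μ, σ (ddof = 1)
  from the sample's observed log values; defaults width 0.3, downshift 1.8.
  Observed values are never touched; draws are reproducible from the seed.
  A sample with fewer than 2 observed values is an error (σ undefined).
* **iBAQ conversion** divides intensities by the count of theoretically
  observable tryptic peptides — cleavage after K/R except before P, zero
  missed cleavages, observable length 7–30 inclusive (a declared convention,
  echoed in output metadata) — then rescales each sample to sum to 1.
  Proteins with no observable peptide are excluded with a warning.
* **Pseudocount** default is the smallest nonzero intensity of the matrix;
  it makes enrichment ratios of proteins absent in a reference sample
  finite and is used for display/enrichment, not for testing.

## Differential testing

**NB Wald route** (count-like iBAQ data). Intensities are scaled so the
matrix median of positive entries is ≥ 10 and rounded to integers; size
factors come from the median-of-ratios against the per-protein geometric
mean (this normalization assumes most proteins are unchanged between
groups — a global fold change would be absorbed). Per-protein dispersion is
the moment estimate (s² − μ̄)/μ̄² on normalized counts (pooled within-group
variance), floored at 1e−8 and shrunk with weight 0.5 toward a fitted trend
α(μ) = a₀ + a₁/μ — a deliberate simplification of the reference tool's
Cox–Reid/empirical-Bayes machinery; fold changes are reported unshrunk. The
two-group log-link NB fit is solved exactly by a vectorised Newton iteration
on the group log-means (the groups decouple in the saturated design); the
Wald z uses the Fisher information Σ μ/(1 + αμ). Measured over 20
independent 2000-protein null simulations (μ = 100, dispersion 0.05, 3 vs
3), the empirical type-I error at α = 0.05 is 0.065 ± 0.005 — slightly
anticonservative, as expected for a Wald z with 6 samples. Acceptance
checks average 5 such simulations so the Monte-Carlo error is small
relative to the tolerance band.

**Mean reference.** "Testing against the mean" appends a pseudo-condition
whose replicate j is the across-condition arithmetic mean of each
condition's replicate j (replicate-index pairing — the simplest reading,
recorded in output metadata; missing values count as 0, so pseudocount
first). Requires equal replicate counts.

**Moderated t route** (log-scale data, e.g. cytosolic RNA interactomes).
Ordinary pooled-variance t ingredients per protein; the empirical-Bayes
prior (d₀, s₀²) is fitted by matching the mean and variance of log s² using
the digamma/trigamma identities of the scaled-F model, with the trigamma
inverse obtained by bracketed root finding; the moderated variance is
(d₀s₀² + d·s²)/(d₀ + d) on d₀ + d degrees of freedom. d₀ = 0 reduces to the
ordinary t (tested against scipy); d₀ = ∞ (no excess spread in log s²)
uses the prior scale with a normal reference.

**Multiplicity.** Benjamini–Hochberg step-up for proteome-wide tests; Holm
step-down where a small family of group comparisons is tested. Both clip to
1 and enforce monotonicity; Holm dominates BH elementwise (property-tested).

**Batches.** Differential contrasts are restricted to samples of one
processing batch (each batch carries its own control); a cross-batch
contrast is an error, enforced in the orchestration layer.

## Photoconversion kinetics

A single first-order rate per photoprobe: remaining fraction after dose D
(intensity × time, J/cm²) is e^(−kD), so conversion depends on dose only
(reciprocity), time-to-target scales inversely with intensity, and the
fold-acceleration between two sources at a fixed conversion target equals
their intensity ratio. Rates are fitted by OLS of ln(remaining) on dose with
R² reported. Hardware intensities are inputs, never constants in code.

## Structure validation

Cα–Cα Euclidean distances on author residue numbering (insertion codes
rejected; first altLoc kept; an optional per-chain integer offset bridges
sequence-vs-author numbering). For homomultimers the chain assignment
defaults to the minimal distance over all chain combinations (the standard
convention for indistinguishable chains); a fixed mode trusts chain hints.
"Below the limit" is implemented as distance ≤ limit with an epsilon guard,
and records exactly at the limit are flagged, because the strictness of the
printed convention is not decidable from text. Summaries report the
satisfied fraction over *mapped* (displayable) pairs only.

## Synthetic data

The time-course generator emulates: saturating first-order yield with
per-protein rate k (log-uniform 10^−2.5..10^−1 s⁻¹, the mid-rise regime for
the default {0, 1, 2, 4, 8, 16, 32, 64} s grid) and plateau (0.5–1.0);
protein abundance scales log-uniform over 1e4–1e8 (4 decades of dynamic
range — recovery must not depend on abundance); a crosslink-independent,
glycoprotein-flagged constant background; multiplicative log-normal noise
with CV 0.2 (3 replicates); and logistic left-censoring with midpoint
ln 300 ≈ a detection limit at the bottom of the abundance range (~16%
overall missingness, DIA-like), which is what justifies the down-shifted
imputation model. It does **not** emulate: post-optimum photodamage decline,
match-between-runs artifacts, peptide-level quantification, batch effects,
or interference — so passing recovery tests bound what the estimator can do
under clean conditions and say nothing about search-engine artifacts.

The two-pulse generator mixes each protein's two states with the pulse-
duration weights (default 1:5): observed = (w₁·state1 + w₂·state2)/(w₁+w₂),
recruited proteins having state2 = fold·state1 and released state1/fold in
the delayed condition. A recruited protein with fold 4 therefore shows an
observed fold of (1 + 5·4)/6 = 3.5 — the closed form the differential tests
are checked against.

Structure fixtures are random 3.8 Å-step Cα walks, optionally duplicated
into translated chains, emitted as PDB text (coordinates pre-rounded to the
format's 3 decimals so parsing is exact) together with the true distance
table.

All generators are bit-reproducible from their config seed, and every
generated protein appears exactly once in the truth table.

## Numerical and interface conventions

* Sample metadata uniqueness is keyed on (condition, irradiation time,
  replicate) — a time course measures the same condition/replicate at many
  times. Irradiation time 0 iff source "none".
* Raw intensity matrices are non-negative (enforced by the readers);
  log-scale matrices (moderated-t input) are ordinary QuantMatrix values.
* Results TSVs print floats with 17 significant digits; reading uses
  correctly rounded parsing, so seeded pipelines round-trip bit-identically.
* Provenance: every orchestrated run carries a SHA-256 config hash, the
  seed, and a parameter echo sufficient to re-run bit-identically, plus a
  JSON-lines stage log.
* Acceptance problem sizes (1000-protein time course; 5 × 2000-protein null
  count simulations; 200 two-pulse simulations of 60 proteins; 10⁵ imputed
  values) are chosen so Monte-Carlo error is small relative to each
  tolerance while the whole script completes in seconds.
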