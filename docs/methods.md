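# Methods

This note documents the quantification model, the numerical choices, the
synthetic-data generator and its defaults, and what the validation suite
does and does not demonstrate.

## Study design and data model

The design is a paired comparison: `n` animals (default 6, analyzed as two
batches of three on separate days), each contributing a lesioned and an
intact hemisphere, each split into an extrasynaptic (S2) and a synaptic (S3)
fraction — 24 spectral-count samples.  Animals qualify only if striatal
tyrosine-hydroxylase immunoreactivity on the lesioned side is reduced by
strictly more than 90 % (summed over cytosolic and membrane blots by
default; a per-fraction mode is available), a gate that validates lesion
efficiency before any quantification.

## Spectral-count interactome

Let `c[p, s]` be spectral counts of protein `p` in sample `s`.

1. **Total-count filter.** Keep proteins with `sum_s c[p, s] >= 48`, an
   average of 2 spectra per sample over the 24-sample design (use
   `2 * n_samples` for other designs).  The bait is always retained since it
   is the normalizer.
2. **Bait normalization.** Within each (fraction, hemisphere) stratum,
   counts are summed across the replicates *first*, then each prey total is
   divided by the bait total.  Total-over-total (rather than a mean of
   per-replicate ratios) is the primary estimate; per-animal ratios are
   emitted separately for the paired t-test, because the two answer
   different questions (point estimate vs within-animal inference).
3. **Ratio and classification.** `ratio = normalized_lesion /
   normalized_intact` per fraction.  Proteins reaching ≥ 50 counts in at
   least one fraction (summed over both hemispheres) are classified:
   increased if `ratio >= 1.18`, decreased if `ratio <= 0.82`, else
   unchanged.  Thresholds are **inclusive** (the ±18 % figure is stated
   without strictness; inclusivity is configurable).  A protein with zero
   intact but nonzero lesion counts has no finite ratio; it is reported as
   increased with `ratio_defined = False` rather than silently dropped.
4. **Category roll-up.** A user-supplied protein → functional-class map
   groups increased/decreased proteins per fraction; unmapped proteins land
   in "other".  No enrichment statistics are computed (out of scope).

Error structure worth knowing: with negative-binomial counts at dispersion
`k = 10` summed over 6 replicates, a stratum total has CV
`sqrt(1/(6*mu) + 1/60) ≈ 13 %` regardless of abundance, so a single
protein's ratio estimate — four such totals — carries ~18 % CV (log-sd
≈ 0.26).  Boundary effects of ±18–28 % therefore have ~50 % detection
probability per experiment, while 1.5-fold effects are detected with
~95–98 % probability.  The bait totals are shared normalizers: a low bait
draw shifts an entire stratum's ratios jointly, which is visible in single
seeds as a coherent wave of weak calls in one fraction.

## XIC quantification

An extracted ion chromatogram for a target ion of theoretical m/z `m` keeps
all points with m/z in `[m (1 - tol·1e-6), m (1 + tol·1e-6)]` (default
tol = 10 ppm).  The trace grid is the *scan grid*: every retention time
sampled within the integration window becomes a node, with intensity the
sum of in-window points at that time (zero where nothing matched; times are
considered identical within 1e-4 min).  This mirrors full-range MS1
acquisition and makes the AUC exactly nondecreasing in the tolerance —
binning only over matched points would let sparse selections overshoot the
trapezoid.  The AUC is the trapezoid rule over that grid; a single point
integrates to zero.  Traces of the same modified peptide at different
charge states are summed *after* per-charge extraction (summation before
ratioing), which preserves scale invariance of every downstream ratio.
Integration bounds default to apex ± 4 σ for generated peaks and are
user-specified per target otherwise; no baseline subtraction is applied
(the generator correspondingly emits a near-zero baseline).

**Occupancy.** `p / (p + n)` for the phospho and nonphospho AUCs of the
same peptide from the same run — bounded in [0, 1] and invariant to any
whole-run intensity scaling.  If the nonphosphorylated counterpart is not
detected in every run of a target, the whole target switches to reference
mode — `p / AUC(reference peptide)` with a designated nonphosphorylated
reference (EQLQGLNDR on the NF-M analog) — so its per-sample values remain
mutually comparable.  Reference-mode values are unbounded above; their
lesion/intact *ratios* still estimate the occupancy ratio.

**Abundance.** Target AUC divided by the arithmetic mean of the AUCs of
bait reference peptides (three spinophilin peptides by default), cancelling
IP yield and loading differences; a change in this quantity is a change in
prey per unit bait.

**Pairing and testing.** Every per-sample quantity is converted to a
lesion/intact ratio within animal (the lesion value divided by the matched
intact value), and each target's ratios are tested two-sided against the
theoretical no-change value 1 with a one-sample t-test.

## Phosphosite ambiguity

Tryptic digestion uses the trypsin rule (cleave after K/R except before P)
with configurable missed cleavages (default 2 — the search-engine maximum
is not knowable from count data, so this is a recorded configuration
default, not an assertion).  Peptides are deduplicated by sequence and
carry *every* occurrence position on the parent (exhaustive substring
search, overlapping matches included).  A peptide-relative phosphosite then
maps to the set `{start + position - 1}` over all occurrences: a unique
peptide yields a singleton, a repeat-domain peptide yields one candidate
residue per repeat copy.  For the KSP repeat domain of the neurofilament-
medium analog, SPVPKSPVEEK phosphorylated on its second serine maps to
{620, 633, 646, 659} — site-level assignment is genuinely impossible and
the ambiguity set is the honest output.  An optional
`phospho_blocks_cleavage` digest mode additionally emits the longer forms
arising when phosphorylation of a repeat's first serine prevents cleavage
of the preceding lysine (junctions followed by serine do not count against
the missed-cleavage budget); it never removes fully cleaved products, since
blocking is possible rather than certain.

Mass arithmetic uses standard monoisotopic residue masses with
water = 18.010565 Da, proton = 1.007276 Da and +79.966331 Da per phosphate,
fixed in one constants module; b/y fragment series attach the phosphate to
its residue and satisfy `b_i + y_(n-i) = M + 2·proton` identically.

## Statistics

* **One-sample t vs 1**: `t = (mean - 1)/(sd/sqrt(n))`, df `n - 1`,
  two-sided; zero-variance samples are rejected as degenerate.  All tests
  are two-sided at α = 0.05.
* **Two-way ANOVA + Fisher LSD**: sums of squares are Type II via nested
  least-squares model comparisons, which reduce to the classical cell-means
  decomposition on balanced data; the default blot design (cell sizes
  8/8/7/7, 30 lanes) gives the error df of 26 the analysis is built
  around.  LSD compares cell means with the pooled error mean square and
  error df, deliberately uncorrected for multiplicity.
* **Grubbs**: single-pass two-sided test, `G = max|x - mean|/sd`, critical
  value `((n-1)/sqrt(n))·sqrt(t²/(n-2+t²))` with `t = t_(1-α/(2n), n-2)`;
  at most one point is ever removed per series, matching the screening
  protocol of removing at most one outlier.

## Synthetic-data generator

The generator is first-class, tested code: its defaults *are* the study
conditions, chosen once.

* **Counts**: negative binomial with variance `mu + mu²/k`, `k = 10`
  (spectral counts are overdispersed), bait mean 500 per replicate per
  stratum.  The default prey panel mirrors the effect sizes the pipeline is
  designed around — NF-M at 0.82 in both fractions and PP1 at 1.28 in S3 —
  plus six strong changers at 2×/0.5×/3×/0.33× (a recovery benchmark needs
  effects comfortably above the classification thresholds given the ~18 %
  ratio CV derived above), moderate boundary effects, abundant nulls, and
  two low-abundance proteins that exercise the 48-count filter.
* **Chromatograms**: Gaussian elution peaks (σ = 0.05 min) sampled at σ/5
  over apex ± 4 σ; point m/z jitter N(0, 3 ppm) so the 10 ppm window is
  exercised meaningfully (99.9 % capture); species amplitudes split by the
  planted occupancy and perturbed by mean-one lognormal noise (CV 10 %);
  near-zero flat baseline.  Planted occupancies are elevated in the
  lesioned hemisphere (Ser17 0.25 → 0.40, Ser100 0.20 → 0.32); one
  phosphopeptide is emitted without its nonphospho partner to force the
  reference-fallback path.
* **Blots**: 2×2 genotype × coactivator design with lognormal channel noise
  (σ_log = 0.2), per-gel gain factors (which cancel in the per-gel
  reference ratios), and a planted 0.6× main effect of the coactivator on
  the co-IP channel with no genotype effect and no interaction.
* **TH gate**: six animals with planted reductions of 92–98 % and one at
  85 % that the strict > 90 % gate must exclude.

One subtlety the validation respects: with *independent* per-species
amplitude noise, the population mean of realized per-sample occupancies
differs from the planted parameter by O(CV²) ≈ 7e-4 (the ratio-of-noisy-
sums effect); the estimator itself reproduces each sample's realized
occupancy essentially exactly.  Recovery is therefore checked on two
scales: estimate vs realized per-sample truth (tight), and grand mean vs
planted parameter within three standard errors of a single simulated
experiment's mean — the uncertainty scale at which such an experiment
reports its result.

**What passing does not show.**  The generator emits well-separated
Gaussian peaks on a common scan grid with known integration windows and
given identities; real data add retention-time drift between runs,
co-eluting interferences, isotope envelopes, peak-shape asymmetry,
peptide-spectrum-match errors and missingness that correlates with
abundance.  Recovery here validates the *arithmetic and inference chain*,
not robustness to those artifacts — peak detection, RT alignment,
match-between-runs and identity scoring are explicit non-goals.

## Problem sizes

The validation suite uses 50 random Gaussian peaks for the integration
oracle, 200 simulated experiments for occupancy recovery under noise,
50 simulated experiments for classification recovery, and 10,000 null
simulations for the t-test type-I rate; the acceptance script uses 25
simulated experiments for the count-branch summaries.  These sizes give
Monte-Carlo standard errors well below every tolerance they are checked
against.

## Known limitations

* Ratio thresholds are crude relative to the counting noise at this depth;
  the per-animal t-test pathway exists precisely because the thresholded
  call ignores pairing.  No multiple-testing correction is applied anywhere
  (by design, matching the analysis the package implements).
* Occupancies from reference-mode targets are not stoichiometries; only
  their condition ratios are interpretable.
* The S1-dialect reader infers animal identity from replicate numbers in
  the column headers; if replicate numbering does not track animals, the
  per-animal ratio table (not the primary totals-based estimates) is
  affected.
* mzML ingestion is deliberately a thin adapter question left to the
  caller: the core consumes (rt, m/z, intensity) tables, which any raw-file
  converter can produce.
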