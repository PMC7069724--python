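# Methods

## The growth/sequencing model

A bulk competition is modeled as a set of lineages growing exponentially and
sampled by sequencing. Lineage *i* has growth rate *r_i* and initial size
*n_i(0)*; at sampling time *t* the expected read fraction is

    p_i(t) = n_i exp(r_i t) / sum_j n_j exp(r_j t)

and the observed counts at each timepoint are an independent multinomial draw
of the sequencing depth over these probabilities. The likelihood is invariant
to a common shift of all rates and a common rescaling of all initial sizes,
so the wild-type reference is pinned at r = 1, log n = 0. Time is measured in
wild-type generations (wall-clock hours divided by a configurable doubling
time, default 4 h): with r_wt = 1, a complete loss-of-function allele sits at
r = 0, i.e. s = r − 1 = −1. The unit convention is arbitrary, and
deliberately so — the anchor normalization below removes any affine ambiguity
(this is proved as a property test: normalizing a·s + b gives the same result
as normalizing s, to 1e−12).

Serial dilution during the competition is not modeled; continuous exponential
growth yields identical relative frequencies, which are all the multinomial
sees.

## Posterior sampling

Parameters (r_i, log n_i) for every non-reference lineage are sampled by
Metropolis–Hastings with per-parameter Gaussian random-walk proposals and
improper flat priors on r and log n0. Internally the intercept is
reparameterized as the log-abundance at the mean timepoint, which removes
most of the slope/intercept correlation and lets independent per-parameter
proposals mix well. Proposal scales adapt during burn-in (every 50 sweeps,
multiplicative update toward ~25% acceptance); burn-in is 10% of total sweeps.
By default 10,000 post-burn-in sweeps are retained and summaries (median,
central 95% interval) use every 10th sample, i.e. 1,000 thinned draws. The
update for one lineage touches only its own terms and the per-timepoint
normalizers, so a sweep is O(variants × timepoints); the kernel is
numba-compiled, and a 500-variant × 8-timepoint table runs 11,000 sweeps in a
few seconds on one core. A split-chain R-hat above 1.2 for any variant
triggers a warning (never an exception).

Initialization uses the log-linear regression of log(c_i/c_ref) against time
with a 0.5 pseudocount — the same quantity that serves as an independent
oracle in the tests, where the posterior median for a high-depth two-variant
table must match the regression slope within 2%.

Zero counts at late timepoints are retained (the multinomial handles them);
no pseudocounts enter the likelihood.

## Anchor normalization

Raw s = median(r) − 1 is mapped through

    s_norm = (s_raw − mean_wt) / (mean_wt − mean_stop)

where mean_wt is the mean over wild-type synonyms and mean_stop the mean over
stop-codon variants, excluding stops beyond position 677 by default: the last
32 positions of the full-length chaperone are dispensable, so their stops are
not null alleles. Both anchor sets can additionally be restricted to a
position window (`position_mask`) for conditions where one anchor class
misbehaves in part of the gene. After scaling, the wild-type-synonym mean is
exactly 0 and the stop mean exactly −1 — these identities are what
`scripts/acceptance.py` recomputes end to end.

## The synthetic generator

`SimulationConfig` defaults describe the experiment the analysis is built
for:

- 709-codon protein, positions 2–709 mutagenized: 63 alternative codons per
  position (44,604 codon variants; 14,160 amino-acid variants = 19
  substitutions + stop per position, synonyms flagged separately);
- Poisson(15) barcodes per variant (the library aims for 10–20), unique
  uniform-random 18-mers, collisions resampled;
- a three-component Gaussian mixture over selection coefficients — neutral
  (weight 0.60, mean 0, sd 0.02), null (0.35, −1, 0.05), beneficial (0.05,
  +0.03, 0.02) — reproducing the bimodal DFE with peaks at s = 0 and s = −1
  and a small beneficial tail. Wild-type synonyms are exactly neutral; stop
  codons draw from the null component, except within the dispensable
  C-terminal window (32 positions for the full-length protein; the window
  auto-clamps to zero for synthetic proteins too short to have one), where
  they draw from the neutral component;
- 8 timepoints at 0–28 h, doubling time 4 h;
- sequencing depth defaulting to 500 reads per variant per timepoint (the
  experimental average at t = 0), drawn multinomially so column sums equal
  the configured depth exactly;
- initial sizes log-normal (sd 0.3) around a common scale, plus one explicit
  unmutated wild-type lineage seeded at 20× the median variant abundance.
  The pipeline pins this lineage as the MCMC reference; giving it higher
  abundance keeps the reference trajectory low-noise, which benefits every
  relative estimate. An optional pre-selection interval (in generations)
  depletes deleterious lineages before t = 0, mimicking the partial stop
  depletion real t = 0 samples show; its default is 0 because no duration is
  known.
- error knobs (`base_error_rate`, `low_quality_fraction`) default to 0 so
  that the defaults describe the competition process itself; checks that
  specify noise pass it explicitly (e.g. 1% substitutions for association
  recovery, 5% low-quality reads for the filter-loss check).

Association reads are emitted as pairs (18-mer barcode read; single-window
ORF read), competition reads as 100-base single-end reads with the barcode at
bases 1–18, an 8-base sample identifier at 91–98, and a fixed template
elsewhere. Emission followed by parsing, counting and aggregation reproduces
the input count table exactly at error rate 0 (tested), and all generator
output is byte-identical under a fixed seed.

What the generator does **not** emulate: PCR amplification bias and jackpot
effects, indel sequencing errors, chimeric reads, paired-end overlap, barcode
cross-contamination between samples, and overdispersion beyond multinomial
sampling. Passing tests therefore demonstrate correctness of the inference
given the stated model, not robustness to these real-data pathologies.

## Read processing rules

- Association: a read pair is dropped if any base is below Phred 10; groups
  need at least 3 reads; consensus requires a strict (> half) per-base
  majority, and ties, length discrepancies or multi-codon differences reject
  the barcode. The strict-majority rule is deliberately conservative: an
  error can only propagate if the same misread occurs in most reads of a
  barcode. (Whether a no-majority barcode should instead be resolved by
  quality weighting is an open choice; rejection was chosen.)
- Competition: bases are interpreted only at the barcode, identifier, and
  template anchor positions; each must exceed Phred 20 (a base at exactly 20
  fails) and anchors must match the template exactly. Full-template matching
  is available behind a flag. Identifier matching is exact (no
  error-correction). Unknown barcodes — overwhelmingly sequencing errors,
  since a misread barcode almost never collides with a valid one — are
  discarded and tallied.
- Variants with fewer than 100 reads at t = 0 are dropped before inference.

## Classification

Bands use the anchor distributions per condition: wild-type-like within 2 SD
of the wild-type-synonym mean, beneficial above, strongly deleterious within
2 SD of the stop mean, intermediate between. When the bands overlap the
precedence is strongly-deleterious, then beneficial, then wild-type-like
(each variant gets exactly one label). The ts screen uses explicit cutoffs —
defaults s_standard ≥ −0.11 (the lower limit of wild-type synonyms under
standard conditions) and s_stress ≤ −0.47 (the upper limit of stops at
37 °C); for new data the natural choice is wt_mean − 2·wt_sd
and stop_mean + 2·stop_sd. Position categories: critical = position mean
(excluding stops) null-like in every environment; environmentally responsive
= shifted from standard by more than one wild-type-synonym SD in ≥ 3 stress
environments (the five stress conditions count, not replicates); tolerant =
shifted in none. The cross-condition "deleterious" set for overlap counting
is intermediate ∪ strongly-deleterious — i.e. everything below the
wild-type-like band — which is an interpretation, flagged here, since a Venn
of "deleterious mutations" does not itself define the class.

## Clustering null

Observed mutations of a class are reduced to a histogram of positions by
count. The null places the same number of mutations uniformly at random over
the candidate positions, capped at 19 distinct amino-acid changes per
position (observed data cannot exceed this either; draws violating the cap
are redrawn), 1000 simulations by default. Significance per bin is the
one-tailed normal tail probability of the z-score against the simulated
mean/SD — at 1000 simulations this is equivalent to the t-test variant, and
avoids committing to a degrees-of-freedom convention for a simulated null.
Bins with zero simulation variance but an exceeding observation are reported
at the simulation resolution, p = 1/n_sim.

## Displaced-gamma fit

For each environment the neutral + beneficial subset (classification labels,
stops excluded) is fit with s = d − X, X ~ Gamma(shape, scale). For fixed d
the inner gamma MLE reduces to a one-dimensional score equation in the shape,
log k − ψ(k) = log(mean) − mean(log), solved by bracketed root finding; the
profile over d is maximized on a 60-point grid from max(s) + 1e−6 to max(s) +
5 sample SDs and refined by bounded scalar minimization (xatol 1e−10). All
bounds are defined relative to max(s) and the sample SD, making the fitted d
exactly translation-equivariant (verified to 1e−8). Fits pinned at the
support boundary are flagged `converged=False` rather than hidden. Because
the fitted d depends on exactly which variants enter the neutral +
beneficial subset, fitted distances are best treated as an ordering across
environments, not as point estimates comparable between analyses.

## Statistical comparisons

Kolmogorov–Smirnov two-sample tests use the exact D statistic with the
asymptotic p-value (scipy), cross-checked in the tests against an exhaustive
small-sample ECDF oracle. Two-proportion z-tests use the pooled-variance
formula (cross-checked against statsmodels) with Benjamini–Hochberg step-up
adjustment; the two-stage adaptive BH variant is available behind a flag
since "adaptive step-up" admits both readings. Alignment-column entropy is
Shannon entropy in nats (−Σ p ln p); the base is unstated in the comparisons
this supports and only relative values matter. Gaps are excluded from column
frequencies rather than counted as a 21st state. Structural quantities
(SASA, distances to the ATP γ-phosphate, predicted ΔΔG, conservation scores)
are consumed from a precomputed per-position TSV — they come from external
structure-based tools and are inputs here, never computed.

## Problem sizes used in the checks

The test suite and acceptance script run compact competitions chosen to keep
anchor classes well populated: 12–26-codon proteins, 120–500 variants,
depths 1e5–2e5 reads per timepoint, 1,500–10,000 retained MCMC samples. At
these sizes the posterior-median normalized coefficients correlate with the
planted truth at r ≥ 0.998 with RMSE ≈ 0.03, and the displaced-gamma fit
recovers a planted d = 0.07 within ±0.01 at n = 5,000.

## Known limitations

- Replicates are analyzed independently and compared; there is no
  hierarchical multi-replicate model.
- The sampler is single-chain (with split-chain diagnostics); no HMC or
  ensemble samplers.
- Indels are neither simulated nor called; the library is substitution-only.
- The clustering test is positional, not spatial (no 3-D distances).
- Whether the random-placement null should be capped at 19 changes per
  position is a modeling choice; the cap matches what observed data can
  contain and only matters near saturation.
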