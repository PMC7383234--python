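# Methods

This note records the models, defaults and numerical choices behind each
module, what the synthetic generators do and do not emulate, and the known
limitations.

## Rare-allele enrichment scan

**Model.** Each SNP is a binomial experiment: under the null, the cohort's
rare-allele count is Binomial(2·n_assessed, f_ref) in allele mode, or its
carrier count is Binomial(n_assessed, f_carrier) in carrier mode.
Deviation from the reference frequency is tested with a two-tailed
chi-square with Yates continuity correction, df = 1:

- goodness-of-fit: χ² = Σ (|O−E| − ½)² / E, used when only the reference
  frequency is known;
- 2×2 contingency: χ² = N(|ad−bc| − N/2)² / [(a+b)(c+d)(a+c)(b+d)], used
  when the reference cohort size is known (the reference is then a finite
  comparison group, not a fixed expectation).

In both forms the corrected deviation is floored at zero, so a table at
independence gives χ² = 0 rather than a spurious positive value (the
uncorrected cross-product form and some library implementations overshoot
when |O−E| < ½).  As the reference cohort grows the 2×2 statistic
converges to the goodness-of-fit statistic; the test suite asserts < 1%
relative difference at reference size 10⁷.

**Layout and reference-count conventions.** For the pooled
discovery + replication carrier test the default is the 2×2 layout with
the reference carrier count rounded to an integer
(round(f·N_ref) carriers); an unrounded variant is exposed.  Both
conventions and the goodness-of-fit fallback are available because
published chi-square values rarely state which was used; the rounded 2×2
is the default because it reproduces the worked example in the test suite
to three decimals.  The phrase "allele frequency for heterozygote
carriers" in such studies is read as a carrier frequency (n × f then
matches the printed expected carrier counts); both `ref_freq_kind`
conventions are supported per record.

**Multiple testing.** Bonferroni and Benjamini–Hochberg step-up q-values
are computed over the set of SNPs actually tested in the run (records
skipped for missing reference frequency or low coverage do not count
toward m).  Both corrections go through
`statsmodels.stats.multitest.multipletests`; the tests pin them to
hand-computed step-up values and to the bounds raw p ≤ q ≤ Bonferroni.

**Expected-count floor.** Records with expected count below 0.5 are still
tested but flagged `small_expected`: rare-allele scans must test expected
counts below one (the worked examples include an expected 0.7), and the
chi-square approximation degrades there — the flag lets a caller decide.
The null-calibration benchmark therefore restricts itself to expected
counts ≥ 5 (see Benchmarks).

**Filter cascade.** Stages run in a configurable order (default:
significance gate on q or Bonferroni p; protein-changing consequence;
gene-set membership; not-common-in-orthologs; no artifact flag), each
recording n_in/n_out and the removed SNP ids.  Annotation flags are
consumed as given — computing SIFT/conservation annotations is out of
scope.

**Ranking and ties.** Outputs are stably sorted by (raw p, snp_id) so
reruns are byte-identical.

## Sensory-testing statistics

Two-sample comparisons from summary triples use the standard pooled
(Student, df = n₁+n₂−2) or Welch (Welch–Satterthwaite df) t statistics;
the 95% CI of the mean difference uses the same SE and df as the test.
Welch is the default (robust to unequal variances); the choice matters in
practice: on the cuff-pressure worked example the pooled test gives
p = 2.1 × 10⁻⁵ (printing as 0.00002 at five decimals) while Welch gives
1.5 × 10⁻⁵ (printing as 0.00001) — published tables that print 0.00002
are consistent with the pooled variant.  Mann-Whitney U uses the exact
null distribution for ≤ 20 pooled observations without ties and the
tie-corrected normal approximation otherwise.

Šidák correction `1 − (1 − p)^m` is applied per assessment family
(detection thresholds, pain thresholds, tolerance, questionnaires …);
family membership is configuration, not inference, and m is the number of
rows sharing the family label.  Šidák is bounded above by Bonferroni and
is order-invariant within a family.

## Patch-clamp analysis

Units are mV, ms, pA throughout.

**Leak subtraction** fits I = g(V − V_rev) by least squares to the
steady-state currents (mean of the last 10% of the step) of sweeps whose
command lies in a caller-chosen leak window, then subtracts the ohmic
prediction everywhere (using the tail command voltage over an annotated
tail segment).  The window must be hyperpolarized enough that channels
are genuinely closed; residual activation inside the window biases g.

**Tail activation curves.** Tail amplitude = peak |I − late-tail
baseline| within the first 10 ms of the tail (both windows configurable);
the curve is normalized to its maximum.  This early-peak-minus-baseline
convention is one of several reasonable readings of "normalized tail
currents"; it is robust to slow deactivation because the baseline comes
from the final 20% of the tail.

**Boltzmann fits.** y = t/(1 + exp((V₅₀−E)/k)) with k constrained
positive; default initialisation t = max y, V₅₀ from the interpolated
half-max crossing, k = (V₉₀−V₁₀)/4.39 (the exact relation for a
Boltzmann).  The top can be frozen (`fix_top=1`) for pre-normalized
curves; it is free by default.  Two-component sums bound F to [0, 1] and
use five seeded multistarts; after fitting, components are ordered so
component 1 is the more depolarized (larger F breaks ties), and
|ΔV₅₀| < 2 mV sets a `degenerate` flag instead of failing.

Identifiability is the dominant error source, not optimisation: with 16
points on [−110, +40] mV and noise SD 0.02 (normalized units) the
Cramér–Rao bound for a two-component fit with midpoints ~30 mV apart and
slope factors 10–12 mV is ≈ 11 mV per midpoint — such curves cannot be
decomposed reliably at that noise, and the package flags rather than
guesses.  With ~60 mV separation (the wild-type regime the benchmarks
emulate) the bound drops to ≈ 3 mV and the fitted medians are 1.6–2.3 mV.

**Toxin subtraction** is exact pointwise arithmetic (pre − post) after
validating matching commands and time grids; the result is marked
ScTx-sensitive in metadata.  `fractional_reduction` reports the
steady-state block fraction at a chosen step potential.

**Recovery from inactivation** fits y = 1 − A·exp(−Δt/τ) (an anchored
single exponential; a y₀ + (1−y₀)(1−exp) variant is available since
"single exponential" underdetermines the form).

**Action-potential thresholds.** A spike is a sample run with
dV/dt ≥ 10 mV/ms whose voltage exceeds 0 mV within the following 2 ms
(both criteria configurable; they are a package convention — threshold
papers rarely state one).  Ramp threshold is the injected current at the
first spike onset; step threshold is the smallest step current eliciting
a spike, i.e. an overestimate of rheobase by at most one grid step.
Capsaicin responders show a mean in-window inward deflection exceeding
5× the pre-application baseline SD.

## Single-cell qRT-PCR calls

A gene is positive in a cell iff its Cq is present and strictly below 35
cycles.  Cells enter analysis only if the housekeeping gene (Gapdh by
convention) is positive; any positive call in a bath-control column flags
the whole run as contaminated.  Co-expression summaries report, per
population, the percentage of cells positive for an anchor gene and —
among anchor-positive cells — for each partner, always alongside the
raw count and denominator.  Percentages round to the nearest integer
(30/45 reports as 67; a table printing 66 for that ratio truncated
instead — counts disambiguate).  Zero denominators report NaN, never 0.

## Synthetic data

All generators are pure functions of (spec, seed) and return ground
truth.  They emulate the statistical structure of each input, not its
biology:

- **Cohorts**: reference frequencies log-uniform on [10⁻⁴, 0.5] by
  default (uniform available for calibration studies); carrier mode draws
  carrier counts directly (all carriers heterozygous, appropriate for
  rare alleles); allele mode draws per-individual genotypes
  Binomial(2, p) under Hardy–Weinberg.  Coverage dropout removes each
  individual at a SNP independently.  Defaults (100 individuals) mirror a
  discovery-exome-cohort scale.
- **QST groups**: i.i.d. Gaussians at the requested (n, mean, SD) — no
  skew, censoring or session effects.
- **Sweeps**: currents from the Boltzmann/double-Boltzmann/exponential
  forms plus ohmic leak and additive Gaussian noise; tails decay
  exponentially (τ 50 ms).  The pre/post toxin pair shares one noise
  draw on the sensitive component so subtraction is exactly invertible;
  its default conductance split puts ~52.7% of the +20 mV steady-state
  current on the toxin-sensitive component, the scale reported for
  K_V_2-dominated sensory-neuron currents.
- **Spiking cell**: a leaky integrate-and-fire neuron (V_rest −60 mV,
  V_th −40 mV, R 100 MΩ, τ 10 ms ⇒ rheobase 200 pA) with a painted
  spike waveform so dV/dt + overshoot detection behaves as on real
  traces.  It is a minimal stand-in, not a conductance-based model of
  K_V_2.1/K_V_6.4 heterotetramers; channel effects on excitability are
  outside the simulation's scope.
- **Cq matrices**: Bernoulli positivity per gene (optionally conditional
  on an anchor gene's state), Gaussian Cq around a gene-level mean
  truncated below 35, housekeeping always positive except in requested
  QC-failure cells, all-negative bath controls.

Passing tests on these generators demonstrates correctness of the
analysis chain under its own assumptions; they say nothing about
real-data pathologies (batch effects, stratified ancestry, series
resistance, amplification efficiency).

## Benchmarks (`nocistat.benchmarks`)

Seeded closed-loop experiments used by the test suite and the
reproduction script; per-replicate seeds derive from one master seed.

- *Single-Boltzmann recovery*: 100 replicates, 16 voltages, noise SD
  0.02 → median |V̂₅₀ − V₅₀| ≈ 0.4 mV (asserted < 1 mV).
- *Double-Boltzmann recovery*: 100 noisy curves at the well-separated
  component regime (midpoints −0.8/−60.2 mV; slopes 10/12 mV and F = 0.4
  are unreported in the motivating data and set to plausible
  delayed-rectifier values) → median midpoint errors ≈ 2 mV and F error
  ≈ 0.04 (asserted < 3 mV and < 0.1).  The close-midpoint regime
  (−30/−60) is kept as a graceful-degradation check: errors there are
  several-fold larger, as the Cramér–Rao analysis predicts.
- *Recovery-τ*: 100 replicates at noise SD 0.03 → median relative τ
  error ≈ 6% (asserted < 10%).
- *Null type-I error*: 2,000 null SNPs, 100 individuals, carrier
  frequencies uniform on [0.05, 0.3] (expected counts ≥ 5) → empirical
  rate ≈ 0.03–0.04 at α = 0.05, inside [0.03, 0.07]; the Yates
  correction keeps the test conservative, increasingly so at smaller
  expected counts.
- *Spike detection power*: 200 replicates of a 50-SNP candidate panel
  (one SNP at 6× a reference carrier frequency of 0.007, n = 100) →
  the spike reaches BH q < 0.05 in ≈ 60–65% of replicates and ranks
  first by raw p in ≈ 65%.  The panel size is a deliberate study
  condition: detecting an expected-0.7-carrier signal requires ≥ 4
  observed carriers, whose raw p ≈ 8 × 10⁻⁴ survives BH only when the
  tested universe is of candidate-panel size (a few dozen SNPs, the
  scale of an ion-channel gene panel); at genome scale the same signal
  is undetectable by design of the correction, which is why such scans
  confirm candidates in replication cohorts rather than by FDR alone.

## Mapping VCF-style inputs

VCF ingestion is out of scope.  To use variant data: one row per SNP with
snp_id = the VCF ID (or chrom:pos:ref:alt), n_assessed = individuals with
a genotype call, rare_allele_count = allele-count sum of the minor
allele, carrier_count = individuals with ≥ 1 copy, ref_freq +
ref_cohort_size from the chosen population database, and annotation
flags from the caller's own pipeline.

## Known limitations

- The chi-square scan treats SNPs independently; linkage disequilibrium
  between panel SNPs is not modelled.
- Reference frequencies are treated as known constants in
  goodness-of-fit mode; sampling error in the reference enters only
  through the 2×2 layout.
- No normality or variance-homogeneity gating is wired in front of the
  t-tests; the caller chooses the method.
- Leak subtraction assumes a purely ohmic leak and no capacitance
  transients; P/N protocols and series-resistance artefacts are out of
  scope.
- Double-Boltzmann fits near component coincidence are reported with the
  degenerate flag rather than refused; F is meaningless in that regime.
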