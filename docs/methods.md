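# Methods

`daycast` predicts days-to-heading (DTH) of rice-like short-day crops in
environments that have never been observed, by coupling theoretical day
length (DL) with genomic prediction. This note documents the models, the
numerical choices, and what the bundled simulator does and does not show.

## Day length

Day length depends only on latitude and calendar date, so it is the one
environmental covariate a breeder can compute *before* planting. We use
the CBM model (Forsythe et al. 1995): the Earth's revolution angle
θ = 0.2163108 + 2·arctan(0.9671396·tan(0.00860·(J − 186))) gives the solar
declination φ = arcsin(0.39795·cos θ), and daylight is the fraction of the
day the sun's upper limb is above the horizon after refraction
(daylength coefficient p = 0.8333°). The arccos argument is clipped to
[−1, 1] so polar day/night return 24/0 h instead of raising; simulations
at extreme latitudes degrade gracefully. No longitude, timezone or
elevation correction is applied: duration of daylight, not clock time of
sunrise, is what the phenology model consumes. Day 1 of every
environment's series is the planting date itself, and leap years are
handled through the actual calendar day-of-year.

## GBLUP

Phenotypes follow Y_ij = μ + E_j + g_i + e_ij with environment effects
E ~ N(0, Iσ²_E), genomic effects g ~ N(0, Gσ²_g), residuals
N(0, Iσ²_e), and G = XX′/p the genomic relationship matrix on the
column-standardized marker matrix (divisor-n standard deviation, so a
two-genotype opposite-homozygote panel gives G = [[1, −1], [−1, 1]]
exactly, and mean diag(G) = 1 with complete data). Missing dosages are
mean-imputed per marker before standardization; QC drops markers with
more than 50% missing calls, minor allele frequency below 0.03 (computed
on non-missing calls), or no polymorphism.

Variance components are estimated by REML rather than MCMC: the
restricted likelihood is profiled over σ²_e, leaving a two-parameter
surface in the ratios (σ²_E/σ²_e, σ²_g/σ²_e) that is scanned on a 9×9
log₁₀ grid over [−4, 4] and refined with Nelder-Mead (cap 200 iterations,
absolute function tolerance 1e−8). Every evaluation solves Henderson's
mixed-model equations, whose order is 1 + n_envs + n_genotypes regardless
of record count, so a fit costs milliseconds and exact per-task refits in
cross-validation are affordable. G is jittered with 1e−8·I before any
inversion. The fit is deterministic: identical data give identical
estimates.

BLUPs for genotypes without records come from the conditional-expectation
projection ĝ_u = G[u,T]·G[T,T]⁻¹·ĝ_T, which is algebraically identical to
refitting the mixed-model equations with the recordless genotype carried
in G; the joint refit serves as a test oracle, not the runtime path.

## The C method

Across environments, the DL observed on a genotype's heading day traces a
smooth genotype-specific curve against DTH. The C method fits a cubic of
DL-at-heading on DTH over the genotype's training environments (curve C1;
at least four distinct DTH values required, DL looked up at the integer
heading day on each training environment's own series), fits a cubic to
the target environment's daily DL over days 1–160 from planting (curve
C2; the window is clipped to the series and configurable), and estimates
DTH as the abscissa where the curves intersect.

Intersection numerics: real roots of the difference cubic come from the
companion matrix; roots are filtered to a plausibility window
[0.8·min training DTH, 1.2·max training DTH]. A unique in-window root is
returned as-is; several are resolved toward the genotype's mean training
DTH (flagged `tie_broken`); none triggers a nearest-approach scan of
|C1 − C2| at 0.01-day resolution (flagged `fallback_nearest_approach`)
so cross-validation loops complete instead of aborting. Curves whose
difference coefficients are all below 1e−10 raise a degenerate-system
error (constant-DL worlds have no isolated intersection).

The window multipliers deserve a note. A cubic is only trustworthy near
its data support; far outside it the tails dive and can cross the
environment curve at biologically absurd times (e.g. heading at half the
genotype's typical duration), and with a wide window such spurious
crossings win as "unique" roots. A ±20% band around the observed
phenology rejects them, and the nearest-approach fallback then recovers
tangent-like geometry at the support edge. In our experiments this
reduced worst-case errors several-fold without touching interior cases;
wider bands are one config key away for panels whose target environments
genuinely sit far outside the training phenology.

## CB and GS under CV0/CV00

CV0 deletes every record of the target environment; CV00 additionally
deletes every record of the target genotype in all environments. The C
method serves CV0 directly. Under CV00 the CB method first predicts the
target environment's mean as the average of C-method estimates over all
eligible training genotypes (the target genotype never contributes; a
genotype with fewer than four usable records is skipped with a count) and
adds the untested genotype's projected BLUP; the decomposition
predicted = E-mean + ĝ holds exactly for every CB result. The GS baseline
is μ̂ + ĝ: because random effects are centered on zero, its implied
environmental mean is the same overall mean for every unobserved
environment — the structural bias the CB method exists to remove. The
GBLUP fit is re-estimated exactly for each excluded genotype × environment
pair; the batch runner shares the per-task fit between CB and GS and
caches per-environment C estimates, producing results identical to the
one-task-at-a-time calls.

Metrics: RMSE, Pearson correlation, and the environmental-mean difference
EMD = mean(predicted) − mean(observed), each within environments (then
averaged) and pooled across environments. A within-environment Pearson
over fewer than two results or zero observed variance is reported as NaN
and excluded from the average with a count. E-means are presented at one
decimal and final predictions at two in files, rounding half away from
zero (an E-mean of 108.25 presents as 108.3; full precision is kept
internally). The `cdl_diagnostic` regression of DTH on cumulative day
length is reported for context only — computing CDL requires knowing DTH,
so it cannot itself predict.

## The simulator

The generator is mechanistic, not statistical: each genotype carries a
base development rate r_i (1/days) and a short-day photoperiod
sensitivity s_i (1/hours), both scaled linear blends of standardized
marker scores and a marker-free residual mixed to the target heritability
(default 0.8; coefficients of variation 0.08 for r and 0.25 for s).
Development accrues daily as d_t = r_i·max(0, 1 − s_i·max(0, DL_t −
critical_dl)) and heading occurs when the accumulated total reaches 1;
rounded Gaussian observation noise (default sd 1 day) is added to the day
count. The genotype-specific DL-at-heading curve that the C method relies
on therefore *emerges* from the mechanism rather than being baked in,
which is what makes recovery tests meaningful.

Default conditions: 100 genotypes × 500 independent biallelic markers
(allele frequencies U(0.1, 0.9), no linkage) × 20 environments, latitudes
U(35.5, 36.5)°N, plantings mid-May to mid-July (day-of-year 134–196,
leap-year 2016 calendar), base rate mean 0.015–0.016 ≈ a 60–70-day
insensitive duration, sensitivity mean 0.25, critical day length 12.5 h.
Realized DTH spans roughly 65–140 days with environment means spread over
20–30 days and within-environment genotype SD near 9 — the proportions of
a temperate japonica multi-environment trial.

Two of these defaults are deliberately narrower than the geography they
emulate, and the reason is a genuine property of a day-length-only
developmental model. First, with April plantings the model lets crops
race through development while spring days are still short, making DTH
non-monotone in planting date, so the same DTH can occur at two different
day lengths and no single-valued genotype curve exists; real spring cold
suppresses early development and restores monotonicity, but temperature
is out of scope here, so the planting window starts where the
day-length-only response is monotone. Second, DL-at-heading differs by
~0.1 h per degree of latitude at heading time; against a genotype curve
whose slope is only ~0.02–0.05 h/day, a ±4° latitude spread injects
transverse scatter worth 10+ days of intersection error and destroys the
single-curve premise outright — demonstrated, not conjectured, during
development. A one-degree band keeps the environment family effectively
one-parameter, which is the regime the curve methods assume and which
real trial networks (sites typically clustered within a few degrees, with
temperature gradients compensating) approximate. Consequently, passing tests show
the methods work where their premise holds; they do not show robustness
to wide latitude spreads, and on real data from climatically diverse
sites the C method's curve residuals should be inspected before trusting
its estimates.

Records whose development never reaches 1 within 366 days are dropped
with a logged count (none occur under defaults). Noise applies to the
observed day count, not the development rates, so the per-cell truth is
deterministic and `TrueParams` can expose exact genotype main effects.

## Known limitations

- No temperature or photothermal interaction; planting-date effects are
  entirely photoperiod-mediated.
- Markers are unlinked with no major-gene architecture; genomic
  prediction accuracy for untested genotypes is therefore lower than a
  real panel with large-effect heading-date loci would allow, which
  mainly depresses the within-environment correlation of the CB method.
- The cubic family is fixed; no splines or physiological response curves.
- CV1/CV2 schemes (observed target environments) are out of scope.
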