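# Methods

This note records the models, priors, numerical choices and known
limitations behind `phasecal`, in the order a user meets them.

## Units and conventions

Calendar time is years cal BP (before AD 1950); larger is older. "ka" is a
display unit only: cal BP / 1000 rounded to 0.1. Measurements are
conventional ¹⁴C ages (CRA) in ¹⁴C yr BP. Curves are stored on strictly
decreasing cal BP knots and evaluated by piecewise-linear interpolation of
both μc and σc; evaluation outside the knot range raises rather than
extrapolates, because silent extrapolation corrupts posteriors — callers
clip their grids instead.

## Single-date calibration

The posterior is the normalised likelihood
N(x; μc(θ), √(σ² + σc(θ)²)) on a regular grid under a uniform prior; the
marine variant adds ΔR to the mean and σ_ΔR² to the variance. Default grid
step is 1 yr for reporting and 5 yr inside MCMC proposal tables (the
coarser step changes point summaries by well under 5 yr on smooth curves).
Degenerate inputs (total likelihood mass below 1e−300 on the grid) raise
instead of returning a normalised artefact. HPD sets pick cells by
descending mass with ties broken toward older cells; the mode tie-break is
also toward older — both purely for determinism. The agreement index is
A = 100·Σ(p_post·p_prior)/Σ(p_prior²) on a shared grid; the 60 % screening
threshold is exposed as a constant.

## Phase models

Phases are ordered older → younger over an overall range [young, old] of
length R; the default range is the union of the members' 99.9 % calibrated
supports padded by 500 yr.

*Uniform boundaries.* Events are uniform on [end, start] (factor span⁻ⁿ)
and the boundary pair carries the factor 1/(R − span). This is the
construction under which the marginal prior on the span is exactly
Uniform(0, R) for every n — verified by a prior-predictive
Kolmogorov–Smirnov test — so adding dates does not in itself squeeze the
boundaries. A phase whose boundaries are pinned (`fixed_start`/`fixed_end`)
omits the correction, which is then a constant.

*Sigma boundaries.* The per-event density is a plateau on [end, start] with
Gaussian tails of scale τ outside, normalised by (span + √(2π)·τ), with
τ ~ half-Normal(100 yr) per phase. Tails let abutting phases overlap,
reflecting diffuse physical boundaries; the reported boundary is the
plateau edge. Because the normalisation penalises large τ as n grows, the
posterior plateau can sit slightly inside the envelope of the dated events
— the tails absorb the extremes. This is intended behaviour, not a defect.

*Contiguity.* Contiguous phases share boundaries (P phases → P+1
boundaries) with non-strict ≥ ordering (ties are measure-zero). The
non-contiguous layout gives each phase its own pair, orders starts and ends
across phases, and forbids overlap only between adjacent uniform–uniform
phases.

*Outlier model.* Each date carries φ_i ~ Bernoulli(0.05); when flagged its
measurement is taken at θ_i + t_i·10^{u_i} with t ~ Student-t(5),
u ~ U(0, 4) — heavy-tailed calendar shifts spanning 1 yr to 10 kyr. The
posterior mean of φ_i is the per-date outlier probability. Note the
consequence: a clean date whose lab error happens to land ≥3σ from its
phase's prediction legitimately attracts posterior outlier mass of 0.2–0.5;
with 20 dates per site this happens in roughly 5 % of clean synthetic
sites. Interpret moderate probabilities as "partially explained as an
outlier", not as a verdict.

## Sampler

A Metropolis-within-Gibbs kernel vectorised over chains and over replicate
datasets (for recovery studies):

- event ages: element-wise Gaussian random walks, plus (every 4th sweep) an
  independence proposal drawn from each date's precomputed calibration
  density over the effective age θ + shift;
- boundaries and τ: coordinate-wise random walks;
- (t, u): exact prior redraws where φ = 0 (their conditional is the prior),
  Metropolis where φ = 1, and a "blame-shift" move that changes (t, u) and
  θ jointly at fixed θ + shift — exchanging event-age displacement for
  outlier shift without touching the likelihood;
- φ: Gibbs flips from the full conditional Bernoulli.

Proposal scales adapt toward fixed acceptance targets during burn-in only,
so retained draws come from a fixed kernel; a fixed seed reproduces every
draw bit-for-bit. Initialisation places events at their single-date
calibrated medians and boundaries just outside the member extremes, with up
to 1000 jittered retries before an initialisation error. Split R-hat and
bulk ESS (via arviz) are recorded per boundary; R-hat > 1.05 flags the
result without raising. Defaults for a single site model are 4 chains ×
20,000 iterations (5,000 burn-in, thin 5); the bundled studies use
2 chains × 3,000–8,000 iterations, which their diagnostics support.

## Reservoir (ΔR) estimation

One latent event age per context; a single shared ΔR ~ Uniform(−h, +h)
with h = 1000 ¹⁴C yr by default — "wide but proper". θ_c priors are uniform
over a data-derived range padded by h + 500 yr. A pre-check compares each
context's best joint likelihood with ΔR free versus clipped to the prior
box; a deficit above 50 nats raises a divergence error naming the context.
Screening is a single iteration by design: fit, drop dates with A < 60 %
(their own calibration versus the context posterior binned on a shared
grid; marine unmodelled densities use the first-pass ΔR mean ± sd), refit
once. Because context posteriors are much narrower than single-date
calibrations, A < 60 % is not rare even for clean dates; the excluded list
should be reviewed, not trusted blindly. A per-context ΔR variant is out of
scope.

## Age–depth regression

θ_i = β0 + β1·d_i + ε_i, ε ~ N(0, σ_ε), with the calibration likelihood as
the measurement term and latent θ_i sampled explicitly — so calibration
uncertainty propagates exactly as in single-date calibration, and no
ordering constraint is imposed. Priors: β0 ~ N(data centre, 10,000 yr),
β1 ~ N(0, 10,000 yr/unit), σ_ε ~ half-Normal(1,000 yr); all configurable.
(β0, β1) are updated by conjugate Gibbs, σ_ε by a random walk on log σ_ε,
θ_i element-wise. The slope initialisation jitter is scaled in
yr-per-depth-unit so the sampler is exactly equivariant under depth-unit
rescaling (metres → centimetres rescales β1 draws by 1/100 with matched
seeds and transformed priors). The reversal diagnostic counts adjacent
depth pairs whose single-date calibrated posterior means decrease with
depth; medians give the same counts on well-separated dates. The monotone
baseline (isotonic ages via pool-adjacent-violators + parametric bootstrap
OLS slope) exists as a diagnostic foil; under redeposition its intervals
are too narrow and under-cover the true accumulation rate.

## Synthetic data

Generators are pure functions of (config, seed). Curves are
μc(θ) = θ + A·sin(2πθ/P) + smooth coarse-knot noise with constant σc; the
study curves use A ≈ 10–15 ¹⁴C yr, P ≈ 600–900 yr, σc ≈ 8–10 ¹⁴C yr —
mild, Holocene-like wiggliness. Sites draw true ages uniform within each
phase and observe CRA ~ N(μc(θ)+ΔR·marine, √(σ_lab² + σc²)); outliers get
Student-t(5) calendar shifts (matching the inference family, i.e. the
recovery tests are well-specified). The controlled detection experiment
instead plants one deterministic +1000-yr shift on the date nearest
mid-phase — a shift planted at the young edge can land back inside the
phase and would not constitute an outlier. Latent ages are clipped into
curve support (recorded in the truth record); CRAs are never clipped.
Cores follow the linear model with a fraction of samples shifted
+800 yr by default (old material moved up).

What the generators do **not** emulate: real curve plateaus and reversals
at IntCal amplitude, material-specific offsets (old wood, diet), lab
inter-comparison biases, non-uniform within-phase deposition and compaction
or hiatuses in cores. Passing recovery tests therefore demonstrates the
machinery is correct and calibrated under its own assumptions — not that
any particular field dataset satisfies them.

## Validation studies and problem sizes

The studies in `phasecal.experiments` (rerun by `scripts/acceptance.py`)
use 100 replicates each at desk scale: single-phase sites with n = 30,
σ = 40 for boundary coverage; 20-date sites for outlier detection; 5
contexts × (2 + 3) dates, σ = 35, true ΔR = 150 for reservoir recovery;
12-depth cores with 2 redeposited samples for the age–depth comparison.
Replicates run through the batched kernel, so a full study takes tens of
seconds. Measured behaviour: start-boundary coverage sits slightly above
nominal (96–100 % across seeds) — the span-uniform prior is mildly
conservative at a fixed truth; ΔR and slope coverage sit at nominal; the
monotone baseline covers the true slope in well under half its replicates.

## Known limitations

- No curve mixing for part-marine diets, no post-bomb calibration, no
  Δ¹⁴C-space computation.
- Sequence (total-order) models beyond ordered phases are not implemented.
- The sigma-boundary form is one defensible reading of plateau-with-tails
  boundary softening; other parameterisations (e.g. boundary-position
  convolution) would differ in detail.
- Screening (A < 60 %) is a hard threshold applied once; borderline dates
  near 60 % flip in or out with Monte-Carlo noise.
- The ΔR model assumes one regional offset constant in time and species.
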