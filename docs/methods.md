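# Methods

## Scope and model

The package tunes the two hyper-parameters of an ε-support-vector
regressor — penalty C and RBF kernel width γ — with a Bald Eagle Search
(BES) metaheuristic and a chaotic-map-modified variant (MBES), for the
task of predicting daily soil moisture content from six sensor channels.
The tube half-width ε is held fixed at 0.01 (% SMC units): the search is
deliberately two-dimensional, matching the convention of treating ε as a
small constant and letting C and γ carry the bias/variance trade-off.

Assumptions baked into the pipeline:

* observations are a time-ordered daily record; train/test splitting is
  chronological (first 70% / last 30%), never shuffled, so evaluation
  measures genuine forward generalization;
* features are standardized to zero mean and unit variance using
  statistics of the split they are fitted on — the RBF distance must
  weigh °C, %, lux, mm and μS/cm channels comparably — while the target
  stays on its native percent scale;
* the tuning objective (fitness) is the MSE of a model fitted on the
  earlier part of the training split and evaluated on its chronological
  tail (the last 20% of the training rows). Evaluating fitness on the
  final test set instead is supported (`fitness_holdout="paper_test_set"`)
  but leaks the test period into the search and is off by default.

## SVR solver

Training solves the Wolfe dual of the ε-insensitive problem, a convex QP
in the 2m stacked multipliers with one equality and box constraints, by
sequential minimal optimization: at each step the maximal-violating pair
is updated analytically, with a curvature guard (`quad ≥ 1e−12`) for
coincident points. Numerical contracts:

* default KKT stationarity tolerance 1e−5, iteration cap 1e5. The tight
  default keeps the decision function within ~1e−5 of a dense
  reference QP solve of the same dual (the test suite checks 1e−4
  max-abs over random instances); inside the tuning objective, where
  thousands of candidate fits are only ranked, a coarser 1e−3 is used;
* bias b* is the mean of the per-sample KKT estimates over multipliers
  strictly inside (0, C); if none are interior it falls back to the
  midpoint of the KKT-feasible interval for b;
* a fit that exhausts the iteration cap raises; the tuning objective
  converts that to `+inf` fitness so the optimizer simply discards the
  candidate. Non-finite objective values are likewise treated as `+inf`
  and can never be accepted;
* fewer than two training samples is a domain error.

The SMO inner loop is numba-compiled; kernel matrices and the pairwise
squared distances behind them are built once per fit (and once per
tuning run for the cached objective) with vectorized numpy.

## Optimizer

One iteration is select → search → swoop, each phase followed by greedy
acceptance (an eagle moves only if its fitness strictly improves; ties
keep the incumbent). This makes the best-so-far trace monotone by
construction and fixes the budget at `n_agents · (1 + 3·max_iter)`
objective calls. Out-of-bounds proposals are clipped to the nearest
bound. The spiral coefficients are normalized by their population
maximum; if that maximum is zero the coefficients are set to zero. The
ring neighbour of the last eagle wraps to the first. All arithmetic runs
in the search space's internal coordinates — log10(C), log10(γ) for the
default space — so population means and differences are taken on the
scale where the problem is approximately isotropic.

Control parameters (defaults follow standard practice for this
optimizer): α = 1.5 (position-change gain, admissible [1.5, 2]), spiral
angle a = 10 ([5, 10]), search cycle R = 1.5 ([0.5, 2]), swoop
intensities c1 = c2 = 2 ([1, 2]), population N = 100, budget T = 100.
Experiments in this repository run reduced budgets (stated below).

The adaptive swoop weight is

    ω = 0.9 · cos( (π/2) · (1 − t/T) · r ),
    r = (fitᵢ − g_best) / (avgfit − g_best)   if fitᵢ < avgfit, else 1,

with r clipped to [0, 1] and defined as 0 when the population has
collapsed (avgfit = g_best). The cosine argument therefore stays in
[0, π/2] and ω in [0, 0.9]; ω = 0.9 exactly at the final iteration and
for the incumbent best eagle. The piecewise convention (full fitness
ratio below the mean, plain time decay above) is the only non-degenerate
reading of this weight family and is fixed as this package's definition.
The Fuch stream supplies one selection factor per eagle per selection
call; a Fuch iterate that lands exactly on zero (an absorbing value) is
re-seeded from the run's generator on its next use. The tent map's
additive perturbation `rand/N` can push an iterate above 1; it is wrapped
modulo 1. Tent iterates are consumed agent-major, then dimension-major,
which pins the initialization layout for reproducibility. N in the
perturbation defaults to the population size but is a separate knob
(`chaos_particles`).

Diagnostic overrides (`init_mode`, `gamma_source`, `weight_mode`) let
MBES be run with any modification neutralized; with uniform init,
uniform selection factor and unit weight it reproduces plain BES
bit-for-bit from the same seed, which the suite asserts.

## Search space

Default: C ∈ [0.01, 100], γ ∈ [10⁻³, 100], both searched in log10. The
C range follows the conventional [0, 100] bound for this task with the
floor raised to 0.01 (0 is not an admissible penalty). For γ the floor
sits one decade below the classical 0.01: with six standardized
features, squared distances concentrate around 2·dim ≈ 12, and on
near-linear targets the holdout-optimal width is of order 10⁻³ — with a
0.01 floor the optimum pins to the box boundary, which is the textbook
sign that the box is too small.

## Synthetic data generator

The generator emulates a ~216-day daily record from a subtropical
plantation: climate constants (annual mean 20.4 °C, mean relative
humidity 77%) anchor a sinusoidal seasonal temperature with AR(1) noise
(ρ = 0.7, marginal sd 1.2 °C); rain falls on 35% of days with
exponential wet-day totals (mean 8 mm); humidity rises 8 points on wet
days and drifts against temperature; light is lognormal and halved under
rain cloud; soil temperature is a 3-day EMA of air temperature.

Latent moisture follows a bucket water balance

    smc_t = clip(smc_{t−1} + k_in·rain_t − k_et·ET_t, floor, capacity),
    ET_t = et0 + et_temp·(T_air − 20) + et_light·light/10⁴ − et_hum·hum/100,

with defaults k_in = 0.35 %/mm, k_et = 1, et0 = 1.6 %/day,
et_temp = 0.03, et_light = 0.04, et_hum = 0.35, bounds [5, 45] %. These
were chosen to make the bucket *fast-draining*: a rain event relaxes
back toward the floor within a few days in every season, so the 151-day
training period and the 65-day test period sample the same regime. A
slowly integrating bucket is superficially more dramatic but drifts out
of the training support, and no per-row regressor — however tuned — can
extrapolate an RBF model there; a generator that defeats every model
cannot certify a tuner.

SEC is coupled to the latent moisture (5 μS/cm per % SMC around 118
μS/cm at 25%) plus a mean-reverting sensor drift (AR(1), ρ = 0.97,
innovation sd 0.1 μS/cm). The coupling is the physically expected
behaviour of bulk electrical conductivity and is also what makes the
task learnable from daily rows at all: the bucket state integrates past
rainfall, and without a state-carrying channel that memory is invisible
to any model of the current day's readings. Observed SMC adds Gaussian
noise (sd 0.5 %) to the latent state, so `noise_sd² = 0.25` is the known
test-MSE floor; the suite requires tuned models to land within 1.5× of
it and to reach R² ≥ 0.85 in at least 8 of 10 seeds.

What the generator does **not** emulate: spatial variability across
sensor nodes, diurnal cycles (the sub-daily expansion adds zero-sum
jitter, not weather), instrument drift and dropout, irrigation
interventions, and genuine soil physics (no Richards-equation dynamics).
Passing tests therefore certify the machinery — solver correctness,
optimizer behaviour, leak-free protocol, noise-floor recovery on a known
ground truth — not field performance on any real plantation.

The aggregation stage averages sub-daily readings per calendar day
(rainfall is summed as an accumulation); the cleaning stage drops rows
violating physical sensor ranges (humidity and SMC in [0, 100] %, SEC in
[0, 5000] μS/cm, non-negative rainfall and light) or exceeding a
modified z-score of 3.5 (median/MAD with consistency constant 0.6745)
on any screened channel; light is screened on a log scale and rainfall
is exempt from the z-screen (zero-inflated channels have degenerate
MAD). The collection-narrative fixture plants 13 corrupt days in a
229-day record after winsorizing the base record to a modified z of 3.0,
so cleaning recovers exactly 216 rows by construction.

## Experiment sizes and determinism

Default experiment sizes in the suite and acceptance script: tuning runs
use N = 20, T = 30 (1,820 fitness evaluations) on the 216-day record;
benchmark-function checks use N = 30, T = 100 (sphere) and N = 50,
T = 200 (Rastrigin) over 20 seeds; the matched-budget comparison with
random search uses N = 10, T = 10 (310 evaluations each) — sizes chosen
so the whole battery completes in minutes while leaving the statistical
conclusions stable across seeds. Every run is driven by a single integer
seed through one `numpy` generator per run; identical seeds give
bit-identical traces, positions and metrics.

## Known limitations

* The SMO solver is dense and targets records of a few hundred rows;
  it is not intended for large-scale kernel regression.
* The optimizer handles box constraints only; no equality/inequality
  constraint machinery.
* R² is reported in the standard `1 − SS_res/SS_tot` form; the
  explained-variance ratio is exposed alongside (`r2_ratio`) because
  both conventions circulate for this statistic, and on a constant
  measured vector both are undefined (reported as NaN with a warning).
* Chronological splitting assumes the record is stationary enough that
  a single 70/30 cut is informative; no rolling-origin evaluation.
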