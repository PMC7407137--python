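# Methods

## Problem and model

`memflux` quantifies water permeation through a lipid bilayer from MD
trajectory coordinates in two steps: (1) count complete water traversals of
the membrane slab in consecutive observation windows, giving a series of
non-negative integers Y₁…Yₙ; (2) infer the underlying flow rate with a
Bayesian state-space count model built for *bursty* transport — transport
whose events cluster in time far more than a Poisson process would allow.

The observation model is an autoregressive latent log-rate with Student-t
drift and negative-binomial emission:

    λᵢ ~ t_ν(ρ·λᵢ₋₁, σ)
    Yᵢ ~ NegBin(mean = exp(λᵢ), overdispersion = φ)

λᵢ is the log expected transition count in window *i* (log counts/window);
ρ is the autocorrelation of the latent rate, σ the innovation scale on the
log scale and ν the Student-t degrees of freedom (heavy-tailed innovations
let the rate jump between quiescent and bursting regimes); φ controls
marginal overdispersion, Var(Y) = μ + μ²/φ, so φ → ∞ is the Poisson limit.
The NegBin argument is the *log* rate: the emission mean is exp(λᵢ). This is
the only reading that keeps the model coherent with a prior placed on 1/φ,
and it is the parameterization implemented throughout (the "size"
parameterization; `negbin_logpmf` in `distributions.py` is the closed
form).

Priors (weakly informative): 1/φ ~ HalfCauchy(0,5), σ ~ HalfCauchy(0,5),
ν ~ Gamma(2, 0.1) (shape/rate, mean 20 — the standard weakly informative
choice for a t degrees-of-freedom parameter), ρ ~ Normal(0,1),
λ₁ ~ Cauchy(0,5). ν is sampled continuously on ν > 0 with no truncation;
ν ≤ 2 implies infinite innovation variance, which the prior admits and the
generator permits (heavy-tail consequence documented here rather than
forbidden).

Flow rates are reported in molecules/ns: exp(λᵢ)/window_ns with
window_ns = window_ps/1000, so 0.37 counts per 10 ps window = 37
molecules/ns. Two time averages are reported: the time average of the
per-window posterior *median* flow (the headline number, matching what the
rate curve shows) and the full posterior mean. The posterior mean can be
dominated by rare draws in which φ is tiny and a zero-count window barely
penalizes an enormous rate (the NegBin zero probability decays only like
φ·log μ); with well-populated count series the two agree, with sparse ones
the median-based average is the one to trust.

## Crossing counter

The membrane slab is two z-planes. The counter replays a three-state machine
(above / inside / below) per molecule: the *last definite side* is tracked,
"inside" preserves it (hysteresis against boundary jitter), and a crossing
is recorded when a molecule whose last definite side was one bulk region
first reaches the other. Re-entries that back out record nothing; a molecule
with no definite side yet (started inside the slab) records nothing until it
first reaches a bulk region. A coordinate exactly on a boundary plane
classifies as inside (deterministic tie-break). Each crossing is assigned to
the window containing its completing frame, which is unambiguous for
traversals spanning several frames. Down and up crossings both contribute to
Yᵢ; per-direction totals are retained.

Periodic boundaries: when the box height is known, a consecutive-frame z
displacement exceeding box_z/2 is treated as an image wrap. The state
machine resets that molecule's side to its new definite region without
recording a crossing — wraps are bookkeeping, not permeation.

Slab placement: the analysis convention is planes at the time-averaged mean
z of each phosphate leaflet (leaflets split per frame at the median z),
implemented in `infer_slab` and overridable with explicit bounds. A
degenerate split (all reference atoms on one side of the median) is an
error, not a guess.

Windows must be an integer multiple of the frame interval; the default is
one 10 ps window per saved frame, mirroring trajectories saved every 10 ps.

## Posterior computation

Inference is gradient-based MCMC: a No-U-Turn sampler (multinomial variant,
diagonal mass matrix adapted over Stan-style expanding warmup windows, step
size tuned by dual averaging to a 0.9 target acceptance — conservative
because the latent states are heavy-tailed). The sampler lives in `nuts.py`
and is generic over a log-density-and-gradient callable.

The model's log posterior and its gradient are evaluated by hand-derived
reverse-mode accumulation in numba-jitted kernels (`_kernels.py`):
the latent path enters non-centered — λ rebuilt from standardized t
innovations zᵢ, λᵢ = ρλᵢ₋₁ + σzᵢ — which is distributionally identical to
the centered form (the test suite verifies the densities differ by exactly
the σ^(n-1) Jacobian) and much better conditioned for HMC. A centered
kernel exists for cross-validation. φ is handled through 1/φ as the prior is
stated; all sampling runs on unconstrained coordinates
(ρ, log σ, log ν, log 1/φ, λ₁, z₂…zₙ) with the change-of-variables terms
included. Gradients are verified against finite differences, and the digamma
routine used inside the kernels (recurrence + asymptotic series; scipy is
not callable from jitted code) against `scipy.special.digamma`.

Defaults: 4 chains × 2000 draws after 1000 warmup iterations per chain.
Convergence is checked with split R-hat and bulk ESS (via arviz) on ρ, σ, ν,
φ and summarized over the λ path; R-hat > 1.05 on any reported parameter
fails the run loudly (warn above 1.01), with `rhat_action="warn"` available
for batch studies where one transient blip should not abort a replicate
sweep. Divergent transitions (energy error > 1000) are counted and reported.
Trajectories double up to depth 10 by default; the validation studies cap
depth at 8, which leaves the equilibrium tree depths (5–6 on typical
problems) untouched while preventing early-warmup trees from exploding.

Identified numerical choices: initialization jitters a heuristic point
(λ ≈ log of the mean count, ρ = 0.5, σ = 0.5, ν = 10, φ = 1); each chain
gets an independent stream from one `SeedSequence`, so runs are bit
reproducible for a given seed; all-zero series are legal input and the
posterior rate simply concentrates low.

## Synthetic data

The count generator is the forward model itself (t-driven latent
autoregression, gamma-Poisson mixture for the NegBin), so simulate-and-refit
studies have exact ground truth. The bursty reference regime used throughout
validation is ρ = 0.9, σ = 0.4–0.5, ν = 4–5, φ = 0.5–0.6 — strong
autocorrelation, heavy-tailed rate jumps, strong overdispersion. The Poisson
limit is reached with large finite φ (no separate code path).

The trajectory generator produces kinematic fixtures, not physics: molecules
jitter in bulk bands that never touch the slab, and each scheduled crossing
is carved in explicitly (inside the slab one frame before the completing
frame, emerging on the far side at it). Optional periodic-image wraps
teleport a molecule across the box (|Δz| ≈ box_z, always > box_z/2).
Because every traversal and wrap is constructed, the counter can be tested
for *exact* agreement with the schedule and with an independent brute-force
replay. What these fixtures do not emulate: boundary re-crossing jitter at
realistic densities, correlated water motion, slab breathing, incomplete
traversals trapped inside the membrane. Passing tests therefore establish
the counting logic, not robustness to every artifact of real MD output —
though boundary jitter is specifically covered by the hysteresis design and
random-walk comparisons against the replay oracle.

Anchored flow emulations ("monomer-like" at 0.07 counts/window = 7
molecules/ns, "dimer-like" at 0.37 = 37 molecules/ns) hold the latent level
constant (ρ = 1, σ = 0) with φ = 0.5 overdispersion. Within this generative
family that is the only way to pin the time-averaged flow: any |ρ| < 1
autoregression reverts toward 0 log-rate (1 count/window) and a ρ = 1 random
walk drifts arbitrarily far from its anchor over thousands of windows.

## Validation studies and problem sizes

* Counter equivalence: 100 random trajectories (up to ~120 molecules × 600
  frames, with wraps on a third of them) against the schedule and the
  brute-force replay — exact, window-by-window.
* NegBin closed form: grid y ≤ 50, μ ∈ [0.01, 50], φ ∈ [0.1, 100] against
  `scipy.stats.nbinom` (agreement to 1e-10) and the Poisson limit at
  φ = 1e8 (1e-5).
* Parameter recovery: 20 simulate-and-refit replicates (10 in the quicker
  `scripts/acceptance.py` variant) at n = 2000 windows,
  4 chains × 500 draws after 500 warmup, depth cap 8 — the package's
  reduced-budget study configuration (the library default of 1000 warmup is
  unchanged). Central 95% intervals are expected to cover ρ, σ, φ in at
  least 16 of 20 replicates. σ sits closest to that line: σ and ν trade off
  (a larger ν means thinner-tailed innovations, forcing σ up to explain the
  same spread), ν is weakly identified through the NegBin observation
  noise, and its prior mass at larger values leans on σ — so σ's marginal
  coverage runs a few points below nominal at this n. That is a property of
  the stated model and priors, not of the sampler; the quadrature check
  below is the sampler-correctness control.
* Quadrature cross-check: the 1-D conditional posterior of ρ (latent path,
  σ, ν fixed at truth, n = 20) from the sampler against direct numerical
  integration, agreement in posterior mean within 0.05.
* Overdispersion diagnostic: Poisson input must look Poisson (dispersion
  index and tail-mass ratio within Monte-Carlo error of 1); bursty-generator
  input must have tail-mass ratio > 1. The tail-mass ratio — observed
  P(Y ≥ k*) over Poisson P(Y ≥ k*) at the Poisson 99th-percentile threshold
  k* — is this package's quantitative form of "heavier-tailed than Poisson";
  the threshold quantile is configurable, and both pmf and survival-function
  forms are reported. The matched Poisson mean is the sample mean of the
  counts; when posterior draws are supplied the posterior flow is reported
  alongside.

## Known limitations

* No ion or lipid flip-flop counting, no free-energy or diffusivity
  estimation, no pore-geometry analysis.
* The sampler implements the stated priors only; non-default `PriorSpec`
  values are supported for density evaluation but not sampling (the jitted
  kernels carry the prior constants).
* E[φ] does not exist under the HalfCauchy-on-1/φ prior tail; posterior
  summaries for φ use quantiles.
* Fitting very long series (10⁴ windows) with near-zero σ is slow (funnel
  geometry); the analysis drivers fit a 2000-window segment by default.
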