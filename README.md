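# memflux

Membrane water-permeation analysis for molecular-dynamics trajectories:
count water molecules crossing a lipid bilayer per observation window, then
infer the underlying — typically *bursty* — flow rate with a Bayesian
autoregressive latent-rate model.

Antimicrobial peptides and other membrane-active proteins (the motivating
systems are saposin-like domains that form water channels in phospholipid
bilayers) induce permeability that is irregular in time: water passes in
bursts separated by quiescent stretches. A raw average flux hides this;
`memflux` models it. For each observation window *i* (default 10 ps, one per
saved frame) the transition count Yᵢ is modelled as

    λᵢ ~ t_ν(ρ·λᵢ₋₁, σ)            latent log rate, heavy-tailed drift
    Yᵢ ~ NegBin(exp(λᵢ), φ)         overdispersed counts, Var = μ + μ²/φ

with weakly informative priors (1/φ ~ HalfCauchy(0,5), σ ~ HalfCauchy(0,5),
ν ~ Gamma(2, 0.1), ρ ~ Normal(0,1), λ₁ ~ Cauchy(0,5)). Posterior inference
runs four No-U-Turn HMC chains with hand-derived gradients (numba-jitted);
burstiness is additionally quantified by comparing the marginal count
distribution against a Poisson with the same expectation. See
`docs/methods.md` for the full model account.

## What's in the box

- `src/memflux/counting.py` — slab definition, leaflet-based slab inference,
  and the windowed three-state crossing counter (periodic-image aware).
- `src/memflux/model.py`, `nuts.py`, `_kernels.py` — the latent-rate model,
  an in-package NUTS sampler, and jitted log-posterior/gradient kernels.
- `src/memflux/diagnostics.py` — marginal-versus-Poisson comparison
  (dispersion index, tail-mass ratio) and plots.
- `src/memflux/synthetic.py` — generators for count series with known
  parameters and kinematic membrane trajectories with known crossing
  schedules.
- `src/memflux/mdio.py` — standard MD formats (PDB/PSF + DCD/XTC, anything
  MDAnalysis opens) to water/lipid z-coordinates.
- `analysis/01–04_*.py` — the narrative pipeline over synthetic data:
  simulate, count, fit, diagnose; outputs under `results/`.
- `memflux` CLI — `simulate`, `count`, `fit`, `diagnose`, `run` subcommands.

## Worked example

Generate a bursty synthetic series anchored at 0.37 expected crossings per
10 ps window (i.e. 37 molecules/ns, the "dimer-like" regime), fit it, and
check burstiness:

```sh
python analysis/01_simulate_flux_data.py
python analysis/02_count_crossings.py
python analysis/03_fit_latent_rates.py
python analysis/04_burstiness_diagnostics.py
```

prints (seeds fixed in the scripts):

```
monomer_like: 714 crossings over 10000 windows (7.1 molecules/ns empirical) -> monomer_like_counts.csv
dimer_like: 3596 crossings over 10000 windows (36.0 molecules/ns empirical) -> dimer_like_counts.csv
toy trajectory: 35 scheduled crossings, 2 image wraps -> toy_trajectory.tsv
counted 35 crossings (17 down, 18 up) over 999 windows
schedule ground truth: 35 -> counter matches
monomer_like: flow 7.5 molecules/ns (posterior medians rho=1.000, sigma=0.010, nu=31.0, phi=0.289)
dimer_like: flow 38.6 molecules/ns (posterior medians rho=1.000, sigma=0.004, nu=17.6, phi=0.577)
monomer_like: dispersion index 1.16, tail-mass ratio 2.7 at k*=2 (observed tail 0.0065 vs Poisson 2.43e-03)
dimer_like: dispersion index 1.67, tail-mass ratio 4.3 at k*=3 (observed tail 0.0258 vs Poisson 5.93e-03)
```

Reading this: the counter reproduces the scheduled ground truth exactly and
refuses to count periodic-image wraps; the fitted posterior recovers the
anchored flow levels (7 and 37 molecules/ns) with a constant latent rate
(σ → 0) and the negative-binomial overdispersion carrying the burstiness;
and both series are heavier-tailed than a Poisson
with the same mean (tail-mass ratio ≫ 1) — the signature of bursty
transport. The same `fit`/`diagnose` stages run unchanged on counts produced
from real MD output via `memflux count --traj traj.dcd --top system.psf ...`.

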