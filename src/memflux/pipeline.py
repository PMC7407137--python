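"""End-to-end orchestration: simulate -> count -> fit -> diagnose.

Each stage reads the previous stage's files, so ``fit`` on a counts CSV is
independent of whether the counts came from MD output or the synthetic
generator. A manifest (JSON) recording the configuration, stage seeds, wall
times and every output path is written into the output directory; a rerun
from the same manifest reproduces the outputs. All randomness flows from a
single root seed, split per stage with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .counting import MembraneSlab, count_crossings
from .diagnostics import compare_to_poisson, plot_marginal_comparison, plot_rate_function
from .io import read_count_series, read_trajectory_tsv, write_count_series
from .model import PosteriorDraws, sample_posterior, summarize_rates
from .synthetic import GeneratorConfig, simulate_count_series

logger = logging.getLogger("memflux")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

_STAGES = ("simulate", "count", "fit", "diagnose")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2^31)."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(idx,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Configuration of a pipeline run.

    ``stages`` selects which stages run, in canonical order. ``counts_path``
    / ``trajectory_path`` point at existing inputs when the producing stage
    is not selected.
    """

    out_dir: str
    stages: Sequence[str] = ("simulate", "fit", "diagnose")
    seed: int = 0
    window_ps: float = 10.0
    # simulate stage
    generator: Optional[GeneratorConfig] = None
    # count stage
    trajectory_path: Optional[str] = None
    z_lower: Optional[float] = None
    z_upper: Optional[float] = None
    box_z: Optional[float] = None
    # fit stage
    counts_path: Optional[str] = None
    n_chains: int = 4
    n_draws: int = 2000
    n_warmup: int = 1000
    rhat_action: str = "raise"
    # diagnose stage
    tail_threshold_quantile: float = 0.99
    make_plots: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in _STAGES if s in self.stages)
        if not self.stages:
            raise ValueError("no stages selected")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the selected stages; returns the manifest dict.

    A stage failure halts the pipeline: the manifest is still written, with
    ``complete: false`` and the failing stage named, and the exception is
    re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "memflux_version": __version__,
        "config": _config_dict(config),
        "root_seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "stages_run": [],
        "outputs": {},
        "complete": False,
    }
    counts_path = Path(config.counts_path) if config.counts_path else None
    traj_path = Path(config.trajectory_path) if config.trajectory_path else None
    draws: Optional[PosteriorDraws] = None

    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            sseed = manifest["stage_seeds"][stage]
            logger.info("stage %s starting (seed %d)", stage, sseed)

            if stage == "simulate":
                gen = config.generator or GeneratorConfig()
                gen = GeneratorConfig(**{**asdict(gen), "seed": sseed, "window_ps": config.window_ps})
                sim = simulate_count_series(gen)
                counts_path = out / "counts.csv"
                write_count_series(
                    sim.series,
                    counts_path,
                    seed=sseed,
                    extra={
                        "true_params": {
                            "rho": gen.rho, "sigma": gen.sigma, "nu": gen.nu,
                            "phi": gen.phi, "lambda1": gen.lambda1,
                        },
                        "latent_log_rate": sim.latent_log_rate,
                    },
                )
                manifest["outputs"]["counts"] = str(counts_path)

            elif stage == "count":
                if traj_path is None or not traj_path.exists():
                    raise FileNotFoundError(f"trajectory input not found: {traj_path}")
                traj, slab = read_trajectory_tsv(traj_path)
                if config.z_lower is not None and config.z_upper is not None:
                    slab = MembraneSlab(z_lower=config.z_lower, z_upper=config.z_upper)
                if slab is None:
                    raise ValueError(
                        "no slab available: give z_lower/z_upper or a trajectory "
                        "sidecar with slab bounds"
                    )
                if config.box_z is not None:
                    traj.box_z = config.box_z
                series = count_crossings(traj, slab, window_ps=config.window_ps)
                counts_path = out / "counts.csv"
                write_count_series(series, counts_path, seed=None)
                manifest["outputs"]["counts"] = str(counts_path)

            elif stage == "fit":
                if counts_path is None or not counts_path.exists():
                    raise FileNotFoundError(f"counts input not found: {counts_path}")
                series = read_count_series(counts_path)
                draws = sample_posterior(
                    series,
                    n_chains=config.n_chains,
                    n_draws=config.n_draws,
                    n_warmup=config.n_warmup,
                    seed=sseed,
                    rhat_action=config.rhat_action,
                )
                summary = summarize_rates(draws, series.window_ps)
                _write_posterior(out, draws, summary)
                manifest["outputs"]["posterior"] = str(out / "posterior.csv")
                manifest["outputs"]["posterior_summary"] = str(out / "posterior_summary.json")
                if config.make_plots:
                    plot_rate_function(summary, out / "rate_function.png")
                    manifest["outputs"]["rate_plot"] = str(out / "rate_function.png")

            elif stage == "diagnose":
                if counts_path is None or not counts_path.exists():
                    raise FileNotFoundError(f"counts input not found: {counts_path}")
                series = read_count_series(counts_path)
                comp = compare_to_poisson(
                    series, tail_threshold_quantile=config.tail_threshold_quantile
                )
                report = comp.to_dict()
                if draws is not None:
                    summary = summarize_rates(draws, series.window_ps)
                    report["posterior_median_flow_per_ns"] = summary["median_flow_per_ns"]
                    report["posterior_mean_flow_per_ns"] = summary["mean_flow_per_ns"]
                (out / "diagnostics.json").write_text(json.dumps(report, indent=1))
                manifest["outputs"]["diagnostics"] = str(out / "diagnostics.json")
                if config.make_plots:
                    plot_marginal_comparison(comp, out / "marginal_vs_poisson.png")
                    manifest["outputs"]["marginal_plot"] = str(out / "marginal_vs_poisson.png")

            dt = time.perf_counter() - t0
            logger.info("stage %s done in %.2f s", stage, dt)
            manifest["stages_run"].append({"stage": stage, "seconds": round(dt, 3)})

        manifest["complete"] = True
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["stages"] = list(config.stages)
    return d


def _write_posterior(out: Path, draws: PosteriorDraws, summary: dict) -> None:
    import pandas as pd

    rows = []
    for name, arr in draws.scalars.items():
        n_chains, n_draws = arr.shape
        for c in range(n_chains):
            rows.append(
                pd.DataFrame(
                    {
                        "chain": c,
                        "draw": np.arange(n_draws),
                        "parameter": name,
                        "value": arr[c],
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(out / "posterior.csv", index=False)
    js = {
        "diagnostics": draws.diagnostics,
        "n_chains": draws.n_chains,
        "n_draws": draws.n_draws,
        "n_divergent": draws.n_divergent,
        "seed": draws.seed,
        "median_flow_per_ns": summary["median_flow_per_ns"],
        "mean_flow_per_ns": summary["mean_flow_per_ns"],
        "window_ps": summary["window_ps"],
        "flow_quantiles": {
            "q2.5": np.asarray(summary["q2.5"]).tolist(),
            "median": np.asarray(summary["median"]).tolist(),
            "q97.5": np.asarray(summary["q97.5"]).tolist(),
        },
        "scalar_posterior_medians": {
            k: float(np.median(v)) for k, v in draws.scalars.items()
        },
    }
    (out / "posterior_summary.json").write_text(json.dumps(js, indent=1))
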