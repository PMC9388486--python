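"""Scripted in-silico studies: the default time course and the four
sensitivity experiments (injection interval, injection count, initial
Kupffer ratio, initial stellate ratio), each run over an ensemble of seeds
with per-seed tables retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import metrics
from .config import SimulationConfig, default_config
from .engine import RunResult, run

DEFAULT_SEEDS = (1, 2, 3, 4, 5)
KC_SWEEP_RATIOS = (0.0015, 0.07, 0.15, 0.40)
HSC_SWEEP_RATIOS = (0.01, 0.05, 0.15, 0.35)
INTERVALS = (6, 10, 14, 18)


@dataclass
class SweepSpec:
    parameter: str
    values: tuple
    seeds: tuple[int, ...] = DEFAULT_SEEDS
    horizon: int = 120
    base_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("sweep needs at least one value")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")

    def configs(self) -> list[tuple[object, int, SimulationConfig]]:
        out = []
        for v in self.values:
            for s in self.seeds:
                cfg = default_config(
                    **{self.parameter: v, "seed": s, "n_steps": self.horizon},
                    **self.base_overrides,
                )
                out.append((v, s, cfg))
        return out


@dataclass
class ExperimentResult:
    timecourses: pd.DataFrame  # tidy long format: seed, step, variable, value
    summary: pd.DataFrame
    manifest: dict


def _ensemble(configs: list[tuple[object, int, SimulationConfig]]) -> dict:
    runs: dict[tuple[object, int], RunResult] = {}
    for value, seed, cfg in configs:
        runs[(value, seed)] = run(cfg)
    return runs


def exp_timecourse(
    seeds: tuple[int, ...] = DEFAULT_SEEDS, n_steps: int = 120, **overrides
) -> ExperimentResult:
    """Default-run time courses of every agent class and mediator."""
    runs = _ensemble(
        [(None, s, default_config(seed=s, n_steps=n_steps, **overrides)) for s in seeds]
    )
    tables = {seed: r.timecourse for (_, seed), r in runs.items()}
    tidy = metrics.tidy_timecourses(tables)
    rows = []
    for seed, tc in tables.items():
        rows.append(
            {
                "seed": seed,
                "tnfa_peak_step": metrics.peak_step(tc["tnfa_total"]),
                "kc_activation_step": metrics.onset_step(tc["kc_activated"], 0.0),
                "collagen_mfb_onset": metrics.onset_step(tc["collagen_mfb"]),
                "collagen_pf_onset": metrics.onset_step(tc["collagen_pf"]),
                "dead_cell_period": metrics.dominant_period(tc["dead_total"]),
                "final_collagen": tc["collagen_total"].iloc[-1],
            }
        )
    summary = pd.DataFrame(rows)
    manifest = {"seeds": list(seeds), "n_steps": n_steps, "overrides": overrides}
    return ExperimentResult(tidy, summary, manifest)


def exp_interval_sweep(
    intervals: tuple[int, ...] = INTERVALS,
    seeds: tuple[int, ...] = DEFAULT_SEEDS,
    horizon: int = 120,
    **overrides,
) -> ExperimentResult:
    """Collagen accumulation under different injection intervals, same dose."""
    spec = SweepSpec("interval", intervals, seeds, horizon, overrides)
    runs = _ensemble(spec.configs())
    frames, rows = [], []
    for (interval, seed), r in runs.items():
        tc = r.timecourse
        sub = tc[["step", "collagen_total", "collagen_mfb", "collagen_pf"]].copy()
        sub.insert(0, "seed", seed)
        sub.insert(0, "interval", interval)
        frames.append(sub)
        rows.append(
            {
                "interval": interval,
                "seed": seed,
                "endpoint_collagen": tc["collagen_total"].iloc[-1],
            }
        )
    tidy = pd.concat(frames, ignore_index=True)
    summary = (
        pd.DataFrame(rows)
        .groupby("interval", as_index=False)["endpoint_collagen"]
        .mean()
    )
    manifest = {
        "intervals": list(intervals),
        "seeds": list(seeds),
        "horizon": horizon,
        "overrides": overrides,
    }
    return ExperimentResult(tidy, summary, manifest)


def exp_injection_count(
    seeds: tuple[int, ...] = DEFAULT_SEEDS, horizon: int = 100, **overrides
) -> ExperimentResult:
    """Paired comparison of 2 versus 3 toxin injections at a 10-step
    interval (injections at steps 0,10 versus 0,10,20), horizon 100."""
    frames, rows = [], []
    for n_inj in (2, 3):
        for seed in seeds:
            cfg = default_config(seed=seed, n_steps=horizon, **overrides)
            cfg.schedule.n_injections = n_inj
            r = run(cfg)
            tc = r.timecourse
            sub = tc[
                ["step", "dead_total", "collagen_total", "tnfa_total"]
            ].copy()
            sub.insert(0, "seed", seed)
            sub.insert(0, "n_injections", n_inj)
            frames.append(sub)
            rows.append(
                {
                    "n_injections": n_inj,
                    "seed": seed,
                    "last_dead_step": metrics.last_positive_step(tc["dead_total"]),
                    "dead_surge_step": metrics.largest_increase_step(
                        tc["dead_total"], after=12
                    ),
                    "endpoint_collagen": tc["collagen_total"].iloc[-1],
                }
            )
    tidy = pd.concat(frames, ignore_index=True)
    summary = pd.DataFrame(rows)
    manifest = {"seeds": list(seeds), "horizon": horizon, "overrides": overrides}
    return ExperimentResult(tidy, summary, manifest)


def _ratio_sweep(
    parameter: str,
    ratios: tuple[float, ...],
    seeds: tuple[int, ...],
    horizon: int,
    overrides: dict,
) -> ExperimentResult:
    spec = SweepSpec(parameter, ratios, seeds, horizon, overrides)
    runs = _ensemble(spec.configs())
    frames, rows = [], []
    for (ratio, seed), r in runs.items():
        tc = r.timecourse
        sub = tc[
            ["step", "dead_total", "collagen_total", "collagen_mfb", "collagen_pf", "blank"]
        ].copy()
        sub.insert(0, "seed", seed)
        sub.insert(0, "ratio", ratio)
        frames.append(sub)
        rows.append(
            {
                "ratio": ratio,
                "seed": seed,
                "endpoint_blank": tc["blank"].iloc[-1],
                "endpoint_collagen_mfb": tc["collagen_mfb"].iloc[-1],
                "endpoint_collagen_pf": tc["collagen_pf"].iloc[-1],
                "collagen_onset": metrics.onset_step(tc["collagen_total"]),
                "dead_at_40": tc["dead_total"].iloc[min(40, horizon)],
            }
        )
    tidy = pd.concat(frames, ignore_index=True)
    summary = pd.DataFrame(rows)
    manifest = {
        "parameter": parameter,
        "ratios": list(ratios),
        "seeds": list(seeds),
        "horizon": horizon,
        "overrides": overrides,
    }
    return ExperimentResult(tidy, summary, manifest)


def exp_kc_sweep(
    ratios: tuple[float, ...] = KC_SWEEP_RATIOS,
    seeds: tuple[int, ...] = DEFAULT_SEEDS,
    horizon: int = 100,
    **overrides,
) -> ExperimentResult:
    """Outcomes as a function of the initial Kupffer-cell ratio."""
    return _ratio_sweep("kupffer_ratio", ratios, seeds, horizon, overrides)


def exp_hsc_sweep(
    ratios: tuple[float, ...] = HSC_SWEEP_RATIOS,
    seeds: tuple[int, ...] = DEFAULT_SEEDS,
    horizon: int = 100,
    **overrides,
) -> ExperimentResult:
    """Outcomes as a function of the initial stellate-cell ratio."""
    return _ratio_sweep("hsc_ratio", ratios, seeds, horizon, overrides)
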