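"""Simulation orchestration: initialisation, the per-step rule order,
random-number management, and per-step metric recording.

One step executes, in order:

a. toxin injection (if scheduled);
b. hepatocyte death checks (toxin necrosis takes precedence over
   TNF-alpha apoptosis);
c. HMGB1 release by necrotic dead cells (apoptotic cells release none);
d. Kupffer replenishment at the portal tracts, then every Kupffer cell's
   move/phagocytose/activate/secrete update, in random order;
e. stellate-cell activation checks;
f. collagen secretion by myofibroblasts and portal fibroblasts, in random
   order;
g. hepatocyte proliferation into blank sites, in random order;
h. ageing and lifespan culling;
i. diffusion then decay of all four mediator fields.

Within each phase, threshold decisions read the field values snapshotted
at the start of that phase, so results do not depend on scan order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agents as ag
from .agents import Population
from .config import SimulationConfig
from .dosing import maybe_inject
from .fields import DiffusibleField
from .lattice import DEAD_NECROTIC, LobuleGrid, build_lobule


@dataclass
class SimulationState:
    step: int
    grid: LobuleGrid
    fields: dict[str, DiffusibleField]
    population: Population
    rng: np.random.Generator
    config: SimulationConfig
    hmgb1_deposited: float = 0.0  # cumulative, for conservation checks
    records: list[dict] = field(default_factory=list)


def initialize(config: SimulationConfig) -> SimulationState:
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid, population = build_lobule(config, rng)
    shape = (grid.height, grid.width)
    fields_ = {
        name: DiffusibleField(name, shape, fc.share_fraction, fc.decay_rate)
        for name, fc in config.fields.items()
    }
    state = SimulationState(
        step=0,
        grid=grid,
        fields=fields_,
        population=population,
        rng=rng,
        config=config,
    )
    state.records.append(record_metrics(state))
    return state


def record_metrics(state: SimulationState) -> dict:
    grid = state.grid
    counts = grid.counts()
    pop = state.population.counts()
    return {
        "step": state.step,
        "hepatocytes": counts["hepatocyte"],
        "dead_necrotic": counts["dead_necrotic"],
        "dead_apoptotic": counts["dead_apoptotic"],
        "dead_total": counts["dead_necrotic"] + counts["dead_apoptotic"],
        "kc_quiescent": pop["kc_quiescent"],
        "kc_m1": pop["kc_m1"],
        "kc_m2": pop["kc_m2"],
        "kc_activated": pop["kc_m1"] + pop["kc_m2"],
        "hsc": pop["hsc"],
        "myofibroblasts": pop["myofibroblast"],
        "portal_fibroblasts": pop["portal_fibroblast"],
        "collagen_mfb": counts["collagen_mfb"],
        "collagen_pf": counts["collagen_pf"],
        "collagen_total": counts["collagen_mfb"] + counts["collagen_pf"],
        "blank": counts["blank"],
        "ccl4_total": state.fields["CCl4"].total(),
        "hmgb1_total": state.fields["HMGB1"].total(),
        "tnfa_total": state.fields["TNFa"].total(),
        "tgfb_total": state.fields["TGFb"].total(),
    }


def step(state: SimulationState) -> SimulationState:
    """Advance the simulation by one step (in place; returns the state)."""
    grid = state.grid
    rng = state.rng
    params = state.config.agents
    pop = state.population
    ccl4 = state.fields["CCl4"]
    hmgb1 = state.fields["HMGB1"]
    tnfa = state.fields["TNFa"]
    tgfb = state.fields["TGFb"]

    # (a) toxin injection
    maybe_inject(state.step, state.config.schedule, ccl4, grid)

    # (b) hepatocyte death checks (phase-start field snapshot)
    necro, apo = ag.death_masks(grid, ccl4.values, tnfa.values, params)
    ag.apply_deaths(grid, necro, apo)

    # (c) HMGB1 release from necrotic dead cells only
    necrotic_now = grid.occupancy == DEAD_NECROTIC
    if params.hmgb1_secretion > 0 and necrotic_now.any():
        amounts = necrotic_now * params.hmgb1_secretion
        hmgb1.deposit_array(amounts)
        state.hmgb1_deposited += float(amounts.sum())

    # (d) Kupffer replenishment and updates, random order
    ag.kupffer_replenish(grid, pop, params.kc_replenish_rate, rng)
    hmgb1_snap = hmgb1.values.copy()
    order = rng.permutation(len(pop.kupffer))
    for i in order:
        ag.kupffer_step(pop.kupffer[i], grid, hmgb1_snap, tnfa, tgfb, rng, params)

    # (e) stellate-cell activation (phase-start TNF snapshot)
    tnfa_snap = tnfa.values
    remaining_hscs = []
    for hsc in pop.hscs:
        mfb = ag.hsc_activation(hsc, tnfa_snap, params)
        if mfb is None:
            remaining_hscs.append(hsc)
        else:
            pop.myofibroblasts.append(mfb)
    pop.hscs = remaining_hscs

    # (f) collagen secretion, random order over all fibroblasts
    tgfb_snap = tgfb.values.copy()
    fibs: list = list(pop.myofibroblasts) + list(pop.portal_fibroblasts)
    order = rng.permutation(len(fibs))
    spent: set[int] = set()
    for i in order:
        fib = fibs[i]
        ag.fibroblast_secrete(fib, grid, tgfb_snap, rng, params)
        if (
            isinstance(fib, ag.Myofibroblast)
            and fib.collagens_produced >= params.max_collagen_per_mfb
        ):
            spent.add(id(fib))
    if spent:
        pop.myofibroblasts = [m for m in pop.myofibroblasts if id(m) not in spent]

    # (g) hepatocyte proliferation
    ag.proliferation_phase(grid, rng, params)

    # (h) ageing and culling
    ag.age_and_cull(grid, pop, params)

    # (i) diffusion then decay, every field
    for f in state.fields.values():
        f.diffuse()
        f.decay()

    state.step += 1
    state.records.append(record_metrics(state))
    return state


@dataclass
class RunResult:
    config: SimulationConfig
    timecourse: pd.DataFrame
    snapshots: dict[int, np.ndarray]
    final_grid: LobuleGrid
    hmgb1_deposited: float

    def manifest(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "n_steps": int(self.timecourse["step"].max()),
            "seed": self.config.seed,
        }


def run(config: SimulationConfig, progress: bool = False) -> RunResult:
    """Run ``config.n_steps`` steps and collect the per-step time course.

    Snapshots (copies of the occupancy layer) are taken at the requested
    ``snapshot_steps``, including step 0.
    """
    state = initialize(config)
    snapshots: dict[int, np.ndarray] = {}
    want = set(config.snapshot_steps)
    if 0 in want:
        snapshots[0] = state.grid.occupancy.copy()
    iterator = range(config.n_steps)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="simulate")
    for _ in iterator:
        step(state)
        if state.step in want:
            snapshots[state.step] = state.grid.occupancy.copy()
    tc = pd.DataFrame(state.records)
    return RunResult(
        config=config,
        timecourse=tc,
        snapshots=snapshots,
        final_grid=state.grid,
        hmgb1_deposited=state.hmgb1_deposited,
    )
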