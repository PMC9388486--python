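"""Agent classes and their update rules.

Space-occupying agents (hepatocytes, dead cells, collagen, structures) live
in the grid's occupancy layer and are stored as per-site codes with
per-site age/cooldown arrays.  Non-occupying cells are Python objects:

* Kupffer cells random-walk, phagocytose dead cells, and carry the
  quiescent -> M1 -> M2 activation program (M1 secretes TNF-alpha, M2
  secretes TGF-beta).
* Hepatic stellate cells (HSC) are sessile and transform in place into
  myofibroblasts when local TNF-alpha exceeds a threshold.
* Myofibroblasts and portal fibroblasts are sessile collagen producers;
  a myofibroblast is removed after producing its quota of deposits, a
  portal fibroblast persists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

from .lattice import (
    COLLAGEN_MFB,
    COLLAGEN_PF,
    DEAD_APOPTOTIC,
    DEAD_CODES,
    DEAD_NECROTIC,
    DIAGONAL_OFFSETS,
    EMPTY,
    HEPATOCYTE,
    MOORE_OFFSETS,
    ORTHOGONAL_OFFSETS,
    LobuleGrid,
    Position,
)

# Kupffer phenotypes
QUIESCENT = 0
M1 = 1
M2 = 2


@dataclass(slots=True)
class KupfferCell:
    row: int
    col: int
    state: int = QUIESCENT
    age: int = 0
    steps_since_activation: int = -1  # defined (>= 0) once activated


@dataclass(slots=True)
class HSC:
    row: int
    col: int
    age: int = 0


@dataclass(slots=True)
class Myofibroblast:
    row: int
    col: int
    age: int = 0
    collagens_produced: int = 0


@dataclass(slots=True)
class PortalFibroblast:
    row: int
    col: int
    age: int = 0


@dataclass
class Population:
    """All non-occupying agents of a simulation."""

    kupffer: list[KupfferCell]
    hscs: list[HSC]
    myofibroblasts: list[Myofibroblast]
    portal_fibroblasts: list[PortalFibroblast]

    def counts(self) -> dict[str, int]:
        kc_q = sum(1 for k in self.kupffer if k.state == QUIESCENT)
        kc_m1 = sum(1 for k in self.kupffer if k.state == M1)
        kc_m2 = sum(1 for k in self.kupffer if k.state == M2)
        return {
            "kc_quiescent": kc_q,
            "kc_m1": kc_m1,
            "kc_m2": kc_m2,
            "hsc": len(self.hscs),
            "myofibroblast": len(self.myofibroblasts),
            "portal_fibroblast": len(self.portal_fibroblasts),
        }


# ---------------------------------------------------------------------------
# Hepatocyte rules
# ---------------------------------------------------------------------------

def hepatocyte_death_check(pos, ccl4_values, tnfa_values, zonation, params) -> int | None:
    """Death rule for the hepatocyte at ``pos``.

    The toxin acts through its metabolically activated form, so the CCl4
    concentration is weighted by the local zonation factor.  The toxin test
    takes precedence: a cell over both thresholds dies by necrosis.
    Returns DEAD_NECROTIC, DEAD_APOPTOTIC or None.
    """
    if ccl4_values[pos] * zonation[pos] > params.theta_ccl4:
        return DEAD_NECROTIC
    if tnfa_values[pos] > params.theta_tnf_death:
        return DEAD_APOPTOTIC
    return None


def death_masks(grid: LobuleGrid, ccl4_values, tnfa_values, params):
    """Vectorised death rule over all hepatocytes.

    Returns boolean (necrotic, apoptotic) masks; disjoint, necrosis wins.
    """
    hep = grid.occupancy == HEPATOCYTE
    necro = hep & (ccl4_values * grid.zonation > params.theta_ccl4)
    apo = hep & ~necro & (tnfa_values > params.theta_tnf_death)
    return necro, apo


def apply_deaths(grid: LobuleGrid, necro, apo) -> tuple[int, int]:
    """Replace hepatocytes by dead cells in place; returns (n_necro, n_apo)."""
    grid.occupancy[necro] = DEAD_NECROTIC
    grid.occupancy[apo] = DEAD_APOPTOTIC
    fresh = necro | apo
    grid.dead_age[fresh] = 0
    return int(necro.sum()), int(apo.sum())


def collagen_neighbor_counts(grid: LobuleGrid) -> np.ndarray:
    """Number of collagen deposits in each site's Moore neighbourhood."""
    collagen = (
        (grid.occupancy == COLLAGEN_MFB) | (grid.occupancy == COLLAGEN_PF)
    ).astype(float)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    return convolve2d(collagen, kernel, mode="same", boundary="fill")


def hepatocyte_proliferate(
    grid: LobuleGrid,
    pos,
    rng: np.random.Generator,
    params,
    collagen_neighbors: float | None = None,
) -> Position | None:
    """Division rule for the hepatocyte at ``pos``.

    Divides into a uniformly chosen vacant Moore neighbour provided the
    replication cooldown has elapsed and the neighbourhood is not
    collagen-rich; the parent then enters its cooldown.  Returns the child
    position, or None if no division happened.
    """
    if grid.occupancy[pos] != HEPATOCYTE or grid.hep_cooldown[pos] > 0:
        return None
    if collagen_neighbors is None:
        collagen_neighbors = sum(
            1 for q in grid.moore_neighbors(pos)
            if grid.occupancy[q] in (COLLAGEN_MFB, COLLAGEN_PF)
        )
    if collagen_neighbors >= params.collagen_rich_threshold:
        return None
    vacant = grid.vacant_neighbors(pos)
    if not vacant:
        return None
    child = vacant[int(rng.integers(len(vacant)))]
    grid.place(child, HEPATOCYTE)
    grid.hep_cooldown[pos] = params.replication_cooldown
    return child


def proliferation_phase(grid: LobuleGrid, rng: np.random.Generator, params) -> int:
    """Run the division rule for every eligible hepatocyte, in random order.

    Only hepatocytes adjacent to at least one blank site can divide, so the
    scan is restricted to those candidates; the collagen-rich test uses the
    phase-start collagen layout (collagen does not change in this phase).
    """
    occ = grid.occupancy
    blank = occ == EMPTY
    if not blank.any():
        return 0
    kernel = np.ones((3, 3))
    near_blank = convolve2d(blank.astype(float), kernel, mode="same", boundary="fill") > 0
    coll_counts = collagen_neighbor_counts(grid)
    cand = (
        (occ == HEPATOCYTE)
        & (grid.hep_cooldown == 0)
        & near_blank
        & (coll_counts < params.collagen_rich_threshold)
    )
    idx = np.argwhere(cand)
    if len(idx) == 0:
        return 0
    rng.shuffle(idx)
    h, w = grid.height, grid.width
    births = 0
    for r, c in idx:
        r, c = int(r), int(c)
        vac = [
            (r + dr, c + dc)
            for dr, dc in MOORE_OFFSETS
            if 0 <= r + dr < h and 0 <= c + dc < w and occ[r + dr, c + dc] == EMPTY
        ]
        if not vac:
            continue
        child = vac[int(rng.integers(len(vac)))]
        grid.place(child, HEPATOCYTE)
        grid.hep_cooldown[r, c] = params.replication_cooldown
        births += 1
    return births


# ---------------------------------------------------------------------------
# Kupffer-cell rules
# ---------------------------------------------------------------------------

def kupffer_step(
    kc: KupfferCell,
    grid: LobuleGrid,
    hmgb1_snapshot: np.ndarray,
    tnfa_field,
    tgfb_field,
    rng: np.random.Generator,
    params,
) -> None:
    """One update of a Kupffer cell.

    (i) undirected move to a random in-bounds Moore neighbour;
    (ii) phagocytose a co-located dead cell (frees the space; a quiescent
    cell is thereby activated to M1); (iii) quiescent cells are also
    activated by local HMGB1 above threshold; (iv) M1 secretes TNF-alpha
    and switches to M2 once tau_m1m2 steps have passed since activation;
    (v) M2 secretes TGF-beta.
    """
    h, w = grid.height, grid.width
    r, c = kc.row, kc.col
    neigh = [
        (r + dr, c + dc)
        for dr, dc in MOORE_OFFSETS
        if 0 <= r + dr < h and 0 <= c + dc < w
    ]
    r, c = neigh[int(rng.integers(len(neigh)))]
    kc.row, kc.col = r, c

    activated_now = False
    occ = int(grid.occupancy[r, c])
    if occ in DEAD_CODES:
        grid.remove((r, c))
        if kc.state == QUIESCENT:
            kc.state = M1
            kc.steps_since_activation = 0
            activated_now = True
    if kc.state == QUIESCENT and hmgb1_snapshot[r, c] > params.theta_hmgb1:
        kc.state = M1
        kc.steps_since_activation = 0
        activated_now = True

    if kc.state != QUIESCENT and not activated_now:
        kc.steps_since_activation += 1
        if kc.state == M1 and kc.steps_since_activation >= params.tau_m1m2:
            kc.state = M2

    if kc.state == M1:
        tnfa_field.deposit((r, c), params.tnf_secretion)
    elif kc.state == M2:
        tgfb_field.deposit((r, c), params.tgf_secretion)


def kupffer_replenish(
    grid: LobuleGrid,
    population: Population,
    rate: float,
    rng: np.random.Generator,
) -> int:
    """Recruit new quiescent Kupffer cells at the portal tracts.

    With probability ``rate`` per tract per step one quiescent cell appears
    on a uniformly chosen site of that tract (macrophages recruited from
    circulating blood enter the lobule at the portal field).
    """
    n_new = 0
    for tract in grid.portal_tracts:
        if rate >= 1.0 or rng.random() < rate:
            pos = tract[int(rng.integers(len(tract)))]
            population.kupffer.append(KupfferCell(pos[0], pos[1]))
            n_new += 1
    return n_new


# ---------------------------------------------------------------------------
# Stellate-cell and fibroblast rules
# ---------------------------------------------------------------------------

def hsc_activation(hsc: HSC, tnfa_values, params) -> Myofibroblast | None:
    """Transform the stellate cell into a myofibroblast if local TNF-alpha
    exceeds the activation threshold.  The myofibroblast inherits the
    position (neither cell ever moves) and starts at age 0."""
    if tnfa_values[hsc.row, hsc.col] > params.theta_tnf_hsc:
        return Myofibroblast(hsc.row, hsc.col)
    return None


def _collagen_site(grid: LobuleGrid, pos, rng: np.random.Generator):
    """Nearest vacant site for a new deposit: the producer's own site if
    vacant, else a random vacant orthogonal neighbour, else a random vacant
    diagonal neighbour, else None."""
    if grid.occupancy[pos] == EMPTY:
        return pos
    h, w = grid.height, grid.width
    r, c = pos
    for ring in (ORTHOGONAL_OFFSETS, DIAGONAL_OFFSETS):
        vac = [
            (r + dr, c + dc)
            for dr, dc in ring
            if 0 <= r + dr < h and 0 <= c + dc < w
            and grid.occupancy[r + dr, c + dc] == EMPTY
        ]
        if vac:
            return vac[int(rng.integers(len(vac)))]
    return None


def fibroblast_secrete(
    fib,
    grid: LobuleGrid,
    tgfb_values,
    rng: np.random.Generator,
    params,
) -> bool:
    """Collagen-secretion rule for a myofibroblast or portal fibroblast.

    If local TGF-beta exceeds the threshold and a vacant site exists at or
    around the producer, one origin-tagged collagen deposit is placed in
    the nearest vacant site.  A myofibroblast is spent after
    ``max_collagen_per_mfb`` deposits (it dies upon collagen production);
    portal fibroblasts persist.  Returns True iff a deposit was placed.
    """
    pos = (fib.row, fib.col)
    if tgfb_values[pos] <= params.theta_tgf:
        return False
    site = _collagen_site(grid, pos, rng)
    if site is None:
        return False
    if isinstance(fib, Myofibroblast):
        grid.place(site, COLLAGEN_MFB)
        fib.collagens_produced += 1
    else:
        grid.place(site, COLLAGEN_PF)
    return True


# ---------------------------------------------------------------------------
# Ageing
# ---------------------------------------------------------------------------

def age_and_cull(grid: LobuleGrid, population: Population, params) -> None:
    """Advance every agent's age and remove those at/above their lifespan.

    Space-occupying agents leave blank sites behind.  Collagen deposits are
    permanent (no fibrosis regression is modelled).  The hepatocyte
    replication cooldown also ticks down here.
    """
    hep = grid.occupancy == HEPATOCYTE
    grid.hep_age[hep] += 1
    np.maximum(grid.hep_cooldown - 1, 0, out=grid.hep_cooldown)
    if params.hepatocyte_lifespan is not None:
        expired = hep & (grid.hep_age >= params.hepatocyte_lifespan)
        grid.occupancy[expired] = EMPTY

    dead = (grid.occupancy == DEAD_NECROTIC) | (grid.occupancy == DEAD_APOPTOTIC)
    grid.dead_age[dead] += 1
    if params.dead_cell_lifespan is not None:
        expired = dead & (grid.dead_age >= params.dead_cell_lifespan)
        grid.occupancy[expired] = EMPTY

    def _survivors(agents, lifespan):
        for a in agents:
            a.age += 1
        if lifespan is None:
            return agents
        return [a for a in agents if a.age < lifespan]

    population.kupffer = _survivors(population.kupffer, params.kupffer_lifespan)
    population.hscs = _survivors(population.hscs, params.hsc_lifespan)
    population.myofibroblasts = _survivors(
        population.myofibroblasts, params.myofibroblast_lifespan
    )
    population.portal_fibroblasts = _survivors(
        population.portal_fibroblasts, params.portal_fibroblast_lifespan
    )
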