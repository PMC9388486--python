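"""Lobule geometry and the exclusive-occupancy layer.

The simulated tissue is a rectangular lattice representing a section of a
liver lobule: one central vein in the middle, portal tracts at the corners,
and every other site initially filled by a hepatocyte.  Space-occupying
agents (hepatocytes, dead cells, collagen deposits, portal/vein/septa
structures) exclude each other; mesenchymal and immune cells (Kupffer
cells, stellate cells, myofibroblasts, portal fibroblasts) live in a
separate non-occupying layer and may share a site with anything.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np
from scipy import ndimage

# Occupancy-layer codes.  EMPTY means "blank space" in the histological
# sense: no parenchymal cell, no scar, no vascular structure.
EMPTY = 0
HEPATOCYTE = 1
DEAD_NECROTIC = 2
DEAD_APOPTOTIC = 3
COLLAGEN_MFB = 4
COLLAGEN_PF = 5
PORTAL = 6
VEIN = 7
SEPTA = 8

DEAD_CODES = (DEAD_NECROTIC, DEAD_APOPTOTIC)
COLLAGEN_CODES = (COLLAGEN_MFB, COLLAGEN_PF)
STRUCTURAL_CODES = (PORTAL, VEIN, SEPTA)
OCCUPYING_CODES = (
    HEPATOCYTE,
    DEAD_NECROTIC,
    DEAD_APOPTOTIC,
    COLLAGEN_MFB,
    COLLAGEN_PF,
    PORTAL,
    VEIN,
    SEPTA,
)

CODE_NAMES = {
    EMPTY: "blank",
    HEPATOCYTE: "hepatocyte",
    DEAD_NECROTIC: "dead_necrotic",
    DEAD_APOPTOTIC: "dead_apoptotic",
    COLLAGEN_MFB: "collagen_mfb",
    COLLAGEN_PF: "collagen_pf",
    PORTAL: "portal",
    VEIN: "vein",
    SEPTA: "septa",
}

# Moore neighbourhood offsets, row-major order.
MOORE_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)
# Offsets split by Euclidean distance, for nearest-vacant searches.
ORTHOGONAL_OFFSETS = ((-1, 0), (0, -1), (0, 1), (1, 0))
DIAGONAL_OFFSETS = ((-1, -1), (-1, 1), (1, -1), (1, 1))


class Position(NamedTuple):
    row: int
    col: int


class OccupancyError(ValueError):
    """Raised when a space-occupying agent is placed on an occupied site."""


class ConfigurationError(ValueError):
    """Raised when a configuration violates a structural precondition."""


class LobuleGrid:
    """2-D lobule lattice with an exclusive occupancy layer.

    Parameters
    ----------
    height, width:
        Lattice dimensions in grid cells.
    central_vein_sites, portal_tract_sites:
        Iterables of (row, col) positions of the vascular landmarks.
        The two sets must be disjoint.
    portal_tracts:
        Optional grouping of portal sites into tracts (one group per
        anatomical tract); used by Kupffer-cell replenishment.  If not
        given, connected components of the portal mask are used.
    zonation_lambda:
        Length scale (cells) of the pericentral metabolic-activation
        gradient: weight(d) = exp(-d / lambda) with d the Euclidean
        distance to the nearest central-vein site.
    """

    def __init__(
        self,
        height: int,
        width: int,
        central_vein_sites: Iterable[tuple[int, int]],
        portal_tract_sites: Iterable[tuple[int, int]],
        portal_tracts: list[list[tuple[int, int]]] | None = None,
        zonation_lambda: float | None = None,
    ) -> None:
        self.height = int(height)
        self.width = int(width)
        cv = {Position(*p) for p in central_vein_sites}
        pt = {Position(*p) for p in portal_tract_sites}
        if cv & pt:
            raise ConfigurationError(
                f"central-vein and portal-tract sites overlap: {sorted(cv & pt)}"
            )
        for p in cv | pt:
            if not self.in_bounds(p):
                raise ConfigurationError(f"structural site out of bounds: {p}")
        self.central_vein_sites = cv
        self.portal_tract_sites = pt

        self.occupancy = np.zeros((self.height, self.width), dtype=np.uint8)
        # Per-site hepatocyte bookkeeping (valid only where occupancy is
        # HEPATOCYTE) and dead-cell age (valid only on dead sites).
        self.hep_age = np.zeros((self.height, self.width), dtype=np.int32)
        self.hep_cooldown = np.zeros((self.height, self.width), dtype=np.int32)
        self.dead_age = np.zeros((self.height, self.width), dtype=np.int32)

        for p in cv:
            self.occupancy[p] = VEIN
        for p in pt:
            self.occupancy[p] = PORTAL

        if portal_tracts is not None:
            self.portal_tracts = [[Position(*q) for q in t] for t in portal_tracts]
        else:
            self.portal_tracts = self._connected_portal_tracts()

        if zonation_lambda is None:
            zonation_lambda = self.width / 4.0
        self.zonation_lambda = float(zonation_lambda)
        self.zonation = self._compute_zonation()

    # -- geometry ---------------------------------------------------------

    def in_bounds(self, pos: tuple[int, int]) -> bool:
        r, c = pos
        return 0 <= r < self.height and 0 <= c < self.width

    def moore_neighbors(self, pos: tuple[int, int]) -> list[Position]:
        """Up-to-8 in-bounds Moore neighbours of ``pos`` (no wrap-around)."""
        if not self.in_bounds(pos):
            raise ValueError(f"position out of bounds: {pos}")
        r, c = pos
        out = []
        for dr, dc in MOORE_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < self.height and 0 <= cc < self.width:
                out.append(Position(rr, cc))
        return out

    def _connected_portal_tracts(self) -> list[list[Position]]:
        mask = np.zeros((self.height, self.width), dtype=bool)
        for p in self.portal_tract_sites:
            mask[p] = True
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        tracts = []
        for i in range(1, n + 1):
            rows, cols = np.nonzero(labels == i)
            tracts.append([Position(int(r), int(c)) for r, c in zip(rows, cols)])
        return tracts

    def _compute_zonation(self) -> np.ndarray:
        if not self.central_vein_sites:
            return np.ones((self.height, self.width), dtype=float)
        vein_mask = np.zeros((self.height, self.width), dtype=bool)
        for p in self.central_vein_sites:
            vein_mask[p] = True
        # Euclidean distance to the nearest vein site; weight 1 on the vein.
        dist = ndimage.distance_transform_edt(~vein_mask)
        return np.exp(-dist / self.zonation_lambda)

    # -- occupancy contract ----------------------------------------------

    def is_vacant(self, pos: tuple[int, int]) -> bool:
        return self.occupancy[pos] == EMPTY

    def place(self, pos: tuple[int, int], code: int) -> None:
        """Place a space-occupying agent; the target site must be vacant."""
        if code not in OCCUPYING_CODES:
            raise ValueError(f"not a space-occupying code: {code}")
        if self.occupancy[pos] != EMPTY:
            raise OccupancyError(
                f"site {tuple(pos)} already holds "
                f"{CODE_NAMES[int(self.occupancy[pos])]}"
            )
        self.occupancy[pos] = code
        if code == HEPATOCYTE:
            self.hep_age[pos] = 0
            self.hep_cooldown[pos] = 0
        elif code in DEAD_CODES:
            self.dead_age[pos] = 0

    def remove(self, pos: tuple[int, int]) -> None:
        """Free the space at ``pos`` (structural sites cannot be removed)."""
        code = int(self.occupancy[pos])
        if code in STRUCTURAL_CODES:
            raise ValueError(f"cannot remove structural agent at {tuple(pos)}")
        self.occupancy[pos] = EMPTY

    def replace(self, pos: tuple[int, int], code: int) -> None:
        """Atomically swap the occupant at ``pos`` (in-place transformation)."""
        self.remove(pos)
        self.place(pos, code)

    # -- queries ----------------------------------------------------------

    def vacant_neighbors(self, pos: tuple[int, int]) -> list[Position]:
        return [q for q in self.moore_neighbors(pos) if self.occupancy[q] == EMPTY]

    def counts(self) -> dict[str, int]:
        flat = np.bincount(self.occupancy.ravel(), minlength=9)
        return {CODE_NAMES[i]: int(flat[i]) for i in range(9)}

    def blank_count(self) -> int:
        return int((self.occupancy == EMPTY).sum())

    def occupancy_ok(self) -> bool:
        """True iff the occupancy layer holds only known codes and the
        structural sites are intact (the exclusive-occupancy invariant is
        enforced by construction: one uint8 code per site)."""
        if not np.isin(self.occupancy, [EMPTY, *OCCUPYING_CODES]).all():
            return False
        for p in self.central_vein_sites:
            if self.occupancy[p] != VEIN:
                return False
        for p in self.portal_tract_sites:
            if self.occupancy[p] != PORTAL:
                return False
        return True


def build_lobule(config, rng: np.random.Generator | None = None):
    """Build the initial lobule from a simulation config.

    The occupancy layer starts confluent: a hepatocyte on every
    non-structural site.  Kupffer and stellate cells (and optionally a
    myofibroblast pool) are scattered uniformly over non-structural sites
    at their configured fractions of all lattice sites; portal fibroblasts
    sit on and immediately around the portal tracts.

    Returns (grid, population).
    """
    from .agents import HSC, KupfferCell, Myofibroblast, Population, PortalFibroblast

    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    geo = config.geometry
    grid = LobuleGrid(
        geo.height,
        geo.width,
        geo.central_vein_sites,
        geo.portal_sites,
        portal_tracts=geo.portal_tracts,
        zonation_lambda=geo.zonation_lambda,
    )
    free = grid.occupancy == EMPTY
    grid.occupancy[free] = HEPATOCYTE
    # Pre-existing tissue: hepatocyte ages start at steady state so that
    # age-limited turnover (if enabled) is stationary rather than a
    # synchronized cohort die-off.
    lifespan = config.agents.hepatocyte_lifespan
    if lifespan is not None:
        grid.hep_age[free] = rng.integers(0, lifespan, size=int(free.sum()))

    n_sites = grid.height * grid.width
    rows, cols = np.nonzero(free)
    n_free = len(rows)

    def _scatter(n):
        picks = rng.integers(0, n_free, size=n)
        return [(int(rows[i]), int(cols[i])) for i in picks]

    n_kc = int(round(config.ratios.kupffer * n_sites))
    n_hsc = int(round(config.ratios.hsc * n_sites))
    n_mfb = int(round(config.ratios.myofibroblast * n_sites))
    kupffer = [KupfferCell(r, c) for r, c in _scatter(n_kc)]
    hscs = [HSC(r, c) for r, c in _scatter(n_hsc)]
    myofibroblasts = [Myofibroblast(r, c) for r, c in _scatter(n_mfb)]

    # Portal fibroblasts on portal sites and their in-bounds neighbours.
    eligible: set[Position] = set()
    for tract in grid.portal_tracts:
        for p in tract:
            eligible.add(p)
            eligible.update(grid.moore_neighbors(p))
    density = config.agents.portal_fibroblast_density
    portal_fibroblasts = []
    for p in sorted(eligible):
        n_here = int(density) + (1 if rng.random() < density - int(density) else 0)
        for _ in range(n_here):
            portal_fibroblasts.append(PortalFibroblast(p.row, p.col))

    pop = Population(
        kupffer=kupffer,
        hscs=hscs,
        myofibroblasts=myofibroblasts,
        portal_fibroblasts=portal_fibroblasts,
    )
    return grid, pop
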