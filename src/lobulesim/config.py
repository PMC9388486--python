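"""Simulation configuration: geometry, field, agent and schedule blocks.

A :class:`SimulationConfig` fully determines a run together with its seed.
Configs round-trip through plain dictionaries and YAML so that every run
can be archived and re-derived from its manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

from .calibration import DEFAULT_CALIBRATION
from .dosing import InjectionSchedule
from .lattice import ConfigurationError


@dataclass
class GeometryConfig:
    height: int = 101
    width: int = 101
    central_vein_sites: list[tuple[int, int]] = field(default_factory=list)
    portal_tracts: list[list[tuple[int, int]]] = field(default_factory=list)
    zonation_lambda: float | None = None  # None -> width / 4

    def validate(self) -> None:
        if self.height < 20 or self.width < 20:
            raise ConfigurationError("lattice must be at least 20 x 20")
        if len(self.central_vein_sites) < 1:
            raise ConfigurationError("at least one central-vein site required")
        if len(self.portal_tracts) < 2:
            raise ConfigurationError("at least two portal tracts required")
        vein = set(map(tuple, self.central_vein_sites))
        portal = {tuple(p) for t in self.portal_tracts for p in t}
        if vein & portal:
            raise ConfigurationError("central-vein and portal sites overlap")

    @property
    def portal_sites(self) -> list[tuple[int, int]]:
        return [tuple(p) for t in self.portal_tracts for p in t]


def _block(center: tuple[int, int], size: int) -> list[tuple[int, int]]:
    r0, c0 = center
    half = size // 2
    return [
        (r0 + dr, c0 + dc)
        for dr in range(-half, size - half)
        for dc in range(-half, size - half)
    ]


def default_geometry(
    height: int = 101,
    width: int = 101,
    vein_block: int = 3,
    portal_block: int = 3,
    zonation_lambda: float | None = None,
    portal_inset: float = 0.35,
) -> GeometryConfig:
    """One central vein block at the centre of the lattice and one portal
    tract block at each vertex of a compact lobule unit.

    ``portal_inset`` is the fractional distance of the portal tract centres
    from the lattice edges; the default 0.35 puts the four tracts ~21 cells
    from the vein on the 101 x 101 default, i.e. the rendered field is one
    lobule with surrounding parenchyma.  ``portal_inset=0`` recovers
    corner-adjacent tracts.
    """
    center = (height // 2, width // 2)
    half = portal_block // 2
    r_lo = max(half, int(round(portal_inset * (height - 1))))
    c_lo = max(half, int(round(portal_inset * (width - 1))))
    r_hi, c_hi = height - 1 - r_lo, width - 1 - c_lo
    corners = [(r_lo, c_lo), (r_lo, c_hi), (r_hi, c_lo), (r_hi, c_hi)]
    return GeometryConfig(
        height=height,
        width=width,
        central_vein_sites=_block(center, vein_block),
        portal_tracts=[_block(c, portal_block) for c in corners],
        zonation_lambda=zonation_lambda,
    )


@dataclass
class FieldConfig:
    share_fraction: float
    decay_rate: float


@dataclass
class InitialRatios:
    """Initial cell counts as fractions of all lattice sites.

    The occupancy layer always starts confluent (hepatocytes on every
    non-structural site); the hepatocyte entry records the nominal share of
    the cell population used for validation and reporting.
    """

    hepatocyte: float = 0.60
    kupffer: float = 0.15
    hsc: float = 0.05
    myofibroblast: float = 0.0

    def validate(self) -> None:
        vals = (self.hepatocyte, self.kupffer, self.hsc, self.myofibroblast)
        if any(v < 0 or v > 1 for v in vals):
            raise ConfigurationError("initial ratios must lie in [0, 1]")
        # Non-occupying cells share space with the parenchyma, so the
        # hepatocyte share does not join the budget: only the scattered
        # (non-occupying) populations are bounded jointly.
        if self.kupffer + self.hsc + self.myofibroblast > 1.0 + 1e-9:
            raise ConfigurationError("initial ratios exceed 100%")


@dataclass
class AgentParams:
    theta_ccl4: float
    theta_tnf_death: float
    theta_tnf_hsc: float
    theta_tgf: float
    theta_hmgb1: float
    hmgb1_secretion: float
    tnf_secretion: float
    tgf_secretion: float
    tau_m1m2: int
    kc_replenish_rate: float
    replication_cooldown: int
    collagen_rich_threshold: int
    max_collagen_per_mfb: int
    portal_fibroblast_density: float
    hepatocyte_lifespan: int | None
    dead_cell_lifespan: int | None
    kupffer_lifespan: int | None
    hsc_lifespan: int | None
    myofibroblast_lifespan: int | None
    portal_fibroblast_lifespan: int | None

    def validate(self) -> None:
        for name in (
            "theta_ccl4",
            "theta_tnf_death",
            "theta_tnf_hsc",
            "theta_tgf",
            "theta_hmgb1",
            "hmgb1_secretion",
            "tnf_secretion",
            "tgf_secretion",
            "kc_replenish_rate",
            "portal_fibroblast_density",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.tau_m1m2 < 1:
            raise ConfigurationError("tau_m1m2 must be >= 1")
        if not 0 <= self.kc_replenish_rate <= 1:
            raise ConfigurationError("kc_replenish_rate must lie in [0, 1]")


@dataclass
class SimulationConfig:
    geometry: GeometryConfig
    fields: dict[str, FieldConfig]
    agents: AgentParams
    schedule: InjectionSchedule
    ratios: InitialRatios
    n_steps: int = 120
    seed: int = 0
    snapshot_steps: tuple[int, ...] = ()

    def validate(self) -> None:
        self.geometry.validate()
        self.ratios.validate()
        self.agents.validate()
        self.schedule.validate()
        if self.n_steps < 0:
            raise ConfigurationError("n_steps must be >= 0")
        for name in ("CCl4", "HMGB1", "TNFa", "TGFb"):
            if name not in self.fields:
                raise ConfigurationError(f"missing field config: {name}")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["snapshot_steps"] = list(self.snapshot_steps)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        geo = d["geometry"]
        geometry = GeometryConfig(
            height=geo["height"],
            width=geo["width"],
            central_vein_sites=[tuple(p) for p in geo["central_vein_sites"]],
            portal_tracts=[[tuple(p) for p in t] for t in geo["portal_tracts"]],
            zonation_lambda=geo.get("zonation_lambda"),
        )
        fields_ = {k: FieldConfig(**v) for k, v in d["fields"].items()}
        agents = AgentParams(**d["agents"])
        schedule = InjectionSchedule(**d["schedule"])
        ratios = InitialRatios(**d["ratios"])
        return cls(
            geometry=geometry,
            fields=fields_,
            agents=agents,
            schedule=schedule,
            ratios=ratios,
            n_steps=d.get("n_steps", 120),
            seed=d.get("seed", 0),
            snapshot_steps=tuple(d.get("snapshot_steps", ())),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(**overrides) -> SimulationConfig:
    """The reference calibrated configuration (see :mod:`calibration`).

    Keyword overrides accept any key of ``DEFAULT_CALIBRATION`` plus
    ``seed``, ``n_steps`` and ``snapshot_steps``.
    """
    cal = dict(DEFAULT_CALIBRATION)
    snapshot_steps = overrides.pop("snapshot_steps", ())
    unknown = set(overrides) - set(cal)
    if unknown:
        raise TypeError(f"unknown calibration overrides: {sorted(unknown)}")
    cal.update(overrides)

    geometry = default_geometry(
        height=cal["height"],
        width=cal["width"],
        vein_block=cal["vein_block"],
        portal_block=cal["portal_block"],
        zonation_lambda=cal["zonation_lambda"],
        portal_inset=cal["portal_inset"],
    )
    fields_ = {
        "CCl4": FieldConfig(cal["ccl4_share"], cal["ccl4_decay"]),
        "HMGB1": FieldConfig(cal["hmgb1_share"], cal["hmgb1_decay"]),
        "TNFa": FieldConfig(cal["tnfa_share"], cal["tnfa_decay"]),
        "TGFb": FieldConfig(cal["tgfb_share"], cal["tgfb_decay"]),
    }
    agents = AgentParams(
        theta_ccl4=cal["theta_ccl4"],
        theta_tnf_death=cal["theta_tnf_death"],
        theta_tnf_hsc=cal["theta_tnf_hsc"],
        theta_tgf=cal["theta_tgf"],
        theta_hmgb1=cal["theta_hmgb1"],
        hmgb1_secretion=cal["hmgb1_secretion"],
        tnf_secretion=cal["tnf_secretion"],
        tgf_secretion=cal["tgf_secretion"],
        tau_m1m2=cal["tau_m1m2"],
        kc_replenish_rate=cal["kc_replenish_rate"],
        replication_cooldown=cal["replication_cooldown"],
        collagen_rich_threshold=cal["collagen_rich_threshold"],
        max_collagen_per_mfb=cal["max_collagen_per_mfb"],
        portal_fibroblast_density=cal["portal_fibroblast_density"],
        hepatocyte_lifespan=cal["hepatocyte_lifespan"],
        dead_cell_lifespan=cal["dead_cell_lifespan"],
        kupffer_lifespan=cal["kupffer_lifespan"],
        hsc_lifespan=cal["hsc_lifespan"],
        myofibroblast_lifespan=cal["myofibroblast_lifespan"],
        portal_fibroblast_lifespan=cal["portal_fibroblast_lifespan"],
    )
    schedule = InjectionSchedule(
        interval=cal["interval"],
        first_step=cal["first_step"],
        last_step=cal["last_step"],
        dose=cal["dose"],
    )
    ratios = InitialRatios(
        hepatocyte=cal["hepatocyte_ratio"],
        kupffer=cal["kupffer_ratio"],
        hsc=cal["hsc_ratio"],
        myofibroblast=cal["myofibroblast_ratio"],
    )
    return SimulationConfig(
        geometry=geometry,
        fields=fields_,
        agents=agents,
        schedule=schedule,
        ratios=ratios,
        n_steps=cal["n_steps"],
        seed=cal["seed"],
        snapshot_steps=tuple(snapshot_steps),
    )
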