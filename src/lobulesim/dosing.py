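"""Toxin (CCl4) injection schedule.

Each injection distributes a fixed total dose over the lattice weighted by
the zonation map, so pericentral sites -- where the toxin undergoes
metabolic activation -- receive proportionally more.  The deposit is
normalised so that exactly ``dose`` units enter the field per injection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class InjectionSchedule:
    interval: int = 10
    first_step: int = 0
    last_step: int | None = 120
    dose: float = 0.0
    n_injections: int | None = None  # when set, overrides last_step

    def validate(self) -> None:
        if self.interval < 1:
            raise ValueError("interval must be >= 1")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.n_injections is not None and self.n_injections < 0:
            raise ValueError("n_injections must be non-negative")

    def is_injection_step(self, step: int) -> bool:
        if step < self.first_step:
            return False
        if (step - self.first_step) % self.interval != 0:
            return False
        k = (step - self.first_step) // self.interval  # 0-based injection index
        if self.n_injections is not None:
            return k < self.n_injections
        return self.last_step is None or step <= self.last_step

    def injection_steps(self, horizon: int) -> list[int]:
        """All injection steps in [0, horizon)."""
        return [s for s in range(horizon) if self.is_injection_step(s)]


def maybe_inject(step: int, schedule: InjectionSchedule, ccl4_field, grid) -> bool:
    """Deposit one zonation-weighted dose if ``step`` is an injection step.

    Returns True iff an injection was performed.
    """
    if not schedule.is_injection_step(step) or schedule.dose == 0.0:
        return schedule.is_injection_step(step)
    weights = grid.zonation
    total = weights.sum()
    ccl4_field.deposit_array(schedule.dose * weights / total)
    return True
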