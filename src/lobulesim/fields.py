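"""Diffusible mediator fields.

Each mediator (CCl4, HMGB1, TNF-alpha, TGF-beta) is a non-negative
concentration lattice.  Diffusion is the discrete share-with-neighbours
scheme: per step every site keeps (1 - p) of its value and sends p/8 to
each of its eight Moore neighbour slots; at the lattice edge the slots
falling outside are lost (absorbing boundary), so total mass is
non-increasing.  Decay is first-order: values are multiplied by
(1 - decay_rate) once per step.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import convolve2d

FIELD_NAMES = ("CCl4", "HMGB1", "TNFa", "TGFb")


class DiffusibleField:
    """One mediator concentration lattice.

    Parameters
    ----------
    name:
        Mediator label, conventionally one of ``FIELD_NAMES``.
    shape:
        (height, width) of the lattice.
    share_fraction:
        Fraction p in [0, 1] of each site's value redistributed to its
        Moore neighbours per diffusion step.
    decay_rate:
        Fraction in [0, 1) removed per decay step.
    """

    def __init__(
        self,
        name: str,
        shape: tuple[int, int],
        share_fraction: float,
        decay_rate: float,
        values: np.ndarray | None = None,
    ) -> None:
        if not 0.0 <= share_fraction <= 1.0:
            raise ValueError(f"share_fraction out of [0,1]: {share_fraction}")
        if not 0.0 <= decay_rate < 1.0:
            raise ValueError(f"decay_rate out of [0,1): {decay_rate}")
        self.name = name
        self.share_fraction = float(share_fraction)
        self.decay_rate = float(decay_rate)
        if values is None:
            self.values = np.zeros(shape, dtype=float)
        else:
            values = np.asarray(values, dtype=float)
            if values.shape != tuple(shape):
                raise ValueError("values shape mismatch")
            if (values < 0).any():
                raise ValueError("negative initial concentration")
            self.values = values.copy()
        p = self.share_fraction
        self._kernel = np.full((3, 3), p / 8.0)
        self._kernel[1, 1] = 1.0 - p

    def diffuse(self, wrap: bool = False) -> None:
        """One synchronous share-with-neighbours step.

        ``wrap=True`` uses periodic boundaries (a torus), under which total
        mass is conserved exactly; the default absorbing boundary loses the
        shares sent off-lattice.
        """
        boundary = "wrap" if wrap else "fill"
        self.values = convolve2d(self.values, self._kernel, mode="same", boundary=boundary)
        # Convolution of non-negative data with a non-negative kernel can
        # only produce negatives through rounding; clip at zero.
        np.maximum(self.values, 0.0, out=self.values)

    def decay(self) -> None:
        self.values *= 1.0 - self.decay_rate

    def deposit(self, pos: tuple[int, int], amount: float) -> None:
        if amount < 0:
            raise ValueError(f"negative deposit: {amount}")
        self.values[pos] += amount

    def deposit_array(self, amounts: np.ndarray) -> None:
        amounts = np.asarray(amounts, dtype=float)
        if (amounts < 0).any():
            raise ValueError("negative deposit in array")
        self.values += amounts

    def total(self) -> float:
        return float(self.values.sum())

    def copy(self) -> "DiffusibleField":
        return DiffusibleField(
            self.name,
            self.values.shape,
            self.share_fraction,
            self.decay_rate,
            values=self.values,
        )


def diffuse(field: DiffusibleField, wrap: bool = False) -> DiffusibleField:
    """Functional wrapper: return a diffused copy of ``field``."""
    out = field.copy()
    out.diffuse(wrap=wrap)
    return out


def decay(field: DiffusibleField) -> DiffusibleField:
    out = field.copy()
    out.decay()
    return out


def deposit(field: DiffusibleField, pos: tuple[int, int], amount: float) -> DiffusibleField:
    out = field.copy()
    out.deposit(pos, amount)
    return out


def diffuse_reference(values: np.ndarray, share_fraction: float) -> np.ndarray:
    """Naive double-loop reference implementation of one diffusion step.

    Kept deliberately independent of the convolution kernel; used as the
    oracle in tests.
    """
    values = np.asarray(values, dtype=float)
    h, w = values.shape
    out = (1.0 - share_fraction) * values.copy()
    per_neighbor = share_fraction / 8.0
    for r in range(h):
        for c in range(w):
            v = values[r, c]
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        out[rr, cc] += per_neighbor * v
    return out
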