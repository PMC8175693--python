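"""Simulated fingertip: receptive-field lattice and receptor-to-pin coupling.

The fingertip is a 10 mm x 20 mm patch of skin carrying 72 afferents on a
6 x 12 square lattice (spacing 10/6 mm).  Each afferent owns a circular
receptive field of radius 1 mm containing 4 randomly placed receptors.  A
receptor is a candidate for every pin whose centre lies within twice the
pin-head radius (2 r1); by default it is driven by the nearest such pin (the
skin directly under a pin head follows that pin).  Maximum and sum
combination rules over all candidate pins are available for sensitivity
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimulus import PinMatrixConfig

__all__ = [
    "Fingertip",
    "PinArray",
    "build_fingertip",
    "build_pin_array",
    "couple",
    "coupling_map",
    "receptor_input",
]


@dataclass(frozen=True)
class Fingertip:
    """72 receptive fields with 4 receptors each on a 10 mm x 20 mm patch."""

    neuron_xy: np.ndarray     # (Nn, 2)
    receptor_xy: np.ndarray   # (Nn, Nr, 2)
    extent: tuple[float, float] = (10.0, 20.0)
    rf_radius: float = 1.0

    @property
    def n_neurons(self) -> int:
        return self.neuron_xy.shape[0]

    @property
    def n_receptors(self) -> int:
        return self.receptor_xy.shape[1]

    def receptors_flat(self) -> np.ndarray:
        """Receptor positions flattened to ``(Nn * Nr, 2)``."""
        return self.receptor_xy.reshape(-1, 2)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_neurons):
            for j in range(self.n_receptors):
                rows.append(
                    (
                        i,
                        self.neuron_xy[i, 0],
                        self.neuron_xy[i, 1],
                        j,
                        self.receptor_xy[i, j, 0],
                        self.receptor_xy[i, j, 1],
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["neuron_id", "neuron_x", "neuron_y", "receptor_idx", "rx", "ry"],
        )


def build_fingertip(
    seed,
    n_cols: int = 6,
    n_rows: int = 12,
    extent: tuple[float, float] = (10.0, 20.0),
    n_receptors: int = 4,
    rf_radius: float = 1.0,
) -> Fingertip:
    """Deterministically build a fingertip layout from a seed.

    Afferent centres sit at the cell centres of an ``n_cols x n_rows`` grid
    covering the extent, with the spine axis at ``x = 0`` (extent centred in
    x, starting at 0 in y).  Receptors are sampled uniformly in the disc of
    radius ``rf_radius`` around their afferent; edge receptors may fall up to
    one radius outside the rectangle, which is harmless because the pin
    lattice extends beyond it.
    """
    rng = np.random.default_rng(seed)
    width, height = extent
    xs = -width / 2.0 + (np.arange(n_cols) + 0.5) * width / n_cols
    ys = (np.arange(n_rows) + 0.5) * height / n_rows
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    neuron_xy = np.column_stack([gx.ravel(), gy.ravel()])

    n_n = neuron_xy.shape[0]
    # Uniform sampling in a disc: radius ~ r * sqrt(U), angle uniform.
    radii = rf_radius * np.sqrt(rng.random((n_n, n_receptors)))
    theta = rng.uniform(0.0, 2.0 * np.pi, (n_n, n_receptors))
    offsets = np.stack([radii * np.cos(theta), radii * np.sin(theta)], axis=-1)
    receptor_xy = neuron_xy[:, None, :] + offsets
    return Fingertip(
        neuron_xy=neuron_xy,
        receptor_xy=receptor_xy,
        extent=extent,
        rf_radius=rf_radius,
    )


@dataclass(frozen=True)
class PinArray:
    """Square lattice of pins covering the fingertip plus a margin."""

    config: PinMatrixConfig
    xy: np.ndarray  # (Np, 2)

    @property
    def n_pins(self) -> int:
        return self.xy.shape[0]


def build_pin_array(
    config: PinMatrixConfig,
    extent: tuple[float, float] = (10.0, 20.0),
    margin: float | None = None,
    offset: tuple[float, float] = (0.0, 0.0),
) -> PinArray:
    """Build the pin lattice covering the fingertip extent plus a margin.

    The default margin of ``2 r1`` guarantees that every receptor, including
    those just outside the rectangle, sees its full set of candidate pins.
    With zero offsets one pin column lies at ``x = 0``, under the spine
    centre.
    """
    if margin is None:
        margin = 2.0 * config.r1
    width, height = extent
    s = config.spacing
    ox, oy = offset

    def lattice(lo: float, hi: float, off: float) -> np.ndarray:
        k_lo = int(np.ceil((lo - off) / s - 1e-12))
        k_hi = int(np.floor((hi - off) / s + 1e-12))
        return off + np.arange(k_lo, k_hi + 1) * s

    xs = lattice(-width / 2.0 - margin, width / 2.0 + margin, ox)
    ys = lattice(-margin, height + margin, oy)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return PinArray(config=config, xy=np.column_stack([gx.ravel(), gy.ravel()]))


def couple(receptor_xy, pins: PinArray) -> np.ndarray:
    """Indices of pins whose centre lies within ``2 r1`` of the receptor.

    May be empty for the coarse matrices; such a receptor receives no input.
    """
    receptor_xy = np.asarray(receptor_xy, dtype=float)
    d = np.hypot(pins.xy[:, 0] - receptor_xy[0], pins.xy[:, 1] - receptor_xy[1])
    return np.nonzero(d <= 2.0 * pins.config.r1)[0]


def coupling_map(
    fingertip: Fingertip, pins: PinArray, rule: str = "all"
) -> list[np.ndarray]:
    """Coupled pin indices for every receptor (flattened neuron-major order).

    ``rule="all"`` keeps every pin within reach; ``rule="nearest"`` keeps
    only the closest one (ties broken toward the lower pin index).
    """
    out = []
    for r in fingertip.receptors_flat():
        idx = couple(r, pins)
        if rule == "nearest" and idx.size > 1:
            d = np.hypot(pins.xy[idx, 0] - r[0], pins.xy[idx, 1] - r[1])
            idx = idx[[int(np.argmin(d))]]
        elif rule not in ("all", "nearest"):
            raise ValueError(f"unknown coupling-map rule {rule!r}")
        out.append(idx)
    return out


def receptor_input(h_coupled, chi: float, rule: str = "max"):
    """Channel displacement sigma (um) from the coupled pins' heights (mm).

    ``h_coupled`` has shape ``(n_coupled,)`` or ``(n_coupled, n_times)``.
    Empty coupling yields 0.  ``rule`` is ``"max"`` (skin follows the highest
    pin; default) or ``"sum"``.
    """
    h = np.atleast_1d(np.asarray(h_coupled, dtype=float))
    if h.shape[0] == 0:
        return 0.0 if h.ndim == 1 else np.zeros(h.shape[1])
    if rule == "max":
        combined = h.max(axis=0)
    elif rule == "sum":
        combined = h.sum(axis=0)
    else:
        raise ValueError(f"unknown coupling rule {rule!r}")
    return chi * combined * 1000.0
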