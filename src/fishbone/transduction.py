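"""Mechanosensitive-channel model of a rapidly adapting mechanoreceptor.

Skin displacement under a pin is converted linearly into a channel
displacement sigma (micrometres).  The receptor conductance is
``g = gmax * p * (1 - q)`` where ``p`` is the channel open probability and
``q`` the inactivation probability; both relax sigmoidally toward
displacement-dependent targets:

    tau_p dp/dt = -p + 1 / (1 + exp[-k_p (sigma - x_p - alpha_p q)])
    tau_q dq/dt = -q + 1 / (1 + exp[-k_q (sigma - x_q)])

The ``-alpha_p q`` shift of the activation midpoint implements adaptation
(the effective threshold rises under sustained stimulation) and the
``(1 - q)`` factor implements inactivation (a second stimulus arriving before
``q`` has relaxed evokes a smaller conductance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "ChannelParams",
    "ChannelState",
    "channel_stimulus",
    "channel_rhs",
    "conductance",
    "channel_equilibrium",
]


@dataclass(frozen=True)
class ChannelParams:
    """Parameters of the mechanosensitive-channel model.

    Defaults are the values used throughout the numerical experiments:
    time constants in ms, slopes in 1/um, half-activation displacements in
    um, and ``chi`` the dimensionless skin-to-channel displacement conversion
    ratio (applied to the pin height expressed in um).
    """

    gmax: float = 1.0       # maximal receptor conductance
    tau_p: float = 2.5      # ms, activation time constant
    tau_q: float = 8.0      # ms, inactivation time constant
    k_p: float = 2.6        # 1/um, activation slope
    k_q: float = 1.2        # 1/um, inactivation slope
    x_p: float = 4.0        # um, activation midpoint
    x_q: float = 6.0        # um, inactivation midpoint
    alpha_p: float = 4.6    # um, adaptation coupling of q into the p midpoint
    chi: float = 0.07       # displacement conversion ratio

    def __post_init__(self) -> None:
        for name in ("tau_p", "tau_q", "k_p", "k_q"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ChannelState:
    """Open probability ``p`` and inactivation probability ``q``.

    Either scalars or arrays (one entry per receptor)."""

    p: np.ndarray | float
    q: np.ndarray | float


def channel_stimulus(h_mm, params: ChannelParams):
    """Channel displacement sigma (um) from pin displacement ``h`` (mm).

    ``sigma = chi * h`` with ``h`` expressed in micrometres, so the 0.1 mm
    print height maps to 7.0 um at the default ``chi = 0.07``.
    """
    return params.chi * np.asarray(h_mm, dtype=float) * 1000.0


def channel_rhs(state: ChannelState, sigma, params: ChannelParams):
    """Time derivatives ``(dp/dt, dq/dt)`` at channel displacement ``sigma`` (um)."""
    p = np.asarray(state.p, dtype=float)
    q = np.asarray(state.q, dtype=float)
    p_target = expit(params.k_p * (sigma - params.x_p - params.alpha_p * q))
    q_target = expit(params.k_q * (sigma - params.x_q))
    return (p_target - p) / params.tau_p, (q_target - q) / params.tau_q


def conductance(state: ChannelState, params: ChannelParams):
    """Receptor conductance ``g = gmax * p * (1 - q)``."""
    return params.gmax * np.asarray(state.p) * (1.0 - np.asarray(state.q))


def channel_equilibrium(sigma, params: ChannelParams) -> ChannelState:
    """Fixed point of the channel dynamics at constant ``sigma`` (um).

    ``q`` does not depend on ``p``, so its equilibrium is explicit; ``p``'s
    target then follows from the equilibrium ``q``.  Used to initialise
    receptors at their actual t = 0 stimulus and avoid onset artefacts.
    """
    sigma = np.asarray(sigma, dtype=float)
    q_inf = expit(params.k_q * (sigma - params.x_q))
    p_inf = expit(params.k_p * (sigma - params.x_p - params.alpha_p * q_inf))
    if sigma.ndim == 0:
        return ChannelState(p=float(p_inf), q=float(q_inf))
    return ChannelState(p=p_inf, q=q_inf)
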