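"""Hodgkin-Huxley spike-initiation-zone model of a tactile afferent.

Receptor currents from the mechanoreceptors attached to one afferent are
summed at a spike initiation zone modelled as a single Hodgkin-Huxley
compartment (0-mV-rest convention):

    Cm dv/dt = -gK n^4 (v - vK) - gNa m^3 h (v - vNa) - gL (v - vL) - Istim
    Istim    = sum_j g_j(t) (v - v_eq + v_offset)

Note on naming: the sodium inactivation gate (the classical ``h``) is called
``h_gate`` throughout this package because ``h`` is already the pin height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .transduction import ChannelParams, ChannelState, channel_rhs, conductance

__all__ = [
    "HHParams",
    "NeuronState",
    "CoupledState",
    "SpikeTrainSet",
    "hh_rates",
    "receptor_current",
    "hh_rhs",
    "resting_state",
    "rk4_step",
    "integrate_fiber",
    "detect_spikes",
]


@dataclass(frozen=True)
class HHParams:
    """Hodgkin-Huxley parameters (squid-axon values, 0-mV-rest convention).

    Conductances in mS/cm^2, potentials in mV, capacitance in uF/cm^2, rate
    constants A in 1/ms and B, C in mV.
    """

    C_m: float = 1.0
    g_Na: float = 120.0
    g_K: float = 36.0
    g_L: float = 0.3
    v_Na: float = 115.0
    v_K: float = -12.0
    v_L: float = 10.6
    v_eq: float = 60.0       # membrane equilibrium potential in the receptor current
    v_offset: float = -10.0  # offset so pin contact depolarises from rest

    # Rate-function constants (alpha_m, alpha_n, alpha_h, beta_m, beta_n, beta_h).
    A1: float = 0.1
    B1: float = 25.0
    C1: float = 10.0
    A2: float = 0.01
    B2: float = 10.0
    C2: float = 10.0
    A3: float = 0.07
    C3: float = 20.0
    A4: float = 4.0
    C4: float = 18.0
    A5: float = 0.125
    C5: float = 80.0
    A6: float = 1.0
    B6: float = 30.0
    C6: float = 10.0


@dataclass
class NeuronState:
    """Membrane potential and gating variables of one afferent."""

    v: np.ndarray | float
    m: np.ndarray | float
    n: np.ndarray | float
    h_gate: np.ndarray | float


@dataclass
class CoupledState:
    """One afferent plus the channel states of its attached receptors."""

    neuron: NeuronState
    channels: ChannelState  # arrays of shape (n_receptors,)


def _ratio_expm1(x: np.ndarray) -> np.ndarray:
    """``x / (exp(x) - 1)`` with the removable singularity at 0 filled in."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = x[nz] / np.expm1(x[nz])
    return out


def hh_rates(v, params: HHParams = HHParams()):
    """The six voltage-dependent rate functions (1/ms).

    Returns ``(alpha_m, beta_m, alpha_n, beta_n, alpha_h, beta_h)``.  The
    removable singularities of ``alpha_m`` at ``v = B1`` and ``alpha_n`` at
    ``v = B2`` evaluate to the analytic limits ``A1*C1`` and ``A2*C2``.
    """
    scalar = np.isscalar(v)
    v = np.asarray(v, dtype=float)
    p = params
    alpha_m = p.A1 * p.C1 * _ratio_expm1((p.B1 - v) / p.C1)
    alpha_n = p.A2 * p.C2 * _ratio_expm1((p.B2 - v) / p.C2)
    alpha_h = p.A3 * np.exp(-v / p.C3)
    beta_m = p.A4 * np.exp(-v / p.C4)
    beta_n = p.A5 * np.exp(-v / p.C5)
    beta_h = p.A6 / (np.exp((p.B6 - v) / p.C6) + 1.0)
    rates = (alpha_m, beta_m, alpha_n, beta_n, alpha_h, beta_h)
    if scalar:
        return tuple(float(r) for r in rates)
    return rates


def receptor_current(g_list, v, params: HHParams = HHParams()):
    """Summed receptor current ``Istim = sum_j g_j (v - v_eq + v_offset)``.

    Negative for ``v < v_eq - v_offset``; since ``Istim`` enters the voltage
    equation with a minus sign, pin contact depolarises the afferent.
    """
    g_total = np.sum(np.asarray(g_list, dtype=float), axis=0)
    return g_total * (v - params.v_eq + params.v_offset)


def hh_rhs(state: NeuronState, i_stim, params: HHParams = HHParams()):
    """Derivatives ``(dv/dt, dm/dt, dn/dt, dh_gate/dt)``."""
    p = params
    v = np.asarray(state.v, dtype=float)
    m = np.asarray(state.m, dtype=float)
    n = np.asarray(state.n, dtype=float)
    hg = np.asarray(state.h_gate, dtype=float)
    alpha_m, beta_m, alpha_n, beta_n, alpha_h, beta_h = hh_rates(v, p)
    dv = (
        -p.g_K * n**4 * (v - p.v_K)
        - p.g_Na * m**3 * hg * (v - p.v_Na)
        - p.g_L * (v - p.v_L)
        - i_stim
    ) / p.C_m
    dm = alpha_m * (1.0 - m) - beta_m * m
    dn = alpha_n * (1.0 - n) - beta_n * n
    dh = alpha_h * (1.0 - hg) - beta_h * hg
    return dv, dm, dn, dh


def _gate_steady(v: float, params: HHParams) -> tuple[float, float, float]:
    alpha_m, beta_m, alpha_n, beta_n, alpha_h, beta_h = hh_rates(float(v), params)
    return (
        alpha_m / (alpha_m + beta_m),
        alpha_n / (alpha_n + beta_n),
        alpha_h / (alpha_h + beta_h),
    )


def resting_state(params: HHParams = HHParams()) -> NeuronState:
    """Resting fixed point of the membrane with zero stimulus current.

    With the default parameters the rest potential is within a few hundredths
    of a millivolt of 0 mV (the leak reversal is chosen for that).
    """

    def steady_current(v: float) -> float:
        m_inf, n_inf, h_inf = _gate_steady(v, params)
        return (
            -params.g_K * n_inf**4 * (v - params.v_K)
            - params.g_Na * m_inf**3 * h_inf * (v - params.v_Na)
            - params.g_L * (v - params.v_L)
        )

    v0 = brentq(steady_current, -10.0, 10.0, xtol=1e-12)
    m_inf, n_inf, h_inf = _gate_steady(v0, params)
    return NeuronState(v=float(v0), m=m_inf, n=n_inf, h_gate=h_inf)


def _coupled_rhs(y, sigma, ch: ChannelParams, hh: HHParams):
    v, m, n, hg, p_ch, q_ch = y
    dp, dq = channel_rhs(ChannelState(p=p_ch, q=q_ch), sigma, ch)
    g = conductance(ChannelState(p=p_ch, q=q_ch), ch)
    i_stim = receptor_current(g, v, hh)
    dv, dm, dn, dh = hh_rhs(NeuronState(v=v, m=m, n=n, h_gate=hg), i_stim, hh)
    return np.array([dv, dm, dn, dh], dtype=float), dp, dq


def rk4_step(
    state: CoupledState,
    sigma,
    dt: float,
    ch_params: ChannelParams = ChannelParams(),
    hh_params: HHParams = HHParams(),
) -> CoupledState:
    """Advance the coupled afferent + receptor system one classical RK4 step.

    ``sigma`` (um, shape ``(n_receptors,)`` or scalar) is held constant over
    the step; receptor conductances are recomputed from the channel states at
    every RK4 stage.  Raises on non-finite state (integration blow-up).
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    sigma = np.asarray(sigma, dtype=float)
    y0 = (
        float(state.neuron.v),
        float(state.neuron.m),
        float(state.neuron.n),
        float(state.neuron.h_gate),
        np.asarray(state.channels.p, dtype=float),
        np.asarray(state.channels.q, dtype=float),
    )

    def add(y, k, factor):
        return (
            y[0] + factor * k[0][0],
            y[1] + factor * k[0][1],
            y[2] + factor * k[0][2],
            y[3] + factor * k[0][3],
            y[4] + factor * k[1],
            y[5] + factor * k[2],
        )

    k1 = _coupled_rhs(y0, sigma, ch_params, hh_params)
    k2 = _coupled_rhs(add(y0, k1, dt / 2.0), sigma, ch_params, hh_params)
    k3 = _coupled_rhs(add(y0, k2, dt / 2.0), sigma, ch_params, hh_params)
    k4 = _coupled_rhs(add(y0, k3, dt), sigma, ch_params, hh_params)

    w = dt / 6.0
    hh_new = y0[0:4] + w * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
    p_new = y0[4] + w * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
    q_new = y0[5] + w * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2])
    if not (np.all(np.isfinite(hh_new)) and np.all(np.isfinite(p_new))):
        raise FloatingPointError("integration blow-up: non-finite state (dt too large?)")
    return CoupledState(
        neuron=NeuronState(v=float(hh_new[0]), m=float(hh_new[1]), n=float(hh_new[2]), h_gate=float(hh_new[3])),
        channels=ChannelState(p=p_new, q=q_new),
    )


def integrate_fiber(
    sigma_steps: np.ndarray,
    dt: float,
    ch_params: ChannelParams = ChannelParams(),
    hh_params: HHParams = HHParams(),
    initial: CoupledState | None = None,
) -> tuple[np.ndarray, CoupledState]:
    """Integrate one afferent over ``sigma_steps`` (shape ``(n_steps, Nr)``).

    ``sigma_steps[i]`` is held constant over step ``i`` (sample-and-hold of
    the stimulus trace).  Returns the voltage trace (length ``n_steps + 1``)
    and the final state.  Receptors start at the equilibrium of their t = 0
    stimulus; the afferent starts at its resting fixed point.
    """
    from .transduction import channel_equilibrium

    sigma_steps = np.atleast_2d(np.asarray(sigma_steps, dtype=float))
    if initial is None:
        rest = resting_state(hh_params)
        eq = channel_equilibrium(sigma_steps[0], ch_params)
        initial = CoupledState(
            neuron=rest,
            channels=ChannelState(p=np.atleast_1d(eq.p).copy(), q=np.atleast_1d(eq.q).copy()),
        )
    state = initial
    v_trace = np.empty(sigma_steps.shape[0] + 1)
    v_trace[0] = state.neuron.v
    for i in range(sigma_steps.shape[0]):
        state = rk4_step(state, sigma_steps[i], dt, ch_params, hh_params)
        v_trace[i + 1] = state.neuron.v
    return v_trace, state


def detect_spikes(v_trace: np.ndarray, v_star: float = 40.0, dt: float = 0.01) -> np.ndarray:
    """Firing-event times: upward crossings of the threshold ``v_star``.

    An event is registered at ``t_{i+1}`` whenever
    ``v(t_i) < v_star <= v(t_{i+1})``.  Touching the threshold from below
    without crossing does not count.
    """
    v = np.asarray(v_trace, dtype=float)
    crossed = (v[:-1] < v_star) & (v[1:] >= v_star)
    return (np.nonzero(crossed)[0] + 1) * dt


@dataclass
class SpikeTrainSet:
    """Per-afferent firing-event times (ms) within the window ``[0, T]``."""

    trains: list[np.ndarray]
    T: float

    def __post_init__(self) -> None:
        for i, tr in enumerate(self.trains):
            tr = np.asarray(tr, dtype=float)
            if tr.size and (np.any(np.diff(tr) <= 0) or tr[0] < 0 or tr[-1] > self.T):
                raise ValueError(f"train {i}: times must be strictly increasing within [0, T]")
            self.trains[i] = tr

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    @property
    def n_events(self) -> int:
        return int(sum(tr.size for tr in self.trains))

    def pooled(self) -> np.ndarray:
        """All event times across afferents, sorted."""
        if not self.trains:
            return np.empty(0)
        return np.sort(np.concatenate(self.trains))

    def to_frame(self, sample_id: int = 0) -> pd.DataFrame:
        rows = [
            (sample_id, i, t)
            for i, tr in enumerate(self.trains)
            for t in tr
        ]
        return pd.DataFrame(rows, columns=["sample_id", "neuron_id", "t_ms"])
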