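"""Numerical experiment orchestration: condition sweeps over pin matrices,
rib intervals, and finger samples.

A "finger sample" is one random realisation of receptor placement plus one
scan phase draw; the same finger samples are reused across rib intervals so
conditions can be compared within a sample.  All randomness derives from a
master seed through a stable splitting scheme (sample ``k`` always receives
the same stream no matter how many samples are run).

The population integrator advances all afferents of a batch (typically every
finger sample of one condition) through one vectorised classical RK4 loop.
Stimulus traces are periodic in time, so the per-receptor channel stimulus is
tabulated over a single rib period and indexed modulo the period length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import expit

from .fingertip import (
    Fingertip,
    PinArray,
    build_fingertip,
    build_pin_array,
    coupling_map,
)
from .metrics import bin_events, mean_firing_rate, shannon_entropy
from .neuron import HHParams, SpikeTrainSet
from .stimulus import (
    PIN_MATRICES,
    DisplacementTrace,
    FishbonePattern,
    PinMatrixConfig,
    ScanConfig,
    pin_displacement,
)
from .transduction import ChannelParams, channel_equilibrium

__all__ = [
    "EXPERIMENTAL_RIB_INTERVALS",
    "SimulationConfig",
    "sample_seed_sequence",
    "run_condition",
    "run_sweep",
    "aggregate",
    "condition_pin_traces",
]

#: Rib intervals (L2, mm) used in the experiments.
EXPERIMENTAL_RIB_INTERVALS: tuple[float, ...] = (
    0.2,
    0.4,
    1.0,
    1.4,
    1.8,
    2.0,
    2.2,
    3.0,
    4.0,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce a numerical experiment.

    Geometry in mm, time in ms.  ``V = 0.05`` mm/ms is the 50 mm/s scan
    speed; ``T = 800`` ms the analysis window; ``v_star`` the spike
    threshold; ``bin_dt`` the entropy bin width.
    """

    h0: float = 0.1
    Lw: float = 4.0
    L1: float = 1.0
    V: float = 0.05
    T: float = 800.0
    dt: float = 0.01
    n_samples: int = 20
    master_seed: int = 0
    v_star: float = 40.0
    bin_dt: float = 4.0
    coupling_rule: str = "nearest"  # "nearest" | "max" | "sum"
    fixed_phase0: float | None = None
    backend: str = "auto"  # "auto" | "numba" | "numpy"
    channel: ChannelParams = field(default_factory=ChannelParams)
    hh: HHParams = field(default_factory=HHParams)

    def pattern(self, L2: float) -> FishbonePattern:
        return FishbonePattern(Lw=self.Lw, L1=self.L1, L2=L2, h0=self.h0)

    def scan(self, phase0: float = 0.0) -> ScanConfig:
        return ScanConfig(V=self.V, T=self.T, dt=self.dt, phase0=phase0)


def sample_seed_sequence(master_seed: int, sample_index: int) -> np.random.SeedSequence:
    """Stable per-sample seed stream; independent of how many samples run."""
    return np.random.SeedSequence(master_seed, spawn_key=(sample_index,))


def _finger_sample(
    config: SimulationConfig, sample_seed
) -> tuple[Fingertip, float]:
    """Build one finger sample: receptor layout plus a scan-phase fraction.

    Returns the fingertip and the phase draw as a fraction of the rib period
    (so one draw serves every rib interval of the sweep).
    """
    if not isinstance(sample_seed, np.random.SeedSequence):
        sample_seed = np.random.SeedSequence(sample_seed)
    layout_ss, phase_ss = sample_seed.spawn(2)
    fingertip = build_fingertip(layout_ss)
    phase_fraction = float(np.random.default_rng(phase_ss).random())
    return fingertip, phase_fraction


def _sigma_table(
    fingertip: Fingertip,
    pins: PinArray,
    pattern: FishbonePattern,
    scan: ScanConfig,
    ch: ChannelParams,
    rule: str,
) -> tuple[np.ndarray, int]:
    """Tabulate the channel stimulus sigma (um) for every receptor.

    Returns ``(table, period_steps)`` with ``table`` of shape
    ``(period_steps, Nn, Nr)``; the stimulus at integration step ``i`` is
    ``table[i % period_steps]``.  Falls back to tabulating the full window
    when the rib period is not an integer number of steps.
    """
    if rule not in ("nearest", "max", "sum"):
        raise ValueError(f"unknown coupling rule {rule!r}")
    n_steps = scan.n_steps
    steps_f = pattern.period / (scan.V * scan.dt)
    if abs(steps_f - round(steps_f)) < 1e-6 and round(steps_f) <= n_steps:
        period_steps = int(round(steps_f))
    else:
        period_steps = n_steps
    t = np.arange(period_steps) * scan.dt

    cmap = coupling_map(
        fingertip, pins, rule="nearest" if rule == "nearest" else "all"
    )
    needed = sorted({int(i) for idx in cmap for i in idx})
    traces: dict[int, np.ndarray] = {}
    rp = pins.config.rp
    for pin_idx in needed:
        xp, yp = pins.xy[pin_idx]
        y_eff = yp - scan.V * t - scan.phase0
        traces[pin_idx] = np.asarray(
            pin_displacement(np.full_like(t, xp), y_eff, pattern, rp)
        )

    n_n, n_r = fingertip.n_neurons, fingertip.n_receptors
    table = np.zeros((period_steps, n_n, n_r))
    for flat, idx in enumerate(cmap):
        if idx.size == 0:
            continue
        stacked = np.stack([traces[int(i)] for i in idx])
        combined = stacked.sum(axis=0) if rule == "sum" else stacked.max(axis=0)
        table[:, flat // n_r, flat % n_r] = ch.chi * combined * 1000.0
    return table, period_steps


def _integrate_population(
    sigma_table: np.ndarray,
    n_steps: int,
    dt: float,
    ch: ChannelParams,
    hh: HHParams,
    v_star: float,
    backend: str = "auto",
) -> list[np.ndarray]:
    """Coupled RK4 over a batch of afferents.

    ``sigma_table`` has shape ``(period, B, Nr)`` and is sampled-and-held
    over each step.  Receptors start at the channel equilibrium of their
    t = 0 stimulus and each afferent at the quiescent fixed point consistent
    with the resulting standing conductance (see :func:`_coupled_rest`).
    Returns per-afferent spike times (threshold ``v_star``, upward
    crossings).

    The channel inactivation target depends only on the (held) stimulus, so
    it is tabulated once per period and reused at all four RK4 stages — an
    exact rewrite of the scheme, not an approximation.  ``backend`` selects
    the compiled kernel (``"numba"``), the vectorised NumPy loop
    (``"numpy"``), or the compiled kernel when available (``"auto"``).
    Afferents are advanced independently, so batching does not alter any
    per-afferent result.
    """
    from ._kernel import HAVE_NUMBA, rk4_population_kernel

    period, n_b, _ = sigma_table.shape
    eq = channel_equilibrium(sigma_table[0], ch)
    p = np.array(eq.p, dtype=float)
    q = np.array(eq.q, dtype=float)
    g0 = ch.gmax * (p * (1.0 - q)).sum(axis=1)
    v, m, n_g, h_g = _coupled_rest(g0, hh)
    q_target = expit(ch.k_q * (sigma_table - ch.x_q))

    if backend == "auto":
        backend = "numba" if HAVE_NUMBA else "numpy"
    if backend == "numba":
        if not HAVE_NUMBA:
            raise RuntimeError("numba backend requested but numba is unavailable")
        ev_t, ev_id, n_ev = rk4_population_kernel(
            np.ascontiguousarray(sigma_table),
            np.ascontiguousarray(q_target),
            n_steps, dt, v, m, n_g, h_g, p, q,
            ch.k_p, ch.x_p, ch.alpha_p, 1.0 / ch.tau_p, 1.0 / ch.tau_q, ch.gmax,
            hh.g_K, hh.g_Na, hh.g_L, hh.v_K, hh.v_Na, hh.v_L, 1.0 / hh.C_m,
            hh.v_eq - hh.v_offset,
            hh.A1, hh.B1, hh.C1, hh.A2, hh.B2, hh.C2, hh.A3, hh.C3,
            hh.A4, hh.C4, hh.A5, hh.C5, hh.A6, hh.B6, hh.C6,
            v_star,
        )
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(
                "integration blow-up: non-finite membrane potential (dt too large?)"
            )
        return _assemble_trains(np.asarray(ev_t), np.asarray(ev_id, dtype=np.intp), n_b)
    if backend != "numpy":
        raise ValueError(f"unknown backend {backend!r}")

    # Hoisted constants.
    kp, xp_, ap = ch.k_p, ch.x_p, ch.alpha_p
    itp, itq, gmax = 1.0 / ch.tau_p, 1.0 / ch.tau_q, ch.gmax
    g_k, g_na, g_l = hh.g_K, hh.g_Na, hh.g_L
    v_k, v_na, v_l = hh.v_K, hh.v_Na, hh.v_L
    i_cm = 1.0 / hh.C_m
    veq_off = hh.v_eq - hh.v_offset
    a1, b1, c1 = hh.A1, hh.B1, hh.C1
    a2, b2, c2 = hh.A2, hh.B2, hh.C2
    a3, c3, a4, c4, a5, c5 = hh.A3, hh.C3, hh.A4, hh.C4, hh.A5, hh.C5
    a6, b6, c6 = hh.A6, hh.B6, hh.C6

    def xexpm1(x):
        with np.errstate(invalid="ignore", divide="ignore"):
            out = x / np.expm1(x)
        return np.where(np.abs(x) < 1e-12, 1.0, out)

    def rhs(v, m, n_g, h_g, p, q, s, q_t):
        p_t = expit(kp * (s - xp_ - ap * q))
        dp = (p_t - p) * itp
        dq = (q_t - q) * itq
        i_stim = (gmax * (p * (1.0 - q)).sum(axis=1)) * (v - veq_off)
        am = a1 * c1 * xexpm1((b1 - v) / c1)
        an = a2 * c2 * xexpm1((b2 - v) / c2)
        ah = a3 * np.exp(-v / c3)
        bm = a4 * np.exp(-v / c4)
        bn = a5 * np.exp(-v / c5)
        bh = a6 / (np.exp((b6 - v) / c6) + 1.0)
        n2 = n_g * n_g
        dv = (
            -g_k * n2 * n2 * (v - v_k)
            - g_na * m * m * m * h_g * (v - v_na)
            - g_l * (v - v_l)
            - i_stim
        ) * i_cm
        dm = am * (1.0 - m) - bm * m
        dn = an * (1.0 - n_g) - bn * n_g
        dh = ah * (1.0 - h_g) - bh * h_g
        return dv, dm, dn, dh, dp, dq

    half, sixth = 0.5 * dt, dt / 6.0
    times_acc: list[np.ndarray] = []
    ids_acc: list[np.ndarray] = []
    for i in range(n_steps):
        ip = i % period
        s = sigma_table[ip]
        q_t = q_target[ip]
        k1 = rhs(v, m, n_g, h_g, p, q, s, q_t)
        k2 = rhs(
            v + half * k1[0], m + half * k1[1], n_g + half * k1[2],
            h_g + half * k1[3], p + half * k1[4], q + half * k1[5], s, q_t,
        )
        k3 = rhs(
            v + half * k2[0], m + half * k2[1], n_g + half * k2[2],
            h_g + half * k2[3], p + half * k2[4], q + half * k2[5], s, q_t,
        )
        k4 = rhs(
            v + dt * k3[0], m + dt * k3[1], n_g + dt * k3[2],
            h_g + dt * k3[3], p + dt * k3[4], q + dt * k3[5], s, q_t,
        )
        v_new = v + sixth * (k1[0] + 2.0 * (k2[0] + k3[0]) + k4[0])
        m = m + sixth * (k1[1] + 2.0 * (k2[1] + k3[1]) + k4[1])
        n_g = n_g + sixth * (k1[2] + 2.0 * (k2[2] + k3[2]) + k4[2])
        h_g = h_g + sixth * (k1[3] + 2.0 * (k2[3] + k3[3]) + k4[3])
        p = p + sixth * (k1[4] + 2.0 * (k2[4] + k3[4]) + k4[4])
        q = q + sixth * (k1[5] + 2.0 * (k2[5] + k3[5]) + k4[5])
        crossed = (v < v_star) & (v_new >= v_star)
        if crossed.any():
            idx = np.nonzero(crossed)[0]
            times_acc.append(np.full(idx.size, (i + 1) * dt))
            ids_acc.append(idx)
        v = v_new
        if i % 4000 == 0 and not np.all(np.isfinite(v)):
            raise FloatingPointError(
                "integration blow-up: non-finite membrane potential (dt too large?)"
            )
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("integration blow-up: non-finite membrane potential")

    all_t = np.concatenate(times_acc) if times_acc else np.empty(0)
    all_i = np.concatenate(ids_acc) if ids_acc else np.empty(0, dtype=np.intp)
    return _assemble_trains(all_t, all_i, n_b)


def _coupled_rest(
    g0: np.ndarray, hh: HHParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Quiescent state of each afferent given its standing receptor
    conductance ``g0`` at t = 0.

    Sustained contact leaves a small steady conductance on the membrane; the
    afferent then has a stable quiescent fixed point (the adapted state of a
    rapidly adapting unit) coexisting with a tonic limit cycle.  Starting
    every afferent at the fixed point consistent with its actual t = 0
    stimulus selects the quiescent branch and avoids artificial onset
    firing; afferents under a time-varying stimulus are perturbed away from
    it within the first scan cycle regardless.
    """
    from scipy.optimize import brentq

    def steady_current(v: float, g: float) -> float:
        m_inf, n_inf, h_inf = _gate_steady_scalar(v, hh)
        return (
            -hh.g_K * n_inf**4 * (v - hh.v_K)
            - hh.g_Na * m_inf**3 * h_inf * (v - hh.v_Na)
            - hh.g_L * (v - hh.v_L)
            - g * (v - hh.v_eq + hh.v_offset)
        )

    n_b = g0.size
    v = np.empty(n_b)
    m = np.empty(n_b)
    n_g = np.empty(n_b)
    h_g = np.empty(n_b)
    cache: dict[float, tuple[float, float, float, float]] = {}
    grid = np.linspace(-20.0, 115.0, 136)
    for b in range(n_b):
        key = round(float(g0[b]), 12)
        if key not in cache:
            v0 = None
            for k in range(1, grid.size):
                f_lo = steady_current(grid[k - 1], g0[b])
                if f_lo == 0.0:
                    v0 = float(grid[k - 1])
                    break
                if f_lo * steady_current(grid[k], g0[b]) < 0:
                    v0 = brentq(
                        steady_current, grid[k - 1], grid[k], args=(g0[b],), xtol=1e-12
                    )
                    break
            if v0 is None:  # pragma: no cover - defensive; always bracketed
                raise RuntimeError("no quiescent fixed point found")
            m_inf, n_inf, h_inf = _gate_steady_scalar(v0, hh)
            cache[key] = (v0, m_inf, n_inf, h_inf)
        v[b], m[b], n_g[b], h_g[b] = cache[key]
    return v, m, n_g, h_g


def _gate_steady_scalar(v: float, hh: HHParams) -> tuple[float, float, float]:
    from .neuron import hh_rates

    alpha_m, beta_m, alpha_n, beta_n, alpha_h, beta_h = hh_rates(float(v), hh)
    return (
        alpha_m / (alpha_m + beta_m),
        alpha_n / (alpha_n + beta_n),
        alpha_h / (alpha_h + beta_h),
    )


def _assemble_trains(all_t: np.ndarray, all_i: np.ndarray, n_b: int) -> list[np.ndarray]:
    """Split pooled (time, afferent) event pairs into per-afferent trains."""
    trains: list[np.ndarray] = [np.empty(0) for _ in range(n_b)]
    if all_t.size:
        order = np.lexsort((all_t, all_i))
        all_t, all_i = all_t[order], all_i[order]
        bounds = np.searchsorted(all_i, np.arange(n_b + 1))
        for b in range(n_b):
            trains[b] = all_t[bounds[b] : bounds[b + 1]]
    return trains


def _summary_row(
    spikes: SpikeTrainSet,
    config: SimulationConfig,
    matrix: str,
    L2: float,
    sample_id: int,
) -> dict:
    counts = bin_events(spikes, dt=config.bin_dt, T=config.T)
    return {
        "matrix": matrix,
        "L2_mm": L2,
        "sample_id": sample_id,
        "n_events": spikes.n_events,
        "mean_rate_per_ms": mean_firing_rate(counts, spikes.n_neurons),
        "entropy_nats": shannon_entropy(counts),
    }


def _resolve_matrix(matrix: str | PinMatrixConfig) -> PinMatrixConfig:
    if isinstance(matrix, PinMatrixConfig):
        return matrix
    try:
        return PIN_MATRICES[matrix]
    except KeyError:
        raise ValueError(f"unknown pin matrix {matrix!r}; known: {sorted(PIN_MATRICES)}")


def run_condition(
    config: SimulationConfig,
    matrix: str | PinMatrixConfig,
    L2: float,
    sample_seed,
    sample_id: int = 0,
) -> tuple[SpikeTrainSet, dict]:
    """Simulate one (pin matrix, rib interval, finger sample) cell.

    Deterministic given ``(config, matrix, L2, sample_seed)``.  Returns the
    spike trains of the 72 afferents and a summary row with the mean firing
    rate and spike-time entropy.
    """
    mat = _resolve_matrix(matrix)
    pattern = config.pattern(L2)
    fingertip, phase_fraction = _finger_sample(config, sample_seed)
    phase0 = (
        config.fixed_phase0
        if config.fixed_phase0 is not None
        else phase_fraction * pattern.period
    )
    scan = config.scan(phase0)
    pins = build_pin_array(mat, extent=fingertip.extent)
    table, _ = _sigma_table(
        fingertip, pins, pattern, scan, config.channel, config.coupling_rule
    )
    trains = _integrate_population(
        table, scan.n_steps, scan.dt, config.channel, config.hh, config.v_star,
        backend=config.backend,
    )
    spikes = SpikeTrainSet(trains=trains, T=config.T)
    return spikes, _summary_row(spikes, config, mat.name or str(matrix), L2, sample_id)


def run_sweep(
    config: SimulationConfig,
    L2_values=EXPERIMENTAL_RIB_INTERVALS,
    matrices=("PM1",),
    n_samples: int | None = None,
    collect_spikes: bool = False,
    progress=None,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Sweep over pin matrices, rib intervals, and finger samples.

    All finger samples of one (matrix, rib interval) condition are stacked
    into a single batch and integrated together; the batched results are
    bit-identical to running :func:`run_condition` per cell.  Returns one
    summary row per cell; with ``collect_spikes`` also a tidy spike table
    (columns: matrix, L2_mm, sample_id, neuron_id, t_ms).  A condition whose
    integration blows up is flagged (NaN metrics, ``n_events = -1``) with a
    warning and the sweep continues.
    """
    if n_samples is None:
        n_samples = config.n_samples
    if not (len(list(L2_values)) and len(list(matrices)) and n_samples > 0):
        raise ValueError("sweep dimensions must be non-empty")

    samples = [
        _finger_sample(config, sample_seed_sequence(config.master_seed, k))
        for k in range(n_samples)
    ]
    rows: list[dict] = []
    spike_rows: list[pd.DataFrame] = []
    for matrix in matrices:
        mat = _resolve_matrix(matrix)
        for L2 in L2_values:
            pattern = config.pattern(L2)
            tables = []
            for fingertip, phase_fraction in samples:
                phase0 = (
                    config.fixed_phase0
                    if config.fixed_phase0 is not None
                    else phase_fraction * pattern.period
                )
                scan = config.scan(phase0)
                pins = build_pin_array(mat, extent=fingertip.extent)
                table, _ = _sigma_table(
                    fingertip, pins, pattern, scan, config.channel,
                    config.coupling_rule,
                )
                tables.append(table)
            batched = np.concatenate(tables, axis=1)
            scan = config.scan(0.0)
            try:
                trains = _integrate_population(
                    batched, scan.n_steps, scan.dt, config.channel, config.hh,
                    config.v_star, backend=config.backend,
                )
            except FloatingPointError as err:
                # Flag the failed condition and keep sweeping.
                warnings.warn(f"condition {mat.name} L2={L2}: {err}", RuntimeWarning)
                for k in range(n_samples):
                    rows.append(
                        {
                            "matrix": mat.name,
                            "L2_mm": L2,
                            "sample_id": k,
                            "n_events": -1,
                            "mean_rate_per_ms": float("nan"),
                            "entropy_nats": float("nan"),
                        }
                    )
                continue
            n_n = samples[0][0].n_neurons
            for k in range(n_samples):
                spikes = SpikeTrainSet(
                    trains=trains[k * n_n : (k + 1) * n_n], T=config.T
                )
                rows.append(_summary_row(spikes, config, mat.name, L2, k))
                if collect_spikes:
                    frame = spikes.to_frame(sample_id=k)
                    frame.insert(0, "L2_mm", L2)
                    frame.insert(0, "matrix", mat.name)
                    spike_rows.append(frame)
            if progress is not None:
                progress(mat.name, L2)
    summary = pd.DataFrame(rows)
    if collect_spikes:
        spikes_frame = (
            pd.concat(spike_rows, ignore_index=True)
            if spike_rows
            else pd.DataFrame(columns=["matrix", "L2_mm", "sample_id", "neuron_id", "t_ms"])
        )
        return summary, spikes_frame
    return summary


def aggregate(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean and standard deviation over finger samples."""
    agg = (
        summary.groupby(["matrix", "L2_mm"], as_index=False)
        .agg(
            mean_rate_per_ms=("mean_rate_per_ms", "mean"),
            sd_rate_per_ms=("mean_rate_per_ms", "std"),
            entropy_nats=("entropy_nats", "mean"),
            sd_entropy_nats=("entropy_nats", "std"),
            n_events=("n_events", "mean"),
            n_samples=("sample_id", "nunique"),
        )
        .sort_values(["matrix", "L2_mm"])
        .reset_index(drop=True)
    )
    return agg


def condition_pin_traces(
    config: SimulationConfig,
    matrix: str | PinMatrixConfig,
    L2: float,
    phase0: float = 0.0,
) -> Iterator[DisplacementTrace]:
    """Yield the displacement trace of every pin of one condition.

    Used for the stimulus-incoherence analysis; traces are generated lazily
    so the full pin set never resides in memory at once.
    """
    mat = _resolve_matrix(matrix)
    pattern = config.pattern(L2)
    scan = config.scan(phase0)
    pins = build_pin_array(mat)
    t = scan.times()
    for xp, yp in pins.xy:
        y_eff = yp - scan.V * t - scan.phase0
        h = np.asarray(pin_displacement(np.full_like(t, xp), y_eff, pattern, mat.rp))
        yield DisplacementTrace(xp=float(xp), yp=float(yp), t=t, h=h)
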