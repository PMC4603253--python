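"""Fixed-step network simulation engine.

Advances every neuron of a realized connectome with the same
exponential-Euler scheme as the single-cell model (see
:mod:`cpgnet.neuron`), delivers synaptic events with a one-step delay, and
records spikes.  Fully deterministic given (connectome, protocol, seed, dt);
optional Ornstein–Uhlenbeck conductance noise is seeded from the same
configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .drive import DriveProtocol
from .network import Connectome
from .neuron import NumericalInstabilityError

__all__ = ["SimulationConfig", "SpikeRecord", "simulate"]


@dataclass(frozen=True)
class SimulationConfig:
    duration: float               # ms
    dt: float = 0.1               # ms
    seed: int = 0
    noise_sigma: float = 0.0      # nS, OU excitatory-conductance noise
    noise_tau: float = 5.0        # ms
    init_v_halfwidth: float = 5.0  # mV, uniform initial V spread
    record_v: tuple[int, ...] = ()  # neuron indices whose V is traced
    v_stride: int = 10            # record every v_stride-th step
    max_spikes: int = 20_000_000

    def __post_init__(self):
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("require dt > 0 and duration >= dt")


@dataclass
class SpikeRecord:
    """Raw spikes of one simulation, time-ordered."""

    neuron_ids: np.ndarray        # int32 [k]
    times: np.ndarray             # float64 [k], ms
    n_neurons: int
    duration: float
    pop_slices: dict              # population name -> (start, stop)
    meta: dict = field(default_factory=dict)
    v_traces: np.ndarray | None = None   # [n_rec, n_samples]
    v_times: np.ndarray | None = None

    def spikes_of(self, name: str) -> np.ndarray:
        """Spike times of one population (ms, sorted)."""
        start, stop = self.pop_slices[name]
        mask = (self.neuron_ids >= start) & (self.neuron_ids < stop)
        return self.times[mask]

    def per_neuron(self) -> list[np.ndarray]:
        out = [[] for _ in range(self.n_neurons)]
        for nid, t in zip(self.neuron_ids, self.times):
            out[nid].append(t)
        return [np.asarray(x) for x in out]

    def pop_size(self, name: str) -> int:
        start, stop = self.pop_slices[name]
        return stop - start

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(self.neuron_ids.tobytes())
        h.update(self.times.tobytes())
        return h.hexdigest()

    def to_tsv(self) -> str:
        lines = ["neuron_id\tt_ms"]
        lines += [f"{int(n)}\t{t:.3f}" for n, t in zip(self.neuron_ids, self.times)]
        return "\n".join(lines) + "\n"

    def pop_map_tsv(self) -> str:
        lines = ["population\tstart\tstop"]
        lines += [f"{k}\t{v[0]}\t{v[1]}" for k, v in self.pop_slices.items()]
        return "\n".join(lines) + "\n"


@njit(cache=False)
def _run_kernel(
    n_steps, dt,
    # membrane constants
    C, gNa, gK, gL, ENa, EK, EsynE, EsynI, tauE, tauI, Vth, refr,
    mNa_h, mNa_k, hNa_h, hNa_k, hNa_tau, nK_h, nK_k, nK_tau,
    mNaP_h, mNaP_k, hNaP_h, hNaP_k, hNaP_tau, hNaP_tauw,
    # per-neuron arrays
    gNaP, EL0, gain, gtonic,
    # schedule
    alpha,
    # pulses: [n_pulse] arrays
    pulse_n0, pulse_n1, pulse_step0, pulse_step1, pulse_gE, pulse_gI,
    # adjacency
    syn_ptr, syn_tgt, syn_w,
    # state (modified in place)
    V, hNa, nK, hNaP, gE, gI,
    # noise
    noise_sigma, noise_tau, noise_seed,
    # recording
    spike_n, spike_t, rec_idx, rec_stride, rec_V,
):
    n = V.size
    decE = np.exp(-dt / tauE)
    decI = np.exp(-dt / tauI)
    last_spike = np.full(n, -1e9)
    incE = np.zeros(n)
    incI = np.zeros(n)
    noise = np.zeros(n)
    use_noise = noise_sigma > 0.0
    if use_noise:
        np.random.seed(noise_seed)
    nd = np.exp(-dt / noise_tau)
    nsig = noise_sigma * np.sqrt(1.0 - nd * nd)
    k_spk = 0
    n_rec = rec_idx.size
    rec_col = 0
    for step in range(n_steps):
        a = alpha[step]
        t_next = (step + 1) * dt
        for i in range(n):
            v = V[i]
            m = 1.0 / (1.0 + np.exp((v - mNa_h) / mNa_k))
            mp = 1.0 / (1.0 + np.exp((v - mNaP_h) / mNaP_k))
            g_na = gNa * m * m * m * hNa[i]
            g_k = gK * nK[i] * nK[i] * nK[i] * nK[i]
            g_nap = gNaP[i] * mp * hNaP[i]
            ge = gE[i] + gtonic[i]
            gi = gI[i]
            if use_noise:
                noise[i] = noise[i] * nd + nsig * np.random.normal()
                gn = noise[i]
                if gn > 0.0:
                    ge += gn
            # perturbation pulses
            for q in range(pulse_n0.size):
                if pulse_n0[q] <= i < pulse_n1[q] and pulse_step0[q] <= step < pulse_step1[q]:
                    ge += pulse_gE[q]
                    gi += pulse_gI[q]
            el = EL0[i] * (1.0 - gain[i] * a)
            g_tot = g_na + g_k + g_nap + gL + ge + gi
            v_inf = (
                g_na * ENa + g_k * EK + g_nap * ENa + gL * el + ge * EsynE + gi * EsynI
            ) / g_tot
            v_new = v_inf + (v - v_inf) * np.exp(-g_tot * dt / C)
            # gates relax toward steady state at pre-step V
            h_inf = 1.0 / (1.0 + np.exp((v - hNa_h) / hNa_k))
            tau_h = hNa_tau / np.cosh((v - hNa_h) / (2.0 * hNa_k))
            hNa[i] = h_inf + (hNa[i] - h_inf) * np.exp(-dt / tau_h)
            n_inf = 1.0 / (1.0 + np.exp((v - nK_h) / nK_k))
            tau_n = nK_tau / np.cosh((v - nK_h) / (2.0 * nK_k))
            nK[i] = n_inf + (nK[i] - n_inf) * np.exp(-dt / tau_n)
            hp_inf = 1.0 / (1.0 + np.exp((v - hNaP_h) / hNaP_k))
            tau_hp = hNaP_tau / np.cosh((v - hNaP_h) / hNaP_tauw)
            hNaP[i] = hp_inf + (hNaP[i] - hp_inf) * np.exp(-dt / tau_hp)
            # synaptic decay + events from the previous step (one-step delay)
            gE[i] = gE[i] * decE + incE[i]
            gI[i] = gI[i] * decI + incI[i]
            incE[i] = 0.0
            incI[i] = 0.0
            V[i] = v_new
            if v < Vth <= v_new and t_next - last_spike[i] >= refr:
                last_spike[i] = t_next
                if k_spk >= spike_n.size:
                    return -1, step
                spike_n[k_spk] = i
                spike_t[k_spk] = t_next
                k_spk += 1
                for s in range(syn_ptr[i], syn_ptr[i + 1]):
                    w = syn_w[s]
                    if w >= 0.0:
                        incE[syn_tgt[s]] += w
                    else:
                        incI[syn_tgt[s]] -= w
            if not np.isfinite(v_new):
                return -2 - i, step
        if n_rec > 0 and step % rec_stride == 0:
            for r in range(n_rec):
                rec_V[r, rec_col] = V[rec_idx[r]]
            rec_col += 1
    return k_spk, n_steps


def simulate(
    connectome: Connectome,
    protocol: DriveProtocol,
    cfg: SimulationConfig,
) -> SpikeRecord:
    """Run the network under a drive protocol and return its spikes.

    Deterministic for fixed (connectome, protocol, cfg): initial conditions
    and noise are drawn from ``cfg.seed``.  Synaptic events take effect one
    step after the presynaptic threshold crossing.
    """
    if protocol.duration < cfg.duration:
        raise ValueError("protocol duration must cover the simulation duration")
    m = connectome.membrane
    n = connectome.n_neurons
    n_steps = int(round(cfg.duration / cfg.dt))
    rng = np.random.default_rng(cfg.seed)

    record = SpikeRecord(
        neuron_ids=np.empty(0, dtype=np.int32),
        times=np.empty(0),
        n_neurons=n,
        duration=cfg.duration,
        pop_slices=dict(connectome.pop_slices),
        meta={
            "seed": cfg.seed,
            "dt": cfg.dt,
            "connectome_seed": connectome.seed,
            "noise_sigma": cfg.noise_sigma,
        },
    )
    if n == 0:
        return record

    alpha0 = float(protocol.alpha(0.0))
    el0 = connectome.E_L0 * (1.0 - connectome.drive_gain * alpha0)
    V = el0 + rng.uniform(-cfg.init_v_halfwidth, cfg.init_v_halfwidth, n)
    hNa = 1.0 / (1.0 + np.exp((V - m.h_Na.v_half) / m.h_Na.k))
    nK = 1.0 / (1.0 + np.exp((V - m.n_K.v_half) / m.n_K.k))
    hNaP = 1.0 / (1.0 + np.exp((V - m.h_NaP.v_half) / m.h_NaP.k))
    gEa = np.zeros(n)
    gIa = np.zeros(n)

    alpha = protocol.alpha_samples(cfg.dt)

    # perturbation pulses -> neuron-range/step-range tables
    pulses = protocol.perturbations
    n_p = len(pulses)
    p_n0 = np.zeros(n_p, dtype=np.int64)
    p_n1 = np.zeros(n_p, dtype=np.int64)
    p_s0 = np.zeros(n_p, dtype=np.int64)
    p_s1 = np.zeros(n_p, dtype=np.int64)
    p_ge = np.zeros(n_p)
    p_gi = np.zeros(n_p)
    for i, p in enumerate(pulses):
        if p.target not in connectome.pop_slices:
            raise KeyError(f"perturbation target {p.target!r} not in network")
        p_n0[i], p_n1[i] = connectome.pop_slices[p.target]
        p_s0[i] = int(round(p.onset / cfg.dt))
        p_s1[i] = int(round(p.offset / cfg.dt))
        if p.sign == "excitatory":
            p_ge[i] = p.amplitude
        else:
            p_gi[i] = p.amplitude

    cap = min(cfg.max_spikes, max(1000, int(n * cfg.duration / 1000.0 * 120)))
    spike_n = np.empty(cap, dtype=np.int32)
    spike_t = np.empty(cap)
    rec_idx = np.asarray(cfg.record_v, dtype=np.int64)
    n_cols = (n_steps + cfg.v_stride - 1) // cfg.v_stride if rec_idx.size else 0
    rec_V = np.empty((rec_idx.size, max(n_cols, 1)))

    noise_seed = int(rng.integers(0, 2**31 - 1))
    k, stop_step = _run_kernel(
        n_steps, cfg.dt,
        m.C, m.g_Na, m.g_K, m.g_L, m.E_Na, m.E_K, m.E_synE, m.E_synI,
        m.tau_E, m.tau_I, m.V_th, m.refractory,
        m.m_Na.v_half, m.m_Na.k,
        m.h_Na.v_half, m.h_Na.k, m.h_Na.tau_max,
        m.n_K.v_half, m.n_K.k, m.n_K.tau_max,
        m.m_NaP.v_half, m.m_NaP.k,
        m.h_NaP.v_half, m.h_NaP.k, m.h_NaP.tau_max,
        m.h_NaP.tau_width if m.h_NaP.tau_width is not None else 2.0 * m.h_NaP.k,
        connectome.g_NaP, connectome.E_L0, connectome.drive_gain,
        connectome.g_tonic_E,
        alpha,
        p_n0, p_n1, p_s0, p_s1, p_ge, p_gi,
        connectome.syn_ptr, connectome.syn_tgt, connectome.syn_w,
        V, hNa, nK, hNaP, gEa, gIa,
        cfg.noise_sigma, cfg.noise_tau, noise_seed,
        spike_n, spike_t, rec_idx, cfg.v_stride, rec_V,
    )
    if k == -1:
        raise MemoryError(
            f"spike buffer overflow at step {stop_step}; raise max_spikes or "
            "lower the firing load"
        )
    if k < -1:
        neuron = -(k + 2)
        raise NumericalInstabilityError(
            f"non-finite membrane potential of neuron {neuron} at "
            f"t = {stop_step * cfg.dt:.2f} ms"
        )

    record.neuron_ids = spike_n[:k].copy()
    record.times = spike_t[:k].copy()
    if rec_idx.size:
        record.v_traces = rec_V[:, :n_cols]
        record.v_times = np.arange(n_cols) * cfg.v_stride * cfg.dt
    cfg_digest = hashlib.sha256(
        json.dumps(
            {"dt": cfg.dt, "duration": cfg.duration, "seed": cfg.seed,
             "noise": cfg.noise_sigma, "conn_seed": connectome.seed},
            sort_keys=True,
        ).encode()
    ).hexdigest()[:16]
    record.meta["config_digest"] = cfg_digest
    return record
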