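"""Single-neuron conductance dynamics with a slowly inactivating persistent
sodium current.

The cell model is a minimal Hodgkin–Huxley-style point neuron carrying the
currents that matter for conditional intrinsic bursting in spinal
rhythm-generating populations:

* fast sodium ``I_Na = g_Na * m_Na_inf(V)**3 * h_Na * (V - E_Na)`` with
  instantaneous activation and a first-order inactivation gate,
* delayed-rectifier potassium ``I_K = g_K * n_K**4 * (V - E_K)``,
* persistent sodium ``I_NaP = g_NaP * m_NaP_inf(V) * h_NaP * (V - E_Na)``
  with instantaneous activation and *slow* inactivation ``h_NaP`` whose
  recovery times the interburst interval,
* ohmic leak ``I_L = g_L * (V - E_L)`` and conductance-based synapses with
  single-exponential decay.

Depending on the leak reversal potential (the excitability parameter) a cell
with ``g_NaP > 0`` is silent, bursts intrinsically, or fires tonically; the
three regimes partition the leak-reversal axis into contiguous intervals.

Units throughout: mV, ms, nS, pF (so ``C / g`` is in ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GateParams",
    "MembraneParameters",
    "MembraneState",
    "DEFAULT_MEMBRANE",
    "gate_steady_state",
    "gate_tau",
    "neuron_step",
    "simulate_neuron",
    "reference_trajectory",
    "single_neuron_regime",
]


class InvalidParameterError(ValueError):
    """Raised when a membrane or gate parameter violates its constraints."""


class NumericalInstabilityError(RuntimeError):
    """Raised when an integrated state becomes non-finite."""


class InsufficientObservationError(ValueError):
    """Raised when an observation window is too short for a classification."""


def gate_steady_state(v: float, v_half: float, k: float):
    """Steady-state value of an HH gate, ``1 / (1 + exp((v - v_half) / k))``.

    ``k < 0`` gives an activation gate (opens with depolarization), ``k > 0``
    an inactivation gate.  Strictly monotone in ``v``; the sign of the slope
    is the sign of ``-k``.
    """
    if k == 0:
        raise InvalidParameterError("gate slope k must be nonzero")
    return 1.0 / (1.0 + np.exp((v - v_half) / k))


def gate_tau(v: float, v_half: float, k: float, tau_max: float, tau_width: float | None = None):
    """Voltage-dependent gate time constant ``tau_max / cosh((v - v_half) / w)``.

    The bell-shaped form peaks at ``v_half``; the width ``w`` defaults to
    ``2 k`` (the canonical choice for first-order HH gates) but may be set
    independently to flatten the voltage dependence.  ``tau_max`` in ms.
    """
    if tau_max <= 0:
        raise InvalidParameterError("tau_max must be positive")
    w = 2.0 * k if tau_width is None else tau_width
    return tau_max / np.cosh((v - v_half) / w)


@dataclass(frozen=True)
class GateParams:
    """Half-voltage (mV), slope (mV) and time-constant scale (ms) of one gate.

    ``tau_max = 0`` marks a gate treated as instantaneous (always at its
    steady state).
    """

    v_half: float
    k: float
    tau_max: float = 0.0
    tau_width: float | None = None  # cosh width; None -> 2k

    def __post_init__(self):
        if self.k == 0:
            raise InvalidParameterError("gate slope k must be nonzero")
        if self.tau_max < 0:
            raise InvalidParameterError("tau_max must be >= 0")

    def steady_state(self, v):
        return gate_steady_state(v, self.v_half, self.k)

    def tau(self, v):
        return gate_tau(v, self.v_half, self.k, self.tau_max, self.tau_width)


@dataclass(frozen=True)
class MembraneParameters:
    """Frozen parameter set of the point-neuron model.

    The defaults (see :data:`DEFAULT_MEMBRANE`) are a calibrated,
    versioned choice placing the intrinsic bursting window of a ``g_NaP``
    carrying cell inside the leak-reversal ramp used by the rhythm-generation
    experiments; they are a model choice, frozen once, not literature values.
    """

    C: float = 20.0          # pF
    g_Na: float = 28.0       # nS
    g_NaP: float = 2.8       # nS (0 for non-rhythmogenic cells)
    g_K: float = 11.2        # nS
    g_L: float = 2.8         # nS
    E_Na: float = 50.0       # mV
    E_K: float = -85.0       # mV
    E_L: float = -65.0       # mV (baseline; drive supplies an effective value)
    E_synE: float = -10.0    # mV
    E_synI: float = -75.0    # mV
    m_Na: GateParams = field(default_factory=lambda: GateParams(-41.0, -5.0))
    h_Na: GateParams = field(default_factory=lambda: GateParams(-36.0, 4.0, 10.0))
    n_K: GateParams = field(default_factory=lambda: GateParams(-36.0, -4.0, 10.0))
    m_NaP: GateParams = field(default_factory=lambda: GateParams(-45.5, -6.0))
    h_NaP: GateParams = field(default_factory=lambda: GateParams(-53.5, 6.0, 3000.0))
    V_th: float = -10.0      # mV, spike detection threshold
    refractory: float = 1.5  # ms, detection refractory gate
    tau_E: float = 5.0       # ms, excitatory synaptic decay
    tau_I: float = 15.0      # ms, inhibitory synaptic decay

    def __post_init__(self):
        if self.C <= 0:
            raise InvalidParameterError("capacitance C must be positive")
        for name in ("g_Na", "g_NaP", "g_K", "g_L"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise InvalidParameterError("synaptic decay constants must be positive")
        if not (self.E_K < self.E_L < self.E_Na):
            raise InvalidParameterError("require E_K < E_L < E_Na")
        if not (self.E_synI <= self.E_L < self.E_synE):
            raise InvalidParameterError("require E_synI <= E_L < E_synE")
        if self.g_NaP > 0 and self.g_L > 0:
            membrane_tau = self.C / self.g_L
            if self.h_NaP.tau_max < 100.0 * membrane_tau:
                raise InvalidParameterError(
                    "h_NaP must be slow: tau_max(h_NaP) >= 100 * C/g_L"
                )

    def without_nap(self) -> "MembraneParameters":
        """A copy with the persistent sodium conductance removed."""
        return replace(self, g_NaP=0.0)


#: Frozen default parameter set used by every rhythm-generating population.
DEFAULT_MEMBRANE = MembraneParameters()

#: Frozen default for non-rhythmogenic relay / inhibitory populations.
RELAY_MEMBRANE = DEFAULT_MEMBRANE.without_nap()


@dataclass
class MembraneState:
    """Instantaneous state of one neuron."""

    V: float
    h_Na: float
    n_K: float
    h_NaP: float
    g_E: float = 0.0
    g_I: float = 0.0
    last_spike_time: float | None = None

    @classmethod
    def at_rest(cls, params: MembraneParameters, v: float | None = None) -> "MembraneState":
        """State with gates at steady state for potential ``v`` (default ``E_L``)."""
        v0 = params.E_L if v is None else v
        return cls(
            V=v0,
            h_Na=float(params.h_Na.steady_state(v0)),
            n_K=float(params.n_K.steady_state(v0)),
            h_NaP=float(params.h_NaP.steady_state(v0)),
        )

    def is_valid(self) -> bool:
        gates_ok = all(0.0 <= g <= 1.0 for g in (self.h_Na, self.n_K, self.h_NaP))
        return (
            gates_ok
            and self.g_E >= 0.0
            and self.g_I >= 0.0
            and math.isfinite(self.V)
            and -100.0 <= self.V <= 60.0
        )


def neuron_step(
    state: MembraneState,
    params: MembraneParameters,
    syn_events: tuple[float, float] = (0.0, 0.0),
    E_L_effective: float | None = None,
    dt: float = 0.1,
    t: float = 0.0,
    g_tonic_E: float = 0.0,
) -> tuple[MembraneState, bool]:
    """Advance one neuron by one exponential-Euler step of length ``dt`` ms.

    ``syn_events`` are the (excitatory, inhibitory) conductance increments in
    nS delivered at this step.  Returns the new state and a flag marking an
    upward threshold crossing (subject to the refractory gate).

    The voltage update treats the total conductance as frozen over the step
    and relaxes ``V`` exponentially toward the instantaneous equilibrium
    potential; gates relax exponentially toward their steady states at the
    pre-step voltage.  This is the stiff-safe scheme used by the network
    engine, reproduced here for single cells.
    """
    if not (0.0 < dt <= 1.0):
        raise InvalidParameterError("dt must be in (0, 1] ms")
    e_l = params.E_L if E_L_effective is None else E_L_effective
    v = state.V

    m_na = params.m_Na.steady_state(v)
    m_nap = params.m_NaP.steady_state(v)
    g_na = params.g_Na * m_na**3 * state.h_Na
    g_k = params.g_K * state.n_K**4
    g_nap = params.g_NaP * m_nap * state.h_NaP
    g_e = state.g_E + g_tonic_E
    g_tot = g_na + g_k + g_nap + params.g_L + g_e + state.g_I
    v_inf = (
        g_na * params.E_Na
        + g_k * params.E_K
        + g_nap * params.E_Na
        + params.g_L * e_l
        + g_e * params.E_synE
        + state.g_I * params.E_synI
    ) / g_tot
    v_new = v_inf + (v - v_inf) * math.exp(-g_tot * dt / params.C)

    def _relax(x, gate: GateParams):
        x_inf = gate.steady_state(v)
        if gate.tau_max == 0.0:
            return x_inf
        return x_inf + (x - x_inf) * math.exp(-dt / gate.tau(v))

    h_na = _relax(state.h_Na, params.h_Na)
    n_k = _relax(state.n_K, params.n_K)
    h_nap = _relax(state.h_NaP, params.h_NaP)

    g_e_new = state.g_E * math.exp(-dt / params.tau_E) + syn_events[0]
    g_i_new = state.g_I * math.exp(-dt / params.tau_I) + syn_events[1]

    spiked = False
    t_new = t + dt
    if v < params.V_th <= v_new:
        if state.last_spike_time is None or t_new - state.last_spike_time >= params.refractory:
            spiked = True

    new = MembraneState(
        V=v_new,
        h_Na=h_na,
        n_K=n_k,
        h_NaP=h_nap,
        g_E=g_e_new,
        g_I=g_i_new,
        last_spike_time=t_new if spiked else state.last_spike_time,
    )
    if not (math.isfinite(v_new) and math.isfinite(h_nap)):
        raise NumericalInstabilityError(f"non-finite state at t = {t_new:.3f} ms")
    return new, spiked


def simulate_neuron(
    params: MembraneParameters,
    E_L_effective: float,
    T: float,
    dt: float = 0.1,
    v0: float | None = None,
):
    """Deterministic single-neuron trajectory over ``[0, T]`` ms.

    Returns ``(t, V, spike_times)`` with ``t`` including the initial sample.
    """
    n_steps = int(round(T / dt))
    state = MembraneState.at_rest(params, v0 if v0 is not None else E_L_effective)
    t = np.arange(n_steps + 1) * dt
    v = np.empty(n_steps + 1)
    v[0] = state.V
    spikes = []
    for i in range(n_steps):
        state, spiked = neuron_step(
            state, params, E_L_effective=E_L_effective, dt=dt, t=i * dt
        )
        v[i + 1] = state.V
        if spiked:
            spikes.append((i + 1) * dt)
    return t, v, np.asarray(spikes)


def _rhs(t, y, params: MembraneParameters, e_l: float):
    v, h_na, n_k, h_nap = y
    m_na = params.m_Na.steady_state(v)
    m_nap = params.m_NaP.steady_state(v)
    i_na = params.g_Na * m_na**3 * h_na * (v - params.E_Na)
    i_k = params.g_K * n_k**4 * (v - params.E_K)
    i_nap = params.g_NaP * m_nap * h_nap * (v - params.E_Na)
    i_l = params.g_L * (v - e_l)
    dv = -(i_na + i_k + i_nap + i_l) / params.C
    dh_na = (params.h_Na.steady_state(v) - h_na) / params.h_Na.tau(v)
    dn_k = (params.n_K.steady_state(v) - n_k) / params.n_K.tau(v)
    dh_nap = (params.h_NaP.steady_state(v) - h_nap) / params.h_NaP.tau(v)
    return [dv, dh_na, dn_k, dh_nap]


def reference_trajectory(
    params: MembraneParameters,
    E_L_effective: float,
    T: float,
    v0: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    t_eval=None,
):
    """High-accuracy adaptive integration of the same single-neuron ODE.

    Independent oracle for the fixed-step scheme: integrates with scipy's
    adaptive LSODA at tight tolerances.  Returns ``(t, V)``.
    """
    from scipy.integrate import solve_ivp

    state = MembraneState.at_rest(params, v0 if v0 is not None else E_L_effective)
    y0 = [state.V, state.h_Na, state.n_K, state.h_NaP]
    sol = solve_ivp(
        _rhs,
        (0.0, T),
        y0,
        args=(params, E_L_effective),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        max_step=1.0,
    )
    if not sol.success:
        raise NumericalInstabilityError(f"reference integration failed: {sol.message}")
    return sol.t, sol.y[0]


def _spike_based_regime(spike_times: np.ndarray, T: float, settle: float):
    """Classify a spike train as silence / bursting / tonic.

    Bursting is recognized from the inter-spike-interval histogram: a
    bursting train has long silent gaps (interburst intervals) separating
    runs of short intervals, i.e. max ISI >> median ISI.
    """
    spikes = spike_times[spike_times >= settle]
    if spikes.size < 5:
        return "silence"
    isi = np.diff(spikes)
    if isi.size < 4:
        return "silence"
    med = np.median(isi)
    # Gaps an order of magnitude above the intra-burst interval mark bursts.
    gap_mask = isi > max(6.0 * med, 60.0)
    n_gaps = int(gap_mask.sum())
    if n_gaps >= 3:
        return "bursting"
    return "tonic"


def single_neuron_regime(
    params: MembraneParameters,
    E_L_effective: float,
    T: float = 40_000.0,
    dt: float = 0.1,
    settle: float = 4_000.0,
) -> str:
    """Label the deterministic single-neuron trajectory at a fixed excitability.

    Returns one of ``{"silence", "bursting", "tonic"}``.  ``T`` must be long
    enough to contain at least ~5 burst cycles at the slowest expected burst
    rate; with the frozen defaults the slowest period is a few seconds, so
    the 40 s default is safe.
    """
    if T - settle < 10_000.0:
        raise InsufficientObservationError(
            "observation window too short: need >= 10 s after settling"
        )
    _, _, spikes = simulate_neuron(params, E_L_effective, T, dt=dt)
    return _spike_based_regime(spikes, T, settle)
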