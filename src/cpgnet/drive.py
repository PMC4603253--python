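"""Excitability drive schedules and probe perturbations.

The network's excitability is set by a dimensionless drive ``alpha`` in
``[0, 1)`` emulating neuroactive-drug concentration.  Each drive-sensitive
neuron maps it onto its leak reversal potential as

    E_L = E_L0 * (1 - drive_gain * alpha)

so that (with ``E_L0 < 0``) increasing drive depolarizes.  Populations
differ in ``drive_gain``, which is what makes the commissural pathway
balance frequency-dependent.

Perturbations are constant synaptic-conductance pulses onto one population,
used to elicit controlled burst deletions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DriveProtocol",
    "PerturbationSpec",
    "drive_to_leak",
    "alpha_ramp",
    "constant_drive",
    "add_perturbation",
]


def drive_to_leak(E_L0: float, alpha, drive_gain: float = 1.0):
    """Map drive ``alpha`` onto an effective leak reversal potential (mV).

    ``alpha`` must lie in [0, 1).  Vectorized over ``alpha``.
    """
    a = np.asarray(alpha, dtype=float)
    if np.any(a < 0.0) or np.any(a >= 1.0):
        raise ValueError("alpha must be in [0, 1)")
    out = E_L0 * (1.0 - drive_gain * a)
    return float(out) if np.isscalar(alpha) else out


@dataclass(frozen=True)
class PerturbationSpec:
    target: str          # population name
    onset: float         # ms
    duration: float      # ms
    sign: str            # "excitatory" | "inhibitory"
    amplitude: float     # nS, constant added conductance

    def __post_init__(self):
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError("sign must be 'excitatory' or 'inhibitory'")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.duration < 0 or self.onset < 0:
            raise ValueError("onset and duration must be >= 0")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class DriveProtocol:
    """Piecewise-linear alpha(t) schedule plus optional perturbation pulses.

    ``times`` (ms) must be increasing and span ``[0, duration]``; ``alphas``
    are the node values, interpolated linearly in between.
    """

    times: tuple[float, ...]
    alphas: tuple[float, ...]
    duration: float
    perturbations: tuple[PerturbationSpec, ...] = ()

    def __post_init__(self):
        t = np.asarray(self.times)
        a = np.asarray(self.alphas)
        if t.size != a.size or t.size < 2:
            raise ValueError("times and alphas must have equal length >= 2")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[0] != 0.0 or t[-1] < self.duration:
            raise ValueError("schedule must be defined on [0, duration]")
        if np.any(a < 0.0) or np.any(a >= 1.0):
            raise ValueError("alpha values must be in [0, 1)")
        for p in self.perturbations:
            if p.offset > self.duration:
                raise ValueError(
                    f"perturbation on {p.target} extends past protocol duration"
                )

    def alpha(self, t):
        """Evaluate alpha(t); pure and repeatable."""
        return np.interp(t, self.times, self.alphas)

    def alpha_samples(self, dt: float) -> np.ndarray:
        """alpha at every integration step midpoint over [0, duration)."""
        n = int(round(self.duration / dt))
        return self.alpha((np.arange(n) + 0.5) * dt)

    def to_tsv(self, dt: float = 100.0) -> str:
        t = np.arange(0.0, self.duration + dt / 2, dt)
        lines = ["t_ms\talpha"] + [
            f"{ti:.1f}\t{ai:.6f}" for ti, ai in zip(t, self.alpha(t))
        ]
        return "\n".join(lines) + "\n"


def alpha_ramp(alpha_start: float, alpha_end: float, T: float) -> DriveProtocol:
    """Linear drive ramp over ``T`` ms (constant drive if start == end)."""
    if not (0.0 <= alpha_start <= alpha_end < 1.0):
        raise ValueError("require 0 <= alpha_start <= alpha_end < 1")
    if T <= 0:
        raise ValueError("T must be positive")
    return DriveProtocol(times=(0.0, T), alphas=(alpha_start, alpha_end), duration=T)


def constant_drive(alpha: float, T: float) -> DriveProtocol:
    return alpha_ramp(alpha, alpha, T)


def add_perturbation(protocol: DriveProtocol, pert: PerturbationSpec) -> DriveProtocol:
    """Return a protocol with an added conductance pulse; pure.

    Two pulses overlapping in time on the same target are rejected.
    """
    if pert.offset > protocol.duration:
        raise ValueError("perturbation must lie within the protocol window")
    for p in protocol.perturbations:
        if p.target == pert.target and not (
            pert.onset >= p.offset or pert.offset <= p.onset
        ):
            raise ValueError(f"overlapping perturbations on {pert.target}")
    return DriveProtocol(
        times=protocol.times,
        alphas=protocol.alphas,
        duration=protocol.duration,
        perturbations=protocol.perturbations + (pert,),
    )
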