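"""Circuit architectures of the bilateral locomotor CPG as data.

Populations and projections are declarative specs; three builders construct
the canonical architectures:

* :func:`build_model1` — left/right flexor–extensor half-centers coupled by
  three commissural pathways: inhibitory V0_D (flexor-driven, inhibits the
  contralateral flexor center), excitatory V3 (flexor-driven, excites the
  contralateral flexor center), and the indirect V2a → V0_V route in which
  flexor-driven V2a neurons excite ipsilateral V0_V cells whose crossing
  axons recruit a contralateral inhibitory relay (InV0V) onto the flexor
  center.
* :func:`build_model2` — identical except the V2a population is driven by
  the ipsilateral *extensor* center and V0_V excites the contralateral
  flexor center directly (no relay).
* :func:`build_unified` — either core extended with the V1/V2b circuits
  that secure flexor–extensor alternation and gate locomotor frequency.

Lesions (population removal, hemisection) and axon-guidance knockouts
(Netrin-1, DCC, EphA4) are pure spec→spec transforms.  ``instantiate``
realizes a spec into a seeded synapse-level connectome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .neuron import DEFAULT_MEMBRANE, MembraneParameters

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationSpec",
    "ProjectionSpec",
    "TonicDrive",
    "NetworkSpec",
    "LesionSpec",
    "KnockoutSpec",
    "Connectome",
    "build_model1",
    "build_model2",
    "build_unified",
    "instantiate",
    "apply_lesion",
    "apply_knockout",
    "mirror",
    "scale_network",
    "DEFAULTS",
]

SIDES = ("l", "r")

ROLES = (
    "RG-F", "RG-E", "Inrg-F", "Inrg-E",
    "V0D", "V0V", "V3", "V2a", "V1", "V2b", "InV0V", "InV1",
)

#: Roles whose output synapses are inhibitory; all others excite.
INHIBITORY_ROLES = frozenset({"V0D", "V1", "V2b", "Inrg-F", "Inrg-E", "InV0V", "InV1"})


def _other(side: str) -> str:
    return "r" if side == "l" else "l"


def pop_name(side: str, role: str) -> str:
    return f"{side}-{role}"


def _split(name: str) -> tuple[str, str]:
    side, role = name.split("-", 1)
    return side, role


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    side: str
    role: str
    size: int
    E_L0: float                 # baseline leak reversal (mV), pre-drive
    E_L_spread: float = 0.5     # half-width of per-neuron uniform jitter (mV)
    drive_sensitive: bool = True
    drive_gain: float = 1.0
    rhythmogenic: bool = False  # carries g_NaP > 0

    def __post_init__(self):
        if self.size < 1:
            raise ValueError(f"population {self.name}: size must be >= 1")
        if self.E_L_spread < 0:
            raise ValueError(f"population {self.name}: E_L_spread must be >= 0")
        if self.side not in SIDES:
            raise ValueError(f"population {self.name}: side must be 'l' or 'r'")


@dataclass(frozen=True)
class ProjectionSpec:
    source: str
    target: str
    sign: str                   # "excitatory" | "inhibitory"
    p_connect: float
    weight: float               # conductance increment per spike (nS)
    weight_jitter: float = 0.0  # fractional uniform jitter on weight
    commissural: bool = False
    crossing_fraction: float = 1.0  # fraction of axons reaching the named
    # target; the remainder synapse on the contralateral homolog of the target

    def __post_init__(self):
        if not (0.0 < self.p_connect <= 1.0):
            raise ValueError(
                f"projection {self.source}->{self.target}: p_connect must be in (0, 1]"
            )
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError("sign must be 'excitatory' or 'inhibitory'")
        if not (0.0 <= self.crossing_fraction <= 1.0):
            raise ValueError("crossing_fraction must be in [0, 1]")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass(frozen=True)
class TonicDrive:
    """Constant excitatory conductance onto a population.

    ``source_side`` tags the (unmodeled) side of origin of the driving
    commissural axons, so hemisection of that side removes the drive.
    ``None`` marks an ipsilateral/local drive that survives hemisection.
    """

    target: str
    conductance: float  # nS
    source_side: str | None = None


@dataclass(frozen=True)
class NetworkSpec:
    populations: tuple[PopulationSpec, ...]
    projections: tuple[ProjectionSpec, ...]
    tonic_drives: tuple[TonicDrive, ...] = ()

    def __post_init__(self):
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        known = set(names)
        for proj in self.projections:
            for end in (proj.source, proj.target):
                if end not in known:
                    raise ValueError(f"projection endpoint {end!r} names no population")
        for d in self.tonic_drives:
            if d.target not in known:
                raise ValueError(f"tonic drive target {d.target!r} names no population")

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    def has_population(self, name: str) -> bool:
        return any(p.name == name for p in self.populations)

    def canonical(self):
        """Order-independent canonical form (for symmetry/equality tests)."""
        pops = tuple(sorted(self.populations, key=lambda p: p.name))
        projs = tuple(sorted(self.projections, key=lambda p: (p.source, p.target, p.sign)))
        drives = tuple(sorted(self.tonic_drives, key=lambda d: (d.target, d.source_side or "")))
        return (pops, projs, drives)

    def edge_table(self):
        """Multiset of (source role, target role, sign, commissural) edges.

        Within-population recurrent projections are included.  Used for the
        frozen schematic audits.
        """
        rows = []
        for pr in self.projections:
            _, sr = _split(pr.source)
            _, tr = _split(pr.target)
            rows.append((sr, tr, pr.sign, pr.commissural))
        return sorted(rows)

    def edge_list_tsv(self) -> str:
        """Plain-text export of the projection list for auditing."""
        lines = ["source\ttarget\tsign\tp_connect\tweight\tcommissural\tcrossing_fraction"]
        for pr in sorted(self.projections, key=lambda p: (p.source, p.target)):
            lines.append(
                f"{pr.source}\t{pr.target}\t{pr.sign}\t{pr.p_connect}\t"
                f"{pr.weight}\t{int(pr.commissural)}\t{pr.crossing_fraction}"
            )
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class LesionSpec:
    """Population removals and/or hemisection."""

    removed_roles: frozenset[str] = frozenset()
    side: str | None = None          # restrict removals to one side
    hemisection_side: str | None = None

    def __post_init__(self):
        if self.hemisection_side not in (None, "l", "r"):
            raise ValueError("hemisection_side must be None, 'l' or 'r'")


@dataclass(frozen=True)
class KnockoutSpec:
    """Axon-guidance knockout: a fraction of affected axons fails guidance."""

    type: str                  # "Netrin1" | "DCC" | "EphA4"
    f_reroute: float = 0.8

    def __post_init__(self):
        if self.type not in ("Netrin1", "DCC", "EphA4"):
            raise ValueError(f"unknown knockout type {self.type!r}")
        if not (0.0 <= self.f_reroute <= 1.0):
            raise ValueError("f_reroute must be in [0, 1]")


# ---------------------------------------------------------------------------
# Frozen default parameters of the architectures.
#
# Connection probabilities, synaptic weights and per-population excitability
# parameters are not dictated by the circuit diagrams; the values below were
# calibrated once against the qualitative regime structure (alternating
# intact locomotion, frequency-dependent V0 ablation phenotypes, V1/V2b
# flexor-extensor control) and then frozen.  Weights are quoted at the
# reference population sizes; ``scale_network`` keeps the expected total
# synaptic input invariant when sizes are scaled.
# ---------------------------------------------------------------------------

DEFAULTS: dict = {
    "sizes": {"RG-F": 200, "RG-E": 200},  # all other roles: 50
    "other_size": 50,
    "p_connect": 0.1,
    "weight_jitter": 0.2,
    "populations": {
        # role: (E_L0, spread, drive_sensitive, gain, rhythmogenic)
        "RG-F":   (-70.0, 3.0, True, 1.00, True),
        "RG-E":   (-64.0, 2.0, True, 0.10, True),
        "Inrg-F": (-67.0, 0.5, True, 1.00, False),
        "Inrg-E": (-67.0, 0.5, True, 1.00, False),
        "V0D":    (-64.0, 0.5, True, 0.30, False),
        "V3":     (-66.5, 0.5, True, 1.15, False),
        "V2a":    (-76.0, 0.5, True, 2.00, False),
        "V0V":    (-68.0, 0.5, True, 1.00, False),
        "InV0V":  (-66.0, 0.5, True, 1.00, False),
        "V2b":    (-67.0, 0.5, True, 1.00, False),
        "V1":     (-67.0, 0.5, True, 1.00, False),
        "InV1":   (-51.0, 0.5, False, 0.00, False),
    },
    "weights": {
        # (source role, target role): weight nS at reference sizes
        ("RG-F", "RG-F"): 0.03,
        ("RG-E", "RG-E"): 0.03,
        ("RG-F", "Inrg-F"): 0.40,
        ("Inrg-F", "RG-E"): 1.20,
        ("RG-E", "Inrg-E"): 0.40,
        ("Inrg-E", "RG-F"): 0.03,
        ("RG-F", "V0D"): 0.70,
        ("V0D", "RG-F"): 0.50,
        ("RG-F", "V3"): 0.25,
        ("V3", "RG-F"): 0.22,
        ("RG-F", "V2a"): 0.30,
        ("RG-E", "V2a"): 0.30,
        ("V2a", "V0V"): 0.80,
        ("V0V", "InV0V"): 1.20,
        ("InV0V", "RG-F"): 0.50,
        ("V0V", "RG-F"): 0.06,
        # unified extension
        ("RG-F", "V2b"): 0.40,
        ("RG-E", "V2b"): 0.0001,
        ("V2b", "RG-E"): 1.20,
        ("V2b", "RG-F"): 0.0001,
        ("V0D", "V1"): 0.40,
        ("V1", "RG-E"): 0.30,
        ("V1", "InV1"): 0.60,
        ("InV1", "RG-F"): 0.30,
        ("RG-F", "RG-E"): 0.15,
        ("RG-E", "RG-F"): 0.02,
    },
    "v1_tonic_drive": 1.4,       # nS, sourced from the contralateral side
    "unified_inrg_scale": 0.10,   # Inrg weight fraction retained alongside V2b
}


def _mk_pop(side: str, role: str, defaults: dict, size_overrides: dict | None) -> PopulationSpec:
    el0, spread, sens, gain, rhythm = defaults["populations"][role]
    size = defaults["sizes"].get(role, defaults["other_size"])
    if size_overrides and role in size_overrides:
        size = size_overrides[role]
    return PopulationSpec(
        name=pop_name(side, role), side=side, role=role, size=size,
        E_L0=el0, E_L_spread=spread, drive_sensitive=sens,
        drive_gain=gain, rhythmogenic=rhythm,
    )


def _mk_proj(
    src: str, tgt: str, defaults: dict, weight_scale: float = 1.0
) -> ProjectionSpec:
    s_side, s_role = _split(src)
    t_side, t_role = _split(tgt)
    sign = "inhibitory" if s_role in INHIBITORY_ROLES else "excitatory"
    return ProjectionSpec(
        source=src, target=tgt, sign=sign,
        p_connect=defaults["p_connect"],
        weight=defaults["weights"][(s_role, t_role)] * weight_scale,
        weight_jitter=defaults["weight_jitter"],
        commissural=(s_side != t_side),
    )


def _core_edges(model: int, side: str) -> list[tuple[str, str]]:
    o = _other(side)
    edges = [
        # rhythm-generating kernels with sparse recurrent excitation
        (pop_name(side, "RG-F"), pop_name(side, "RG-F")),
        (pop_name(side, "RG-E"), pop_name(side, "RG-E")),
        # flexor-extensor half-center inhibition via Inrg
        (pop_name(side, "RG-F"), pop_name(side, "Inrg-F")),
        (pop_name(side, "Inrg-F"), pop_name(side, "RG-E")),
        (pop_name(side, "RG-E"), pop_name(side, "Inrg-E")),
        (pop_name(side, "Inrg-E"), pop_name(side, "RG-F")),
        # inhibitory commissural pathway (V0_D)
        (pop_name(side, "RG-F"), pop_name(side, "V0D")),
        (pop_name(side, "V0D"), pop_name(o, "RG-F")),
        # excitatory synchronizing pathway (V3)
        (pop_name(side, "RG-F"), pop_name(side, "V3")),
        (pop_name(side, "V3"), pop_name(o, "RG-F")),
    ]
    if model == 1:
        edges += [
            (pop_name(side, "RG-F"), pop_name(side, "V2a")),
            (pop_name(side, "V2a"), pop_name(side, "V0V")),
            (pop_name(side, "V0V"), pop_name(o, "InV0V")),
            (pop_name(side, "InV0V"), pop_name(side, "RG-F")),
        ]
    else:
        edges += [
            (pop_name(side, "RG-E"), pop_name(side, "V2a")),
            (pop_name(side, "V2a"), pop_name(side, "V0V")),
            (pop_name(side, "V0V"), pop_name(o, "RG-F")),
        ]
    return edges


def _build_core(model: int, size_overrides=None, parameter_config=None) -> NetworkSpec:
    defaults = parameter_config or DEFAULTS
    roles = ["RG-F", "RG-E", "Inrg-F", "Inrg-E", "V0D", "V3", "V2a", "V0V"]
    if model == 1:
        roles.append("InV0V")
    pops = [_mk_pop(s, r, defaults, size_overrides) for s in SIDES for r in roles]
    projs = [
        _mk_proj(src, tgt, defaults)
        for s in SIDES
        for src, tgt in _core_edges(model, s)
    ]
    return NetworkSpec(tuple(pops), tuple(projs))


def build_model1(size_overrides=None, parameter_config=None) -> NetworkSpec:
    """Bilateral CPG with the flexor-driven, relayed V2a → V0_V pathway."""
    return _build_core(1, size_overrides, parameter_config)


def build_model2(size_overrides=None, parameter_config=None) -> NetworkSpec:
    """Bilateral CPG with the extensor-driven, direct V0_V pathway."""
    return _build_core(2, size_overrides, parameter_config)


def build_unified(core: str = "model1", size_overrides=None, parameter_config=None) -> NetworkSpec:
    """Extend a core architecture with the V1/V2b flexor–extensor circuits.

    Per side the extension adds: a V2b population implementing
    flexor–extensor mutual inhibition (driven mostly by the flexor center,
    inhibiting mostly the extensor center) in parallel with the Inrg
    populations, whose weights are scaled down so that V2b carries a share
    of the half-center inhibition; a V1 population kept tonically active by
    a constant excitatory drive of contralateral origin, phasically
    inhibited by the contralateral V0_D, inhibiting the ipsilateral extensor
    center; and an interposed, intrinsically active inhibitory population
    (InV1) that V1 suppresses, so that V1 activity disinhibits the
    ipsilateral flexor center.  Weak direct mutual excitation between the
    flexor and extensor centers is included; it is functionally silent under
    normal inhibition but synchronizes the two centers when the V1/V2b
    inhibition is removed.
    """
    if core == "model1":
        model = 1
    elif core == "model2":
        model = 2
    else:
        raise ValueError(f"unknown core label {core!r}")
    defaults = parameter_config or DEFAULTS
    base = _build_core(model, size_overrides, defaults)

    inrg_scale = defaults["unified_inrg_scale"]
    projs = []
    for pr in base.projections:
        _, s_role = _split(pr.source)
        if s_role in ("Inrg-F", "Inrg-E"):
            pr = replace(pr, weight=pr.weight * inrg_scale)
        projs.append(pr)

    pops = list(base.populations)
    drives = []
    for s in SIDES:
        o = _other(s)
        for role in ("V2b", "V1", "InV1"):
            pops.append(_mk_pop(s, role, defaults, size_overrides))
        new_edges = [
            (pop_name(s, "RG-F"), pop_name(s, "V2b")),
            (pop_name(s, "RG-E"), pop_name(s, "V2b")),
            (pop_name(s, "V2b"), pop_name(s, "RG-E")),
            (pop_name(s, "V2b"), pop_name(s, "RG-F")),
            (pop_name(s, "V0D"), pop_name(o, "V1")),
            (pop_name(s, "V1"), pop_name(s, "RG-E")),
            (pop_name(s, "V1"), pop_name(s, "InV1")),
            (pop_name(s, "InV1"), pop_name(s, "RG-F")),
            (pop_name(s, "RG-F"), pop_name(s, "RG-E")),
            (pop_name(s, "RG-E"), pop_name(s, "RG-F")),
        ]
        projs += [_mk_proj(src, tgt, defaults) for src, tgt in new_edges]
        drives.append(TonicDrive(pop_name(s, "V1"), defaults["v1_tonic_drive"], source_side=o))

    # sort pops so both sides share ordering
    return NetworkSpec(tuple(pops), tuple(projs), tuple(drives))


def mirror(spec: NetworkSpec) -> NetworkSpec:
    """Swap left and right labels throughout the spec."""

    def mname(name: str) -> str:
        side, role = _split(name)
        return pop_name(_other(side), role)

    pops = tuple(
        replace(p, name=mname(p.name), side=_other(p.side)) for p in spec.populations
    )
    projs = tuple(
        replace(pr, source=mname(pr.source), target=mname(pr.target))
        for pr in spec.projections
    )
    drives = tuple(
        replace(d, target=mname(d.target),
                source_side=None if d.source_side is None else _other(d.source_side))
        for d in spec.tonic_drives
    )
    return NetworkSpec(pops, projs, drives)


def scale_network(spec: NetworkSpec, scale: float, min_size: int = 3) -> NetworkSpec:
    """Scale population sizes by ``scale``, preserving synaptic statistics.

    Connection probabilities are scaled by ``1/scale`` so the expected
    in-degree of every target neuron is unchanged; where the probability
    would exceed 1 the excess is folded into the weight, keeping the
    expected total synaptic conductance onto each neuron invariant.  Regime
    structure of scaled-down runs is thereby preserved.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if scale == 1.0:
        return spec
    pops = tuple(
        replace(p, size=max(min_size, round(p.size * scale))) for p in spec.populations
    )
    projs = []
    for pr in spec.projections:
        p_new = pr.p_connect / scale
        if p_new <= 1.0:
            projs.append(replace(pr, p_connect=p_new))
        else:
            projs.append(replace(pr, p_connect=1.0, weight=pr.weight * p_new))
    return NetworkSpec(pops, tuple(projs), spec.tonic_drives)


def apply_lesion(spec: NetworkSpec, lesion: LesionSpec) -> NetworkSpec:
    """Remove populations (by role, optionally one side) and/or hemisect."""
    removed: set[str] = set()
    for role in lesion.removed_roles:
        hits = [
            p.name for p in spec.populations
            if p.role == role and (lesion.side is None or p.side == lesion.side)
        ]
        if not hits:
            logger.warning("lesion: role %r absent from network, ignored", role)
        removed.update(hits)
    if lesion.hemisection_side is not None:
        removed.update(p.name for p in spec.populations if p.side == lesion.hemisection_side)

    pops = tuple(p for p in spec.populations if p.name not in removed)
    projs = tuple(
        pr for pr in spec.projections
        if pr.source not in removed and pr.target not in removed
    )
    drives = tuple(
        d for d in spec.tonic_drives
        if d.target not in removed and d.source_side != lesion.hemisection_side
    )
    return NetworkSpec(pops, projs, drives)


def apply_knockout(spec: NetworkSpec, ko: KnockoutSpec) -> NetworkSpec:
    """Model an axon-guidance knockout as partial rerouting of axons.

    Netrin-1 loss: commissural V0_D/V0_V axons fail to cross (rerouted to
    the ipsilateral homolog of their target); V3 unaffected.  DCC loss: the
    same failure for V0_D, V0_V *and* V3.  EphA4 loss: a fraction of
    V2a → V0_V axons aberrantly cross to the contralateral V0_V population.
    """
    f = ko.f_reroute

    def affected(pr: ProjectionSpec) -> bool:
        _, s_role = _split(pr.source)
        _, t_role = _split(pr.target)
        if ko.type == "Netrin1":
            return pr.commissural and s_role in ("V0D", "V0V")
        if ko.type == "DCC":
            return pr.commissural and s_role in ("V0D", "V0V", "V3")
        return (not pr.commissural) and s_role == "V2a" and t_role == "V0V"

    projs = tuple(
        replace(pr, crossing_fraction=pr.crossing_fraction * (1.0 - f))
        if affected(pr) else pr
        for pr in spec.projections
    )
    return NetworkSpec(spec.populations, projs, spec.tonic_drives)


# ---------------------------------------------------------------------------
# Connectome realization
# ---------------------------------------------------------------------------


@dataclass
class Connectome:
    """Synapse-level realization of a NetworkSpec.

    Adjacency is stored in CSR layout by source neuron; weights are signed
    (negative = inhibitory).  Per-neuron excitability arrays carry the
    jittered leak-reversal baselines and drive gains consumed by the engine.
    """

    spec: NetworkSpec
    seed: int
    membrane: MembraneParameters
    pop_names: list[str]
    pop_slices: dict                 # name -> (start, stop)
    pop_of: np.ndarray               # int32 [n]
    E_L0: np.ndarray                 # float64 [n], jittered baselines
    drive_gain: np.ndarray           # float64 [n] (0 = drive-insensitive)
    g_NaP: np.ndarray                # float64 [n]
    g_tonic_E: np.ndarray            # float64 [n]
    syn_ptr: np.ndarray              # int64 [n+1]
    syn_tgt: np.ndarray              # int32 [nsyn]
    syn_w: np.ndarray                # float64 [nsyn], signed

    @property
    def n_neurons(self) -> int:
        return self.pop_of.size

    @property
    def n_synapses(self) -> int:
        return self.syn_tgt.size

    def neurons_of(self, name: str) -> np.ndarray:
        start, stop = self.pop_slices[name]
        return np.arange(start, stop)

    def synapse_count(self, source: str, target: str) -> int:
        """Number of realized synapses from one population onto another."""
        s0, s1 = self.pop_slices[source]
        t0, t1 = self.pop_slices[target]
        count = 0
        for i in range(s0, s1):
            tgts = self.syn_tgt[self.syn_ptr[i]:self.syn_ptr[i + 1]]
            count += int(np.sum((tgts >= t0) & (tgts < t1)))
        return count


def instantiate(
    spec: NetworkSpec,
    seed: int,
    membrane: MembraneParameters = DEFAULT_MEMBRANE,
) -> Connectome:
    """Realize per-pair Bernoulli synapses and per-neuron parameter jitter.

    Identical ``(spec, seed)`` pairs yield bit-identical connectomes.  Axons
    of a projection with ``crossing_fraction < 1`` are rerouted per source
    neuron: a Bernoulli(crossing_fraction) draw decides whether each axon
    reaches the named target population or its contralateral homolog.
    """
    rng = np.random.default_rng(seed)
    pops = list(spec.populations)
    pop_names = [p.name for p in pops]
    sizes = [p.size for p in pops]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n = int(offsets[-1])
    pop_slices = {
        name: (int(offsets[i]), int(offsets[i + 1])) for i, name in enumerate(pop_names)
    }
    pop_of = np.repeat(np.arange(len(pops), dtype=np.int32), sizes)

    E_L0 = np.empty(n)
    drive_gain = np.zeros(n)
    g_NaP = np.zeros(n)
    g_tonic_E = np.zeros(n)
    for i, p in enumerate(pops):
        s0, s1 = int(offsets[i]), int(offsets[i + 1])
        E_L0[s0:s1] = p.E_L0 + rng.uniform(-p.E_L_spread, p.E_L_spread, s1 - s0)
        if p.drive_sensitive:
            drive_gain[s0:s1] = p.drive_gain
        if p.rhythmogenic:
            g_NaP[s0:s1] = membrane.g_NaP

    for d in spec.tonic_drives:
        t0, t1 = pop_slices[d.target]
        g_tonic_E[t0:t1] += d.conductance

    def homolog(name: str) -> str:
        side, role = _split(name)
        return pop_name(_other(side), role)

    # per-source-neuron synapse lists
    per_source_tgts: list[list[np.ndarray]] = [[] for _ in range(n)]
    per_source_ws: list[list[np.ndarray]] = [[] for _ in range(n)]

    for pr in spec.projections:
        s0, s1 = pop_slices[pr.source]
        sign = -1.0 if pr.sign == "inhibitory" else 1.0
        targets = []
        if pr.crossing_fraction > 0.0:
            targets.append((pr.target, pr.crossing_fraction))
        if pr.crossing_fraction < 1.0:
            hom = homolog(pr.target)
            if hom not in pop_slices:
                logger.warning(
                    "rerouted axons of %s->%s have no homologous target; dropped",
                    pr.source, pr.target,
                )
            else:
                targets.append((hom, 1.0 - pr.crossing_fraction))
        if not targets:
            continue
        # decide per-axon destination
        u = rng.random(s1 - s0)
        for src_local, src in enumerate(range(s0, s1)):
            tgt_name = targets[0][0] if u[src_local] < targets[0][1] or len(targets) == 1 else targets[1][0]
            t0, t1 = pop_slices[tgt_name]
            cand = np.arange(t0, t1)
            if tgt_name == pr.source:
                cand = cand[cand != src]  # no autapses
            hit = rng.random(cand.size) < pr.p_connect
            tgts = cand[hit]
            if tgts.size == 0:
                continue
            w = np.full(tgts.size, pr.weight)
            if pr.weight_jitter > 0:
                w *= 1.0 + rng.uniform(-pr.weight_jitter, pr.weight_jitter, tgts.size)
            per_source_tgts[src].append(tgts.astype(np.int32))
            per_source_ws[src].append(sign * w)

    syn_ptr = np.zeros(n + 1, dtype=np.int64)
    tgt_chunks = []
    w_chunks = []
    for i in range(n):
        if per_source_tgts[i]:
            t = np.concatenate(per_source_tgts[i])
            w = np.concatenate(per_source_ws[i])
        else:
            t = np.empty(0, dtype=np.int32)
            w = np.empty(0)
        syn_ptr[i + 1] = syn_ptr[i] + t.size
        tgt_chunks.append(t)
        w_chunks.append(w)
    syn_tgt = np.concatenate(tgt_chunks) if tgt_chunks else np.empty(0, dtype=np.int32)
    syn_w = np.concatenate(w_chunks) if w_chunks else np.empty(0)

    return Connectome(
        spec=spec, seed=seed, membrane=membrane,
        pop_names=pop_names, pop_slices=pop_slices, pop_of=pop_of,
        E_L0=E_L0, drive_gain=drive_gain, g_NaP=g_NaP, g_tonic_E=g_tonic_E,
        syn_ptr=syn_ptr, syn_tgt=syn_tgt.astype(np.int32), syn_w=syn_w,
    )
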