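"""Experiment configuration, execution and outputs.

An :class:`ExperimentConfig` is a fully declarative, JSON-serializable
description of one in-silico experiment: which architecture to build, which
lesion/knockout transform to apply, the drive protocol, simulation settings
and analysis parameters.  ``run_experiment`` resolves it into a seeded
pipeline (build -> instantiate -> simulate -> analyze) and returns an
:class:`ExperimentResult`; ``write_outputs`` materializes TSV/JSON files
plus a manifest.  Identical config + seed reproduce identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import analysis as an
from .drive import DriveProtocol, PerturbationSpec, add_perturbation
from .engine import SimulationConfig, SpikeRecord, simulate
from .network import (
    Connectome,
    KnockoutSpec,
    LesionSpec,
    NetworkSpec,
    build_model1,
    build_model2,
    build_unified,
    instantiate,
    scale_network,
)
from .network import DEFAULTS, PopulationSpec, ProjectionSpec

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "write_outputs", "PRESETS"]

VERSION = "0.1.0"


def _isolated_rg_spec(parameter_config=None) -> NetworkSpec:
    """A single rhythm-generating flexor population with recurrent excitation."""
    d = parameter_config or DEFAULTS
    el0, spread, sens, gain, rhythm = d["populations"]["RG-F"]
    pop = PopulationSpec("l-RG-F", "l", "RG-F", d["sizes"]["RG-F"], el0, spread, sens, gain, rhythm)
    proj = ProjectionSpec(
        "l-RG-F", "l-RG-F", "excitatory", d["p_connect"],
        d["weights"][("RG-F", "RG-F")], d["weight_jitter"],
    )
    return NetworkSpec((pop,), (proj,))


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one experiment; digest-stable."""

    name: str
    architecture: str                    # isolated_rg | model1 | model2 | unified:model1 | unified:model2
    kind: str                            # regime_ramp | coordination | deletion
    protocol: dict = field(default_factory=dict)    # {type, alpha0, alpha1, t_hold_ms, t_ramp_ms, t_top_ms, duration_ms}
    lesion: dict | None = None           # {removed_roles: [...], side, hemisection_side}
    knockout: dict | None = None         # {type, f_reroute}
    sim: dict = field(default_factory=lambda: {"dt": 0.1, "noise_sigma": 0.0})
    analysis: dict = field(default_factory=dict)
    probe: dict | None = None            # deletion probes
    scale: float = 0.25

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # -- resolution helpers -------------------------------------------------

    def build_network(self) -> NetworkSpec:
        if self.architecture == "isolated_rg":
            spec = _isolated_rg_spec()
        elif self.architecture == "model1":
            spec = build_model1()
        elif self.architecture == "model2":
            spec = build_model2()
        elif self.architecture.startswith("unified"):
            core = self.architecture.split(":")[1] if ":" in self.architecture else "model1"
            spec = build_unified(core)
        else:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.knockout:
            from .network import apply_knockout
            spec = apply_knockout(spec, KnockoutSpec(**self.knockout))
        if self.lesion:
            from .network import apply_lesion
            les = dict(self.lesion)
            if "removed_roles" in les:
                les["removed_roles"] = frozenset(les["removed_roles"])
            # hemisection is applied first so role removals act on the
            # surviving side
            if les.get("hemisection_side"):
                from .network import apply_lesion as _al
                spec = _al(spec, LesionSpec(hemisection_side=les["hemisection_side"]))
                les["hemisection_side"] = None
            if les.get("removed_roles"):
                spec = apply_lesion_roles(spec, les)
        return scale_network(spec, self.scale)

    def build_protocol(self) -> DriveProtocol:
        p = self.protocol
        if p["type"] == "constant":
            T = p["duration_ms"]
            return DriveProtocol(times=(0.0, T), alphas=(p["alpha0"], p["alpha0"]), duration=T)
        if p["type"] == "hold_ramp":
            t_hold = p.get("t_hold_ms", 0.0)
            t_ramp = p["t_ramp_ms"]
            t_top = p.get("t_top_ms", 0.0)
            T = t_hold + t_ramp + t_top
            times = [0.0]
            alphas = [p["alpha0"]]
            if t_hold > 0:
                times.append(t_hold)
                alphas.append(p["alpha0"])
            times.append(t_hold + t_ramp)
            alphas.append(p["alpha1"])
            if t_top > 0:
                times.append(T)
                alphas.append(p["alpha1"])
            return DriveProtocol(times=tuple(times), alphas=tuple(alphas), duration=T)
        raise ValueError(f"unknown protocol type {p['type']!r}")

    @property
    def duration(self) -> float:
        p = self.protocol
        if p["type"] == "constant":
            return p["duration_ms"]
        return p.get("t_hold_ms", 0.0) + p["t_ramp_ms"] + p.get("t_top_ms", 0.0)


def apply_lesion_roles(spec: NetworkSpec, les: dict) -> NetworkSpec:
    from .network import apply_lesion
    return apply_lesion(
        spec,
        LesionSpec(
            removed_roles=frozenset(les.get("removed_roles", ())),
            side=les.get("side"),
        ),
    )


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    seed: int
    record: SpikeRecord
    traces: dict
    reports: dict                       # name -> json-serializable dict
    summary: dict                       # headline numbers / labels

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(self.config.digest().encode())
        h.update(self.record.digest().encode())
        h.update(json.dumps(self.summary, sort_keys=True, default=str).encode())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Preset catalog.  Drive levels and durations below define the study
# conditions of each experiment and are frozen; `scale` may be overridden
# for larger runs.
# ---------------------------------------------------------------------------

_RAMP = {"type": "hold_ramp", "alpha0": 0.06, "alpha1": 0.115,
         "t_hold_ms": 20_000.0, "t_ramp_ms": 90_000.0}
_COORD_ANALYSIS = {"window_ms": 15_000.0, "t0_ms": 20_000.0, "min_cycles": 4, "bin_ms": 100.0}


def _coord(name, architecture, protocol, lesion=None, knockout=None, analysis=None, sim=None):
    return ExperimentConfig(
        name=name, architecture=architecture, kind="coordination",
        protocol=protocol, lesion=lesion, knockout=knockout,
        analysis={**_COORD_ANALYSIS, **(analysis or {})},
        sim={"dt": 0.1, "noise_sigma": 0.0, **(sim or {})},
    )


PRESETS: dict[str, ExperimentConfig] = {}

PRESETS["isolated_rg_ramp"] = ExperimentConfig(
    name="isolated_rg_ramp", architecture="isolated_rg", kind="regime_ramp",
    protocol={"type": "hold_ramp", "alpha0": 0.0, "alpha1": 1.0 - 56.5 / 70.0,
              "t_hold_ms": 15_000.0, "t_ramp_ms": 90_000.0, "t_top_ms": 15_000.0},
    analysis={"window_ms": 15_000.0, "t0_ms": 5_000.0, "bin_ms": 100.0,
              "silence_rate": 1.0, "coherent_frac": 0.2, "freq_window_ms": 10_000.0},
)

PRESETS["model1_ramp"] = _coord("model1_ramp", "model1", _RAMP)
PRESETS["model2_ramp"] = _coord("model2_ramp", "model2", _RAMP)

for model in ("model1", "model2"):
    tag = "" if model == "model1" else "_m2"
    PRESETS[f"ablate_v0_both{tag}"] = _coord(
        f"ablate_v0_both{tag}", model, _RAMP, lesion={"removed_roles": ["V0D", "V0V"]})
    PRESETS[f"ablate_v0v{tag}"] = _coord(
        f"ablate_v0v{tag}", model, _RAMP, lesion={"removed_roles": ["V0V"]})
    PRESETS[f"ablate_v2a{tag}"] = _coord(
        f"ablate_v2a{tag}", model, _RAMP, lesion={"removed_roles": ["V2a"]})
    PRESETS[f"ablate_v0d{tag}"] = _coord(
        f"ablate_v0d{tag}", model, _RAMP, lesion={"removed_roles": ["V0D"]})

_KO_PROTO = {"type": "constant", "alpha0": 0.08, "duration_ms": 100_000.0}
PRESETS["ko_netrin1"] = _coord(
    "ko_netrin1", "model1", _KO_PROTO, knockout={"type": "Netrin1", "f_reroute": 0.8},
    analysis={"window_ms": 25_000.0, "t0_ms": 15_000.0})
PRESETS["ko_dcc"] = _coord(
    "ko_dcc", "model1", _KO_PROTO, knockout={"type": "DCC", "f_reroute": 0.8},
    analysis={"window_ms": 25_000.0, "t0_ms": 15_000.0})
PRESETS["ko_epha4"] = _coord(
    "ko_epha4", "model1",
    {"type": "constant", "alpha0": 0.095, "duration_ms": 100_000.0},
    knockout={"type": "EphA4", "f_reroute": 0.8},
    analysis={"window_ms": 25_000.0, "t0_ms": 15_000.0})

_UNI = {"type": "constant", "alpha0": 0.08, "duration_ms": 80_000.0}
PRESETS["unified_intact"] = _coord("unified_intact", "unified:model1", _UNI,
                                   analysis={"t0_ms": 20_000.0})
PRESETS["unified_v1_silence"] = _coord(
    "unified_v1_silence", "unified:model1", _UNI,
    lesion={"removed_roles": ["V1"]}, analysis={"t0_ms": 20_000.0})
PRESETS["unified_v1v2b_silence"] = _coord(
    "unified_v1v2b_silence", "unified:model1",
    {"type": "constant", "alpha0": 0.12, "duration_ms": 80_000.0},
    lesion={"removed_roles": ["V1", "V2b"]}, analysis={"t0_ms": 20_000.0})
PRESETS["hemicord"] = _coord(
    "hemicord", "unified:model1",
    {"type": "constant", "alpha0": 0.14, "duration_ms": 80_000.0},
    lesion={"hemisection_side": "r"},
    analysis={"t0_ms": 20_000.0, "window_ms": 30_000.0})
PRESETS["hemicord_v2b_silence"] = _coord(
    "hemicord_v2b_silence", "unified:model1",
    {"type": "constant", "alpha0": 0.115, "duration_ms": 80_000.0},
    lesion={"hemisection_side": "r", "removed_roles": ["V2b"]},
    analysis={"t0_ms": 20_000.0, "window_ms": 30_000.0})

for kind, target, sign in (("flexor", "l-RG-F", "inhibitory"),
                           ("extensor", "l-Inrg-F", "excitatory")):
    PRESETS[f"deletion_probe_{kind}"] = ExperimentConfig(
        name=f"deletion_probe_{kind}", architecture="model1", kind="deletion",
        protocol={"type": "constant", "alpha0": 0.08, "duration_ms": 70_000.0},
        probe={"deletion_type": kind, "target": target, "sign": sign,
               "amplitude_ns": 3.0, "n_cycles": 1.55, "t_earliest_ms": 42_000.0,
               "fit_t0_ms": 15_000.0, "fit_t1_ms": 45_000.0},
        analysis={"bin_ms": 100.0},
    )


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------


def _analyze_regime_ramp(cfg, record, traces, protocol):
    a = cfg.analysis
    tr = traces["l-RG-F"]
    W = a["window_ms"]
    windows = []
    for w0 in np.arange(a["t0_ms"], cfg.duration - W + 1, W):
        sl = tr.slice(w0, w0 + W)
        b = an.detect_bursts(sl)
        lab = an.classify_regime(sl, b, silence_rate=a.get("silence_rate", 1.0))
        windows.append({
            "t0_ms": float(w0),
            "alpha_mid": float(protocol.alpha(w0 + W / 2)),
            "regime": lab,
            "n_bursts": int(b.n),
            "mean_rate": sl.mean_rate(),
        })
    bursts = an.detect_bursts(tr)
    # coherent-burst filtered frequency / amplitude series
    if bursts.n >= 5:
        smoothed = np.convolve(bursts.peaks, np.ones(5) / 5, mode="valid")
        keep = bursts.peaks >= a.get("coherent_frac", 0.2) * smoothed.max()
        onsets = bursts.onsets[keep]
        freq = []
        for w0 in np.arange(0.0, cfg.duration, a.get("freq_window_ms", 10_000.0)):
            sel = (onsets >= w0) & (onsets < w0 + a.get("freq_window_ms", 10_000.0))
            if sel.sum() >= 2:
                freq.append({"t0_ms": float(w0), "frequency_hz": float(1000.0 / np.diff(onsets[sel]).mean())})
        amp = {
            "smoothed_first": float(smoothed[0]),
            "smoothed_max": float(smoothed.max()),
            "argmax": int(np.argmax(smoothed)),
            "n": int(smoothed.size),
            "smoothed_last": float(smoothed[-1]),
        }
    else:
        freq, amp = [], {}
    seq = [w["regime"] for w in windows]
    dedup = [s for i, s in enumerate(seq) if i == 0 or s != seq[i - 1]]
    reports = {
        "regime_windows": windows,
        "frequency_series": freq,
        "amplitude_summary": amp,
    }
    summary = {"regime_sequence": dedup, "n_bursts": int(bursts.n)}
    return reports, summary


def _analyze_coordination(cfg, record, traces, protocol):
    a = cfg.analysis
    side = "l" if "l-RG-F" in traces else "r"
    other = "r" if side == "l" else "l"
    bilateral = f"{other}-RG-F" in traces
    rep = an.windowed_coordination(
        traces,
        ref_pop=f"{side}-RG-F",
        lr_pop=f"{other}-RG-F" if bilateral else f"{side}-RG-F",
        fe_pop=f"{side}-RG-E",
        window_ms=a["window_ms"],
        t0=a["t0_ms"],
        min_cycles=a["min_cycles"],
    )
    table = rep.table
    if not bilateral:
        for col in ("left_right_label", "left_right_phase", "left_right_R"):
            table[col] = None if col.endswith("label") else np.nan
    lr = [x for x in table["left_right_label"] if isinstance(x, str)]
    fe = [x for x in table["flexor_extensor_label"] if isinstance(x, str)]
    freqs = [f for f in table["frequency_hz"] if np.isfinite(f)]
    summary = {
        "left_right_labels": lr,
        "flexor_extensor_labels": fe,
        "frequency_first_hz": freqs[0] if freqs else None,
        "frequency_last_hz": freqs[-1] if freqs else None,
        "mean_frequency_hz": float(np.mean(freqs)) if freqs else None,
    }
    return {"coordination": rep.to_json_dict()}, summary


def _analyze_deletion(cfg, connectome, protocol, sim_seed):
    """Two-stage deletion probe: fit the rhythm, place the pulse, re-run."""
    p = cfg.probe
    a = cfg.analysis
    T = cfg.duration
    stage1 = simulate(
        connectome, protocol,
        SimulationConfig(duration=p["fit_t1_ms"], dt=cfg.sim["dt"], seed=sim_seed,
                         noise_sigma=cfg.sim.get("noise_sigma", 0.0)),
    )
    traces1 = an.rate_histogram(stage1, a.get("bin_ms", 100.0))
    ref_pop = "l-RG-F" if p["deletion_type"] == "flexor" else "l-RG-E"
    b1 = an.detect_bursts(traces1[ref_pop].slice(p["fit_t0_ms"], p["fit_t1_ms"]))
    if b1.n < 6:
        raise an.InsufficientObservationError("pre-probe rhythm too sparse to place the pulse")
    period = float(np.diff(b1.onsets).mean())
    anchor = float(b1.onsets[-1])
    k = int(np.ceil((p["t_earliest_ms"] - anchor) / period))
    center = anchor + k * period
    dur = p["n_cycles"] * period
    onset = center - dur / 2.0
    pert = PerturbationSpec(p["target"], onset, dur, p["sign"], p["amplitude_ns"])
    proto2 = add_perturbation(protocol, pert)
    record = simulate(
        connectome, proto2,
        SimulationConfig(duration=T, dt=cfg.sim["dt"], seed=sim_seed,
                         noise_sigma=cfg.sim.get("noise_sigma", 0.0)),
    )
    traces = an.rate_histogram(record, a.get("bin_ms", 100.0))
    w0, w1 = onset, onset + dur
    if p["deletion_type"] == "flexor":
        target_b = an.detect_bursts(traces["l-RG-F"].slice(p["fit_t0_ms"], T))
        antagonist = traces["l-RG-E"]
        contra_b = an.detect_bursts(traces["r-RG-F"].slice(p["fit_t0_ms"], T))
    else:
        target_b = an.detect_bursts(traces["l-RG-E"].slice(p["fit_t0_ms"], T))
        antagonist = traces["l-RG-F"]
        contra_b = an.detect_bursts(traces["l-RG-F"].slice(p["fit_t0_ms"], T))
    dele = an.classify_deletions(
        target_b, antagonist, contra_b, (w0, w1), deletion_type=p["deletion_type"]
    )
    # ipsilateral flexor timing deviation (for extensor probes the
    # "contralateral" series above is the ipsilateral flexor)
    flex_b = an.detect_bursts(traces["l-RG-F"].slice(p["fit_t0_ms"], T))
    pre = flex_b.onsets[flex_b.onsets < w0]
    flex_dev = np.nan
    if pre.size >= 3:
        Tm = float(np.diff(pre).mean())
        anchor2 = float(pre[-1])
        post = flex_b.onsets[(flex_b.onsets >= w0) & (flex_b.onsets < w1 + Tm)]
        devs = [abs(t - (anchor2 + round((t - anchor2) / Tm) * Tm)) / Tm for t in post]
        flex_dev = float(np.median(devs)) if devs else np.nan
    reports = {"deletions": dele.to_json_dict(),
               "probe": {"onset_ms": onset, "duration_ms": dur, "period_ms": period}}
    summary = {
        "n_deletions": dele.n_deletions,
        "antagonist_labels": [e["antagonist"] for e in dele.events],
        "contralateral_deviation": dele.contralateral_deviation,
        "flexor_onset_deviation": None if np.isnan(flex_dev) else flex_dev,
        "resetting": dele.resetting,
    }
    return record, traces, reports, summary


def run_experiment(
    preset: str | ExperimentConfig,
    seed: int = 0,
    scale: float | None = None,
    overrides: dict | None = None,
) -> ExperimentResult:
    """Execute a preset or explicit config; idempotent for a fixed seed.

    ``seed`` feeds both the connectome realization and the simulation's
    initial conditions (derived sub-seeds).  ``scale`` overrides the
    population-size scale factor; ``overrides`` is a shallow dict merge into
    the config fields.
    """
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise KeyError(f"unknown preset {preset!r}; known: {sorted(PRESETS)}")
        cfg = PRESETS[preset]
    else:
        cfg = preset
    if scale is not None or overrides:
        d = cfg.to_dict()
        if scale is not None:
            d["scale"] = scale
        for k, v in (overrides or {}).items():
            if isinstance(d.get(k), dict) and isinstance(v, dict):
                d[k] = {**d[k], **v}
            else:
                d[k] = v
        cfg = ExperimentConfig.from_dict(d)

    spec = cfg.build_network()
    conn = instantiate(spec, seed=seed)
    protocol = cfg.build_protocol()
    sim_seed = seed + 1

    if cfg.kind == "deletion":
        record, traces, reports, summary = _analyze_deletion(cfg, conn, protocol, sim_seed)
    else:
        record = simulate(
            conn, protocol,
            SimulationConfig(duration=cfg.duration, dt=cfg.sim["dt"], seed=sim_seed,
                            noise_sigma=cfg.sim.get("noise_sigma", 0.0)),
        )
        traces = an.rate_histogram(record, cfg.analysis.get("bin_ms", 100.0))
        if cfg.kind == "regime_ramp":
            reports, summary = _analyze_regime_ramp(cfg, record, traces, protocol)
        elif cfg.kind == "coordination":
            reports, summary = _analyze_coordination(cfg, record, traces, protocol)
        else:
            raise ValueError(f"unknown experiment kind {cfg.kind!r}")

    logger.info("experiment %s seed=%s digest=%s", cfg.name, seed, cfg.digest())
    return ExperimentResult(
        config=cfg, seed=seed, record=record, traces=traces,
        reports=reports, summary=summary,
    )


def write_outputs(result: ExperimentResult, out_dir: str | Path) -> dict:
    """Write spikes, traces, reports and a manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = result.config.digest()
    header = f"# preset={result.config.name} seed={result.seed} config_digest={digest}\n"
    files = []

    spikes_path = out / "spikes.tsv"
    spikes_path.write_text(header + result.record.to_tsv())
    files.append(spikes_path.name)
    popmap_path = out / "populations.tsv"
    popmap_path.write_text(header + result.record.pop_map_tsv())
    files.append(popmap_path.name)

    for name, tr in result.traces.items():
        p = out / f"trace_{name}.tsv"
        lines = [header.rstrip(), "t_ms\trate"] + [
            f"{t:.1f}\t{r:.4f}" for t, r in zip(tr.t, tr.rate)
        ]
        p.write_text("\n".join(lines) + "\n")
        files.append(p.name)

    for name, rep in result.reports.items():
        p = out / f"report_{name}.json"
        p.write_text(json.dumps({"config_digest": digest, **_jsonable(rep)},
                                indent=2, default=str))
        files.append(p.name)

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(
        {"config_digest": digest, "seed": result.seed, "version": VERSION,
         "summary": _jsonable(result.summary)}, indent=2, default=str))
    files.append(summary_path.name)

    manifest = {
        "preset": result.config.name,
        "config": result.config.to_dict(),
        "config_digest": digest,
        "result_digest": result.digest(),
        "seed": result.seed,
        "version": VERSION,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj
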