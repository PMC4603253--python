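"""From spike records to locomotor measurements.

All classifiers are pure functions of their inputs plus explicitly passed
thresholds.  The measurement chain is:

    SpikeRecord -> rate histograms -> burst series -> regime labels,
    frequency/amplitude curves, left-right and flexor-extensor phase
    statistics, deletion classification, phase-duration asymmetry.

Phase conventions follow the flexor-dominated framing: cycles are delimited
by flexor burst onsets, the flexor phase is the flexor burst duration and
the extensor phase is the inter-flexor-burst gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import SpikeRecord
from .neuron import InsufficientObservationError

__all__ = [
    "ActivityTrace",
    "BurstSeries",
    "PhaseStats",
    "CoordinationReport",
    "DeletionReport",
    "PhaseDurationFit",
    "rate_histogram",
    "detect_bursts",
    "classify_regime",
    "frequency_amplitude_series",
    "phase_relation",
    "windowed_coordination",
    "classify_deletions",
    "phase_duration_slopes",
    "BURST_THRESHOLDS",
]

#: Frozen burst-detection thresholds: hysteresis on/off as fractions of the
#: running 90th-percentile reference (20 s sliding window), minimum burst
#: duration in ms.
BURST_THRESHOLDS = {"on_frac": 0.3, "off_frac": 0.15, "min_dur": 200.0, "ref_window": 20_000.0}

#: Coordination label thresholds: phase tolerance around 0 (synchrony) or
#: 0.5 (alternation) and the minimum circular concentration.
PHASE_TOL = 0.2
R_MIN = 0.7


@dataclass
class ActivityTrace:
    """Mean population firing rate per time bin, spikes/(neuron*s)."""

    population: str
    bin_ms: float
    t: np.ndarray       # bin start times, ms
    rate: np.ndarray

    @property
    def duration(self) -> float:
        return self.t[-1] + self.bin_ms if self.t.size else 0.0

    def mean_rate(self, t0: float = 0.0, t1: float | None = None) -> float:
        sel = self.t >= t0
        if t1 is not None:
            sel &= self.t < t1
        return float(self.rate[sel].mean()) if sel.any() else 0.0

    def slice(self, t0: float, t1: float) -> "ActivityTrace":
        sel = (self.t >= t0) & (self.t < t1)
        return ActivityTrace(self.population, self.bin_ms, self.t[sel], self.rate[sel])


@dataclass
class BurstSeries:
    """Ordered burst events of one population trace."""

    population: str
    onsets: np.ndarray      # ms
    offsets: np.ndarray     # ms
    peaks: np.ndarray       # spikes/(neuron*s)
    thresholds: dict = field(default_factory=dict)
    on_level: np.ndarray | None = None   # per-bin on threshold (for audits)
    off_level: np.ndarray | None = None
    level_t: np.ndarray | None = None

    def __post_init__(self):
        if self.onsets.size:
            if np.any(np.diff(self.onsets) <= 0):
                raise ValueError("burst onsets must be strictly increasing")
            if np.any(self.offsets <= self.onsets):
                raise ValueError("burst offsets must follow onsets")
            if np.any(self.onsets[1:] < self.offsets[:-1]):
                raise ValueError("bursts must not overlap")

    @property
    def n(self) -> int:
        return self.onsets.size

    def durations(self) -> np.ndarray:
        return self.offsets - self.onsets

    def periods(self) -> np.ndarray:
        return np.diff(self.onsets)

    def slice(self, t0: float, t1: float) -> "BurstSeries":
        sel = (self.onsets >= t0) & (self.onsets < t1)
        return BurstSeries(
            self.population, self.onsets[sel], self.offsets[sel], self.peaks[sel],
            self.thresholds,
        )


def rate_histogram(record: SpikeRecord, bin_ms: float = 100.0) -> dict[str, ActivityTrace]:
    """Average population rate histograms, spikes/(neuron*s).

    The rate in a bin is the spike count of the population in that bin
    divided by population size and bin width in seconds; summed back over
    bins this conserves the total spike count exactly.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    n_bins = int(np.ceil(record.duration / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms
    out = {}
    for name, (start, stop) in record.pop_slices.items():
        size = stop - start
        if size <= 0:
            raise ValueError(f"population {name!r} is empty")
        t = record.spikes_of(name)
        counts, _ = np.histogram(t, bins=edges)
        rate = counts / (size * bin_ms / 1000.0)
        out[name] = ActivityTrace(name, bin_ms, edges[:-1], rate)
    return out


def _running_reference(rate: np.ndarray, bin_ms: float, window_ms: float) -> np.ndarray:
    w = max(1, int(round(window_ms / bin_ms)))
    ser = pd.Series(rate)
    return ser.rolling(w, center=True, min_periods=1).quantile(0.9).to_numpy()


def detect_bursts(
    trace: ActivityTrace,
    on_frac: float = BURST_THRESHOLDS["on_frac"],
    off_frac: float = BURST_THRESHOLDS["off_frac"],
    min_dur: float = BURST_THRESHOLDS["min_dur"],
    ref_window: float = BURST_THRESHOLDS["ref_window"],
) -> BurstSeries:
    """Hysteresis burst detection against a running reference level.

    The reference is the 90th percentile of the trace over a sliding
    window; a burst opens when the rate rises above ``on_frac * reference``
    and closes when it falls below ``off_frac * reference``.  Bursts
    shorter than ``min_dur`` ms are discarded.
    """
    if not (0.0 < off_frac < on_frac <= 1.0):
        raise ValueError("require 0 < off_frac < on_frac <= 1")
    rate = trace.rate
    thresholds = {
        "on_frac": on_frac, "off_frac": off_frac,
        "min_dur": min_dur, "ref_window": ref_window,
    }
    empty = BurstSeries(
        trace.population, np.empty(0), np.empty(0), np.empty(0), thresholds
    )
    if rate.size == 0 or not np.any(rate > 0):
        return empty
    ref = _running_reference(rate, trace.bin_ms, ref_window)
    on_level = on_frac * ref
    off_level = off_frac * ref

    onsets, offsets, peaks = [], [], []
    above = rate[0] > on_level[0]
    cur_on = None
    cur_peak = 0.0
    for i in range(1, rate.size):
        if not above and rate[i] > on_level[i] and rate[i - 1] <= on_level[i - 1]:
            above = True
            cur_on = trace.t[i]
            cur_peak = rate[i]
        elif above:
            cur_peak = max(cur_peak, rate[i]) if cur_on is not None else 0.0
            if rate[i] < off_level[i]:
                above = False
                if cur_on is not None:
                    off_t = trace.t[i]
                    if off_t - cur_on >= min_dur:
                        onsets.append(cur_on)
                        offsets.append(off_t)
                        peaks.append(cur_peak)
                    cur_on = None
    return BurstSeries(
        trace.population,
        np.asarray(onsets), np.asarray(offsets), np.asarray(peaks),
        thresholds, on_level, off_level, trace.t.copy(),
    )


def classify_regime(
    trace: ActivityTrace,
    bursts: BurstSeries | None = None,
    silence_rate: float = 0.1,
) -> str:
    """Label a population window as silence / bursting / tonic.

    Silence: mean rate below ``silence_rate`` spikes/(neuron*s).  Bursting:
    at least three detected bursts (whose detection already requires the
    rate to drop below the off threshold between bursts).  Tonic otherwise.
    """
    if trace.duration - (trace.t[0] if trace.t.size else 0.0) < 10_000.0:
        raise InsufficientObservationError("regime window must span >= 10 s")
    if trace.mean_rate() < silence_rate:
        return "silence"
    if bursts is None:
        bursts = detect_bursts(trace)
    if bursts.n >= 3:
        return "bursting"
    return "tonic"


def frequency_amplitude_series(
    bursts: BurstSeries, window_ms: float = 10_000.0, duration: float | None = None
) -> pd.DataFrame:
    """Per-window oscillation frequency (Hz) and mean burst amplitude.

    Frequency is the reciprocal of the mean inter-onset interval of bursts
    whose onset falls in the window; windows with fewer than two onsets are
    marked undefined (NaN).
    """
    if duration is None:
        duration = float(bursts.offsets[-1]) if bursts.n else 0.0
    starts = np.arange(0.0, duration, window_ms)
    rows = []
    for t0 in starts:
        sel = (bursts.onsets >= t0) & (bursts.onsets < t0 + window_ms)
        k = int(sel.sum())
        if k >= 2:
            ioi = np.diff(bursts.onsets[sel])
            freq = 1000.0 / ioi.mean()
            amp = bursts.peaks[sel].mean()
        else:
            freq, amp = np.nan, np.nan
        rows.append((t0, freq, amp, k))
    return pd.DataFrame(rows, columns=["t0_ms", "frequency_hz", "amplitude", "n_bursts"])


def burst_frequency(
    trace: ActivityTrace,
    t0: float = 0.0,
    t1: float | None = None,
    min_peak: float = 10.0,
) -> float:
    """Mean burst rate (Hz) from coherent bursts over ``[t0, t1)``.

    Restricting to bursts whose peak exceeds ``min_peak`` spikes/(neuron*s)
    excludes the small incoherent avalanches that inflate event counts in
    slow or ragged rhythms; NaN when fewer than two such bursts exist.
    """
    if t1 is None:
        t1 = trace.duration
    b = detect_bursts(trace.slice(t0, t1))
    keep = b.peaks >= min_peak
    onsets = b.onsets[keep]
    if onsets.size < 2:
        return float("nan")
    return float(1000.0 / np.diff(onsets).mean())


@dataclass
class PhaseStats:
    """Circular statistics of one burst series against a reference."""

    mean_phase: float   # in [0, 1)
    R: float            # circular concentration in [0, 1]
    n: int              # phase samples
    label: str          # alternation | synchrony | uncoordinated


def _circular_stats(phases: np.ndarray) -> tuple[float, float]:
    ang = 2.0 * np.pi * phases
    z = np.exp(1j * ang).mean()
    mean = (np.angle(z) / (2.0 * np.pi)) % 1.0
    return float(mean), float(np.abs(z))


def _circ_dist(a: float, b: float) -> float:
    d = abs(a - b) % 1.0
    return min(d, 1.0 - d)


def phase_relation(
    ref: BurstSeries,
    other: BurstSeries,
    min_cycles: int = 5,
    phase_tol: float = PHASE_TOL,
    r_min: float = R_MIN,
) -> PhaseStats:
    """Phase of ``other``'s burst onsets within the reference burst cycle.

    Labels: synchrony when the circular mean lies within ``phase_tol`` of 0
    and the concentration R is at least ``r_min``; alternation when the mean
    lies within ``phase_tol`` of 0.5 at the same concentration;
    uncoordinated otherwise (including concentrated but intermediate
    phases).  Invariant to a common time shift and to a common uniform time
    rescaling of both series.
    """
    if ref.n < min_cycles + 1:
        raise InsufficientObservationError(
            f"need >= {min_cycles} reference cycles, got {max(ref.n - 1, 0)}"
        )
    phases = []
    for t0, t1 in zip(ref.onsets[:-1], ref.onsets[1:]):
        sel = (other.onsets >= t0) & (other.onsets < t1)
        for s in other.onsets[sel]:
            phases.append((s - t0) / (t1 - t0))
    phases = np.asarray(phases)
    if phases.size < min_cycles:
        raise InsufficientObservationError(
            f"need >= {min_cycles} phase samples, got {phases.size}"
        )
    mean, r = _circular_stats(phases)
    if r < r_min:
        label = "uncoordinated"
    elif _circ_dist(mean, 0.0) <= phase_tol:
        label = "synchrony"
    elif _circ_dist(mean, 0.5) <= phase_tol:
        label = "alternation"
    else:
        label = "uncoordinated"
    return PhaseStats(mean, r, int(phases.size), label)


@dataclass
class CoordinationReport:
    """Windowed frequency, amplitude and coordination labels of a run."""

    window_ms: float
    table: pd.DataFrame     # per-window rows
    thresholds: dict

    def labels(self, relation: str) -> list[str]:
        """Defined per-window labels for 'left_right' or 'flexor_extensor'."""
        col = f"{relation}_label"
        return [x for x in self.table[col] if isinstance(x, str)]

    def to_json_dict(self) -> dict:
        return {
            "window_ms": self.window_ms,
            "thresholds": self.thresholds,
            "windows": self.table.where(pd.notna(self.table), None).to_dict("records"),
        }


def windowed_coordination(
    traces: dict[str, ActivityTrace],
    ref_pop: str = "l-RG-F",
    lr_pop: str = "r-RG-F",
    fe_pop: str = "l-RG-E",
    window_ms: float = 15_000.0,
    t0: float = 0.0,
    min_cycles: int = 5,
) -> CoordinationReport:
    """Per-window coordination labels of a bilateral run.

    Cycles are referenced to the left flexor center; the left-right
    relation compares the right flexor onsets against them and the
    flexor-extensor relation compares the left extensor onsets.
    """
    all_bursts = {k: detect_bursts(v) for k, v in (
        (ref_pop, traces[ref_pop]), (lr_pop, traces[lr_pop]), (fe_pop, traces[fe_pop])
    )}
    duration = traces[ref_pop].duration
    rows = []
    for w0 in np.arange(t0, duration - window_ms / 2, window_ms):
        w1 = w0 + window_ms
        ref = all_bursts[ref_pop].slice(w0, w1)
        fa = frequency_amplitude_series(ref, window_ms=window_ms)
        # frequency over the whole window
        freq = (
            1000.0 / np.diff(ref.onsets).mean() if ref.n >= 2 else np.nan
        )
        amp = ref.peaks.mean() if ref.n else np.nan
        row = {"t0_ms": w0, "frequency_hz": freq, "amplitude": amp,
               "n_cycles": max(ref.n - 1, 0)}
        for rel, pop in (("left_right", lr_pop), ("flexor_extensor", fe_pop)):
            try:
                st = phase_relation(ref, all_bursts[pop].slice(w0, w1), min_cycles=min_cycles)
                row[f"{rel}_label"] = st.label
                row[f"{rel}_phase"] = st.mean_phase
                row[f"{rel}_R"] = st.R
            except InsufficientObservationError:
                row[f"{rel}_label"] = None
                row[f"{rel}_phase"] = np.nan
                row[f"{rel}_R"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    return CoordinationReport(
        window_ms=window_ms,
        table=table,
        thresholds={"phase_tol": PHASE_TOL, "r_min": R_MIN, **BURST_THRESHOLDS},
    )


@dataclass
class DeletionReport:
    """Classification of missed bursts around a probe perturbation."""

    events: list            # dicts: expected_onset, type, antagonist, ...
    mean_period: float
    resetting: bool
    contralateral_deviation: float   # max deviation, fraction of a cycle
    params: dict = field(default_factory=dict)

    @property
    def n_deletions(self) -> int:
        return len(self.events)

    def to_json_dict(self) -> dict:
        return {
            "events": self.events,
            "mean_period_ms": self.mean_period,
            "resetting": self.resetting,
            "contralateral_deviation": self.contralateral_deviation,
            "params": self.params,
        }


def classify_deletions(
    target: BurstSeries,
    antagonist_trace: ActivityTrace,
    contralateral: BurstSeries,
    probe_window: tuple[float, float],
    deletion_type: str = "flexor",
    tol: float = 0.25,
    max_period_cv: float = 0.2,
) -> DeletionReport:
    """Detect and classify burst deletions against an expected-cycle grid.

    The expected grid (mean period and phase) is fitted on the cycles
    preceding the probe window; a deletion is an expected onset inside the
    probe window with no observed burst onset within ``tol`` cycles.  For
    each deletion the ipsilateral antagonist is labelled *sustained* if its
    rate stays above its own burst on-threshold throughout the expected
    burst, *rhythmic* otherwise.  The rhythm is flagged as resetting when
    post-probe onsets deviate more than ``tol`` cycles from the
    extrapolated grid.
    """
    w0, w1 = probe_window
    pre = target.onsets[target.onsets < w0]
    if pre.size < 6:
        raise InsufficientObservationError(
            "need >= 5 clean pre-perturbation cycles to fit the expected grid"
        )
    periods = np.diff(pre)
    T = float(periods.mean())
    cv = float(periods.std() / T)
    if cv > max_period_cv:
        raise InsufficientObservationError(
            f"pre-perturbation rhythm unstable (period CV {cv:.2f} > {max_period_cv})"
        )
    t_anchor = float(pre[-1])

    # antagonist burst-on threshold level over time
    ant_bursts = detect_bursts(antagonist_trace)
    ant_on = ant_bursts.on_level
    ant_t = ant_bursts.level_t

    events = []
    k = 1
    grid = []
    while t_anchor + k * T < min(w1 + 2 * T, target.onsets[-1] + T if target.n else w1):
        grid.append(t_anchor + k * T)
        k += 1
    grid = np.asarray(grid)

    for g in grid:
        if not (w0 - tol * T <= g <= w1 + tol * T):
            continue
        dev = np.min(np.abs(target.onsets - g)) / T if target.n else np.inf
        if dev <= tol:
            continue  # burst present on schedule
        # deletion: sample the antagonist over the expected burst window,
        # clipped to the probe so post-probe cycling is not counted
        w_end = min(g + T, w1)
        bin_ms = antagonist_trace.bin_ms
        t_sel = (ant_t >= g) & (ant_t + bin_ms <= w_end) if ant_t is not None else None
        if t_sel is not None and t_sel.any():
            sustained = bool(np.all(antagonist_trace.rate[t_sel] > ant_on[t_sel]))
        else:
            sustained = antagonist_trace.mean_rate(g, w_end) > 0
        events.append({
            "expected_onset_ms": float(g),
            "type": deletion_type,
            "antagonist": "sustained" if sustained else "rhythmic",
        })

    # contralateral deviation against its own pre-probe grid
    c_pre = contralateral.onsets[contralateral.onsets < w0]
    c_dev = np.nan
    if c_pre.size >= 3:
        c_T = float(np.diff(c_pre).mean())
        c_anchor = float(c_pre[-1])
        c_post = contralateral.onsets[
            (contralateral.onsets >= w0) & (contralateral.onsets < w1 + 2 * c_T)
        ]
        devs = []
        for t in c_post:
            k = round((t - c_anchor) / c_T)
            if k >= 1:
                devs.append(abs(t - (c_anchor + k * c_T)) / c_T)
        c_dev = float(max(devs)) if devs else np.nan

    post = target.onsets[target.onsets >= w1]
    resetting = False
    if post.size:
        devs = []
        for t in post[:3]:
            k = round((t - t_anchor) / T)
            devs.append(abs(t - (t_anchor + k * T)) / T)
        resetting = bool(np.median(devs) > tol)

    return DeletionReport(
        events=events,
        mean_period=T,
        resetting=resetting,
        contralateral_deviation=c_dev,
        params={"tol": tol, "probe_window": list(probe_window), "period_cv": cv},
    )


@dataclass
class PhaseDurationFit:
    flexor_slope: float
    extensor_slope: float
    n_cycles: int
    period_range: float   # max period / min period


def phase_duration_slopes(
    flexor: BurstSeries,
    extensor: BurstSeries | None = None,
    min_cycles: int = 10,
    min_range: float = 1.5,
) -> PhaseDurationFit:
    """Least-squares slopes of phase durations against cycle period.

    The flexor phase of cycle *i* is the flexor burst duration; the
    extensor phase is the remainder of the cycle (inter-flexor-burst gap).
    In a flexor-dominated rhythm the extensor slope far exceeds the flexor
    slope: period changes are absorbed almost entirely by the extensor
    phase.
    """
    if flexor.n < min_cycles + 1:
        raise InsufficientObservationError(f"need >= {min_cycles} cycles")
    T = flexor.periods()
    flex_dur = flexor.durations()[:-1]
    ext_dur = T - flex_dur
    rng_ratio = float(T.max() / T.min())
    if rng_ratio < min_range:
        raise InsufficientObservationError(
            f"insufficient period range ({rng_ratio:.2f}x < {min_range}x)"
        )
    A = np.vstack([T, np.ones_like(T)]).T
    flex_slope = float(np.linalg.lstsq(A, flex_dur, rcond=None)[0][0])
    ext_slope = float(np.linalg.lstsq(A, ext_dur, rcond=None)[0][0])
    return PhaseDurationFit(flex_slope, ext_slope, int(T.size), rng_ratio)
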