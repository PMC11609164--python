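"""Spike detection, burst segmentation and dynamical-mode classification.

The membrane trace analysis is deliberately simple and auditable: spikes
are upward threshold crossings (default threshold -0.30 model volts, the
level separating sub- from supra-threshold responses), bursts are groups
of spikes separated by inter-spike intervals much longer than the typical
intra-burst interval, and dynamical modes are decided by whether constant
drive sustains spiking from the resting state and/or from an initial
condition near the limit cycle (excitable / bistable / self-oscillatory).
Forward-reverse amplitude sweeps expose the hysteresis of the subcritical
onset: the cycle born at a fold of limit cycles persists below the
amplitude at which the rest state destabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neuron import (IntegratorConfig, NeuronParams, NeuronState,
                     SimulationTrace, find_fixed_point, integrate_rk4)
from .stimulus import StimulusProtocol

__all__ = [
    "SPIKE_THRESHOLD",
    "SpikeEvents",
    "BurstSummary",
    "ModeClassification",
    "BifurcationResult",
    "detect_spikes",
    "segment_bursts",
    "classify_mode",
    "sweep_bifurcation",
]

#: Default spike-detection level in model volts.  The figure scale maps one
#: model volt to 100 mV of plotted membrane potential, so this is the
#: "-30 mV" threshold of the single-pulse response experiments.
SPIKE_THRESHOLD: float = -0.30


@dataclass
class SpikeEvents:
    spike_times: np.ndarray
    peak_values: np.ndarray
    peak_times: np.ndarray
    threshold_used: float = SPIKE_THRESHOLD

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.peak_values = np.asarray(self.peak_values, dtype=float)
        if np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass
class BurstSummary:
    burst_windows: list[tuple[float, float]]
    spikes_per_burst: list[int]
    isi_gap_used: float

    def __post_init__(self) -> None:
        for (a, b), (c, d) in zip(self.burst_windows, self.burst_windows[1:]):
            if not (a <= b < c <= d):
                raise ValueError("burst windows must be ordered and disjoint")
        if any(n < 1 for n in self.spikes_per_burst):
            raise ValueError("burst counts must be >= 1")


@dataclass
class ModeClassification:
    label: str  # excitable | bistable | self_oscillatory
    rest_sustains: bool
    cycle_sustains: bool
    low_confidence: bool = False
    evidence: dict = field(default_factory=dict)


@dataclass
class BifurcationResult:
    amplitudes: np.ndarray
    forward_sustains: np.ndarray
    reverse_sustains: np.ndarray
    labels: list[str]
    lower_edge: float | None = None
    upper_edge: float | None = None
    edge_uncertainty: float = 0.0


def detect_spikes(trace: SimulationTrace, threshold: float = SPIKE_THRESHOLD,
                  min_isi: float = 0.0) -> SpikeEvents:
    """Find upward threshold crossings and their peaks.

    Each spike is the interval from an upward crossing to the next downward
    crossing; the spike's peak is the maximum of u over that interval.
    Crossings closer than ``min_isi`` to the previous accepted spike are
    merged into it (their peak absorbed).
    """
    u = np.asarray(trace.u)
    t = np.asarray(trace.time)
    if u.size == 0:
        return SpikeEvents(np.empty(0), np.empty(0), np.empty(0), threshold)
    above = u >= threshold
    ups = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    downs = np.nonzero(~above[1:] & above[:-1])[0] + 1

    times, peaks, ptimes = [], [], []
    for i in ups:
        j = downs[downs > i]
        end = int(j[0]) if j.size else len(u)
        seg = slice(i, end)
        k = i + int(np.argmax(u[seg]))
        if times and (t[i] - times[-1]) < min_isi:
            if u[k] > peaks[-1]:
                peaks[-1] = float(u[k])
                ptimes[-1] = float(t[k])
            continue
        times.append(float(t[i]))
        peaks.append(float(u[k]))
        ptimes.append(float(t[k]))
    return SpikeEvents(np.array(times), np.array(peaks), np.array(ptimes), threshold)


def segment_bursts(events: SpikeEvents, gap_factor: float = 3.0) -> BurstSummary:
    """Partition spikes into bursts at inter-spike intervals larger than
    ``gap_factor`` times the median ISI.

    A single spike forms one burst of count 1.  For a tonic (equally
    spaced) train every ISI equals the median, so one burst contains all
    spikes.
    """
    n = len(events)
    if n == 0:
        raise ValueError("no spikes to segment")
    st = events.spike_times
    if n == 1:
        return BurstSummary([(float(st[0]), float(st[0]))], [1], 0.0)
    isi = np.diff(st)
    med = float(np.median(isi))
    gap = gap_factor * med
    breaks = np.nonzero(isi > gap)[0]
    edges = [0, *(b + 1 for b in breaks), n]
    windows, counts = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        windows.append((float(st[a]), float(st[b - 1])))
        counts.append(b - a)
    return BurstSummary(windows, counts, gap)


# ---------------------------------------------------------------------------
# Mode classification
# ---------------------------------------------------------------------------

def _constant_drive(a_ex: float) -> StimulusProtocol:
    return StimulusProtocol(kind="constant", amplitude=abs(a_ex),
                            polarity=1 if a_ex >= 0 else -1)


def _sustains(trace: SimulationTrace, threshold: float) -> tuple[bool, bool]:
    """(spiking in final third, spiking in middle third)."""
    n = len(trace.u)
    def spiking(seg: np.ndarray) -> bool:
        return bool(seg.max() >= threshold and seg.min() < threshold)
    return (spiking(trace.u[2 * n // 3:]), spiking(trace.u[n // 3: 2 * n // 3]))


def _resting_state(params: NeuronParams, config: IntegratorConfig) -> NeuronState:
    fp = find_fixed_point(params, u_guess=config.initial_state.u)
    if fp is not None:
        return fp
    return config.initial_state


def cycle_state(params: NeuronParams, config: IntegratorConfig,
                kick_amplitude: float) -> NeuronState:
    """A state on/near the limit cycle: end state of a strongly driven run.

    The strong drive guarantees we start inside the cycle's basin when one
    exists; the snapshot is taken at the end of the run.
    """
    cfg = IntegratorConfig(step=config.step, duration=config.duration,
                           seed=config.seed, initial_state=config.initial_state,
                           record_every=config.record_every)
    tr = integrate_rk4(params, _constant_drive(kick_amplitude), cfg)
    tail = slice(int(len(tr.u) * 0.9), None)
    i = int(len(tr.u) * 0.9) + int(np.argmax(tr.u[tail]))
    return NeuronState(u=float(tr.u[i]), theta=float(tr.theta[i]),
                       x1=float(tr.x1[i]), x2=float(tr.x2[i]))


def classify_mode(params: NeuronParams, a_ex: float, config: IntegratorConfig,
                  threshold: float = SPIKE_THRESHOLD,
                  kick_amplitude: float | None = None,
                  cycle_ic: NeuronState | None = None) -> ModeClassification:
    """Label the constant-drive dynamics at amplitude ``a_ex``.

    Two runs: (i) from the resting state, (ii) from a near-cycle state
    (obtained by a strong kick unless supplied).  Sustained oscillation
    means threshold crossings still occur in the final third of the run.
    neither sustains -> excitable; only (ii) -> bistable; both ->
    self_oscillatory.  If spiking is present mid-run but dies before the
    final third, the label carries a low-confidence flag.
    """
    if kick_amplitude is None:
        kick_amplitude = max(4.0 * abs(a_ex), 4e-4)
    rest = _resting_state(params, config)
    prot = _constant_drive(a_ex)
    cfg_rest = IntegratorConfig(step=config.step, duration=config.duration,
                                seed=config.seed, initial_state=rest,
                                record_every=config.record_every)
    tr_rest = integrate_rk4(params, prot, cfg_rest)
    if cycle_ic is None:
        cycle_ic = cycle_state(params, config, kick_amplitude)
    cfg_cyc = IntegratorConfig(step=config.step, duration=config.duration,
                               seed=config.seed, initial_state=cycle_ic,
                               record_every=config.record_every)
    tr_cyc = integrate_rk4(params, prot, cfg_cyc)

    rest_fin, rest_mid = _sustains(tr_rest, threshold)
    cyc_fin, cyc_mid = _sustains(tr_cyc, threshold)
    if rest_fin and cyc_fin:
        label = "self_oscillatory"
    elif cyc_fin:
        label = "bistable"
    else:
        label = "excitable"
    low_conf = (rest_mid and not rest_fin) or (cyc_mid and not cyc_fin)
    return ModeClassification(
        label=label, rest_sustains=rest_fin, cycle_sustains=cyc_fin,
        low_confidence=low_conf,
        evidence={"rest_mid": rest_mid, "cycle_mid": cyc_mid,
                  "a_ex": a_ex, "kick_amplitude": kick_amplitude})


def sweep_bifurcation(params: NeuronParams, grid, config: IntegratorConfig,
                      threshold: float = SPIKE_THRESHOLD,
                      bisect_depth: int = 8) -> BifurcationResult:
    """Forward-reverse amplitude sweep revealing the bistable band.

    The forward pass ascends the grid carrying each run's end state into
    the next amplitude (so it tracks the rest branch until it loses
    stability); the reverse pass descends from above carrying the cycle.
    The bistable band is where the forward pass is quiescent but the
    reverse pass sustains the oscillation.  Band edges are refined by
    bisection (fresh runs from the appropriate carried states) and carry a
    +- half-interval uncertainty.
    """
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size < 2:
        raise ValueError("need a monotone grid of >= 2 amplitudes")

    def run_from(a_ex: float, ic: NeuronState) -> SimulationTrace:
        cfg = IntegratorConfig(step=config.step, duration=config.duration,
                               seed=config.seed, initial_state=ic,
                               record_every=config.record_every)
        return integrate_rk4(params, _constant_drive(a_ex), cfg)

    # forward: continue the rest branch upward
    state = _resting_state(params, config)
    fwd = np.zeros(grid.size, dtype=bool)
    fwd_states = []
    for i, a in enumerate(grid):
        tr = run_from(a, state)
        fwd[i] = _sustains(tr, threshold)[0]
        state = tr.final_state()
        fwd_states.append(state)

    # reverse: continue the cycle downward, seeded above the top of the grid
    state = cycle_state(params, config, kick_amplitude=2.0 * grid[-1])
    rev = np.zeros(grid.size, dtype=bool)
    rev_states = [None] * grid.size
    for i in range(grid.size - 1, -1, -1):
        tr = run_from(grid[i], state)
        rev[i] = _sustains(tr, threshold)[0]
        state = tr.final_state()
        rev_states[i] = state

    labels = []
    for i in range(grid.size):
        if fwd[i] and rev[i]:
            labels.append("self_oscillatory")
        elif rev[i]:
            labels.append("bistable")
        else:
            labels.append("excitable")

    lower = upper = None
    unc = 0.0
    band = np.nonzero(rev & ~fwd)[0]
    if band.size:
        # lower edge: last reverse-sustaining amplitude going down
        i0 = band[0]
        lo, hi = (grid[i0 - 1], grid[i0]) if i0 > 0 else (0.0, grid[i0])
        ic = rev_states[i0]
        for _ in range(bisect_depth):
            mid = 0.5 * (lo + hi)
            if _sustains(run_from(mid, ic), threshold)[0]:
                hi = mid
            else:
                lo = mid
        lower, unc = 0.5 * (lo + hi), 0.5 * (hi - lo)
        # upper edge: first forward-sustaining amplitude going up
        i1 = band[-1]
        if i1 + 1 < grid.size:
            lo, hi = grid[i1], grid[i1 + 1]
            ic = fwd_states[i1]
            for _ in range(bisect_depth):
                mid = 0.5 * (lo + hi)
                if _sustains(run_from(mid, ic), threshold)[0]:
                    hi = mid
                else:
                    lo = mid
            upper = 0.5 * (lo + hi)
            unc = max(unc, 0.5 * (hi - lo))
        else:
            upper = grid[i1]
    return BifurcationResult(amplitudes=grid, forward_sustains=fwd,
                             reverse_sustains=rev, labels=labels,
                             lower_edge=lower, upper_edge=upper,
                             edge_uncertainty=unc)
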