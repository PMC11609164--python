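"""Synaptic potentiation in the counter-parallel device pair.

The two devices share the drive node; wired counter-parallel, one
experiences +V(t) and the other -V(t).  A unipolar pulse train whose
amplitude exceeds a device's SET threshold ratchets that device's filament
up a little on every pulse, so consecutive pulses draw larger and larger
peak currents — the electronic analog of synaptic potentiation, driven by
charge accumulation in the filament.  Sub-threshold trains leave the
states untouched and the response is flat.

Potentiation is quantified by the least-squares slope of per-pulse peak
current versus pulse index, normalized by the first peak (fraction per
pulse), and classified none / weak / strong by two configurable
thresholds.  The full-neuron experiment drives the membrane model with a
low-frequency spike train and reports the staircase trajectories of the
device states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .device import (X_MIN, MemristorParams, SwitchingNoise, device_current,
                     draw_vset, get_preset, state_rate)
from .neuron import IntegratorConfig, NeuronParams, SimulationTrace, integrate_rk4
from .stimulus import StimulusProtocol, sample_waveform

__all__ = [
    "PairCircuitParams",
    "PairTraces",
    "PotentiationMetrics",
    "simulate_pair",
    "peak_current_series",
    "pulse_charge_series",
    "classify_potentiation",
    "neuron_potentiation_run",
]

#: Normalized-slope class boundaries (fraction of first peak, per pulse).
TOL_NONE: float = 0.01
TOL_STRONG: float = 0.10


@dataclass(frozen=True)
class PairCircuitParams:
    """The isolated counter-parallel sub-circuit of the pair experiment."""

    device_a: MemristorParams = field(default_factory=lambda: get_preset("Ta"))
    device_b: MemristorParams = field(
        default_factory=lambda: get_preset("Ru", polarity=-1))
    noise: SwitchingNoise = field(default_factory=SwitchingNoise)

    def __post_init__(self) -> None:
        if self.device_a.polarity == self.device_b.polarity:
            raise ValueError("pair devices must have opposite polarity")


@dataclass
class PairTraces:
    time: np.ndarray
    drive: np.ndarray
    i_a: np.ndarray
    i_b: np.ndarray
    x_a: np.ndarray
    x_b: np.ndarray
    protocol: StimulusProtocol | None = None


@dataclass
class PotentiationMetrics:
    peak_currents: np.ndarray
    growth_slope: float  # normalized, per pulse
    classification: str  # none | weak | strong
    depression: bool = False
    charges: np.ndarray | None = None


def simulate_pair(circuit: PairCircuitParams, protocol: StimulusProtocol,
                  config: IntegratorConfig) -> PairTraces:
    """Integrate both devices' filament kinetics under the shared drive.

    Each device sees ``polarity * V(t)``; its current is the physical
    (signed) current at that voltage.  Deterministic with noise disabled.
    """
    if protocol.kind not in ("pulse_train", "spike_train", "single_pulse"):
        raise ValueError("pair drive must be a pulsed protocol")
    dt = config.step
    n = int(round(config.duration / dt))
    t_half = np.arange(2 * n + 1) * (dt / 2.0)
    v_half = sample_waveform(protocol, t_half)
    devs = (circuit.device_a, circuit.device_b)
    noise = circuit.noise
    rng = np.random.default_rng(noise.seed ^ config.seed)
    x = [X_MIN, X_MIN]
    vse = [draw_vset(d, noise, rng) for d in devs]
    seen_hi = [False, False]
    time = np.arange(n) * dt
    out_i = [np.empty(n), np.empty(n)]
    out_x = [np.empty(n), np.empty(n)]
    for i in range(n):
        v0, vh, v1 = v_half[2 * i], v_half[2 * i + 1], v_half[2 * i + 2]
        for k, dev in enumerate(devs):
            va = dev.polarity * v0
            out_x[k][i] = x[k]
            out_i[k][i] = math.copysign(device_current(va, x[k], dev), va) if va else 0.0
            k1 = state_rate(va, x[k], dev, vse[k])
            k2 = state_rate(dev.polarity * vh, x[k] + 0.5 * dt * k1, dev, vse[k])
            k3 = state_rate(dev.polarity * vh, x[k] + 0.5 * dt * k2, dev, vse[k])
            k4 = state_rate(dev.polarity * v1, x[k] + dt * k3, dev, vse[k])
            x[k] = min(max(x[k] + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0, X_MIN),
                       1.0 - X_MIN)
            if x[k] > noise.hi_band:
                seen_hi[k] = True
            elif seen_hi[k] and x[k] < noise.lo_band:
                seen_hi[k] = False
                vse[k] = draw_vset(dev, noise, rng)
    return PairTraces(time=time, drive=v_half[::2][:n], i_a=out_i[0], i_b=out_i[1],
                      x_a=out_x[0], x_b=out_x[1], protocol=protocol)


def _pulse_windows(protocol: StimulusProtocol, t_end: float) -> list[tuple[float, float]]:
    wins = []
    k = 0
    while True:
        try:
            a, b = protocol.pulse_window(k)
        except IndexError:
            break
        if a >= t_end:
            break
        wins.append((a, min(b, t_end)))
        k += 1
        if protocol.kind == "single_pulse":
            break
    return wins


def peak_current_series(time: np.ndarray, current: np.ndarray,
                        protocol: StimulusProtocol) -> np.ndarray:
    """Maximum |current| within each pulse's high window, in pulse order."""
    time = np.asarray(time)
    current = np.asarray(current)
    peaks = []
    for a, b in _pulse_windows(protocol, float(time[-1]) if time.size else 0.0):
        m = (time >= a) & (time < b)
        if not np.any(m):
            raise ValueError(f"pulse window [{a}, {b}) contains no samples")
        peaks.append(float(np.max(np.abs(current[m]))))
    return np.array(peaks)


def pulse_charge_series(time: np.ndarray, current: np.ndarray,
                        protocol: StimulusProtocol) -> np.ndarray:
    """Integrated |current| (charge) per pulse window — the accumulation
    readout behind the potentiation effect."""
    time = np.asarray(time)
    current = np.asarray(current)
    out = []
    for a, b in _pulse_windows(protocol, float(time[-1]) if time.size else 0.0):
        m = (time >= a) & (time < b)
        if not np.any(m):
            raise ValueError(f"pulse window [{a}, {b}) contains no samples")
        out.append(float(np.trapezoid(np.abs(current[m]), time[m])))
    return np.array(out)


def classify_potentiation(peaks, charges=None,
                          tol_none: float = TOL_NONE,
                          tol_strong: float = TOL_STRONG) -> PotentiationMetrics:
    """Least-squares growth slope of the peak series, normalized by the
    first peak; classify none/weak/strong (negative slopes are flagged as
    depression and classified none)."""
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size < 3:
        raise ValueError("need >= 3 pulses to quantify potentiation")
    if peaks[0] == 0.0:
        raise ValueError("first peak is zero: normalization undefined")
    idx = np.arange(peaks.size, dtype=float)
    slope = float(np.polyfit(idx, peaks, 1)[0]) / float(peaks[0])
    depression = slope < -tol_none
    if slope >= tol_strong:
        cls = "strong"
    elif slope >= tol_none:
        cls = "weak"
    else:
        cls = "none"
    return PotentiationMetrics(peak_currents=peaks, growth_slope=slope,
                               classification=cls, depression=depression,
                               charges=None if charges is None else np.asarray(charges))


def neuron_potentiation_run(params: NeuronParams, spike_train: StimulusProtocol,
                            config: IntegratorConfig,
                            noise: SwitchingNoise | None = None):
    """Full-membrane potentiation: drive the neuron with a spike train and
    report the device-state staircases and per-pulse response currents.

    Returns ``(trace, summary)`` where summary holds per-pulse peak
    currents for both devices and the x staircases' start/end values.
    """
    if spike_train.kind not in ("spike_train", "pulse_train"):
        raise ValueError("neuron potentiation expects a periodic train")
    trace = integrate_rk4(params, spike_train, config, noise=noise)
    p1 = peak_current_series(trace.time, trace.i1, spike_train)
    p2 = peak_current_series(trace.time, trace.i2, spike_train)
    summary = {
        "peaks_device1": p1,
        "peaks_device2": p2,
        "x1_path": trace.x1,
        "x2_path": trace.x2,
        "x1_gain": float(trace.x1[-1] - trace.x1[0]),
        "x2_gain": float(trace.x2[-1] - trace.x2[0]),
        "n_pulses": len(p1),
    }
    return trace, summary
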