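"""External drive construction: W_ex(t).

Four protocol kinds cover the stimulation repertoire: a single square
pulse, a periodic square-pulse train with duty cycle Q, a constant
depolarization step, and a low-frequency input spike train (square pulses
by default, optionally a stereotyped fast-rise/exponential-decay spike
template).  Sampling is pure: the same (protocol, t) always yields the
same value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import units

__all__ = ["StimulusProtocol", "waveform_at", "sample_waveform", "build_protocol"]

_KINDS = ("single_pulse", "pulse_train", "constant", "spike_train")

#: Default width of a spike-train pulse, as a fraction of the period.
SPIKE_WIDTH_FRACTION = 0.1


@dataclass(frozen=True)
class StimulusProtocol:
    """Parameters of the external drive W_ex(t).

    ``amplitude`` is non-negative; the sign of the drive is carried by
    ``polarity``.  For periodic kinds, ``duty_cycle`` (Q) sets the high
    fraction of each period when given, otherwise ``pulse_width`` does.
    ``n_pulses = 0`` means unlimited.
    """

    kind: str
    amplitude: float
    onset: float = 0.0
    pulse_width: float | None = None
    period: float | None = None
    duty_cycle: float | None = None
    n_pulses: int = 0
    polarity: int = 1
    shape: str = "square"  # spike_train only: "square" or "template"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}; have {_KINDS}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0 (use polarity for sign)")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")
        if self.duty_cycle is not None and not (0.0 < self.duty_cycle <= 1.0):
            raise ValueError(f"duty cycle Q must lie in (0, 1], got {self.duty_cycle}")
        if self.kind == "single_pulse" and (self.pulse_width is None or self.pulse_width <= 0):
            raise ValueError("single_pulse needs a positive pulse_width")
        if self.kind in ("pulse_train", "spike_train"):
            if self.period is None or self.period <= 0:
                raise ValueError(f"{self.kind} needs a positive period (or frequency)")
            if self.high_time() > self.period + 1e-12:
                raise ValueError("pulse_width must not exceed period")
        if self.shape not in ("square", "template"):
            raise ValueError(f"unknown spike shape {self.shape!r}")

    def high_time(self) -> float:
        """High duration within one period (or the single-pulse width)."""
        if self.kind == "constant":
            return math.inf
        if self.kind == "single_pulse":
            return self.pulse_width
        if self.duty_cycle is not None:
            return self.duty_cycle * self.period
        if self.pulse_width is not None:
            return self.pulse_width
        if self.kind == "spike_train":
            return SPIKE_WIDTH_FRACTION * self.period
        raise ValueError("pulse_train needs duty_cycle or pulse_width")

    def pulse_window(self, k: int) -> tuple[float, float]:
        """(start, end) of the k-th pulse's high window, k = 0, 1, ..."""
        if self.kind == "constant":
            return self.onset, math.inf
        if self.kind == "single_pulse":
            if k != 0:
                raise IndexError("single_pulse has one pulse")
            return self.onset, self.onset + self.pulse_width
        if self.n_pulses and k >= self.n_pulses:
            raise IndexError(f"protocol has {self.n_pulses} pulses")
        start = self.onset + k * self.period
        return start, start + self.high_time()


def waveform_at(protocol: StimulusProtocol, t: float) -> float:
    """Drive value at a single model time t >= 0."""
    return float(sample_waveform(protocol, np.asarray([t]))[0])


def sample_waveform(protocol: StimulusProtocol, t: np.ndarray) -> np.ndarray:
    """Vectorized drive values at the given model times."""
    t = np.asarray(t, dtype=float)
    a = protocol.amplitude * protocol.polarity
    rel = t - protocol.onset
    if protocol.kind == "constant":
        return np.where(rel >= 0.0, a, 0.0)
    if protocol.kind == "single_pulse":
        return np.where((rel >= 0.0) & (rel < protocol.pulse_width), a, 0.0)

    period = protocol.period
    k = np.floor(rel / period)
    phase = rel - k * period
    active = rel >= 0.0
    if protocol.n_pulses:
        active &= k < protocol.n_pulses
    high = protocol.high_time()
    if protocol.kind == "spike_train" and protocol.shape == "template":
        # stereotyped spike: instantaneous rise, exponential decay with a
        # time constant of half the nominal width (alpha-like, peak = a)
        tau = 0.5 * high
        w = a * np.exp(-np.maximum(phase, 0.0) / tau)
        return np.where(active & (phase < period), w, 0.0)
    return np.where(active & (phase < high), a, 0.0)


def build_protocol(spec: dict) -> StimulusProtocol:
    """Validate and unit-normalize a protocol mapping from a config file.

    Accepts ``frequency`` ("3 Hz") as an alternative to ``period``; voltage
    and time fields may carry unit suffixes.
    """
    spec = dict(spec)
    kind = spec.pop("kind", None)
    if kind not in _KINDS:
        raise ValueError(f"protocol kind must be one of {_KINDS}, got {kind!r}")
    kw: dict = {"kind": kind}
    if "amplitude" in spec:
        kw["amplitude"] = units.parse_voltage(spec.pop("amplitude"))
    for key in ("onset", "pulse_width", "period"):
        if key in spec:
            kw[key] = units.parse_time(spec.pop(key))
    if "width" in spec:  # accepted alias
        kw["pulse_width"] = units.parse_time(spec.pop("width"))
    if "frequency" in spec:
        if "period" in kw:
            raise ValueError("give frequency or period, not both")
        kw["period"] = units.parse_frequency_to_period(spec.pop("frequency"))
    for key in ("duty_cycle", "Q"):
        if key in spec:
            kw["duty_cycle"] = float(spec.pop(key))
    for key in ("n_pulses", "polarity", "shape"):
        if key in spec:
            kw[key] = spec.pop(key)
    if spec:
        raise ValueError(f"unknown protocol fields: {sorted(spec)}")
    if "amplitude" not in kw:
        raise ValueError("protocol needs an amplitude")
    try:
        return StimulusProtocol(**kw)
    except ValueError as exc:
        raise ValueError(f"invalid protocol: {exc}") from exc
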