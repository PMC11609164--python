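"""Unit handling for configuration values.

All internal quantities use a single coherent system: voltages in volts,
currents in amperes, resistances in ohms, and time in dimensionless "model
time" units.  Configs may (and for physical quantities must) carry unit
suffixes ("120 uV", "11 ms", "3 Hz", "4.3 kohm"); these are normalized on
load so that scale ambiguity never leaks past the config layer.

The mapping between model time and wall-clock time is a single module-level
scale factor ``TIME_UNIT_S`` (seconds per model-time unit, default 1 ms).
It is used only to interpret time-suffixed config values and sweep rates
given in V/s; the integrator itself is agnostic.
"""

from __future__ import annotations

import re

#: Seconds of wall-clock time represented by one model-time unit.
TIME_UNIT_S: float = 1e-3

_NUM = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?"
_VALUE_RE = re.compile(rf"^\s*({_NUM})\s*([a-zA-Zμ/]*)\s*$")

_VOLT = {"v": 1.0, "mv": 1e-3, "uv": 1e-6, "μv": 1e-6, "kv": 1e3}
_OHM = {"ohm": 1.0, "kohm": 1e3, "mohm": 1e6}
_AMP = {"a": 1.0, "ma": 1e-3, "ua": 1e-6, "μa": 1e-6, "na": 1e-9}
_TIME_S = {"s": 1.0, "ms": 1e-3, "us": 1e-6, "μs": 1e-6}


class UnitError(ValueError):
    """A config value had a missing, unknown or dimensionally wrong suffix."""


def _split(value) -> tuple[float, str]:
    if isinstance(value, (int, float)):
        return float(value), ""
    m = _VALUE_RE.match(str(value))
    if m is None:
        raise UnitError(f"cannot parse quantity {value!r}")
    return float(m.group(1)), m.group(2).lower()


def parse_voltage(value) -> float:
    """Return volts. Bare numbers are taken as volts already."""
    num, suf = _split(value)
    if suf == "":
        return num
    if suf not in _VOLT:
        raise UnitError(f"{value!r}: expected a voltage suffix (uV/mV/V)")
    return num * _VOLT[suf]


def parse_resistance(value) -> float:
    num, suf = _split(value)
    if suf == "":
        return num
    if suf not in _OHM:
        raise UnitError(f"{value!r}: expected a resistance suffix (ohm/kohm)")
    return num * _OHM[suf]


def parse_current(value) -> float:
    num, suf = _split(value)
    if suf == "":
        return num
    if suf not in _AMP:
        raise UnitError(f"{value!r}: expected a current suffix (nA/uA/mA/A)")
    return num * _AMP[suf]


def parse_time(value) -> float:
    """Return model-time units. Bare numbers are model time already."""
    num, suf = _split(value)
    if suf == "":
        return num
    if suf not in _TIME_S:
        raise UnitError(f"{value!r}: expected a time suffix (us/ms/s)")
    return num * _TIME_S[suf] / TIME_UNIT_S


def parse_frequency_to_period(value) -> float:
    """Return the period, in model-time units, of a frequency like '3 Hz'."""
    num, suf = _split(value)
    if suf in ("hz",):
        if num <= 0:
            raise UnitError(f"{value!r}: frequency must be positive")
        return 1.0 / num / TIME_UNIT_S
    raise UnitError(f"{value!r}: expected a frequency suffix (Hz)")


def parse_sweep_rate(value) -> float:
    """Return volts per model-time unit from e.g. '7.25 V/s'."""
    num, suf = _split(value)
    if suf == "":
        return num
    if suf in ("v/s",):
        return num * TIME_UNIT_S
    raise UnitError(f"{value!r}: expected a sweep-rate suffix (V/s)")
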