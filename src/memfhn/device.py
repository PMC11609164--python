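"""Memristive ion-channel device physics.

A bipolar resistive-switching device is reduced to one internal state
variable ``x`` in [0, 1] describing how far the conductive filament has
formed: ``x = 1`` is the low-resistance state (LRS, ohmic branch), ``x = 0``
the high-resistance state (HRS, field-emission branch).  The through-current
density mixes the two branches linearly in ``x``; the state drifts only when
the applied voltage leaves the dead zone (V_reset, V_set), at an ion-hop
rate that is exponential in the voltage, throttled by a polynomial window
function that pins x inside [0, 1].

Cycle-to-cycle variability of real devices is represented by redrawing the
SET threshold from a normal distribution once per completed switching
cycle; all stochastic features are off by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "X_MIN",
    "EXP_CAP",
    "MemristorParams",
    "MemristorState",
    "SwitchingNoise",
    "IVTrace",
    "window_function",
    "current_density",
    "device_current",
    "state_rate",
    "draw_vset",
    "iv_sweep",
    "extract_resistances",
    "dynamic_range_ratio",
    "fit_device_params",
    "get_preset",
    "preset_names",
]

#: Lower clamp for the filament state; keeps the window f(x) > 0 so a device
#: parked at a boundary can still re-switch.  Matches the reference initial
#: condition x0 = 0.00001.
X_MIN: float = 1e-5

#: Cap on exponent arguments, to keep exp() finite far outside the physical
#: voltage range.
EXP_CAP: float = 50.0


def _cexp(arg: float) -> float:
    """exp with the argument clipped to +-EXP_CAP."""
    return math.exp(min(max(arg, -EXP_CAP), EXP_CAP))


@dataclass(frozen=True)
class MemristorParams:
    """Physics constants of one device.

    Parameters
    ----------
    sigma
        Specific resistance of the ohmic (LRS) branch; ``j_lin = |u| / sigma``.
        With ``S_el`` in the same area units, the LRS resistance read out at
        low voltage is ``sigma / S_el`` ohms.
    B, b, E_b
        Non-linear (HRS) branch: ``j_nonlin = |u| * B * exp(b*|u| - E_b)``.
        ``E_b`` is the effective electron-jump barrier (dimensionless
        exponent), ``b`` the field coefficient in 1/V.
    A_rate, E_m, delta
        State-variable kinetics: ion-hop attempt rate (1/model-time),
        effective ion-hop barrier, and field coupling (1/V).
    V_set, V_reset
        Switching thresholds; the state is frozen for voltages strictly
        between them.
    S_el
        Electrode area (current = density * area).
    d
        Load resistance seen by the device in the neuron circuit (ohm).
    gamma
        Least-squares circuit coupling coefficient (1/V) scaling this
        device's contribution ``gamma * I * d`` to the membrane equation.
    p
        Window exponent (positive integer).
    polarity
        +1 or -1: sign of the shared voltage this device experiences in a
        counter-parallel pair.
    field_convention
        "field_assisted" (default): drift rate grows exponentially with the
        magnitude of the over-threshold voltage.  "printed": the literal
        sign convention of the source model, where the SET rate decreases
        with voltage.
    """

    name: str = "custom"
    sigma: float = 700.0
    B: float = 1.0
    b: float = 1.0
    E_b: float = 9.0
    A_rate: float = 1.0
    E_m: float = 2.0
    delta: float = 1.0
    V_set: float = 1.0
    V_reset: float = -1.4
    S_el: float = 1.0
    d: float = 700.0
    gamma: float = 1.0
    p: int = 1
    polarity: int = 1
    field_convention: str = "field_assisted"

    def __post_init__(self) -> None:
        if not (self.V_reset < 0.0 < self.V_set):
            raise ValueError(f"need V_reset < 0 < V_set, got ({self.V_reset}, {self.V_set})")
        if self.p < 1 or int(self.p) != self.p:
            raise ValueError(f"window exponent p must be a positive integer, got {self.p}")
        if self.sigma <= 0 or self.S_el <= 0 or self.d <= 0:
            raise ValueError("sigma, S_el and d must be positive")
        if self.B < 0 or self.A_rate < 0:
            raise ValueError("B and A_rate must be non-negative")
        if self.polarity not in (+1, -1):
            raise ValueError(f"polarity must be +1 or -1, got {self.polarity}")
        if self.field_convention not in ("field_assisted", "printed"):
            raise ValueError(f"unknown field_convention {self.field_convention!r}")

    def with_(self, **kw) -> "MemristorParams":
        """Copy with fields replaced (convenience for sweeps/fits)."""
        return replace(self, **kw)


@dataclass
class MemristorState:
    """Dynamic state of one device: filament variable and active SET threshold."""

    x: float = X_MIN
    v_set_eff: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.x <= 1.0):
            raise ValueError(f"x must lie in [0, 1], got {self.x}")
        if self.v_set_eff <= 0:
            raise ValueError("v_set_eff must be positive")


@dataclass(frozen=True)
class SwitchingNoise:
    """Cycle-to-cycle SET-threshold variability.

    When enabled, ``v_set_eff`` is redrawn from Normal(V_set, rel_std*V_set)
    each time the filament completes a switching cycle (crosses above
    ``hi_band`` and then back below ``lo_band``).  Draws are truncated at a
    small positive floor.
    """

    enabled: bool = False
    rel_std: float = 0.05
    seed: int = 0
    hi_band: float = 0.9
    lo_band: float = 0.1

    def __post_init__(self) -> None:
        if self.rel_std < 0:
            raise ValueError("rel_std must be >= 0")
        if not (0.0 < self.lo_band < self.hi_band < 1.0):
            raise ValueError("need 0 < lo_band < hi_band < 1")


@dataclass
class IVTrace:
    """A quasi-static current-voltage sweep record."""

    voltage: np.ndarray
    current: np.ndarray
    sweep_rate: float = 7.25e-3  # V per model-time unit (7.25 V/s at 1 ms/unit)
    compliance: float = 1e-3  # A
    x: np.ndarray | None = None  # optional state trajectory (diagnostics)

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.voltage.shape != self.current.shape:
            raise ValueError("voltage and current series must have equal length")
        if self.current.size and np.max(np.abs(self.current)) > self.compliance * (1 + 1e-12):
            raise ValueError("current exceeds compliance")


# ---------------------------------------------------------------------------
# Elementary device relations
# ---------------------------------------------------------------------------

def window_function(x: float, p: int) -> float:
    """Joglekar window ``f(x, p) = 1 - (2x - 1)^(2p)``.

    Vanishes at both boundaries (f(0) = f(1) = 0 for every positive integer
    p), peaks at f(0.5) = 1, and is symmetric about x = 0.5.
    """
    if p < 1 or int(p) != p:
        raise ValueError(f"window exponent p must be a positive integer, got {p}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError("window argument x must lie in [0, 1]")
    out = 1.0 - (2.0 * x - 1.0) ** (2 * int(p))
    return float(out) if out.ndim == 0 else out


def current_density(u: float, x: float, params: MemristorParams) -> float:
    """Mixed-branch current density ``j = x*j_lin + (1-x)*j_nonlin``.

    ``j_lin = |u|/sigma`` (ohmic LRS filament), ``j_nonlin = |u|*B*
    exp(b*|u| - E_b)`` (HRS field emission).  Non-negative, zero at u = 0,
    continuous in u and x.
    """
    au = abs(u)
    j_lin = au / params.sigma
    j_non = au * params.B * _cexp(params.b * au - params.E_b)
    return x * j_lin + (1.0 - x) * j_non


def device_current(u: float, x: float, params: MemristorParams) -> float:
    """Device current magnitude ``I = j * S_el`` in amperes."""
    return current_density(u, x, params) * params.S_el


def state_rate(u: float, x: float, params: MemristorParams,
               v_set_eff: float | None = None) -> float:
    """Filament drift rate dx/dt at device voltage ``u``.

    Zero inside the dead zone (V_reset, v_set_eff); positive (toward LRS)
    above the SET threshold; negative (toward HRS) below the RESET
    threshold.  The window factor kills the rate at x = 0 and x = 1.
    """
    if v_set_eff is None:
        v_set_eff = params.V_set
    if params.V_reset < u < v_set_eff:
        return 0.0
    f = window_function(min(max(x, 0.0), 1.0), params.p)
    if params.field_convention == "field_assisted":
        if u >= v_set_eff:
            return params.A_rate * _cexp(-params.E_m + params.delta * u) * f
        return -params.A_rate * _cexp(-params.E_m - params.delta * u) * f
    # literal printed convention
    if u >= v_set_eff:
        return params.A_rate * _cexp(-params.E_m - params.delta * u) * f
    return -params.A_rate * _cexp(-params.E_m + params.delta * u) * f


def draw_vset(params: MemristorParams, noise: SwitchingNoise,
              rng: np.random.Generator | None = None) -> float:
    """Draw an effective SET threshold for the next switching cycle.

    Normal(V_set, rel_std * V_set), truncated at a small positive floor;
    with noise disabled (or rel_std = 0) returns the nominal threshold.
    """
    if not noise.enabled or noise.rel_std == 0.0:
        return params.V_set
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    floor = 1e-3 * params.V_set
    for _ in range(100):
        v = rng.normal(params.V_set, noise.rel_std * params.V_set)
        if v > floor:
            return float(v)
    return floor


# ---------------------------------------------------------------------------
# Quasi-static I-V simulation
# ---------------------------------------------------------------------------

def _triangle_voltage(v_min: float, v_max: float, rate: float, n_cycles: int,
                      dt: float) -> np.ndarray:
    """0 -> v_max -> v_min -> 0 triangular sweep, repeated n_cycles times."""
    seg_up = np.arange(0.0, v_max, rate * dt)
    seg_down = np.arange(v_max, v_min, -rate * dt)
    seg_back = np.arange(v_min, 0.0, rate * dt)
    cycle = np.concatenate([seg_up, seg_down, seg_back])
    return np.concatenate([cycle] * n_cycles + [np.array([0.0])])


def iv_sweep(params: MemristorParams, v_min: float, v_max: float,
             sweep_rate: float = 7.25e-3, n_cycles: int = 1,
             noise: SwitchingNoise | None = None,
             compliance: float = 1e-3, x0: float = X_MIN,
             dt: float | None = None) -> IVTrace:
    """Simulate a triangular voltage sweep through the state kinetics.

    The reported current is clipped at the compliance limit, but the
    unclipped voltage still drives the kinetics (the compliance of a real
    source-measure unit caps the measured current, not the field across the
    device).  With noise disabled the trace is bit-reproducible.
    """
    if noise is None:
        noise = SwitchingNoise(enabled=False)
    if not (v_min < params.V_reset and params.V_set < v_max):
        warnings.warn(
            "sweep window does not enclose both switching thresholds; "
            "no switching is possible", stacklevel=2)
    if dt is None:
        # keep voltage increments ~2 mV per step for a smooth loop
        dt = min(2e-3 / sweep_rate, 1.0)
    volts = _triangle_voltage(v_min, v_max, sweep_rate, n_cycles, dt)
    rng = np.random.default_rng(noise.seed)
    v_set_eff = draw_vset(params, noise, rng)

    x = min(max(x0, X_MIN), 1.0 - X_MIN)
    xs = np.empty_like(volts)
    cur = np.empty_like(volts)
    seen_hi = False
    for i, u in enumerate(volts):
        xs[i] = x
        cur[i] = math.copysign(device_current(u, x, params), u) if u else 0.0
        # RK4 step for the scalar state ODE (voltage held piecewise constant
        # over one step: dt is small relative to the sweep rate)
        k1 = state_rate(u, x, params, v_set_eff)
        k2 = state_rate(u, x + 0.5 * dt * k1, params, v_set_eff)
        k3 = state_rate(u, x + 0.5 * dt * k2, params, v_set_eff)
        k4 = state_rate(u, x + dt * k3, params, v_set_eff)
        x += dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        x = min(max(x, X_MIN), 1.0 - X_MIN)
        if x > noise.hi_band:
            seen_hi = True
        elif seen_hi and x < noise.lo_band:
            seen_hi = False  # completed switching cycle: redraw threshold
            v_set_eff = draw_vset(params, noise, rng)
    cur = np.clip(cur, -compliance, compliance)
    return IVTrace(voltage=volts, current=cur, sweep_rate=sweep_rate,
                   compliance=compliance, x=xs)


# ---------------------------------------------------------------------------
# Trace analysis and calibration
# ---------------------------------------------------------------------------

def extract_resistances(trace: IVTrace, read_voltage: float = 0.1,
                        rel_tol: float = 0.05) -> tuple[float, float]:
    """Read (R_HRS, R_LRS) off the two hysteresis branches at ``read_voltage``.

    R = V/I evaluated where the sweep passes the read voltage on the way up
    (HRS, pre-SET) and on the way down (LRS, post-SET).  For a non-switching
    (single-branch) trace both values coincide and a warning is issued.
    """
    v, i = trace.voltage, trace.current
    if read_voltage <= 0 or read_voltage > np.max(v):
        raise ValueError(f"read voltage {read_voltage} outside swept range")
    near = np.abs(v - read_voltage) <= rel_tol * read_voltage
    idx = np.nonzero(near)[0]
    if idx.size == 0:
        raise ValueError("no samples near the read voltage")
    cur = np.abs(i[idx])
    cur = np.where(cur > 0, cur, np.nan)
    r_all = np.abs(v[idx]) / cur  # local V/I, robust to grid spacing
    r_hrs = float(np.nanmax(r_all))
    r_lrs = float(np.nanmin(r_all))
    if r_hrs / r_lrs < 1.5:
        warnings.warn("trace looks ohmic (single branch): device did not switch",
                      stacklevel=2)
    return r_hrs, r_lrs


def dynamic_range_ratio(r_hrs: float, r_lrs: float) -> float:
    """Switching dynamic range R_HRS / R_LRS."""
    if r_hrs <= 0 or r_lrs <= 0:
        raise ValueError("resistances must be positive")
    return r_hrs / r_lrs


def replay_current(params: MemristorParams, voltage: np.ndarray, dt: float,
                   x0: float = X_MIN) -> np.ndarray:
    """Forward-model the signed current response to a voltage waveform.

    Re-integrates the state kinetics over the given samples (noise off);
    used as the residual model inside :func:`fit_device_params`.
    """
    x = min(max(x0, X_MIN), 1.0 - X_MIN)
    out = np.empty_like(np.asarray(voltage, dtype=float))
    for i, u in enumerate(voltage):
        out[i] = math.copysign(device_current(u, x, params), u) if u else 0.0
        k1 = state_rate(u, x, params)
        k2 = state_rate(u, x + 0.5 * dt * k1, params)
        k3 = state_rate(u, x + 0.5 * dt * k2, params)
        k4 = state_rate(u, x + dt * k3, params)
        x = min(max(x + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0, X_MIN), 1.0 - X_MIN)
    return out


_FITTABLE = ("gamma", "sigma", "B", "b", "delta")


def fit_device_params(trace: IVTrace, params0: MemristorParams,
                      free: tuple[str, ...] = ("sigma", "B"),
                      dt: float | None = None):
    """Least-squares calibration of device constants against an I-V trace.

    Minimizes the RMS difference between the forward-modelled current
    (state kinetics replayed over the trace's voltage waveform) and the
    recorded current, over the chosen free parameters.  Returns
    ``(fitted_params, rms_residual)``.  Free parameters are optimized in
    log-space (all are positive scale factors).

    Raises ``RuntimeError`` with the solver diagnostics on non-convergence.
    """
    from scipy.optimize import least_squares

    bad = set(free) - set(_FITTABLE)
    if bad:
        raise ValueError(f"cannot fit {sorted(bad)}; fittable: {_FITTABLE}")
    if dt is None:
        dt = 2e-3 / trace.sweep_rate
    scale = max(float(np.max(np.abs(trace.current))), 1e-300)

    cc = trace.compliance

    def residual(logvals: np.ndarray) -> np.ndarray:
        pk = {k: math.exp(v) for k, v in zip(free, logvals)}
        model = replay_current(params0.with_(**pk), trace.voltage, dt)
        # the instrument clips the recorded current; clip the model alike
        return (np.clip(model, -cc, cc) - trace.current) / scale

    x0 = np.array([math.log(getattr(params0, k)) for k in free])
    sol = least_squares(residual, x0, method="lm", xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise RuntimeError(f"device fit did not converge: {sol.message} "
                           f"(cost={sol.cost:.3e}, nfev={sol.nfev})")
    fitted = params0.with_(**{k: math.exp(v) for k, v in zip(free, sol.x)})
    rms = float(np.sqrt(np.mean(sol.fun ** 2))) * scale
    return fitted, rms


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _load_preset_file() -> dict:
    import tomllib
    from importlib import resources

    with resources.files("memfhn").joinpath("data/presets.toml").open("rb") as fh:
        return tomllib.load(fh)


_PRESET_CACHE: dict | None = None


def preset_names() -> list[str]:
    global _PRESET_CACHE
    if _PRESET_CACHE is None:
        _PRESET_CACHE = _load_preset_file()
    return sorted(_PRESET_CACHE.keys())


def get_preset(name: str, **overrides) -> MemristorParams:
    """Load a named device preset ("Ta" or "Ru"), with optional overrides."""
    global _PRESET_CACHE
    if _PRESET_CACHE is None:
        _PRESET_CACHE = _load_preset_file()
    if name not in _PRESET_CACHE:
        raise KeyError(f"unknown device preset {name!r}; have {preset_names()}")
    from .units import parse_resistance, parse_voltage

    raw = dict(_PRESET_CACHE[name])
    raw.pop("provenance", None)
    kw = {
        "name": name,
        "sigma": parse_resistance(raw.pop("sigma")),
        "V_set": parse_voltage(raw.pop("V_set")),
        "V_reset": parse_voltage(raw.pop("V_reset")),
        "d": parse_resistance(raw.pop("d")),
    }
    kw.update(raw)  # dimensionless / already-coherent fields
    kw.update(overrides)
    return MemristorParams(**kw)
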