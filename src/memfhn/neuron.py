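"""The modified FitzHugh-Nagumo membrane model with memristive channels.

State vector (u, theta, x1, x2): membrane voltage, slow recovery, and the
filament states of the two counter-parallel devices.  The membrane
non-linearity F(u) is not a fitted cubic but the sum of the two devices'
circuit contributions gamma_k * I_k * d_k, where I_k is the physical
device current at the (magnitude of the) membrane voltage.  The recovery
variable follows the piecewise-linear kinetics g(u) = alpha*u (u < 0) /
beta*u (u >= 0) with timescale separation epsilon and offset eta.

Integration is classic fixed-step 4th-order Runge-Kutta.  The filament
states are clamped to [X_MIN, 1 - X_MIN] after every step so the window
function never freezes a device at a boundary.  With noise disabled a run
is bit-reproducible; an optional audit re-runs at half step and reports
the largest membrane-voltage discrepancy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .device import EXP_CAP, X_MIN, MemristorParams, SwitchingNoise, draw_vset, get_preset
from .stimulus import StimulusProtocol, sample_waveform

__all__ = [
    "NeuronParams",
    "NeuronState",
    "IntegratorConfig",
    "SimulationTrace",
    "recovery_g",
    "membrane_nonlinearity_F",
    "system_rhs",
    "integrate_rk4",
    "find_fixed_point",
    "default_neuron",
]

try:  # numba is an optional accelerator; the kernel runs unmodified without it
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    def _njit(*a, **k):
        def deco(fn):
            return fn
        return deco if not (a and callable(a[0])) else a[0]
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class NeuronParams:
    """Membrane parameters plus the two channel devices.

    ``literal_eq7`` disables the counter-parallel polarity flip, so both
    devices' threshold logic sees the raw membrane voltage (the literal
    magnitude form of the summarized system); by default device 2 sees
    ``polarity * u`` as the physical wiring implies.
    """

    alpha: float = 0.78
    beta: float = 1.86
    epsilon: float = 0.009
    eta: float = 0.1
    device1: MemristorParams = field(default_factory=lambda: get_preset("Ta"))
    device2: MemristorParams = field(default_factory=lambda: get_preset("Ru"))
    literal_eq7: bool = False

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


@dataclass
class NeuronState:
    """A point in the 4-dimensional phase space."""

    u: float = -0.65
    theta: float = 0.0
    x1: float = X_MIN
    x2: float = X_MIN

    def __post_init__(self) -> None:
        for name in ("u", "theta", "x1", "x2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite initial {name}")
        self.x1 = min(max(self.x1, X_MIN), 1.0 - X_MIN)
        self.x2 = min(max(self.x2, X_MIN), 1.0 - X_MIN)

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.theta, self.x1, self.x2], dtype=float)


@dataclass(frozen=True)
class IntegratorConfig:
    """Fixed-step RK4 settings.

    ``err_check`` is the tolerance of the optional step-halving audit (the
    integrator is fixed-step; the audit re-runs at s/2 and warns if the
    membrane voltage deviates by more than this).
    """

    step: float = 0.02
    duration: float = 1000.0
    err_check: float = 1e-10
    seed: int = 0
    initial_state: NeuronState = field(default_factory=NeuronState)
    record_every: int = 1
    audit: bool = False

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.duration <= self.step:
            raise ValueError("duration must exceed one step")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass
class SimulationTrace:
    """Time-indexed record of a run: state, stimulus and device currents."""

    time: np.ndarray
    u: np.ndarray
    theta: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    w_ex: np.ndarray
    i1: np.ndarray
    i2: np.ndarray
    step: float = 0.02
    seed: int = 0
    decimation: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("u", "theta", "x1", "x2", "w_ex", "i1", "i2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series {name} length mismatch")

    def final_state(self) -> NeuronState:
        return NeuronState(u=float(self.u[-1]), theta=float(self.theta[-1]),
                           x1=float(self.x1[-1]), x2=float(self.x2[-1]))


# ---------------------------------------------------------------------------
# Right-hand side (reference implementation, used for tests and root-finding)
# ---------------------------------------------------------------------------

def recovery_g(u: float, alpha: float = 0.78, beta: float = 1.86) -> float:
    """Piecewise-linear recovery kinetics, continuous with g(0) = 0."""
    return alpha * u if u < 0.0 else beta * u


def membrane_nonlinearity_F(u: float, x1: float, x2: float,
                            params: NeuronParams) -> float:
    """Channel non-linearity F(u) = sum_k gamma_k * I_k(u, x_k) * d_k.

    In the default counter-parallel wiring each device's current carries the
    sign of the voltage it experiences (``polarity_k * u``), so the two
    channels pull the membrane in opposite directions and F is odd in u
    (the N-shaped excitable characteristic).  With ``literal_eq7`` the
    magnitude form is used instead and F is even.
    """
    total = 0.0
    for dev, x in ((params.device1, x1), (params.device2, x2)):
        au = abs(u)
        j = x * au / dev.sigma + (1.0 - x) * au * dev.B * math.exp(
            min(max(dev.b * au - dev.E_b, -EXP_CAP), EXP_CAP))
        if params.literal_eq7:
            sgn = 1.0
        else:
            v = dev.polarity * u
            sgn = 1.0 if v >= 0 else -1.0
        total += dev.gamma * j * dev.S_el * dev.d * sgn
    return total


def _device_voltage(u: float, dev: MemristorParams, literal: bool) -> float:
    return u if literal else dev.polarity * u


def system_rhs(state, t: float, params: NeuronParams,
               protocol: StimulusProtocol | None = None,
               w_value: float | None = None,
               v_set_eff: tuple[float, float] | None = None) -> np.ndarray:
    """Time derivative of (u, theta, x1, x2).

    The drive may be given directly (``w_value``) or sampled from a
    protocol at time ``t``.  Raises on non-finite state.
    """
    from .device import state_rate

    if hasattr(state, "as_array"):
        state = state.as_array()
    u, th, x1, x2 = (float(v) for v in state)
    if not all(map(math.isfinite, (u, th, x1, x2))):
        raise FloatingPointError(f"non-finite state at t={t}: {state}")
    if w_value is None:
        w_value = 0.0 if protocol is None else float(
            sample_waveform(protocol, np.asarray([t]))[0])
    if v_set_eff is None:
        v_set_eff = (params.device1.V_set, params.device2.V_set)
    du = membrane_nonlinearity_F(u, x1, x2, params) - th + w_value
    dth = params.epsilon * (recovery_g(u, params.alpha, params.beta) - th - params.eta)
    dx1 = state_rate(_device_voltage(u, params.device1, params.literal_eq7),
                     x1, params.device1, v_set_eff[0])
    dx2 = state_rate(_device_voltage(u, params.device2, params.literal_eq7),
                     x2, params.device2, v_set_eff[1])
    return np.array([du, dth, dx1, dx2])


# ---------------------------------------------------------------------------
# Compiled RK4 kernel
# ---------------------------------------------------------------------------
# Device constant layout (one row per device):
#  0 gamma, 1 sigma, 2 B, 3 b, 4 E_b, 5 A_rate, 6 E_m, 7 delta,
#  8 V_set, 9 V_reset, 10 S_el, 11 d, 12 p, 13 polarity(effective),
#  14 convention (1 = field-assisted, 0 = printed),
#  15 signed current sum (1 = counter-parallel wiring, 0 = magnitude form)

def _pack_devices(params: NeuronParams) -> np.ndarray:
    rows = []
    for dev in (params.device1, params.device2):
        pol = 1.0 if params.literal_eq7 else float(dev.polarity)
        conv = 1.0 if dev.field_convention == "field_assisted" else 0.0
        signed = 0.0 if params.literal_eq7 else 1.0
        rows.append([dev.gamma, dev.sigma, dev.B, dev.b, dev.E_b, dev.A_rate,
                     dev.E_m, dev.delta, dev.V_set, dev.V_reset, dev.S_el,
                     dev.d, float(dev.p), pol, conv, signed])
    return np.array(rows, dtype=np.float64)


@_njit(cache=False)
def _device_term(u, x, row, vset):
    """(F contribution, dx/dt) of one device at membrane voltage u."""
    au = abs(u)
    arg = row[3] * au - row[4]
    if arg > EXP_CAP:
        arg = EXP_CAP
    elif arg < -EXP_CAP:
        arg = -EXP_CAP
    j = x * au / row[1] + (1.0 - x) * au * row[2] * math.exp(arg)
    v = row[13] * u
    sgn = 1.0
    if row[15] > 0.5 and v < 0.0:
        sgn = -1.0
    F = row[0] * j * row[10] * row[11] * sgn
    if row[9] < v < vset:
        return F, 0.0
    xc = x
    if xc < 0.0:
        xc = 0.0
    elif xc > 1.0:
        xc = 1.0
    f = 1.0 - (2.0 * xc - 1.0) ** (2 * int(row[12]))
    if row[14] > 0.5:  # field-assisted: rate grows with the driving voltage
        sgn_delta = row[7] if v >= vset else -row[7]
    else:  # literal printed signs
        sgn_delta = -row[7] if v >= vset else row[7]
    arg = -row[6] + sgn_delta * v
    if arg > EXP_CAP:
        arg = EXP_CAP
    elif arg < -EXP_CAP:
        arg = -EXP_CAP
    r = row[5] * math.exp(arg) * f
    if v < vset:
        r = -r
    return F, r


@_njit(cache=False)
def _rhs_kernel(u, th, x1, x2, w, dev, alpha, beta, eps, eta, vse1, vse2):
    F1, dx1 = _device_term(u, x1, dev[0], vse1)
    F2, dx2 = _device_term(u, x2, dev[1], vse2)
    g = alpha * u if u < 0.0 else beta * u
    du = F1 + F2 - th + w
    dth = eps * (g - th - eta)
    return du, dth, dx1, dx2


@_njit(cache=False)
def _rk4_kernel(y0, n_steps, s, w_half, dev, alpha, beta, eps, eta,
                vset_pool1, vset_pool2, hi_band, lo_band,
                out_u, out_th, out_x1, out_x2, out_i1, out_i2, rec_every):
    u, th, x1, x2 = y0[0], y0[1], y0[2], y0[3]
    xmin = X_MIN
    xmax = 1.0 - X_MIN
    p1 = 0
    p2 = 0
    vse1 = vset_pool1[0]
    vse2 = vset_pool2[0]
    hi1 = False
    hi2 = False
    irec = 0
    for i in range(n_steps):
        if i % rec_every == 0:
            out_u[irec] = u
            out_th[irec] = th
            out_x1[irec] = x1
            out_x2[irec] = x2
            v1 = dev[0, 13] * u
            v2 = dev[1, 13] * u
            a1 = abs(v1)
            a2 = abs(v2)
            e1 = dev[0, 3] * a1 - dev[0, 4]
            e2 = dev[1, 3] * a2 - dev[1, 4]
            if e1 > EXP_CAP:
                e1 = EXP_CAP
            if e2 > EXP_CAP:
                e2 = EXP_CAP
            j1 = x1 * a1 / dev[0, 1] + (1.0 - x1) * a1 * dev[0, 2] * math.exp(e1)
            j2 = x2 * a2 / dev[1, 1] + (1.0 - x2) * a2 * dev[1, 2] * math.exp(e2)
            out_i1[irec] = (j1 * dev[0, 10]) * (1.0 if v1 >= 0 else -1.0)
            out_i2[irec] = (j2 * dev[1, 10]) * (1.0 if v2 >= 0 else -1.0)
            irec += 1

        w0 = w_half[2 * i]
        wh = w_half[2 * i + 1]
        w1 = w_half[2 * i + 2]
        k1 = _rhs_kernel(u, th, x1, x2, w0, dev, alpha, beta, eps, eta, vse1, vse2)
        k2 = _rhs_kernel(u + 0.5 * s * k1[0], th + 0.5 * s * k1[1],
                         x1 + 0.5 * s * k1[2], x2 + 0.5 * s * k1[3],
                         wh, dev, alpha, beta, eps, eta, vse1, vse2)
        k3 = _rhs_kernel(u + 0.5 * s * k2[0], th + 0.5 * s * k2[1],
                         x1 + 0.5 * s * k2[2], x2 + 0.5 * s * k2[3],
                         wh, dev, alpha, beta, eps, eta, vse1, vse2)
        k4 = _rhs_kernel(u + s * k3[0], th + s * k3[1],
                         x1 + s * k3[2], x2 + s * k3[3],
                         w1, dev, alpha, beta, eps, eta, vse1, vse2)
        u += s * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]) / 6.0
        th += s * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]) / 6.0
        x1 += s * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]) / 6.0
        x2 += s * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3]) / 6.0
        if x1 < xmin:
            x1 = xmin
        elif x1 > xmax:
            x1 = xmax
        if x2 < xmin:
            x2 = xmin
        elif x2 > xmax:
            x2 = xmax
        if not (math.isfinite(u) and math.isfinite(th)):
            return i, u, th, x1, x2, irec

        # switching-cycle bookkeeping for the stochastic SET threshold
        if x1 > hi_band:
            hi1 = True
        elif hi1 and x1 < lo_band:
            hi1 = False
            if p1 + 1 < vset_pool1.shape[0]:
                p1 += 1
            vse1 = vset_pool1[p1]
        if x2 > hi_band:
            hi2 = True
        elif hi2 and x2 < lo_band:
            hi2 = False
            if p2 + 1 < vset_pool2.shape[0]:
                p2 += 1
            vse2 = vset_pool2[p2]
    return -1, u, th, x1, x2, irec


def integrate_rk4(params: NeuronParams, protocol: StimulusProtocol | None,
                  config: IntegratorConfig,
                  noise: SwitchingNoise | None = None) -> SimulationTrace:
    """Integrate the full system with fixed-step RK4.

    Returns a trace sampled every ``config.record_every`` steps.  Aborts
    with ``FloatingPointError`` (time-stamped) if the state leaves the
    finite domain.  With ``config.audit`` set, re-runs at half step and
    warns if the membrane voltage deviates by more than ``err_check``.
    """
    s = config.step
    n_steps = int(round(config.duration / s))
    t_half = np.arange(2 * n_steps + 1) * (s / 2.0)
    w_half = (np.zeros_like(t_half) if protocol is None
              else sample_waveform(protocol, t_half).astype(np.float64))
    dev = _pack_devices(params)

    if noise is not None and noise.enabled:
        rng = np.random.default_rng(noise.seed ^ config.seed)
        pool1 = np.array([draw_vset(params.device1, noise, rng) for _ in range(256)])
        pool2 = np.array([draw_vset(params.device2, noise, rng) for _ in range(256)])
        hi, lo = noise.hi_band, noise.lo_band
    else:
        pool1 = np.array([params.device1.V_set])
        pool2 = np.array([params.device2.V_set])
        hi, lo = 0.9, 0.1

    n_rec = (n_steps + config.record_every - 1) // config.record_every
    out = {k: np.empty(n_rec) for k in ("u", "th", "x1", "x2", "i1", "i2")}
    y0 = config.initial_state.as_array()
    bad, *_fin, irec = _rk4_kernel(
        y0, n_steps, s, w_half, dev, params.alpha, params.beta,
        params.epsilon, params.eta, pool1, pool2, hi, lo,
        out["u"], out["th"], out["x1"], out["x2"], out["i1"], out["i2"],
        config.record_every)
    if bad >= 0:
        raise FloatingPointError(
            f"integration diverged at t = {bad * s:.4f} (step {bad})")

    time = np.arange(irec) * (s * config.record_every)
    trace = SimulationTrace(
        time=time, u=out["u"][:irec], theta=out["th"][:irec],
        x1=out["x1"][:irec], x2=out["x2"][:irec],
        w_ex=w_half[::2][:n_steps:config.record_every][:irec],
        i1=out["i1"][:irec], i2=out["i2"][:irec],
        step=s, seed=config.seed, decimation=config.record_every,
        meta={"duration": config.duration, "n_steps": n_steps,
              "numba": _HAVE_NUMBA})

    if config.audit:
        half_cfg = IntegratorConfig(step=s / 2, duration=config.duration,
                                    err_check=config.err_check, seed=config.seed,
                                    initial_state=config.initial_state,
                                    record_every=2 * config.record_every,
                                    audit=False)
        half = integrate_rk4(params, protocol, half_cfg, noise=noise)
        n = min(len(half.u), len(trace.u))
        dev_u = float(np.max(np.abs(half.u[:n] - trace.u[:n])))
        trace.meta["audit_max_du"] = dev_u
        if dev_u > config.err_check:
            warnings.warn(f"step-halving audit: max |du| = {dev_u:.3e} exceeds "
                          f"tolerance {config.err_check:.1e}", stacklevel=2)
    return trace


# ---------------------------------------------------------------------------
# Fixed-point location
# ---------------------------------------------------------------------------

def find_fixed_point(params: NeuronParams, w: float = 0.0,
                     u_guess: float = -0.65,
                     x: tuple[float, float] = (X_MIN, X_MIN)) -> NeuronState | None:
    """Locate the resting equilibrium (frozen filament states).

    Solves F(u) - theta + w = 0 with theta = g(u) - eta on the hyperpolarized
    branch by scalar root refinement; returns None if no root is bracketed.
    """
    from scipy.optimize import brentq

    x1, x2 = x

    def h(u: float) -> float:
        th = recovery_g(u, params.alpha, params.beta) - params.eta
        return membrane_nonlinearity_F(u, x1, x2, params) - th + w

    span = np.linspace(u_guess - 1.5, min(u_guess + 1.5, -1e-6), 600)
    vals = np.array([h(v) for v in span])
    sign = np.sign(vals)
    flips = np.nonzero(np.diff(sign))[0]
    best = None
    for i in flips:
        root = brentq(h, span[i], span[i + 1], xtol=1e-14)
        if best is None or abs(root - u_guess) < abs(best - u_guess):
            best = root
    if best is None:
        return None
    th = recovery_g(best, params.alpha, params.beta) - params.eta
    return NeuronState(u=float(best), theta=float(th), x1=x1, x2=x2)


def default_neuron(**overrides) -> NeuronParams:
    """The reference Ta/Ru neuron (excitable configuration)."""
    return NeuronParams(**overrides)
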