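import numpy as np
import pytest

import memfhn as m


@pytest.fixture(scope="session")
def ta():
    return m.get_preset("Ta")


@pytest.fixture(scope="session")
def ru():
    return m.get_preset("Ru")


@pytest.fixture(scope="session")
def neuron():
    return m.NeuronParams()


@pytest.fixture(scope="session")
def rest(neuron):
    fp = m.find_fixed_point(neuron, u_guess=-0.6)
    assert fp is not None
    return fp


def constant_drive(a_ex: float) -> m.StimulusProtocol:
    return m.StimulusProtocol(kind="constant", amplitude=abs(a_ex),
                              polarity=1 if a_ex >= 0 else -1)


def run_constant(params, a_ex, ic, duration=10000.0, record_every=10, step=0.02):
    cfg = m.IntegratorConfig(step=step, duration=duration, initial_state=ic,
                             record_every=record_every)
    return m.integrate_rk4(params, constant_drive(a_ex), cfg)


@pytest.fixture(scope="session")
def cycle_ic(neuron, rest):
    """A state on the large limit cycle (snapshot of a strongly driven run)."""
    tr = run_constant(neuron, 500e-6, rest, duration=8000.0)
    tail = int(len(tr.u) * 0.9)
    i = tail + int(np.argmax(tr.u[tail:]))
    return m.NeuronState(u=float(tr.u[i]), theta=float(tr.theta[i]),
                         x1=float(tr.x1[i]), x2=float(tr.x2[i]))


def brute_force_crossings(u, t, threshold):
    """O(n) reference spike scan: upward crossings with interval peaks.

    An initial above-threshold stretch is not a spike (no upward crossing).
    """
    times, peaks = [], []
    inside = False
    best = start = None
    for k in range(1, len(u)):
        if not inside and u[k] >= threshold > u[k - 1]:
            inside, best, start = True, u[k], t[k]
        elif inside:
            if u[k] > best:
                best = u[k]
            if u[k] < threshold:
                inside = False
                times.append(start)
                peaks.append(best)
    if inside:
        times.append(start)
        peaks.append(best)
    return np.array(times), np.array(peaks)
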