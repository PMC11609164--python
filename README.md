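# memfhn — a memristive FitzHugh–Nagumo neuron simulator

`memfhn` models a spiking electronic neuron whose voltage-gated ion
channels are two bipolar resistive-switching (memristive) devices —
ZrO₂(Y₂O₃) stacks with Ta and Ru electrodes — wired counter-parallel into a
modified FitzHugh–Nagumo (mFHN) membrane circuit.  It is written for
computational neuroscientists and neuromorphic-hardware researchers who
want a reproducible software twin of such a circuit: device-level I–V
characterization, the full coupled neuron dynamics, and the analysis
pipeline that identifies its operating regimes.

## The model

Each device carries one internal filament state `x ∈ [0, 1]` (`x = 1`:
low-resistance state, LRS; `x = 0`: high-resistance state, HRS).  Its
current density mixes an ohmic and a field-emission branch,

    j = x·|u|/σ + (1−x)·|u|·B·exp(b·|u| − E_b),

and the filament drifts only outside the dead zone `(V_reset, V_set)`, at
an ion-hop rate exponential in the voltage, throttled by the Joglekar
window `f(x, p) = 1 − (2x − 1)^(2p)` which pins `x` inside `[0, 1]`
(`f(0) = f(1) = 0`, `f(1/2) = 1`).  Cycle-to-cycle variability is a normal
perturbation of `V_set`, redrawn once per completed switching cycle
(off by default).

The membrane couples the two channels through their loads:

    du/dt = γ₁·I₁·d₁ + γ₂·I₂·d₂ − ϑ + W_ex(t)
    dϑ/dt = ε·(g(u) − ϑ − η),     g(u) = α·u (u<0), β·u (u≥0)

with α = 0.78, β = 1.86, and the signed device currents
`I_k = sign(polarity_k·u)·j_k·S_el`.  The counter-parallel wiring makes
the channel sum an odd, N-shaped characteristic — the Ta channel
depolarizes (Na⁺-like), the Ru channel repolarizes (K⁺-like).  Integration
is fixed-step RK4 (`s = 0.02` model time, initial state
`(−0.65, 0, 10⁻⁵, 10⁻⁵)`), numba-accelerated when numba is present.

With the shipped calibrated presets the model reproduces, from one
parameter set:

* **Device characterization** — SET/RESET at +1/−1.4 V (Ta) and +4/−2 V
  (Ru), R_HRS ≈ 10.5–12 kΩ, R_LRS = 700/200 Ω, dynamic range 60 for Ru.
* **Excitability** — all-or-none spikes with a refractory period; three
  constant-drive regimes (excitable / bistable / self-oscillatory)
  separated by a fold of limit cycles below a subcritical
  Andronov–Hopf point, i.e. a hysteretic micro-volt bistability band.
* **Spike-burst dynamics** — under 0.30 V constant drive the Ta filament
  itself terminates bursts: 3 spikes/burst at ε = 0.0028 and 6 at
  ε = 0.0049, with the count a non-decreasing step function of ε.
* **Synaptic potentiation** — pulse trains (duty cycle 0.3) on the device
  pair leave sub-threshold responses flat and grow supra-threshold
  responses pulse by pulse (charge accumulation in the filament); input
  spike trains (1 V, 3 Hz) drive a staircase HRS→LRS transition.

## Worked example

```python
import memfhn as m
from memfhn.io import load_experiment

# spike bursts under constant 0.30 V drive (three-spike configuration)
cfg = load_experiment("fig4a_burst3")
trace = m.integrate_rk4(cfg.neuron, cfg.protocol, cfg.integrator)
bursts = m.segment_bursts(m.detect_spikes(trace))
print(bursts.spikes_per_burst)        # [3]
print(m.detect_spikes(trace).peak_values.round(3))  # [1.029 1.029 1.03]

# pair-circuit potentiation at 1.3 V, duty cycle 0.3
pcfg = load_experiment("fig7_pair")
pair = m.PairCircuitParams(device_a=pcfg.neuron.device1,
                           device_b=pcfg.neuron.device2)
tr = m.simulate_pair(pair, pcfg.protocol, pcfg.integrator)
peaks = m.peak_current_series(tr.time, tr.i_a, pcfg.protocol)
print(m.classify_potentiation(peaks).classification)  # 'strong'
print(peaks.round(5))  # strictly increasing, 0.00032 ... 0.00182 A
```

The burst run fires groups of exactly three spikes (peaks ≈ 1.03 model
volts, crossing the Ta SET threshold so each spike ratchets the filament
until the burst self-terminates).  The 1.3 V pulse train potentiates: the
per-pulse peak current grows from 0.32 mA to 1.82 mA over ten pulses, a
normalized growth slope of 0.575 per pulse (≥ 0.10 ⇒ "strong"); at 0.2 V
the same train is flat ("none").

The same experiments are scriptable from the shell:

```bash
memfhn iv --preset Ru --out ru.csv          # hysteresis loop, R ratio ~60
memfhn simulate --experiment fig4a_burst3 --out burst.csv
memfhn potentiate --experiment fig7_pair --out pot.json
memfhn sweep --experiment fig3c_sweep --out band.json   # bistable band edges
```

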