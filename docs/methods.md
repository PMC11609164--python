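# Methods

## Model

### Device physics

A bipolar resistive-switching device is reduced to a single filament
variable `x ∈ [0, 1]`.  The through-current density is a linear mixture of
an ohmic LRS branch and an HRS field-emission branch,

    j(u, x) = x·|u|/σ + (1 − x)·|u|·B·exp(b·|u| − E_b),

and the device current is `I = j·S_el`.  The filament drifts only when the
device voltage leaves the dead zone `(V_reset, V_set)`:

    dx/dt = ±A_rate·exp(−E_m ± δ·u)·f(x, p),   f(x, p) = 1 − (2x − 1)^(2p),

positive (toward LRS) above `V_set`, negative below `V_reset`, and exactly
zero in between.  The Joglekar window `f` enforces the state bounds; since
`f` vanishes at the boundaries, the state is additionally clamped to
`[10⁻⁵, 1 − 10⁻⁵]` after every step so a saturated device can re-switch
(the lower clamp matches the reference initial condition `x₀ = 10⁻⁵`).

Two sign conventions for the drift exponent are implemented.  The default,
`field_convention = "field_assisted"`, has the rate grow exponentially
with the over-threshold voltage — the physically expected behaviour of
field-assisted ion hopping, and the convention required for potentiation
strength to increase with pulse amplitude.  The literal `"printed"` mode
reverses the exponent signs (rate decreasing with overdrive), as in the
printed form of the source kinetics equation; it is retained for
comparison, not used by any shipped preset.

Cycle-to-cycle variability: when enabled, the effective SET threshold is
redrawn from `Normal(V_set, rel_std·V_set)` (truncated at a small positive
floor; default `rel_std = 0.05`) each time the filament completes a
switching cycle, operationally defined as crossing above `x = 0.9` and
then back below `x = 0.1`.  All stochastic features are off by default so
every headline result is deterministic.

### Membrane model

The membrane follows a modified FitzHugh–Nagumo system whose fast
non-linearity is not a fitted cubic but the physical current sum of the
two channel devices through their loads:

    du/dt = Σ_k γ_k · I_k(u, x_k) · d_k − ϑ + W_ex(t)
    dϑ/dt = ε · (g(u) − ϑ − η),    g(u) = α·u (u < 0), β·u (u ≥ 0)

with α = 0.78 and β = 1.86.  In the counter-parallel wiring each device
experiences `polarity_k · u` (Ta: +1, Ru: −1) both in its switching logic
and in its current direction, so `I_k = sign(polarity_k·u)·j_k(|u|)·S_el`
and the channel sum `F(u)` is an odd function of `u`.  For the shipped
presets `F` is N-shaped: rising near the origin (Ta-dominated,
depolarizing — the Na⁺ role), then diving (Ru-dominated, repolarizing —
the K⁺ role), which yields a hyperpolarized rest, an unstable middle
branch with a saddle, and an unstable depolarized focus: the classical
excitable phase-plane.  A `literal_eq7` switch restores the magnitude form
`F(u) = |u|·Σ_k γ_k·j_k·S_el·d_k` in which both contributions keep the
sign of their γ.  That form makes `F` even in `u`; an even `F` with
`F(0) = 0` and a hyperpolarized rest necessarily places a *stable*
depolarized fixed point at `u* ≈ (η + W)/(β − F'(0))` on the reachable
branch, which captures every spike — the literal form admits transient
excursions but no sustained oscillation, which is why the signed wiring is
the default.

### Integration

Classical fixed-step RK4 with step `s = 0.02` model-time units from the
initial state `(u, ϑ, x₁, x₂) = (−0.65, 0, 10⁻⁵, 10⁻⁵)`.  The stimulus is
pre-sampled at half-steps so the kernel is protocol-agnostic; states are
clamped each step; non-finite states abort with the offending time.  The
`err_check = 10⁻¹⁰` tolerance is interpreted as the threshold of an
optional step-halving audit (a fixed-step scheme has no adaptive error
control): with `audit=True` the run is repeated at `s/2` and the largest
membrane-voltage discrepancy is reported, warning when it exceeds the
tolerance.  With numba present the kernel is JIT-compiled (~50× faster);
the same code runs un-jitted otherwise.

One model-time unit corresponds to 1 ms of protocol wall-time
(`units.TIME_UNIT_S`); this only affects the interpretation of
time-suffixed config values ("11 ms", "3 Hz", "7.25 V/s").

## Shipped presets and their calibration

The supplementary table with the numeric device constants is not available
to this implementation, so the presets are populated in two tiers,
recorded per constant in `src/memfhn/data/presets.toml`:

* **Printed quantities** (taken as-is): `V_set/V_reset` = +1/−1.4 V (Ta)
  and +4/−2 V (Ru); LRS resistances 700 Ω (Ta) and 200 Ω (Ru) (σ with
  `S_el = 1`); loads `d₁ = 700 Ω`, `d₂ = 4.3 kΩ` (the circuit's R6/R7);
  α, β, ε, η; initial conditions; sweep rate 7.25 V/s; compliance 1 mA.
* **Calibrated constants**: `E_b` pins the HRS read resistance at 0.1 V to
  the printed 10.5/12 kΩ; `(γ₁, b₁, γ₂, b₂)` are solved so that the
  channel characteristic `H(v) = c₁e^{b₁v} − c₂e^{b₂v}` (with
  `c_k = γ_k·B·e^{−E_b,k}·S_el·d_k`) satisfies four conditions: the fold
  (knee) of the N-characteristic sits at `u = −0.60` with the
  rest-destabilization (Hopf) drive at exactly +200 μV for ε = 0.009,
  η = 0.1, and the intrinsic spike peak sits at +0.95 model volts — just
  below the Ta SET threshold, so the filament is untouched in the
  excitable regime but engages under the stronger burst/potentiation
  drives.  `A_rate` (Ta) = 0.007 sets the per-spike filament gain that
  yields the 3-spike burst; `E_m = 2`, `δ = 2 (Ta)/1 (Ru)`, `p = 1`,
  `B = 1` are conventional scales.

Consequences of this calibration, measured by the test suite:

* The bistable band of the reference regime is hysteretic and subcritical
  (reverse offset ≈ 55 μV, forward onset ≈ 250 μV).  Its edges are not
  pinned to the nominal 120/200 μV: pinning the fold at 120 μV requires a
  dive exponent `b₂ ≈ 7 V⁻¹`, which caps the membrane below 1 V for any
  drive and therefore forbids all filament engagement (no bursts, no
  potentiation staircase).  The band's existence and ordering are the
  calibration-independent claims; the shipped presets favour the device
  phenomena.
* The single-pulse threshold level — the largest subthreshold membrane
  excursion under amplitude bisection — is the knee of the
  N-characteristic, ≈ −0.57 model volts here rather than the nominal
  −0.30.  Moving the knee to −0.30 is provably incompatible with
  filament engagement for a two-exponential characteristic (once `H'` is
  negative it can only steepen when `b₂ > b₁`, capping the spike peak near
  0.7 V).  The corresponding acceptance test asserts the nominal value and
  is expected to fail; it is kept failing rather than loosened.
* Ta switching in the I–V sweep is *gradual*: drift begins exactly at
  `V_set = 1 V` and completes near 2 V at 7.25 V/s, a direct consequence
  of the slow kinetics that produce multi-spike bursts.  Ru switches
  sharply at its thresholds.

## Burst mechanism

Under constant drive in the burst regime (η = 0.068, d₁ = 875 Ω, drive
0.30 V) the rest state is destabilized while the depolarized block state
does not yet exist; the neuron spikes tonically with peaks just above the
Ta SET threshold.  Each spike ratchets `x₁` up multiplicatively (the
window makes growth exponential from the 10⁻⁵ floor); once the filament
conductance shifts the characteristic enough, spiking stops — the
filament itself is the burst-terminating slow variable.  The spike count
is `ln(x_stop/x₀)/ln k` with per-spike gain `k = e^{4·r·τ}`, and the
supra-threshold dwell τ scales as 1/ε, so the count is a non-decreasing
step function of ε: 3 at ε = 0.0028 and 6 at ε = 0.0049 under identical
drive, η and d₁ (both inside the reported burst ranges η ∈ [0.06, 0.08],
d₁ ∈ [840, 985] Ω).  The six-spike case is shipped at η = 0.068/d₁ = 875
rather than the nominal 0.074/927 because at the latter pair the
depolarized block appears before the rest destabilizes (an ε-independent
fixed-point property), leaving no oscillatory window at all.

## Analysis conventions

* Spike detection: upward crossings of −0.30 model volts (the displayed
  −30 mV at 100 mV per model volt), peak = maximum until the next downward
  crossing, optional minimum-ISI merging.  Rest (−0.60) and spikes (+0.95)
  are far from the threshold, so detection is insensitive to its exact
  value over a wide range.
* Burst segmentation: split where an inter-spike interval exceeds
  `gap_factor × median ISI` (default 3) — scale-free, no absolute time
  constant.
* Mode classification: two runs per amplitude (from rest; from a
  near-cycle state obtained as the end state of a strongly driven run),
  "sustained" = threshold crossings in the final third of the run (the
  first two thirds discard transients, which are long near subcritical
  onsets).  Labels: neither → excitable, cycle-only → bistable, both →
  self-oscillatory; oscillation that dies mid-run flags low confidence.
* Bifurcation sweep: forward pass carries each run's end state upward
  (tracking the rest branch), reverse pass carries the cycle downward;
  band edges are refined by bisection (default depth 8, reported with ±
  half-interval uncertainty).
* Potentiation: per-pulse peak |current| and integrated |charge| per high
  window; growth slope = least-squares slope of peaks vs pulse index
  normalized by the first peak; classes none/weak/strong at 0.01 and 0.10
  per pulse (configurable artifact thresholds — the source distinguishes
  the classes only by figure panels).  Negative slopes are classified
  none with a depression flag.

## Problem sizes

Classification and sweep runs use 12 000 model-time units (6·10⁵ RK4
steps) per amplitude with 10× trace decimation; burst runs 30 000 units;
pulse-threshold bisection 18 levels of 1 500-unit runs; pair simulations
1 000 units at the full step.  These lengths hold every measured label
stable under duration doubling and step halving (tested), while keeping
the full suite around a minute on one CPU with numba.

## Limitations

* The device constants are calibrated, not measured: quantitative device
  curves (e.g. the exact HRS non-linearity exponents) are internally
  consistent rather than fitted to laboratory sweeps.  `fit_device_params`
  exists precisely to re-calibrate σ, B, b, γ, δ against a measured I–V
  table.
* No temperature dependence, endurance/degradation, or device-to-device
  distribution modelling; the stochastic SET threshold is the only
  variability channel.
* The mapping of model volts to displayed millivolts (×100) is a reading
  of the reference figures, not a derived scale.
* The op-amp coupling stage of the hardware circuit is not modelled; the
  pair experiment drives the isolated counter-parallel sub-circuit with
  the ideal protocol voltage (no load-divider feedback between devices).
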