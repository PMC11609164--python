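# Device presets for the two ZrO2(Y2O3) memristive stacks.
#
# Provenance key (recorded per constant in each table's `provenance` string):
#   printed    - value printed in the source characterization (thresholds,
#                branch resistances, load resistances)
#   calibrated - value fixed by this package's calibration so the coupled
#                neuron reproduces the reported regime structure (resting
#                level near -0.65, micro-volt bistability band, switching
#                sharpness at the sweep rate of 7.25 V/s)
#   chosen     - conventional modelling choice (window exponent, unit area)
#
# All voltages/resistances carry unit suffixes and are normalized on load.

[Ta]
# Au/Ta/ZrO2(Y2O3)/Pt/Ti stack ("sodium-channel" role, polarity +1)
sigma = "700 ohm"      # LRS specific resistance; R_LRS = sigma/S_el = 700 ohm
B = 1.0                # HRS branch prefactor (shared between devices)
b = 0.782572           # HRS field coefficient, 1/V
E_b = 9.337388       # electron barrier: R_HRS(0.1 V) = exp(E_b - 0.1 b)/B = 10.5 kohm
A_rate = 0.007         # ion-hop attempt rate, 1/model-time
E_m = 2.0              # ion-hop barrier
delta = 2.0            # kinetics field coupling, 1/V
V_set = "1 V"
V_reset = "-1.4 V"
S_el = 1.0             # electrode area (unit area; sigma, B absorb the scale)
d = "700 ohm"          # load resistance in the neuron circuit
gamma = 17.628620      # circuit coupling, 1/V (least-squares role)
p = 1
polarity = 1
provenance = "V_set/V_reset/sigma/d printed; E_b from printed R_HRS; b/A_rate/E_m/delta/gamma calibrated; B/S_el/p chosen"

[Ru]
# Au/Ru/ZrO2(Y2O3)/Pt/Ti stack ("potassium-channel" role, polarity -1)
sigma = "200 ohm"      # R_LRS = 200 ohm
B = 1.0
b = 3.695726
E_b = 9.762234       # R_HRS(0.1 V) = exp(E_b - 0.1 b)/B = 12 kohm
A_rate = 0.1
E_m = 2.0
delta = 1.0
V_set = "4 V"
V_reset = "-2 V"
S_el = 1.0
d = "4.3 kohm"         # fixed second load (R7 = 4.3 kohm in the reference circuit)
gamma = 0.347853
p = 1
polarity = -1
provenance = "V_set/V_reset/sigma/d printed; E_b from printed R_HRS; b/A_rate/E_m/delta/gamma calibrated; B/S_el/p chosen"
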