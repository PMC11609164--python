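# Forward/reverse constant-drive amplitude sweep exposing the hysteretic
# (bistable) band between the fold of limit cycles and the subcritical
# Hopf point.
[device1]
preset = "Ta"
[device2]
preset = "Ru"
[neuron]
epsilon = 0.009
eta = 0.1
[integrator]
duration = "12 s"
record_every = 10
[analysis]
grid_min = "20 uV"
grid_max = "300 uV"
grid_step = "20 uV"
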