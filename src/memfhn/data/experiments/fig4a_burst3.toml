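# Spike-burst regime, three spikes per burst: constant 0.30 V drive,
# epsilon = 0.0028.  Burst termination is by Ta filament (SET) accumulation.
[device1]
preset = "Ta"
d = "875 ohm"
[device2]
preset = "Ru"
[neuron]
epsilon = 0.0028
eta = 0.068
[protocol]
kind = "constant"
amplitude = "0.30 V"
[integrator]
duration = "30 s"
record_every = 10
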