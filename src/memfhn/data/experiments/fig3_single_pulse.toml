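# Single-pulse excitability test: 11 ms suprathreshold pulse, excitable
# configuration (epsilon = 0.009, eta = 0.1).
[device1]
preset = "Ta"
[device2]
preset = "Ru"
[neuron]
epsilon = 0.009
eta = 0.1
[protocol]
kind = "single_pulse"
amplitude = "90 mV"
onset = "200 ms"
width = "11 ms"
[integrator]
duration = "1500 ms"
[analysis]
spike_threshold = "-300 mV"
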