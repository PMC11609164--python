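# Full-neuron synaptic potentiation: 1 V input spike train at 8 Hz.
[device1]
preset = "Ta"
[device2]
preset = "Ru"
[neuron]
epsilon = 0.009
eta = 0.1
[protocol]
kind = "spike_train"
amplitude = "1 V"
frequency = "8 Hz"
[integrator]
duration = "10 s"
record_every = 5
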