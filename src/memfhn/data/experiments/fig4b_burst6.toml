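# Spike-burst regime, six spikes per burst: same drive, epsilon = 0.0049.
# eta and d1 sit at the same point of the reported burst ranges
# (eta in [0.06, 0.08], d1 in [840, 985] ohm) as the three-spike case;
# the spike count per burst is controlled by epsilon.
[device1]
preset = "Ta"
d = "875 ohm"
[device2]
preset = "Ru"
[neuron]
epsilon = 0.0049
eta = 0.068
[protocol]
kind = "constant"
amplitude = "0.30 V"
[integrator]
duration = "30 s"
record_every = 10
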