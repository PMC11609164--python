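# Counter-parallel pair potentiation: positive square-pulse train,
# duty cycle 0.3.  Amplitudes 0.2-1.3 V are applied by the experiment
# driver; the value here is the strong-potentiation case.
[device1]
preset = "Ta"
[device2]
preset = "Ru"
[protocol]
kind = "pulse_train"
amplitude = "1.3 V"
period = "100 ms"
Q = 0.3
n_pulses = 10
[integrator]
duration = "1000 ms"
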