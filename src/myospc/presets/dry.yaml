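# Dry metal prosthesis electrode: ~100-200 kΩ at 100 Hz, impedance
# roughly halves within 2 h of donning, strong powerline pickup
# (~500 μV_RMS raw at rest), strongly vibration-sensitive, repositioned
# every day.
kind: dry
z_100hz_ohm: 150000.0
z_alpha: 0.7
z_corner_hz: 10.0
powerline_coupling_uvrms: 500.0
harmonic_rolloff: 1.0
broadband_noise_uvrms: 15.0
vibration_coupling: 1.0
donning_floor: 0.5
donning_tau_min: 40.0
day_shift_sd: 0.5
heterogeneity: 0.1
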