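# Gelled Ag/AgCl surface electrode: ~10-20 kΩ at 100 Hz, mild donning
# transient (decays to ~0.8 of the fresh value over 2 h), moderate
# powerline pickup, small vibration sensitivity, repositioned every day.
kind: gelled
z_100hz_ohm: 15000.0
z_alpha: 0.5
z_corner_hz: 10.0
powerline_coupling_uvrms: 50.0
harmonic_rolloff: 1.0
broadband_noise_uvrms: 10.0
vibration_coupling: 0.03
donning_floor: 0.78
donning_tau_min: 40.0
day_shift_sd: 0.4
heterogeneity: 0.1
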