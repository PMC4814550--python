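# Percutaneous titanium implant: ~200-300 Ω at 100 Hz, no donning
# transient, negligible powerline pickup, insensitive to vibration,
# cannot be repositioned between days.
kind: implant
z_100hz_ohm: 250.0
z_alpha: 0.25
z_corner_hz: 10.0
powerline_coupling_uvrms: 0.85
harmonic_rolloff: 1.0
broadband_noise_uvrms: 6.0
vibration_coupling: 0.015
donning_floor: 1.0
donning_tau_min: 40.0
day_shift_sd: 0.0
heterogeneity: 0.1
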