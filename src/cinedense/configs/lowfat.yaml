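# Control (low-fat diet) phantom: geometry and function transcribed from the
# low-fat group means (EDV ~61 uL, mass ~100 mg, Ecc endo -17% / epi -9.4%,
# Ell -12%, torsion 8.8 deg/cm over a 1.0 cm ventricle, HR 457 bpm).
# Noise-free: this configuration doubles as the parameter-recovery truth.
endo_radius_ed: 1.41
epi_radius_ed: 2.26
long_axis_length_ed: 10.0
circ_stretch_endo: 0.83
circ_stretch_epi: 0.906
long_stretch: 0.88
twist_base_peak: 0.0
twist_apex_peak: 8.8
activation_delay: null
heart_rate: 457.0
systole_ms: 45.0
apex_wall_thickness: 0.8
encoding_frequency: 0.9
field_of_view: 32.0
matrix_size: 128
repetition_time: 7.1
phase_noise_sd: 0.0
random_seed: 20
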