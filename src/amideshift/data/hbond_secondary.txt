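# amideshift coefficient file v1
# kind: hbond_secondary
# Perturbation on the amide proton when the carbonyl oxygen of its own
# amide group accepts a hydrogen bond; same functional form as the primary
# amide surface with its own (smaller) amplitude.
#   ddelta(r, theta2) = amplitude * exp(-decay * r_HO) * cos^2(theta2)
amplitude_ppm 9.0
decay_inv_angstrom 1.5
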