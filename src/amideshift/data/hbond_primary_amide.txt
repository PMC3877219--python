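# amideshift coefficient file v1
# kind: hbond_primary_amide
# Closed-form primary hydrogen-bond perturbation for amide-amide and
# sidechain-amide acceptors (formamide-dimer-style surface):
#   ddelta(r, theta2) = amplitude * exp(-decay * r_HO) * cos^2(theta2)
# with r_HO in A and theta2 the H...O=C angle.
amplitude_ppm 52.0
decay_inv_angstrom 1.5
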