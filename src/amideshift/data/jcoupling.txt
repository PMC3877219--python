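# amideshift coefficient file v1
# kind: h3j_nc_coupling
# Trans-hydrogen-bond h3J(NC') closed form:
#   J(r, theta1, theta2) = amplitude * exp(-decay * r_HO)
#                          * cos^2(theta1) * cos^2(theta2)   [Hz]
# theta1 = N-H...O angle, theta2 = H...O=C angle, r_HO in A.
amplitude_hz -360.0
decay_inv_angstrom 3.2
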