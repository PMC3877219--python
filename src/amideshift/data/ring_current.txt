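# amideshift coefficient file v1
# kind: ring_current_point_dipole
# B is the point-dipole constant in ppm A^3; the remaining rows are the
# dimensionless intensity factors i per aromatic ring kind.
B 30.42
PHE6 1.00
TYR6 0.81
TRP5 0.90
TRP6 1.04
HIS5 0.53
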