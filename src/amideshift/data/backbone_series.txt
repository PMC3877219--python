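# amideshift coefficient file v1
# kind: backbone_cosine_series
# Truncated 2-D trigonometric series for the phi/psi backbone contribution
# to the backbone amide proton shift (ppm, DSS-referenced), evaluated as
#   S(phi, psi) = sum_k coeff_k * basis_k(m_k * phi, n_k * psi)
# basis codes: cc = cos(m phi) cos(n psi), cs = cos(m phi) sin(n psi),
#              sc = sin(m phi) cos(n psi), ss = sin(m phi) sin(n psi)
# columns: m n basis coeff_ppm
0 0 cc  5.20
1 0 cc  0.35
0 1 cc -0.54
1 1 cc  0.12
2 0 cc -0.08
0 2 cc  0.10
2 1 cc  0.05
1 2 cc -0.03
1 1 sc  0.07
1 1 cs -0.05
1 1 ss  0.04
2 1 ss -0.02
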