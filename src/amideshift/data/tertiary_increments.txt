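# amideshift coefficient file v1
# kind: tertiary_increments
# Small additive polarization corrections (ppm) applied when a bonding
# partner is itself hydrogen bonded.
primary_partner_bonded 0.25
secondary_partner_bonded 0.10
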