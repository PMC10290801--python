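# Rasfonin as a retro-biosynthetic chain description.
# Two acetate-derived chains joined by an ester bond; see docs/methods.md
# for how the beta-states were assigned.
name: rasfonin
formula: C25H38O6
ester_links: [[tetraketide, 1]]
post_pks_hydroxylations: [[tetraketide, 8], [tetraketide, 10]]
chains:
  - name: hexaketide
    release: pyrone_cyclization
    units:
      - {beta_state: starter}
      - {beta_state: enoyl}
      - {beta_state: hydroxyl, alpha_methyl: true}
      - {beta_state: reduced, alpha_methyl: true}
      - {beta_state: enoyl, alpha_methyl: true}
      - {beta_state: reduced}
  - name: tetraketide
    release: ester_transfer
    units:
      - {beta_state: starter}
      - {beta_state: reduced, alpha_methyl: true}
      - {beta_state: enoyl, alpha_methyl: true}
      - {beta_state: reduced}
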