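# Default substrate-specificity rule cascade for granzyme-family serine
# proteases, evaluated top to bottom; the first matching rule wins.
# Conditions are canonical S1-region residue numbers mapped to the residues
# accepted at that position. The metase rule is first because granzyme M is
# recognised by Lys192/Ser216 alone and must shadow the S1-triplet rules.
rules:
  - id: metase
    group: metase
    p1: [M, L]
    conditions:
      192: [K]
      216: [S]
  - id: aspase
    group: aspase
    p1: [D]
    conditions:
      189: [N]
      216: [G]
      226: [R]
  - id: trypsin_like
    group: trypsin_like
    p1: [R, K]
    conditions:
      189: [D]
      216: [G]
      226: [G]
  - id: chymase
    group: chymase
    p1: [F, Y]
    conditions:
      189: [T, A, S]
      216: [G]
      226: [G]
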