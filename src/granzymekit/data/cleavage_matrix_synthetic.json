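{
 "comment": "Synthetic position-weight matrix for signal-peptide cleavage-site scoring over window -13..+2. Not transcribed from a published count table: columns encode the standard qualitative preferences (hydrophobic h-region, small residues at -3/-1).",
 "positions": [
  -13,
  -12,
  -11,
  -10,
  -9,
  -8,
  -7,
  -6,
  -5,
  -4,
  -3,
  -2,
  -1,
  1,
  2
 ],
 "weights": {
  "A": [
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   0.5,
   1.0,
   2.5,
   0.0,
   3.0,
   0.3,
   0.0
  ],
  "C": [
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   -0.5,
   1.0,
   1.0,
   0.0,
   1.0,
   0.0,
   0.0
  ],
  "D": [
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -0.5,
   -0.5,
   -2.0,
   0.0,
   -3.0,
   0.3,
   0.0
  ],
  "E": [
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -0.5,
   -0.5,
   -2.0,
   0.0,
   -3.0,
   0.3,
   0.0
  ],
  "F": [
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   -0.5,
   1.5,
   -2.0,
   0.5,
   -3.0,
   0.0,
   0.0
  ],
  "G": [
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   0.5,
   -0.5,
   1.0,
   0.0,
   2.2,
   0.0,
   0.0
  ],
  "H": [
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -0.5,
   -0.5,
   -2.0,
   0.0,
   -3.0,
   0.0,
   0.0
  ],
  "I": [
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   -0.5,
   1.0,
   -2.0,
   0.0,
   -3.0,
   0.3,
   0.0
  ],
  "K": [
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -0.5,
   -0.5,
   -2.0,
   0.0,
   -3.0,
   0.0,
   0.0
  ],
  "L": [
   2.0,
   1.0,
   2.0,
   1.0,
   2.0,
   1.0,
   2.0,
   1.0,
   -0.5,
   1.0,
   -2.0,
   0.0,
   -3.0,
   0.0,
   0.0
  ],
  "M": [
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   -0.5,
   1.0,
   -2.0,
   0.0,
   -3.0,
   0.0,
   0.0
  ],
  "N": [
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -0.5,
   -0.5,
   -2.0,
   0.0,
   -3.0,
   0.3,
   0.0
  ],
  "P": [
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   1.5,
   -0.5,
   -2.0,
   0.0,
   -3.0,
   0.0,
   -0.5
  ],
  "Q": [
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -0.5,
   -0.5,
   -2.0,
   0.0,
   1.0,
   0.3,
   0.0
  ],
  "R": [
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -0.5,
   -0.5,
   -2.0,
   0.0,
   -3.0,
   0.0,
   0.0
  ],
  "S": [
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   0.5,
   -0.5,
   1.0,
   0.0,
   2.0,
   0.3,
   0.0
  ],
  "T": [
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -0.5,
   -0.5,
   1.0,
   0.0,
   1.0,
   0.0,
   0.0
  ],
  "V": [
   1.0,
   2.0,
   1.0,
   2.0,
   1.0,
   2.0,
   1.0,
   2.0,
   -0.5,
   1.0,
   1.0,
   0.0,
   -3.0,
   0.0,
   0.0
  ],
  "W": [
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   -0.5,
   1.0,
   -2.0,
   0.5,
   -3.0,
   0.0,
   0.0
  ],
  "Y": [
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -1.0,
   -0.5,
   -0.5,
   -2.0,
   1.2,
   -3.0,
   0.0,
   0.0
  ]
 }
}
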