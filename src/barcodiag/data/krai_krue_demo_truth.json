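{
  "seed": 20180823,
  "species": [
    "A_pothieri_like",
    "A_pierrei_like",
    "A_tagala_like",
    "substitute_sp"
  ],
  "planted_motifs": [
    {
      "species": "A_pothieri_like",
      "start": 356,
      "width": 2,
      "kind": "substitution",
      "allele": "CC"
    },
    {
      "species": "A_pierrei_like",
      "start": 289,
      "width": 1,
      "kind": "substitution",
      "allele": "G"
    },
    {
      "species": "A_tagala_like",
      "start": 212,
      "width": 4,
      "kind": "substitution",
      "allele": "CAGG"
    },
    {
      "species": "A_pothieri_like",
      "start": 30,
      "width": 6,
      "kind": "deletion",
      "allele": "------"
    }
  ],
  "background_columns": [
    58,
    130,
    159,
    167,
    206,
    208,
    232,
    251,
    270,
    292,
    299,
    320,
    328,
    331,
    364,
    375,
    409,
    420,
    428,
    432,
    467,
    495,
    504,
    512
  ],
  "conserved_blocks": [
    [
      61,
      100
    ],
    [
      441,
      460
    ]
  ],
  "individuals": {
    "A_pothieri_like_01": "A_pothieri_like",
    "A_pothieri_like_02": "A_pothieri_like",
    "A_pothieri_like_03": "A_pothieri_like",
    "A_pierrei_like_01": "A_pierrei_like",
    "A_pierrei_like_02": "A_pierrei_like",
    "A_pierrei_like_03": "A_pierrei_like",
    "A_tagala_like_01": "A_tagala_like",
    "A_tagala_like_02": "A_tagala_like",
    "A_tagala_like_03": "A_tagala_like",
    "substitute_sp_01": "substitute_sp",
    "substitute_sp_02": "substitute_sp",
    "substitute_sp_03": "substitute_sp"
  },
  "intra_rate": 0.0,
  "interspecies_rate": 0.05
}
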