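{
  "comment": "Published pentaplex ITS2 panel for the three Krai-Krue species: three allele-specific forward primers plus the universal internal-control pair; expected product sizes in bp.",
  "primers": [
    {
      "name": "ITS2-poF",
      "role": "species_specific",
      "orientation": "forward",
      "target_species": "Aristolochia_pothieri",
      "sequence": "GCCGCGAGGACCCAATG",
      "specific_3prime_len": 4
    },
    {
      "name": "ITS2-piF",
      "role": "species_specific",
      "orientation": "forward",
      "target_species": "Aristolochia_pierrei",
      "sequence": "GACTACTGGTGGCTCCACGCA",
      "specific_3prime_len": 1
    },
    {
      "name": "ITS2-taF",
      "role": "species_specific",
      "orientation": "forward",
      "target_species": "Aristolochia_tagala",
      "sequence": "GGCGGGGGCGAGCAGGC",
      "specific_3prime_len": 2
    },
    {
      "name": "ITS-Aris-390F",
      "role": "universal_forward",
      "orientation": "forward",
      "target_species": null,
      "sequence": "AATTGCAGAATCCCGCGAAC",
      "specific_3prime_len": 0
    },
    {
      "name": "ITS4",
      "role": "universal_reverse",
      "orientation": "reverse",
      "target_species": null,
      "sequence": "TCCTCCGCTTATTGATATGC",
      "specific_3prime_len": 0
    }
  ],
  "expected_bands": {
    "Aristolochia_pothieri": [123],
    "Aristolochia_pierrei": [191],
    "Aristolochia_tagala": [265]
  },
  "control_band": 400
}
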