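{
  "primers": [
    {
      "name": "ctrl-F1",
      "role": "universal_forward",
      "orientation": "forward",
      "target_species": null,
      "sequence": "ATACGACCTCTACGTAT",
      "specific_3prime_len": 0,
      "tm_wallace": 48.0,
      "gc_percent": 41.1764705882353
    },
    {
      "name": "A_pothieri_like-F357",
      "role": "species_specific",
      "orientation": "forward",
      "target_species": "A_pothieri_like",
      "sequence": "CTCTAGCCGGACCCC",
      "specific_3prime_len": 2,
      "tm_wallace": 52.0,
      "gc_percent": 73.33333333333333
    },
    {
      "name": "A_pierrei_like-F289",
      "role": "species_specific",
      "orientation": "forward",
      "target_species": "A_pierrei_like",
      "sequence": "GTATTTGTGTTCCGACG",
      "specific_3prime_len": 1,
      "tm_wallace": 50.0,
      "gc_percent": 47.05882352941177
    },
    {
      "name": "A_tagala_like-F215",
      "role": "species_specific",
      "orientation": "forward",
      "target_species": "A_tagala_like",
      "sequence": "TTCATTAGCTATTTCAGG",
      "specific_3prime_len": 4,
      "tm_wallace": 48.0,
      "gc_percent": 33.333333333333336
    },
    {
      "name": "ctrl-R494",
      "role": "universal_reverse",
      "orientation": "reverse",
      "target_species": null,
      "sequence": "CGGTAAGGGTAGTATAA",
      "specific_3prime_len": 0,
      "tm_wallace": 48.0,
      "gc_percent": 41.1764705882353
    }
  ],
  "expected_bands": {
    "A_pothieri_like": [
      152
    ],
    "A_pierrei_like": [
      222
    ],
    "A_tagala_like": [
      297
    ]
  },
  "control_band": 488
}
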