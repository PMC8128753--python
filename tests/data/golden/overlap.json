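{
  "as_only": [
    "G17",
    "G55",
    "G60"
  ],
  "both": [],
  "de_only": [
    "G06",
    "G15",
    "G19",
    "G23",
    "G28",
    "G35",
    "G40",
    "G46"
  ],
  "n_as": 3,
  "n_both": 0,
  "n_de": 8
}
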