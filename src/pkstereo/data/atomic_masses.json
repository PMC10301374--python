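{
  "_comment": "Monoisotopic masses (Da) of the most abundant isotopes; pinned so mass output is reproducible. Electron mass deliberately ignored (matches 'calcd.' adduct convention).",
  "H": 1.00782503207,
  "C": 12.0,
  "N": 14.0030740048,
  "O": 15.9949146196,
  "F": 18.9984031627,
  "Na": 22.9897692809,
  "Cl": 34.968852682,
  "Br": 78.9183376
}
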