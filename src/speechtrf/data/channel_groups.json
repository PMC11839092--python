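{
 "left temporal": [
  "AF7",
  "F7",
  "FT7",
  "T7",
  "TP7",
  "P7",
  "P9",
  "PO7"
 ],
 "frontal": [
  "Fp1",
  "AF3",
  "F1",
  "F3",
  "F5",
  "Fpz",
  "Fp2",
  "AF4",
  "AFz",
  "Fz",
  "F2",
  "F4",
  "F6"
 ],
 "right temporal": [
  "AF8",
  "F8",
  "FT8",
  "T8",
  "TP8",
  "P8",
  "P10",
  "PO8"
 ],
 "central": [
  "FC5",
  "FC3",
  "FC1",
  "C1",
  "C3",
  "C5",
  "FC6",
  "FC4",
  "FC2",
  "FCz",
  "Cz",
  "C2",
  "C4",
  "C6"
 ],
 "parietal": [
  "CP5",
  "CP3",
  "CP1",
  "P1",
  "P3",
  "P5",
  "Pz",
  "CPz",
  "CP6",
  "CP4",
  "CP2",
  "P2",
  "P4",
  "P6"
 ],
 "occipital": [
  "PO3",
  "O1",
  "Iz",
  "Oz",
  "POz",
  "PO4",
  "O2"
 ]
}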