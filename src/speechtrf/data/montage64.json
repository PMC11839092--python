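{
 "Fp1": [
  -0.3,
  0.9
 ],
 "AF7": [
  -0.72,
  0.7
 ],
 "AF3": [
  -0.36,
  0.7
 ],
 "F1": [
  -0.18,
  0.5
 ],
 "F3": [
  -0.36,
  0.5
 ],
 "F5": [
  -0.54,
  0.5
 ],
 "F7": [
  -0.72,
  0.5
 ],
 "FT7": [
  -0.85,
  0.3
 ],
 "FC5": [
  -0.54,
  0.3
 ],
 "FC3": [
  -0.36,
  0.3
 ],
 "FC1": [
  -0.18,
  0.3
 ],
 "C1": [
  -0.18,
  0.0
 ],
 "C3": [
  -0.36,
  0.0
 ],
 "C5": [
  -0.54,
  0.0
 ],
 "T7": [
  -0.85,
  0.0
 ],
 "TP7": [
  -0.85,
  -0.3
 ],
 "CP5": [
  -0.54,
  -0.3
 ],
 "CP3": [
  -0.36,
  -0.3
 ],
 "CP1": [
  -0.18,
  -0.3
 ],
 "P1": [
  -0.18,
  -0.55
 ],
 "P3": [
  -0.36,
  -0.55
 ],
 "P5": [
  -0.54,
  -0.55
 ],
 "P7": [
  -0.72,
  -0.55
 ],
 "P9": [
  -0.95,
  -0.55
 ],
 "PO7": [
  -0.72,
  -0.75
 ],
 "PO3": [
  -0.36,
  -0.75
 ],
 "O1": [
  -0.18,
  -0.9
 ],
 "Iz": [
  0.0,
  -1.0
 ],
 "Oz": [
  0.0,
  -0.9
 ],
 "POz": [
  0.0,
  -0.75
 ],
 "Pz": [
  0.0,
  -0.55
 ],
 "CPz": [
  0.0,
  -0.3
 ],
 "Fpz": [
  0.0,
  0.9
 ],
 "Fp2": [
  0.3,
  0.9
 ],
 "AF8": [
  0.72,
  0.7
 ],
 "AF4": [
  0.36,
  0.7
 ],
 "AFz": [
  0.0,
  0.7
 ],
 "Fz": [
  0.0,
  0.5
 ],
 "F2": [
  0.18,
  0.5
 ],
 "F4": [
  0.36,
  0.5
 ],
 "F6": [
  0.54,
  0.5
 ],
 "F8": [
  0.72,
  0.5
 ],
 "FT8": [
  0.85,
  0.3
 ],
 "FC6": [
  0.54,
  0.3
 ],
 "FC4": [
  0.36,
  0.3
 ],
 "FC2": [
  0.18,
  0.3
 ],
 "FCz": [
  0.0,
  0.3
 ],
 "Cz": [
  0.0,
  0.0
 ],
 "C2": [
  0.18,
  0.0
 ],
 "C4": [
  0.36,
  0.0
 ],
 "C6": [
  0.54,
  0.0
 ],
 "T8": [
  0.85,
  0.0
 ],
 "TP8": [
  0.85,
  -0.3
 ],
 "CP6": [
  0.54,
  -0.3
 ],
 "CP4": [
  0.36,
  -0.3
 ],
 "CP2": [
  0.18,
  -0.3
 ],
 "P2": [
  0.18,
  -0.55
 ],
 "P4": [
  0.36,
  -0.55
 ],
 "P6": [
  0.54,
  -0.55
 ],
 "P8": [
  0.72,
  -0.55
 ],
 "P10": [
  0.95,
  -0.55
 ],
 "PO8": [
  0.72,
  -0.75
 ],
 "PO4": [
  0.36,
  -0.75
 ],
 "O2": [
  0.18,
  -0.9
 ]
}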