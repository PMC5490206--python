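{
 "comment": "Published conditional-probability tables for the Detroit network: P(variable | evidence) for both treatments. Entries printed as '<0.001' are encoded as 0.0005. Used by the table-backed inference stub for worked-example reproduction.",
 "blocks": [
  {
   "variable": "G",
   "evidence": {"S": "0"},
   "probs": {
    "BCS":  {"I": 0.144, "II": 0.226, "III": 0.114, "IV": 0.003, "Undetermined": 0.512},
    "BCSR": {"I": 0.169, "II": 0.405, "III": 0.329, "IV": 0.014, "Undetermined": 0.083}
   }
  },
  {
   "variable": "H",
   "evidence": {"S": "0", "G": "Undetermined"},
   "probs": {
    "BCS":  {"8201": 0.005, "8211": 0.0005, "8230": 0.005, "8480": 0.0005, "8500": 0.069, "8501": 0.013, "8503": 0.003, "8507": 0.003, "8520": 0.858, "8522": 0.011, "8523": 0.021, "Other": 0.011},
    "BCSR": {"8201": 0.079, "8211": 0.0005, "8230": 0.024, "8480": 0.001, "8500": 0.399, "8501": 0.079, "8503": 0.056, "8507": 0.008, "8520": 0.059, "8522": 0.048, "8523": 0.221, "Other": 0.026}
   }
  },
  {
   "variable": "A",
   "evidence": {"S": "0", "G": "Undetermined", "H": "8520"},
   "probs": {
    "BCS":  {"≤25": 0.0005, "26−50": 0.266, "51−75": 0.609, ">75": 0.125, "Unknown": 0.0005},
    "BCSR": {"≤25": 0.001, "26−50": 0.153, "51−75": 0.715, ">75": 0.13, "Unknown": 0.001}
   }
  },
  {
   "variable": "A",
   "evidence": {"S": "I"},
   "probs": {
    "BCS":  {"≤25": 0.001, "26−50": 0.115, "51−75": 0.478, ">75": 0.405, "Unknown": 0.001},
    "BCSR": {"≤25": 0.001, "26−50": 0.192, "51−75": 0.646, ">75": 0.161, "Unknown": 0.0005}
   }
  },
  {
   "variable": "A",
   "evidence": {"S": "IIA"},
   "probs": {
    "BCS":  {"≤25": 0.001, "26−50": 0.124, "51−75": 0.482, ">75": 0.392, "Unknown": 0.001},
    "BCSR": {"≤25": 0.001, "26−50": 0.194, "51−75": 0.645, ">75": 0.160, "Unknown": 0.0005}
   }
  },
  {
   "variable": "A",
   "evidence": {"S": "IIB"},
   "probs": {
    "BCS":  {"≤25": 0.002, "26−50": 0.134, "51−75": 0.486, ">75": 0.377, "Unknown": 0.002},
    "BCSR": {"≤25": 0.001, "26−50": 0.203, "51−75": 0.641, ">75": 0.155, "Unknown": 0.0005}
   }
  },
  {
   "variable": "G",
   "evidence": {"S": "I", "A": "51−75"},
   "probs": {
    "BCS":  {"I": 0.302, "II": 0.387, "III": 0.232, "IV": 0.003, "Undetermined": 0.076},
    "BCSR": {"I": 0.329, "II": 0.428, "III": 0.202, "IV": 0.0005, "Undetermined": 0.041}
   }
  },
  {
   "variable": "G",
   "evidence": {"S": "IIA", "A": "51−75"},
   "probs": {
    "BCS":  {"I": 0.155, "II": 0.362, "III": 0.415, "IV": 0.015, "Undetermined": 0.052},
    "BCSR": {"I": 0.176, "II": 0.417, "III": 0.376, "IV": 0.002, "Undetermined": 0.029}
   }
  },
  {
   "variable": "G",
   "evidence": {"S": "IIB", "A": "51−75"},
   "probs": {
    "BCS":  {"I": 0.105, "II": 0.342, "III": 0.482, "IV": 0.028, "Undetermined": 0.043},
    "BCSR": {"I": 0.122, "II": 0.402, "III": 0.448, "IV": 0.003, "Undetermined": 0.024}
   }
  }
 ]
}
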