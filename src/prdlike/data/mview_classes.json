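{
  "comment": "Physicochemical residue classes for MView-style consensus lines, tried in order (most specific first); the first class whose members reach the consensus level supplies the symbol.",
  "classes": [
    ["o", "ST"],
    ["u", "AGS"],
    ["n", "DE"],
    ["+", "HKR"],
    ["l", "ILV"],
    ["a", "FHWY"],
    ["c", "DEHKR"],
    ["s", "ACDGNPSTV"],
    ["p", "CDEHKNQRST"],
    ["h", "ACFGHIKLMRTVWY"],
    ["t", "ACDEGHKNQRST"]
  ]
}
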