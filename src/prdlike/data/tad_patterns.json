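{
  "comment": "Nine-position amino-acid class constraints for 9aaTAD motif matching. Each pattern lists, per position, the set of allowed residues. Two stringency levels are shipped; both demand the mixed acidic/hydrophobic character of nine-amino-acid transactivation domains (polar/acidic opener, hydrophobic core free of P and positive charge). The tables are data, editable without touching the matching engine.",
  "patterns": [
    {
      "id": "tad_less_stringent",
      "stringency": "less",
      "positions": [
        "MDENQSTYG",
        "ILVFWMAY",
        "ILVFWMAY",
        "DENQSTAGILVFWMY",
        "DENQSTAGILVFWMY",
        "ILVFWMAY",
        "DENQSTAGILVFWMY",
        "DENQSTAGILVFWMY",
        "DENQSTAGILVFWMY"
      ]
    },
    {
      "id": "tad_more_stringent",
      "stringency": "more",
      "positions": [
        "MDENQSTY",
        "ILVFWMAY",
        "ILVFWMAY",
        "DENQST",
        "DENQSTAG",
        "ILVFWMAY",
        "DENQSTAG",
        "DENQSTAGILVFWMY",
        "DENQSTG"
      ]
    }
  ]
}
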