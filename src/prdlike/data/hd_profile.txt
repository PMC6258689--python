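# Default 60-column homeodomain profile (one consensus residue per column).
# K50-type PRD-LIKE consensus used for translated-genome scanning; columns are
# homeodomain positions 1-60. Derived from the engrailed-class consensus with
# the K50 specificity residue of TAATCC-binding factors.
EKRPRTAFSSEQLARLKREFNENRYLTERRRQQLSSELGLNEAQIKIWFKNKRAKIKKST
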