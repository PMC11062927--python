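# Myofibre-type marker panels used for module scoring and hierarchical
# myonucleus classification.  MYH2 is shared between type II and type IIA;
# MYH1 between type II and type IIX.
type_I: [TNNT1, MYH7, MYH7B, TNNC1, TNNI1, ATP2A2]
type_II: [TNNT3, MYH1, MYH2, TNNC2, TNNI2, ATP2A1]
type_IIA: [MYH2, ANKRD2, NDUFA8, MYOM3, CASQ2, HSPB6, RDH11, AIMP1]
type_IIX: [MYH1, MYLK2, ACTN3, MYBPC2, PCYOX1, CAPZA1, CD38, PDLIM7, COBL, TMEM159, HNRNPA1, TFRC]
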