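# Published motif-event counts for white wheat flour, chymotrypsin digestion.
# sample: wheat_chymotrypsin
category	perfect	one_mismatch
CD_epitope	49	47
p31_43	6	9
moAb_R5	27	156
moAb_G12	22	112
moAb_A1	31	93
IgE_site	61	377
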