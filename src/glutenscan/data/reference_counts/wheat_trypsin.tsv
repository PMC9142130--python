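# Published motif-event counts for white wheat flour, trypsin digestion.
# sample: wheat_trypsin
category	perfect	one_mismatch
CD_epitope	64	73
p31_43	0	0
moAb_R5	8	71
moAb_G12	3	52
moAb_A1	1	16
IgE_site	195	536
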