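# Published motif-event counts for tritordeum flour, trypsin digestion.
# sample: tritordeum_trypsin
category	perfect	one_mismatch
CD_epitope	24	33
p31_43	0	0
moAb_R5	2	31
moAb_G12	1	22
moAb_A1	1	9
IgE_site	116	280
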