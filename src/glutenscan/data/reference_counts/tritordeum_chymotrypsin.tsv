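# Published motif-event counts for tritordeum flour, chymotrypsin digestion.
# sample: tritordeum_chymotrypsin
category	perfect	one_mismatch
CD_epitope	14	15
p31_43	2	5
moAb_R5	8	64
moAb_G12	4	31
moAb_A1	8	26
IgE_site	33	176
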