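# Default motif inventory: celiac-disease T-cell epitope 9-mer cores (native
# glutamine forms, no deamidation applied), the p31-43 innate peptide, the
# R5/G12/A1 monoclonal-antibody recognition sites used in gluten ELISAs, and
# IgE-binding sites linked to WDEIA / baker's asthma / atopic dermatitis.
# Curated from the cited literature (see source tags); replace freely with
# your own inventory -- the pipeline takes any file in this format.
motif_id	category	sequence	source
DQ2.5-glia-a1a	CD_epitope	PFPQPQLPY	sollid2020
DQ2.5-glia-a1b	CD_epitope	PYPQPQLPY	sollid2020
DQ2.5-glia-a2	CD_epitope	PQPQLPYPQ	sollid2020
DQ2.5-glia-a3	CD_epitope	FRPQQPYPQ	sollid2020
DQ2.5-glia-g1	CD_epitope	PQQSFPQQQ	sollid2020
DQ2.5-glia-g2	CD_epitope	IQPQQPAQL	sollid2020
DQ2.5-glia-g3	CD_epitope	QQPQQPYPQ	sollid2020
DQ2.5-glia-g4a	CD_epitope	SQPQQQFPQ	sollid2020
DQ2.5-glia-g4b	CD_epitope	PQPQQQFPQ	sollid2020
DQ2.5-glia-g4c	CD_epitope	QQPQQPFPQ	sollid2020
DQ2.5-glia-g5	CD_epitope	QQPFPQQPQ	sollid2020
DQ2.5-glia-w1	CD_epitope	PFPQPQQPF	sollid2020
DQ2.5-glia-w2	CD_epitope	PQPQQPFPW	sollid2020
DQ2.5-hor-2	CD_epitope	PQPQQPFPQ	sollid2020
DQ8-glia-a1	CD_epitope	QGSFQPSQQ	sollid2020
DQ8-glut-H1	CD_epitope	QGYYPTSPQ	sollid2020
p31-43	p31_43	LGQQQPFPPQQPY	maiuri2003
R5-QQPFP	moAb_R5	QQPFP	osman2001
R5-QQQFP	moAb_R5	QQQFP	osman2001
R5-LQPFP	moAb_R5	LQPFP	osman2001
R5-QLPYP	moAb_R5	QLPYP	osman2001
G12-QPQLPY	moAb_G12	QPQLPY	moron2008
G12-QPQQPY	moAb_G12	QPQQPY	moron2008
G12-QPQLPF	moAb_G12	QPQLPF	moron2008
A1-QLPYPQP	moAb_A1	QLPYPQP	moron2008
IgE-QQIPQQQ	IgE_site	QQIPQQQ	matsuo2004
IgE-QQFPQQQ	IgE_site	QQFPQQQ	matsuo2004
IgE-QQSPEQQ	IgE_site	QQSPEQQ	matsuo2004
IgE-QQSPQQQ	IgE_site	QQSPQQQ	matsuo2004
IgE-QQQPP	IgE_site	QQQPP	tanabe1996
IgE-QQPGQGQQ	IgE_site	QQPGQGQQ	matsuo2004
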