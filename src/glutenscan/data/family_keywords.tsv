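# Keyword -> grain protein family table for description-based classification.
# Tab-separated: family<TAB>keyword. Matching is case-insensitive substring;
# families are tried in precedence order (omega > alpha > gamma gliadins >
# HMW > LMW glutenins > ATI > avenin > LTP > serpin > globulin), then row
# order within a family. Edit freely to match your search-engine export.
omega_gliadin	omega-gliadin
omega_gliadin	omega gliadin
omega_gliadin	omega-5 gliadin
omega_gliadin	w-gliadin
alpha_gliadin	alpha/beta-gliadin
alpha_gliadin	alpha-beta-gliadin
alpha_gliadin	alpha-gliadin
alpha_gliadin	alpha gliadin
alpha_gliadin	beta-gliadin
gamma_gliadin	gamma-gliadin
gamma_gliadin	gamma gliadin
HMW_glutenin	high molecular weight glutenin
HMW_glutenin	high-molecular-weight glutenin
HMW_glutenin	hmw glutenin
HMW_glutenin	hmw-gs
HMW_glutenin	glutenin, high molecular weight
LMW_glutenin	low molecular weight glutenin
LMW_glutenin	low-molecular-weight glutenin
LMW_glutenin	lmw glutenin
LMW_glutenin	lmw-gs
LMW_glutenin	glutenin, low molecular weight
ATI	amylase/trypsin inhibitor
ATI	amylase/trypsin-inhibitor
ATI	alpha-amylase inhibitor
ATI	alpha-amylase/trypsin inhibitor
ATI	trypsin inhibitor
ATI	chloroform/methanol-soluble
avenin	avenin
LTP	lipid transfer protein
LTP	lipid-transfer protein
LTP	nsltp
serpin	serpin
globulin	globulin
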