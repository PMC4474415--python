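gobp_name	F	C	A	E	P	I	H
activation of plasma proteins involved in acute inflammatory response	0	1	0	0	0	0	0
acute inflammatory response	0	1	0	0	0	0	0
blood coagulation	1	1	1	1	0	1	1
blood coagulation, extrinsic pathway	0	0	1	1	0	0	0
coagulation	1	1	1	1	0	1	1
complement activation	0	1	0	0	0	0	0
developmental growth	1	0	0	0	1	0	0
fibrinolysis	1	0	0	0	1	0	0
growth	1	0	0	0	1	0	0
hemostasis	1	1	1	1	0	1	1
negative regulation of blood coagulation	1	1	1	0	1	1	0
negative regulation of coagulation	1	1	1	0	1	1	0
negative regulation of multicellular organismal process	0	0	0	0	1	0	0
platelet activation	1	0	1	1	0	0	0
positive regulation of blood coagulation	1	0	1	1	1	0	0
positive regulation of calcium ion transport	1	0	0	1	0	0	0
positive regulation of coagulation	1	0	1	1	1	0	0
positive regulation of collagen biosynthetic process	1	0	1	1	0	0	0
positive regulation of collagen metabolic process	1	0	1	1	0	0	0
protein maturation	0	1	0	0	0	0	0
protein maturation by peptide bond cleavage	0	1	0	0	0	0	0
protein processing	0	1	0	0	0	0	0
regeneration	1	0	0	0	0	0	0
regulation of blood coagulation	1	1	1	0	1	1	0
regulation of body fluid levels	1	1	1	1	0	1	1
regulation of coagulation	1	1	1	0	1	1	0
regulation of collagen metabolic process	1	0	0	1	0	0	0
regulation of fibrinolysis	0	0	0	0	1	0	0
regulation of multicellular organismal metabolic process	1	0	0	1	0	0	0
regulation of response to external stimulus	0	1	0	0	0	0	0
response to wounding	0	1	0	0	0	0	0
tissue regeneration	1	0	0	0	1	0	0
tyrosine phosphorylation of STAT protein	1	0	1	1	0	0	0
wound healing	0	1	1	0	0	1	1
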