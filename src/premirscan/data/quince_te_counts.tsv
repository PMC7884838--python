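# Transposable-element family counts for the quince draft assembly (JADOBS000000000)
class	family	count
Class I	LTR/Ty3/Gypsy	48178
Class I	LTR/Ty1/Copia	41781
Class I	LINE	5594
Class I	Pararetrovirus	453
Class I	Unclassified	147
Class II	Helitron	2224
Class II	TIR/hAT	2446
Class II	TIR/MuDR/Mutator	1452
Class II	TIR/PIF/Harbinger	1377
Class II	TIR/EnSpm/CACTA	931
Class II	TIR/Novosib	8
Class II	TIR/unclassified	6
Ambiguous	Ambiguous	113
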