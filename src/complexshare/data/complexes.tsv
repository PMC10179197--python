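group	genes	note
eIF2	EIF2S1, EIF2S2, EIF2S3	ternary-complex factor eIF2 (alpha, beta, gamma subunits)
eIF2B	EIF2B1, EIF2B2, EIF2B3, EIF2B4, EIF2B5	guanine nucleotide exchange factor for eIF2, subunits alpha-epsilon
eIF3	EIF3A, EIF3B, EIF3C, EIF3D, EIF3E, EIF3F, EIF3G, EIF3H, EIF3I, EIF3J, EIF3J, EIF3K, EIF3L, EIF3M	multisubunit initiation factor eIF3 (subunits a-m; source lists EIF3J twice)
Multifactor complex (MFC)	EIF1, EIF1AX, EIF1AY, EIF2B1, EIF2B2, EIF2B3, EIF2B4, EIF2B5, EIF2S1, EIF2S2, EIF2S3, EIF3A, EIF3B, EIF3C, EIF3D, EIF3E, EIF3F, EIF3G, EIF3H, EIF3I, EIF3J, EIF3J, EIF3K, EIF3L, EIF3M, EIF5	multifactor initiation complex
eIF4s	EIF4A1, EIF4A2, EIF4B, EIF4H, EIF4E, EIF4E1B, EIF4E3, EIF4G1, EIF4G3	eIF4 family cap-binding/helicase/scaffold factors
eIF4, 4EBP	EIF4EBP1, EIF4EBP2, EIF4EBP3, EIF4A1, EIF4A2, EIF4B, EIF4H, EIF4E, EIF4E1B, EIF4E3, EIF4G1, EIF4G3	eIF4 family plus 4E-binding proteins
INITIATION	EIF1, EIF1AX, EIF1AY, EIF1B, EIF2B1, EIF2B2, EIF2B3, EIF2B4, EIF2B5, EIF2S1, EIF2S2, EIF2S3, EIF3A, EIF3B, EIF3C, EIF3D, EIF3E, EIF3F, EIF3G, EIF3H, EIF3I, EIF3J, EIF3J, EIF3K, EIF3L, EIF3M, EIF4A1, EIF4A2, EIF4B, EIF4H, EIF4E, EIF4E1B, EIF4E3, EIF4G1, EIF4G3, DDX3X, DDX3Y, DHX29, EIF4EBP1, EIF4EBP2, EIF4EBP3, EIF5, EIF5B, PABPC1	consolidated initiation factors
INITIATION+	EIF1, EIF1AX, EIF1AY, EIF1B, EIF2B1, EIF2B2, EIF2B3, EIF2B4, EIF2B5, EIF2S1, EIF2S2, EIF2S3, EIF3A, EIF3B, EIF3C, EIF3D, EIF3E, EIF3F, EIF3G, EIF3H, EIF3I, EIF3J, EIF3J, EIF3K, EIF3L, EIF3M, EIF4A1, EIF4A2, EIF4B, EIF4H, EIF4E, EIF4E1B, EIF4E3, EIF4G1, EIF4G3, DDX3X, DDX3Y, DHX29, EIF4EBP1, EIF4EBP2, EIF4EBP3, EIF5, EIF5B, EIF6, PABPC1, ABCE1, EIF2D, MCTS1, DENR, MCTS2P, BZW1, BZW2, EIF4E2, EIF4G2, CTIF, PAIP1, PAIP2, EIF2A, ABCF1, NCBP1, NCBP2	initiation factors plus reinitiation/non-canonical components
eEF1B	EEF1B2, EEF1D, EEF1G	guanine nucleotide exchange factor for eEF1A
eEF1H	EEF1A1, EEF1A2, EEF1B2, EEF1D, EEF1G, VARS1	eEF1A-eEF1B-valyl-tRNA-synthetase supercomplex
ELONGATION	EEF1A1, EEF1A2, EEF1B2, EEF1B2P2, EEF1D, EEF1G, EEF2, EEFSEC, EIF5A, EIF5A2	core elongation factors
ELONGATION+	EEF1A1, EEF1A2, EEF1B2, EEF1B2P2, EEF1D, EEF1G, EEF2, DPH1, DPH2, DPH3, DPH5, DPH6, DPH7, EEFSEC, EIF5A, EIF5A2, EIF5AL1, DHPS, DOHH	elongation factors plus diphthamide/hypusine pathway enzymes
ELONGATION+GTPBPs	GTPBP1, GTPBP2, EEF1A1, EEF1A2, EEF1B2, EEF1B2P2, EEF1D, EEF1G, EEF2, DPH1, DPH2, DPH3, DPH5, DPH6, DPH7, EEFSEC, EIF5A, EIF5A2, EIF5AL1, DHPS, DOHH	elongation factors plus GTP-binding proteins 1/2
TERMINATION	ETF1, GSPT1, GSPT2	release factors eRF1, eRF3a, eRF3b
TERMINATION+	ETF1, GSPT1, GSPT2, PABPC1, ABCE1, EIF2D, MCTS1, DENR, MCTS2P, HBS1L, PELO	release factors plus recycling/rescue components
PABPC paralogs	PABPC1L, PABPC1L2A, PABPC1L2B, PABPC3, PABPC4, PABPC4L, PABPC5, PABPC1	cytoplasmic poly(A)-binding protein paralogs
ARSases	AIMP1, AIMP2, EEF1E1, NARS, RARS, EPRS, MARS, QARS, IARS, KARS, LARS, YARS, VARS, AARS, CARS, DARS, FARSA, FARSB, GARS, HARS, HARS2, SARS, SARS2, TARS, TARSL2, WARS, LARS2, RARS2, VARS2, AARS2, TARS2, YARS2, WARS2, NARS2, PARS2, MARS2, IARS2, FARS2, EARS2, DARS2, CARS2	aminoacyl-tRNA synthetases (cytoplasmic, mitochondrial, dual) plus scaffold proteins
ARSase COMPLEX	AIMP1, AIMP2, EEF1E1, NARS, RARS, EPRS, MARS, QARS, IARS, KARS, LARS	multi-synthetase complex components and scaffolds
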