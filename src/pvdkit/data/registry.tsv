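id	name	role	formula	mono_mass
Gly	glycine	residue	C2H3NO	57.02146
Ala	alanine	residue	C3H5NO	71.03711
Ser	serine	residue	C3H5NO2	87.03203
Pro	proline	residue	C5H7NO	97.05276
Val	valine	residue	C5H9NO	99.06841
Thr	threonine	residue	C4H7NO2	101.04768
Cys	cysteine	residue	C3H5NOS	103.00918
Leu/Ile	leucine/isoleucine (isobaric)	residue	C6H11NO	113.08406
Asn	asparagine	residue	C4H6N2O2	114.04293
Asp	aspartate	residue	C4H5NO3	115.02694
Gln	glutamine	residue	C5H8N2O2	128.05858
Lys	lysine	residue	C6H12N2O	128.09496
Glu	glutamate	residue	C5H7NO3	129.04259
Met	methionine	residue	C5H9NOS	131.04048
His	histidine	residue	C6H7N3O	137.05891
Phe	phenylalanine	residue	C9H9NO	147.06841
Arg	arginine	residue	C6H12N4O	156.10111
Tyr	tyrosine	residue	C9H9NO2	163.06333
Trp	tryptophan	residue	C11H10N2O	186.07931
Orn	ornithine	residue	C5H10N2O	114.07931
fOHOrn	L-N5-formyl-N5-hydroxy-ornithine	residue	C6H10N2O3	158.06914
Dab	L-2,4-diaminobutyrate	residue	C4H8N2O	100.06366
azHA	4-azido-L-homoalanine	residue	C4H6N4O	126.05416
Chr-sa	PVD chromophore-acyl, succinamide side chain	chromophore_acyl	C17H15N3O6	357.09609
Chr-sc	PVD chromophore-acyl, succinate side chain	chromophore_acyl	C17H14N2O7	358.08010
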