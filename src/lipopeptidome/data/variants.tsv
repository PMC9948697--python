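# Characterized peptide sequence variants per family, schema v1 (see data/SCHEMA.md)
# sequence: residues joined by '-', over the LP residue alphabet
# leu5_stereo: L/D tag for the Viscosin-family position-5 leucine, '.' elsewhere
family	name	sequence	leu5_stereo	source	provenance
Viscosin	viscosin	Leu-Glu-Thr-Val-Leu-Ser-Leu-Ser-Ile	L	characterized	TabS1:viscosin
Viscosin	WLIP	Leu-Glu-Thr-Val-Leu-Ser-Leu-Ser-Ile	D	characterized	TabS1:WLIP
Viscosin	viscosinamide	Leu-Gln-Thr-Val-Leu-Ser-Leu-Ser-Ile	L	characterized	TabS1:viscosinamide
Viscosin	pseudodesmin	Leu-Gln-Thr-Val-Leu-Ser-Leu-Ser-Ile	D	characterized	TabS1:pseudodesmin
Viscosin	massetolide	Leu-Glu-Thr-Ile-Leu-Ser-Leu-Ser-Ile	L	characterized	TabS1:massetolide
Viscosin	pseudophomin	Leu-Glu-Thr-Ile-Leu-Ser-Leu-Ser-Ile	D	characterized	TabS1:pseudophomin
Amphisin	lokisin	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Ser-Leu-Ile-Asp	.	characterized	TabS1:lokisin/anikasin
Amphisin	tensin	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Gln-Leu-Ile-Glu	.	characterized	TabS1:milkisin/stechlisin/tensin
Amphisin	arthrofactin	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Ser-Ile-Ile-Asp	.	characterized	TabS1:arthrofactin
Amphisin	amphisin	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Gln-Leu-Ile-Asp	.	characterized	TabS1:amphisin
Amphisin	oakridgin	Leu-Asp-Thr-Val-Leu-Ser-Leu-Gln-Leu-Ile-Asp	.	characterized	TabS1:oakridgin
Amphisin	nepenthesin	Leu-Asp-Thr-Val-Leu-Gln-Leu-Ser-Leu-Ile-Asp	.	characterized	TabS1:nepenthesin
Bananamide	bananamide_A	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Ile	.	characterized	TabS1:bananamide_A-C
Bananamide	bananamide_D	Leu-Glu-Thr-Leu-Leu-Ser-Leu-Val	.	characterized	TabS1:bananamide_D-G
Bananamide	MDN-0066	Leu-Gln-Thr-Leu-Leu-Ser-Leu-Val	.	characterized	TabS1:MDN-0066
Bananamide	prosekin	Leu-Glu-Thr-Leu-Leu-Gln-Leu-Leu	.	characterized	TabS1:prosekin
Orfamide	orfamide_A	Leu-Glu-Thr-Ile-Leu-Ser-Leu-Leu-Ser-Val	.	characterized	TabS1:orfamide_A
Poaeamide	PPZPM	Leu-Glu-Thr-Ile-Leu-Ser-Leu-Leu-Ser-Ile	.	characterized	TabS1:PPZPM
Poaeamide	poaeamide_A	Leu-Glu-Thr-Leu-Leu-Ser-Leu-Leu-Ser-Ile	.	characterized	TabS1:poaeamide_A
Tolaasin	tolaasin_I	Dhb-Pro-Ser-Leu-Val-Ser-Leu-Val-Val-Gln-Leu-Val-Dhb-Thr-Ile-Hse-Dab-Lys	.	characterized	TabS1:tolaasin_I
Tolaasin	sessilin	Dhb-Pro-Ser-Leu-Val-Gln-Leu-Val-Val-Gln-Leu-Val-Dhb-Thr-Ile-Hse-Dab-Lys	.	characterized	TabS1:sessilin_A
Tolaasin	tolaasin_F	Dhb-Pro-Ser-Leu-Val-Ser-Leu-Val-Val-Gln-Leu-Val-Dhb-Thr-Leu-Hse-Dab-Lys	.	characterized	TabS1:tolaasin_F
Putisolvin	putisolvin_I	Leu-Glu-Leu-Ile-Gln-Ser-Val-Ile-Ser-Leu-Val-Ser	.	characterized	TabS1:putisolvin_I-II
Putisolvin	putisolvin_III	Leu-Glu-Leu-Leu-Gln-Ser-Val-Leu-Ser-Leu-Val-Ser	.	characterized	TabS1:putisolvin_III-V
Entolysin	entolysin_A	Leu-Glu-Gln-Val-Gln-Ser-Val-Leu-Gln-Ser-Val-Leu-Ser-Ile	.	characterized	TabS1:entolysin_A
Xantholysin	xantholysin_A	Leu-Glu-Gln-Val-Gln-Ser-Val-Leu-Gln-Gln-Val-Leu-Gln-Ile	.	characterized	TabS1:xantholysin_A
Gacamide	gacamide_A	Leu-Asp-Ser-Val-Leu-Gln-Ser-Val-Leu-Ser-Ile	.	characterized	TabS1:gacamide_A
Asplenin	asplenin	Leu-Glu-Leu-Leu-Gln-Ser-Val-Leu-Ser-Leu-Val-Ser-Ile	.	characterized	TabS1:asplenin
Factin	syringafactin	Leu-Leu-Gln-Leu-Thr-Val-Leu-Leu	.	characterized	TabS1:syringafactin_A
Factin	cichofactin	Leu-Leu-Gln-Leu-Gln-Val-Leu-Leu	.	characterized	TabS1:cichofactin_A
Factin	virginiafactin	Leu-Leu-Gln-Leu-Ser-Val-Leu-Leu	.	characterized	TabS1:virginiafactin_A
Thanafactin	thanafactin_A	Val-Gly-Ser-Pro-Val-Leu-Ser-Gly	.	characterized	TabS1:thanafactin_A
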