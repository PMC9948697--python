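# Predicted lipopeptides (BGC-inferred, chemically unvalidated), schema v1
# Kept apart from variants.tsv: their lengths may deviate from the related
# family's peptide length and they are excluded from classification references.
name	sequence	related_family	module_config	provenance
LP4	Val-Leu-Ser-Gly	Thanafactin	4	TabS4L:LP4
LP7	Leu-Asp-Thr-Leu-Ser-Leu-Ile	Bananamide	2-3-2	TabS4L:LP7
LP9	Leu-Glu-Leu-Leu-Gln-Ser-Leu-Val-Ser	Putisolvin	2-4-3	TabS4L:LP9
LP10a	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Gln-Ile-Glu	Bananamide	2-4-4	TabS4L:LP10a
LP10b	Leu-Glu-Gln-Val-Gln-Gln-Val-Leu-Gln-Ile	Xantholysin	2-4-4	TabS4L:LP10b
LP12	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Ser-Leu-Gln-Ile-Glu	Bananamide	2-4-6	TabS4L:LP12
LP13a	Leu-Glu-Leu-Leu-Ser-Ser-Val-Leu-Ser-Leu-Val-Ser-Ile	Asplenin	1-8-4	TabS4L:LP13a
LP13b	Leu-Glu-Leu-Ile-Gln-Ser-Val-Leu-Ser-Leu-Ile-Ser-Ile	Asplenin	2-7-4	TabS4L:LP13b
LP13c	Leu-Glu-Leu-Leu-Gln-Ser-Val-Leu-Ser-Leu-Val-Ser-Val	Asplenin	2-7-4	TabS4L:LP13c
LP13d	Leu-Glu-Leu-Leu-Gln-Ser-Val-Leu-Gln-Leu-Val-Gln-Val	Asplenin	2-7-4	TabS4L:LP13d
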