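# Lipopeptide family table, schema v1 (see data/SCHEMA.md)
# module_configs: per-gene module counts, genes joined by '-', alternatives by ';'
# superfamily: A-domain homology superfamily (1-4), 0 = not grouped
name	aliases	peptide_length	macrocycle_size	module_configs	organizations	taxon_groups	accessory_genes	superfamily	provenance
Viscosin		9	7	2-4-3	contiguous;bifurcate	Fluorescens_SG;Gessardii_SG;Chlororaphis_SG;Putida_G	none	1	TabS1:Viscosin
Amphisin		11	9	2-4-5	contiguous	Koreensis_SG	none	3	TabS1:Amphisin
Bananamide		8	6	2-4-2	contiguous	Koreensis_SG;Fluorescens_SG;Mandelii_SG	none	3	TabS1:Bananamide
Orfamide		10	8	2-4-4	contiguous	Protegens_SG	none	0	TabS1:Orfamide
Poaeamide		10	8	2-4-4	bifurcate	Fluorescens_SG	none	1	TabS1:Poaeamide
Tolaasin		18	5	6-6-6;3-3-3-3-6;3-3-6-6	contiguous	Fluorescens_G;Protegens_SG	syrD_dab	0	TabS1:Tolaasin
Putisolvin		12	4	2-7-3	contiguous;bifurcate	Putida_G	none	2	TabS1:Putisolvin
Entolysin		14	5	2-8-4	bifurcate	Putida_G	none	2	TabS1:Entolysin
Xantholysin		14	8	2-8-4	bifurcate	Putida_G	none	2	TabS1:Xantholysin
Gacamide	Cocoyamide	11	5	2-4-5	contiguous	Koreensis_SG	none	3	TabS1:Gacamide
Asplenin		13	8	2-7-4;1-8-4	contiguous	Asplenii_SG;Chlororaphis_SG;Putida_G	none	4	TabS1:Asplenin
Factin	Syringafactin;Factin/Syringafactin	8	0	3-5	contiguous	Syringae_G;Putida_G;Asplenii_SG	none	2	TabS1:Factin
Thanafactin		8	0	3-5	contiguous	Corrugata_SG	mfs	0	TabS1:Thanafactin
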