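# Knowledge-base table schemas (v1)

All tables are tab-separated, `#` lines are comments, first non-comment row is
the header. A knowledge base can be loaded from any directory holding files
with these names and schemas (`KnowledgeBase.load(path)`), so the packaged
tables can be extended or replaced by the user.

## families.tsv

| column | meaning |
| --- | --- |
| name | family identifier (unique, case-insensitive lookup) |
| aliases | alternative names, `;`-separated, may be empty |
| peptide_length | residue count *l* of the encoded peptide |
| macrocycle_size | residue count *m* of the lactone ring; 0 for linear families |
| module_configs | per-gene module counts; genes joined by `-`, alternative architectures by `;` (each must sum to *l*) |
| organizations | subset of `contiguous`, `bifurcate` (`;`-separated) |
| taxon_groups | Pseudomonas (sub)group labels of known producers |
| accessory_genes | synteny template: `none`, `syrD_dab`, or `mfs` |
| superfamily | A-domain homology superfamily 1-4, 0 if not grouped |
| provenance | source row of the transcription |

## variants.tsv

| column | meaning |
| --- | --- |
| family | owning family name |
| name | compound name |
| sequence | residues joined by `-`; length must equal the family's peptide_length; alphabet: Leu Ile Val Ser Thr Glu Gln Asp Gly Pro Lys Hse Dab Dhb |
| leu5_stereo | `L`/`D` stereo tag of Leu5 (Viscosin family), `.` if not applicable |
| source | `characterized` or `predicted` |
| provenance | source row of the transcription |

## predicted_lps.tsv

BGC-inferred peptides without chemical validation. Lengths may deviate from
the related family's peptide length (they arise from module insertion or
deletion), so they are stored apart from `variants.tsv` and are excluded from
classification references. Columns: name, sequence, related_family,
module_config, provenance.
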