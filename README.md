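# lipopeptidome

Mining, classification and dereplication of *Pseudomonas* lipopeptide
(LP) NRPS systems.

Nonpathogenic pseudomonads of the *P. fluorescens* lineage secrete cyclic
and linear lipopeptides assembled by type I nonribosomal peptide
synthetases (NRPSs). These enzymes are chains of C-A-T modules — a
starter condensation domain (C_s) acylates the first residue with a fatty
acid, each adenylation (A) domain selects one amino acid, a thiolation
(T) domain tethers the growing chain, and a tandem of two thioesterase
(TE) domains releases the linear or macrolactone product. Because
biosynthesis is collinear, the module order across the consecutively
acting enzymes *is* the peptide sequence, and the peptide length *l*
together with the macrocycle size *m* (the `[l:m]` signature) defines the
chemical family.

This package implements the full in-silico workflow a natural-product
genomics group uses to chart this lipopeptidome, for people who mine
bacterial genomes for LP biosynthetic gene clusters (BGCs) and
dereplicate their products:

- **knowledge_base** — versioned tables of the 13 LP families
  (Viscosin, Amphisin, Bananamide, Orfamide, Poaeamide, Tolaasin,
  Putisolvin, Entolysin, Xantholysin, Gacamide, Asplenin,
  Factin/Syringafactin, Thanafactin): `[l:m]` signatures, per-gene module
  configurations, peptide variants, superfamily membership.
- **synthetic_data** — deterministic, seeded generators for reference
  A-domain sets, family-templated BGCs and annotated genomes (GenBank /
  GFF3 / protein FASTA + truth sidecar), rpoD-like marker sequences, and
  HSQC peak lists, so every stage is testable offline.
- **nrps_parser** — nearest-reference domain calling, module
  segmentation, and multi-gene assembly in biosynthetic order.
- **bgc_miner** — the diagnostic screen: A+C domain content, tandem-TE
  termination, exclusion of standalone-E / single-TE (siderophore-type)
  and fragmented systems, LuxR/PleABC flanking-synteny evidence, and
  resolution of split ("bifurcate") clusters by module-count completion.
- **adomain_specificity** — substrate calls by nearest reference over
  pairwise identity, with the observed clade behaviour: promiscuous Ile
  (Val/Leu) calls and mutual Glu/Gln/Asp ambiguity.
- **peptide_family** — collinear peptide prediction, family/variant
  status (known member, new variant, candidate new family), Q-S switch
  analysis, and A-domain homology-profile superfamilies.
- **phylogenetics** — identity distances, neighbor joining, bootstrap,
  and NRPS-vs-rpoD congruence (normalized Robinson-Foulds, cophenetic
  correlation, discordant-leaf ranking for HGT candidates).
- **module_evolution** — duplication (α), deletion (δ) and exchange (ε)
  events from module-level alignments; sliding-window (50-residue)
  identity profiles over Blosum62 alignments.
- **nmr_fingerprint** — CHα HSQC peak-list dereplication by optimal
  bipartite assignment under ppm tolerances.

## Worked example

```python
from lipopeptidome import synthetic_data as sd, bgc_miner as bm, peptide_family as pf

cfg = sd.SimConfig(seed=7, mutation_rate=0.05)
library = sd.make_domain_library(cfg)          # domain-caller references
refs = sd.make_reference_set(cfg)              # labelled A-domain references

genome = sd.make_genome(
    [("Viscosin", "contiguous"), ("Xantholysin", "bifurcate")], cfg
)
result = bm.mine_genome(genome.records, library)
for bgc in result.bgcs:
    pred = pf.predict_peptide(bgc.system, refs)
    call = pf.assign_family(
        pred,
        organization=bgc.organization,
        module_config=bgc.system.module_config,
        a_sequences=bgc.system.a_sequences,
        reference_systems=sd.reference_systems(cfg),
    )
    print(bgc.organization, bgc.system.module_config, bgc.spacers,
          call.status, call.family, call.matched_variant)
```

prints

```
contiguous (2, 4, 3) [194, 185] known_member Viscosin viscosin
bifurcate (2, 8, 4) [255] known_member Xantholysin xantholysin_A
```

The contiguous Viscosin cluster is a trigenic 2-4-3 system with its two
intergenic spacers (194 and 185 bp) inside the conserved 150-300 bp
range; the Xantholysin system is recovered across two records (its
bimodular initiator gene is genomically separated from the 8+4 operon)
and both predicted peptides match a packaged characterized variant, so
the assignments are `known_member` with the implied macrocycles taken
from the family table.

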