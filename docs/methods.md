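# Methods

## The biological model

Nonpathogenic *Pseudomonas* lipopeptides (LPs) are assembled by type I
NRPS systems with a highly conserved layout that this package treats as
diagnostic:

- an initiator module C_s-A-T that acylates the first residue with the
  fatty acid, followed by elongation modules whose condensation domains
  are either plain (^L C_L) or dual-function condensation/epimerization
  (C/E) domains;
- termination by a **tandem of two thioesterase domains** — abundant
  siderophore and Mycin-type synthetases carry a single TE, and
  pyoverdine-type systems carry standalone epimerization (E) domains, so
  single-TE termination or a called E domain excludes a system;
- **collinearity**: the peptide sequence equals the module order across
  the consecutively acting enzymes, so peptide length *l* equals total
  module count and one A-domain specificity call per module predicts the
  product;
- conserved flanking synteny: an antisense LuxR-family regulator and
  PleC upstream of the initiator gene, PleA/PleB (the tripartite
  exporter) plus often a second LuxR gene downstream of the terminator;
  SyrD/Dab accessory genes in the Tolaasin family; a lone MFS
  transporter next to the thanafactin genes;
- either a contiguous cluster — with a 150–300 bp intergenic
  untranslated region between the initiator and middle NRPS genes — or a
  "bifurcate" organization with the initiator gene at a distant genomic
  location (typical for Xantholysin, Entolysin and Poaeamide producers
  and frequent in the Viscosin family).

Families are the `[l:m]` classes of the knowledge base. The macrocycle
size *m* is a *family attribute*: TE-domain phylogeny discriminates the
cyclization pattern poorly, so the package never derives *m* from a
sequence; novel families simply get no macrocycle value. Stereochemistry
is stored as an annotation (e.g. the L/D-Leu5 pairs of the Viscosin
family) and never predicted, because C/E domains are frequently
epimerization-inactive.

The knowledge-base tables were transcribed from the primary literature
on these compounds; each row carries a provenance tag. Where sources
count variants differently (the Viscosin family can be read as six named
stereo types or as three sequence variants × two Leu5 stereoforms), the
tables store both views. For putisolvin both the reported structure
(Ile4/Ile8) and the A-domain-based reading (Leu4/Leu8) are packaged, and
either is accepted as a family match. BGC-predicted peptides (LP4, LP7,
LP9, LP10a/b, LP12, LP13a–d) live in a separate table and are excluded
from classification references to avoid circular assignment. Two linear
families (Factin and Thanafactin) share the 8:0 signature; they are
separated by architecture and synteny, so the only informative `[l:m]`
collision is Orfamide/Poaeamide at 10:8.

## Synthetic study conditions

The generator emulates the structure the pipeline exploits, not real
sequence content. Synthetic domains are random 20-letter sequences
anchored per domain kind (C_s, ^L C_L, C/E: 440 aa; A: 450; T: 80; TE:
230; E: 300 — approximate real NRPS domain sizes). One anchor per
substrate specificity is built by rejection sampling to below 40%
mutual identity. Three divergence layers mimic real A-domain homology
structure:

1. specificity anchor (the clade ancestor),
2. a per-(variant, module-position) **module anchor** at 10% per-site
   divergence from the specificity anchor — so modules activating the
   same residue are homologous but distinct, as in real systems, and
   adjacent same-substrate modules do not masquerade as duplications,
3. per-BGC instances at the configured `mutation_rate` (default 0.05,
   the default study condition for recovery experiments).

Intergenic spacers are drawn uniformly from 150–300 bp; flanking and
decoy genes are random 300-aa proteins with role-labelled products;
decoy NRPS mimics (single-TE "siderophore-like", standalone-E, and
internally-stopped fragments) can be planted to exercise the exclusion
rules. Genomes are emitted as GenBank (1-based inclusive; all internal
coordinates 0-based half-open) with GFF3, protein FASTA and a JSON truth
sidecar; the GenBank date field is fixed so outputs are byte-identical
per seed. Every generator derives its RNG stream from `(seed, call
tag)`, so adding generators never shifts existing outputs.

What the generator does **not** emulate — and therefore what green
recovery tests do not show about real data: realistic codon-level
nucleotide sequences, Pfam-profile-like domain conservation gradients,
fatty-acid tails and congener mixtures, annotation noise (miscalled gene
boundaries, missing translations), and cross-family sequence homology
beyond the shared anchor alphabet. For real genomes, the domain-caller
thresholds would need calibration against curated annotations; an
adapter accepts externally produced domain tables (TSV) and externally
computed newick trees for exactly that use.

## Algorithms and numerical choices

**Identity.** Pairwise identity is `1 − Levenshtein/max(len)` (edlib).
A score-matrix alignment admits co-optimal tracebacks whose match counts
differ, which would make nearest-neighbour classification depend on
implementation details; edit-distance identity is unique, symmetric and
order-free. The windowed profiles, whose purpose is visual comparison of
aligned synthetases, instead recount identity per 50-column window over
a Blosum62-scored global alignment (open −11, extend −1), gap columns
counting as mismatches; the three display bins are 100%, 30–99%, <30%.

**Domain calling** slides each reference along the protein (stride 10,
local refinement ±9), keeps windows at ≥0.5 identity to the best
reference of a kind, and resolves overlaps greedily (higher score, then
longer hit, then smaller start, then reference id — deterministic and
permutation-stable). The threshold is calibrated on synthetic data only:
instances sit near `1 − module_divergence − mutation_rate ≈ 0.85`
identity and background near 0.3, so 0.5 splits them with wide margins.

**Cluster resolution.** Candidate genes (≥1 A and ≥1 C-type domain)
within 5 kbp on one record form a cluster; real intra-operon spacers are
≤300 bp, so the gap is generous. An orphan C_s-initiated cluster is
paired with the operon whose module total best completes a family
peptide length, ties broken by A-domain homology between the parts; an
equal tie raises an ambiguity report rather than guessing. Flanking
roles are read from annotation keywords within 5 genes / 10 kbp per
side (the sources give no numeric window; this is a repo choice).
Spacer lengths are recorded but never used as a detection filter.

**Specificity calls.** Nearest reference by identity; confidence is that
identity. The ambiguity set contains every specificity within 0.05 of
the best hit; Glu/Gln/Asp mutually inflate each other's sets when
confidence < 0.75 (the acidic clades interdigitate); Ile calls below
0.9 carry a {Val, Leu} promiscuity note; calls below 0.4 are `unknown`.
The 0.05/0.75/0.4 values are repo calibrations on synthetic data —
no numeric thresholds exist in the source literature — and are exposed
as keyword arguments. Thanafactin A domains behave as an outgroup and
its family is its own single-member reference group.

**Family assignment** ranks length-matching families by architecture
template match, organization match, then mean per-module identity to
family reference systems, but lets an ambiguity-aware match to a
characterized variant override the ranking (the predicted peptide is the
strongest discriminator; this separates xantholysin from entolysin and
Orfamide from Poaeamide). `new_variant` requires family homology ≥ 0.7.
Superfamilies: average-linkage clustering of all A domains at 0.6
identity, profile overlap = shared cluster-id multiset / shorter profile
length, systems joined transitively at overlap ≥ 0.5. The 0.6/0.5
values reproduce planted-pool partitions on synthetic analogues.

**Phylogenetics.** Neighbor joining (scikit-bio) over identity
distances replaces maximum-likelihood inference: at desk scale the
claims under test concern congruence structure, not branch-length
estimation. Negative NJ branches are clamped to zero with a warning.
Robinson-Foulds distance is computed over non-trivial bipartitions
(polytomies contribute only resolved splits) and normalized by 2n−6;
cophenetic correlation is Pearson over path-length tip distances;
bootstrap is site resampling over NJ with per-split support fractions.
Discordant leaves are ranked by the greedy improvement in normalized RF
upon their removal — a report of candidates (top-k, no hard cutoff),
because congruence reading is inherently comparative.

**Module events.** Systems are aligned module-by-module with
Needleman-Wunsch on A-domain identity (gap penalty 0.4/module — below
any within-clade match score, above background). Gap runs are deletions
reported with flanking-module homology (the recombination substrate);
aligned pairs with differing specificities and both flanks ≥ 0.8
identity are exchanges; terminal mismatches are reported as plain
substitutions because single-sided flank support cannot distinguish an
exchange from divergence. Adjacent modules at ≥ 0.9 identity are
duplications ("near-identical" is not quantified in the sources; 0.9 is
calibrated on planted duplications and exposed as a parameter).

**HSQC matching.** One CHα peak per residue, ¹H 3.5–5.5 / ¹³C 48–65 ppm.
Matching minimizes the summed tolerance-normalized distance
`d = √((Δh/tol_h)² + (Δc/tol_c)²)` by Hungarian assignment on a
dummy-augmented cost matrix (unmatched peaks cost 1, pair costs capped
at 2); pairs with d > 1 are rejected afterwards. Defaults tol_h = 0.03,
tol_c = 0.4 ppm reflect typical HSQC reproducibility under identical
acquisition conditions; the match verdict needs coverage ≥ 0.9 and RMSD
≤ √(tol_h² + tol_c²). The qualitative "match" criterion of practice has
no published tolerance, so these defaults are config-exposed and the
ranking (not the verdict) is what dereplication tests rely on.

## Problem sizes

The test suite and acceptance script run at desk scale as the package's
own study design: 50 single-BGC genomes (all 13 families, both
organizations) for end-to-end recovery, 14 × 10 references for
leave-one-out classification, 50 random 6–10-leaf trees for NJ
recovery, 10 planted regrafts, 20 random module-block deletions, and
100 BGCs for the spacer measurement. The headline census numbers of a
GenBank-scale survey (producer counts per family, species tallies)
depend on thousands of live genomes and are out of scope here.

## Known limitations

- The domain caller assumes roughly reference-length domains; grossly
  truncated or fused domains would need the external-table adapter.
- Initiator/operon pairing uses module-count completion and homology; a
  genome with several equally plausible pairings is reported as
  ambiguous instead of resolved.
- `unknown` specificity calls still count toward peptide length; there
  is no module-skipping model.
- Bootstrap supports are NJ supports, not posterior probabilities, and
  are only as good as the p-distance model behind them.
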