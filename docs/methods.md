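# Methods

`panoeno` implements the analysis chain used for large bacterial strain
collections — ortholog clustering with conserved gene neighborhood,
core/pan rarefaction, consensus pan-genome assembly, SNP phylogenomics
and functional profiling — together with a synthetic pan-genome
generator that plants every structure the chain is supposed to recover.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic data do and do not show about real data.

## The synthetic pan-genome generator

The generator is first-class, tested code: it defines the conditions
under which every downstream claim is checked.

**Strain tree.** `simulate_tree(n, seed)` joins random pairs of active
lineages coalescent-style; each join adds `0.02 + Exp(0.08)` to the
height, so all branch lengths are strictly positive.  Leaves are
`strain_001 …`.

**Gene content.** An ancestral genome of `n_core_genes` protein-coding
genes (lengths uniform on 80–260 aa, sequences uniform over the
20-letter alphabet) is arranged on a circle.  Three kinds of accessory
structure are planted:

* **Flexible genomic islands (fGIs).**  Each island is a block of
  `fgi_size_range` new genes inserted at one intergenic slot and
  assigned to one tree edge: exactly the strains below that edge carry
  it.  Internal (≥2-leaf) clades are preferred — an island seen by a
  single strain cannot be reassembled if that strain's contig structure
  happens to cut through it, which is an evidence limit rather than an
  algorithm defect.  Insertion slots are pairwise non-adjacent on the
  circle; two fused islands would otherwise be indistinguishable from
  one larger island and "exact recovery per island" would be ill-posed.
* **IS elements.**  One transposase-like protein is copied verbatim into
  every strain at `is_element_copies` distinct slots.  Each slot is its
  own true cluster: the copies are byte-identical but their
  neighborhoods differ, which is precisely the case neighborhood-aware
  clustering exists for.
* **Truncations.**  With probability `truncation_rate` per gene per
  strain, a member is cut to a uniform 15–85% prefix of its full length
  (the frameshift-to-premature-stop outcome).  The realized fraction is
  recorded; optionally the downstream fragment is emitted as a second
  short ORF (`emit_downstream_orf`, off by default).

**Sequence evolution.**  Each non-IS gene evolves along the tree at
`snp_rate` substitutions per site per unit branch length (default 0.02),
protein and nucleotide alike, so sequence similarity mirrors the tree
and one simulation exercises clustering and phylogeny at once.  A
separate random nucleotide reference (`genome_bp`, default 100 kb)
accumulates SNPs the same way; per-strain variant lists are taken
against the first strain, the designated reference.

**Layout.**  Every strain's gene list is the same circular order,
linearised at a strain-specific random origin and split by
`Poisson(contig_break_rate)` breaks placed between genes, never inside
one; every contig keeps at least two genes (a single stranded ORF has no
neighborhood at all and no method could place it).  Coordinates are
1-based inclusive; minus-strand ORFs are written with start > end in the
att table.  ORFs at contig edges are flagged — their lengths are treated
as unreliable downstream.

**Scale of the defaults.**  The default configuration (12 strains, 120
core genes, 4 islands) is the demonstration scale used in the examples
and pipeline demo; the clustering and assembly checks run at 20 strains
× 100 core genes and 12 × 120 respectively.  These are deliberate
scale-downs of a real collection (hundreds of strains, ~1.8 Mb genomes,
~1800 gene families); all structural properties being tested are
scale-free.

**Determinism.**  One seed drives six named child streams (families,
placement, evolution, truncation, layout, SNPs); fixing the seed fixes
every emitted byte.

## Ortholog clustering

**Similarity.**  The internal scorer aligns candidate pairs (sharing ≥4
protein 4-mers) with local alignment, BLOSUM62, BLAST-style affine gaps
(a gap of length L costs 11 + L), and normalizes by the smaller
self-score.  This score ratio is 1.0 for identical sequences *and* for
exact prefix truncations, so truncated members still join their family.
A 12-column BLAST tabular file can be supplied instead; bitscores are
normalized the same way using the self-hit rows.

**Neighborhood.**  `neighborhood_score(a, b)` is the fraction of the up
to `2*window` (default 10) same-offset flanking positions of `a` whose
best match in `b`'s strain sits at the corresponding flank of `b`.
Offsets truncated by contig ends reduce the denominator and never count
as mismatches; with no comparable positions the score is 0.  Only the
same-offset correspondence is used: the generator plants no inversions,
and a mirrored correspondence turns out to award coincidental credit to
unrelated contexts (strand is recorded but ignored, and real inverted
segments are a documented limitation).

**Greedy merge.**  Cross-strain pairs are ranked by
`C = norm + λ·neigh` (λ default 1.0) and merged single-linkage under two
constraints: at most one member per strain per cluster, and
`C ≥ min_normalized_score + λ·min_neighborhood_score` (defaults 0.35 and
0.7, so τ = 1.05 at λ = 1).  The λ-scaled threshold is what separates
identical IS copies in novel contexts (C = 1.0 + λ·0 < τ) while leaving
λ = 0 a pure-similarity clustering (τ = 0.35).  For ranking, the
neighborhood term pools the comparable flank positions of both
directions, `(n_ab + n_ba)/(d_ab + d_ba)`; a pair with *no* comparable
positions at all — one ORF hard against a contig end, the other against
a contig start — carries no neighborhood evidence either way, so for
that pair the λ term is waived from both score and threshold and
similarity alone decides (the limit of the edges-reduce-the-denominator
principle: absence of evidence is not contradiction).  Ties break on the
lexicographic ORF-id pair; unmerged ORFs become singletons; the centroid
is the longest member (ties to the smallest id) and every member carries
its percent-of-longest length.

**Exhaustive oracle.**  For small inputs, `exhaustive_best_partition`
maximises the total *realised evidence*: the sum of `C − τ` over
co-clustered pairs at or above the threshold (sub-threshold pairs carry
no evidence, positive or negative — single-linkage can legitimately
place them together transitively), ties preferring finer partitions.
This is the objective the greedy ascends, and the two are required to
agree on all small random instances.

**Core definition.**  A cluster is core iff it has members (partial or
complete — any truncation still counts as presence) in at least
`ceil(core_fraction · n_strains)` strains; `core_fraction` defaults to
0.75.

## Rarefaction and the exponential law

For each subset size n, `n_samples` strain subsets are drawn uniformly
without replacement (independently per n, not one global permutation);
core(n) uses the same ≥75% ceiling rule as the global definition, with a
strict 100% core available by flag.  All medians are **lower medians**
(lower central order statistic), so they are integers and exhaustive
comparisons are exact.

Two consequences are worth stating plainly:

* The ceiling-rule core is **not monotone in n**: the required coverage
  fraction steps down wherever `ceil(0.75·n)/n` drops (3/3 at n=3 → 3/4
  at n=4), and the exact enumeration shows the median core rising there.
  Monotonicity is therefore a theorem only for the pan curve and the
  strict core, and is asserted for those.
* With a discrete sampling distribution the empirical lower median can
  legitimately land on either central order statistic when the CDF sits
  near 0.5; equivalence checks against `exhaustive_curves` therefore
  accept either the lower or upper exhaustive median (the "median tie"
  convention).

The medians are fitted with `f(n) = A·exp(−n/B) + C` by least squares
with multi-start initial B (1 … N); an all-equal series returns the
degenerate exact fit A=0, C=mean.  The open/closed call evaluates the
fitted slope `f′(N) = −(A/B)·exp(−N/B)` at the full collection size:
open iff it exceeds `threshold` new genes per genome (default 1.0, a
package decision — the notion "still expanding, albeit at a slowing
rate" has no canonical quantitative form).  A non-converged fit yields
an explicit *indeterminate* status, never a silent default.
`clade_exclusion_rerun` repeats fixed-size sampling with a set of
(closely related) strains excluded, the standard oversampling-bias
check.

## Consensus assembly

Adjacencies are counted between immediately neighboring clusters within
contigs only — a contig break never contributes.  The consensus core
order is a greedy walk over majority core-to-core transitions, computed
with flexible clusters treated as transparent (otherwise every
clade-specific island would fragment the core path).  The designated
reference strain contributes only the start cluster and initial
direction — rotation and orientation, never weights.  Ties go to the
smaller cluster id; if the walk starves before covering the core, the
remainder opens new flagged segments rather than raising.  The assembly
is circular when one segment covers everything and the last cluster is
adjacent to the first.  Recovery comparisons are made up to rotation and
reflection (`canonical_circular`), the symmetry the data actually
determine; island member order is likewise compared up to the same
global orientation.

Flexible clusters chain into maximal linear paths by majority adjacency;
a cycle (not expected — islands are linear) is broken at its weakest
edge with a warning.  Paths are anchored by majority vote of the core
clusters flanking their endpoint members in carrier strains, with the
anchors themselves trimmed from the member list; carriers are the union
of strains contributing any member.  Chains shorter than `min_fgi_size`
(default 3) go to a discard log, not the island list — on simulated
collections the planted IS elements surface exactly there, as singleton
discards.  Island ids sort by (left-anchor position in the core order,
length descending).

The layout heatmap reports `100·len(member)/len(longest member)` per
strain over core positions and island members, NaN for absence, with a
parallel contig-edge flag matrix.

## SNP phylogenomics

`apply_snps` substitutes validated biallelic SNPs (1-based; ref alleles
checked against the reference, catching coordinate-convention bugs) into
the reference; indels in VCFs are skipped with a count so pseudo-genomes
stay length-aligned.  All non-variant positions are treated as
reference-equal — no coverage masking, a documented simplification.
Distances are Hamming counts (per-site by flag).

Neighbour joining is the classic Saitou–Nei agglomeration with the exact
Q-criterion and branch-length formulas, written here rather than taken
from a library because the package pins down two contracts a library
does not: deterministic tie-breaking (ties in Q break on the
lexicographically smallest label pair, a merged node inheriting its
smallest leaf label) and exactness on additive matrices (path lengths on
the output reproduce the input to 1e-9), which the tests exercise
against an independent reference implementation.  Negative branch
lengths are clamped to zero with the deficit moved to the sibling edge;
the count of clamped branches is reported on the result.
`group_strains(tree, k)` removes the k−1 longest internal edges (ties by
the clade's smallest leaf) to produce the deepest-split partition.

## Functional profiling

Each (strain, function) cell takes one status from
`absent < contig_break < truncated < functional`; with several ORFs
mapping to one function the best status wins (one full-length copy
suffices for capability).  *Functional* means strictly longer than
`threshold` (default 0.9) times the function's reference length — a
member at exactly 90% is truncated.  Reference lengths default to the
longest member across the function's clusters (a curated database of
"commonly represented" lengths is not assumed); user-supplied lengths
override, and a function with neither is a configuration error.
Contig-edge members are *indeterminate*: their length is unreliable, so
they are never promoted to functional and never demoted to absent.

A pathway is complete iff every required group has a functional member
(groups encode alternative enzymes and alternative KEGG module
variants); incompleteness caused by an indeterminate cell is flagged in
a parallel caveat matrix rather than silently blamed on a truncation.
Subunit systems (PTS enzyme II) are complete/partial/absent by the count
of functional subunits.  Per-enzyme strain counts come with a
square-root-scaled shading value for relative display.

The shipped `data/pathways.yaml` transcribes the amino-acid pathway
tables (complete and incomplete sets, including the three alternative
organic-acid routes to aspartate), eight PTS subunit systems, the
xylose/arabinose/xylulose enzyme sets and the five competence genes.
One published listing of the malate route carries the identifier
`K014454`, an apparent typo for K14454 (aspartate aminotransferase,
matching the lactate and citrate routes); the config uses K14454.  The
four lysine-route KEGG modules are encoded as one any-of group, since
they are variant routes rather than sequential steps.

## Pipeline

`run_all` executes simulate → cluster → rarefy → assemble → phylo →
profile with file-only contracts: each stage reads nothing but the
on-disk outputs of earlier stages, so steps toggle independently
(profiling needs clusters, not the assembly).  One global seed derives
per-stage sub-seeds; the manifest lists every output with its SHA-256
and two runs of the same config are byte-identical.  A stage failure
aborts with the stage name and the partial manifest already written.
The simulator annotates core gene families with the function ids of the
shipped pathway config, so the profile stage runs on simulated
collections without external annotation.

## What passing tests do and do not show

The generator plants clean signal: families are well separated in
sequence space, gene order is rearrangement-free, truncations are exact
prefixes, SNPs are biallelic substitutions with no missing data.
Passing therefore demonstrates the *machinery* — correctness of the
scoring, the constraints, the consensus logic, the formulas, the
determinism — under the stated conditions.  It does not calibrate
thresholds for real data, where domain shuffling, paralog families with
genuine neighborhood conservation, inversions and rearrangements,
assembly errors inside ORFs, and uneven coverage all exist.  Known
limitations, explicitly: no inversion handling in the neighborhood
correspondence or the assembly; no coverage masking in distances; no
bootstrap support; reference lengths from cluster maxima are biased low
when every member of a family is truncated.
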