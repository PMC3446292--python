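# Methods

## Genome model

All statistics operate on a scaffold-resolved gene-order model: each genome
is an ordered list of scaffolds with lengths, each scaffold a list of gene
spans sorted by start coordinate and numbered with 0-based *ordinals*.
Adjacency — the primitive behind the colinearity statistic — is defined on
ordinals and never spans a scaffold boundary. Internal coordinates are
0-based half-open everywhere; GFF3 I/O converts from the format's 1-based
inclusive convention and BED is native, so exactly one conversion happens
at each boundary. Genes with identical starts are ordered by (end,
gene_id) so ordinals are deterministic; overlapping genes are allowed and
ranked by start like any others. Gene identity comes from a configurable
GFF3 attribute (default `ID`, feature type `gene`) because annotation
dialects differ in where they keep stable identifiers. Only gene-level
spans are modeled: every statistic in the package depends on order and
scaffold membership, not exon structure.

## Orthology

Putative orthologs are reciprocal best hits (RBH) in the two directional
all-vs-all similarity tables: (g, h) is kept iff h is g's best subject and
g is h's best subject. "Best" is maximal bitscore, with ties broken by
lower e-value and then lexicographically smaller subject id — the ordering
is total, so the pairing is identical across runs and platforms. No score
threshold is applied by default (`min_bitscore` / `max_evalue` are
available); genes absent from the tables, or not reciprocated, simply stay
unpaired, which is the normal situation — typically only about half of the
genes of two moderately diverged genomes form RBH pairs. The output is
one-to-one by construction.

## Synteny statistics

The ortholog-sharing contingency table has one row per scaffold of A and
one column per scaffold of B; `n_ij` counts mapped pairs landing on
scaffold pair (i, j). Two statistics are computed on it.

**Synteny correlation.** `rho = sum_ij (n_ij − e_ij)² / (n · min(r−1, c−1)
· e_ij)` with `e_ij = n_i. n_.j / n` — a chi-square association measure
normalized to [0, 1] (the square of Cramér's V). Rows and columns with
zero marginals are excluded and the effective r and c shrink accordingly:
their `e_ij = 0` makes the summand undefined, and a scaffold with no
orthologs carries no association information. `rho` is undefined (an
explicit error, not 0) when n = 0 or fewer than two non-empty scaffolds
remain on a side.

**Scaffold-pair Z-scores.** Each `n_ij` is compared with a *re-association
null*: the B-side genes of the ortholog pairs are permuted uniformly among
the pairs, which conserves every row and column marginal by construction
(only the pairing is randomized, not which genes are orthologous). The same
null drives the significance of `rho`; because marginals are invariant,
`e_ij` and the non-empty-scaffold set are fixed across replicates and only
cell counts are recomputed, which is what makes 1,000-replicate runs cheap.

**CPAO.** A conserved pair of adjacent orthologs is an unordered pair of
genes consecutive by ordinal on a scaffold of A, both mapped, whose images
are consecutive by ordinal on a scaffold of B. Orientation and strand are
ignored. Adjacency is computed over *all* annotated genes by default — an
intervening non-ortholog breaks adjacency, the literal reading of
"adjacent genes" — with `adjacency_mode="orthologs_only"` available for
the laxer convention that skips unmapped genes; the choice matters when
ortholog density is low, and exposing both makes the convention explicit
rather than implicit. The CPAO null is different from the synteny null: it
reshuffles the order of all genes of one genome across gene slots
genome-wide, keeping per-scaffold gene counts constant, and recounts. This
randomizes gene order *and* scaffold assignment while preserving the
scaffold size structure.

**Z-score conventions.** All nulls default to 1,000 seeded replicates
(configurable). `z = (observed − null mean) / null sd` with the
*population* (÷R) standard deviation of the replicate values; when the
null sd is zero (degenerate setups such as a single scaffold per genome)
the Z is reported as an explicit undefined marker (NaN + flag), never 0 or
±inf. Significance is read one-sided at z > 3 (normal tail ≈ 0.0013 <
0.01); the false-positive calibration of that convention on null-generated
maps is itself part of the test suite and the acceptance script. Every
stochastic result records its seed and replicate count.

## Landscape analyses

GC tracks tile each scaffold with windows (default 10 kb every 2 kb); N
and ambiguity codes are excluded from numerator and denominator, and
all-N windows are NaN — draft assemblies contain long N runs and silently
counting them would bias the track. Telomere arrays are called when at
least `min_copies` (default 5) gap-free tandem copies of the motif or its
reverse complement occur within `end_window` (default 1 kb) of a scaffold
end; scanning both orientations makes detection strand-symmetric. The
motif defaults to the plant-type heptamer TTTAGGG, the natural choice for
green-algal nuclear genomes, and is configurable. Scaffolds are classified
complete / one-ended / none by how many ends carry an array.

Repeat clusters are single-linkage merges of same-scaffold intervals
separated by ≤ `max_gap` (default 2 kb), discarding merged spans below
`min_span` (default 1 kb) — thresholds chosen so that kilobase-scale
clusters of nested retrotransposon copies merge into one unit while
isolated fragments drop out; both are configurable and the merge is
idempotent. A cluster is *sub-telomeric* when its midpoint lies within 5%
of the scaffold length from either end; the threshold is a fraction rather
than absolute bp because scaffold lengths in draft assemblies span more
than an order of magnitude, and a relative rule behaves consistently
across that range.

## The simulator

The generator produces the structure the statistics assume, with ground
truth attached. An ancestor has `n_scaffolds × genes_per_scaffold` genes
with uniform strands and exponential gene/intergenic lengths (defaults
1500/500 bp). Descendants are derived by a shuffled schedule of events:
inversion (reverse a contiguous gene segment, flipping strands),
transposition (move a segment within its scaffold), translocation (move a
segment to another scaffold, one-way), fusion (concatenate two scaffolds),
fission (split at an ordinal), plus per-gene loss and gain. Segment
lengths are geometric in gene units (mean 3) — the minimal one-parameter
length model in the absence of any empirical rearrangement-size
distribution. Event logs carry concrete parameters, so replaying a log on
the ancestor reproduces the derived gene order exactly; this replay oracle
anchors the simulator tests. Coordinates of derived genomes are re-laid
out with the ancestral spacing model rather than tracked through
breakpoints, because nothing downstream depends on base-pair positions.

Similarity tables plant the RBH signal: each truth pair gets reciprocal
records near a high bitscore (default 500), background records connect
random gene pairs near a low one (default 100), and a `confusion_rate`
fraction of pairs have one direction's best hit redirected to a higher-
scoring decoy — each confusion can break at most two RBH pairs, so
recovery degrades gracefully and measurably. Landscape sequences use
i.i.d. bases at GC 0.53 with planted cluster spans resampled at GC 0.61 —
the background-vs-retrotransposon contrast reported for compact
trebouxiophyte genomes — plus tandem telomere arrays at both ends.

What the simulator does *not* emulate: sequence-level divergence (scores
are drawn, not aligned), nested repeat structure beyond abutting
intervals, paralogous gene families, correlated event placement, or
assembly artifacts. Passing tests therefore demonstrate the correctness
and calibration of the statistics under their own model assumptions, not
robustness to the full messiness of real annotations.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale: genome pairs of
3–10 scaffolds × 10–100 genes, 200–1,000 null replicates, 20-seed
repetition for the stochastic claims, and a 10,000-evaluation
false-positive calibration (100 null maps × a 10×10 scaffold grid at 200
replicates each) — sizes at which the permutation machinery is exercised
end to end while the whole suite stays fast. The CPAO null's Monte-Carlo
moments are validated against exhaustive enumeration at 7 genes (5,040
permutations). Monte-Carlo tolerances follow the usual 3-standard-error
envelopes; equality assertions on `rho` use floating-point-tight
`approx` comparisons since within-scaffold rearrangements change the
contingency table not at all.

## Known limitations

- Statistics are genome-pair operations; no multi-genome synteny, no
  synteny-block segmentation or chaining, and no phylogenetic modeling.
- The re-association and reshuffling nulls are exchangeable-permutation
  models; they do not condition on gene spacing, scaffold ends or local
  gene density.
- RBH orthology is one-to-one by construction and will under-recover in
  the presence of recent duplications; no family-aware refinement is
  attempted.
- Telomere detection requires gap-free tandem arrays; degenerate or
  interrupted arrays at real chromosome ends will be missed at the default
  settings.
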