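# Methods

This note records the models, conventions and numerical choices behind each
stage of the pipeline, the conditions the synthetic generators emulate, and
the limits of what the test suite demonstrates.

## Phylogenetic profiles

A protein's phylogenetic profile is the vector of best homology-search bit
scores against each genome of a reference panel. Retention follows the
standard thresholded scheme: a cell qualifies only with bit score strictly
above 50 bits and e-value strictly below 1e-5 (both inequalities strict, as
conventionally printed), and a protein is kept only when it qualifies in at
least 5 genomes. Absent hits are stored as 0 bits rather than missing
values — profiles are heavily zero-inflated, and a concrete zero keeps rank
correlation defined without imputation. Exact self hits are always
discarded, and by default all hits into the query's own genome are too, so
a profile describes presence in *other* genomes; a self-genome column would
otherwise dominate every profile identically and carry no phylogenetic
signal. Best-hit reduction breaks bit-score ties by lower e-value, then by
lexicographic subject id, making the matrix independent of input order.
Scores are kept as raw bits; no normalization by self-score or protein
length is applied.

## Mountain maps

Profile similarity is Spearman's rank correlation with average ranks on
ties. The tie rule matters: the zero cells form large tie groups, and
average ranking is the convention under which the statistic equals the
Pearson correlation of the rank transforms (which is how the test oracle
computes it). Rows with constant profiles have undefined rank correlation;
they are recorded as 0 with a warning rather than dropped, so row indexing
is stable.

Each protein keeps its 50 most positively correlated partners (fewer when
fewer exist; ties at the cutoff break lexicographically); the directed
lists are symmetrized by union — an edge survives if either endpoint ranks
the other. Union keeps mutual-neighbour structure intact; intersection
symmetrization is available via the same function by post-filtering but is
not the default, since it disconnects peripheral proteins whose top lists
are asymmetric.

The 2D layout is deterministic: per connected component, classical
(Torgerson) multidimensional scaling on graph shortest-path distances with
edge length 1 − ρ (floored at 1e-3 so perfectly correlated pairs stay at a
small positive distance), followed by Fruchterman–Reingold spring
iterations (default 60) with attraction weighted by ρ and a linearly
cooling step cap. The seed only jitters exactly coincident initial
positions (scale 1e-6) so repulsion is defined. Components are normalized
to boxes with side proportional to the square root of their membership and
shelf-packed with a 0.5 gap, largest first. All per-node computations run
in lexicographic protein-id order, so the layout — and every downstream
label — is invariant to the order proteins are supplied in.

Mountains are called on an isotropic Gaussian kernel density estimate
evaluated on a 128 × 128 grid padded by three bandwidths. The default
bandwidth is 1.75 × the median nearest-neighbour distance between embedded
points (floored at 1.5 grid cells). The nearest-neighbour scale tracks
within-cluster spacing, which is the quantity the kernel must smooth over;
global variance rules (Scott/Silverman) are also provided but over-smooth
badly here because map extent reflects between-cluster layout rather than
cluster width. Basins are grown by watershed from local density maxima
restricted to cells above a floor (default 5% of the peak density). Two
post-processing rules formalize what a human does when reading such maps:

* a basin whose saddle toward a neighbour exceeds 0.8 of the lower of the
  two peak densities *and* whose weaker side holds at most 3 × min_members
  points is treated as a sampling artifact and absorbed (finite samples
  from one mountain routinely split its density estimate into shallow
  twin modes); well-populated basins are never merged this way, because
  two genuinely distinct modules can abut with a high saddle;
* basins with fewer than min_members (default 5) proteins are merged into
  the nearest surviving peak within four bandwidths, otherwise their
  members are left unassigned (label 0).

Labels are ordered by descending member count, ties by peak density.

## Enrichment statistics

GO-term over-representation of a mountain against its genome background is
the hypergeometric upper tail P(X ≥ k) with X ~ Hypergeom(N, K, n) (N =
background genes, K = term carriers in the background, n = mountain size).
The correction family is every term annotated in the background, with
Bonferroni as the default (none and Benjamini–Hochberg exposed); the three
best corrected terms are flagged as each mountain's summary. Annotations
are consumed as given — no parent-term propagation through the ontology is
performed.

Niche and taxonomy enrichment pools profiles rather than genes: each genome
with a positive profile cell for a mountain protein contributes one count
to its category (host-associated or not; γ-proteobacterium or not), counted
once per protein and *not* deduplicated across proteins, so a genome shared
by ten mountain proteins carries ten counts — the tally measures profile
composition, not genome membership. The mountain tally is compared to the
genome-wide tally with a two-sided Fisher exact test (sum of all tables
with probability ≤ the observed), labelled Over when the sample odds ratio
exceeds 1 and Under otherwise. By default the mountain's counts are
subtracted from the background row so the 2 × 2 table is disjoint; the
alternative (background as grand total) is a flag. Zero-margin tables
report p = 1 with no direction and a degenerate flag.

## Orthology

minLrap is the alignment length divided by the shorter of the two protein
lengths, capped at 1 (end-overhang artifacts can push the raw ratio above
1; the cap is logged). Orthologs between two genomes are reciprocal best
hits among hits passing minLrap ≥ 0.6 and identity ≥ 30% — both inclusive
boundaries — with the same deterministic tie-breaking as profile reduction.
Reciprocal best hit is deliberately the *minimal* orthology model: it
yields a one-to-one table, which is what Venn-region counting over gene
sets requires; no in-paralog clustering or synteny support is attempted.

The Venn partition is anchored: for each genome in turn, each of its genes
is assigned the region given by the set of genomes holding an ortholog to
it, so per anchor the region counts always sum to the proteome size.
(Counts for the same region can differ between anchors when RBH chains are
not transitive; both per-anchor views are reported rather than a single
family-level count.) Class extraction — genes with an ortholog in every
required genome and none in any excluded genome — is a predicate over the
same presence sets; requiring the other genomes of two genera and
excluding enteric outgroups yields shared-lifestyle gene classes, and
requiring only the sister species while excluding everything else yields
genus-specific classes.

## Genome identity

ANIb fragments the query genome into consecutive non-overlapping 1,020-bp
windows (the trailing shorter fragment is kept and flagged), aligns each
fragment against the reference, and averages the percent identity of
fragments whose best hit reaches ≥ 30% identity over ≥ 70% of the fragment.
The computation owned here is the retention rule and averaging; the
aligner is pluggable. The built-in aligner is semi-global edit distance
(edlib): the fragment aligns in full against any region of either strand
of the reference, identity = 1 − distance/length. For substitution-only
divergence this equals true identity up to the rare case where an indel
path is cheaper than the substitution path. ANIb is reported per direction
and as the two-direction mean.

The tetranucleotide signature is the 256-vector of z-scores
z(w) = (O(w) − E(w)) / √E(w) with the maximal-order Markov expectation
E(w₁w₂w₃w₄) = N(w₁w₂w₃)·N(w₂w₃w₄)/N(w₂w₃); √E is the Poisson
approximation of the model variance. Counts are pooled over the sequence
and its reverse complement (never across the junction), which makes the
signature strand-invariant by construction. Counting is *circular* by
default — bacterial chromosomes are circular, and circular counting has
the clean property that every position contributes one word of each
length, so O = E holds exactly on homopolymers; linear counting differs
by O(1/L) edge terms and is available as an option. Words containing
ambiguous bases are skipped. Two genomes are compared by the Pearson
correlation of their z-vectors; a zero-variance vector (e.g. a
homopolymer) yields NaN rather than an arbitrary value.

Global pairwise identity (used for rRNA-level comparisons) is a
Needleman–Wunsch alignment at match +1 / mismatch −1 / gap −2, identity =
matches over alignment columns. Among co-optimal alignments the first
reported by the aligner is used; on the short, highly similar sequences
this is intended for, co-optimal identity differences are negligible.

Genome statistics from annotated records: G+C is computed over unambiguous
bases and rounded to two decimals; the coding fraction uses the interval
union of CDS spans (compound locations contribute each part), so
overlapping genes are not double-counted.

## Synthetic data: what it emulates and what it does not

`simulate_profile_matrix` plants each module as a fixed *characteristic
genome set* (a random half of the panel by default); module proteins carry
hits inside that set with probability 0.9 and outside with 0.05, background
proteins use 0.05 everywhere, and every cell's presence is flipped with the
given noise probability. Equal inside/outside probabilities therefore
collapse to pure noise — the no-signal control. Present cells draw
bit scores from a normal (mean 150, sd 30 bits) truncated just above the
50-bit retention threshold, so planted structure survives filtering by
construction. Two planted modules can share most of their characteristic
genomes by chance; when they do, the map legitimately merges them — the
end-to-end recovery figures should be read with that in mind.

`simulate_genome_pair` evolves one derived genome from an ancestor by
independent per-site substitution, uniform over the three alternative bases
(Jukes–Cantor-like, matching the "fraction of identical sites" semantics of
ANI), plus optional single-base indels (deletion and insertion each at half
the indel rate); realized divergence is reported exactly as substituted
over aligned (non-deleted) sites, giving identity metrics an analytic
oracle. `simulate_annotations` assigns categories at a background
frequency, with one gene set carrying one category at
min(1, frequency × factor); an explicit probability override expresses
degenerate designs the product form cannot reach (such as a category
absent from the background). `simulate_ortholog_hits` emits reciprocal
full-length high-identity hit pairs for true orthologs plus weaker
cross-hits standing in for paralogs.

None of the generators model realistic protein evolution (no substitution
matrices, domain architecture, rate heterogeneity), genome rearrangement,
compositional skew, or horizontal transfer. Passing tests therefore
demonstrate algorithmic correctness and statistical calibration under the
stated generative conditions — not performance on real proteomes, where
profile noise is structured rather than independent.

## Verification conditions and problem sizes

The end-to-end recovery surface uses five 30-protein modules over 60
genomes at 5% flip noise (150 proteins total). The statistical oracles are
checked exhaustively — every 2 × 2 table with total N ≤ 60 for the
two-sided Fisher test and every (N, K, n, k) configuration with N ≤ 200
for the hypergeometric upper tail, both through their symmetry-canonical
forms, against direct enumeration from binomial coefficients at 1e-12.
Spearman is checked against an independent rank-then-Pearson computation on
one hundred 20 × 15 matrices. ANIb recovery uses 100-kb pairs at 2%, 5%
and 10% substitution. The planted-enrichment condition is a 20-gene set
enriched 5-fold in a 1,000-gene background at a background term frequency
of 0.15 — the scale of a broad (GO-slim-level) functional category, chosen
so the planted effect is comfortably detectable by a calibrated test —
over 100 replicates at Bonferroni-corrected p < 0.01.

## Known limitations

* The layout is a deterministic surrogate for interactive force-directed
  map tools; coordinates are reproducible but not comparable across
  different inputs, and only the partition (not geometry) is contractual.
* Mountain calling exposes bandwidth, floor and min_members; the defaults
  are tuned for planted-module geometry and may need adjustment for real
  maps with strongly unequal cluster densities.
* RBH orthology under-calls recent duplications by construction.
* ANIm (maximal-exact-match based ANI) is not implemented; ANIb and TETRA
  are the supported whole-genome metrics.
* Published genome-level numbers (replicon statistics, 16S identity,
  ortholog counts for the four deposited genomes) can be recomputed with
  these tools only when the deposited records and an all-vs-all search
  result are supplied locally; the package performs no downloads.
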