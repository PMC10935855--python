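# Methods

This note records the scientific conventions, parameter choices and known
limitations of `cladescan`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and offset conventions

GFF3 coordinates are 1-based inclusive externally and are kept that way on
`GeneAnnotation`; all internal slicing is 0-based half-open. Motif hits are
reported in a start-codon-anchored signed convention: offset −1 is the base
immediately 5′ of the start codon, a hit's offset is the position of its
5′-most base, so a k-mer flush against the ATG has offset −k. Within a
promoter fragment of length L the window starting at 0-based position i has
offset i − L. This convention survives truncation (fragments clipped at
contig boundaries keep their 3′ anchor at the start codon).

Promoter fragments are the reference slice `[start−length, start−1]` for
plus-strand genes and the reverse complement of `[end+1, end+length]` for
minus-strand genes. Fragments are **not** clipped at upstream genes — the
analysis this package implements used fixed-length fragments — but an
overlapping gene span sets `upstream_gene_in_window` so downstream consumers
can filter. N bases are preserved and match no motif symbol.

## Selection

Thresholds are applied with inclusive operators exactly as conventionally
printed: up-regulated means p ≤ p_max **and** log₂FC ≥ lfc_min; down uses
log₂FC ≤ −lfc_min. The magnitude rule is split by direction because both
regulated sets are reported from the same cutoffs. The p-value column is
configurable (`p_column`); the package takes no position on raw vs adjusted
p-values because the DE statistic itself is consumed, never computed —
the pipeline's contract starts at the DE table.

## The conservation criterion

For one gene and motif, over the gene's collected ortholog promoters
(`n_orthologs_collected`, which **includes the focal species' own
fragment** — a clade comparison on 12 species uses up to 12 fragments, the
focal one among them):

* reference offset = the focal hit nearest the start codon (largest offset;
  deterministic anchor when the motif occurs in repeats);
* a promoter *agrees* when any of its hits, either strand, lies within
  `position_window` bp of the reference;
* **conserved** ⇔ the group is evaluable (≥ `min_orthologs` collected
  promoters and ≥ 1 focal hit) and the agreeing fraction reaches
  `presence_threshold` (inclusive: 9 of 12 is exactly 75% and passes);
* **majority** ⇔ a hit anywhere in strictly more than half of the collected
  promoters; computed even when the focal promoter lacks the motif.

Defaults: `presence_threshold = 0.75`, `position_window = 200` bp,
`min_orthologs = 8` (two-thirds of a 12-species clade). The positional
window is a genuine free parameter — "similar position" has no published
magnitude — so it is surfaced in every output (`summary.json` echoes all
three values). 200 bp is conservative relative to 1,000 bp fragments: for a
5-mer at GC 0.5 a ±200 bp window still contains a chance hit with
probability ≈ 0.5 per strand pair, which is why the positional rule, not
bare presence, does the discriminating (compare the conserved vs majority
columns of any run).

### Summary denominators

The three-column summary uses two denominators deliberately: column 1
(present in focal promoter) is computed over regulated genes that have a
focal promoter; columns 2–3 (conserved / majority) over regulated genes
whose ortholog group has at least `min_orthologs` collected promoters. The
funnel (selected → with-promoter → evaluable) is printed in the manifest and
in `summary.json`; nothing is silently dropped (genes without promoters are
listed in `missing_promoters`). Percentages are rounded half-up to integers
for display; the underlying counts are always emitted alongside.

## Discovery

Candidates are every k-mer (kmin ≤ k ≤ kmax) occurring in the focal
promoters of the seed cluster, folded with reverse complements into
canonical keys (lexicographically smaller of the pair; palindromic keys
count each window once). Each candidate is classified with the same
conservation rule against every cluster gene; candidates conserved in at
least `min_cluster_fraction` of cluster genes are returned. Ranking is fully
deterministic: score (descending), then total occurrences across all cluster
promoters (ascending — rarer is more specific; this also breaks ties
*against* high-background words), then lexicographic. The discovery path
shares its agreement-counting core with `classify_conservation`, and the
test suite re-checks every returned motif through the public classifier.

## Synthetic data: the stated world

The generator emulates exactly what the downstream stages consume:

* i.i.d. base composition with P(G) = P(C) = gc/2 (default gc = 0.5,
  matching the ~49% GC of the motivating yeast genome); no dinucleotide
  structure;
* one planted motif per ortholog group at `anchor_offset` (default −200 bp)
  plus Gaussian positional jitter (default SD 30 bp), rounded and clipped to
  the valid window, on a uniformly random strand; per-species presence is an
  independent Bernoulli draw (`presence_prob`); `focal_presence_prob`
  optionally pins the focal species (recovery studies set it to 1.0, i.e.
  they condition on the motif being observed in the focal promoter — the
  question asked of a motif is "is it conserved?", which presupposes it was
  seen);
* DE truth is generated at the statistics level: null genes p ~ U(0,1),
  log₂FC ~ N(0, 0.3); regulated genes p ~ Beta(shape, 1) with small shape
  and log₂FC ~ N(±effect, 0.3), signs recorded;
* fixture genomes place each gene in its own block (promoter + 120 bp gene
  body beginning with ATG) so that extraction round-trips exactly on both
  strands; explicit placements are checked for collisions.

What a green test therefore establishes: correctness of the scanning,
extraction, selection and conservation *logic* against known truth and
independent oracles. What it does not establish: robustness to promoter
evolution (indels shift positions between species), phylogenetic
correlation among species (all draws are exchangeable), motif degeneracy in
real binding sites, or read-level noise — none of which the generator
simulates.

### Choice of planted motif length in recovery studies

The conservation Monte-Carlo (high presence recovered, low presence
rejected) uses a planted 8-mer. This is an analytical choice made before
simulation: a 5-mer occurs by chance in ~86% of random 1 kb promoters at
GC 0.5 (expected both-strand count 2·996/4⁵ ≈ 1.9), so background hits, not
planted presence, would dominate any presence/absence recovery study — the
low-presence rejection bound would be unreachable. An 8-mer has expected
background count ≈ 0.03 per promoter, making recovery reflect the planted
per-species presence. Discovery recovery uses a planted 5-mer as its target
(background-heavy, deliberately) because its ranking is relative: the
planted key must merely beat every background key, which positional
agreement across 5 independent cluster genes makes overwhelming.

## Normalization

TPM: per sample, rate = count / length(kb), rescaled to 10⁶ (columns sum to
10⁶ to 10⁻⁶ relative tolerance); an all-zero sample yields a zero column
with a warning. FPKM = count · 10⁹ / (length(bp) · library size); an
all-zero sample is an error unless explicitly allowed, since the division is
undefined. Row normalization for heatmaps uses the z-score with population
SD (divisor n, matching common heatmap tools; configurable to minmax);
constant rows become zeros with a warning rather than NaNs.

## Determinism

Every stochastic component is driven by `numpy.random.default_rng` seeds
threaded through explicitly. A pipeline run with a fixed seed and identical
inputs is byte-identical across reruns and across directories, with two
documented exceptions: the manifest's `timestamp` field and the run log's
stage timings. The manifest records input paths as basenames plus SHA-256
content checksums so that provenance is location-independent.

## Known limitations

* Species are exchangeable: no phylogenetic weighting of conservation, and
  no correction for shared ancestry inflating apparent conservation.
* No statistical null model is attached to a "conserved" verdict; the
  criterion is a rule, not a test, and the background calibration in the
  test suite shows its false-positive behaviour varies strongly with motif
  length and window width.
* Gene-level promoters only: no transcript/TSS resolution, no
  intergenic-aware truncation.
* Plain-text formats only (FASTA/GFF3/TSV); no remote database retrieval.
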