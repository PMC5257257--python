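# Methods

## The screen model

The package analyzes forward-genetic screens in near-haploid human cells
mutagenized with a gene-trap (GT) retrovirus. The working assumptions, which
also define the synthetic generator, are:

* **one insertion per cell** — the cells are haploid and infected at low
  multiplicity, so a single insertion suffices for a null phenotype; the
  hundreds of independent insertions seen per gene are a population-level
  property;
* **directional trapping** — the GT cassette carries a splice acceptor and
  polyadenylation signal, so an intronic insertion truncates the transcript
  only in the sense orientation, while exonic insertions disrupt in either
  orientation. "Inactivating" therefore means exonic (sense or antisense) or
  sense-intronic;
* **selection via a FACS gate** — sorted cells are an enriched sample of the
  mutagenized population; the control dataset is the same population without
  selection.

## Unique-site derivation

Junction reads are 36-bp genomic sequences flanking the LTR. A read's
alignment report lists every candidate placement at 0–2 mismatches. Rules:

1. **uniqueness:** keep a read iff it has exactly one zero-mismatch placement
   and no other placement at ≤ 2 mismatches; the retained read contributes
   its zero-mismatch placement only;
2. **coordinate dedup:** reads sharing (chrom, position, strand) become one
   site with read support equal to the read count;
3. **collapse:** within a (chrom, strand) group, sites whose positions differ
   by ≤ 2 bp are merged transitively; the retained representative is the
   member with the greatest read support (ties: smallest position), carrying
   the summed support.

Design choices where the procedure is underdetermined: collapse is
strand-restricted by default (opposite-strand junction reads represent
different provirus orientations; a `same_strand_only=False` flag merges
across strands); the 1–2 bp rule is applied transitively within a chain; the
insertion position is the leftmost aligned base of the junction read and the
GT orientation is the alignment strand. Coordinates are 0-based half-open
internally (BED native; refFlat native; GTF converted on read).

## Gene models and classification

All transcripts of a gene are reduced to one span (union of transcript
extents) and one exon-interval union, so an insertion in a region shared by
several transcripts is counted once. Two resolution modes exist for
positions whose exon/intron status differs between isoforms: `any`
(default — exonic if exonic in any transcript) and `all` (exonic only if no
transcript makes it intronic). A site overlapping two distinct genes is
counted in each, with orientation evaluated per gene. The per-gene 500-bp
insertion histogram tiles the span from the gene's 5' end (rightmost
coordinate for minus-strand genes), split into sense/antisense columns.

## Enrichment statistics

Per gene, the 2×2 table compares the gene's share of **inactivating**
insertions among all inactivating insertions in the sorted dataset (k of N)
with its share of **any-orientation** insertions in the control dataset
(m of M). The p-value is the exact hypergeometric upper tail (one-sided
Fisher test, alternative: enriched in sorted), computed via
`scipy.stats.hypergeom`; no pseudocounts or continuity correction. The
multiple-testing family is the set of genes with ≥ 1 insertion in either
dataset — never-hit genes carry no information and would only dilute the
correction. q-values are Benjamini–Hochberg (statsmodels); hits are called
at q < 0.01, and results are ordered by (q, p, gene_id) for stable output.

The test suite validates the p-values against an independent oracle that
enumerates all tables with the same margins in exact rational arithmetic
(`Fraction` over binomial coefficients): exhaustively for all tables with
N + M ≤ 40 and on a seeded sample of 2000 tables up to N + M ≤ 200, at
relative error < 1e-12. The exhaustive bound is set by oracle cost, which
grows steeply with table size; the sampled layer covers the larger margins.

## IGTIOB and cross-screen comparison

`IGTIOB = log2(S/A) · ln(S·A)`, `S = 1 + S_raw`, `A = 1 + A_raw`, where
S_raw/A_raw are the unique sense/antisense intronic insertion counts of a
gene in the sorted dataset. The score is exactly 0 at S_raw = A_raw (hence
also for genes with no insertions — 0 is the formula's own value, not an
imputation) and antisymmetric under count exchange.

Genes enter the comparison matrix when q < 1e-4 in at least one screen, and
are scored in every screen. Gene rows are ordered by agglomerative
complete-linkage clustering under the city-block (L1) distance with no row
normalization. The clustering is implemented in-package (naive O(n³)
agglomeration) so that tie-breaking is fully specified: tied merges pick the
pair with the lowest original row index, and the child containing the lower
original index comes first in the leaf order. scipy's linkage serves as an
independent cross-check in the tests on tie-free inputs; heat-map matrices
are at most a few hundred rows, so the naive algorithm is ample. Clustering
runs on **signed** scores by default; the "absolute value/city block"
phrasing of the original clustering tool is ambiguous, so a
`distance_on="absolute"` flag clusters |score| instead. Negative scores are
clipped to 0 **for display only, after clustering**.

`median_sem` reports the sample median with SEM = 1.253·σ/√n (σ the n−1
sample standard deviation); 1.253 ≈ √(π/2) is the large-sample ratio of the
standard errors of median and mean under normality.

## The synthetic generator

The generator emulates the statistical structure the analysis relies on; it
is a model of the screen, not of the sequencing:

* **integration positions** — a two-component mixture: with probability
  `tss_bias_weight` uniform in a `tss_window` downstream of a uniformly
  chosen gene's transcription start (retroviral integration favors TSSs; the
  bias strength is a free parameter, defaulting to weight 0.3 and a 2 kb
  window as a moderate, qualitative bias), otherwise uniform over the
  genome. An optional `intergenic_rate` reweights the uniform component
  between intergenic and genic space (unset = plain genome-uniform).
  Orientation is uniform on ±.
* **selection** — each pool cell passes the gate independently with
  probability `gate_fraction` (default 0.1, the looser of the gates used in
  practice; suppressor-type screens gate at 0.02), multiplied by the gene's
  `effect_strength` (capped at 1) when the insertion qualifies:
  `lof_positive_regulator` — any inactivating insertion;
  `three_prime_sense_dominant` — sense insertions in the 3'-terminal intron
  only (the AXIN2-like dominant-truncation pattern);
  `orientation_independent_intronic` — intronic insertions in either
  orientation (the TFAP4-like pattern); `null` — base probability only.
  Bernoulli sampling is simpler than an exact-quantile gate and equivalent
  in expectation.
* **genome layout** — `random_genome` places non-overlapping genes
  (10–40 kb, 4–10 exons of 100–300 bp) separated by 20–80 kb gaps; with
  1e5 cells this yields tens to a couple of hundred unique insertions per
  gene, the density of a saturating screen. Genes assigned the
  3'-sense-dominant class get ~60% of their intronic length in the terminal
  intron, since the class is only observable when that intron is large.
* **alignment-report emission** — re-emits sites as per-read reports,
  injecting second placements at 0–2 mismatches (must be excluded by the
  uniqueness rule) and 1–2 bp position offsets (must be re-merged by the
  collapse rule) at configured rates. No sequence-level synthesis (no
  FASTQ), and no PCR-amplification bias model.

One integer seed drives a single `numpy.random.Generator`; fixed seed gives
bit-identical datasets.

What passing tests on this generator show — and what they do not: the
pipeline recovers planted effects and controls false positives under the
model's assumptions (independent single insertions, Bernoulli gating,
position-independent recovery). Real screens add LAM-PCR jackpotting,
mappability holes, chromatin-dependent integration preferences and
non-independent growth effects, none of which are modeled; results on real
data depend on those factors as well.

## Scale of the validation runs

The acceptance checks run a scaled-down screen: 200 genes, 1e5 cells in
each population, one planted loss-of-function gene at effect strength 50,
and 20 null replicates for calibration. At this scale the planted gene is
recovered at rank 1 with q far below 0.01, null screens produce no hits at
q < 0.01, and the pooled fraction of null genes with p < 0.05 sits in the
conservative band expected of a discrete one-sided test (~0.03–0.05).

## Pipeline and degenerate inputs

`run_pipeline` validates before executing (duplicate screen ids, missing
files, threshold ranges, sites on chromosomes absent from the annotation),
persists every stage as TSV/BED, and writes a manifest with a configuration
hash and per-output sha256 checksums; manifests contain no timestamps, so
identical config + seed reproduce identical bytes. Degenerate cases: an
empty sorted dataset is an error (nothing to test); a gene with zero counts
in one dataset is still tested if hit in the other; an empty comparison
matrix (no gene passes the stringent threshold) is valid output; a
single-gene matrix skips clustering (identity order).

## Known limitations

* No aligner: the package consumes SAM/BAM or a 5-column placement TSV; it
  does not trim LTR sequence or map reads.
* Multi-chromosome synthetic genomes are not generated (analysis handles
  them; the generator uses one chromosome).
* Overlapping genes are supported in the analysis (a site counts in each)
  but not in the generator.
* The GTF reader ignores transcript grouping, so the `all` exon-resolution
  mode is only meaningful with refFlat input.
* Benchmarking against the original deep-sequencing datasets requires the
  deposited FASTQ archives and a genome-scale alignment, which is outside
  the scope of this package's test surface.
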