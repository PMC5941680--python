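# Methods

This note documents the models implemented in `circnet`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Caller harmonization

The four supported dialects (CIRI-like, CIRCexplorer-like, find_circ-like,
KNIFE-like) are tab-separated, one back-splice junction per line; column
layouts are documented in `circnet.callers`. CIRI reports 1-based inclusive
start coordinates and is decremented on parse; everything downstream is
0-based half-open.

Candidate identity is the exact `(chrom, start, end)` triple after
normalization. No fuzzy (±1) merging is attempted: the tools' residual
coordinate disagreements are a known problem, but without a principled
tolerance an exact join is the reproducible choice. Strand is recorded by
majority vote but excluded from identity, because not every dialect emits
it reliably.

When several tools report the same junction in the same sample, the
per-sample read count is the **maximum** across tools. The alternatives —
summing (double-counts the same fragments) or averaging (mixes different
capture efficiencies) — both conflate tool behaviour with abundance; the
max is a conservative single number. The ≥ 2-read support filter is applied
to this per-sample maximum, and a candidate survives if any sample
survives. The recurrence filter (`filter_recurrent`) keeps candidates with
at least `min_samples` samples at `min_reads_per_sample` or more; network
input uses detection in at least half the cohort (10 of 20 by default).

## Annotation

A candidate is *exonic* when both back-splice boundaries lie inside exons
of a single transcript (half-open containment; boundaries need not coincide
with annotated exon edges), *intronic* when it overlaps a gene body without
satisfying the exonic rule, *intergenic* otherwise. With conflicting
transcripts the most specific class wins, and `exons_spanned` is taken from
the transcript that maximizes it. CDS membership uses BED12
thickStart/thickEnd: a circle is `in_CDS` only when every exonic base it
overlaps lies inside the thick span, i.e. it touches no UTR. Candidates on
chromosomes absent from the gene models are classified intergenic with a
warning rather than an error, since a missing contig in the annotation is
common and not the candidate's fault.

## Circular-to-linear quantification

For one candidate in one sample, with `Nc` back-spliced reads and `Nl5`,
`Nl3` linear reads at the circle's two splice sites:

    ratio = Nc / max(Nl5, Nl3)

Cohort summaries average the counts across the samples in which the
candidate was detected and divide once (mean-of-counts). This matches the
convention of reporting "average back-spliced reads" next to "average
linear reads" and is more stable than a mean of per-sample ratios, which
is dominated by samples with tiny linear counts. `Nl5` is looked up at the
candidate's start coordinate and `Nl3` at its end; since the ratio uses the
maximum of the two, the 5′/3′ naming convention cannot change any result.

A candidate with `max(Nl5, Nl3) = 0` and `Nc > 0` has no finite ratio and
is written as the flag `CIRC_ONLY`, never as infinity. Classes:
`circ_dominant_ge10` (ratio ≥ 10 with a nonzero linear count), `no_linear`,
`linear_higher` (`max(Nl5, Nl3) > Nc`), `other`. These are mutually
exclusive — ratio ≥ 10 implies the linear count is at most `Nc/10`.

## miRNA binding-site prediction

Two independent criteria are computed for every circRNA × miRNA pair and a
site must pass both, mirroring the common practice of intersecting a
match-score predictor with a hybridization-energy predictor.

**Sequence extraction.** Exonic candidates yield the spliced exon sequence
clipped to the back-splice interval; other candidates the genomic span;
minus-strand candidates are reverse-complemented. Because the molecule is
circular, the first `L − 1` nt (`L` = longest miRNA) are appended at the
end so junction-spanning sites fall inside the linear scan. Sequences are
handled as RNA; genomic input is converted T→U.

**Match score.** A Smith–Waterman local alignment of the miRNA (3′→5′)
against the target (5′→3′), scored by complementarity: Watson–Crick +5,
G:U wobble +2, mismatch −3, affine gaps (open −9, extend −4), with
substitution scores doubled at miRNA positions 2–8 so that seed pairing
dominates. These parameters put strong sites on the familiar 140–190
scale, so the conventional 150 (low) and 180 (high) thresholds apply
directly; they live in `AlignmentParams`, not in code. Two scale
properties worth knowing:

* the maximum score of an L-nt miRNA is `5·L + 35` (perfect complement),
  i.e. exactly 150 for 23 nt and 155 for 24 nt — under this table the 180
  tier is unreachable for natural-length miRNAs, so on synthetic data the
  high-stringency network is empty and the 180 threshold functions purely
  as a monotone filter (verified as such);
* reverse-complement symmetry of the score holds only for unweighted,
  wobble-free scoring — seed doubling privileges the 5′ end, and a G:U
  pair complements to an A:C mismatch.

Sites are non-overlapping alignment maxima chosen greedily by descending
score (leftmost wins ties), which makes site counts deterministic.

**Duplex energy.** A nearest-neighbor stand-in for a full hybridization
model: consecutive Watson–Crick pairs contribute Turner-style stacking
free energies (37 °C table keyed by the target dinucleotide), steps
involving G:U contribute a flat −0.5 kcal/mol, each internal non-paired
alignment column adds +0.5 kcal/mol, and loop entropy is ignored. Totals
above zero are reported as 0 (no stable duplex). The model preserves the
rankings that matter at this scale — longer and more GC-rich duplexes are
more favorable, truncations are strictly less favorable — without claiming
quantitative ΔG accuracy. The default acceptance threshold is
−20 kcal/mol; no published cutoff exists for the second predictor in this
workflow, so the value is an explicit package choice (a perfect ~23-nt
site sits near −45, random sequence near 0, leaving a wide margin).

## Network assembly

circRNA–miRNA pairs passing the score threshold **and** the dual-predictor
requirement form the left layer; miRNA–gene edges come from the exact,
case-normalized intersection of two target databases; genes are filtered
by differential expression (low tier: uncorrected p < 0.05; high tier:
additionally |log2FC| ≥ 2 and score ≥ 180). Pruning order is fixed —
genes filtered, then miRNAs without surviving genes, then circRNAs without
surviving miRNAs — which yields the maximal consistent subnetwork and is a
fixed point (re-pruning changes nothing). circ–mir edge weights are
binding-site counts; mir–gene edges have unit weight. Exports: SIF with
`binds`/`targets` relations and GraphML with layer/weight attributes;
GraphML re-import round-trips node and edge sets.

Gene identifiers are canonicalized to uppercase (HGNC style) and miRNA
identifiers to lowercase on load. The DE sign convention is
first-group-over-second with groups ordered alphabetically (AD over ND for
the default labels).

The package bundles a reference high-stringency edge table from a
published posterior-cingulate astrocyte study
(`data/high_stringency_network.tsv`: circRNA, miRNA, predicted site count,
DE target genes); `network_from_edge_table()` rebuilds that network and
its statistics (4 circRNAs, 11 miRNAs, 49 genes).

## Enrichment and differential testing

Pathway enrichment is classic over-representation: a one-sided
hypergeometric tail `P[X ≥ k]` per gene set (scipy), Benjamini–Hochberg
across pathways (statsmodels), default report threshold FDR < 0.01. The
universe defaults to all genes in the DE table; pathway definitions come
from a user GMT, so proprietary pathway databases and their p-values are
explicitly not reproduced.

circRNA differential expression uses a two-sided, equal-variance Student's
t-test on per-sample junction counts (Welch behind `equal_var=False`),
restricted to candidates detected in at least 2 samples per group;
undetected cohort samples count as 0 reads. Counts are used raw — the
intended input is depth-matched libraries — with an optional median
library-size normalization for unmatched data. log2 fold changes use a
pseudo-count of 1 on group means. Degenerate inputs: identical constant
groups are reported as t = 0, p = 1; zero within-group variance with
different means diverges (p → 0), which is the correct limit of the
statistic.

## Synthetic cohort generator

The generator emulates the *statistical shape* of a two-group (10 + 10)
cohort study: per-tool sensitivity/false-positive profiles with the usual
size ordering (KNIFE > find_circ > CIRI > CIRCexplorer), negative-binomial
junction reads (`var = mean + mean²/size`, default mean 8, size 2, so the
≥ 2-read filter is exercised nontrivially), 70% exonic / 15% intronic /
15% intergenic true circles, ratio classes in roughly the proportions seen
in brain cohorts (≈45% of circles with no linear signal, ≈10% forced
circle-dominant), CIRI's 1-based starts, and partially overlapping target
databases (40% common core). False-positive calls are placed in intergenic
space so truth-aware tests can separate them; real false positives are not
so obliging, which is a deliberate trade of realism for testability.

Sponge circRNAs (default 6, hosted by plus-strand genes with enlarged
exons) carry exact reverse complements of their assigned miRNAs written
into the genome through the spliced-coordinate map — 12 sites per
interaction by default, each inside a single exon. Planted sites are
perfect 23-nt complements and hence score exactly 150; at the default
thresholds they are recoverable, and an exhaustive motif search on the
extracted circRNA sequence finds exactly the planted count. Sponge hosts
use a higher read depth (mean 40), reflecting the empirical pattern that
the circRNAs recurrent enough to enter network construction are the
strongly supported ones.

What the generator does **not** emulate: read-level errors and alignment
artifacts, correlated tool errors (each tool thins the truth
independently), isoform structure within a circle, expression correlation
between a circle and its host gene, miRNA families with shared seeds, and
realistic false-positive placement. Green tests therefore demonstrate
correctness of the computations and filters under known truth — not
detection performance on real libraries.

## Determinism and numerics

All randomness flows from a single integer seed through
`numpy.random.default_rng([seed, stage_offset])`; per-stage offsets keep
emission order-independent. Reruns with the same config are byte-identical
(SHA-256 manifest). Ties in site selection break leftmost; candidate
tables sort by coordinate; float formatting in output files is fixed.
Problem sizes were chosen so a full default run (simulation through
enrichment) completes in well under a minute on one CPU: 80 true circles
over 0.9 Mb of genome, 40 miRNAs, 20 samples, ~3200 scanned
circRNA–miRNA pairs.

## Known limitations

* Exact-coordinate merging understates cross-tool consensus when tools
  disagree by a base.
* The duplex-energy model is a ranking device, not a thermodynamic
  predictor; its −20 kcal/mol cutoff is a package default, not a
  literature value.
* The 180-score tier cannot be met by natural-length miRNAs under the
  default scoring table (see above); it is retained as a configurable
  filter for compatibility with score scales that do reach it.
* Multi-gene read-through circles and circles spanning > 100 exons receive
  no special handling; classification simply picks the transcript
  maximizing the exon span.
* The t-test stage assumes depth-matched libraries by default.
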