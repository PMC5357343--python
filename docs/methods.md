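# Methods

## Duplicate model

A sequencing library is modelled as a set of cDNA molecules, each defined by
its fragment interval on the genome and its ligated index pair. Observed
reads arise from molecules by amplification: every molecule is read once,
plus G extra PCR copies with G ~ Geometric(p) on {0, 1, ...}
(mean (1-p)/p), plus optional optical copies (an exact copy of an emitted
read with fixed probability). A *true duplicate* is any read beyond the
first observation of its molecule. A *false duplicate* is a pair of reads
from different molecules whose duplicate key happens to collide.

Deduplication groups primary alignments by a key and keeps one
representative per group:

* `SAM` — (reference, leftmost position), both mates for paired ends,
  orientation ignored, mate coordinates order-normalised so FR/RF pairs at
  the same coordinates collide. Position is taken as reported by the
  aligner, with no soft-clip correction.
* `1MI` — the `SAM` key plus the forward read's 8-mer index.
* `2MI` — additionally the reverse index; on single-end data the
  concatenated 16-mer (the two 8-mers behave as one longer index).
* `ND` — the identity regime.

Because each key refines the previous one, the retained-count ordering
`ND >= 2MI >= 1MI >= SAM` is a theorem, and the test suite checks it as an
invariant alongside exact agreement with a brute-force all-pairs grouping
oracle.

The representative is the member with maximal summed base quality, ties
broken by lexicographically smallest read name. The rule is arbitrary but
deterministic and quality-preserving; with equal qualities it favours the
earliest-named read, which in simulations is the molecule's original
observation. Secondary, supplementary and unmapped alignments are excluded
from grouping and dropped from output (with counts); strand can be added to
the key with `use_strand=True` for users who want the stranded variant.

## Index extraction and statistics

Reads carry an 8-nt index, one adenylation spacer base ('A'), then the
insert; extraction slices at fixed offsets and flags spacer mismatches.
Reads failing the spacer check are excluded by default (`--keep-bad-spacer`
retains them) — index filtering is meant to be strict, and a wrong spacer
base indicates a mis-synthesised or mis-called prefix. Whitelist matching
defaults to exact membership (`max_mismatch=0`); with a mismatch budget, a
hit must be unique at the minimal distance or it is rejected as ambiguous.
The perfect-index rate is reported both per read and per pair, since the two
conventions differ and published figures rarely say which is meant.

Index-usage uniformity and between-sample homogeneity use Pearson
chi-squared tests (`scipy.stats`). Expected counts below 5 set a warning
flag rather than aborting. Note that *read-level* index counts are
overdispersed whenever PCR duplication is present (copies of a molecule
share its index); the uniformity question about the adapter mix is properly
asked of per-molecule (deduplicated) counts, as `examples/01` demonstrates.

## Counting and retention

Gene counting is union-mode on each gene's exon union: a read (fragment for
paired ends, counted once) overlapping exactly one gene counts for it;
overlapping two or more genes is ambiguous and discarded; overlap uses an
interval tree per reference. Strandedness defaults to `reverse`
(dUTP/fr-firststrand: the forward read is antisense to the transcript).

RPKM = count x 10^9 / (gene length x total mapped), with the dataset's own
mapped total as denominator by default (callers may fix the ND total
instead; the choice is exposed because either convention is defensible).

The retention profile is the per-gene ratio of deduplicated to ND counts
from the same sample, with expression measured as ND RPKM; genes with zero
ND count are excluded. Binned curves use deciles of log10(RPKM + 0.01).
`min_count` optionally drops genes below an ND-count floor before binning:
a fraction estimated from a handful of reads is quantized, and because the
observed ND count is the fraction's own denominator, selecting on a low
count biases the fraction upward. At the shallow depths of desk-scale
simulation this floor (10 reads in the shipped analyses) keeps per-bin
means interpretable; at production depth it is a no-op.

## Normalization and concordance

Size factors are median-of-ratios: s_j = median over genes of
k_ij / (prod_v k_vj)^(1/m), computed over genes nonzero in every sample.
DE thresholding follows FDR < 0.05 and fold change >= 2 (or <= 1/2);
adjusted p-values are consumed, not produced — the negative-binomial DE
test itself is deliberately out of scope, and DE lists arrive either from
external tools or from simulator truth. FN% is the fraction of the
standard's DE genes missing from the test list; FP% the fraction of the
test list absent from the standard. A gene called in both lists with
opposite directions counts toward both. Empty denominators yield
"undefined", never zero.

The grid's built-in caller (size factors, Welch t-test on log2 normalized
counts, Benjamini–Hochberg, then the thresholds) exists so that every cell
is compared under one fixed, simple caller; it is plumbing for
regime-to-regime comparison, not a DE method, and it needs >= 3 replicates
per condition to have any power (the shipped experiment default).

## Simulator design and defaults

The generator emulates an indexed bulk RNA-seq library at desk scale.
Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| genes | 2,000 non-overlapping, single-exon | enough for decile analyses; spliced alignment is out of scope |
| gene length | log-normal, median 1,500 nt, sd 0.4 (clip 300–20,000) | typical mRNA scale |
| expression | log-normal molecule counts, median 30, sd 1.5 | multi-decade dynamic range so top-decile genes approach position saturation |
| fragment length | Normal(250, 30), min 120 | standard library insert sizes |
| read length | 100 nt raw (8 + 1 + 91 cDNA) | the reference layout; 50-nt and SE layouts are derived |
| whitelist | 96 x 96 random distinct 8-mers | the adapter-set geometry |
| PCR copies | extra copies ~ Geometric(p = 0.5), mean 1 | gives ~0.5 overall retention, a realistic duplication load |
| optical duplicates | probability 0 | off unless studied explicitly |

Fragments longer than their gene are redrawn (5 rounds) then skipped.
Fragment positions are uniform within the gene; two molecules at the same
position with the same index pair are an intended, measurable collision in
whitelist-random mode, while `collision-free` mode assigns every molecule a
unique pair so two-index deduplication is provably exact (the truth-recovery
tests assert sensitivity 1.0 and false removal 0.0 there).

PCR copies are exact sequence copies: position+index keys are blind to
sequence errors, so polymerase error modelling would not change any
grouping decision (an extension point, not an omission that affects
results). Alignments are emitted directly at true coordinates instead of
running an aligner; this removes mapping from the test loop while
exercising identical downstream contracts (SAM in/out via pysam, indices in
read names and `RX` tags). Layout derivation follows how real datasets are
made from one paired-end run: single-end keeps the forward mate (both
indices remain attached); 50-nt derivation truncates the cDNA to its first
50 bases, qualities alongside.

What the simulator does *not* model: sequencing errors and quality-score
structure, intron-spanning reads, rRNA contamination, GC/length
amplification bias (the duplication distribution is homogeneous across
fragments), and mapping ambiguity. Passing tests therefore demonstrate the
correctness and the expression-dependence of the *deduplication logic*, not
robustness to alignment or base-calling artifacts in real libraries.

## Problem sizes in the shipped analyses

The acceptance script and end-to-end tests use: a 2,000-gene library
(~180k molecules, ~370k fragments) for the retention-vs-expression curves;
a 500-gene collision-free library (>= 10^4 molecules) for exact truth
recovery; 1,000 multinomial replicates (96 categories, 10,000 draws each)
for chi-squared calibration; and a 400-gene, 3+3-replicate experiment for
the grid/concordance demonstration. These sizes make every quantity
recomputable in about two minutes on one CPU while keeping each phenomenon
well inside statistical resolution.

## Known limitations

* Index error correction (directional networks) is out of scope; a one-base
  index error creates a spurious molecule under the MI regimes.
* The position key uses the aligner-reported leftmost coordinate; soft-clip
  5' adjustment (as Picard does) is not applied.
* Whether mate positions should collide as an ordered or unordered pair is
  ambiguous in rmdup-style tools; this implementation normalises order, so
  FR and RF pairs at identical coordinates merge.
* Coordinate-streaming over chromosomes larger than memory is not
  implemented; inputs are desk-scale.
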