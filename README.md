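# midedup

Molecular-index aware deduplication for RNA-seq, with the evaluation
machinery to show what each deduplication choice does to expression
estimates: retention-vs-expression profiling, index-distribution tests,
DE-gene-list concordance, and a lineage-tracked read simulator so every
claim about true vs false duplicates is testable without external data.

## The problem

RNA-seq read counts are taken as proxies for transcript abundance, but PCR
amplification and optical artifacts duplicate some fragments more than
others. Removing duplicates by mapping position alone (the `samtools rmdup`
approach) cannot distinguish a *true duplicate* (a re-sequenced copy of one
cDNA molecule) from a *false duplicate* (two independent molecules that
happen to map to the same coordinates). False duplicates concentrate in
highly expressed genes — the number of distinct start positions inside a
gene is finite — so position-only deduplication selectively deflates exactly
the genes a differential-expression analysis cares most about, producing
false negatives; skipping deduplication keeps PCR noise and leans toward
false positives.

Molecular indices (MI/UMI) resolve this: an 8-nt quasi-random index on each
adapter (96 forward x 96 reverse combinations, plus one adenylation spacer
base, so the insert starts at base 10) tags each molecule before
amplification. Duplicates are then reads with the same mapping position
**and** the same index.

The package is for bioinformaticians building or evaluating UMI-aware
RNA-seq pipelines, and for anyone who wants to quantify what position-only
deduplication would cost on their library design (single- vs paired-end,
read length, index count).

## Method

For a primary alignment (or mate pair) the duplicate key under each regime
is:

| regime | key |
|---|---|
| `ND`  | — (no deduplication; every read kept) |
| `SAM` | (reference, position) — both mates for PE, orientation-blind, mate order normalised |
| `1MI` | `SAM` key + forward-read index |
| `2MI` | `1MI` key + reverse index (SE: the two 8-mers act as one 16-nt index) |

Keys refine each other, so retained counts always satisfy
`ND >= 2MI >= 1MI >= SAM`. One representative is kept per group: highest
summed base quality, ties broken by read name, making output a deterministic
function of the input set.

Downstream, the package provides union-mode gene counting (a read/fragment
overlapping exactly one gene's exon union counts; default reverse-stranded),
RPKM = count x 10^9 / (length x total), per-gene retention fractions
(count after dedup / ND count) binned over expression deciles, Pearson
chi-squared tests of index uniformity and between-sample homogeneity,
median-of-ratios size factors, and FN/FP percentages between DE gene lists
(`FN% = 100 |standard \ test| / |standard|`, `FP% = 100 |test \ standard| / |test|`).

The simulator generates a synthetic genome with non-overlapping genes,
log-normal expression, uniform fragment positions, per-molecule index pairs,
geometric PCR copy numbers and optional optical copies — emitting FASTQ with
the 9-nt prefix, perfect SAM alignments, and a truth table linking every
read to its molecule, so duplicate-removal sensitivity and false-removal
rates are measured exactly, not estimated.

## Worked example

`python examples/04_truth_recovery.py` simulates a 400-gene collision-free
library (every molecule gets a unique index pair) and scores each regime
against the known lineage:

```
library: 39510 molecules, 78745 fragments (39235 true PCR duplicates)
   2MI: sensitivity 1.0000, false removal 0.0000
   SAM: sensitivity 1.0000, false removal 0.0023
```

Sensitivity is the fraction of true duplicates removed; false removal is the
fraction of independent reads wrongly discarded. Two-index deduplication is
exact by construction here; the position-only regime already discards 0.2%
of independent paired-end fragments, and the damage grows on single-end
data. `python examples/03_retention_vs_expression.py` shows where it goes:

```
  decile      SAM      2MI
       1    0.545    0.546
     ...
       9    0.467    0.503
      10    0.394    0.498

SAM retention vs expression: Spearman rho = -0.447 (p = 4.38e-74)
```

Per-gene retained fraction is flat across expression deciles for 2MI
(~0.50, the inverse of the mean amplification factor) but sinks to 0.39 in
the top decile for position-only deduplication — those missing reads are
false duplicates, and they are why single-end position-only pipelines miss
differential calls on highly expressed genes
(`examples/05_grid_concordance.py` runs the full 4-layout x 4-regime grid
with DE concordance against the PE100_2MI standard).

A thin CLI mirrors the library: `midedup extract | dedup | count |
retention | concordance | simulate | grid` (see `midedup --help`).

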