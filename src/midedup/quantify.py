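"""Gene-level read counting, RPKM and duplicate-retention diagnostics.

Counting follows union semantics on the exon union of each gene: a read
(paired-end: a fragment, counted once) that overlaps exactly one gene's exons
increments that gene, a read overlapping two or more genes is ambiguous and
dropped, a read overlapping none is dropped.  Strandedness defaults to
``reverse`` (a dUTP / fr-firststrand library: the forward read is antisense
to the transcript).

Retention diagnostics compare a deduplicated count column against the
no-deduplication (ND) column from the same sample: per-gene retained
fraction, its distribution across deduplication regimes, and its dependence
on expression (deciles of log-scaled RPKM) — the signature that separates
true-duplicate removal (flat in expression) from coincidental-position
removal (dropping sharply for highly expressed genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .dedup import AlignmentRecord, Layout, Record


@dataclass(frozen=True)
class GeneModel:
    """A gene as the union of its exon intervals (half-open, 0-based)."""

    gene_id: str
    reference_name: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        merged = merge_intervals(self.exons)
        if merged != tuple(self.exons):
            object.__setattr__(self, "exons", merged)
        if self.length <= 0:
            raise ValueError(f"gene {self.gene_id!r} has zero-length exon union")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Sort and union-merge half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return tuple((s, e) for s, e in out)


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Load gene models from a GTF, grouping exon features by ``gene_id``."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        gid = feat.attributes["gene_id"][0]
        info = by_gene.setdefault(
            gid, {"ref": feat.seqid, "strand": feat.strand, "exons": []}
        )
        info["exons"].append((feat.start - 1, feat.end))  # GTF is 1-based closed
    return [
        GeneModel(gid, info["ref"], tuple(info["exons"]), strand=info["strand"])
        for gid, info in by_gene.items()
    ]


_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
]


def read_bed12(path: str | Path) -> list[GeneModel]:
    """Load gene models from BED12 (blocks are exons, one line per gene)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=_BED12_COLS)
    genes = []
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        exons = tuple(
            (row.start + off, row.start + off + size) for off, size in zip(starts, sizes)
        )
        genes.append(GeneModel(str(row.name), str(row.chrom), exons, strand=str(row.strand)))
    return genes


def write_gtf(genes: Sequence[GeneModel], path: str | Path, source: str = "midedup") -> None:
    with open(path, "w") as fh:
        for g in genes:
            for s, e in g.exons:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
                fh.write(
                    f"{g.reference_name}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


class GeneIndex:
    """Interval index over exon unions, one tree per reference sequence."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = {g.gene_id: g for g in genes}
        if len(self.genes) != len(genes):
            raise ValueError("duplicate gene_id in annotation")
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault(g.reference_name, IntervalTree())
            for s, e in g.exons:
                tree[s:e] = g.gene_id

    def overlapping(self, reference: str, start: int, end: int) -> set[str]:
        tree = self._trees.get(reference)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    @property
    def references(self) -> set[str]:
        return set(self._trees)

    def lengths(self) -> pd.Series:
        return pd.Series(
            {gid: g.length for gid, g in self.genes.items()}, name="length"
        ).sort_index()


@dataclass
class CountingStats:
    counted: int = 0
    ambiguous: int = 0
    no_feature: int = 0
    wrong_strand: int = 0
    unknown_reference: int = 0

    @property
    def total(self) -> int:
        return (
            self.counted + self.ambiguous + self.no_feature
            + self.wrong_strand + self.unknown_reference
        )


def _fragment_sense(item: Record) -> tuple[str, int, int, str]:
    """(reference, span start, span end, fragment sense strand) of a record.

    The forward read of a dUTP library is antisense to the transcript, so the
    fragment's sense strand is the opposite of the forward read's strand.
    """
    if isinstance(item, tuple):
        fwd, rev = item
        start = min(fwd.pos, rev.pos)
        end = max(fwd.end or fwd.pos + 1, rev.end or rev.pos + 1)
        return fwd.reference_name, start, end, ("-" if fwd.strand == "+" else "+")
    end = item.end if item.end is not None else item.pos + 1
    return item.reference_name, item.pos, end, ("-" if item.strand == "+" else "+")


def count_per_gene(
    records: Sequence[Record],
    index: GeneIndex,
    stranded: str = "reverse",
) -> tuple[pd.Series, CountingStats]:
    """Union-mode gene counts for one sample.

    ``stranded`` is ``"reverse"`` (fr-firststrand, the default), ``"forward"``
    or ``"none"``.  Returns a count column over all annotated genes (zeros
    included) plus counting statistics; the stats' total is the number of
    input records, which callers use as the per-sample total mapped count.
    """
    if stranded not in ("reverse", "forward", "none"):
        raise ValueError(f"unknown strandedness {stranded!r}")
    counts = {gid: 0 for gid in index.genes}
    st = CountingStats()
    missing_refs: set[str] = set()
    for item in records:
        ref, start, end, sense = _fragment_sense(item)
        if ref not in index.references:
            if ref not in missing_refs:
                missing_refs.add(ref)
                warnings.warn(f"reference {ref!r} absent from annotation; skipping its reads")
            st.unknown_reference += 1
            continue
        hits = index.overlapping(ref, start, end)
        if stranded != "none" and hits:
            # "reverse" libraries: the *fragment sense* computed above already
            # flips the forward read, so the gene strand must equal the sense.
            want = sense if stranded == "reverse" else ("-" if sense == "+" else "+")
            strand_hits = {g for g in hits if index.genes[g].strand == want}
            if hits and not strand_hits:
                st.wrong_strand += 1
                continue
            hits = strand_hits
        if not hits:
            st.no_feature += 1
        elif len(hits) > 1:
            st.ambiguous += 1
        else:
            counts[hits.pop()] += 1
            st.counted += 1
    col = pd.Series(counts, name="count").sort_index()
    return col, st


@dataclass
class CountTable:
    """Genes x samples integer counts with gene lengths and mapped totals."""

    counts: pd.DataFrame
    gene_lengths: pd.Series
    totals: pd.Series  # per-sample total mapped reads/fragments

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = self.gene_lengths[self.gene_lengths.isna()].index[:5].tolist()
            raise ValueError(f"genes without length: {missing}")
        short = self.counts.sum(axis=0) > self.totals.reindex(self.counts.columns)
        if short.any():
            raise ValueError("per-sample totals smaller than counted reads")

    def rpkm(self) -> pd.DataFrame:
        return self.counts.apply(
            lambda col: rpkm_column(col, self.gene_lengths, int(self.totals[col.name]))
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.gene_lengths)
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path, totals: Mapping[str, int] | None = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        lengths = df.pop("length")
        if totals is None:
            totals = df.sum(axis=0)
        return cls(df, lengths, pd.Series(totals))


def rpkm(count: int, gene_length_nt: int, total_mapped: int) -> float:
    """Reads (fragments) per kilobase of transcript per million mapped reads.

    RPKM = count * 1e9 / (gene_length_nt * total_mapped).
    """
    if gene_length_nt <= 0:
        raise ValueError("gene length must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped count must be positive")
    return count * 1e9 / (gene_length_nt * total_mapped)


def rpkm_column(counts: pd.Series, lengths: pd.Series, total_mapped: int) -> pd.Series:
    if total_mapped <= 0:
        raise ValueError("total mapped count must be positive")
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all gene lengths must be positive")
    return counts * 1e9 / (lengths * total_mapped)


# ---------------------------------------------------------------------------
# retention diagnostics
# ---------------------------------------------------------------------------

@dataclass
class RetentionProfile:
    """Per-gene retained fraction after deduplication, with ND expression.

    ``data`` has columns ``fraction`` (dedup count / ND count) and
    ``expression`` (RPKM computed from the ND column); genes with zero ND
    count are excluded.
    """

    data: pd.DataFrame
    regime: str

    @property
    def fractions(self) -> pd.Series:
        return self.data["fraction"]

    @property
    def mean_fraction(self) -> float:
        return float(self.data["fraction"].mean())


def retention_profile(
    counts_nd: pd.Series,
    counts_dedup: pd.Series,
    rpkm_nd: pd.Series,
    regime: str = "",
) -> RetentionProfile:
    """Per-gene fraction of reads remaining after deduplication.

    The denominator is the ND count of the same sample and pipeline stage;
    a deduplicated count exceeding its ND count violates the subset property
    and is an error.
    """
    idx = counts_nd.index
    if not idx.equals(counts_dedup.index) or not idx.equals(rpkm_nd.index):
        counts_dedup = counts_dedup.reindex(idx)
        rpkm_nd = rpkm_nd.reindex(idx)
        if counts_dedup.isna().any() or rpkm_nd.isna().any():
            raise ValueError("count columns cover different gene universes")
    over = counts_dedup > counts_nd
    if over.any():
        bad = counts_nd.index[over][:5].tolist()
        raise ValueError(f"deduplicated count exceeds ND count for genes {bad}")
    keep = counts_nd > 0
    df = pd.DataFrame(
        {
            "fraction": counts_dedup[keep] / counts_nd[keep],
            "expression": rpkm_nd[keep],
            "count_nd": counts_nd[keep],
            "count_dedup": counts_dedup[keep],
        }
    )
    return RetentionProfile(data=df, regime=regime)


def bin_retention_by_expression(
    profile: RetentionProfile,
    n_bins: int = 10,
    edges: Sequence[float] | None = None,
    epsilon: float = 0.01,
    min_count: int = 0,
) -> pd.DataFrame:
    """Mean retained fraction per expression bin.

    Default bins are ``n_bins`` quantiles (deciles) of log10(RPKM + epsilon);
    explicit ``edges`` on the same log scale override.  Bins that end up empty
    are reported with NaN mean, never a fabricated zero.

    ``min_count`` drops genes whose ND count is below the floor before
    binning.  A fraction estimated from a handful of reads is quantized and,
    because the ND count sits in its own denominator, selecting on a low
    observed count biases the fraction upward; at shallow depth this floor
    keeps the per-bin means interpretable.
    """
    data = profile.data
    if min_count > 0:
        data = data[data["count_nd"] >= min_count]
        profile = RetentionProfile(data=data, regime=profile.regime)
    log_expr = np.log10(profile.data["expression"] + epsilon)
    if edges is not None:
        labels = pd.cut(log_expr, bins=list(edges))
    else:
        labels = pd.qcut(log_expr, q=n_bins, duplicates="drop")
    grouped = profile.data.groupby(labels, observed=False)
    out = grouped["fraction"].agg(mean="mean", sd="std", n="count")
    # pooled binomial standard error of the bin's retained fraction
    reads = grouped["count_nd"].sum()
    pooled = grouped["count_dedup"].sum() / reads.where(reads > 0)
    out["pooled_fraction"] = pooled
    out["binomial_se"] = np.sqrt(pooled * (1 - pooled) / reads.where(reads > 0))
    out.index.name = "expression_bin"
    return out


@dataclass
class RetentionComparison:
    summaries: pd.DataFrame            # per-regime mean/quantiles
    t_tests: pd.DataFrame              # pairwise Welch t-tests on fractions


def retention_distribution_summary(
    profiles: Mapping[str, RetentionProfile],
    quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> RetentionComparison:
    """Distribution summaries per regime plus pairwise Welch t-tests."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 regimes to compare")
    rows = {}
    for label, prof in profiles.items():
        if len(prof.data) < 2:
            raise ValueError(f"regime {label!r} has fewer than 2 genes")
        frac = prof.fractions
        rows[label] = {
            "mean": frac.mean(),
            "sd": frac.std(),
            "n": len(frac),
            **{f"q{int(q * 100):02d}": frac.quantile(q) for q in quantiles},
        }
    labels = list(profiles)
    tests = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            t, p = stats.ttest_ind(
                profiles[a].fractions, profiles[b].fractions, equal_var=False
            )
            tests.append({"regime_a": a, "regime_b": b, "t": float(t), "p_value": float(p)})
    return RetentionComparison(
        summaries=pd.DataFrame(rows).T, t_tests=pd.DataFrame(tests)
    )
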