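"""Size-factor normalization and DE-gene-list concordance.

Count columns from different samples are made comparable with median-of-ratios
size factors: for sample j, s_j is the median over genes of k_ij divided by the
gene's geometric mean across samples, computed over genes observed in every
sample.  DE gene lists produced under different deduplication regimes are then
compared against a designated standard (conventionally the paired-end,
two-index cell): genes called only in the standard are false negatives of the
test set, genes called only in the test set are false positives, each
expressed as a percentage of the respective list size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DEGeneSet:
    """Up- and down-regulated gene ids called differentially expressed."""

    label: str
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        both = self.up & self.down
        if both:
            raise ValueError(f"{self.label}: genes in both directions: {sorted(both)[:5]}")

    @property
    def all(self) -> frozenset[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one positive factor per sample (column).

    Genes with a zero count in any sample are excluded from the reference,
    since their geometric mean across samples is degenerate.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has a nonzero count in every sample")
    log_counts = np.log(counts.loc[positive].astype(float))
    log_geomean = log_counts.mean(axis=1)
    factors = np.exp((log_counts.sub(log_geomean, axis=0)).median(axis=0))
    factors.name = "size_factor"
    return factors


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    if factors is None:
        factors = size_factors(counts)
    return counts.div(factors, axis=1)


def apply_de_thresholds(
    stats: pd.DataFrame,
    fdr: float = 0.05,
    fc: float = 2.0,
    label: str = "",
) -> DEGeneSet:
    """Call DE genes from per-gene (fold_change, padj) statistics.

    A gene is differentially expressed iff its adjusted p-value is below
    ``fdr`` and its fold change is at least ``fc`` in either direction
    (fc >= 2 or fc <= 1/2 at the default); direction follows the fold change
    relative to 1.  Rows with missing values are excluded.  ``stats`` must be
    indexed by gene id with columns ``fold_change`` and ``padj`` (a ``log2fc``
    column is accepted in place of ``fold_change``).
    """
    df = stats.copy()
    if "fold_change" not in df.columns:
        if "log2fc" not in df.columns:
            raise ValueError("need a fold_change or log2fc column")
        df["fold_change"] = 2.0 ** df["log2fc"]
    df = df[["fold_change", "padj"]].dropna()
    if (df["fold_change"] <= 0).any():
        raise ValueError("fold changes must be positive")
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise ValueError("adjusted p-values must lie in [0, 1]")
    sig = df["padj"] < fdr
    up = df.index[sig & (df["fold_change"] >= fc)]
    down = df.index[sig & (df["fold_change"] <= 1.0 / fc)]
    return DEGeneSet(label=label, up=frozenset(up), down=frozenset(down))


@dataclass
class ConcordanceResult:
    """Agreement between a test DE list and the standard DE list.

    ``fn_percent`` = 100 * |standard \\ test| / |standard| (genes the test set
    misses), ``fp_percent`` = 100 * |test \\ standard| / |test| (genes only the
    test set calls).  A gene DE in both lists but with opposite direction is
    discordant and counts toward both.  Percentages are ``None`` when their
    denominator list is empty (undefined, not zero).
    """

    standard_label: str
    test_label: str
    shared: int
    standard_only: int
    test_only: int
    fn_percent: float | None
    fp_percent: float | None
    per_direction: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "standard": self.standard_label,
            "test": self.test_label,
            "shared": self.shared,
            "standard_only": self.standard_only,
            "test_only": self.test_only,
            "fn_percent": self.fn_percent,
            "fp_percent": self.fp_percent,
            "per_direction": self.per_direction,
        }


def _direction_counts(std: frozenset[str], test: frozenset[str]) -> dict:
    shared = len(std & test)
    return {
        "shared": shared,
        "standard_only": len(std) - shared,
        "test_only": len(test) - shared,
        "fn_percent": 100.0 * (len(std) - shared) / len(std) if std else None,
        "fp_percent": 100.0 * (len(test) - shared) / len(test) if test else None,
    }


def fn_fp(standard: DEGeneSet, test: DEGeneSet) -> ConcordanceResult:
    """False-negative / false-positive percentages of ``test`` vs ``standard``.

    Direction-aware: a gene counts as shared only when both lists call it in
    the same direction, so an opposite-direction call appears in both the
    standard-only (FN) and test-only (FP) tallies.
    """
    shared = len(standard.up & test.up) + len(standard.down & test.down)
    n_std, n_test = len(standard), len(test)
    standard_only = n_std - shared
    test_only = n_test - shared
    return ConcordanceResult(
        standard_label=standard.label,
        test_label=test.label,
        shared=shared,
        standard_only=standard_only,
        test_only=test_only,
        fn_percent=100.0 * standard_only / n_std if n_std else None,
        fp_percent=100.0 * test_only / n_test if n_test else None,
        per_direction={
            "up": _direction_counts(standard.up, test.up),
            "down": _direction_counts(standard.down, test.down),
        },
    )


# ---------------------------------------------------------------------------
# plain-file interfaces
# ---------------------------------------------------------------------------

def read_de_table(path: str | Path, label: str | None = None, fdr: float = 0.05, fc: float = 2.0) -> DEGeneSet:
    """Load a DE list from TSV.

    Two layouts are accepted: ``gene_id`` + ``direction`` (up/down) for
    pre-thresholded lists, or ``gene_id`` + ``fold_change``/``log2fc`` +
    ``padj`` for per-gene statistics (thresholds applied here).
    """
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError("DE table needs a gene_id column")
    label = label if label is not None else Path(path).stem
    if "direction" in df.columns:
        up = frozenset(df.loc[df["direction"].str.lower() == "up", "gene_id"])
        down = frozenset(df.loc[df["direction"].str.lower() == "down", "gene_id"])
        return DEGeneSet(label=label, up=up, down=down)
    return apply_de_thresholds(df.set_index("gene_id"), fdr=fdr, fc=fc, label=label)


def write_concordance(result: ConcordanceResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")
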