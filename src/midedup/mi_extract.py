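"""Molecular-index extraction, whitelist filtering and index statistics.

Libraries built with molecular-index (MI) adapters carry an 8-nt quasi-random
index at the 5' end of every read, followed by a single adenine left over from
cDNA-fragment adenylation, so the insert itself starts at base 10.  This module
strips that 9-nt prefix, validates the index against the adapter whitelist
(96 forward x 96 reverse combinations by default), re-emits reads with the
index encoded in the read name, and provides the Pearson chi-squared checks
used to verify that index usage is uniform within a sample and homogeneous
between samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from scipy import stats


class Mate(str, Enum):
    SINGLE = "single"
    FORWARD = "forward"
    REVERSE = "reverse"


class MIExtractionError(ValueError):
    """Raised when a read is too short to carry index + spacer + insert."""


class DelimiterCollisionError(ValueError):
    """Raised when the tag delimiter already occurs in a read name."""


@dataclass(frozen=True)
class RawRead:
    """A FASTQ read before index stripping."""

    read_id: str
    sequence: str
    qualities: str
    mate: Mate = Mate.SINGLE

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )


@dataclass(frozen=True)
class TaggedRead:
    """A read after index stripping.

    ``whitelist_ok`` is ``None`` until the read has been checked against a
    whitelist (see :func:`filter_whitelist`).
    """

    read_id: str
    cdna_sequence: str
    cdna_qualities: str
    mi: str
    spacer_ok: bool
    whitelist_ok: bool | None = None
    mate: Mate = Mate.SINGLE


@dataclass(frozen=True)
class MIWhitelist:
    """The per-side sets of admissible index sequences."""

    forward_set: frozenset[str]
    reverse_set: frozenset[str]

    def __post_init__(self) -> None:
        if not self.forward_set or not self.reverse_set:
            raise ValueError("whitelist sides must be non-empty")
        lengths = {len(m) for m in self.forward_set} | {len(m) for m in self.reverse_set}
        if len(lengths) != 1:
            raise ValueError(f"whitelist entries have mixed lengths: {sorted(lengths)}")

    @property
    def mi_length(self) -> int:
        return len(next(iter(self.forward_set)))

    def side(self, mate: Mate) -> frozenset[str]:
        return self.reverse_set if mate is Mate.REVERSE else self.forward_set

    @classmethod
    def from_files(cls, forward_path: str | Path, reverse_path: str | Path) -> "MIWhitelist":
        """Load the two plain-text whitelists (one 8-mer per line)."""
        read = lambda p: frozenset(
            line.strip().upper() for line in Path(p).read_text().splitlines() if line.strip()
        )
        return cls(read(forward_path), read(reverse_path))

    def to_files(self, forward_path: str | Path, reverse_path: str | Path) -> None:
        Path(forward_path).write_text("\n".join(sorted(self.forward_set)) + "\n")
        Path(reverse_path).write_text("\n".join(sorted(self.reverse_set)) + "\n")


def extract_mi(read: RawRead, mi_length: int = 8, spacer: str = "A") -> TaggedRead:
    """Strip the index + spacer prefix from a raw read.

    The first ``mi_length`` bases are the molecular index, base ``mi_length+1``
    is the adenylation spacer (expected to equal ``spacer``), and the remainder
    is the cDNA insert.  Qualities are sliced identically.

    Raises
    ------
    MIExtractionError
        If the read is shorter than ``mi_length + 2`` (no insert left).
    """
    if len(read.sequence) < mi_length + 2:
        raise MIExtractionError(
            f"read {read.read_id!r} has length {len(read.sequence)}, "
            f"needs > {mi_length + 1} to carry index, spacer and insert"
        )
    mi = read.sequence[:mi_length]
    spacer_base = read.sequence[mi_length]
    return TaggedRead(
        read_id=read.read_id,
        cdna_sequence=read.sequence[mi_length + 1 :],
        cdna_qualities=read.qualities[mi_length + 1 :],
        mi=mi,
        spacer_ok=(spacer_base == spacer),
        mate=read.mate,
    )


def extract_stream(
    reads: Iterable[RawRead], mi_length: int = 8, spacer: str = "A"
) -> tuple[list[TaggedRead], list[dict]]:
    """Extract indices from a stream, collecting per-read error records.

    Too-short reads are rejected with an error record instead of aborting the
    whole stream.  Returns ``(tagged, errors)`` where each error is a dict with
    ``read_id`` and ``reason`` keys.
    """
    tagged: list[TaggedRead] = []
    errors: list[dict] = []
    for read in reads:
        try:
            tagged.append(extract_mi(read, mi_length=mi_length, spacer=spacer))
        except MIExtractionError as exc:
            errors.append({"read_id": read.read_id, "reason": str(exc)})
    return tagged, errors


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def match_whitelist(mi: str, entries: frozenset[str] | set[str], max_mismatch: int = 0) -> bool:
    """Whether ``mi`` matches some entry within ``max_mismatch`` Hamming distance.

    With ``max_mismatch == 0`` this is exact set membership.  With tolerance,
    a hit is accepted only when the best-matching entry is unique: an index
    equidistant from two entries at the minimal distance is ambiguous and
    rejected.
    """
    if max_mismatch == 0:
        return mi in entries
    if mi in entries:
        return True
    best = max_mismatch + 1
    best_count = 0
    for entry in entries:
        d = _hamming(mi, entry)
        if d < best:
            best, best_count = d, 1
        elif d == best:
            best_count += 1
    return best <= max_mismatch and best_count == 1


def filter_whitelist(
    tagged: TaggedRead, wl: MIWhitelist, max_mismatch: int = 0
) -> TaggedRead:
    """Check a tagged read's index against the whitelist side for its mate.

    Returns a copy with ``whitelist_ok`` set; callers decide whether to drop
    rejected reads.
    """
    ok = match_whitelist(tagged.mi, wl.side(tagged.mate), max_mismatch=max_mismatch)
    return replace(tagged, whitelist_ok=ok)


def pair_passes(
    forward: TaggedRead, reverse: TaggedRead, wl: MIWhitelist, max_mismatch: int = 0
) -> bool:
    """A pair is accepted only if both mates' indices pass the whitelist."""
    return match_whitelist(forward.mi, wl.forward_set, max_mismatch) and match_whitelist(
        reverse.mi, wl.reverse_set, max_mismatch
    )


@dataclass
class PerfectIndexSummary:
    """Fraction of perfect (whitelisted, mismatch-free) indices.

    Reported per read and — for paired data — per pair (both mates perfect),
    since the two conventions differ and published figures rarely say which
    one they use.
    """

    n_reads: int
    n_perfect_reads: int
    n_pairs: int | None = None
    n_perfect_pairs: int | None = None

    @property
    def per_read_fraction(self) -> float:
        return self.n_perfect_reads / self.n_reads if self.n_reads else float("nan")

    @property
    def per_pair_fraction(self) -> float | None:
        if self.n_pairs is None:
            return None
        return self.n_perfect_pairs / self.n_pairs if self.n_pairs else float("nan")


def perfect_index_summary(
    forward_ok: Sequence[bool], reverse_ok: Sequence[bool] | None = None
) -> PerfectIndexSummary:
    """Summarise whitelist pass flags per read and (if paired) per pair."""
    fwd = np.asarray(forward_ok, dtype=bool)
    if reverse_ok is None:
        return PerfectIndexSummary(n_reads=fwd.size, n_perfect_reads=int(fwd.sum()))
    rev = np.asarray(reverse_ok, dtype=bool)
    if rev.size != fwd.size:
        raise ValueError("forward and reverse flag vectors differ in length")
    both = fwd & rev
    return PerfectIndexSummary(
        n_reads=2 * fwd.size,
        n_perfect_reads=int(fwd.sum()) + int(rev.sum()),
        n_pairs=fwd.size,
        n_perfect_pairs=int(both.sum()),
    )


# ---------------------------------------------------------------------------
# tagged FASTQ round trip
# ---------------------------------------------------------------------------

def tagged_name(
    read_id: str,
    mis: Sequence[str],
    delimiter: str = "_",
    on_collision: str = "error",
) -> str:
    """Encode indices into a read name: ``id<d>mi_fwd[<d>mi_rev]``.

    The name encoding is the canonical MI carrier because it survives any
    aligner.  If the delimiter already occurs in the read id the encoding
    would not round-trip; ``on_collision`` is either ``"error"`` (fail loudly)
    or ``"escape"`` (percent-encode the delimiter in the id).
    """
    if delimiter in read_id:
        if on_collision == "error":
            raise DelimiterCollisionError(
                f"delimiter {delimiter!r} occurs in read id {read_id!r}"
            )
        if on_collision == "escape":
            read_id = read_id.replace("%", "%25").replace(delimiter, "%5F")
        else:
            raise ValueError(f"unknown on_collision mode {on_collision!r}")
    return delimiter.join([read_id, *mis])


def parse_tagged_name(
    name: str, n_mis: int, delimiter: str = "_"
) -> tuple[str, tuple[str, ...]]:
    """Invert :func:`tagged_name`; returns ``(read_id, indices)``."""
    parts = name.rsplit(delimiter, n_mis)
    if len(parts) != n_mis + 1:
        raise ValueError(f"name {name!r} does not carry {n_mis} indices")
    read_id = parts[0].replace("%5F", delimiter).replace("%25", "%")
    return read_id, tuple(parts[1:])


def read_fastq(path: str | Path, mate: Mate = Mate.SINGLE) -> Iterator[RawRead]:
    """Stream a (plain-text, Phred+33) FASTQ file as :class:`RawRead`."""
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield RawRead(title.split()[0], seq, qual, mate=mate)


def write_tagged_fastq(
    path: str | Path,
    records: Iterable[tuple[str, str, str, Sequence[str]]],
    delimiter: str = "_",
    on_collision: str = "error",
) -> int:
    """Write ``(read_id, sequence, qualities, indices)`` records as FASTQ.

    Indices are appended to the read name (forward first).  Returns the number
    of records written.
    """
    n = 0
    with open(path, "w") as handle:
        for read_id, seq, qual, mis in records:
            name = tagged_name(read_id, mis, delimiter=delimiter, on_collision=on_collision)
            handle.write(f"@{name}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_tagged_fastq(
    path: str | Path, n_mis: int, delimiter: str = "_"
) -> Iterator[tuple[str, str, str, tuple[str, ...]]]:
    """Stream a tagged FASTQ back as ``(read_id, seq, qual, indices)``."""
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            read_id, mis = parse_tagged_name(title.split()[0], n_mis, delimiter=delimiter)
            yield read_id, seq, qual, mis


# ---------------------------------------------------------------------------
# index distribution statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    low_expected: bool = False  # some expected cell count < 5; test still valid asymptotically


def _as_count_array(counts: Mapping[str, int] | Sequence[int]) -> np.ndarray:
    if isinstance(counts, Mapping):
        arr = np.asarray([counts[k] for k in sorted(counts)], dtype=float)
    else:
        arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


def chi_square_uniform(counts: Mapping[str, int] | Sequence[int]) -> ChiSquareResult:
    """Pearson chi-squared test of a single index-count vector against uniform.

    With k categories and N total observations the expected count per category
    is N/k and the statistic has k-1 degrees of freedom.  Used to check that
    all adapter indices were ligated/amplified at equal rates.
    """
    arr = _as_count_array(counts)
    if arr.size < 2:
        raise ValueError("need at least 2 index categories")
    total = arr.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    expected = total / arr.size
    stat, p = stats.chisquare(arr)
    return ChiSquareResult(
        statistic=float(stat),
        df=arr.size - 1,
        p_value=float(p),
        low_expected=bool(expected < 5),
    )


def chi_square_homogeneity(
    counts_by_sample: Sequence[Mapping[str, int]]
) -> ChiSquareResult:
    """Pearson contingency test that index usage is homogeneous across samples.

    Rows are samples, columns are indices; df = (rows-1)(cols-1).  All samples
    must cover the same index categories.  Indices unobserved in every sample
    carry no information and are dropped before testing.
    """
    if len(counts_by_sample) < 2:
        raise ValueError("need at least 2 samples")
    keysets = [frozenset(c) for c in counts_by_sample]
    universe = keysets[0]
    for i, ks in enumerate(keysets[1:], start=1):
        if ks != universe:
            offending = sorted((ks ^ universe))
            raise ValueError(
                f"sample {i} covers different index categories; "
                f"mismatched indices: {offending[:10]}"
            )
    keys = sorted(universe)
    table = np.asarray([[s[k] for k in keys] for s in counts_by_sample], dtype=float)
    nonzero = table.sum(axis=0) > 0
    table = table[:, nonzero]
    if table.shape[1] < 2:
        raise ValueError("need at least 2 observed index categories")
    stat, p, df, expected = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        low_expected=bool((expected < 5).any()),
    )


def index_counts(mis: Iterable[str]) -> dict[str, int]:
    """Tally observed index usage (an IndexCountVector)."""
    out: dict[str, int] = {}
    for mi in mis:
        out[mi] = out.get(mi, 0) + 1
    return out
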