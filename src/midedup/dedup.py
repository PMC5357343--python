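"""Duplicate grouping of aligned reads under position and molecular-index keys.

Four regimes are supported, named after the key that defines a duplicate:

* ``ND``  — no deduplication; every read is retained.
* ``SAM`` — mapping position only, orientation-blind (the rmdup-style key:
  for paired-end data both mates' positions must match).
* ``1MI`` — position plus the forward read's molecular index.
* ``2MI`` — position plus both indices (for single-end data the two 8-mers
  act as one 16-nt index).

Keys refine each other (2MI ⊆ 1MI ⊆ SAM as equivalence relations), so
retained counts are always ordered ND ≥ 2MI ≥ 1MI ≥ SAM.  Within each group
one representative is retained: the member with the highest summed base
quality, ties broken by the lexicographically smallest read name, which makes
the output a deterministic function of the input set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

import pysam

from .mi_extract import TaggedRead, parse_tagged_name, tagged_name


class Regime(str, Enum):
    ND = "nd"
    SAM = "sam"
    MI1 = "1mi"
    MI2 = "2mi"


class Layout(str, Enum):
    SE = "se"
    PE = "pe"


@dataclass(frozen=True, slots=True)
class AlignmentRecord:
    """A primary alignment of one read, as relevant to duplicate keys.

    ``pos`` is the leftmost mapped reference coordinate, 0-based (SAM POS-1),
    taken as reported by the aligner with no soft-clip adjustment.  ``end`` is
    the exclusive end of the aligned span (used for gene-overlap counting, not
    for duplicate keys).
    """

    query_name: str
    reference_name: str
    pos: int
    strand: str = "+"
    end: int | None = None
    layout: Layout = Layout.SE
    mate_reference: str | None = None
    mate_pos: int | None = None
    mi_forward: str | None = None
    mi_reverse: str | None = None
    quality_sum: int = 0
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position for {self.query_name!r}")
        if self.quality_sum < 0:
            raise ValueError(f"negative quality sum for {self.query_name!r}")


ReadPair = tuple[AlignmentRecord, AlignmentRecord]
Record = Union[AlignmentRecord, ReadPair]


@dataclass(frozen=True)
class DuplicateGroup:
    key: tuple
    members: tuple[Record, ...]
    representative: Record


class MissingIndexError(ValueError):
    pass


def _mis(item: Record) -> tuple[str | None, str | None]:
    rec = item[0] if isinstance(item, tuple) else item
    return rec.mi_forward, rec.mi_reverse


def _require_mi(value: str | None, item: Record, which: str) -> str:
    if value is None:
        name = (item[0] if isinstance(item, tuple) else item).query_name
        raise MissingIndexError(f"read {name!r} lacks a {which} molecular index")
    return value


def build_key(item: Record, regime: Regime, use_strand: bool = False) -> tuple:
    """The duplicate-grouping key of a read (SE) or pair (PE) under a regime.

    Orientation is ignored by default ("irrespective of orientation"); pass
    ``use_strand=True`` for the stranded variant.  Paired-end position keys
    are order-normalised over the two mates' (reference, pos) so that the
    key does not depend on which mate is called first.
    """
    regime = Regime(regime)
    if regime is Regime.ND:
        name = (item[0] if isinstance(item, tuple) else item).query_name
        return ("nd", name)
    if isinstance(item, tuple):
        a, b = item
        coords = tuple(sorted([(a.reference_name, a.pos), (b.reference_name, b.pos)]))
        key: tuple = coords[0] + coords[1]
        if use_strand:
            key = key + (tuple(sorted([a.strand, b.strand])),)
    else:
        key = (item.reference_name, item.pos)
        if use_strand:
            key = key + (item.strand,)
    if regime in (Regime.MI1, Regime.MI2):
        mi_f, mi_r = _mis(item)
        key = key + (_require_mi(mi_f, item, "forward"),)
    if regime is Regime.MI2:
        mi_f, mi_r = _mis(item)
        mi_r = _require_mi(mi_r, item, "reverse")
        if isinstance(item, tuple):
            key = key + (mi_r,)
        else:
            # single-end: the two 8-mers were ligated as one 16-nt index
            key = key[:-1] + (key[-1] + mi_r,)
    return key


def _infer_layout(records: Sequence[Record]) -> Layout:
    kinds = {isinstance(r, tuple) for r in records}
    if len(kinds) > 1:
        raise ValueError(
            "mixed single-end records and read pairs in one input; "
            "pass a homogeneous list or set layout explicitly"
        )
    return Layout.PE if kinds == {True} else Layout.SE


def elect_representative(members: Sequence[Record]) -> Record:
    """Pick the retained member: max summed base quality, then smallest name."""
    if not members:
        raise ValueError("empty duplicate group")

    def rank(item: Record):
        if isinstance(item, tuple):
            qual = item[0].quality_sum + item[1].quality_sum
            name = item[0].query_name
        else:
            qual, name = item.quality_sum, item.query_name
        return (-qual, name)

    return min(members, key=rank)


@dataclass
class DedupResult:
    retained: list[Record]
    groups: list[DuplicateGroup]
    regime: Regime
    layout: Layout

    @property
    def n_input(self) -> int:
        return sum(len(g.members) for g in self.groups)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def retained_names(self) -> set[str]:
        out = set()
        for item in self.retained:
            rec = item[0] if isinstance(item, tuple) else item
            out.add(rec.query_name)
        return out


def deduplicate(
    records: Sequence[Record],
    regime: Regime | str,
    layout: Layout | str | None = None,
    use_strand: bool = False,
) -> DedupResult:
    """Two-stage duplicate removal: group by key, then retain one per group.

    Candidates first collide on mapping position (both mates for pairs), then
    — for the MI regimes — on index identity.  ``ND`` is the identity regime:
    every record forms its own group and is retained.  Output order is sorted
    by key, so the result is independent of input order.
    """
    regime = Regime(regime)
    if layout is None:
        layout = _infer_layout(records) if records else Layout.SE
    layout = Layout(layout)
    if records and _infer_layout(records) is not layout:
        raise ValueError(f"records do not match declared layout {layout.value!r}")

    by_key: dict[tuple, list[Record]] = {}
    for item in records:
        by_key.setdefault(build_key(item, regime, use_strand=use_strand), []).append(item)

    groups: list[DuplicateGroup] = []
    retained: list[Record] = []
    for key in sorted(by_key):
        members = by_key[key]
        rep = elect_representative(members)
        groups.append(DuplicateGroup(key=key, members=tuple(members), representative=rep))
        retained.append(rep)
    return DedupResult(retained=retained, groups=groups, regime=regime, layout=layout)


# ---------------------------------------------------------------------------
# layout derivation on tagged reads
# ---------------------------------------------------------------------------

def derive_reads(
    pairs: Sequence[tuple[TaggedRead, TaggedRead]],
    target: Layout | str,
    read_length: int,
) -> list[tuple[TaggedRead, ...]]:
    """Derive a shorter/single-end dataset from paired tagged reads.

    Single-end derivation keeps the forward mate (both indices remain known
    to the caller); length derivation truncates the cDNA portion to its first
    ``read_length`` bases with qualities cut identically.  Asking for more
    cDNA than the source carries is an error.
    """
    target = Layout(target)
    out: list[tuple[TaggedRead, ...]] = []
    for fwd, rev in pairs:
        if read_length > len(fwd.cdna_sequence):
            raise ValueError(
                f"target cDNA length {read_length} exceeds source length "
                f"{len(fwd.cdna_sequence)} for read {fwd.read_id!r}"
            )
        cut = lambda r: replace(
            r,
            cdna_sequence=r.cdna_sequence[:read_length],
            cdna_qualities=r.cdna_qualities[:read_length],
        )
        if target is Layout.SE:
            out.append((cut(fwd),))
        else:
            out.append((cut(fwd), cut(rev)))
    return out


# ---------------------------------------------------------------------------
# SAM/BAM input and output
# ---------------------------------------------------------------------------

@dataclass
class SamReadStats:
    n_primary: int = 0
    n_secondary: int = 0
    n_supplementary: int = 0
    n_unmapped: int = 0
    n_unpaired: int = 0  # PE reads whose mate never showed up


def _record_from_pysam(
    aln: pysam.AlignedSegment,
    mi_from: str,
    n_mis: int,
    delimiter: str,
    layout: Layout,
) -> AlignmentRecord:
    mi_f = mi_r = None
    name = aln.query_name
    if mi_from == "name":
        name, mis = parse_tagged_name(aln.query_name, n_mis, delimiter=delimiter)
        mi_f = mis[0]
        mi_r = mis[1] if n_mis > 1 else None
    elif mi_from == "tags":
        if aln.has_tag("RX"):
            rx = aln.get_tag("RX").split("-")
            mi_f = rx[0]
            mi_r = rx[1] if len(rx) > 1 else None
    elif mi_from != "none":
        raise ValueError(f"unknown mi_from {mi_from!r}")
    quals = aln.query_qualities
    return AlignmentRecord(
        query_name=name,
        reference_name=aln.reference_name,
        pos=aln.reference_start,
        end=aln.reference_end,
        strand="-" if aln.is_reverse else "+",
        layout=layout,
        mate_reference=aln.next_reference_name if aln.is_paired else None,
        mate_pos=aln.next_reference_start if aln.is_paired else None,
        mi_forward=mi_f,
        mi_reverse=mi_r,
        quality_sum=int(sum(quals)) if quals is not None else 0,
    )


def read_alignments(
    path: str | Path,
    layout: Layout | str,
    mi_from: str = "name",
    n_mis: int = 2,
    delimiter: str = "_",
) -> tuple[list[Record], SamReadStats]:
    """Load primary alignments from SAM/BAM as dedup records.

    Molecular indices are recovered from the read-name suffix (``mi_from=
    "name"``), from ``RX`` tags (``"tags"``), or not at all (``"none"``).
    Secondary, supplementary and unmapped alignments are dropped and counted.
    Paired-end mates are joined by query name; pairs with a missing mate are
    dropped and counted in ``n_unpaired``.
    """
    layout = Layout(layout)
    stats = SamReadStats()
    singles: list[Record] = []
    pending: dict[str, tuple[AlignmentRecord, bool]] = {}
    pairs: list[ReadPair] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                stats.n_unmapped += 1
                continue
            if aln.is_secondary:
                stats.n_secondary += 1
                continue
            if aln.is_supplementary:
                stats.n_supplementary += 1
                continue
            stats.n_primary += 1
            rec = _record_from_pysam(aln, mi_from, n_mis, delimiter, layout)
            if layout is Layout.SE:
                singles.append(rec)
                continue
            is_forward_mate = aln.is_read1 or not aln.is_paired
            if rec.query_name in pending:
                mate, mate_was_forward = pending.pop(rec.query_name)
                fwd, rev = (mate, rec) if mate_was_forward else (rec, mate)
                pairs.append((fwd, rev))
            else:
                pending[rec.query_name] = (rec, is_forward_mate)
    stats.n_unpaired = len(pending)
    return (singles if layout is Layout.SE else pairs), stats


def filter_sam(
    in_path: str | Path,
    out_path: str | Path,
    retained_names: set[str],
    mi_from: str = "name",
    n_mis: int = 2,
    delimiter: str = "_",
) -> int:
    """Write a SAM keeping only primary alignments of retained read names.

    Read names in ``retained_names`` are the bare ids (indices stripped when
    ``mi_from="name"``).  Returns the number of alignments written.
    """
    n = 0
    with pysam.AlignmentFile(str(in_path), check_sq=False) as fh:
        with pysam.AlignmentFile(str(out_path), "w", template=fh) as out:
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                name = aln.query_name
                if mi_from == "name":
                    name, _ = parse_tagged_name(name, n_mis, delimiter=delimiter)
                if name in retained_names:
                    out.write(aln)
                    n += 1
    return n


def group_report(result: DedupResult) -> list[dict]:
    """Per-group summary rows (key, size, representative name)."""
    rows = []
    for g in result.groups:
        rep = g.representative
        rep_name = (rep[0] if isinstance(rep, tuple) else rep).query_name
        rows.append(
            {
                "key": "|".join(str(c) for c in g.key),
                "group_size": len(g.members),
                "representative": rep_name,
            }
        )
    return rows
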