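"""Shared fixtures: random dedup instances and the brute-force grouping oracle.

The oracle defines duplicate groups from first principles — an all-pairs
equivalence check followed by transitive closure — never touching the key
machinery under test.
"""

from __future__ import annotations

import numpy as np
import pytest

from midedup.dedup import AlignmentRecord, Layout, Record


def _find(parent: list[int], i: int) -> int:
    while parent[i] != i:
        parent[i] = parent[parent[i]]
        i = parent[i]
    return i


def oracle_partition(records: list[Record], regime: str) -> list[frozenset[str]]:
    """Duplicate groups by exhaustive pairwise comparison (union-find closure)."""

    def equivalent(a: Record, b: Record) -> bool:
        if isinstance(a, tuple):
            pa = sorted([(a[0].reference_name, a[0].pos), (a[1].reference_name, a[1].pos)])
            pb = sorted([(b[0].reference_name, b[0].pos), (b[1].reference_name, b[1].pos)])
            if pa != pb:
                return False
            fa, ra = a[0].mi_forward, a[0].mi_reverse
            fb, rb = b[0].mi_forward, b[0].mi_reverse
        else:
            if (a.reference_name, a.pos) != (b.reference_name, b.pos):
                return False
            fa, ra, fb, rb = a.mi_forward, a.mi_reverse, b.mi_forward, b.mi_reverse
        if regime == "1mi":
            return fa == fb
        if regime == "2mi":
            return (fa, ra) == (fb, rb)
        return True  # position-only

    n = len(records)
    parent = list(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if equivalent(records[i], records[j]):
                ri, rj = _find(parent, i), _find(parent, j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, set[str]] = {}
    for i, rec in enumerate(records):
        name = (rec[0] if isinstance(rec, tuple) else rec).query_name
        groups.setdefault(_find(parent, i), set()).add(name)
    return [frozenset(g) for g in groups.values()]


def random_instance(
    rng: np.random.Generator,
    n_records: int,
    layout: Layout = Layout.SE,
    n_positions: int = 200,
    mi_alphabet: tuple[str, ...] = ("AAAA", "CCCC", "GGGG", "TTTT"),
    n_refs: int = 2,
) -> list[Record]:
    """A random dedup instance with a small position/index space (collisions likely)."""
    records: list[Record] = []
    for i in range(n_records):
        ref = f"chr{rng.integers(1, n_refs + 1)}"
        mi_f = str(rng.choice(mi_alphabet))
        mi_r = str(rng.choice(mi_alphabet))
        qual = int(rng.integers(0, 200))
        name = f"r{i:05d}"
        if layout is Layout.SE:
            records.append(
                AlignmentRecord(
                    query_name=name,
                    reference_name=ref,
                    pos=int(rng.integers(0, n_positions)),
                    strand=str(rng.choice(["+", "-"])),
                    layout=Layout.SE,
                    mi_forward=mi_f,
                    mi_reverse=mi_r,
                    quality_sum=qual,
                )
            )
        else:
            p1 = int(rng.integers(0, n_positions))
            p2 = int(rng.integers(0, n_positions))
            ref2 = f"chr{rng.integers(1, n_refs + 1)}"
            fwd = AlignmentRecord(
                query_name=name, reference_name=ref, pos=p1, strand="+",
                layout=Layout.PE, mate_reference=ref2, mate_pos=p2,
                mi_forward=mi_f, mi_reverse=mi_r, quality_sum=qual,
            )
            rev = AlignmentRecord(
                query_name=name, reference_name=ref2, pos=p2, strand="-",
                layout=Layout.PE, mate_reference=ref, mate_pos=p1,
                mi_forward=mi_f, mi_reverse=mi_r, quality_sum=int(rng.integers(0, 200)),
            )
            records.append((fwd, rev))
    return records


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_901)
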