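"""Lineage-tracked RNA-seq read simulation.

The simulator emulates the structure of a molecular-indexed library: a
synthetic genome with non-overlapping single-exon genes, per-gene molecule
counts drawn from a log-normal expression distribution, uniform fragment
positions within each gene, an 8+8-nt index pair per molecule drawn from a
96 x 96 whitelist (or assigned uniquely in collision-free mode), per-molecule
PCR copy numbers (extra copies ~ Geometric(p)) and optional optical copies.
Reads carry the 9-nt prefix (index + adenylation spacer 'A') ahead of the
cDNA, and alignments are emitted directly at their true coordinates — no
external aligner is involved, but the downstream contracts (FASTQ, SAM,
count tables) are identical.

Every emitted read has a truth row recording its molecule, gene, fragment
and duplicate lineage, so true-duplicate removal sensitivity and
false-duplicate removal rates are measurable exactly.

Derived layouts mirror how shorter / single-end datasets are made from a
paired-end run: single-end keeps the forward mate, length derivation
truncates the cDNA (the indices are untouched).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .dedup import AlignmentRecord, Layout, Record
from .mi_extract import MIWhitelist, tagged_name
from .quantify import GeneIndex, GeneModel

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated library.

    ``read_length`` is the raw read length including the 9-nt prefix, so the
    aligned cDNA portion is ``read_length - mi_length - 1`` nt (91 for 100-nt
    reads).  ``pcr_geometric_p`` parametrises the number of extra PCR copies
    per molecule, G ~ Geometric(p) on {0, 1, ...} with mean (1-p)/p; the
    default p = 0.5 gives one extra copy per molecule on average.
    ``mi_mode`` is ``"whitelist-random"`` (indices drawn uniformly from the
    whitelist, collisions possible) or ``"collision-free"`` (every molecule
    gets a unique index pair).
    """

    seed: int
    n_genes: int = 2000
    contig_name: str = "sim1"
    gene_length_log_mean: float = float(np.log(1500.0))
    gene_length_log_sd: float = 0.4
    gene_min_length: int = 300
    gene_max_length: int = 20000
    intergenic_gap: int = 100
    expression_log_mean: float = float(np.log(30.0))
    expression_log_sd: float = 1.5
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 30.0
    fragment_min_length: int = 120
    read_length: int = 100
    layout: Layout = Layout.PE
    mi_length: int = 8
    spacer: str = "A"
    whitelist_size: tuple[int, int] = (96, 96)
    pcr_geometric_p: float = 0.5
    optical_duplicate_prob: float = 0.0
    mi_mode: str = "whitelist-random"

    def __post_init__(self) -> None:
        for p, name in [
            (self.pcr_geometric_p, "pcr_geometric_p"),
            (self.optical_duplicate_prob, "optical_duplicate_prob"),
        ]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.pcr_geometric_p == 0.0:
            raise ValueError("pcr_geometric_p must be positive (p=1 means no extra copies)")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.mi_mode not in ("whitelist-random", "collision-free"):
            raise ValueError(f"unknown mi_mode {self.mi_mode!r}")
        if self.read_length < self.mi_length + 2:
            raise ValueError("read_length must exceed mi_length + 1")

    @property
    def cdna_length(self) -> int:
        return self.read_length - self.mi_length - 1

    def to_json(self) -> str:
        d = asdict(self)
        d["layout"] = Layout(self.layout).value
        return json.dumps(d, indent=2)


def _encode_base4(values: np.ndarray, width: int) -> np.ndarray:
    """Encode integers as ``width``-mer nucleotide strings (base-4, A=0)."""
    out = np.empty((values.size, width), dtype="<U1")
    v = values.astype(np.int64).copy()
    for i in range(width - 1, -1, -1):
        out[:, i] = _BASES[v % 4]
        v //= 4
    return np.array(["".join(row) for row in out])


def simulate_whitelist(config: SimConfig, rng: np.random.Generator) -> MIWhitelist:
    """Draw the forward/reverse index whitelists (distinct random 8-mers)."""
    n_fwd, n_rev = config.whitelist_size
    space = 4 ** config.mi_length
    if n_fwd + n_rev > space:
        raise ValueError("whitelist larger than the index sequence space")
    codes = rng.choice(space, size=n_fwd + n_rev, replace=False)
    mers = _encode_base4(codes, config.mi_length)
    return MIWhitelist(frozenset(mers[:n_fwd]), frozenset(mers[n_fwd:]))


def simulate_reference(
    config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[GeneModel]]:
    """Place non-overlapping single-exon genes on one synthetic contig.

    Gene lengths are log-normal (clipped to the configured range), strands
    alternate at random, and genes are laid out left to right with a fixed
    intergenic gap.  Deterministic given the generator state.
    """
    lengths = np.clip(
        np.round(rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sd, config.n_genes)),
        config.gene_min_length,
        config.gene_max_length,
    ).astype(int)
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    genes: list[GeneModel] = []
    pos = config.intergenic_gap
    width = len(str(config.n_genes))
    for i, (length, strand) in enumerate(zip(lengths, strands)):
        genes.append(
            GeneModel(
                gene_id=f"g{i:0{width}d}",
                reference_name=config.contig_name,
                exons=((pos, pos + int(length)),),
                strand=str(strand),
            )
        )
        pos += int(length) + config.intergenic_gap
    contig_len = pos
    seq = "".join(rng.choice(_BASES, size=contig_len))
    return {config.contig_name: seq}, genes


def simulate_molecules(
    genes: Sequence[GeneModel],
    config: SimConfig,
    rng: np.random.Generator,
    molecule_counts: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw molecules: gene of origin, fragment coordinates, index pair.

    Per-gene molecule counts are ``round(LogNormal(mean, sd))`` unless given
    explicitly.  Fragment lengths are normal; draws longer than the gene are
    redrawn (5 rounds) and molecules still too long are skipped.  Fragment
    starts are uniform within the gene.  Returns one row per molecule with
    columns ``molecule_id, gene_id, frag_start, frag_end, mi_forward,
    mi_reverse`` (genome coordinates, half-open).
    """
    if molecule_counts is None:
        raw = rng.lognormal(config.expression_log_mean, config.expression_log_sd, len(genes))
        molecule_counts = np.round(raw).astype(int)
    else:
        molecule_counts = np.asarray(molecule_counts, dtype=int)
        if molecule_counts.size != len(genes):
            raise ValueError("molecule_counts must have one entry per gene")
    gene_idx = np.repeat(np.arange(len(genes)), molecule_counts)
    n = gene_idx.size
    gene_starts = np.array([g.start for g in genes])[gene_idx]
    gene_lens = np.array([g.length for g in genes])[gene_idx]

    flen = np.round(
        rng.normal(config.fragment_length_mean, config.fragment_length_sd, n)
    ).astype(int)
    flen = np.maximum(flen, config.fragment_min_length)
    for _ in range(5):  # bounded redraws for fragments longer than their gene
        bad = flen > gene_lens
        if not bad.any():
            break
        redraw = np.round(
            rng.normal(config.fragment_length_mean, config.fragment_length_sd, int(bad.sum()))
        ).astype(int)
        flen[bad] = np.maximum(redraw, config.fragment_min_length)
    keep = flen <= gene_lens
    gene_idx, gene_starts, gene_lens, flen = (
        gene_idx[keep], gene_starts[keep], gene_lens[keep], flen[keep]
    )
    n = gene_idx.size

    offset = np.floor(rng.random(n) * (gene_lens - flen + 1)).astype(int)
    frag_start = gene_starts + offset
    frag_end = frag_start + flen

    if config.mi_mode == "collision-free":
        # unique per molecule: molecule index split across the two 8-mers
        half = 4 ** config.mi_length
        idx = np.arange(n)
        mi_f = _encode_base4(idx // half, config.mi_length)
        mi_r = _encode_base4(idx % half, config.mi_length)
    else:
        wl = simulate_whitelist(config, np.random.default_rng(config.seed + 10_007))
        fwd = np.array(sorted(wl.forward_set))
        rev = np.array(sorted(wl.reverse_set))
        mi_f = fwd[rng.integers(0, fwd.size, n)]
        mi_r = rev[rng.integers(0, rev.size, n)]

    width = max(7, len(str(max(n, 1))))
    return pd.DataFrame(
        {
            "molecule_id": [f"m{i:0{width}d}" for i in range(n)],
            "gene_id": [genes[i].gene_id for i in gene_idx],
            "gene_idx": gene_idx,
            "frag_start": frag_start,
            "frag_end": frag_end,
            "mi_forward": mi_f,
            "mi_reverse": mi_r,
        }
    )


@dataclass
class SimulatedDataset:
    """Emitted reads plus lineage truth for one library and layout.

    ``truth`` has one row per emitted read (per fragment for paired-end) with
    the duplicate lineage: ``copy_index`` 0 is the original observation of a
    molecule, higher PCR copy indices and optical copies point back to it via
    ``duplicate_of``.  The same truth frame is shared by all layouts derived
    from the library, since derivation never adds or drops reads.
    """

    config: SimConfig
    genes: list[GeneModel]
    reference: dict[str, str]
    whitelist: MIWhitelist | None
    truth: pd.DataFrame
    layout: Layout
    cdna_length: int
    read_length: int = 0  # nominal raw-read length used in labels (PE100, SE50, ...)
    label: str = ""
    _records: list[Record] | None = field(default=None, repr=False, compare=False)

    @property
    def n_molecules(self) -> int:
        return int(self.truth["molecule_id"].nunique())

    @property
    def n_reads(self) -> int:
        return len(self.truth)

    def gene_index(self) -> GeneIndex:
        return GeneIndex(self.genes)

    # -- alignment records -------------------------------------------------

    def records(self) -> list[Record]:
        """Alignment records at true coordinates (pairs for PE)."""
        if self._records is None:
            self._records = _build_records(self)
        return self._records

    def derive(self, layout: Layout | str, read_length: int | None = None) -> "SimulatedDataset":
        """Derive a single-end and/or shorter-read dataset from this one.

        ``read_length`` is the nominal target read length (e.g. 50); the cDNA
        is truncated to its first ``read_length`` bases where shorter than the
        source cDNA.  Single-end derivation keeps the forward mate; both
        indices stay attached to every read.  A target longer than the source
        is an error.
        """
        layout = Layout(layout)
        nominal = self.read_length if read_length is None else int(read_length)
        if nominal > self.read_length:
            raise ValueError(
                f"cannot derive {nominal}-nt reads from a {self.read_length}-nt source"
            )
        if layout is Layout.PE and self.layout is Layout.SE:
            raise ValueError("cannot derive paired-end data from single-end data")
        return SimulatedDataset(
            config=self.config,
            genes=self.genes,
            reference=self.reference,
            whitelist=self.whitelist,
            truth=self.truth,
            layout=layout,
            cdna_length=min(self.cdna_length, nominal),
            read_length=nominal,
            label=layout_label(layout, nominal),
        )

    # -- file outputs ------------------------------------------------------

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    def write_fastq(self, r1_path: str | Path, r2_path: str | Path | None = None) -> None:
        _write_fastq(self, r1_path, r2_path)

    def write_sam(self, path: str | Path) -> None:
        _write_sam(self, path)

    def write_reference(self, fasta_path: str | Path) -> None:
        with open(fasta_path, "w") as fh:
            for name, seq in self.reference.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_annotation(self, gtf_path: str | Path) -> None:
        from .quantify import write_gtf

        write_gtf(self.genes, gtf_path)


def layout_label(layout: Layout | str, read_length: int) -> str:
    return f"{Layout(layout).value.upper()}{read_length}"


def amplify_and_emit(
    molecules: pd.DataFrame,
    genes: Sequence[GeneModel],
    config: SimConfig,
    rng: np.random.Generator,
    reference: dict[str, str] | None = None,
    whitelist: MIWhitelist | None = None,
) -> SimulatedDataset:
    """Amplify molecules into reads and emit the dataset with truth rows.

    Each molecule yields ``1 + G`` PCR copies, G ~ Geometric(p); every emitted
    read then seeds an optical copy with the configured probability.  All
    copies are exact: the position-plus-index duplicate keys are blind to
    sequence errors, so none are simulated.
    """
    n_mol = len(molecules)
    extra = rng.geometric(config.pcr_geometric_p, n_mol) - 1 if n_mol else np.array([], int)
    n_copies = 1 + extra

    mol_idx = np.repeat(np.arange(n_mol), n_copies)
    copy_idx = np.concatenate([np.arange(c) for c in n_copies]) if n_mol else np.array([], int)
    if config.optical_duplicate_prob > 0:
        optical = rng.random(mol_idx.size) < config.optical_duplicate_prob
        mol_idx = np.concatenate([mol_idx, mol_idx[optical]])
        copy_idx = np.concatenate([copy_idx, copy_idx[optical]])
        is_optical = np.concatenate(
            [np.zeros(n_copies.sum(), bool), np.ones(int(optical.sum()), bool)]
        )
    else:
        is_optical = np.zeros(mol_idx.size, bool)

    mol = molecules.iloc[mol_idx].reset_index(drop=True)
    suffix = np.where(is_optical, "o", "")
    read_ids = [
        f"{m}c{c}{s}" for m, c, s in zip(mol["molecule_id"], copy_idx, suffix)
    ]
    strand_by_gene = {g.gene_id: g.strand for g in genes}
    truth = pd.DataFrame(
        {
            "read_id": read_ids,
            "molecule_id": mol["molecule_id"].to_numpy(),
            "gene_id": mol["gene_id"].to_numpy(),
            "gene_strand": mol["gene_id"].map(strand_by_gene).to_numpy(),
            "frag_start": mol["frag_start"].to_numpy(),
            "frag_end": mol["frag_end"].to_numpy(),
            "copy_index": copy_idx,
            "is_pcr_duplicate": copy_idx > 0,
            "is_optical_duplicate": is_optical,
            "duplicate_of": [f"{m}c0" for m in mol["molecule_id"]],
            "mi_forward": mol["mi_forward"].to_numpy(),
            "mi_reverse": mol["mi_reverse"].to_numpy(),
        }
    )
    truth = truth.sort_values("read_id", kind="stable").reset_index(drop=True)
    return SimulatedDataset(
        config=config,
        genes=list(genes),
        reference=reference or {},
        whitelist=whitelist,
        truth=truth,
        layout=Layout(config.layout),
        cdna_length=config.cdna_length,
        read_length=config.read_length,
        label=layout_label(config.layout, config.read_length),
    )


def simulate_dataset(config: SimConfig, with_sequence: bool = True) -> SimulatedDataset:
    """End-to-end convenience: whitelist, reference, molecules, amplification.

    ``with_sequence=False`` skips generating the contig sequence (alignments
    and truth do not need it; FASTQ/FASTA output does).
    """
    rng = np.random.default_rng(config.seed)
    whitelist = (
        simulate_whitelist(config, np.random.default_rng(config.seed + 10_007))
        if config.mi_mode == "whitelist-random"
        else None
    )
    reference, genes = simulate_reference(config, rng)
    if not with_sequence:
        reference = {name: "" for name in reference}
    molecules = simulate_molecules(genes, config, rng)
    return amplify_and_emit(
        molecules, genes, config, rng, reference=reference, whitelist=whitelist
    )


# ---------------------------------------------------------------------------
# read/alignment materialisation
# ---------------------------------------------------------------------------

def _mate_coords(
    truth: pd.DataFrame, cdna_length: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mapped coordinates of both mates for every fragment.

    In a dUTP library the forward read is antisense to the transcript: for a
    '+' gene it maps on '-' at the fragment end, the reverse read on '+' at
    the fragment start; mirrored for '-' genes.  Returns (r1_start, r1_strand,
    r2_start, r2_strand, aligned_length).
    """
    fs = truth["frag_start"].to_numpy()
    fe = truth["frag_end"].to_numpy()
    length = np.minimum(cdna_length, fe - fs)
    plus_gene = truth["gene_strand"].to_numpy() == "+"
    r1_start = np.where(plus_gene, fe - length, fs)
    r1_strand = np.where(plus_gene, "-", "+")
    r2_start = np.where(plus_gene, fs, fe - length)
    r2_strand = np.where(plus_gene, "+", "-")
    return r1_start, r1_strand, r2_start, r2_strand, length


def _build_records(ds: SimulatedDataset) -> list[Record]:
    ref = ds.config.contig_name
    r1s, r1st, r2s, r2st, length = _mate_coords(ds.truth, ds.cdna_length)
    qual = 40 * length  # perfect reads: every base at Q40
    names = ds.truth["read_id"].to_numpy()
    mi_f = ds.truth["mi_forward"].to_numpy()
    mi_r = ds.truth["mi_reverse"].to_numpy()
    records: list[Record] = []
    if ds.layout is Layout.SE:
        for i in range(len(names)):
            records.append(
                AlignmentRecord(
                    query_name=names[i],
                    reference_name=ref,
                    pos=int(r1s[i]),
                    end=int(r1s[i] + length[i]),
                    strand=str(r1st[i]),
                    layout=Layout.SE,
                    mi_forward=mi_f[i],
                    mi_reverse=mi_r[i],
                    quality_sum=int(qual[i]),
                )
            )
        return records
    for i in range(len(names)):
        fwd = AlignmentRecord(
            query_name=names[i],
            reference_name=ref,
            pos=int(r1s[i]),
            end=int(r1s[i] + length[i]),
            strand=str(r1st[i]),
            layout=Layout.PE,
            mate_reference=ref,
            mate_pos=int(r2s[i]),
            mi_forward=mi_f[i],
            mi_reverse=mi_r[i],
            quality_sum=int(qual[i]),
        )
        rev = AlignmentRecord(
            query_name=names[i],
            reference_name=ref,
            pos=int(r2s[i]),
            end=int(r2s[i] + length[i]),
            strand=str(r2st[i]),
            layout=Layout.PE,
            mate_reference=ref,
            mate_pos=int(r1s[i]),
            mi_forward=mi_f[i],
            mi_reverse=mi_r[i],
            quality_sum=int(qual[i]),
        )
        records.append((fwd, rev))
    return records


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _read_sequence(ref_seq: str, start: int, length: int, strand: str) -> str:
    seq = ref_seq[start : start + length]
    return _revcomp(seq) if strand == "-" else seq


def _require_sequence(ds: SimulatedDataset) -> str:
    seq = ds.reference.get(ds.config.contig_name, "")
    if not seq:
        raise ValueError("dataset was simulated without reference sequence")
    return seq


def _write_fastq(ds: SimulatedDataset, r1_path: str | Path, r2_path: str | Path | None) -> None:
    """Raw FASTQ with the 9-nt prefix (index + spacer) ahead of the cDNA."""
    ref_seq = _require_sequence(ds)
    if ds.layout is Layout.PE and r2_path is None:
        raise ValueError("paired-end output needs an R2 path")
    r1s, r1st, r2s, r2st, length = _mate_coords(ds.truth, ds.cdna_length)
    names = ds.truth["read_id"].to_numpy()
    mi_f = ds.truth["mi_forward"].to_numpy()
    mi_r = ds.truth["mi_reverse"].to_numpy()
    spacer = ds.config.spacer
    with open(r1_path, "w") as f1:
        f2 = open(r2_path, "w") if r2_path is not None else None
        try:
            for i in range(len(names)):
                cdna1 = _read_sequence(ref_seq, int(r1s[i]), int(length[i]), str(r1st[i]))
                seq1 = mi_f[i] + spacer + cdna1
                f1.write(f"@{names[i]}\n{seq1}\n+\n{'I' * len(seq1)}\n")
                if f2 is not None:
                    cdna2 = _read_sequence(ref_seq, int(r2s[i]), int(length[i]), str(r2st[i]))
                    seq2 = mi_r[i] + spacer + cdna2
                    f2.write(f"@{names[i]}\n{seq2}\n+\n{'I' * len(seq2)}\n")
        finally:
            if f2 is not None:
                f2.close()


def _write_sam(ds: SimulatedDataset, path: str | Path) -> None:
    """Perfect alignments of the cDNA portions, indices in name and RX tag."""
    ref_seq = _require_sequence(ds)
    contig = ds.config.contig_name
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": contig, "LN": len(ref_seq)}],
    }
    r1s, r1st, r2s, r2st, length = _mate_coords(ds.truth, ds.cdna_length)
    names = ds.truth["read_id"].to_numpy()
    mi_f = ds.truth["mi_forward"].to_numpy()
    mi_r = ds.truth["mi_reverse"].to_numpy()
    paired = ds.layout is Layout.PE

    def make(i: int, which: int) -> pysam.AlignedSegment:
        start, strand = (r1s[i], r1st[i]) if which == 1 else (r2s[i], r2st[i])
        a = pysam.AlignedSegment()
        a.query_name = tagged_name(str(names[i]), (str(mi_f[i]), str(mi_r[i])))
        a.reference_id = 0
        a.reference_start = int(start)
        a.mapping_quality = 60
        a.cigarstring = f"{int(length[i])}M"
        a.query_sequence = _read_sequence(ref_seq, int(start), int(length[i]), str(strand))
        a.query_qualities = pysam.qualitystring_to_array("I" * int(length[i]))
        flag = 0
        if strand == "-":
            flag |= 0x10
        if paired:
            mate_start, mate_strand = (r2s[i], r2st[i]) if which == 1 else (r1s[i], r1st[i])
            flag |= 0x1 | 0x2 | (0x40 if which == 1 else 0x80)
            if mate_strand == "-":
                flag |= 0x20
            a.next_reference_id = 0
            a.next_reference_start = int(mate_start)
            left = min(int(r1s[i]), int(r2s[i]))
            right = max(int(r1s[i] + length[i]), int(r2s[i] + length[i]))
            tlen = right - left
            a.template_length = tlen if int(start) == left else -tlen
        a.flag = flag
        a.set_tag("RX", f"{mi_f[i]}-{mi_r[i]}")
        return a

    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i in range(len(names)):
            out.write(make(i, 1))
            if paired:
                out.write(make(i, 2))


# ---------------------------------------------------------------------------
# ground-truth evaluation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthMetrics:
    """How a deduplication regime performed against the simulator lineage.

    ``sensitivity``: removed true duplicates / all true duplicates (PCR and
    optical copies).  ``false_removal_rate``: removed original reads / all
    original reads — the damage done to independent molecules.  Per-decile
    rows stratify the false-removal rate by gene expression (molecule count).
    """

    regime: str
    n_reads: int
    n_true_duplicates: int
    n_removed: int
    sensitivity: float
    false_removal_rate: float
    per_decile: pd.DataFrame | None = None


def ground_truth_metrics(
    truth: pd.DataFrame,
    retained_ids: set[str],
    regime: str = "",
    n_deciles: int = 10,
) -> GroundTruthMetrics:
    """Score a retained-read set against the simulator's duplicate lineage."""
    all_ids = set(truth["read_id"])
    stray = retained_ids - all_ids
    if stray:
        raise ValueError(f"retained ids not present in truth: {sorted(stray)[:5]}")
    removed = ~truth["read_id"].isin(retained_ids)
    is_dup = truth["is_pcr_duplicate"] | truth["is_optical_duplicate"]
    n_dup = int(is_dup.sum())
    n_orig = int((~is_dup).sum())
    sensitivity = float((removed & is_dup).sum() / n_dup) if n_dup else float("nan")
    false_removal = float((removed & ~is_dup).sum() / n_orig) if n_orig else float("nan")

    per_decile = None
    if n_deciles and truth["gene_id"].nunique() >= n_deciles:
        expr = truth.groupby("gene_id")["molecule_id"].nunique()
        decile = pd.qcut(expr.rank(method="first"), n_deciles, labels=False)
        frame = pd.DataFrame(
            {
                "gene_id": truth["gene_id"],
                "removed_original": (removed & ~is_dup).to_numpy(),
                "original": (~is_dup).to_numpy(),
            }
        )
        frame["decile"] = frame["gene_id"].map(decile)
        grouped = frame.groupby("decile", observed=False)
        per_decile = pd.DataFrame(
            {
                "n_original": grouped["original"].sum(),
                "n_removed_original": grouped["removed_original"].sum(),
            }
        )
        per_decile["false_removal_rate"] = (
            per_decile["n_removed_original"] / per_decile["n_original"]
        )
    return GroundTruthMetrics(
        regime=regime,
        n_reads=len(truth),
        n_true_duplicates=n_dup,
        n_removed=int(removed.sum()),
        sensitivity=sensitivity,
        false_removal_rate=false_removal,
        per_decile=per_decile,
    )
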