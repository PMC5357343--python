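"""Orchestration of the layout x deduplication-regime comparison grid.

A grid run evaluates every combination of sequencing layout (PE100, PE50,
SE100, SE50 — all derived from one paired-end 100-nt library) and
deduplication regime (ND, SAM, 1MI, 2MI) on the same input, producing per
cell a gene count table, a retention profile against the cell's own ND
counts, and a DE-list concordance against a designated standard cell
(PE100_2MI by default).  Cells are named ``<layout>_<regime>``, e.g.
``SE50_SAM``.

For simulated input the grid starts from a two-condition experiment with
planted fold changes; DE lists per cell come from a deliberately simple
caller (size-factor normalization, Welch t-test on log counts, BH
correction, FDR/fold-change thresholds) applied identically to every cell,
so between-cell differences reflect the deduplication regime, not the
caller.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .concordance import (
    ConcordanceResult,
    DEGeneSet,
    apply_de_thresholds,
    fn_fp,
    size_factors,
)
from .dedup import Layout, Record, Regime, deduplicate
from .quantify import (
    CountTable,
    GeneIndex,
    GeneModel,
    RetentionProfile,
    count_per_gene,
    retention_profile,
    rpkm_column,
)
from .simulate import SimConfig, SimulatedDataset, amplify_and_emit, simulate_molecules, simulate_reference

LAYOUTS = {
    "PE100": (Layout.PE, 100),
    "PE50": (Layout.PE, 50),
    "SE100": (Layout.SE, 100),
    "SE50": (Layout.SE, 50),
}

_REGIME_LABEL = {Regime.ND: "ND", Regime.SAM: "SAM", Regime.MI1: "1MI", Regime.MI2: "2MI"}
_LABEL_REGIME = {v: k for k, v in _REGIME_LABEL.items()}


def cell_label(layout: str, regime: Regime) -> str:
    return f"{layout}_{_REGIME_LABEL[Regime(regime)]}"


@dataclass(frozen=True)
class GridSpec:
    """Which cells to run and which one is the concordance standard."""

    layouts: tuple[str, ...] = ("PE100", "PE50", "SE100", "SE50")
    regimes: tuple[Regime, ...] = (Regime.ND, Regime.SAM, Regime.MI1, Regime.MI2)
    standard: str = "PE100_2MI"
    fdr: float = 0.05
    fc: float = 2.0
    stranded: str = "reverse"

    def __post_init__(self) -> None:
        unknown = set(self.layouts) - set(LAYOUTS)
        if unknown:
            raise ValueError(f"unknown layouts: {sorted(unknown)}")
        std_layout, _, std_regime = self.standard.partition("_")
        if std_layout not in self.layouts or _LABEL_REGIME.get(std_regime) not in self.regimes:
            raise ValueError(f"standard cell {self.standard!r} not in the grid")


@dataclass
class Experiment:
    """A simulated two-condition experiment: one dataset per sample.

    ``design`` maps sample name to condition; ``true_de`` is the planted
    DE-gene truth (direction of condition B relative to condition A).
    """

    config: SimConfig
    genes: list[GeneModel]
    datasets: dict[str, SimulatedDataset]
    design: dict[str, str]
    true_de: DEGeneSet


def simulate_experiment(
    config: SimConfig,
    n_replicates: int = 3,
    de_fraction: float = 0.1,
    de_log2fc: float = 2.0,
    with_sequence: bool = False,
) -> Experiment:
    """Simulate replicated libraries for two conditions with planted DE genes.

    Per-gene expected molecule counts are drawn once from the log-normal
    expression distribution and shared by all samples; a ``de_fraction`` of
    genes gets a ±``de_log2fc`` log2 fold change in condition B (half up,
    half down); per-sample molecule counts are Poisson around the expected
    values, and each sample is amplified into its own lineage-tracked
    dataset.
    """
    rng = np.random.default_rng(config.seed)
    reference, genes = simulate_reference(config, rng)
    if not with_sequence:
        reference = {name: "" for name in reference}
    lam = rng.lognormal(config.expression_log_mean, config.expression_log_sd, len(genes))

    n_de = int(round(de_fraction * len(genes)))
    de_idx = rng.choice(len(genes), size=n_de, replace=False)
    up_idx, down_idx = de_idx[: n_de // 2], de_idx[n_de // 2 :]
    scale_b = np.ones(len(genes))
    scale_b[up_idx] = 2.0 ** de_log2fc
    scale_b[down_idx] = 2.0 ** -de_log2fc
    gene_ids = np.array([g.gene_id for g in genes])
    true_de = DEGeneSet(
        label="truth", up=frozenset(gene_ids[up_idx]), down=frozenset(gene_ids[down_idx])
    )

    datasets: dict[str, SimulatedDataset] = {}
    design: dict[str, str] = {}
    for condition, scale in (("A", np.ones(len(genes))), ("B", scale_b)):
        for rep in range(1, n_replicates + 1):
            name = f"{condition}{rep}"
            counts = rng.poisson(lam * scale)
            molecules = simulate_molecules(genes, config, rng, molecule_counts=counts)
            datasets[name] = amplify_and_emit(
                molecules, genes, config, rng, reference=reference
            )
            design[name] = condition
    return Experiment(
        config=config, genes=genes, datasets=datasets, design=design, true_de=true_de
    )


def call_de(
    table: CountTable,
    design: Mapping[str, str],
    fdr: float = 0.05,
    fc: float = 2.0,
    label: str = "",
) -> DEGeneSet:
    """Simple DE caller applied uniformly to every grid cell.

    Size-factor normalization, Welch t-test on log2(normalized count + 0.5)
    between conditions, Benjamini-Hochberg adjustment, then the FDR and
    fold-change thresholds.  This is grid plumbing for comparing regimes
    under one fixed caller, not a negative-binomial DE method.
    """
    factors = size_factors(table.counts)
    norm = table.counts.div(factors, axis=1)
    a_cols = [s for s in norm.columns if design[s] == "A"]
    b_cols = [s for s in norm.columns if design[s] == "B"]
    if not a_cols or not b_cols:
        raise ValueError("need samples from both conditions")
    log = np.log2(norm + 0.5)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # genes with near-constant counts trip scipy's catastrophic-cancellation
        # warning; their p-values end up NaN/1 and are excluded downstream
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = sp_stats.ttest_ind(log[b_cols], log[a_cols], axis=1, equal_var=False)
    p = pd.Series(p, index=norm.index)
    valid = p.notna()
    padj = pd.Series(np.nan, index=norm.index)
    if valid.any():
        padj[valid] = multipletests(p[valid], method="fdr_bh")[1]
    fold = (norm[b_cols].mean(axis=1) + 0.5) / (norm[a_cols].mean(axis=1) + 0.5)
    stats_df = pd.DataFrame({"fold_change": fold, "padj": padj})
    return apply_de_thresholds(stats_df, fdr=fdr, fc=fc, label=label)


@dataclass
class CellResult:
    label: str
    layout: str
    regime: Regime
    count_table: CountTable | None = None
    retention: RetentionProfile | None = None
    de: DEGeneSet | None = None
    concordance: ConcordanceResult | None = None
    n_input: int = 0
    n_retained: int = 0
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


@dataclass
class GridResult:
    spec: GridSpec
    cells: dict[str, CellResult]

    def summary(self) -> pd.DataFrame:
        rows = []
        for label, cell in self.cells.items():
            row: dict = {
                "cell": label,
                "layout": cell.layout,
                "regime": _REGIME_LABEL[cell.regime],
                "failed": cell.failed,
                "n_input": cell.n_input,
                "n_retained": cell.n_retained,
            }
            if cell.retention is not None:
                row["mean_retention"] = cell.retention.mean_fraction
            if cell.de is not None:
                row["n_de_up"] = len(cell.de.up)
                row["n_de_down"] = len(cell.de.down)
            if cell.concordance is not None:
                row["fn_percent"] = cell.concordance.fn_percent
                row["fp_percent"] = cell.concordance.fp_percent
            if cell.error:
                row["error"] = cell.error
            rows.append(row)
        return pd.DataFrame(rows).set_index("cell")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary().to_csv(outdir / "grid_summary.tsv", sep="\t")
        for label, cell in self.cells.items():
            cdir = outdir / label
            cdir.mkdir(exist_ok=True)
            if cell.count_table is not None:
                cell.count_table.to_tsv(cdir / "counts.tsv")
            if cell.retention is not None:
                cell.retention.data.to_csv(cdir / "retention.tsv", sep="\t", index_label="gene_id")
            if cell.de is not None:
                de_rows = [{"gene_id": g, "direction": "up"} for g in sorted(cell.de.up)]
                de_rows += [{"gene_id": g, "direction": "down"} for g in sorted(cell.de.down)]
                pd.DataFrame(de_rows, columns=["gene_id", "direction"]).to_csv(
                    cdir / "de_genes.tsv", sep="\t", index=False
                )
            if cell.concordance is not None:
                (cdir / "concordance.json").write_text(
                    json.dumps(cell.concordance.to_dict(), indent=2) + "\n"
                )
            if cell.error:
                (cdir / "FAILED.txt").write_text(cell.error + "\n")


def run_grid(
    experiment: Experiment,
    spec: GridSpec = GridSpec(),
    retention_sample: str | None = None,
) -> GridResult:
    """Run every grid cell on a simulated experiment.

    A failing cell is recorded with its error and the grid continues.  The
    retention profile of each cell uses ``retention_sample`` (default: the
    first sample) against the same layout's ND counts.  Concordance is
    computed against the standard cell's DE list; the standard cell itself
    compares to itself (0/0) as a consistency check.
    """
    index = GeneIndex(experiment.genes)
    lengths = index.lengths()
    sample_names = list(experiment.datasets)
    retention_sample = retention_sample or sample_names[0]
    cells: dict[str, CellResult] = {}

    for lay_label in spec.layouts:
        layout, read_len = LAYOUTS[lay_label]
        records_by_sample: dict[str, Sequence[Record]] = {
            name: ds.derive(layout, read_len).records()
            for name, ds in experiment.datasets.items()
        }
        nd_counts: dict[str, pd.Series] = {}
        for name, recs in records_by_sample.items():
            nd_counts[name], _ = count_per_gene(recs, index, stranded=spec.stranded)
        nd_totals = {name: len(recs) for name, recs in records_by_sample.items()}
        nd_rpkm = rpkm_column(
            nd_counts[retention_sample], lengths, nd_totals[retention_sample]
        )

        for regime in spec.regimes:
            regime = Regime(regime)
            label = cell_label(lay_label, regime)
            cell = CellResult(label=label, layout=lay_label, regime=regime)
            cells[label] = cell
            try:
                cols: dict[str, pd.Series] = {}
                totals: dict[str, int] = {}
                for name, recs in records_by_sample.items():
                    if regime is Regime.ND:
                        retained: Sequence[Record] = recs
                    else:
                        retained = deduplicate(recs, regime, layout=layout).retained
                    if name == retention_sample:
                        cell.n_input = len(recs)
                        cell.n_retained = len(retained)
                    if regime is Regime.ND:
                        cols[name] = nd_counts[name]
                    else:
                        cols[name], _ = count_per_gene(retained, index, stranded=spec.stranded)
                    totals[name] = len(retained)
                cell.count_table = CountTable(
                    pd.DataFrame(cols), lengths, pd.Series(totals)
                )
                cell.retention = retention_profile(
                    nd_counts[retention_sample],
                    cell.count_table.counts[retention_sample],
                    nd_rpkm,
                    regime=label,
                )
                cell.de = call_de(
                    cell.count_table, experiment.design, fdr=spec.fdr, fc=spec.fc, label=label
                )
            except Exception as exc:  # cell failure must not sink the grid
                cell.error = f"{type(exc).__name__}: {exc}"

    std = cells.get(spec.standard)
    if std is not None and std.de is not None:
        for cell in cells.values():
            if cell.de is not None:
                cell.concordance = fn_fp(std.de, cell.de)
    return GridResult(spec=spec, cells=cells)
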