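"""The retention-vs-expression curve: why position-only dedup harms
highly expressed genes on single-end data.

Derives a single-end dataset from a paired-end simulation, deduplicates it
with and without index information, and bins the per-gene retained fraction
by expression decile (log10 RPKM).  Position-only retention falls with
expression — those are false duplicates — while two-index retention stays
flat at the true-duplicate level.
"""

import numpy as np
from scipy import stats

from midedup.dedup import Layout, Regime, deduplicate
from midedup.quantify import (
    bin_retention_by_expression,
    count_per_gene,
    retention_profile,
    rpkm_column,
)
from midedup.simulate import SimConfig, simulate_dataset

pe = simulate_dataset(SimConfig(seed=31, n_genes=1500), with_sequence=False)
se = pe.derive(Layout.SE, 100)
index = se.gene_index()
records = se.records()

nd_counts, _ = count_per_gene(records, index)
nd_rpkm = rpkm_column(nd_counts, index.lengths(), len(records))

print(f"{'decile':>8} {'SAM':>8} {'2MI':>8}")
curves = {}
for regime in (Regime.SAM, Regime.MI2):
    retained = deduplicate(records, regime, layout=Layout.SE).retained
    col, _ = count_per_gene(retained, index)
    prof = retention_profile(nd_counts, col, nd_rpkm, regime=regime.value)
    curves[regime] = prof
    binned = bin_retention_by_expression(prof, min_count=10)
    curves[f"{regime}_bins"] = binned["mean"].to_numpy()

for i, (s, m) in enumerate(zip(curves[f"{Regime.SAM}_bins"], curves[f"{Regime.MI2}_bins"])):
    print(f"{i + 1:>8} {s:8.3f} {m:8.3f}")

sam = curves[Regime.SAM].data
rho, p = stats.spearmanr(sam["expression"], sam["fraction"])
print()
print(f"SAM retention vs expression: Spearman rho = {rho:.3f} (p = {p:.2e})")
print("Columns are mean retained fraction per expression decile (low to high).")
print("The SAM column declines toward the top decile; the 2MI column holds at")
print("about the inverse of the mean PCR copy number, independent of expression.")
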