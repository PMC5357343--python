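"""Exact duplicate recovery measured against the simulator lineage.

In collision-free mode every molecule carries a unique index pair, so
two-index deduplication must remove exactly the PCR copies: sensitivity 1.0
and zero false removal.  Position-only deduplication on the same data
removes independent molecules as well, concentrated in expressed genes.
"""

from midedup.dedup import Layout, Regime, deduplicate
from midedup.simulate import SimConfig, ground_truth_metrics, simulate_dataset

ds = simulate_dataset(
    SimConfig(seed=47, n_genes=400, mi_mode="collision-free"), with_sequence=False
)
print(
    f"library: {ds.n_molecules} molecules, {ds.n_reads} fragments "
    f"({ds.n_reads - ds.n_molecules} true PCR duplicates)"
)

for regime in (Regime.MI2, Regime.SAM):
    retained = deduplicate(ds.records(), regime, layout=Layout.PE).retained_names()
    m = ground_truth_metrics(ds.truth, retained, regime=regime.value)
    print(
        f"  {regime.value.upper():>4}: sensitivity {m.sensitivity:.4f}, "
        f"false removal {m.false_removal_rate:.4f}"
    )
print()
print("Sensitivity is the fraction of true duplicates removed; false removal")
print("is the fraction of original (independent) reads wrongly discarded.")
print("With unique indices, 2MI is exact by construction; SAM's false")
print("removals are the coincidental position matches between molecules.")
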