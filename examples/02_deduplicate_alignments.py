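"""Deduplicate one library under all four regimes and compare retention.

The same paired-end alignments are grouped by position only (SAM), position
plus the forward index (1MI) and position plus both indices (2MI); ND keeps
everything.  Retained counts are always ordered ND >= 2MI >= 1MI >= SAM
because each key refines the previous one.
"""

import tempfile
from pathlib import Path

from midedup.dedup import Layout, Regime, deduplicate, read_alignments
from midedup.simulate import SimConfig, simulate_dataset

ds = simulate_dataset(SimConfig(seed=23, n_genes=300))
print(f"library: {ds.n_molecules} molecules amplified into {ds.n_reads} fragments")

# round-trip through a SAM file, as real data would arrive
with tempfile.TemporaryDirectory() as tmp:
    sam = Path(tmp) / "alignments.sam"
    ds.write_sam(sam)
    records, stats = read_alignments(sam, layout=Layout.PE)

print(f"read from SAM: {len(records)} pairs ({stats.n_primary} primary alignments)")
for regime in (Regime.ND, Regime.MI2, Regime.MI1, Regime.SAM):
    res = deduplicate(records, regime, layout=Layout.PE)
    print(f"  {regime.value.upper():>4}: {res.n_retained:6d} fragments retained")
print()
print("2MI stays closest to the true molecule count; the position-only key")
print("also merges fragments from different molecules that landed on the")
print("same coordinates, which is why SAM retains the fewest reads.")
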