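"""Union counting, RPKM and retention diagnostics."""

import numpy as np
import pandas as pd
import pytest

from midedup.dedup import AlignmentRecord, Layout
from midedup.quantify import (
    CountTable,
    GeneIndex,
    GeneModel,
    bin_retention_by_expression,
    count_per_gene,
    merge_intervals,
    read_bed12,
    read_gtf,
    retention_distribution_summary,
    retention_profile,
    rpkm,
    rpkm_column,
    write_gtf,
)


def read_at(pos, end, strand="-", ref="c1", name="r"):
    # default '-' strand: with a reverse-stranded library a '-' read counts
    # toward '+' genes
    return AlignmentRecord(
        query_name=name, reference_name=ref, pos=pos, end=end, strand=strand,
        layout=Layout.SE,
    )


@pytest.fixture
def two_genes():
    return [
        GeneModel("gA", "c1", ((100, 600),), strand="+"),
        GeneModel("gB", "c1", ((1000, 1400), (1600, 1800)), strand="+"),
    ]


class TestGeneModel:
    def test_union_length(self, two_genes):
        assert two_genes[0].length == 500
        assert two_genes[1].length == 600

    def test_overlapping_exons_merged(self):
        g = GeneModel("g", "c1", ((0, 100), (50, 150)))
        assert g.exons == ((0, 150),)
        assert g.length == 150

    def test_merge_intervals_rejects_empty(self):
        with pytest.raises(ValueError):
            merge_intervals([(10, 10)])

    def test_gtf_roundtrip(self, two_genes, tmp_path):
        path = tmp_path / "genes.gtf"
        write_gtf(two_genes, path)
        back = {g.gene_id: g for g in read_gtf(path)}
        for g in two_genes:
            assert back[g.gene_id].exons == g.exons
            assert back[g.gene_id].strand == g.strand

    def test_bed12_blocks_become_exons(self, tmp_path):
        line = "c1\t1000\t1800\tgB\t0\t+\t1000\t1800\t0\t2\t400,200\t0,600\n"
        p = tmp_path / "genes.bed"
        p.write_text(line)
        (g,) = read_bed12(p)
        assert g.exons == ((1000, 1400), (1600, 1800))


class TestCounting:
    def test_read_inside_one_gene(self, two_genes):
        col, st = count_per_gene([read_at(200, 290)], GeneIndex(two_genes))
        assert col["gA"] == 1 and col["gB"] == 0
        assert st.counted == 1

    def test_ambiguous_read_counted_for_neither(self):
        genes = [
            GeneModel("g1", "c1", ((0, 500),), strand="+"),
            GeneModel("g2", "c1", ((400, 900),), strand="+"),
        ]
        col, st = count_per_gene([read_at(450, 480)], GeneIndex(genes))
        assert col.sum() == 0 and st.ambiguous == 1

    def test_intergenic_read_not_counted(self, two_genes):
        col, st = count_per_gene([read_at(700, 790)], GeneIndex(two_genes))
        assert col.sum() == 0 and st.no_feature == 1

    def test_strandedness(self, two_genes):
        # '+' read is sense-flipped to '-' fragment; '+' genes reject it
        col, st = count_per_gene([read_at(200, 290, strand="+")], GeneIndex(two_genes))
        assert col.sum() == 0 and st.wrong_strand == 1
        col, _ = count_per_gene(
            [read_at(200, 290, strand="+")], GeneIndex(two_genes), stranded="none"
        )
        assert col["gA"] == 1

    def test_unknown_reference_warned_and_skipped(self, two_genes):
        with pytest.warns(UserWarning, match="chrZ"):
            col, st = count_per_gene([read_at(5, 50, ref="chrZ")], GeneIndex(two_genes))
        assert st.unknown_reference == 1

    def test_pe_fragment_counted_once(self, two_genes):
        fwd = AlignmentRecord(
            query_name="p", reference_name="c1", pos=480, end=570, strand="-",
            layout=Layout.PE, mate_reference="c1", mate_pos=150,
        )
        rev = AlignmentRecord(
            query_name="p", reference_name="c1", pos=150, end=240, strand="+",
            layout=Layout.PE, mate_reference="c1", mate_pos=480,
        )
        col, st = count_per_gene([(fwd, rev)], GeneIndex(two_genes))
        assert col["gA"] == 1 and st.counted == 1

    def test_counts_match_simulator_truth(self):
        """Simulated reads with known gene of origin are counted exactly."""
        from midedup.simulate import SimConfig, simulate_dataset

        ds = simulate_dataset(
            SimConfig(seed=5, n_genes=80, expression_log_mean=np.log(25.0)),
            with_sequence=False,
        )
        col, st = count_per_gene(ds.records(), ds.gene_index())
        truth = ds.truth.groupby("gene_id").size()
        assert st.ambiguous == 0 and st.no_feature == 0 and st.wrong_strand == 0
        assert (col == truth.reindex(col.index).fillna(0).astype(int)).all()


class TestRpkm:
    def test_closed_form(self):
        assert rpkm(10, 1000, 10**6) == pytest.approx(10.0)
        assert rpkm(0, 1000, 10**6) == 0.0

    def test_zero_length_or_total_rejected(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)

    def test_column_matches_independent_formula(self, rng):
        counts = pd.Series(rng.integers(0, 500, 50), index=[f"g{i}" for i in range(50)])
        lengths = pd.Series(rng.integers(200, 5000, 50), index=counts.index)
        total = int(counts.sum())
        ours = rpkm_column(counts, lengths, total)
        for g in counts.index[:10]:
            per_kb = counts[g] / (lengths[g] / 1000.0)
            per_million = per_kb / (total / 1e6)
            assert ours[g] == pytest.approx(per_million)

    def test_linear_in_count_inverse_in_length_and_total(self):
        base = rpkm(10, 1000, 10**6)
        assert rpkm(20, 1000, 10**6) == pytest.approx(2 * base)
        assert rpkm(10, 2000, 10**6) == pytest.approx(base / 2)
        assert rpkm(10, 1000, 2 * 10**6) == pytest.approx(base / 2)


class TestRetention:
    @staticmethod
    def _cols(nd, dd):
        idx = [f"g{i}" for i in range(len(nd))]
        nd = pd.Series(nd, index=idx)
        dd = pd.Series(dd, index=idx)
        expr = pd.Series(np.linspace(1, 100, len(nd)), index=idx)
        return nd, dd, expr

    def test_identical_columns_give_unit_fractions(self):
        nd, dd, expr = self._cols([5, 10, 0], [5, 10, 0])
        prof = retention_profile(nd, dd, expr)
        assert (prof.fractions == 1.0).all()
        assert len(prof.data) == 2  # zero-ND gene excluded

    def test_half_retained(self):
        nd, dd, expr = self._cols([6], [3])
        assert retention_profile(nd, dd, expr).fractions.iloc[0] == 0.5

    def test_dedup_exceeding_nd_rejected(self):
        nd, dd, expr = self._cols([3], [6])
        with pytest.raises(ValueError, match="exceeds"):
            retention_profile(nd, dd, expr)

    def test_mean_fraction_tracks_true_duplicate_rate(self):
        """With collision-free indices, two-index dedup removes exactly the
        PCR duplicates, so overall retention = molecules / reads."""
        from midedup.dedup import Regime, deduplicate
        from midedup.simulate import SimConfig, simulate_dataset

        ds = simulate_dataset(
            SimConfig(seed=7, n_genes=60, mi_mode="collision-free"), with_sequence=False
        )
        res = deduplicate(ds.records(), Regime.MI2, layout=Layout.PE)
        index = ds.gene_index()
        nd_col, _ = count_per_gene(ds.records(), index)
        dd_col, _ = count_per_gene(res.retained, index)
        expr = rpkm_column(nd_col, index.lengths(), ds.n_reads)
        prof = retention_profile(nd_col, dd_col, expr)
        pooled = prof.data["count_dedup"].sum() / prof.data["count_nd"].sum()
        assert pooled == pytest.approx(ds.n_molecules / ds.n_reads)

    def test_binning_constant_fractions(self):
        nd, dd, expr = self._cols([10] * 40, [4] * 40)
        prof = retention_profile(nd, dd, expr)
        binned = bin_retention_by_expression(prof, n_bins=4)
        assert np.allclose(binned["mean"].dropna(), 0.4)

    def test_binning_two_known_bins(self):
        nd = pd.Series([10, 10, 10, 10], index=list("abcd"))
        dd = pd.Series([10, 8, 5, 1], index=list("abcd"))
        expr = pd.Series([1.0, 2.0, 1000.0, 2000.0], index=list("abcd"))
        prof = retention_profile(nd, dd, expr)
        binned = bin_retention_by_expression(prof, n_bins=2)
        means = binned["mean"].to_numpy()
        assert means[0] == pytest.approx((1.0 + 0.8) / 2)
        assert means[1] == pytest.approx((0.5 + 0.1) / 2)

    def test_distribution_summary_and_welch_oracle(self, rng):
        from midedup.quantify import RetentionProfile

        def prof(frac):
            df = pd.DataFrame(
                {
                    "fraction": frac,
                    "expression": np.ones(len(frac)),
                    "count_nd": np.full(len(frac), 10),
                    "count_dedup": (np.asarray(frac) * 10).astype(int),
                }
            )
            return RetentionProfile(df, "x")

        a = rng.uniform(0.3, 0.9, 200)
        b = rng.uniform(0.2, 0.8, 150)
        comp = retention_distribution_summary({"A": prof(a), "B": prof(b)})
        # independent Welch computation from the textbook formula
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_expect = (a.mean() - b.mean()) / np.sqrt(va + vb)
        row = comp.t_tests.iloc[0]
        assert row["t"] == pytest.approx(t_expect)
        assert comp.summaries.loc["A", "mean"] == pytest.approx(a.mean())

    def test_shifted_profiles_mean_difference(self):
        from midedup.quantify import RetentionProfile

        base = np.linspace(0.2, 0.8, 100)
        make = lambda f: RetentionProfile(
            pd.DataFrame(
                {
                    "fraction": f,
                    "expression": np.ones(100),
                    "count_nd": np.full(100, 10),
                    "count_dedup": np.full(100, 5),
                }
            ),
            "x",
        )
        comp = retention_distribution_summary({"A": make(base), "B": make(base + 0.1)})
        diff = comp.summaries.loc["B", "mean"] - comp.summaries.loc["A", "mean"]
        assert diff == pytest.approx(0.1)


class TestCountTable:
    def test_tsv_roundtrip(self, tmp_path, rng):
        counts = pd.DataFrame(
            rng.integers(0, 100, (20, 3)),
            index=[f"g{i}" for i in range(20)],
            columns=["s1", "s2", "s3"],
        )
        lengths = pd.Series(rng.integers(300, 3000, 20), index=counts.index)
        totals = counts.sum(axis=0) + 50  # unassigned reads included in totals
        ct = CountTable(counts, lengths, totals)
        path = tmp_path / "counts.tsv"
        ct.to_tsv(path)
        back = CountTable.from_tsv(path)
        assert (back.counts == counts).all().all()
        assert (back.gene_lengths == lengths).all()

    def test_totals_smaller_than_counts_rejected(self):
        counts = pd.DataFrame({"s1": [5, 5]}, index=["a", "b"])
        lengths = pd.Series([100, 100], index=["a", "b"])
        with pytest.raises(ValueError, match="totals"):
            CountTable(counts, lengths, pd.Series({"s1": 4}))

    def test_rpkm_table(self):
        counts = pd.DataFrame({"s1": [10]}, index=["a"])
        ct = CountTable(counts, pd.Series({"a": 1000}), pd.Series({"s1": 10**6}))
        assert ct.rpkm().loc["a", "s1"] == pytest.approx(10.0)
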