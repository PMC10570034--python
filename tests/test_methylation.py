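"""Cytosine reports, spike-in calibration, methylation calling and weighted levels."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gbmeth import (
    GeneModel,
    call_methylated,
    classify_gene_methylation,
    estimate_conversion,
    feature_methylation_summary,
    genome_wide_level,
    load_cytosine_report,
    methylation_profile,
    weighted_methylation,
)
from gbmeth.methylation import ConversionStats, binomial_tail_pvalues

from conftest import records_frame


def exact_binomial_tail(k: int, n: int, p_num: int, p_den: int) -> float:
    """Exact rational-arithmetic oracle for P(Binomial(n, p) >= k)."""
    p = Fraction(p_num, p_den)
    return float(sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)))


class TestLoadReport:
    def test_coordinates_converted(self, tmp_path):
        f = tmp_path / "r.tsv"
        f.write_text("chr1\t5\t+\t3\t7\tCpG\tCGA\n")
        df = load_cytosine_report(f)
        assert df.loc[0, "pos"] == 4
        assert (df.loc[0, "n_meth"], df.loc[0, "n_unmeth"]) == (3, 7)

    def test_negative_count_names_line(self, tmp_path):
        f = tmp_path / "r.tsv"
        f.write_text("chr1\t5\t+\t3\t7\tCpG\tCGA\nchr1\t9\t+\t-1\t7\tCpG\tCGA\n")
        with pytest.raises(ValueError, match="line 2"):
            load_cytosine_report(f)

    def test_bad_strand_rejected(self, tmp_path):
        f = tmp_path / "r.tsv"
        f.write_text("chr1\t5\t*\t3\t7\tCpG\tCGA\n")
        with pytest.raises(ValueError, match="strand"):
            load_cytosine_report(f)

    def test_empty_file_gives_empty_frame(self, tmp_path):
        f = tmp_path / "r.tsv"
        f.write_text("")
        df = load_cytosine_report(f)
        assert len(df) == 0

    def test_zero_coverage_rows_retained(self, tmp_path):
        f = tmp_path / "r.tsv"
        f.write_text("chr1\t5\t+\t0\t0\tCpG\tCGA\n")
        assert len(load_cytosine_report(f)) == 1


class TestConversion:
    def test_fully_converted_spike(self):
        rec = records_frame([("spike", 1, "+", "CpG", 0, 50), ("spike", 5, "+", "CHH", 0, 30)])
        assert estimate_conversion(rec, "spike").efficiency == 1.0

    def test_arithmetic(self):
        rec = records_frame([("spike", 1, "+", "CpG", 10, 990)])
        conv = estimate_conversion(rec, "spike")
        assert conv.efficiency == pytest.approx(0.99)
        assert conv.error_rate == pytest.approx(0.01)

    def test_absent_spike_errors(self):
        rec = records_frame([("chr1", 1, "+", "CpG", 3, 7)])
        with pytest.raises(ValueError, match="spike"):
            estimate_conversion(rec, "spike")


class TestGenomeWideLevel:
    def test_subtracts_error_rate(self):
        # raw CpG fraction 0.5% with a 0.1% error rate -> 0.4%
        rec = records_frame([("chr1", i, "+", "CpG", 5, 995) for i in range(10)])
        conv = ConversionStats(efficiency=0.999, n_sites=1, total_reads=1000)
        assert genome_wide_level(rec, conv, "CpG") == pytest.approx(0.4)

    def test_clamped_at_zero(self):
        rec = records_frame([("chr1", 1, "+", "CpG", 1, 999)])
        conv = ConversionStats(efficiency=0.99, n_sites=1, total_reads=1000)
        assert genome_wide_level(rec, conv, "CpG") == 0.0

    def test_uncovered_context_is_missing(self):
        rec = records_frame([("chr1", 1, "+", "CpG", 1, 9)])
        conv = ConversionStats(efficiency=0.99, n_sites=1, total_reads=10)
        assert genome_wide_level(rec, conv, "CHG") is None

    def test_spike_excluded(self):
        rec = records_frame(
            [("chr1", 1, "+", "CpG", 50, 50), ("spike", 1, "+", "CpG", 0, 10_000)]
        )
        conv = ConversionStats(efficiency=1.0, n_sites=1, total_reads=10_000)
        assert genome_wide_level(rec, conv, "CpG", spike_chrom="spike") == pytest.approx(50.0)


class TestCallMethylated:
    def test_minimum_coverage_gate(self):
        rec = records_frame(
            [("chr1", 1, "+", "CpG", 9, 0), ("chr1", 3, "+", "CpG", 10, 0)]
        )
        calls = call_methylated(rec, 0.01, min_cov=10)
        assert list(calls["pos"]) == [3]

    def test_zero_methylated_reads_p_is_one(self):
        rec = records_frame([("chr1", 1, "+", "CpG", 0, 10)])
        calls = call_methylated(rec, 0.01)
        assert calls.loc[calls.index[0], "p"] == pytest.approx(1.0)
        assert not calls["methylated"].any()

    def test_fully_methylated_closed_form(self):
        rec = records_frame([("chr1", 1, "+", "CpG", 10, 0)])
        calls = call_methylated(rec, 0.01)
        assert calls.iloc[0]["p"] == pytest.approx(1e-20, rel=1e-9)

    def test_partial_tail_example(self):
        rec = records_frame([("chr1", 1, "+", "CpG", 2, 8)])
        calls = call_methylated(rec, 0.01)
        assert calls.iloc[0]["p"] == pytest.approx(0.00426620024283142, rel=1e-9)

    def test_degenerate_zero_error_rate(self):
        rec = records_frame(
            [("chr1", 1, "+", "CpG", 1, 9), ("chr1", 3, "+", "CpG", 0, 10)]
        )
        calls = call_methylated(rec, 0.0).set_index("pos")
        assert calls.loc[1, "p"] == 0.0 and calls.loc[3, "p"] == 1.0

    def test_non_cpg_context_not_tested(self):
        rec = records_frame([("chr1", 1, "+", "CHH", 10, 0)])
        assert len(call_methylated(rec, 0.01)) == 0

    def test_tail_matches_exact_rational_oracle(self):
        rng = np.random.default_rng(11)
        for n in [1, 2, 5, 10, 17, 30, 50, 100, 200]:
            ks = np.unique(rng.integers(0, n + 1, size=6))
            p = binomial_tail_pvalues(ks, np.full(ks.shape, n), 0.01)
            for k, pv in zip(ks, p):
                assert abs(pv - exact_binomial_tail(int(k), n, 1, 100)) < 1e-12


class TestWeightedMethylation:
    def test_coverage_weighting_differs_from_site_mean(self):
        rec = records_frame(
            [("chr1", 1, "+", "CpG", 5, 5), ("chr1", 3, "+", "CpG", 0, 30)]
        )
        rm = weighted_methylation(rec, "chr1", [1, 3])
        assert rm.weighted_level == pytest.approx(0.125)  # not the site mean 0.25

    def test_uncovered_cpgs_counted_but_not_zero_inflating(self):
        rec = records_frame([("chr1", 1, "+", "CpG", 5, 5)])
        rm = weighted_methylation(rec, "chr1", [1, 3, 5])
        assert rm.n_cpg == 3 and rm.weighted_level == pytest.approx(0.5)

    def test_empty_region_undefined(self):
        rec = records_frame([("chr1", 1, "+", "CpG", 5, 5)])
        rm = weighted_methylation(rec, "chr1", [])
        assert rm.n_cpg == 0 and rm.weighted_level is None

    @given(
        st.lists(
            st.tuples(st.integers(0, 30), st.integers(0, 30)), min_size=1, max_size=20
        ),
        st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_split_and_pool_invariance(self, counts, data):
        """Weighted level over a region equals the count-pooled level of any split."""
        rows = [("chr1", 2 * i, "+", "CpG", m, u) for i, (m, u) in enumerate(counts)]
        rec = records_frame(rows)
        pos = [2 * i for i in range(len(counts))]
        whole = weighted_methylation(rec, "chr1", pos)
        cut = data.draw(st.integers(0, len(pos)))
        a = weighted_methylation(rec, "chr1", pos[:cut])
        b = weighted_methylation(rec, "chr1", pos[cut:])
        assert whole.sum_meth == a.sum_meth + b.sum_meth
        assert whole.sum_total == a.sum_total + b.sum_total


class TestGeneClasses:
    def _frame(self, levels):
        return pd.DataFrame(
            {"region_id": [f"g{i}" for i in range(len(levels))],
             "category": "gene_body", "n_cpg": 5, "sum_meth": 1, "sum_total": 2,
             "weighted_level": levels}
        )

    def test_class_boundaries(self):
        conv = ConversionStats(efficiency=0.996, n_sites=1, total_reads=100)
        df = classify_gene_methylation(self._frame([0.8, 0.0, 0.003, 0.05]), conv)
        assert list(df["methylation_class"]) == [
            "highly_methylated", "unmethylated", "background", "methylated"
        ]

    def test_undefined_levels_excluded(self):
        conv = ConversionStats(efficiency=0.99, n_sites=1, total_reads=100)
        df = classify_gene_methylation(self._frame([0.5, np.nan]), conv)
        assert len(df) == 1


class TestFeatureSummary:
    def test_structure_rows_per_feature(self, toy_genome):
        genes = [
            GeneModel("g1", "chr1", "+", [(10, 13), (16, 19)], [(10, 13), (16, 19)])
        ]
        rec = records_frame([("chr1", 11, "+", "CpG", 4, 6), ("chr1", 30, "+", "CpG", 1, 9)])
        feat = feature_methylation_summary(rec, toy_genome, genes, [])
        cats = set(feat["category"])
        assert {"exon_rank_1", "exon_rank_2", "intron", "gene_body", "intergenic"} <= cats
        assert "TE" not in cats
        gb = feat[feat["category"] == "gene_body"].iloc[0]
        assert gb["n_cpg"] == 1 and gb["weighted_level"] == pytest.approx(0.4)

    def test_injected_class_ordering_recovered(self, sim):
        """Pooled weighted levels reproduce the injected ordering hk > other > intergenic > TE."""
        feat = feature_methylation_summary(
            sim.records, sim.genome, sim.genes, sim.te_intervals,
            spike_chrom="spike", index=sim.index,
        )
        hk = {g.gene_id for g in sim.genes if g.is_housekeeping}
        gb = feat[feat["category"] == "gene_body"]
        pooled = {}
        pooled["hk"] = gb[gb["region_id"].isin(hk)]
        pooled["other"] = gb[~gb["region_id"].isin(hk)]
        pooled["TE"] = feat[feat["category"] == "TE"]
        pooled["intergenic"] = feat[feat["category"] == "intergenic"]
        level = {
            k: v["sum_meth"].sum() / v["sum_total"].sum() for k, v in pooled.items()
        }
        assert level["hk"] > level["other"] > level["intergenic"] > level["TE"]


class TestProfile:
    def test_uniform_truth_flat_profile(self):
        rng = np.random.default_rng(3)
        pos = np.arange(0, 10_000, 7)
        m = rng.binomial(40, 0.5, size=pos.size)
        rec = records_frame(
            [("chr1", int(p), "+", "CpG", int(mi), int(40 - mi)) for p, mi in zip(pos, m)]
        )
        genome = {"chr1": "A" * 10_000}
        prof = methylation_profile(rec, [("chr1", 3000, 6000)], genome, flank_bp=1000)
        assert np.nanmax(np.abs(prof["weighted_level"] - 0.5)) < 0.05

    def test_empty_bins_missing_and_truncation_flagged(self):
        rec = records_frame([("chr1", 100, "+", "CpG", 1, 1)])
        genome = {"chr1": "A" * 2_000}
        prof = methylation_profile(rec, [("chr1", 0, 1000)], genome, flank_bp=500)
        assert prof["weighted_level"].isna().any()
        assert prof.attrs["n_truncated"] == 1

    def test_step_function_recovered(self):
        rows = []
        for p in range(0, 3000, 10):
            inside = 1000 <= p < 2000
            rows.append(("chr1", p, "+", "CpG", 20 if inside else 1, 0 if inside else 19))
        rec = records_frame(rows)
        genome = {"chr1": "A" * 3_000}
        prof = methylation_profile(
            rec, [("chr1", 1000, 2000)], genome, flank_bp=800, n_body_bins=10, n_flank_bins=5
        )
        body = prof.loc[prof["segment"] == "body", "weighted_level"]
        flank = prof.loc[prof["segment"] != "body", "weighted_level"]
        assert body.min() > flank.max()
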