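"""DMC-calling tests: parsing, filtering, the chi-squared test against
closed-form oracles, direction summaries and transcript/gene tallies."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from met1c import dmc as dmc_mod
from met1c import synthetic as syn
from met1c.dmc import (
    MethylCountMatrix,
    conversion_qc,
    count_transcripts_genes,
    filter_dmc,
    read_coverage,
    summarize_direction,
    test_dmc as run_dmc_test,
    unite_and_filter,
)


def tiny_matrix(meth, cov, samples=None):
    meth = np.asarray(meth)
    n = meth.shape[0]
    sites = pd.DataFrame({"chrom": ["chr1"] * n,
                          "pos": np.arange(100, 100 + n), "strand": "."})
    if samples is None:
        k = meth.shape[1]
        samples = pd.DataFrame({
            "sample": [f"s{i}" for i in range(k)],
            "lineage": ["ICM"] * k,
            "methionine": [10] * (k // 2) + [50] * (k - k // 2),
            "replicate": list(range(1, k + 1)),
        })
    return MethylCountMatrix(sites, meth, np.asarray(cov), samples)


class TestReadCoverage:
    def test_single_line_parsed(self, tmp_path):
        f = tmp_path / "s.cov"
        f.write_text("chr1\t100\t100\t50.0\t5\t5\n")
        meta = pd.DataFrame({"sample": ["s"], "lineage": ["ICM"],
                             "methionine": [10], "replicate": [1]})
        m = read_coverage({"s": f}, meta)
        assert m.n_sites == 1
        assert m.cov[0, 0] == 10
        assert m.meth[0, 0] == 5

    def test_empty_file_gives_empty_matrix_with_warning(self, tmp_path, caplog):
        f = tmp_path / "s.cov"
        f.write_text("")
        meta = pd.DataFrame({"sample": ["s"], "lineage": ["ICM"],
                             "methionine": [10], "replicate": [1]})
        with caplog.at_level("WARNING"):
            m = read_coverage({"s": f}, meta)
        assert m.n_sites == 0
        assert "empty" in caplog.text

    def test_inconsistent_chromosome_naming_is_hard_error(self, tmp_path):
        (tmp_path / "a.cov").write_text("chr1\t100\t100\t50.0\t5\t5\n")
        (tmp_path / "b.cov").write_text("1\t100\t100\t50.0\t5\t5\n")
        meta = pd.DataFrame({"sample": ["a", "b"], "lineage": ["ICM"] * 2,
                             "methionine": [10, 50], "replicate": [1, 1]})
        with pytest.raises(ValueError, match="chromosome naming"):
            read_coverage({"a": tmp_path / "a.cov",
                           "b": tmp_path / "b.cov"}, meta)

    def test_generator_round_trip(self, dataset, matrix):
        """Counts re-read from disk equal what the generator wrote."""
        out, truth = dataset
        non_spike = (matrix.sites["chrom"] != truth.spikein_contig)
        assert int(non_spike.sum()) >= 6000
        assert matrix.cov.min() >= 1
        assert np.all(matrix.meth <= matrix.cov)


class TestUniteAndFilter:
    def test_low_coverage_site_dropped(self):
        m = tiny_matrix([[1, 1], [2, 2]], [[4, 10], [10, 10]])
        u = unite_and_filter(m, mincov=5)
        assert u.n_sites == 1
        assert u.sites["pos"].tolist() == [101]

    def test_masked_variant_position_dropped(self):
        m = tiny_matrix([[1, 1], [2, 2]], [[10, 10], [10, 10]])
        u = unite_and_filter(m, mincov=5, variant_mask=[("chr1", 100)])
        assert u.sites["pos"].tolist() == [101]

    def test_no_mask_full_coverage_is_identity(self):
        m = tiny_matrix([[1, 1], [2, 2]], [[10, 10], [10, 10]])
        u = unite_and_filter(m, mincov=5)
        assert u.n_sites == 2

    def test_raising_mincov_never_retains_more(self, matrix):
        counts = [unite_and_filter(matrix, mincov=c).n_sites
                  for c in (1, 5, 10, 20)]
        assert counts == sorted(counts, reverse=True)


class TestConversionQC:
    def test_pass_and_fail_rates(self):
        meth = np.array([[10], [990 - 980]])
        m = tiny_matrix([[10]], [[1000]],
                        samples=pd.DataFrame({"sample": ["s"],
                                              "lineage": ["ICM"],
                                              "methionine": [10],
                                              "replicate": [1]}))
        m.sites["chrom"] = ["lambda_spike"]
        qc = conversion_qc(m, "lambda_spike", min_rate=0.98)
        assert qc["rate"].iloc[0] == pytest.approx(0.99)
        assert bool(qc["passed"].iloc[0])

        m2 = tiny_matrix([[50]], [[1000]],
                         samples=pd.DataFrame({"sample": ["s"],
                                               "lineage": ["ICM"],
                                               "methionine": [10],
                                               "replicate": [1]}))
        m2.sites["chrom"] = ["lambda_spike"]
        qc2 = conversion_qc(m2, "lambda_spike", min_rate=0.98)
        assert qc2["rate"].iloc[0] == pytest.approx(0.95)
        assert not bool(qc2["passed"].iloc[0])

    def test_missing_spikein_not_assessable(self):
        m = tiny_matrix([[1, 1]], [[10, 10]])
        qc = conversion_qc(m, "lambda_spike")
        assert not qc["assessable"].any()
        assert qc["rate"].isna().all()

    def test_estimated_rate_on_synthetic_data(self, matrix, dataset):
        _, truth = dataset
        qc = conversion_qc(matrix, truth.spikein_contig)
        assert qc["assessable"].all()
        target = 1.0 - truth.conversion_failure_rate
        for r in qc["rate"]:
            se = 4 * np.sqrt(0.01 * 0.99 / 9000)
            assert r == pytest.approx(target, abs=max(se, 0.006))


def g_test_oracle(m1, u1, m2, u2):
    """Closed-form 2×2 likelihood-ratio chi-squared, written independently."""
    table = np.array([[m1, u1], [m2, u2]], dtype=float)
    total = table.sum()
    g = 0.0
    for i in range(2):
        for j in range(2):
            o = table[i, j]
            e = table[i].sum() * table[:, j].sum() / total
            if o > 0:
                g += 2.0 * o * math.log(o / e)
    from scipy.stats import chi2
    return g, float(chi2.sf(g, 1))


class TestDifferentialTest:
    def test_identical_counts_give_p_one(self):
        m = tiny_matrix([[5, 5]], [[10, 10]])
        rec = run_dmc_test(m, np.array([True, False]), np.array([False, True]))
        assert rec["meth_diff"].iloc[0] == 0.0
        assert rec["p_value"].iloc[0] == pytest.approx(1.0)

    def test_single_replicate_groups_match_g_test_oracle(self):
        # 30/10 vs 10/30 methylated/unmethylated
        m = tiny_matrix([[30, 10]], [[40, 40]])
        rec = run_dmc_test(m, np.array([True, False]), np.array([False, True]))
        g, p = g_test_oracle(30, 10, 10, 30)
        assert rec["p_value"].iloc[0] == pytest.approx(p, abs=1e-10)
        # Fisher-exact oracle agrees on the rejection decision
        _, p_fisher = fisher_exact([[30, 10], [10, 30]])
        assert (p < 0.05) == (p_fisher < 0.05)

    def test_deviance_equals_pooled_mode(self, icm_united):
        ga = icm_united.sample_mask(methionine=10)
        gb = icm_united.sample_mask(methionine=50)
        dev = run_dmc_test(icm_united, ga, gb, mode="deviance")
        pooled = run_dmc_test(icm_united, ga, gb, mode="pooled")
        # analytic identity; per-sample vs pooled arithmetic differs only
        # by floating-point accumulation
        np.testing.assert_allclose(dev["p_value"], pooled["p_value"],
                                   atol=1e-6)

    def test_group_label_swap_negates_diff_and_keeps_p(self, icm_united):
        ga = icm_united.sample_mask(methionine=10)
        gb = icm_united.sample_mask(methionine=50)
        ab = run_dmc_test(icm_united, ga, gb)
        ba = run_dmc_test(icm_united, gb, ga)
        np.testing.assert_allclose(ab["meth_diff"], -ba["meth_diff"],
                                   atol=1e-12)
        np.testing.assert_array_equal(ab["p_value"], ba["p_value"])

    def test_zero_coverage_group_sites_excluded(self):
        m = tiny_matrix([[0, 5], [3, 5]], [[0, 10], [10, 10]])
        rec = run_dmc_test(m, np.array([True, False]), np.array([False, True]))
        assert len(rec) == 1
        assert rec.attrs["n_excluded"] == 1

    def test_needs_a_sample_per_group(self, icm_united):
        with pytest.raises(ValueError, match="at least one sample"):
            run_dmc_test(icm_united, np.zeros(6, bool), np.ones(6, bool))


class TestFilterDmc:
    def test_exact_twenty_point_difference_dropped(self, feature_index):
        rec = pd.DataFrame({
            "chrom": ["chr1"] * 2, "pos": [10_100, 10_101], "strand": ".",
            "mean_a": [60.0, 61.0], "mean_b": [40.0, 40.0],
            "meth_diff": [20.0, 21.0], "p_value": [1e-9, 1e-9],
            "q_value": [1e-8, 1e-8], "direction": ["gain", "gain"],
        })
        kept = filter_dmc(rec, feature_index)
        assert kept["pos"].tolist() == [10_101]

    def test_intergenic_record_dropped_despite_significance(self, feature_index):
        rec = pd.DataFrame({
            "chrom": ["chr1"], "pos": [999_999], "strand": ".",
            "mean_a": [90.0], "mean_b": [30.0], "meth_diff": [60.0],
            "p_value": [1e-12], "q_value": [1e-9], "direction": ["gain"],
        })
        assert len(filter_dmc(rec, feature_index)) == 0

    def test_empty_input_gives_empty_output(self, feature_index):
        rec = pd.DataFrame(columns=["chrom", "pos", "strand", "mean_a",
                                    "mean_b", "meth_diff", "p_value",
                                    "q_value", "direction"])
        assert len(filter_dmc(rec, feature_index)) == 0

    def test_lowering_max_q_never_keeps_more(self, icm_united, feature_index):
        ga = icm_united.sample_mask(methionine=10)
        gb = icm_united.sample_mask(methionine=50)
        rec = run_dmc_test(icm_united, ga, gb)
        counts = [len(filter_dmc(rec, feature_index, max_q=q))
                  for q in (0.10, 0.05, 0.01, 0.001)]
        assert counts == sorted(counts, reverse=True)


class TestDirectionSummary:
    @pytest.mark.parametrize("gain,loss,pct_gain,pct_loss", [
        (2449, 7542, 24.5, 75.5),
        (2361, 10762, 18.0, 82.0),
        (6671, 5542, 54.6, 45.4),
        (3365, 4723, 41.6, 58.4),
    ])
    def test_published_count_arithmetic(self, gain, loss, pct_gain, pct_loss):
        s = summarize_direction({"gain": gain, "loss": loss})
        assert s.n_total == gain + loss
        assert s.pct_gain == pct_gain
        assert s.pct_loss == pct_loss

    def test_single_gain_record(self):
        s = summarize_direction(["gain"])
        assert (s.pct_gain, s.pct_loss) == (100.0, 0.0)

    def test_percentages_sum_to_hundred(self):
        s = summarize_direction({"gain": 7, "loss": 13})
        assert s.pct_gain + s.pct_loss == pytest.approx(100.0, abs=0.1)


class TestTranscriptGeneCounts:
    def test_two_transcripts_one_gene(self):
        rec = pd.DataFrame({"gene_id": ["G1", "G1"],
                            "transcript_id": ["G1.t1", "G1.t2"]})
        assert count_transcripts_genes(rec) == (2, 1)

    def test_empty(self):
        assert count_transcripts_genes(pd.DataFrame()) == (0, 0)

    def test_recovers_most_affected_genes(self, icm_united, feature_index,
                                          dataset):
        _, truth = dataset
        ga = icm_united.sample_mask(methionine=10)
        gb = icm_united.sample_mask(methionine=50)
        called = filter_dmc(run_dmc_test(icm_united, ga, gb), feature_index)
        _, n_genes = count_transcripts_genes(called)
        n_affected = len(truth.affected_genes)
        hit = set(called["gene_id"]) & {m["gene_id"]
                                        for m in truth.affected_genes}
        assert len(hit) >= 0.9 * n_affected
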