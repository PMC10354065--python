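"""gCIS statistics: TA counting, enrichment test, Bonferroni, exclusions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sbscreen.annotate import models_from_refflat
from sbscreen.gcis import (
    adjust_and_call,
    apply_exclusions,
    count_ta,
    gcis_test,
    run_gcis,
    ta_in_interval,
)
from sbscreen.io import INSERTION_COLUMNS


def binomial_upper_tail_by_summation(k, n, p):
    """P(X >= k) for X ~ Binomial(n, p) by direct summation of the pmf."""
    return float(sum(stats.binom.pmf(x, n, p) for x in range(k, n + 1)))


class TestCountTa:
    @pytest.mark.parametrize("seq,expected", [("TATA", 2), ("GGCC", 0), ("TA", 1), ("T", 0)])
    def test_hand_counts(self, seq, expected):
        assert count_ta(seq) == expected

    def test_random_sequence_matches_regex_style_oracle(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        oracle = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "TA")
        assert count_ta(seq) == oracle

    def test_subinterval_against_index(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=5_000))
        index = np.array([i for i in range(len(seq) - 1) if seq[i : i + 2] == "TA"])
        for start, end in [(0, 5000), (100, 400), (999, 1000), (2500, 2500)]:
            assert count_ta(seq, start, end) == ta_in_interval(index, start, end)

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            count_ta("ACGT", 3, 2)
        with pytest.raises(ValueError):
            count_ta("ACGT", 0, 10)


class TestGcisTest:
    def test_observed_equals_expected_is_null(self):
        expected, statistic, p = gcis_test(10, 10_000, 100, 100_000)
        assert expected == pytest.approx(10.0)
        assert statistic == 0.0
        assert p == 1.0

    def test_zero_observed_is_one_sided_floor(self):
        _, _, p = gcis_test(0, 1000, 10, 10_000)
        assert p == 1.0

    def test_untestable_gene_without_ta(self):
        assert gcis_test(5, 1000, 0, 10_000) == (0.0, 0.0, 1.0)

    def test_binomial_tail_matches_direct_summation(self):
        _, _, p = gcis_test(10, 1000, 100, 100_000)
        assert p == pytest.approx(binomial_upper_tail_by_summation(10, 1000, 0.001), rel=1e-9)

    def test_binomial_tail_on_random_instances(self):
        rng = np.random.default_rng(10)
        checked = 0
        while checked < 50:
            ta_gene = int(rng.integers(1, 200))
            ta_genome = int(rng.integers(10_000, 100_000))
            n = int(rng.integers(10, 2000))
            obs = int(rng.integers(0, 15))
            expected, _, p = gcis_test(obs, n, ta_gene, ta_genome)
            if obs <= expected:
                assert p == 1.0
                continue
            oracle = binomial_upper_tail_by_summation(obs, n, ta_gene / ta_genome)
            assert p == pytest.approx(oracle, rel=1e-8)
            checked += 1

    def test_chisq_agrees_with_binomial_for_moderate_p(self):
        """Normal-approximation error bounds: ~25% rel. for p>=0.05, ~12% for p>=0.2."""
        rng = np.random.default_rng(11)
        for _ in range(300):
            ta_gene = int(rng.integers(50, 500))
            ta_genome = 100_000
            n = int(rng.integers(5000, 50_000))
            expected = n * ta_gene / ta_genome
            if not 20 <= expected <= 100:
                continue
            obs = int(rng.binomial(n, ta_gene / ta_genome))
            _, _, pb = gcis_test(obs, n, ta_gene, ta_genome, method="binomial")
            _, _, pc = gcis_test(obs, n, ta_gene, ta_genome, method="chisq")
            if pb >= 0.2:
                assert abs(pc - pb) <= 0.12 * pb
            elif pb >= 0.05:
                assert abs(pc - pb) <= 0.25 * pb

    def test_chisq_falls_back_to_exact_below_expected_five(self):
        _, _, pc = gcis_test(8, 1000, 10, 10_000, method="chisq")
        _, _, pb = gcis_test(8, 1000, 10, 10_000, method="binomial")
        assert pc == pb


class TestAdjustAndCall:
    @pytest.mark.parametrize(
        "p_raw,m,p_adj,significant",
        [(0.001, 100, 0.1, False), (1e-6, 100, 1e-4, True), (0.5, 10_000, 1.0, False)],
    )
    def test_bonferroni_arithmetic(self, p_raw, m, p_adj, significant):
        results = pd.DataFrame({"p_raw": [p_raw] + [1.0] * (m - 1)})
        out = adjust_and_call(results)
        assert out.loc[0, "p_adj"] == pytest.approx(p_adj)
        assert bool(out.loc[0, "significant"]) is significant


class TestExclusions:
    @staticmethod
    def _insertions(rows):
        return pd.DataFrame(rows, columns=INSERTION_COLUMNS)

    def test_donor_chromosome_excluded_per_arm(self):
        ins = self._insertions(
            [
                ("sA", "merged", "chr9", 10, "+", 5),
                ("sA", "merged", "chr12", 10, "+", 5),
                ("sB", "merged", "chr9", 10, "+", 5),
                ("sB", "merged", "chr12", 10, "+", 5),
            ]
        )
        meta = pd.DataFrame(
            {"sample_id": ["sA", "sB"], "screen_arm": ["armA", "armB"]}
        )
        kept, donors = apply_exclusions(ins, meta, {"armA": "chr9", "armB": "chr12"})
        assert donors == {"chr9", "chr12"}
        kept_keys = set(zip(kept["sample_id"], kept["chrom"]))
        assert kept_keys == {("sA", "chr12"), ("sB", "chr9")}

    def test_unknown_arm_is_an_error(self):
        ins = self._insertions([("sX", "merged", "chr1", 10, "+", 5)])
        meta = pd.DataFrame({"sample_id": ["sX"], "screen_arm": ["armZ"]})
        with pytest.raises(ValueError, match="armZ"):
            apply_exclusions(ins, meta, {"armA": "chr9"})

    def test_no_exclusions_is_identity(self):
        ins = self._insertions([("sA", "merged", "chr1", 10, "+", 5)])
        meta = pd.DataFrame({"sample_id": ["sA"], "screen_arm": ["armA"]})
        kept, donors = apply_exclusions(ins, meta, None)
        pd.testing.assert_frame_equal(kept, ins)
        assert donors == set()

    def test_blacklisted_gene_absent_from_results(self, default_screen):
        cfg, _, genes, ta_index, table, truth = default_screen
        models = models_from_refflat(genes)
        sub = table[table["library"] == "IRL"].head(2000)
        with_artifact = run_gcis(sub, models, ta_index)
        without = run_gcis(sub, models, ta_index, blacklist={cfg.artifact_gene})
        assert cfg.artifact_gene in set(with_artifact["gene_name"])
        assert cfg.artifact_gene not in set(without["gene_name"])


class TestRunGcis:
    def test_expected_sum_bounded_by_cohort_size(self, default_screen):
        cfg, _, genes, ta_index, table, _ = default_screen
        models = models_from_refflat(genes)
        sub = table[table["library"] == "IRL"].head(5000)
        res = run_gcis(sub, models, ta_index, donor_map=None)
        n = res["n_insertions_cohort"].iloc[0]
        assert res["expected"].sum() <= n
        # expected = n * ta_in_gene / ta_genome, row by row
        recomputed = n * res["ta_in_gene"] / res["ta_genome"]
        assert np.allclose(res["expected"], recomputed)

    def test_family_is_tested_genes(self, default_screen):
        cfg, _, genes, ta_index, table, _ = default_screen
        models = models_from_refflat(genes)
        sub = table[table["library"] == "IRL"].head(5000)
        res = run_gcis(sub, models, ta_index, blacklist={cfg.artifact_gene})
        m = len(res)
        assert np.allclose(res["p_adj"], np.minimum(res["p_raw"] * m, 1.0))

    def test_deterministic_ordering(self, default_screen):
        _, _, genes, ta_index, table, _ = default_screen
        models = models_from_refflat(genes)
        sub = table[table["library"] == "IRL"].head(3000)
        a = run_gcis(sub, models, ta_index)
        b = run_gcis(sub, models, ta_index)
        pd.testing.assert_frame_equal(a, b)
        assert (a.sort_values(["p_adj", "gene_name"]).index == a.index).all()
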