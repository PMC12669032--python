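"""Pooled Tn-seq fitness: masking, TTR, resampling test, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from xenoscreen.simulate import SimulationConfig, TnseqConfig, gen_tnseq
from xenoscreen.tnseq import (
    TnFitnessScreen,
    call_gene_hits,
    central_mask,
    doublings_correct,
    gene_aggregate,
    resampling_test,
    term_enrichment,
    ttr_normalize,
)


class TestCentralMask:
    @pytest.mark.parametrize("pos,kept", [(50, True), (5, False), (95, False)])
    def test_central_80_percent(self, pos, kept):
        assert central_mask(pos, 1, 100) is kept

    def test_exhaustive_enumeration_keeps_80_of_100(self):
        kept = [p for p in range(1, 101) if central_mask(p, 1, 100)]
        assert len(kept) == 80
        assert kept[0] == 11 and kept[-1] == 90

    def test_intergenic_position_is_false(self):
        assert central_mask(200, 1, 100) is False


class TestTtrNormalize:
    @staticmethod
    def _counts(cols):
        return pd.DataFrame({k: np.asarray(v, float) for k, v in cols.items()})

    def test_identical_samples_get_equal_factors(self, rng):
        col = rng.poisson(50, 100).astype(float)
        counts = self._counts({"a": col, "b": col.copy()})
        _, factors = ttr_normalize(counts)
        assert factors["a"] == pytest.approx(factors["b"])

    def test_doubled_sample_inverts_scale(self, rng):
        col = rng.poisson(50, 100).astype(float) + 1
        counts = self._counts({"a": col, "b": 2 * col})
        normalized, factors = ttr_normalize(counts)
        assert factors["b"] == pytest.approx(factors["a"] / 2)
        np.testing.assert_allclose(normalized["a"], normalized["b"])

    def test_trimming_absorbs_extreme_outlier(self, rng):
        col = rng.poisson(50, 500).astype(float) + 1
        spiked = col.copy()
        spiked[0] *= 1000
        _, f_clean = ttr_normalize(self._counts({"a": col, "b": col}))
        _, f_spike = ttr_normalize(self._counts({"a": spiked, "b": col}))
        assert abs(f_spike["a"] / f_clean["a"] - 1) < 0.02

    def test_sparse_sample_rejected(self):
        counts = self._counts({"a": [5.0] * 30, "b": [0.0] * 30})
        with pytest.raises(ValueError, match="nonzero"):
            ttr_normalize(counts)


class TestGeneAggregate:
    def _inputs(self):
        genes = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "start": [1, 201], "end": [100, 300],
             "strand": ["+", "+"]}
        )
        sites = pd.DataFrame(
            {"position": [50, 60, 205, 202], "gene_id": ["g1", "g1", "g2", "g2"],
             "barcode_id": list("abcd")}
        )
        counts = pd.DataFrame({"s1": [5.0, 7.0, 3.0, 9.0]})
        return genes, sites, counts

    def test_sums_central_sites(self):
        genes, sites, counts = self._inputs()
        out, untestable = gene_aggregate(counts, sites, genes)
        assert out.loc["g1", "s1"] == pytest.approx(12.0)

    def test_fully_masked_gene_is_untestable(self):
        genes, sites, counts = self._inputs()
        # g2's sites at offsets 4 and 1 are in the 10% head -> masked
        out, untestable = gene_aggregate(counts, sites, genes)
        assert untestable == ["g2"]
        assert "g2" not in out.index

    def test_retained_plus_masked_counts_conserve_total(self):
        genes, sites, counts = self._inputs()
        out, _ = gene_aggregate(counts, sites, genes)
        kept = [central_mask(p, 1, 100) or central_mask(p, 201, 300)
                for p in sites["position"]]
        masked_total = counts.loc[[not k for k in kept], "s1"].sum()
        assert out["s1"].sum() + masked_total == pytest.approx(counts["s1"].sum())


def _exhaustive_p(cond, ctrl):
    """Enumerate every assignment of samples to arms; two-sided mean-diff p."""
    pooled = np.concatenate([cond, ctrl])
    n, k = pooled.size, len(cond)
    obs = np.mean(cond) - np.mean(ctrl)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), k):
        mask = np.zeros(n, bool)
        mask[list(combo)] = True
        stat = pooled[mask].mean() - pooled[~mask].mean()
        total += 1
        if abs(stat) >= abs(obs) - 1e-12:
            count += 1
    return count / total


class TestResamplingTest:
    def test_identical_arms_are_null(self):
        lfc, p = resampling_test([10.0, 10.0], [10.0, 10.0, 10.0], seed=0)
        assert lfc == 0.0
        assert p == 1.0

    def test_2v3_design_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            cond = rng.poisson(30, 2).astype(float)
            ctrl = rng.poisson(60, 3).astype(float)
            _, p = resampling_test(cond, ctrl, seed=1)
            assert p == pytest.approx(_exhaustive_p(cond, ctrl), abs=1e-12)

    def test_pseudocount_fold_change(self):
        lfc, _ = resampling_test([3.0, 3.0], [63.0, 63.0], seed=0)
        assert lfc == pytest.approx(math.log2(4.0 / 64.0))
        assert lfc == pytest.approx(-4.0)

    def test_sampled_agrees_with_exhaustive_within_monte_carlo_error(self, rng):
        cond = rng.poisson(30, 3).astype(float)
        ctrl = rng.poisson(45, 3).astype(float)
        _, p_ex = resampling_test(cond, ctrl, seed=2, exhaustive=True)
        _, p_s = resampling_test(cond, ctrl, n_perm=20000, seed=2, exhaustive=False)
        assert abs(p_s - p_ex) <= 2 / math.sqrt(20000)

    def test_fixed_seed_is_bit_reproducible(self):
        cond, ctrl = [12.0, 40.0, 9.0], [33.0, 21.0, 50.0]
        runs = {
            resampling_test(cond, ctrl, seed=7, exhaustive=False)[1] for _ in range(3)
        }
        assert len(runs) == 1

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            resampling_test([], [1.0, 2.0])


class TestDoublingsCorrect:
    @pytest.mark.parametrize(
        "lfc,gc,gk,expected", [(-1.0, 5.0, 10.0, -2.0), (0.7, 6.0, 6.0, 0.7), (0.0, 2.0, 9.0, 0.0)]
    )
    def test_per_doubling_rescaling(self, lfc, gc, gk, expected):
        assert doublings_correct(lfc, gc, gk) == pytest.approx(expected)

    def test_nonpositive_doublings_rejected(self):
        with pytest.raises(ValueError):
            doublings_correct(1.0, 0.0, 5.0)


class TestCallGeneHits:
    def test_joint_threshold_rule(self):
        df = pd.DataFrame(
            {"gene_id": list("abc"), "log2fc": [0.3, 0.1, 2.0], "p_adj": [0.01, 0.01, 0.2]}
        )
        out = call_gene_hits(df)
        assert list(out["is_hit"]) == [True, False, False]
        assert out.loc[0, "direction"] == 1


class TestTermEnrichment:
    def test_matches_hypergeometric_tail_oracle(self):
        # table (a, b, c, d) = (5, 5, 5, 85)
        background = {f"g{i}" for i in range(100)}
        hits = {f"g{i}" for i in range(10)}
        term_map = {f"g{i}": ["T"] for i in list(range(5)) + list(range(10, 15))}
        out = term_enrichment(hits, background, term_map)
        p = float(out.loc[out["term_id"] == "T", "p"].iloc[0])
        # oracle: sum of hypergeometric pmf over k >= 5 of 10 draws from 10/100
        oracle = sum(
            math.comb(10, k) * math.comb(90, 10 - k) / math.comb(100, 10)
            for k in range(5, 11)
        )
        assert p == pytest.approx(oracle, abs=1e-12)

    def test_universal_term_is_not_enriched(self):
        background = {f"g{i}" for i in range(20)}
        hits = {f"g{i}" for i in range(5)}
        out = term_enrichment(hits, background, {g: ["ALL"] for g in background})
        assert float(out["p"].iloc[0]) == pytest.approx(1.0)

    def test_hits_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            term_enrichment({"x"}, {"a"}, {})


class TestTnModel:
    def test_planted_depletion_recovered(self):
        cfg = SimulationConfig(
            seed=31,
            tnseq=TnseqConfig(n_genes=300, n_cond=8, n_ctrl=8, n_planted=10,
                              planted_log2fc=-3.0),
        )
        table, genes, truth = gen_tnseq(cfg)
        res = TnFitnessScreen(table, genes).fit("treatment", "control", seed=32)
        hits = set(res.hits()["gene_id"])
        planted = set(truth.gene_fitness)
        assert len(hits & planted) / len(planted) >= 0.9

    def test_doublings_correction_rescales_fold_changes(self):
        cfg = SimulationConfig(
            seed=33,
            tnseq=TnseqConfig(n_genes=100, n_cond=3, n_ctrl=3, n_planted=5,
                              planted_log2fc=-2.0, doublings_cond=4.0,
                              doublings_ctrl=8.0),
        )
        table, genes, _ = gen_tnseq(cfg)
        res = TnFitnessScreen(table, genes).fit("treatment", "control", seed=34)
        np.testing.assert_allclose(
            res.results["log2fc_corrected"], res.results["log2fc"] * 2.0
        )

    def test_enrichment_flags_term_of_planted_genes(self):
        cfg = SimulationConfig(
            seed=35,
            tnseq=TnseqConfig(n_genes=200, n_cond=8, n_ctrl=8, n_planted=10,
                              planted_log2fc=-3.0),
        )
        table, genes, truth = gen_tnseq(cfg)
        res = TnFitnessScreen(table, genes).fit("treatment", "control", seed=36)
        term_map = {g: ["planted_pathway"] for g in truth.gene_fitness}
        term_map.update({g: ["other"] for g in genes["gene_id"] if g not in term_map})
        enr = res.enrichment(term_map)
        row = enr[enr["term_id"] == "planted_pathway"].iloc[0]
        assert row.p_adj < 0.01
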