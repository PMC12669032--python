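"""Monoculture screen: normalization, z-scores, hit calling, MICs."""

import math

import numpy as np
import pandas as pd
import pytest

from xenoscreen.io import PlateMap, WellEntry
from xenoscreen.screen import (
    MonocultureScreen,
    call_compound_hits,
    call_replicate_hit,
    determine_mic,
    normalize_dmso,
    normalize_edge,
    summarize_hits,
    validation_concordance,
    zscore_pvalue,
)
from xenoscreen.simulate import SimulationConfig, gen_screen


def _plate_map(controls=("A01", "A02", "A03"), treatments=("B01",)):
    wells = {w: WellEntry("DMSO", 0.0, "vehicle_control") for w in controls}
    wells.update({w: WellEntry(f"cpd_{w}", 20.0, "treatment") for w in treatments})
    return PlateMap("P1", wells)


class TestNormalizeDmso:
    def test_median_of_controls_anchors_normalization(self):
        pmap = _plate_map(controls=[f"A{i:02d}" for i in range(1, 9)])
        aucs = {f"A{i:02d}": v for i, v in enumerate([10, 10, 10, 12, 12, 12, 8, 8], 1)}
        aucs["B01"] = 5.0
        out = normalize_dmso(aucs, pmap)
        assert out["B01"] == pytest.approx(0.5)
        control_norms = [out[w] for w in pmap.control_wells]
        assert np.median(control_norms) == pytest.approx(1.0)

    def test_uniform_plate_normalizes_to_one(self):
        pmap = _plate_map()
        aucs = {w: 7.0 for w in ["A01", "A02", "A03", "B01"]}
        assert all(v == pytest.approx(1.0) for v in normalize_dmso(aucs, pmap).values())

    def test_dead_controls_reject_plate(self):
        pmap = _plate_map()
        aucs = {"A01": 0.0, "A02": 0.0, "A03": 0.0, "B01": 5.0}
        with pytest.raises(ValueError, match="control median"):
            normalize_dmso(aucs, pmap)


class TestNormalizeEdge:
    @staticmethod
    def _grid(values):
        return {
            f"{chr(65 + r)}{c + 1:02d}": values[r][c]
            for r in range(len(values))
            for c in range(len(values[0]))
        }

    def test_doubled_row_corrected_to_parity(self):
        base = [[1.0] * 6 for _ in range(4)]
        base[0] = [2.0] * 6
        out = normalize_edge(self._grid(base))
        vals = list(out.values())
        assert max(vals) - min(vals) < 1e-9

    def test_uniform_plate_unchanged(self):
        out = normalize_edge(self._grid([[3.0] * 6 for _ in range(4)]))
        assert all(v == pytest.approx(3.0) for v in out.values())

    def test_planted_row_col_effects_removed(self, rng):
        # multiplicative row x column effects on a lognormal plate: correction
        # shrinks the spread of row/column medians below 5%
        row_f = np.exp(rng.normal(0, 0.4, 8))
        col_f = np.exp(rng.normal(0, 0.4, 12))
        base = np.exp(rng.normal(0, 0.05, (8, 12))) * 10
        plate = base * row_f[:, None] * col_f[None, :]
        grid = self._grid(plate.tolist())
        out = normalize_edge(grid)
        corrected = np.array([[out[f"{chr(65 + r)}{c + 1:02d}"] for c in range(12)] for r in range(8)])

        def med_spread(mat, axis):
            med = np.median(mat, axis=axis)
            return (med.max() - med.min()) / np.median(med)

        assert med_spread(plate, 1) > 0.5 or med_spread(plate, 0) > 0.5
        assert med_spread(corrected, 1) < 0.05
        assert med_spread(corrected, 0) < 0.05

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            normalize_edge({"A01": 1.0, "A02": 2.0})


class TestZscore:
    def test_value_at_control_median_is_null(self):
        z, p = zscore_pvalue(1.0, [0.9, 1.0, 1.1])
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_matches_error_function_oracle(self):
        # controls with median 1.0 and sd exactly 0.1
        z, p = zscore_pvalue(0.8, [0.9, 1.0, 1.1])
        assert z == pytest.approx(-2.0)
        oracle = 0.5 * (1 + math.erf(-2.0 / math.sqrt(2)))
        assert p == pytest.approx(oracle, abs=1e-12)

    def test_growth_stimulation_never_a_hit(self):
        _, p = zscore_pvalue(1.3, [0.9, 1.0, 1.1])
        assert p > 0.5

    def test_zero_control_sd_rejected(self):
        with pytest.raises(ValueError, match="s.d."):
            zscore_pvalue(0.5, [1.0, 1.0, 1.0])


class TestHitRules:
    @pytest.mark.parametrize(
        "p_adj,norm_auc,expected",
        [
            (0.01, 0.7, True),
            (0.01, 0.85, False),  # effect-size filter
            (0.2, 0.5, False),    # significance filter
        ],
    )
    def test_replicate_rule(self, p_adj, norm_auc, expected):
        assert call_replicate_hit(p_adj, norm_auc) is expected

    @pytest.mark.parametrize(
        "flags,is_hit,n_sig",
        [([True, True, False], True, 2), ([True, False, False], False, 1),
         ([True, True, True], True, 3)],
    )
    def test_two_of_three_replicates(self, flags, is_hit, n_sig):
        out = call_compound_hits({("c", "s"): flags})
        row = out.iloc[0]
        assert bool(row.is_hit) is is_hit
        assert row.n_significant_reps == n_sig

    def test_pair_without_replicates_marked_missing(self):
        out = call_compound_hits({("c", "s"): []})
        assert bool(out.iloc[0].missing)
        assert not bool(out.iloc[0].is_hit)


class TestSummarizeHits:
    def test_toy_matrix_counts(self):
        rows = []
        for s in range(8):
            rows.append(("A", f"s{s}", True, 0.5))
        rows.append(("B", "s0", True, 0.05))
        rows.append(("C", "s0", False, 0.9))
        df = pd.DataFrame(rows, columns=["compound_id", "strain_id", "is_hit", "mean_norm_auc"])
        s = summarize_hits(df, n_species=22)
        assert s.n_interactions == 9
        assert s.n_active_compounds == 2
        assert s.n_broad_compounds == 1  # A: 8 > 22/3
        assert s.n_strong_compounds == 1  # B at 0.05 < 0.1

    def test_empty_matrix(self):
        df = pd.DataFrame(columns=["compound_id", "strain_id", "is_hit", "mean_norm_auc"])
        df["is_hit"] = df["is_hit"].astype(bool)
        s = summarize_hits(df, n_species=22)
        assert (s.n_interactions, s.n_active_compounds, s.n_broad_compounds,
                s.n_strong_compounds) == (0, 0, 0, 0)


class TestDetermineMic:
    def test_lowest_qualifying_concentration(self):
        r = determine_mic({2.5: 0.9, 5: 0.4, 10: 0.05, 20: 0.02})
        assert r.mic == 10 and not r.censored

    def test_censored_above_max_dose(self):
        r = determine_mic({2.5: 0.9, 5: 0.8, 10: 0.5, 20: 0.3})
        assert r.censored and str(r) == ">20"

    def test_non_monotone_series_uses_literal_rule(self):
        r = determine_mic({2.5: 0.05, 5: 0.6, 10: 0.02})
        assert r.mic == 2.5

    def test_monotone_under_stronger_inhibition(self, rng):
        concs = [2.5, 5, 10, 20]
        values = dict(zip(concs, [0.9, 0.5, 0.15, 0.08]))
        base = determine_mic(values)
        for scale in (0.9, 0.5, 0.1):
            stronger = determine_mic({c: v * scale for c, v in values.items()})
            if not stronger.censored and not base.censored:
                assert stronger.mic <= base.mic


class TestValidationConcordance:
    def test_confirmed_fraction_arithmetic(self):
        hits = pd.DataFrame(
            {"compound_id": list("abcd"), "strain_id": ["s"] * 4, "is_hit": [True] * 4}
        )
        validation = {
            ("a", "s"): {10.0: (0.3, 0.001)},
            ("b", "s"): {20.0: (0.5, 0.01)},
            ("c", "s"): {20.0: (0.9, 0.5)},   # not confirmed
            ("d", "s"): {40.0: (0.1, 0.001)},  # above main dose: not counted
        }
        n_conf, n_tested, frac = validation_concordance(hits, validation)
        assert (n_conf, n_tested) == (2, 4)
        assert frac == pytest.approx(0.5)

    def test_empty_overlap_reported_missing(self):
        hits = pd.DataFrame({"compound_id": ["a"], "strain_id": ["s"], "is_hit": [True]})
        assert validation_concordance(hits, {}) == (0, 0, None)

    def test_resimulated_screen_confirms_planted_hits(self):
        # same planted effects, independent noise: an independent validation
        # experiment should confirm nearly all main-screen hits
        cfg = SimulationConfig(seed=11, n_compounds=87, n_strains=4)
        curves, maps, truth = gen_screen(cfg)
        main = MonocultureScreen(curves, maps).fit()
        curves2, maps2, _ = gen_screen(cfg, truth=truth)
        val = MonocultureScreen(curves2, maps2).fit()
        validation = {}
        for (cpd, strain), grp in val.wells.groupby(["compound_id", "strain_id"]):
            validation[(cpd, strain)] = {
                20.0: (float(grp["norm_auc"].mean()), float(grp["p_adj"].min()))
            }
        _, n_tested, frac = validation_concordance(main.hit_matrix, validation)
        assert n_tested > 10
        assert frac >= 0.9


class TestScreenModel:
    def test_controls_have_null_z_distribution(self):
        cfg = SimulationConfig(seed=3, n_compounds=87, n_strains=2, hit_fraction=0.0)
        curves, maps, _ = gen_screen(cfg)
        model = MonocultureScreen(curves, maps)
        res = model.fit()
        # control-anchored normalization: treated-well z median near 0 under null
        assert abs(float(res.wells["z"].median())) < 0.3
        assert res.hit_matrix["is_hit"].mean() < 0.01

    def test_edge_correction_rescues_hits_on_gradient_plates(self):
        # strong row/column gradients drown the control s.d. unless corrected
        cfg = SimulationConfig(seed=17, n_compounds=87, n_strains=2,
                               edge_effect_amplitude=0.3, hit_fraction=0.1)
        curves, maps, truth = gen_screen(cfg)
        model = MonocultureScreen(curves, maps)

        def sensitivity(res):
            hm = res.hit_matrix
            called = set(map(tuple, hm.loc[hm["is_hit"], ["compound_id", "strain_id"]].values))
            return len(called & set(truth.hits)) / len(truth.hits)

        assert sensitivity(model.fit(edge_correct=True)) >= 0.9
        assert sensitivity(model.fit(edge_correct=False)) < 0.5

    def test_summary_text_reports_counts(self):
        cfg = SimulationConfig(seed=5, n_compounds=87, n_strains=2)
        curves, maps, _ = gen_screen(cfg)
        res = MonocultureScreen(curves, maps).fit()
        text = res.summary()
        assert "interactions" in text and "strains tested" in text
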