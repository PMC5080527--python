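import numpy as np
import pytest

import raschval as rv
from raschval.dif import DtfResult, _strata_tables
from raschval.errors import ValidationError


def _dif_data(seed=0, **kwargs):
    spec = kwargs.pop("dif_spec", [])
    cov = kwargs.pop("covariate_names", ["g"]) if not spec else []
    return rv.generate_responses(
        rv.SyntheticConfig(n_persons=500, seed=seed, dif_spec=spec,
                           covariate_names=cov, **kwargs)
    )[0]


class TestMantelHaenszel:
    def test_single_stratum_equals_corrected_chi2(self):
        """With one score stratum, MH reduces to the 2x2 continuity-corrected test."""
        # two complementary items: everyone scores exactly 1
        rng = np.random.default_rng(5)
        a = (rng.random(300) < 0.5).astype(int)
        g = (rng.random(300) < 0.5).astype(int)
        data = rv.ResponseMatrix(
            np.column_stack([a, 1 - a]), ["x", "y"], {"g": g}
        )
        res = rv.mantel_haenszel(data, "x", "g")
        assert res.n_strata == 1
        tab = np.array(
            [
                [np.sum((g == 1) & (a == 0)), np.sum((g == 1) & (a == 1))],
                [np.sum((g == 0) & (a == 0)), np.sum((g == 0) & (a == 1))],
            ],
            float,
        )
        # hand-computed continuity-corrected chi-square on the single table:
        # (|a - E[a]| - 1/2)^2 / Var(a), hypergeometric variance
        n = tab.sum()
        row, col = tab.sum(1), tab.sum(0)
        e00 = row[0] * col[0] / n
        var00 = row.prod() * col.prod() / (n**2 * (n - 1))
        chi2 = (np.abs(tab[0, 0] - e00) - 0.5) ** 2 / var00
        assert res.mh_chi2 == pytest.approx(chi2, rel=1e-6)

    def test_planted_uniform_dif_is_flagged(self):
        data = _dif_data(seed=1, dif_spec=[rv.DifSpec("sleep", "g", uniform_shift=1.0)])
        res = rv.mantel_haenszel(data, "sleep", "g")
        assert res.mh_p < 0.05

    def test_log_or_orientation_matches_planted_shift(self):
        data = rv.generate_responses(
            rv.SyntheticConfig(
                n_persons=5000,
                seed=42,
                dif_spec=[rv.DifSpec("sleep", "g", uniform_shift=1.0)],
            )
        )[0]
        res = rv.mantel_haenszel(data, "sleep", "g")
        assert res.mh_log_or == pytest.approx(1.0, abs=0.15)

    def test_invariant_to_swapping_group_labels(self):
        data = _dif_data(seed=3)
        res = rv.mantel_haenszel(data, "sad", "g")
        flipped = rv.ResponseMatrix(
            data.responses, data.item_labels, {"g": 1 - data.covariates["g"]}
        )
        res2 = rv.mantel_haenszel(flipped, "sad", "g")
        assert res.mh_chi2 == pytest.approx(res2.mh_chi2, rel=1e-9)
        assert res.mh_log_or == pytest.approx(-res2.mh_log_or, rel=1e-9)

    def test_single_level_covariate_rejected(self):
        data = _dif_data(seed=4)
        bad = rv.ResponseMatrix(
            data.responses, data.item_labels, {"g": np.zeros(data.n_persons, int)}
        )
        with pytest.raises(ValidationError, match="single level"):
            rv.mantel_haenszel(bad, "sad", "g")


class TestBreslowDay:
    def test_nonuniform_dif_detected_where_mh_is_weak(self):
        hits_bd = 0
        for s in range(8):
            data = _dif_data(
                seed=40 + s, dif_spec=[rv.DifSpec("sad", "g", nonuniform_slope_ratio=2.5)]
            )
            if rv.breslow_day(data, "sad", "g").bd_p < 0.05:
                hits_bd += 1
        assert hits_bd >= 4

    def test_invariant_to_swapping_group_labels(self):
        data = _dif_data(seed=6)
        a = rv.breslow_day(data, "sleep", "g")
        flipped = rv.ResponseMatrix(
            data.responses, data.item_labels, {"g": 1 - data.covariates["g"]}
        )
        b = rv.breslow_day(flipped, "sleep", "g")
        assert a.bd_chi2 == pytest.approx(b.bd_chi2, rel=1e-9)

    def test_fewer_than_two_strata_reported_untestable(self):
        rng = np.random.default_rng(5)
        a = (rng.random(200) < 0.5).astype(int)
        g = (rng.random(200) < 0.5).astype(int)
        data = rv.ResponseMatrix(np.column_stack([a, 1 - a]), ["x", "y"], {"g": g})
        res = rv.breslow_day(data, "x", "g")
        assert "breslow_day" in res.untestable
        assert np.isnan(res.bd_p)

    def test_sparse_strata_are_merged(self):
        data = _dif_data(seed=7)
        merged = _strata_tables(data, "sad", "g", min_margin=10)
        unmerged = _strata_tables(data, "sad", "g", min_margin=0)
        assert len(merged) <= len(unmerged)
        for t in merged:
            assert min(t.sum(0).min(), t.sum(1).min()) >= 10


class TestDifDecision:
    @pytest.mark.parametrize(
        "mh_p,bd_p,expected",
        [(0.28, 0.55, False), (0.00, 0.54, True), (0.05, 0.05, False), (0.66, 0.01, True)],
    )
    def test_either_test_significant_flags(self, mh_p, bd_p, expected):
        assert rv.dif_decision(mh_p, bd_p, alpha=0.05) is expected

    def test_untestable_component_treated_as_nonsignificant(self):
        assert rv.dif_decision(0.30, np.nan) is False
        assert rv.dif_decision(0.01, np.nan) is True


class TestDtfTauSquared:
    def test_equal_effects_give_negative_floor_small_band(self):
        res = rv.dtf_tau_squared([(0.4, 0.5), (0.4, 0.5), (0.4, 0.5)])
        assert res.tau2 < 0
        assert res.effect_band == "small"

    def test_hand_plugged_two_item_case(self):
        res = rv.dtf_tau_squared([(0.0, 1.0), (1.0, 1.0)])
        assert res.tau2 == pytest.approx(-0.75)
        assert res.effect_band == "small"

    def test_large_dispersion_banded_large(self):
        res = rv.dtf_tau_squared([(-1.0, 0.01), (1.0, 0.01)])
        assert res.tau2 == pytest.approx(0.99, abs=0.01)
        assert res.effect_band == "large"

    def test_invariant_to_shifting_all_effects(self):
        items = [(0.1, 0.3), (0.5, 0.2), (-0.2, 0.4)]
        shifted = [(l + 2.0, v) for l, v in items]
        assert rv.dtf_tau_squared(items).tau2 == pytest.approx(
            rv.dtf_tau_squared(shifted).tau2, rel=1e-9
        )

    def test_band_boundaries_fall_to_lower_band(self):
        assert DtfResult.band(0.07) == "small"
        assert DtfResult.band(0.14) == "medium"
        assert DtfResult.band(0.141) == "large"

    def test_fewer_than_two_items_rejected(self):
        with pytest.raises(ValidationError):
            rv.dtf_tau_squared([(0.1, 0.2)])


def test_dif_analysis_null_scale_is_clean():
    data = _dif_data(seed=8)
    results, dtf = rv.dif_analysis(data, "g")
    assert len(results) == data.n_items
    assert dtf.effect_band == "small"
    assert sum(r.flagged for r in results) <= 1
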