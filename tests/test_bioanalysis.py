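"""Assay analyzers: fold change, stoichiometry, growth, survival, ROS, IC50."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from celldose import bioanalysis as ba
from celldose import synth
from celldose.errors import AlignmentError, FitError, InvalidArgumentError


class TestFoldChange:
    @pytest.mark.parametrize("treated,control,expected", [
        (250.0, 150.0, 1.7),   # cytoplasmic iron enrichment
        (430.0, 200.0, 2.2),   # nuclear iron enrichment
    ])
    def test_compartment_enrichment(self, treated, control, expected):
        _, reported = ba.fold_change(treated, control)
        assert reported == expected

    def test_identity(self):
        raw, reported = ba.fold_change(123.4, 123.4)
        assert raw == 1.0 and reported == 1.0

    @given(t=st.floats(1.0, 1e3), c=st.floats(1.0, 1e3),
           a=st.floats(0.01, 100.0))
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance(self, t, c, a):
        assert ba.fold_change(a * t, a * c)[0] == pytest.approx(
            ba.fold_change(t, c)[0])

    def test_zero_control_raises(self):
        with pytest.raises(ZeroDivisionError):
            ba.fold_change(1.0, 0.0)


class TestBFeRatio:
    def test_theoretical_stoichiometric_ratio(self):
        # 18 boron atoms and one iron per anion, as a mass ratio
        assert ba.STOICHIOMETRIC_B_FE_MASS_RATIO == pytest.approx(
            18 * 10.811 / 55.845)
        assert ba.STOICHIOMETRIC_B_FE_MASS_RATIO == pytest.approx(3.484, abs=5e-3)

    def test_constructed_records_recover_ratio_exactly(self):
        rows = []
        for comp in ("cytoplasm", "nucleus"):
            rows.append(("B", comp, 3.484 * 10.0, "treated", 0))
            rows.append(("Fe", comp, 10.0, "treated", 0))
        records = pd.DataFrame(rows, columns=[
            "element", "compartment", "amount_ng_per_1e6_cells", "group",
            "replicate"])
        out = ba.b_fe_ratio(records)
        for comp in ("cytoplasm", "nucleus"):
            assert out["ratios"][comp] == pytest.approx(3.484)

    def test_generator_round_trip_noise_free(self):
        records, truth = synth.gen_icpms_uptake(cv=0.0, seed=1)
        out = ba.b_fe_ratio(records)
        for comp in ("cytoplasm", "nucleus"):
            assert out["ratios"][comp] == pytest.approx(
                truth["b_fe_mass_ratio"], rel=1e-12)

    def test_noisy_generator_ratio_near_stoichiometry(self):
        hits = 0
        for seed in range(40):
            records, _ = synth.gen_icpms_uptake(cv=0.10, n=6, seed=seed)
            r = ba.b_fe_ratio(records)["ratios"]["nucleus"]
            hits += 3.0 <= r <= 4.0
        assert hits >= 38   # ~95% coverage of the [3, 4] window

    def test_missing_element_names_compartment(self):
        records = pd.DataFrame(
            [("B", "nucleus", 1.0, "treated", 0)],
            columns=["element", "compartment", "amount_ng_per_1e6_cells",
                     "group", "replicate"])
        with pytest.raises(KeyError, match="nucleus"):
            ba.b_fe_ratio(records)


class TestGrowthRate:
    def test_formula(self):
        curve = ba.GrowthCurve([0, 1, 2], [100.0, 300.0, 50.0])
        assert ba.growth_rate(curve, 1) == pytest.approx(200.0)
        assert ba.growth_rate(curve, 0) == 0.0
        assert ba.growth_rate(curve, 2) == pytest.approx(-50.0)

    def test_scaling_invariance(self):
        a = ba.GrowthCurve([0, 3], [10.0, 25.0])
        b = ba.GrowthCurve([0, 3], [70.0, 175.0])
        assert ba.growth_rate(a, 3) == pytest.approx(ba.growth_rate(b, 3))

    def test_unsampled_time_raises(self):
        with pytest.raises(KeyError):
            ba.growth_rate(ba.GrowthCurve([0, 1], [1.0, 2.0]), 7)


class TestSurvivalFraction:
    def test_by_construction(self):
        assert ba.survival_fraction(50, 100, 0.5).fraction == pytest.approx(1.0)
        assert ba.survival_fraction(0, 100, 0.5).fraction == 0.0

    def test_clipped_flag(self):
        res = ba.survival_fraction(80, 100, 0.5)
        assert res.fraction > 1.0 and res.clipped

    def test_estimator_recovers_truth_over_many_seeds(self):
        sf_true = 0.4
        estimates = []
        for seed in range(1000):
            counts, truth = synth.gen_colony_counts(sf_true, seeded=150,
                                                    pe_control=0.5, wells=3,
                                                    seed=seed)
            sf = np.mean([ba.survival_fraction(
                int(c), truth["seeded"], truth["pe_control"]).fraction
                for c in counts])
            estimates.append(sf)
        assert np.mean(estimates) == pytest.approx(sf_true, abs=0.05)

    @pytest.mark.parametrize("args", [(5, 0, 0.5), (5, 100, 0.0),
                                      (5, 100, 1.5), (-1, 100, 0.5)])
    def test_invalid_inputs(self, args):
        with pytest.raises(InvalidArgumentError):
            ba.survival_fraction(*args)


class TestRosFold:
    def _series(self, values, times=(0.0, 1.0, 2.0)):
        rows = [(t, v, 0) for t, v in zip(times, values)]
        return pd.DataFrame(rows, columns=["time_h", "value", "replicate"])

    def test_identical_series_give_ones(self):
        s = self._series([5.0, 6.0, 7.0])
        out = ba.ros_fold(s, s)
        assert np.allclose(out["fold_change"], 1.0)

    def test_constant_doubling(self):
        out = ba.ros_fold(self._series([8.0, 8.0, 8.0]),
                          self._series([4.0, 4.0, 4.0]))
        assert np.allclose(out["fold_change"], 2.0)

    def test_growing_signal_gives_increasing_fold(self):
        treated, _ = synth.gen_ros_kinetics(slope_per_hour=3.0, cv=0.0, seed=0)
        reference, _ = synth.gen_ros_kinetics(slope_per_hour=0.0, cv=0.0,
                                              seed=1)
        out = ba.ros_fold(treated, reference)
        assert np.all(np.diff(out["fold_change"]) > 0)

    def test_grid_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            ba.ros_fold(self._series([1, 2, 3]),
                        self._series([1, 2, 3], times=(0.0, 1.0, 3.0)))


class TestIc50Fit:
    def test_noiseless_recovery(self):
        data, truth = synth.gen_dose_response(ic50=83.5, cv=0.0, seed=0)
        fit = ba.fit_ic50(data)
        assert fit.ic50 == pytest.approx(truth["ic50"], rel=1e-3)
        assert fit.bottom < fit.top

    def test_fit_is_deterministic(self):
        data, _ = synth.gen_dose_response(ic50=103.0, cv=0.08, seed=3)
        assert ba.fit_ic50(data).ic50 == ba.fit_ic50(data).ic50

    def test_monotone_increasing_viability_raises(self):
        c = np.geomspace(1, 1000, 8)
        data = pd.DataFrame({"concentration_um": c,
                             "viability": np.linspace(0.2, 1.0, 8),
                             "replicate": 0})
        with pytest.raises(FitError):
            ba.fit_ic50(data)

    def test_too_few_concentrations_raises(self):
        data = pd.DataFrame({"concentration_um": [1, 10, 100, 1000],
                             "viability": [1.0, 0.9, 0.4, 0.1],
                             "replicate": 0})
        with pytest.raises(InvalidArgumentError):
            ba.fit_ic50(data)


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (2.15, 2.2), (1.666, 1.7), (0.0449, 0.045), (-2.15, -2.2), (0.0, 0.0),
    ])
    def test_two_significant_figures_half_away_from_zero(self, x, expected):
        assert ba.round_sig(x, 2) == expected
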