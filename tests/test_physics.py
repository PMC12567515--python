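"""Kinematics, yield formula, stopping power and range model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from celldose import physics as ph
from celldose.errors import EnergyRangeError, InvalidArgumentError


class TestTwoBodyKinematics:
    @pytest.mark.parametrize("release,ma,mb,ea,eb,decimals", [
        (2.31, 4, 7, 1.47, 0.84, 2),    # dominant capture branch
        (2.79, 4, 7, 1.78, 1.01, 2),    # ground-state branch
    ])
    def test_capture_product_energies(self, release, ma, mb, ea, eb, decimals):
        e_a, e_b = ph.solve_two_body(release, ma, mb)
        assert round(e_a, decimals) == ea
        assert round(e_b, decimals) == eb

    def test_equal_masses_split_evenly(self):
        e_a, e_b = ph.solve_two_body(5.0, 3.0, 3.0)
        assert e_a == e_b == 2.5

    @given(release=st.floats(1e-6, 50.0), ma=st.floats(0.5, 250.0),
           mb=st.floats(0.5, 250.0))
    @settings(max_examples=200, derandomize=True)
    def test_energy_and_momentum_conservation(self, release, ma, mb):
        e_a, e_b = ph.solve_two_body(release, ma, mb)
        assert math.isclose(e_a + e_b, release, rel_tol=1e-14)
        assert math.isclose(ma * e_a, mb * e_b, rel_tol=1e-12)

    @pytest.mark.parametrize("args", [(-1.0, 4, 7), (0.0, 4, 7),
                                      (2.31, 0, 7), (2.31, 4, -1)])
    def test_invalid_inputs_raise(self, args):
        with pytest.raises(InvalidArgumentError):
            ph.solve_two_body(*args)


class TestCaptureChannels:
    def test_branching_fractions_sum_to_one(self):
        total = (ph.BNCT_GROUND_CHANNEL.branching_fraction
                 + ph.BNCT_EXCITED_CHANNEL.branching_fraction)
        assert abs(total - 1.0) < 1e-9

    def test_photon_energy_is_interchannel_difference(self):
        e = ph.channel_photon_energy(ph.BNCT_GROUND_CHANNEL,
                                     ph.BNCT_EXCITED_CHANNEL)
        assert round(e, 2) == 0.48

    def test_identical_channels_give_zero(self):
        assert ph.channel_photon_energy(ph.BNCT_GROUND_CHANNEL,
                                        ph.BNCT_GROUND_CHANNEL) == 0.0

    def test_generic_difference(self):
        a = ph.ReactionChannel(ph.BNCT_GROUND_CHANNEL.reactants,
                               ph.BNCT_GROUND_CHANNEL.products, 0.5, 3.0)
        b = ph.ReactionChannel(ph.BNCT_GROUND_CHANNEL.reactants,
                               ph.BNCT_GROUND_CHANNEL.products, 0.5, 2.0)
        assert ph.channel_photon_energy(a, b) == pytest.approx(1.0)

    def test_mismatched_reactants_raise(self):
        with pytest.raises(InvalidArgumentError):
            ph.channel_photon_energy(ph.PBFT_CHANNEL, ph.BNCT_EXCITED_CHANNEL)


class TestAlphaYield:
    def test_zero_cross_section(self):
        assert ph.alpha_yield(0.0, 123.0) == 0.0

    def test_solid_sphere_areal_density(self):
        # mean chord 2 µm of solid natural boron, 0.801 atom fraction 11B
        n_b = ph.boron_sphere_areal_density(1.5)
        assert n_b == pytest.approx(2.115e-5, rel=2e-3)
        assert ph.alpha_yield(1.0, n_b) == pytest.approx(n_b)

    @given(sigma=st.floats(0.0, 0.01), n=st.floats(0.0, 1.0))
    @settings(max_examples=100, derandomize=True)
    def test_bilinearity(self, sigma, n):
        y = ph.alpha_yield(sigma, n)
        assert ph.alpha_yield(2 * sigma, n) == pytest.approx(2 * y)
        assert ph.alpha_yield(sigma, 2 * n) == pytest.approx(2 * y)

    def test_warning_above_probability_threshold(self):
        with pytest.warns(UserWarning):
            ph.alpha_yield(1.0, 0.2)

    def test_negative_raises(self):
        with pytest.raises(InvalidArgumentError):
            ph.alpha_yield(-1.0, 1.0)


class TestMeanChord:
    @pytest.mark.parametrize("r,expected", [(1.5, 2.0), (3.0, 4.0)])
    def test_cauchy_formula(self, r, expected):
        assert ph.sphere_mean_chord(r) == pytest.approx(expected)

    def test_monte_carlo_chord_sampling(self):
        # uniform parallel flux: impact parameter b has density 2b/r^2,
        # chord = 2*sqrt(r^2 - b^2)
        rng = np.random.default_rng(42)
        r = 1.5
        b2 = rng.uniform(0.0, r * r, 100_000)
        chords = 2.0 * np.sqrt(r * r - b2)
        assert chords.mean() == pytest.approx(ph.sphere_mean_chord(r), rel=0.01)

    def test_nonpositive_radius_raises(self):
        with pytest.raises(InvalidArgumentError):
            ph.sphere_mean_chord(0.0)


def _independent_bethe_water(e_mev):
    # second, independent coding of the same parameterization (I = 75 eV)
    z_over_a = 0.111894 * 1 / 1.008 + 0.888106 * 8 / 15.999
    gamma = 1 + e_mev / 938.27208816
    beta2 = 1 - gamma ** -2
    arg = 2 * 0.51099895 * beta2 * gamma ** 2 / 75e-6
    return 0.307075 * z_over_a / beta2 * (np.log(arg) - beta2)


class TestStoppingPower:
    def test_decreases_with_energy_above_peak(self):
        s1 = ph.stopping_power(1.0, ph.PROTON, ph.WATER)
        s2 = ph.stopping_power(2.0, ph.PROTON, ph.WATER)
        assert s1 > s2

    def test_against_independent_bethe_implementation(self):
        for e in (0.6, 1.0, 2.0, 5.0, 10.0):
            assert ph.stopping_power(e, ph.PROTON, ph.WATER) == pytest.approx(
                _independent_bethe_water(e), rel=0.05)

    def test_resonance_protons_are_denser_ionizers(self):
        assert (ph.let_kev_per_um(0.675, ph.PROTON, ph.WATER)
                > ph.let_kev_per_um(2.0, ph.PROTON, ph.WATER))

    def test_continuity_across_junction(self):
        below = ph.stopping_power(0.499, ph.PROTON, ph.WATER)
        above = ph.stopping_power(0.501, ph.PROTON, ph.WATER)
        assert abs(below - above) / above < 0.02

    def test_alpha_exceeds_proton_at_same_energy(self):
        assert (ph.stopping_power(3.0, ph.ALPHA, ph.WATER)
                > ph.stopping_power(3.0, ph.PROTON, ph.WATER))

    @pytest.mark.parametrize("e", [1e-4, 25.0])
    def test_out_of_range_energy_raises(self, e):
        with pytest.raises(EnergyRangeError):
            ph.stopping_power(e, ph.PROTON, ph.WATER)


class TestCsdaRange:
    def test_monotone_in_energy(self):
        es = np.geomspace(0.01, 10.0, 12)
        rs = [ph.csda_range(e, ph.PROTON, ph.WATER) for e in es]
        assert np.all(np.diff(rs) > 0)
        for e in (0.05, 0.5, 5.0):
            assert (ph.csda_range(2 * e, ph.PROTON, ph.WATER)
                    > ph.csda_range(e, ph.PROTON, ph.WATER))

    def test_quadrature_matches_euler_integration(self):
        e_top = 2.0
        es = np.linspace(1e-6, e_top, 100_001)
        inv_s = 1.0 / np.array(
            [ph._mass_stopping(e, ph.PROTON, ph.WATER) for e in
             (es[1:] + es[:-1]) / 2.0])
        euler = float(np.sum(inv_s) * (es[1] - es[0]))
        assert ph.csda_range(e_top, ph.PROTON, ph.WATER) == pytest.approx(
            euler, rel=1e-3)

    def test_low_energy_limit(self):
        r = ph.csda_range(0.001, ph.PROTON, ph.WATER, in_um=True)
        assert 0.0 < r < 1.0

    def test_derivative_is_inverse_stopping(self):
        # d(range)/dE = 1/S(E) on a grid
        for e in (0.05, 0.3, 1.0, 5.0):
            h = e * 1e-4
            deriv = (ph.csda_range(e + h, ph.PROTON, ph.WATER)
                     - ph.csda_range(e - h, ph.PROTON, ph.WATER)) / (2 * h)
            assert deriv == pytest.approx(
                1.0 / ph.stopping_power(e, ph.PROTON, ph.WATER), rel=1e-4)

    def test_range_table_matches_quadrature(self):
        tbl = ph.get_range_table("proton", ph.WATER)
        for e in (0.01, 0.675, 2.0, 10.0):
            assert float(tbl.range_of(e)) == pytest.approx(
                ph.csda_range(e, ph.PROTON, ph.WATER), rel=2e-3)
            assert float(tbl.energy_at(tbl.range_of(e))) == pytest.approx(e, rel=1e-6)


class TestValidation:
    def test_stopping_model_fractions_must_sum_to_one(self):
        with pytest.raises(InvalidArgumentError):
            ph.StoppingModel.from_fractions("bad", {"H": 0.5}, 1.0, 75.0)

    def test_nuclide_abundance_bounds(self):
        with pytest.raises(InvalidArgumentError):
            ph.Nuclide("B", 10, 5, 1.2)

    def test_boron_isotope_abundances_sum_to_one(self):
        assert abs(ph.B10.natural_abundance_fraction
                   + ph.B11.natural_abundance_fraction - 1.0) < 1e-6
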