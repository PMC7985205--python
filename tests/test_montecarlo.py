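"""Elementary sampling operations and the slab random walk."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tissueoptics import (
    InvalidParameterError,
    OpticalProperties,
    SimulationConfig,
    SlabGeometry,
    run_simulation,
)
from tissueoptics.montecarlo import (
    C_VACUUM,
    ExitRecord,
    PhotonState,
    attenuate_weight,
    fresnel_reflectance,
    new_direction,
    propagate_photon,
    russian_roulette,
    sample_free_path,
    sample_scatter_cosine,
    specular_reflectance,
)


class TestFreePath:
    @pytest.mark.parametrize(
        "mu_s, u, expected",
        [
            (2.0, 0.5, 0.34657),
            (1.0, np.exp(-1.0), 1.0),
            (5.0, 1.0 - 1e-12, 0.0),
        ],
    )
    def test_inverse_cdf_values(self, mu_s, u, expected):
        assert sample_free_path(mu_s, u) == pytest.approx(expected, abs=1e-5)

    def test_mean_free_path(self, rng):
        draws = sample_free_path(2.0, rng.random(1_000_000))
        # exponential with mean 1/mu_s = 0.5 and sd 0.5
        se = 0.5 / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.5) < 4 * se

    def test_invalid_mu_s(self):
        with pytest.raises(InvalidParameterError):
            sample_free_path(0.0, 0.5)
        with pytest.raises(InvalidParameterError):
            sample_free_path(-1.0, 0.5)


class TestHenyeyGreenstein:
    @pytest.mark.parametrize(
        "g, u, expected",
        [(0.85, 0.0, -1.0), (0.85, 1.0, 1.0), (0.85, 0.5, 0.96794)],
    )
    def test_inverse_cdf_values(self, g, u, expected):
        assert sample_scatter_cosine(g, u) == pytest.approx(expected, abs=1e-5)

    def test_isotropic_limit(self):
        assert sample_scatter_cosine(0.0, 0.75) == pytest.approx(0.5)

    def test_mean_cosine_is_g(self, rng):
        g = 0.85
        draws = sample_scatter_cosine(g, rng.random(1_000_000))
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - g) < 4 * se

    def test_histogram_matches_phase_function(self, rng):
        """Chi-square of binned draws against the analytic CDF at alpha=0.01."""
        from scipy import stats

        g = 0.7
        draws = sample_scatter_cosine(g, rng.random(200_000))

        def cdf(x):
            return (
                (1.0 - g * g)
                / (2.0 * g)
                * (1.0 / np.sqrt(1.0 + g * g - 2.0 * g * x) - 1.0 / (1.0 + g))
            )

        edges = np.linspace(-1.0, 1.0, 41)
        observed, _ = np.histogram(draws, bins=edges)
        expected = draws.size * np.diff(cdf(edges))
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        dof = keep.sum() - 1
        assert chi2 < stats.chi2.ppf(0.99, dof)

    def test_invalid_anisotropy(self):
        with pytest.raises(InvalidParameterError):
            sample_scatter_cosine(1.0, 0.5)


class TestNewDirection:
    def test_no_deflection_preserves_direction(self):
        d = np.array([0.6, 0.0, 0.8])
        out = new_direction(d, cos_theta=1.0, phi=2.1)
        np.testing.assert_allclose(out, d, atol=1e-12)

    def test_axial_special_case(self):
        out = new_direction([0.0, 0.0, 1.0], cos_theta=0.0, phi=0.0)
        np.testing.assert_allclose(out, [1.0, 0.0, 0.0], atol=1e-12)

    def test_non_unit_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            new_direction([1.0, 1.0, 0.0], 0.5, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        # keep clear of the axial special case, which approximates the
        # azimuthal frame for |uz| > 1 - 1e-6
        theta=st.floats(0.01, np.pi - 0.01),
        alpha=st.floats(0.0, 2 * np.pi),
        cos_scatter=st.floats(-1.0, 1.0),
        phi=st.floats(0.0, 2 * np.pi),
    )
    def test_rotation_contract(self, theta, alpha, cos_scatter, phi):
        d = np.array(
            [np.sin(theta) * np.cos(alpha), np.sin(theta) * np.sin(alpha), np.cos(theta)]
        )
        out = new_direction(d, cos_scatter, phi)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-10)
        assert float(out @ d) == pytest.approx(cos_scatter, abs=1e-10)


class TestAttenuation:
    @pytest.mark.parametrize(
        "w, mu_a, d, expected",
        [
            (1.0, 0.0, 123.0, 1.0),
            (1.0, 0.1, 1.0, 0.904837),
            (0.5, 10.0, 1.0, 2.2700e-5),
        ],
    )
    def test_beer_lambert(self, w, mu_a, d, expected):
        assert attenuate_weight(w, mu_a, d) == pytest.approx(expected, rel=1e-4)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            attenuate_weight(1.0, -0.1, 1.0)
        with pytest.raises(InvalidParameterError):
            attenuate_weight(1.0, 0.1, -1.0)


class TestFresnel:
    def test_normal_incidence(self):
        assert fresnel_reflectance(1.0, 1.4, 1.0) == pytest.approx(1.0 / 36.0, abs=1e-9)

    def test_total_internal_reflection(self):
        # critical angle for 1.4 -> 1.0 is ~45.6 deg; 60 deg is beyond it
        assert fresnel_reflectance(1.4, 1.0, 0.5) == 1.0

    def test_matched_boundary(self):
        assert fresnel_reflectance(1.4, 1.4, 0.3) == 0.0

    def test_unpolarized_average_at_45_degrees(self):
        # textbook value for air -> glass (n=1.5) at 45 degrees
        r = fresnel_reflectance(1.0, 1.5, np.cos(np.radians(45.0)))
        assert r == pytest.approx(0.0502, abs=5e-4)

    def test_specular_equals_normal_incidence(self):
        assert specular_reflectance(1.0, 1.4) == pytest.approx(
            fresnel_reflectance(1.0, 1.4, 1.0)
        )


class TestRussianRoulette:
    def test_above_threshold_untouched(self):
        assert russian_roulette(0.5, 1e-6, 10, 0.99) == 0.5

    def test_survival_boost(self):
        assert russian_roulette(1e-7, 1e-6, 10, 0.05) == pytest.approx(1e-6)

    def test_death(self):
        assert russian_roulette(1e-7, 1e-6, 10, 0.5) == 0.0

    def test_unbiasedness(self, rng):
        w = 1e-7
        out = russian_roulette(np.full(200_000, w), 1e-6, 10, rng.random(200_000))
        se = np.std(out) / np.sqrt(out.size)
        assert abs(out.mean() - w) < 4 * se


class TestStateValidation:
    def test_photon_state_requires_unit_direction(self):
        with pytest.raises(InvalidParameterError):
            PhotonState(position=(0, 0, 0), direction=(0, 0, 1.001), weight=1.0, time=0.0)

    def test_exit_record_requires_positive_weight(self):
        with pytest.raises(InvalidParameterError):
            ExitRecord(side="reflection", x=0, y=0, direction=(0, 0, -1), weight=0.0, time=1.0)

    def test_exit_record_radius(self):
        rec = ExitRecord(side="reflection", x=3.0, y=4.0, direction=(0, 0, -1), weight=1.0, time=1.0)
        assert rec.r == pytest.approx(5.0)

    def test_optical_properties_invariants(self):
        props = OpticalProperties(n=1.4, g=0.85, mu_s=20.0, mu_a=0.1)
        assert props.mu_s_prime == pytest.approx((1 - 0.85) * 20.0)
        with pytest.raises(InvalidParameterError):
            OpticalProperties(n=0.9, g=0.85, mu_s=20.0, mu_a=0.1)
        with pytest.raises(InvalidParameterError):
            OpticalProperties(n=1.4, g=1.0, mu_s=20.0, mu_a=0.1)


class TestSimulation:
    def test_conservation_without_absorption(self):
        """Matched boundaries, mu_a=0, roulette off: all weight must exit."""
        props = OpticalProperties(n=1.0, g=0.85, mu_s=5.0, mu_a=0.0)
        config = SimulationConfig(n_photons=20_000, roulette_threshold=0.0, seed=4)
        res = run_simulation(props, SlabGeometry(), config)
        total = res.reflected_weight + res.transmitted_weight + res.specular_weight
        assert total == pytest.approx(config.n_photons, rel=1e-12)
        assert res.n_exit == config.n_photons

    def test_determinism_bit_identical(self, baseline_props):
        config = SimulationConfig(n_photons=5_000, seed=99)
        a = run_simulation(baseline_props, SlabGeometry(), config)
        b = run_simulation(baseline_props, SlabGeometry(), config)
        np.testing.assert_array_equal(a.weight, b.weight)
        np.testing.assert_array_equal(a.time, b.time)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.side, b.side)

    def test_specular_record(self, small_result):
        """Normal-incidence Fresnel deduction: n=1.4 in air reflects 1/36."""
        expected = small_result.config.n_photons * (0.4 / 2.4) ** 2
        assert small_result.specular_weight == pytest.approx(expected, rel=1e-12)
        rec = small_result.specular_record
        assert rec.r == 0.0 and rec.time == 0.0 and rec.side == "reflection"

    def test_ballistic_limit(self):
        """Nearly scatter-free slab: ~exp(-mu_s L) of the weight crosses
        unscattered and arrives at exactly t = L n / c."""
        props = OpticalProperties(n=1.0, g=0.85, mu_s=1e-3, mu_a=0.0)
        geometry = SlabGeometry(thickness=10.0)
        config = SimulationConfig(n_photons=100_000, roulette_threshold=0.0, seed=5)
        res = run_simulation(props, geometry, config)
        t_ballistic = 10.0 / C_VACUUM
        ballistic = (~res.reflected) & np.isclose(res.time, t_ballistic, rtol=1e-12)
        frac = res.weight[ballistic].sum() / config.n_photons
        assert frac == pytest.approx(np.exp(-0.01), abs=2e-3)

    def test_time_accounting_uses_phase_velocity(self):
        """A photon path of d mm at index n takes d * n / c: 5.00346 ps per
        mm of geometric path at n=1.5."""
        props = OpticalProperties(n=1.5, g=0.85, mu_s=1e-4, mu_a=0.0)
        geometry = SlabGeometry(thickness=1.0, n_ambient_top=1.5, n_ambient_bottom=1.5)
        config = SimulationConfig(n_photons=200, roulette_threshold=0.0, seed=6)
        res = run_simulation(props, geometry, config)
        straight = (~res.reflected) & np.isclose(res.r, 0.0, atol=1e-12)
        assert straight.any()
        assert res.time[straight][0] == pytest.approx(5.00346, abs=1e-5)

    def test_absorption_monotone_under_common_random_numbers(self, baseline_props):
        """Same seed, higher mu_a: identical photon paths, strictly lower
        reflected weight."""
        lo = baseline_props
        hi = OpticalProperties(n=lo.n, g=lo.g, mu_s=lo.mu_s, mu_a=0.2)
        config = SimulationConfig(n_photons=10_000, seed=7)
        res_lo = run_simulation(lo, SlabGeometry(), config)
        res_hi = run_simulation(hi, SlabGeometry(), config)
        assert res_hi.reflected_weight < res_lo.reflected_weight
        assert res_hi.absorbed_weight > res_lo.absorbed_weight

    def test_event_cap_is_tallied_not_silent(self):
        props = OpticalProperties(n=1.4, g=0.85, mu_s=50.0, mu_a=0.0)
        config = SimulationConfig(n_photons=500, max_events=3, roulette_threshold=0.0, seed=8)
        with pytest.warns(RuntimeWarning, match="lost weight"):
            res = run_simulation(props, SlabGeometry(), config)
        assert res.n_cap_terminations > 0
        assert res.lost_weight > 0

    def test_propagate_photon_matches_full_run(self, baseline_props):
        """Per-photon substreams make single-photon tracing bit-identical to
        the same photon inside a batched run."""
        config = SimulationConfig(n_photons=5, seed=13)
        full = run_simulation(baseline_props, SlabGeometry(), config)
        singles = [
            propagate_photon(baseline_props, SlabGeometry(), config, photon_index=i)[0]
            for i in range(5)
        ]
        exited = [rec for rec in singles if rec is not None]
        assert len(exited) == full.n_exit
        for rec, w, t in zip(exited, full.weight, full.time):
            assert rec.weight == w and rec.time == t

    def test_energy_balance_closes(self, small_result):
        bal = small_result.energy_balance()
        total = (
            bal["specular"] + bal["reflected"] + bal["transmitted"] + bal["absorbed"] + bal["lost"]
        )
        # roulette boosts make this exact only in expectation; the tally
        # identity itself closes to float precision
        assert total == pytest.approx(bal["launched"], rel=1e-6)

    def test_dataframe_export(self, small_result):
        df = small_result.to_dataframe()
        assert list(df.columns) == ["side", "x", "y", "r", "ux", "uy", "uz", "weight", "time"]
        assert len(df) == small_result.n_exit + 1  # specular row included
        assert df.iloc[0]["weight"] == pytest.approx(small_result.specular_weight)
        no_spec = small_result.to_dataframe(include_specular=False)
        assert len(no_spec) == small_result.n_exit
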