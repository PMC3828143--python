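"""Profiles, Gaussian fits, cumulative curves, orientation asymmetry."""

import numpy as np
import pytest
from scipy import stats

from pollentyping import (
    BreakpointObservation,
    Marker,
    MarkerMap,
    Orientation,
    cumulative_curves,
    fit_gaussian_mixture,
    interval_rates,
    median_breakpoint_position,
    orientation_separation,
)
from pollentyping.hotspot import WIDTH95_FACTOR
from pollentyping.simulate import GaussianComponent, SimulationConfig, simulate_breakpoints


def bp(left, right, orient=Orientation.P1toP2):
    return BreakpointObservation(orientation=orient, left=left, right=right)


class TestIntervalRates:
    def test_single_co_closed_form(self):
        mmap = MarkerMap("r", [Marker("a", 1000, "A", "G"), Marker("b", 2000, "C", "T")])
        prof = interval_rates([bp(1000, 2000)], mmap, frequency=0.001)
        # 0.1 cM over 1000 bp -> 100 cM/Mb
        assert prof.rates_cM_Mb[0] == pytest.approx(100.0)

    def test_empty_intervals_have_zero_rate(self, small_map):
        prof = interval_rates([bp(1000, 1500)], small_map, 0.005)
        assert prof.rates_cM_Mb[2] > 0
        assert np.all(prof.rates_cM_Mb[[0, 1, 3, 4]] == 0.0)

    def test_profile_integrates_to_locus_genetic_length(self, dense_map):
        cfg = SimulationConfig(marker_map=dense_map, seed=21)
        obs = [s.observation for s in simulate_breakpoints(300, cfg)]
        prof = interval_rates(obs, dense_map, 0.0055)
        assert prof.total_cM() == pytest.approx(100 * 0.0055, rel=1e-12)
        assert prof.counts.sum() == prof.n_total


class TestGaussianFit:
    def test_recovery_from_exact_gaussian_draws(self, dense_map):
        """mu within sigma/10 and sigma within 10% at n = 10^4 draws."""
        mu_true, sd_true = 3300.0, 376.0
        cfg = SimulationConfig(
            marker_map=dense_map, seed=22,
            components=(GaussianComponent(mu_true, sd_true, 1.0),),
            orientation_offset=0.0,
        )
        obs = [s.observation for s in simulate_breakpoints(10_000, cfg)]
        prof = interval_rates(obs, dense_map, 0.0055)
        (fit,) = fit_gaussian_mixture(prof, 1, seed=0)
        assert abs(fit.mu - mu_true) < sd_true / 10
        assert abs(fit.sigma - sd_true) / sd_true < 0.10
        assert fit.width95 == pytest.approx(WIDTH95_FACTOR * fit.sigma)

    def test_width95_is_392_sigma(self):
        from pollentyping.hotspot import GaussianFit

        g = GaussianFit(mu=0.0, sigma=376.3, weight=1.0, sse=0.0)
        assert g.width95 == pytest.approx(1475.0, abs=0.5)

    def test_symmetric_data_mu_at_midpoint(self):
        markers = [Marker(f"m{i}", 1000 + 200 * i, "A", "G") for i in range(21)]
        mmap = MarkerMap("sym", markers)
        centre = 3000.0
        obs = []
        for off in (100, 300, 500, 700):
            for o in (-off, +off):
                left = int(centre + o - 100)
                obs += [bp(left, left + 200)] * 10
        prof = interval_rates(obs, mmap, 0.005)
        (fit,) = fit_gaussian_mixture(prof, 1, seed=0)
        assert fit.mu == pytest.approx(centre, abs=20)

    def test_sse_matches_brute_force_grid_search(self, dense_map):
        """The optimizer's SSE is no worse than a coarse independent grid scan."""
        cfg = SimulationConfig(
            marker_map=dense_map, seed=23,
            components=(GaussianComponent(3300, 400, 1.0),),
            orientation_offset=0.0,
        )
        obs = [s.observation for s in simulate_breakpoints(2000, cfg)]
        prof = interval_rates(obs, dense_map, 0.0055)
        (fit,) = fit_gaussian_mixture(prof, 1, seed=0)
        best = np.inf
        for mu in np.linspace(2800, 3800, 41):
            for sd in np.linspace(150, 800, 27):
                pred = stats.norm.cdf(prof.ends, mu, sd) - stats.norm.cdf(prof.starts, mu, sd)
                best = min(best, float(np.sum((prof.fractions - pred) ** 2)))
        assert fit.sse <= best + 1e-12

    def test_two_component_fit_separates_double_hotspot(self, dense_map):
        cfg = SimulationConfig(
            marker_map=dense_map, seed=24,
            components=(
                GaussianComponent(2200, 250, 0.6),
                GaussianComponent(4300, 300, 0.4),
            ),
            orientation_offset=0.0,
        )
        obs = [s.observation for s in simulate_breakpoints(5000, cfg)]
        prof = interval_rates(obs, dense_map, 0.0055)
        fits = fit_gaussian_mixture(prof, 2, seed=0)
        assert abs(fits[0].mu - 2200) < 150
        assert abs(fits[1].mu - 4300) < 150
        assert fits[0].weight == pytest.approx(0.6, abs=0.08)

    def test_too_many_components_rejected(self, small_map):
        prof = interval_rates([bp(1000, 1500)], small_map, 0.005)
        with pytest.raises(ValueError, match="non-empty"):
            fit_gaussian_mixture(prof, 2)


class TestCumulativeCurves:
    def test_single_breakpoint_steps_zero_to_one(self, small_map):
        curves = cumulative_curves([bp(1000, 1500)], small_map)
        c = curves[Orientation.P1toP2]
        assert list(c) == [0, 0, 0, 1, 1, 1]

    def test_identical_sets_identical_curves(self, small_map):
        obs = [bp(500, 1000, Orientation.P1toP2), bp(1500, 2000, Orientation.P1toP2),
               bp(500, 1000, Orientation.P2toP1), bp(1500, 2000, Orientation.P2toP1)]
        curves = cumulative_curves(obs, small_map)
        np.testing.assert_array_equal(
            curves[Orientation.P1toP2], curves[Orientation.P2toP1]
        )

    def test_curves_nondecreasing_and_end_at_one(self, dense_map):
        cfg = SimulationConfig(marker_map=dense_map, seed=25)
        obs = [s.observation for s in simulate_breakpoints(200, cfg)]
        for curve in cumulative_curves(obs, dense_map).values():
            assert np.all(np.diff(curve) >= 0)
            assert curve[-1] == 1.0

    def test_offset_distributions_separate_in_injected_direction(self, dense_map):
        cfg = SimulationConfig(
            marker_map=dense_map, seed=26, orientation_offset=400.0, initiation_bias=0.5,
            components=(GaussianComponent(3300, 376, 1.0),),
        )
        obs = [s.observation for s in simulate_breakpoints(2000, cfg)]
        curves = cumulative_curves(obs, dense_map)
        # P2toP1 shifted left -> its cumulative curve dominates
        diff = curves[Orientation.P2toP1] - curves[Orientation.P1toP2]
        assert diff.max() > 0.1
        assert diff.min() >= -0.05


class TestOrientationSeparation:
    def test_equal_sets_zero(self, small_map):
        obs = [bp(1000, 1500, Orientation.P1toP2), bp(1000, 1500, Orientation.P2toP1)]
        assert orientation_separation(obs) == 0.0

    def test_antisymmetric_under_orientation_swap(self):
        obs = [bp(100, 200, Orientation.P1toP2), bp(300, 400, Orientation.P2toP1)]
        swapped = [
            BreakpointObservation(
                orientation=Orientation.P2toP1 if b.orientation is Orientation.P1toP2
                else Orientation.P1toP2,
                left=b.left, right=b.right,
            )
            for b in obs
        ]
        assert orientation_separation(obs) == -orientation_separation(swapped)

    def test_one_orientation_empty_rejected(self):
        with pytest.raises(ValueError, match="orientation"):
            orientation_separation([bp(100, 200, Orientation.P1toP2)])

    def test_recovers_injected_offset_within_3_se(self, dense_map):
        delta, sd, n = 200.0, 376.0, 1000
        cfg = SimulationConfig(
            marker_map=dense_map, seed=27, orientation_offset=delta,
            initiation_bias=0.5, components=(GaussianComponent(3300, sd, 1.0),),
        )
        obs = [s.observation for s in simulate_breakpoints(n, cfg)]
        n1 = sum(b.orientation is Orientation.P1toP2 for b in obs)
        se = sd * np.sqrt(1 / n1 + 1 / (n - n1))
        assert abs(orientation_separation(obs) - delta) < 3 * se


def test_median_breakpoint_position(small_map):
    obs = [bp(100, 500), bp(1000, 1500), bp(2000, 2600)]
    assert median_breakpoint_position(obs) == pytest.approx(1250.0)


class TestCenterAlleleProportion:
    def test_offset_free_data_balanced(self):
        from pollentyping.hotspot import center_allele_proportion

        obs = [bp(100, 200, Orientation.P1toP2), bp(800, 900, Orientation.P1toP2),
               bp(100, 200, Orientation.P2toP1), bp(800, 900, Orientation.P2toP1)]
        assert center_allele_proportion(obs, 500.0) == 0.5

    def test_leftshifted_p2top1_gives_p1_excess(self, dense_map):
        """P2toP1 exchanges shifted left of P1toP2 leave the first parent's
        allele over-represented at the hotspot centre."""
        from pollentyping.hotspot import center_allele_proportion
        from pollentyping.simulate import GaussianComponent, SimulationConfig, simulate_breakpoints

        cfg = SimulationConfig(
            marker_map=dense_map, seed=28, orientation_offset=400.0,
            initiation_bias=0.5, components=(GaussianComponent(3300, 376, 1.0),),
        )
        obs = [s.observation for s in simulate_breakpoints(2000, cfg)]
        prop = center_allele_proportion(obs, median_breakpoint_position(obs))
        assert prop > 0.55
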