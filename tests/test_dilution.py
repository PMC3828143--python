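"""Poisson PCR model and Bayesian posterior scan: closed forms and oracles."""

import math

import numpy as np
import pytest

from pollentyping import (
    DilutionEntry,
    DilutionSeries,
    ModelParams,
    PrimerKind,
    PriorSpec,
    estimate,
    neg_well_prob,
    posterior_scan,
    quantify_by_poisson,
    series_log_likelihood,
)
from pollentyping.simulate import SimulationConfig, simulate_plates


class TestNegWellProb:
    def test_parental_closed_form(self):
        # f*C*D = 1 -> e^-1
        p = neg_well_prob(ModelParams(C=4.0, f=0.5), 0.5, PrimerKind.PARENTAL)
        assert p == pytest.approx(math.exp(-1.0), abs=1e-12)

    def test_zero_rate_recombinant_never_amplifies(self):
        p = neg_well_prob(ModelParams(C=1e6, r=0.0), 1.0, PrimerKind.RECOMBINANT)
        assert p == 1.0

    def test_recombinant_closed_form(self):
        p = neg_well_prob(ModelParams(C=400.0, r=0.0055, f=0.5), 1.0, PrimerKind.RECOMBINANT)
        assert p == pytest.approx(math.exp(-1.1), rel=1e-12)

    def test_rejects_nonpositive_dilution(self):
        with pytest.raises(ValueError):
            neg_well_prob(ModelParams(C=1.0), 0.0, PrimerKind.PARENTAL)

    def test_strictly_decreasing_in_C_D_r(self):
        ps_C = [neg_well_prob(ModelParams(C=c, r=0.01, f=0.5), 0.5, PrimerKind.RECOMBINANT)
                for c in (10, 100, 1000)]
        ps_D = [neg_well_prob(ModelParams(C=100, r=0.01, f=0.5), d, PrimerKind.RECOMBINANT)
                for d in (0.01, 0.1, 1.0)]
        ps_r = [neg_well_prob(ModelParams(C=100, r=r, f=0.5), 1.0, PrimerKind.RECOMBINANT)
                for r in (0.001, 0.01, 0.1)]
        for ps in (ps_C, ps_D, ps_r):
            assert all(a > b for a, b in zip(ps, ps[1:]))
            assert all(0 < p <= 1 for p in ps)


class TestSeriesLogLikelihood:
    def test_two_wells_one_negative_closed_form(self):
        # p_neg = 0.5 requires f*C*D = ln 2
        C = math.log(2) / 0.5
        series = DilutionSeries(PrimerKind.PARENTAL, [DilutionEntry(1.0, 2, 1)])
        ll = series_log_likelihood(series, ModelParams(C=C, f=0.5))
        assert ll == pytest.approx(math.log(0.5), abs=1e-12)

    def test_all_negative_limit(self):
        series = DilutionSeries(
            PrimerKind.PARENTAL, [DilutionEntry(1e-4, 96, 96), DilutionEntry(1e-3, 96, 96)]
        )
        ll = series_log_likelihood(series, ModelParams(C=1e-6, f=0.5))
        assert ll == pytest.approx(0.0, abs=1e-6)

    def test_matches_brute_force_binomial_product(self):
        """Independent oracle: explicit product of binomial pmfs."""
        from math import comb, exp, log

        rng = np.random.default_rng(42)
        for _ in range(20):
            entries = [
                DilutionEntry(
                    dilution=float(rng.uniform(1e-4, 1.0)),
                    wells=int(rng.integers(1, 200)),
                    negatives=0,
                )
                for _ in range(rng.integers(1, 5))
            ]
            entries = [
                DilutionEntry(e.dilution, e.wells, int(rng.integers(0, e.wells + 1)))
                for e in entries
            ]
            kind = [PrimerKind.PARENTAL, PrimerKind.RECOMBINANT][int(rng.integers(2))]
            params = ModelParams(
                C=float(rng.uniform(0.1, 50.0)), r=float(rng.uniform(0.001, 0.1)),
                f=0.5,
            )
            expected = 0.0
            for e in entries:
                lam = params.f * params.C * e.dilution
                if kind is PrimerKind.RECOMBINANT:
                    lam *= params.r
                p = exp(-lam)
                expected += log(comb(e.wells, e.negatives)) + e.negatives * log(p) \
                    + (e.wells - e.negatives) * log(1 - p)
            got = series_log_likelihood(DilutionSeries(kind, entries), params)
            assert got == pytest.approx(expected, abs=1e-10)


@pytest.fixture
def simulated_series(dense_map):
    cfg = SimulationConfig(marker_map=dense_map, seed=11)
    return simulate_plates(cfg)


class TestPosteriorScan:
    def test_prior_passthrough_without_recombinant_data(self, simulated_series):
        """With parental data only, the r marginal is exactly its uniform prior."""
        parental, _ = simulated_series
        post = posterior_scan(parental, None)
        r_marg = post.r_marginal
        # cellwise: masses proportional to trapezoid weights (uniform density)
        w = np.zeros_like(post.r_grid)
        w[1:] += np.diff(post.r_grid) / 2
        w[:-1] += np.diff(post.r_grid) / 2
        np.testing.assert_allclose(r_marg, w / w.sum(), atol=1e-12)
        est = estimate(post, "r")
        assert est.mean == pytest.approx(0.05, rel=1e-9)
        assert est.lower == pytest.approx(0.0025, rel=1e-6)
        assert est.upper == pytest.approx(0.0975, rel=1e-6)

    def test_matches_dense_grid_oracle_cellwise(self, simulated_series):
        """Direct unnormalized evaluation with plain loops reproduces every cell."""
        from scipy.stats import binom

        parental, recombinant = simulated_series
        post = posterior_scan(parental, recombinant, n_C=60, n_r=60)
        f = 0.5
        logL = np.zeros((60, 60))
        for i, C in enumerate(post.C_grid):
            for j, r in enumerate(post.r_grid):
                for e in parental.entries:
                    logL[i, j] += binom.logpmf(
                        e.negatives, e.wells, math.exp(-f * C * e.dilution)
                    )
                for e in recombinant.entries:
                    logL[i, j] += binom.logpmf(
                        e.negatives, e.wells, math.exp(-f * r * C * e.dilution)
                    )
        wC = np.zeros(60); wC[1:] += np.diff(post.C_grid) / 2; wC[:-1] += np.diff(post.C_grid) / 2
        wr = np.zeros(60); wr[1:] += np.diff(post.r_grid) / 2; wr[:-1] += np.diff(post.r_grid) / 2
        mass = np.exp(logL - logL.max()) * np.outer(wC, wr)
        mass /= mass.sum()
        np.testing.assert_allclose(post.joint, mass, atol=1e-8)

    def test_mode_near_truth_and_refinement_stability(self, simulated_series):
        parental, recombinant = simulated_series
        post = posterior_scan(parental, recombinant, n_C=200, n_r=200)
        est = estimate(post, "r")
        assert 0.003 < est.mode < 0.009  # truth r = 0.0055
        fine = estimate(posterior_scan(parental, recombinant, n_C=400, n_r=400), "r")
        assert abs(fine.mean - est.mean) / est.mean < 0.01

    def test_posterior_invariant_to_entry_order(self, simulated_series):
        parental, recombinant = simulated_series
        rev = DilutionSeries(PrimerKind.PARENTAL, parental.entries[::-1])
        a = posterior_scan(parental, recombinant).joint
        b = posterior_scan(rev, recombinant).joint
        np.testing.assert_allclose(a, b, atol=1e-15)

    def test_joint_masses_sum_to_one_and_marginals_consistent(self, simulated_series):
        parental, recombinant = simulated_series
        post = posterior_scan(parental, recombinant)
        assert post.joint.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(post.C_marginal.sum(), 1.0, atol=1e-9)
        np.testing.assert_allclose(post.r_marginal, post.joint.sum(axis=0))

    def test_incompatible_prior_fails_loudly(self, simulated_series):
        parental, recombinant = simulated_series
        with pytest.raises(ValueError, match="C_lo"):
            posterior_scan(parental, recombinant, PriorSpec(C_lo=1e7, C_hi=1e9))

    def test_point_mass_marginal_degenerate_interval(self):
        from pollentyping.dilution import PosteriorGrid

        n = 60
        joint = np.zeros((n, n))
        joint[30, 30] = 1.0
        post = PosteriorGrid(
            C_grid=np.geomspace(1, 100, n), r_grid=np.linspace(0, 0.1, n), joint=joint
        )
        est = estimate(post, "r")
        spacing = 0.1 / (n - 1)
        assert abs(est.mode - post.r_grid[30]) < 1e-12
        assert abs(est.upper - est.lower) <= 2 * spacing

    def test_parameter_recovery_median_relative_error(self, dense_map):
        """Median |r_hat - r| / r over seeded replicates stays within 25%."""
        errors = []
        for seed in range(30):
            cfg = SimulationConfig(marker_map=dense_map, seed=3000 + seed)
            parental, recombinant = simulate_plates(cfg)
            est = estimate(posterior_scan(parental, recombinant, n_C=120, n_r=120), "r")
            errors.append(abs(est.mean - 0.0055) / 0.0055)
        assert np.median(errors) <= 0.25


class TestQuantifyByPoisson:
    def test_all_negative_gives_zero(self):
        with pytest.warns(UserWarning):
            q = quantify_by_poisson(8, 8, 1.0)
        assert q.m == 0.0

    def test_half_negative_ln2(self):
        q = quantify_by_poisson(8, 4, 1.0, f=0.5)
        assert q.m == pytest.approx(math.log(2), rel=1e-12)
        assert q.undiluted_count == pytest.approx(2 * math.log(2), rel=1e-12)

    def test_all_positive_rejected(self):
        with pytest.raises(ValueError, match="dilute"):
            quantify_by_poisson(8, 0, 1.0)

    def test_round_trip_bias_vanishes_with_wells(self):
        rng = np.random.default_rng(5)
        m_true = 0.8
        wells = 10_000
        negatives = int(np.sum(rng.poisson(m_true, wells) == 0))
        q = quantify_by_poisson(wells, negatives, 1.0)
        assert abs(q.m - m_true) / m_true < 0.05
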