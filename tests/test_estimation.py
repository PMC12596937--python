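"""MLE calibration and D-optimal design of capping experiments."""

import numpy as np
import pytest

from ivtkit.capping import CappingParameters
from ivtkit.errors import IdentifiabilityError, ValidationError
from ivtkit.estimation import (
    CFMeasurement,
    DesignCandidate,
    cf_gradient,
    d_optimal_design,
    fisher_information,
    mle_fit,
)
from ivtkit.scenarios import (
    initial_capping_parameters,
    printed_calibration_table,
    printed_predicted_table,
    synth_cf_measurements,
)

BOUNDS = {"atp": (0.1e-3, 8e-3), "gtp": (0.1e-3, 8e-3), "cap": (0.02e-3, 2e-3)}


@pytest.fixture(scope="module")
def init():
    return initial_capping_parameters()


class TestFisherInformation:
    def test_single_experiment_is_rank_deficient(self, init):
        d = DesignCandidate(((2e-3, 1e-3, 0.3e-3),))
        fim = fisher_information(d, init, 0.05)
        scale = (np.trace(fim) / 2.0) ** 2
        assert abs(np.linalg.det(fim)) <= 1e-12 * scale
        assert np.linalg.matrix_rank(fim, tol=1e-10 * fim.max()) <= 1

    def test_duplicated_experiment_doubles_information(self, init):
        one = DesignCandidate(((2e-3, 1e-3, 0.3e-3),))
        two = DesignCandidate(((2e-3, 1e-3, 0.3e-3),) * 2)
        assert np.allclose(
            fisher_information(two, init, 0.05),
            2 * fisher_information(one, init, 0.05),
        )

    def test_sd_scaling_and_argmax_invariance(self, init):
        d = DesignCandidate(((2e-3, 7e-3, 0.3e-3), (2e-3, 0.25e-3, 0.05e-3)))
        det1 = np.linalg.det(fisher_information(d, init, 0.05))
        detc = np.linalg.det(fisher_information(d, init, 0.05 * 3.0))
        assert detc == pytest.approx(det1 / 3.0**4, rel=1e-9)

    def test_analytic_gradient_matches_central_differences(self, init):
        for atp, gtp, cap in [(2e-3, 1e-3, 0.3e-3), (3.6e-3, 7e-3, 0.3e-3),
                              (2e-3, 0.25e-3, 0.05e-3)]:
            g = cf_gradient(atp, gtp, cap, init)
            from ivtkit.capping import instantaneous_cap_fraction

            fd = np.zeros(2)
            base = np.array([init.lam, init.theta])
            for i in range(2):
                h = 1e-6 * base[i]
                for sign in (1, -1):
                    p = base.copy()
                    p[i] += sign * h
                    fd[i] += sign * instantaneous_cap_fraction(
                        atp, gtp, cap, CappingParameters(lam=p[0], theta=p[1])
                    )
                fd[i] /= 2 * h
            assert np.allclose(g, fd, rtol=1e-6)


class TestMLE:
    def test_noise_free_recovery(self, init):
        truth = CappingParameters(lam=60.0, theta=3e-3)
        meas = [
            CFMeasurement(atp=a, gtp=g, cap=c, cf=truth_cf, sd=0.05)
            for (a, g, c), truth_cf in zip(
                [(3.6e-3, 7e-3, 0.3e-3), (2e-3, 0.25e-3, 0.05e-3)],
                [
                    synth_cf_measurements([(3.6e-3, 7e-3, 0.3e-3)], truth,
                                          sd=1e-9, seed=0)[0].cf,
                    synth_cf_measurements([(2e-3, 0.25e-3, 0.05e-3)], truth,
                                          sd=1e-9, seed=0)[0].cf,
                ],
            )
        ]
        fit = mle_fit(meas, init)
        assert fit.lam == pytest.approx(60.0, rel=1e-4)
        assert fit.theta == pytest.approx(3e-3, rel=1e-4)

    def test_fit_never_worse_than_initial_guess(self, init):
        meas = printed_calibration_table()
        fit = mle_fit(meas, init)

        def nll(p):
            from ivtkit.capping import instantaneous_cap_fraction

            return sum(
                (instantaneous_cap_fraction(m.atp, m.gtp, m.cap, p) - m.cf) ** 2
                / (2 * m.sd**2)
                for m in meas
            )

        assert nll(fit) <= nll(init) + 1e-9

    def test_two_condition_calibration_lands_in_printed_ranges(self, init):
        """Fitting the designed two-experiment protocol recovers composites
        inside 25-150 M^-1 and 0.5-20 mM."""
        fit = mle_fit(printed_predicted_table(),
                      CappingParameters(lam=80.0, theta=5e-3))
        assert 25.0 <= fit.lam <= 150.0
        assert 0.5e-3 <= fit.theta <= 20e-3

    def test_single_gtp_level_is_not_identifiable(self, init):
        meas = [
            CFMeasurement(atp=2e-3, gtp=1e-3, cap=0.3e-3, cf=0.5, sd=0.05),
            CFMeasurement(atp=4e-3, gtp=1e-3, cap=0.3e-3, cf=0.4, sd=0.05),
        ]
        with pytest.raises(IdentifiabilityError) as err:
            mle_fit(meas, init)
        assert err.value.direction == "theta"

    def test_too_few_measurements_rejected(self, init):
        with pytest.raises(ValidationError):
            mle_fit([CFMeasurement(atp=2e-3, gtp=1e-3, cap=0.3e-3,
                                   cf=0.5, sd=0.05)], init)

    def test_replicate_study_recovers_truth_with_calibrated_coverage(self, init):
        """200 seeded synthetic replicates of a D-optimally designed
        4-experiment calibration at sd = 0.05: median relative errors below
        15% and ~95% Wald coverage for both composites."""
        truth = CappingParameters(lam=60.0, theta=3e-3)
        design = list(
            d_optimal_design(4, BOUNDS, truth, seed=7).experiments
        )
        errs, cover = [], np.zeros(2)
        n_ok = 0
        for rep in range(200):
            meas = synth_cf_measurements(design, truth, sd=0.05, n_rep=2,
                                         seed=1000 + rep)
            try:
                fit = mle_fit(meas, init)
            except IdentifiabilityError:
                continue
            n_ok += 1
            errs.append(
                (abs(fit.lam - 60.0) / 60.0, abs(fit.theta - 3e-3) / 3e-3)
            )
            se = np.sqrt(np.diag(fit.covariance))
            cover[0] += abs(fit.lam - 60.0) <= 1.96 * se[0]
            cover[1] += abs(fit.theta - 3e-3) <= 1.96 * se[1]
        errs = np.array(errs)
        assert n_ok >= 190
        assert np.median(errs[:, 0]) < 0.15
        assert np.median(errs[:, 1]) < 0.15
        assert 0.88 <= cover[0] / n_ok <= 0.995
        assert 0.88 <= cover[1] / n_ok <= 0.995


class TestDOptimalDesign:
    def test_separates_gtp_levels_and_beats_random(self, init):
        design = d_optimal_design(2, BOUNDS, init, seed=3)
        gtps = sorted(g for _, g, _ in design.experiments)
        lo, hi = BOUNDS["gtp"]
        assert gtps[0] <= lo * 3.0          # one near the lower GTP bound
        assert gtps[-1] >= hi * 0.7         # one near the upper GTP bound
        det_opt = np.linalg.det(fisher_information(design, init, 0.075))
        rng = np.random.default_rng(99)
        llo = np.log([BOUNDS[k][0] for k in ("atp", "gtp", "cap")])
        lhi = np.log([BOUNDS[k][1] for k in ("atp", "gtp", "cap")])
        for _ in range(1000):
            cand = DesignCandidate(
                (tuple(np.exp(rng.uniform(llo, lhi))),
                 tuple(np.exp(rng.uniform(llo, lhi))))
            )
            assert np.linalg.det(
                fisher_information(cand, init, 0.075)
            ) <= det_opt + 1e-12

    def test_beats_the_printed_two_experiment_protocol(self, init):
        design = d_optimal_design(2, BOUNDS, init, seed=3)
        printed = DesignCandidate(
            ((3.6e-3, 7e-3, 0.3e-3), (2e-3, 0.25e-3, 0.05e-3))
        )
        assert np.linalg.det(
            fisher_information(design, init, 0.075)
        ) >= np.linalg.det(fisher_information(printed, init, 0.075))

    def test_deterministic_given_seed(self, init):
        d1 = d_optimal_design(2, BOUNDS, init, seed=5)
        d2 = d_optimal_design(2, BOUNDS, init, seed=5)
        assert d1 == d2

    def test_degenerate_inputs_rejected(self, init):
        with pytest.raises(ValidationError):
            d_optimal_design(1, BOUNDS, init, seed=0)
        bad = dict(BOUNDS, gtp=(2e-3, 2e-3))
        with pytest.raises(ValidationError):
            d_optimal_design(2, bad, init, seed=0)


def test_log_reparameterization_leaves_design_ranking_invariant(init):
    """det of the log-space information differs from the linear-space one by
    the squared Jacobian determinant (lam*theta)^2 -- a design-independent
    factor, so D-optimal rankings are unchanged."""
    d1 = DesignCandidate(((3.6e-3, 7e-3, 0.3e-3), (2e-3, 0.25e-3, 0.05e-3)))
    d2 = DesignCandidate(((5e-3, 6e-3, 0.2e-3), (1e-3, 0.5e-3, 0.1e-3)))
    jac2 = (init.lam * init.theta) ** 2
    for d in (d1, d2):
        fim = fisher_information(d, init, 0.05)
        g_scaled = fim * np.outer(
            [init.lam, init.theta], [init.lam, init.theta]
        )
        assert np.linalg.det(g_scaled) == pytest.approx(
            np.linalg.det(fim) * jac2, rel=1e-9
        )
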