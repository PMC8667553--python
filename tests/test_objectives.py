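"""Losses and penalties against independent oracles and their algebra."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime

from pathlasso import objectives as obj
from pathlasso.data import PathwayCollection, SurvivalDataset, build_latent_design, standardize
from pathlasso.objectives import (
    PenaltyConfig,
    cox_nll,
    cox_nll_grad,
    coupling_penalty,
    coupling_penalty_grad,
    group_lasso_penalty,
    group_lasso_penalty_grad,
    lasso_penalty,
    total_loss_pair,
    total_loss_single,
)
from conftest import random_survival


def brute_force_nll(beta, X, time, event):
    """Straight-line evaluation of the negative log-partial likelihood."""
    eta = X @ beta
    total = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            total -= eta[i] - np.log(np.sum(np.exp(eta[time >= time[i]])))
    return total


class TestCoxNll:
    def test_zero_beta_counts_risk_sets(self):
        # with beta = 0 every exp term is 1, so each event contributes
        # log of its risk-set size
        time = np.array([3.0, 1.0, 2.0, 4.0])
        event = np.array([1, 1, 0, 1])
        X = np.zeros((4, 2))
        expected = np.log(2) + np.log(4) + np.log(1)
        assert cox_nll(np.zeros(2), X, time, event) == pytest.approx(expected)

    def test_two_sample_hand_value(self):
        # subjects at times 1 < 2, both events, x = (1, 0), beta = 1:
        # l = -[1 - log(e^1 + e^0)] - [0 - log(e^0)]
        X = np.array([[1.0], [0.0]])
        expected = -(1.0 - np.log(np.e + 1.0))
        got = cox_nll(np.array([1.0]), X, np.array([1.0, 2.0]), np.array([1, 1]))
        assert got == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("ties", [False, True])
    def test_matches_brute_force(self, ties):
        rng = np.random.default_rng(3)
        for _ in range(10):
            X, time, event = random_survival(rng, 30, 4, ties=ties)
            beta = rng.normal(size=4)
            assert cox_nll(beta, X, time, event) == pytest.approx(
                brute_force_nll(beta, X, time, event), rel=1e-10)

    def test_column_shift_invariance(self):
        # adding a constant to one covariate column cancels within risk sets
        rng = np.random.default_rng(5)
        X, time, event = random_survival(rng, 25, 3)
        beta = rng.normal(size=3)
        base = cox_nll(beta, X, time, event)
        shifted = X.copy()
        shifted[:, 1] += 5.0
        assert cox_nll(beta, shifted, time, event) == pytest.approx(base, rel=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_nll(np.zeros(1), np.zeros((3, 1)), np.arange(3.0), np.zeros(3))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(11)
        X, time, event = random_survival(rng, 30, 5, ties=True)
        beta = rng.normal(size=5)
        num = approx_fprime(beta, lambda b: cox_nll(b, X, time, event), 1e-6)
        np.testing.assert_allclose(cox_nll_grad(beta, X, time, event), num, atol=1e-4)


class TestLassoPenalty:
    @pytest.mark.parametrize("beta,lam,expected", [
        (np.zeros(4), 2.0, 0.0),
        (np.array([1.0, -2.0]), 0.5, 1.5),
        (np.array([3.0, -4.0]), 0.0, 0.0),
    ])
    def test_values(self, beta, lam, expected):
        assert lasso_penalty(beta, lam) == pytest.approx(expected)


class TestGroupLassoPenalty:
    def test_single_group_sqrt_weight(self):
        # group of 4 latent columns with unit coefficient: sqrt(4) * 1 = 2
        ds = SurvivalDataset(np.zeros((3, 4)), ["a", "b", "c", "d"],
                            [1, 2, 3], [1, 1, 1], ["s1", "s2", "s3"])
        pw = PathwayCollection({"P": ["a", "b", "c", "d"]})
        design = build_latent_design(ds, pw)
        beta = np.array([1.0, 0.0, 0.0, 0.0])
        assert group_lasso_penalty(beta, design, 1.0, 0.5) == pytest.approx(2.0)

    def test_sum_over_groups_and_zero(self, small_design):
        rng = np.random.default_rng(1)
        beta = rng.normal(size=small_design.n_latent)
        total = group_lasso_penalty(beta, small_design, 1.3)
        per_group = sum(
            1.3 * np.sqrt(b - a) * np.linalg.norm(beta[a:b])
            for a, b in small_design.group_slices)
        assert total == pytest.approx(per_group)
        assert group_lasso_penalty(np.zeros_like(beta), small_design, 1.3) == 0.0

    def test_gradient_matches_finite_differences(self, small_design):
        rng = np.random.default_rng(2)
        beta = rng.normal(size=small_design.n_latent)
        num = approx_fprime(beta, lambda b: group_lasso_penalty(b, small_design, 0.7), 1e-7)
        np.testing.assert_allclose(
            group_lasso_penalty_grad(beta, small_design, 0.7), num, atol=1e-5)


class TestCouplingPenalty:
    def direct_main(self, b1, b2, design, mu, w=0.5, eps=1e-8):
        """Independent straight-line evaluation of the main coupling formula."""
        total = 0.0
        for a, b in design.group_slices:
            u, v = b1[a:b], b2[a:b]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu <= eps or nv <= eps:
                continue
            a12 = np.linalg.norm(u - v * (nu / nv))
            a21 = np.linalg.norm(v - u * (nv / nu))
            total += (b - a) ** 0.5 * np.sqrt(a12**2 + a21**2)
        return mu * total

    def test_spot_value_against_direct_evaluation(self, small_design):
        rng = np.random.default_rng(9)
        b1 = rng.normal(size=small_design.n_latent)
        b2 = rng.normal(size=small_design.n_latent)
        got = coupling_penalty(b1, b2, small_design, 1.7)
        assert got == pytest.approx(self.direct_main(b1, b2, small_design, 1.7), rel=1e-10)

    def test_proportional_blocks_give_zero(self, small_design):
        rng = np.random.default_rng(10)
        b1 = rng.normal(size=small_design.n_latent)
        for c in (0.1, 1.0, 42.0):
            assert coupling_penalty(b1, c * b1, small_design, 2.0) == pytest.approx(0.0, abs=1e-9)

    def test_inactive_cohort_gates_everything(self, small_design):
        rng = np.random.default_rng(11)
        b2 = rng.normal(size=small_design.n_latent)
        assert coupling_penalty(np.zeros_like(b2), b2, small_design, 5.0) == 0.0

    def test_symmetry(self, small_design):
        rng = np.random.default_rng(12)
        for _ in range(20):
            b1 = rng.normal(size=small_design.n_latent)
            b2 = rng.normal(size=small_design.n_latent)
            assert coupling_penalty(b1, b2, small_design, 1.0) == coupling_penalty(
                b2, b1, small_design, 1.0)

    def test_zeroing_a_block_never_increases(self, small_design):
        rng = np.random.default_rng(13)
        for _ in range(10):
            b1 = rng.normal(size=small_design.n_latent)
            b2 = rng.normal(size=small_design.n_latent)
            base = coupling_penalty(b1, b2, small_design, 1.0)
            for a, b in small_design.group_slices:
                for which in (0, 1):
                    z1, z2 = b1.copy(), b2.copy()
                    (z1 if which == 0 else z2)[a:b] = 0.0
                    assert coupling_penalty(z1, z2, small_design, 1.0) <= base + 1e-12

    @pytest.mark.parametrize("variant", ["main", "abs_difference", "cosine",
                                         "normalized_difference"])
    def test_gradients_match_finite_differences(self, small_design, variant):
        rng = np.random.default_rng(14)
        cfg = PenaltyConfig(coupling_variant=variant)
        b1 = rng.normal(size=small_design.n_latent)
        b2 = rng.normal(size=small_design.n_latent)
        g1, g2 = coupling_penalty_grad(b1, b2, small_design, 1.3, cfg)
        n1 = approx_fprime(b1, lambda b: coupling_penalty(b, b2, small_design, 1.3, cfg), 1e-7)
        n2 = approx_fprime(b2, lambda b: coupling_penalty(b1, b, small_design, 1.3, cfg), 1e-7)
        np.testing.assert_allclose(g1, n1, atol=1e-5)
        np.testing.assert_allclose(g2, n2, atol=1e-5)

    def test_variant_values(self, small_design):
        rng = np.random.default_rng(15)
        b1 = rng.normal(size=small_design.n_latent)
        # abs_difference of identical vectors is zero
        cfg = PenaltyConfig(coupling_variant="abs_difference")
        assert coupling_penalty(b1, b1.copy(), small_design, 1.0, cfg) == 0.0
        # cosine of positively proportional blocks is zero
        cfg = PenaltyConfig(coupling_variant="cosine")
        assert coupling_penalty(b1, 3.0 * b1, small_design, 1.0, cfg) == pytest.approx(0.0, abs=1e-12)
        # normalized difference of antiparallel blocks: per-group |g|^0.5 * 2
        cfg = PenaltyConfig(coupling_variant="normalized_difference")
        expected = sum((b - a) ** 0.5 * 2.0 for a, b in small_design.group_slices)
        assert coupling_penalty(b1, -b1, small_design, 1.0, cfg) == pytest.approx(expected)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            PenaltyConfig(coupling_variant="bogus")


class TestComposedLosses:
    def test_pair_loss_separates_at_mu_zero(self, small_design):
        rng = np.random.default_rng(20)
        n = small_design.latent_matrix.shape[0]
        time1, event1 = rng.exponential(1, n), (rng.random(n) < 0.7).astype(int)
        time2, event2 = rng.exponential(1, n), (rng.random(n) < 0.7).astype(int)
        event1[0] = event2[0] = 1
        X = small_design.latent_matrix
        b1 = rng.normal(size=small_design.n_latent)
        b2 = rng.normal(size=small_design.n_latent)
        cfg = PenaltyConfig(lambda_=0.4, mu=0.0)
        pair = total_loss_pair(b1, b2, small_design, X, time1, event1,
                               X, time2, event2, cfg)
        singles = (total_loss_single(b1, X, time1, event1, cfg, small_design)
                   + total_loss_single(b2, X, time2, event2, cfg, small_design))
        assert pair == pytest.approx(singles, rel=1e-12)

    def test_lambda_zero_reduces_to_nll(self, small_design):
        rng = np.random.default_rng(21)
        n = small_design.latent_matrix.shape[0]
        time, event = rng.exponential(1, n), np.ones(n, dtype=int)
        X = small_design.latent_matrix
        b = rng.normal(size=small_design.n_latent)
        cfg = PenaltyConfig(lambda_=0.0)
        assert total_loss_single(b, X, time, event, cfg, small_design) == pytest.approx(
            cox_nll(b, X, time, event))

    def test_penalties_nonnegative(self, small_design):
        rng = np.random.default_rng(22)
        n = small_design.latent_matrix.shape[0]
        time, event = rng.exponential(1, n), np.ones(n, dtype=int)
        X = small_design.latent_matrix
        b1 = rng.normal(size=small_design.n_latent)
        b2 = rng.normal(size=small_design.n_latent)
        cfg = PenaltyConfig(lambda_=0.3, mu=0.7)
        pair = total_loss_pair(b1, b2, small_design, X, time, event, X, time, event, cfg)
        assert pair >= cox_nll(b1, X, time, event) + cox_nll(b2, X, time, event) - 1e-12

    def test_penalty_scaling_laws(self, small_design):
        # lasso, group lasso and the main coupling scale linearly under a
        # common positive rescaling; cosine and normalized-difference
        # variants are invariant to separate per-cohort rescaling
        rng = np.random.default_rng(23)
        b = rng.normal(size=small_design.n_latent)
        b2 = rng.normal(size=small_design.n_latent)
        assert lasso_penalty(3.0 * b, 1.0) == pytest.approx(3.0 * lasso_penalty(b, 1.0))
        assert group_lasso_penalty(3.0 * b, small_design, 1.0) == pytest.approx(
            3.0 * group_lasso_penalty(b, small_design, 1.0))
        main = PenaltyConfig()
        assert coupling_penalty(2.5 * b, 2.5 * b2, small_design, 1.0, main) == pytest.approx(
            2.5 * coupling_penalty(b, b2, small_design, 1.0, main), rel=1e-9)
        for variant in ("cosine", "normalized_difference"):
            cfg = PenaltyConfig(coupling_variant=variant)
            base = coupling_penalty(b, b2, small_design, 1.0, cfg)
            scaled = coupling_penalty(2.5 * b, 0.3 * b2, small_design, 1.0, cfg)
            assert scaled == pytest.approx(base, rel=1e-9)
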