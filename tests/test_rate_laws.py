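"""Rate-law kernels checked against hand evaluations and a naive scalar
double-loop oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grnfit import (
    GRNModelParameters,
    RateLaw,
    ann_rhs,
    hill_regulation,
    hill_rhs,
    simulate,
)
from grnfit.rate_laws import ann_rhs_batch, hill_rhs_batch

from conftest import random_params


def naive_hill_rhs(p, x):
    """Two-loop scalar reference for the Hill right-hand side."""
    n = p.n_genes
    out = np.empty(n)
    for i in range(n):
        synth = 0.0
        for j in range(n):
            w = p.omega[i, j]
            if w == 0:
                continue
            t = (x[j] / p.gamma[i]) ** p.hill_n[i, j]
            r = t / (1 + t) if w > 0 else 1 / (1 + t)
            synth += w * r
        out[i] = p.alpha[i] * synth - p.beta[i] * x[i]
    return out


def naive_ann_rhs(p, x):
    n = p.n_genes
    out = np.empty(n)
    for i in range(n):
        u = sum(p.omega[i, j] * x[j] for j in range(n)) - p.gamma[i]
        out[i] = p.alpha[i] / (1 + np.exp(-u)) - p.beta[i] * x[i]
    return out


class TestHillRegulation:
    def test_half_saturation_both_branches(self):
        for n in (0.5, 1.0, 2.0, 7.3):
            for gamma in (0.2, 1.0, 3.0):
                assert hill_regulation(gamma, gamma, n, True) == pytest.approx(0.5)
                assert hill_regulation(gamma, gamma, n, False) == pytest.approx(0.5)

    def test_limits_at_zero(self):
        assert hill_regulation(0.0, 1.0, 2.0, True) == 0.0
        assert hill_regulation(0.0, 1.0, 2.0, False) == 1.0

    def test_hand_value(self):
        # x=2, gamma=1, n=2 activating: 4 / (4 + 1)
        assert hill_regulation(2.0, 1.0, 2.0, True) == pytest.approx(0.8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hill_regulation(1.0, -1.0, 2.0, True)
        with pytest.raises(ValueError):
            hill_regulation(1.0, 1.0, 0.0, True)
        with pytest.raises(ValueError):
            hill_regulation(-1.0, 1.0, 2.0, True)

    @given(
        gamma=st.floats(0.05, 5.0),
        n=st.floats(0.2, 8.0),
        activating=st.booleans(),
    )
    @settings(deadline=None, max_examples=50)
    def test_bounded_and_monotone(self, gamma, n, activating):
        xs = np.linspace(0, 10 * gamma, 200)
        vals = hill_regulation(xs, gamma, n, activating)
        assert np.all((vals >= 0) & (vals <= 1))
        diffs = np.diff(vals)
        assert np.all(diffs >= -1e-12) if activating else np.all(diffs <= 1e-12)


class TestRHS:
    def test_zero_omega_is_pure_decay(self, rng):
        p = random_params(rng, n=3)
        p.omega[:] = 0.0
        x = rng.uniform(0, 2, 3)
        assert np.allclose(hill_rhs(p, x), -p.beta * x)

    def test_single_gene_hand_value(self):
        # 1 gene, omega=+1, x = gamma: alpha*0.5 - beta*gamma
        p = GRNModelParameters(
            rate_law=RateLaw.HILL,
            alpha=[2.0], beta=[1.0], gamma=[0.7],
            omega=[[1.0]], hill_n=[[2.0]],
        )
        assert hill_rhs(p, np.array([0.7]))[0] == pytest.approx(2 * 0.5 - 0.7)

    def test_ann_zero_omega_half_sigmoid(self, rng):
        p = random_params(rng, n=3, rate_law=RateLaw.ANN)
        p.omega[:] = 0.0
        p.gamma[:] = 0.0
        x = rng.uniform(0, 2, 3)
        assert np.allclose(ann_rhs(p, x), p.alpha / 2 - p.beta * x)

    def test_ann_two_gene_hand_value(self):
        p = GRNModelParameters(
            rate_law=RateLaw.ANN,
            alpha=[1.5, 1.0], beta=[1.0, 1.0], gamma=[0.0, 0.0],
            omega=[[0.0, 1.0], [0.0, 0.0]],
        )
        # x2 = 0 so gene 1 synthesis = alpha1 * sigma(0) = alpha1 / 2
        rates = ann_rhs(p, np.array([0.3, 0.0]))
        assert rates[0] == pytest.approx(1.5 / 2 - 0.3)

    def test_negative_concentration_rejected(self, rng):
        p = random_params(rng, n=3)
        with pytest.raises(ValueError):
            hill_rhs(p, np.array([0.5, -0.1, 0.2]))

    def test_tiny_negative_roundoff_tolerated(self, rng):
        p = random_params(rng, n=3)
        x = np.array([0.5, -1e-10, 0.2])
        assert np.all(np.isfinite(hill_rhs(p, x)))

    @pytest.mark.parametrize("law", [RateLaw.HILL, RateLaw.ANN])
    def test_oracle_agreement(self, rng, law):
        oracle = naive_hill_rhs if law is RateLaw.HILL else naive_ann_rhs
        fast = hill_rhs if law is RateLaw.HILL else ann_rhs
        for _ in range(200):
            n = int(rng.integers(1, 6))
            p = random_params(rng, n=n, rate_law=law)
            x = rng.uniform(0, 3, n)
            assert np.allclose(fast(p, x), oracle(p, x), atol=1e-12, rtol=1e-12)

    def test_ann_finite_at_extreme_inputs(self, rng):
        p = random_params(rng, n=3, rate_law=RateLaw.ANN, omega_scale=20.0)
        x = np.array([1e4, 0.0, 5e3])
        assert np.all(np.isfinite(ann_rhs(p, x)))
        assert np.all(np.isfinite(hill_rhs(random_params(rng, n=3), np.array([1e4, 0, 1e4]))))

    @pytest.mark.parametrize("law", [RateLaw.HILL, RateLaw.ANN])
    def test_batch_matches_single(self, rng, law):
        fast = hill_rhs if law is RateLaw.HILL else ann_rhs
        batch_fn = hill_rhs_batch if law is RateLaw.HILL else ann_rhs_batch
        plist = [random_params(rng, n=4, rate_law=law) for _ in range(6)]
        X = rng.uniform(0, 2, (6, 4))
        got = batch_fn(
            X,
            np.stack([p.alpha for p in plist]),
            np.stack([p.beta for p in plist]),
            np.stack([p.gamma for p in plist]),
            np.stack([p.omega for p in plist]),
            np.stack([p.hill_n for p in plist]) if law is RateLaw.HILL else None,
        )
        for k, p in enumerate(plist):
            assert np.allclose(got[k], fast(p, X[k]), atol=1e-12)


def test_zero_omega_row_decouples_gene(rng):
    """A gene whose omega row is all zero is unaffected by other genes."""
    for law in (RateLaw.HILL, RateLaw.ANN):
        p = random_params(rng, n=4, rate_law=law)
        p.omega[2, :] = 0.0
        times = np.linspace(0, 8, 9)
        x0 = rng.uniform(0.2, 1.0, 4)
        base = simulate(p, x0, times)
        x0b = x0.copy()
        x0b[[0, 1, 3]] *= 1.7  # perturb everyone except gene 2
        pert = simulate(p, x0b, times)
        assert np.allclose(base.values[:, 2], pert.values[:, 2], atol=1e-6)


def test_params_validation():
    with pytest.raises(ValueError, match="alpha and beta"):
        GRNModelParameters(RateLaw.ANN, alpha=[-1.0], beta=[1.0], gamma=[0.0], omega=[[0.0]])
    with pytest.raises(ValueError, match="requires hill_n"):
        GRNModelParameters(RateLaw.HILL, alpha=[1.0], beta=[1.0], gamma=[1.0], omega=[[0.0]])
    with pytest.raises(ValueError, match="gamma > 0"):
        GRNModelParameters(
            RateLaw.HILL, alpha=[1.0], beta=[1.0], gamma=[-1.0],
            omega=[[0.0]], hill_n=[[1.0]],
        )


def test_topology_from_sign_of_omega(rng, topology_a):
    p = random_params(rng, n=5, topology=topology_a)
    assert np.array_equal(p.topology().sign, topology_a.sign)
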