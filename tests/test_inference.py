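"""Parameter encoding and the reverse-engineering loop."""

import numpy as np
import pytest

from grnfit import (
    GRNModel,
    ParameterCodec,
    ParameterLimits,
    PSOConfig,
    RateLaw,
    SystemSpec,
    instantiate_system,
    make_dataset_pair,
    reverse_engineer,
    simulate,
)
from grnfit.simulate import default_time_grid

from conftest import random_params


class TestParameterLimits:
    def test_interval_validation(self):
        with pytest.raises(ValueError):
            ParameterLimits(omega_interval=(1.0, -1.0))
        with pytest.raises(ValueError):
            ParameterLimits(alpha_interval=(-0.1, 5.0))

    def test_gamma_defaults_per_law(self):
        lim = ParameterLimits()
        assert lim.gamma_for(RateLaw.HILL)[0] > 0
        assert lim.gamma_for(RateLaw.ANN)[0] < 0

    def test_omega_interval_nesting(self, rng, topology_a):
        """A solution feasible under [-1,1] stays feasible under [-20,20]."""
        narrow = ParameterCodec(5, RateLaw.HILL, ParameterLimits.with_omega(-1, 1),
                                topology_a)
        wide = ParameterCodec(5, RateLaw.HILL, ParameterLimits.with_omega(-20, 20),
                              topology_a)
        p = random_params(rng, n=5, topology=topology_a, omega_scale=0.9)
        p.alpha[:] = np.clip(p.alpha, 0.2, 40)
        wide.encode(p)  # must not raise
        narrow.encode(p)


class TestCodec:
    def test_dimension_without_topology(self):
        codec = ParameterCodec(5, RateLaw.HILL, ParameterLimits())
        assert codec.dim == 25 + 5 + 5 + 5 + 25

    def test_dimension_with_system_a_topology(self, topology_a):
        codec = ParameterCodec(5, RateLaw.HILL, ParameterLimits(), topology_a)
        assert codec.dim == 8 + 5 + 5 + 5 + 8
        ann = ParameterCodec(5, RateLaw.ANN, ParameterLimits(), topology_a)
        assert ann.dim == 8 + 5 + 5 + 5

    @pytest.mark.parametrize("law", [RateLaw.HILL, RateLaw.ANN])
    @pytest.mark.parametrize("with_topo", [False, True])
    def test_round_trip_identity(self, rng, topology_a, law, with_topo):
        topo = topology_a if with_topo else None
        codec = ParameterCodec(5, law, ParameterLimits.with_omega(-5, 5), topo)
        p = random_params(rng, n=5, rate_law=law, topology=topo, omega_scale=3.0)
        back = codec.decode(codec.encode(p))
        assert np.allclose(back.alpha, p.alpha)
        assert np.allclose(back.beta, p.beta)
        assert np.allclose(back.gamma, p.gamma)
        assert np.allclose(back.omega, p.omega)
        if law is RateLaw.HILL:
            mask = topo.sign != 0 if topo is not None else np.ones((5, 5), bool)
            assert np.allclose(back.hill_n[mask], p.hill_n[mask])

    def test_sign_constraint_bounds(self, topology_a):
        codec = ParameterCodec(5, RateLaw.ANN, ParameterLimits.with_omega(-5, 5),
                               topology_a, constrain_signs=True)
        for k, s in enumerate(codec.omega_signs):
            lo, hi = codec.bounds[k]
            assert (lo, hi) == ((0.0, 5.0) if s > 0 else (-5.0, 0.0))
        relaxed = ParameterCodec(5, RateLaw.ANN, ParameterLimits.with_omega(-5, 5),
                                 topology_a, constrain_signs=False)
        assert all(tuple(b) == (-5.0, 5.0) for b in relaxed.bounds[:8])

    def test_encode_rejects_out_of_limits(self, rng, topology_a):
        codec = ParameterCodec(5, RateLaw.ANN, ParameterLimits.with_omega(-1, 1),
                               topology_a)
        p = random_params(rng, n=5, rate_law=RateLaw.ANN, topology=topology_a,
                          omega_scale=3.0)
        with pytest.raises(ValueError, match="limits"):
            codec.encode(p)

    def test_decode_batch_matches_decode(self, rng, topology_a):
        codec = ParameterCodec(5, RateLaw.HILL, ParameterLimits(), topology_a)
        X = rng.uniform(codec.bounds[:, 0], codec.bounds[:, 1], (4, codec.dim))
        batch = codec.decode_batch(X)
        for k in range(4):
            single = codec.decode(X[k])
            assert np.allclose(batch["alpha"][k], single.alpha)
            assert np.allclose(batch["omega"][k], single.omega)
            assert np.allclose(batch["hill_n"][k], single.hill_n)


class TestReverseEngineer:
    @pytest.fixture(scope="class")
    def clean_training(self):
        spec = SystemSpec.builtin("A", 1, "ann", seed=13)
        params = instantiate_system(spec)
        x0 = np.random.default_rng(7).uniform(0.1, 1.0, 5)
        return simulate(params, x0, default_time_grid()), spec.topology

    def test_objective_matches_reference_loss(self, clean_training, rng):
        training, topo = clean_training
        model = GRNModel(training, "ann", topology=topo)
        X = rng.uniform(model.codec.bounds[:, 0], model.codec.bounds[:, 1],
                        (5, model.dim))
        batch_err = model.objective_batch(X)
        for k in range(5):
            ref = model.loss(model.codec.decode(X[k]))
            assert batch_err[k] == pytest.approx(ref, rel=5e-3, abs=5e-4)

    def test_deterministic_under_seed(self, clean_training):
        training, topo = clean_training
        pso = PSOConfig(max_evaluations=1_500, seed=5)
        r1 = reverse_engineer(training, "ann", topology=topo, pso=pso)
        r2 = reverse_engineer(training, "ann", topology=topo, pso=pso)
        assert r1.training_error == r2.training_error
        assert np.array_equal(r1.params.omega, r2.params.omega)

    def test_epsilon_infinity_returns_first_batch(self, clean_training):
        training, topo = clean_training
        pso = PSOConfig(max_evaluations=50_000, error_threshold=np.inf, seed=0)
        res = reverse_engineer(training, "ann", topology=topo, pso=pso)
        assert res.n_evaluations == pso.population
        assert res.converged

    def test_result_respects_limits(self, clean_training):
        training, topo = clean_training
        limits = ParameterLimits.with_omega(-1, 1)
        res = reverse_engineer(
            training, "ann", limits=limits, topology=topo,
            pso=PSOConfig(max_evaluations=2_000, seed=1),
        )
        p = res.params
        assert np.all(np.abs(p.omega) <= 1.0)
        assert np.all(p.alpha >= limits.alpha_interval[0] - 1e-12)
        assert np.all(p.alpha <= limits.alpha_interval[1] + 1e-12)
        assert np.all(p.omega[topo.sign == 0] == 0)
        assert np.all(np.diff(res.trace) <= 0)

    def test_small_budget_recovery_progress(self, clean_training):
        """Even a small budget should fit noise-free data far below the
        trivial baseline."""
        training, topo = clean_training
        res = reverse_engineer(
            training, "ann", topology=topo,
            pso=PSOConfig(max_evaluations=6_000, seed=2),
        )
        assert res.training_error < 0.1

    def test_summary_and_json(self, clean_training, tmp_path):
        training, topo = clean_training
        res = reverse_engineer(
            training, "ann", topology=topo,
            pso=PSOConfig(max_evaluations=1_000, seed=3),
        )
        text = res.summary()
        assert "training NRMSE" in text and "ann" in text
        out = tmp_path / "fit.json"
        res.to_json(out)
        import json

        d = json.loads(out.read_text())
        assert d["training_error"] == pytest.approx(res.training_error)
        assert len(d["trace"]) >= 1

    def test_rejects_constant_training_data(self):
        from grnfit import TimeCourseDataset

        ds = TimeCourseDataset(np.arange(4.0), np.ones((4, 2)))
        with pytest.raises(ValueError, match="constant"):
            GRNModel(ds, "ann")


def test_plot_fit_renders(tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    spec = SystemSpec.builtin("A", 1, "ann", seed=13)
    train, val = make_dataset_pair(spec)
    res = reverse_engineer(train, "ann", topology=spec.topology,
                           pso=PSOConfig(max_evaluations=500, seed=0))
    axes = res.plot_fit(validation=val)
    assert len(axes) == 2
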