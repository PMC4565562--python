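"""Reverse-engineering GRN models from time-course data.

The estimation problem is framed statsmodels-style: :class:`GRNModel` binds
a training dataset to a rate law, parameter limits and (optionally) a known
network topology; :meth:`GRNModel.fit` runs multi-swarm PSO over the
flattened parameter box, scoring every candidate by the NRMSE between the
training data and the candidate's trajectory integrated from the training
set's first row.  The returned :class:`GRNResults` carries the estimated
parameters, the training error, the optimizer trace, and methods to
validate on independent data, re-simulate and summarize.

Candidate trajectories are integrated with a fixed-step RK4 kernel that is
vectorized over the whole particle population (see ``simulate.simulate_batch``);
candidates whose integration blows up receive a large finite penalty so the
swarm keeps moving.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import TimeCourseDataset
from .evaluation import PENALTY_ERROR, nrmse_values, validate_model
from .pso import PSOConfig, PSOResult, pso_minimize
from .rate_laws import GRNModelParameters, RateLaw
from .simulate import simulate, simulate_batch
from .topology import GeneNetworkTopology

__all__ = [
    "ParameterLimits",
    "ParameterCodec",
    "GRNModel",
    "GRNResults",
    "InferenceResult",
    "reverse_engineer",
]


@dataclass(frozen=True)
class ParameterLimits:
    """Box constraints of the search space.

    The omega interval is the experimental factor of the benchmark; the
    remaining intervals bound the kinetic parameters.  The alpha ceiling is
    deliberately generous (50): since only the relative magnitudes of the
    omega weights matter, a model restricted to a narrow omega interval
    compensates by scaling its maximal synthesis rates, and the box must
    leave room for that trade-off.
    """

    omega_interval: tuple[float, float] = (-1.0, 1.0)
    alpha_interval: tuple[float, float] = (0.1, 50.0)
    beta_interval: tuple[float, float] = (0.1, 5.0)
    gamma_interval: tuple[float, float] | None = None  # rate-law dependent default
    hill_n_interval: tuple[float, float] = (0.5, 8.0)

    HILL_GAMMA_DEFAULT = (0.05, 3.0)
    ANN_GAMMA_DEFAULT = (-5.0, 5.0)

    def __post_init__(self) -> None:
        for name, iv in (
            ("omega_interval", self.omega_interval),
            ("alpha_interval", self.alpha_interval),
            ("beta_interval", self.beta_interval),
            ("hill_n_interval", self.hill_n_interval),
        ):
            if iv[0] >= iv[1]:
                raise ValueError(f"{name}: lo must be < hi")
        for name in ("alpha_interval", "beta_interval", "hill_n_interval"):
            if getattr(self, name)[0] <= 0:
                raise ValueError(f"{name} must lie in (0, inf)")
        if self.gamma_interval is not None and self.gamma_interval[0] >= self.gamma_interval[1]:
            raise ValueError("gamma_interval: lo must be < hi")

    def gamma_for(self, rate_law: RateLaw) -> tuple[float, float]:
        if self.gamma_interval is not None:
            if rate_law is RateLaw.HILL and self.gamma_interval[0] <= 0:
                raise ValueError("Hill gamma interval must be positive")
            return self.gamma_interval
        return self.HILL_GAMMA_DEFAULT if rate_law is RateLaw.HILL else self.ANN_GAMMA_DEFAULT

    @classmethod
    def with_omega(cls, lo: float, hi: float, **kwargs) -> "ParameterLimits":
        return cls(omega_interval=(float(lo), float(hi)), **kwargs)


class ParameterCodec:
    """Flatten a GRN parameter set to/from an optimizer vector.

    Without a topology every omega (and Hill-n) entry is searched: a 5-gene
    Hill model has 25 + 5 + 5 + 5 + 25 = 65 dimensions.  With a known
    topology only the support's entries get dimensions (System A's 8 edges:
    8 + 5 + 5 + 5 + 8 = 31) and, in sign-constrained mode (the default),
    each searched omega is restricted to the half-interval matching the
    topology's sign.

    Strictly positive kinetic parameters (alpha, beta, Hill gamma, Hill n)
    are searched on a log scale — they are scale parameters and their
    intervals span orders of magnitude — while omega (signed) and the ANN
    threshold gamma stay linear.  ``encode``/``decode`` hide the transform:
    vectors handed to the optimizer are in search (log) coordinates, model
    parameters are always in natural units.
    """

    def __init__(
        self,
        n_genes: int,
        rate_law: RateLaw | str,
        limits: ParameterLimits,
        topology: GeneNetworkTopology | None = None,
        constrain_signs: bool = True,
        gene_names: tuple[str, ...] = (),
    ) -> None:
        self.n_genes = n_genes
        self.rate_law = RateLaw.coerce(rate_law)
        self.limits = limits
        self.topology = topology
        self.constrain_signs = constrain_signs
        self.gene_names = gene_names or tuple(f"g{k + 1}" for k in range(n_genes))
        if topology is not None and topology.n_genes != n_genes:
            raise ValueError("topology size does not match n_genes")

        n = n_genes
        if topology is None:
            self.omega_idx = [(i, j) for i in range(n) for j in range(n)]
            self.omega_signs = [0] * len(self.omega_idx)
        else:
            self.omega_idx = [(i, j) for i, j, _ in topology.edges()]
            self.omega_signs = [s for _, _, s in topology.edges()]

        lo_w, hi_w = limits.omega_interval
        bounds: list[tuple[float, float]] = []
        for s in self.omega_signs:
            if topology is not None and constrain_signs and s != 0:
                bounds.append((0.0, hi_w) if s > 0 else (lo_w, 0.0))
            else:
                bounds.append((lo_w, hi_w))
        log_flags = [False] * len(self.omega_idx)
        bounds += [limits.alpha_interval] * n
        log_flags += [True] * n
        bounds += [limits.beta_interval] * n
        log_flags += [True] * n
        gamma_iv = limits.gamma_for(self.rate_law)
        bounds += [gamma_iv] * n
        log_flags += [self.rate_law is RateLaw.HILL] * n
        if self.rate_law is RateLaw.HILL:
            bounds += [limits.hill_n_interval] * len(self.omega_idx)
            log_flags += [True] * len(self.omega_idx)
        natural = np.asarray(bounds, dtype=float)
        self.log_scale = np.asarray(log_flags, dtype=bool)
        self.natural_bounds = natural
        self.bounds = natural.copy()
        self.bounds[self.log_scale] = np.log(natural[self.log_scale])

    def _to_search(self, vec: np.ndarray) -> np.ndarray:
        out = np.array(vec, dtype=float)
        out[..., self.log_scale] = np.log(out[..., self.log_scale])
        return out

    def _to_natural(self, vec: np.ndarray) -> np.ndarray:
        out = np.array(vec, dtype=float)
        out[..., self.log_scale] = np.exp(out[..., self.log_scale])
        return out

    @property
    def dim(self) -> int:
        return self.bounds.shape[0]

    def _slices(self):
        m, n = len(self.omega_idx), self.n_genes
        return (
            slice(0, m),
            slice(m, m + n),
            slice(m + n, m + 2 * n),
            slice(m + 2 * n, m + 3 * n),
            slice(m + 3 * n, m + 3 * n + m),
        )

    def encode(self, params: GRNModelParameters) -> np.ndarray:
        if params.rate_law is not self.rate_law:
            raise ValueError("rate law mismatch")
        sw, sa, sb, sg, sn = self._slices()
        vec = np.empty(self.dim)
        vec[sw] = [params.omega[i, j] for i, j in self.omega_idx]
        vec[sa] = params.alpha
        vec[sb] = params.beta
        vec[sg] = params.gamma
        if self.rate_law is RateLaw.HILL:
            vec[sn] = [params.hill_n[i, j] for i, j in self.omega_idx]
        nb = self.natural_bounds
        if np.any(vec < nb[:, 0] - 1e-12) or np.any(vec > nb[:, 1] + 1e-12):
            raise ValueError("parameters fall outside the search limits")
        if self.topology is not None:
            off = np.ones((self.n_genes, self.n_genes), bool)
            for i, j in self.omega_idx:
                off[i, j] = False
            if np.any(params.omega[off] != 0):
                raise ValueError("omega has support outside the known topology")
        return self._to_search(vec)

    def decode(self, vec: np.ndarray) -> GRNModelParameters:
        vec = self._to_natural(np.asarray(vec, float))
        sw, sa, sb, sg, sn = self._slices()
        n = self.n_genes
        omega = np.zeros((n, n))
        for k, (i, j) in enumerate(self.omega_idx):
            omega[i, j] = vec[sw][k]
        hill_n = None
        if self.rate_law is RateLaw.HILL:
            hill_n = np.ones((n, n))
            for k, (i, j) in enumerate(self.omega_idx):
                hill_n[i, j] = vec[sn][k]
        return GRNModelParameters(
            rate_law=self.rate_law,
            alpha=vec[sa].copy(),
            beta=vec[sb].copy(),
            gamma=vec[sg].copy(),
            omega=omega,
            hill_n=hill_n,
            gene_names=self.gene_names,
        )

    def decode_batch(self, X: np.ndarray) -> dict:
        """Decode an (P, dim) population into stacked parameter arrays."""
        X = self._to_natural(np.asarray(X, float))
        P, n = X.shape[0], self.n_genes
        sw, sa, sb, sg, sn = self._slices()
        omega = np.zeros((P, n, n))
        rows = [i for i, _ in self.omega_idx]
        cols = [j for _, j in self.omega_idx]
        omega[:, rows, cols] = X[:, sw]
        hill_n = None
        if self.rate_law is RateLaw.HILL:
            hill_n = np.ones((P, n, n))
            hill_n[:, rows, cols] = X[:, sn]
        return {
            "rate_law": self.rate_law,
            "alpha": X[:, sa],
            "beta": X[:, sb],
            "gamma": X[:, sg],
            "omega": omega,
            "hill_n": hill_n,
        }


class GRNModel:
    """Reverse-engineering problem: fit a rate law to a training series.

    Parameters
    ----------
    training
        Observed expression time course; the first row is the initial
        condition every candidate is simulated from.
    rate_law
        ``'hill'`` or ``'ann'``.
    limits
        Search box (:class:`ParameterLimits`); the omega interval is the
        experimental factor.
    topology
        Optional known network structure.  When given, zero entries are
        fixed at 0 and excluded from the search; with
        ``constrain_signs=True`` (default) each searched weight is also
        restricted to its known sign's half-interval.
    substeps
        RK4 sub-steps per observed interval in the objective integrator.
    """

    def __init__(
        self,
        training: TimeCourseDataset,
        rate_law: RateLaw | str,
        limits: ParameterLimits | None = None,
        topology: GeneNetworkTopology | None = None,
        constrain_signs: bool = True,
        per_gene_nrmse: bool = False,
        substeps: int = 8,
    ) -> None:
        if training.n_timepoints < 2:
            raise ValueError("training data needs at least 2 time points")
        self.training = training
        self.rate_law = RateLaw.coerce(rate_law)
        self.limits = limits or ParameterLimits()
        self.topology = topology
        self.constrain_signs = constrain_signs
        self.per_gene_nrmse = per_gene_nrmse
        self.substeps = substeps
        self.codec = ParameterCodec(
            training.n_genes,
            self.rate_law,
            self.limits,
            topology,
            constrain_signs,
            training.gene_names,
        )
        rng = training.values.max() - training.values.min()
        if rng == 0:
            raise ValueError("training data is constant; NRMSE undefined")

    @classmethod
    def from_csv(cls, path, rate_law, **kwargs) -> "GRNModel":
        return cls(TimeCourseDataset.from_csv(path), rate_law, **kwargs)

    @property
    def dim(self) -> int:
        return self.codec.dim

    def objective_batch(self, X: np.ndarray) -> np.ndarray:
        """Training NRMSE of every row of ``X`` (one candidate per row)."""
        batch = self.codec.decode_batch(np.atleast_2d(X))
        values, failed = simulate_batch(
            x0=self.training.x0,
            times=self.training.times,
            substeps=self.substeps,
            **batch,
        )
        obs = self.training.values
        if self.per_gene_nrmse:
            rng = obs.max(axis=0) - obs.min(axis=0)
            err = np.sqrt(np.mean(((values - obs[None]) / rng) ** 2, axis=(1, 2)))
        else:
            rng = obs.max() - obs.min()
            err = np.sqrt(np.mean((values - obs[None]) ** 2, axis=(1, 2))) / rng
        err = np.where(failed | ~np.isfinite(err), PENALTY_ERROR, err)
        return err

    def loss(self, params: GRNModelParameters) -> float:
        """Training NRMSE of one parameter set, via the reference
        (adaptive) integrator."""
        sim = simulate(params, self.training.x0, self.training.times)
        if sim.meta.get("failed"):
            return PENALTY_ERROR
        return nrmse_values(sim.values, self.training.values, per_gene=self.per_gene_nrmse)

    def fit(self, pso: PSOConfig | None = None, seed: int | None = None) -> "GRNResults":
        """Run multi-swarm PSO and return the best candidate found."""
        config = pso or PSOConfig()
        if seed is not None:
            config = PSOConfig(**{**config.__dict__, "seed": int(seed)})
        res = pso_minimize(self.objective_batch, self.codec.bounds, config, vectorized=True)
        params = self.codec.decode(res.best_vector)
        return GRNResults(model=self, params=params, optimizer_result=res, seed=config.seed)


@dataclass
class GRNResults:
    """Estimation results: parameters, training error, optimizer trace."""

    model: GRNModel
    params: GRNModelParameters
    optimizer_result: PSOResult
    seed: int
    _extra: dict = field(default_factory=dict)

    @property
    def training_error(self) -> float:
        return self.optimizer_result.best_value

    @property
    def trace(self) -> np.ndarray:
        return self.optimizer_result.trace

    @property
    def n_evaluations(self) -> int:
        return self.optimizer_result.n_evaluations

    @property
    def converged(self) -> bool:
        return self.optimizer_result.converged

    def predict(self, x0: np.ndarray | None = None, times: np.ndarray | None = None) -> TimeCourseDataset:
        """Simulate the fitted model (defaults: training grid and x0)."""
        x0 = self.model.training.x0 if x0 is None else x0
        times = self.model.training.times if times is None else times
        return simulate(self.params, x0, times, meta={"role": "prediction"})

    def validate(self, validation: TimeCourseDataset) -> float:
        """Predictive NRMSE on an independent series (its own x0 and grid)."""
        return validate_model(self.params, validation, per_gene=self.model.per_gene_nrmse)

    def summary(self) -> str:
        p = self.params
        lines = [
            "GRN reverse-engineering results",
            "=" * 46,
            f"rate law:          {p.rate_law.value}",
            f"genes:             {p.n_genes} ({', '.join(p.gene_names)})",
            f"search dimensions: {self.model.dim}",
            f"omega interval:    {self.model.limits.omega_interval}",
            f"training NRMSE:    {self.training_error:.4f}",
            f"evaluations:       {self.n_evaluations}",
            f"converged:         {self.converged}",
            "-" * 46,
            "gene   alpha     beta      gamma",
        ]
        for k, name in enumerate(p.gene_names):
            lines.append(
                f"{name:<6} {p.alpha[k]:<9.4f} {p.beta[k]:<9.4f} {p.gamma[k]:<9.4f}"
            )
        lines.append("-" * 46)
        lines.append("omega (rows = targets, cols = regulators):")
        with np.printoptions(precision=3, suppress=True):
            lines.append(str(p.omega))
        return "\n".join(lines)

    def plot_fit(self, validation: TimeCourseDataset | None = None, ax=None):
        """Observed training data (dots) against the fitted trajectories
        (lines); optionally a second panel for a validation series."""
        import matplotlib.pyplot as plt

        datasets = [("training", self.model.training)]
        if validation is not None:
            datasets.append(("validation", validation))
        if ax is None:
            _, axes = plt.subplots(1, len(datasets), figsize=(6 * len(datasets), 4),
                                   squeeze=False)
            axes = axes[0]
        else:
            axes = [ax]
        for a, (role, ds) in zip(axes, datasets):
            sim = simulate(self.params, ds.x0, ds.times)
            for k, name in enumerate(ds.gene_names):
                line, = a.plot(ds.times, sim.values[:, k], label=name)
                a.plot(ds.times, ds.values[:, k], "o", ms=3, color=line.get_color())
            a.set_title(f"{role} fit ({self.params.rate_law.value})")
            a.set_xlabel("time")
            a.set_ylabel("expression")
            a.legend(fontsize="small")
        return axes

    def to_dict(self) -> dict:
        return {
            "rate_law": self.params.rate_law.value,
            "params": self.params.to_dict(),
            "training_error": self.training_error,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "seed": self.seed,
            "trace": self.trace.tolist(),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


InferenceResult = GRNResults


def reverse_engineer(
    training: TimeCourseDataset,
    rate_law: RateLaw | str,
    limits: ParameterLimits | None = None,
    topology: GeneNetworkTopology | None = None,
    pso: PSOConfig | None = None,
    constrain_signs: bool = True,
    seed: int | None = None,
    substeps: int = 8,
) -> GRNResults:
    """One-call reverse engineering: build a :class:`GRNModel` and fit it."""
    model = GRNModel(
        training,
        rate_law,
        limits=limits,
        topology=topology,
        constrain_signs=constrain_signs,
        substeps=substeps,
    )
    return model.fit(pso=pso, seed=seed)
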