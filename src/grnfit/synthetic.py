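"""Synthetic benchmark systems and noisy training/validation data.

A *generating system* is a GRN whose omega entries take only the three
values {−m, 0, +m} for a magnitude m ∈ {1, 5, 10, 20}: the sign pattern is
the network topology, the magnitude is the experimental variant.  Kinetic
parameters (alpha, beta, gamma, Hill n) are sampled from configurable
uniform ranges chosen to keep the dynamics in an order-one, numerically
benign regime; every dataset records the sampled ground truth in its
metadata sidecar.

Measurement noise is zero-mean Gaussian with a scale tied to the global
range of the clean expression values: with ``scale_mode='variance'`` the
noise variance is ``level x range`` (the benchmark's literal convention),
with ``'sd'`` the standard deviation is ``level x range``.  Noisy values
are clamped at zero, as concentrations are non-negative.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .data import TimeCourseDataset
from .rate_laws import GRNModelParameters, RateLaw
from .simulate import default_time_grid, simulate
from .topology import GeneNetworkTopology, builtin_topology

__all__ = [
    "KineticSampler",
    "SystemSpec",
    "NoiseSpec",
    "instantiate_system",
    "add_noise",
    "make_dataset_pair",
    "OMEGA_MAGNITUDES",
]

OMEGA_MAGNITUDES = (1.0, 5.0, 10.0, 20.0)


@dataclass(frozen=True)
class KineticSampler:
    """Uniform sampling ranges for the kinetic parameters of a generating
    system (and its initial conditions)."""

    alpha: tuple[float, float] = (0.5, 2.0)
    beta: tuple[float, float] = (0.5, 2.0)
    hill_gamma: tuple[float, float] = (0.3, 1.5)
    hill_n: tuple[float, float] = (1.0, 4.0)
    ann_gamma: tuple[float, float] = (-1.0, 1.0)
    x0: tuple[float, float] = (0.1, 1.0)

    def _draw(self, rng: np.random.Generator, lohi: tuple[float, float], shape):
        return rng.uniform(lohi[0], lohi[1], size=shape)


@dataclass(frozen=True)
class SystemSpec:
    """One generating system: topology x omega magnitude x rate law."""

    topology: GeneNetworkTopology
    omega_magnitude: float
    rate_law: RateLaw
    kinetic_sampler: KineticSampler = field(default_factory=KineticSampler)
    seed: int = 0
    system_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "rate_law", RateLaw.coerce(self.rate_law))
        if self.omega_magnitude <= 0:
            raise ValueError("omega_magnitude must be positive")

    @classmethod
    def builtin(
        cls,
        system_id: str,
        omega_magnitude: float,
        rate_law: RateLaw | str,
        seed: int = 0,
        kinetic_sampler: KineticSampler | None = None,
    ) -> "SystemSpec":
        return cls(
            topology=builtin_topology(system_id),
            omega_magnitude=float(omega_magnitude),
            rate_law=RateLaw.coerce(rate_law),
            kinetic_sampler=kinetic_sampler or KineticSampler(),
            seed=seed,
            system_id=system_id.upper(),
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian measurement-noise configuration.

    ``level x (global range)`` is the noise *variance* when
    ``scale_mode='variance'`` and the *standard deviation* when ``'sd'``.
    """

    level: float = 0.15
    scale_mode: str = "variance"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("noise level must be >= 0")
        if self.scale_mode not in ("variance", "sd"):
            raise ValueError("scale_mode must be 'variance' or 'sd'")

    def sigma(self, value_range: float) -> float:
        scale = self.level * value_range
        return float(np.sqrt(scale)) if self.scale_mode == "variance" else float(scale)


def instantiate_system(spec: SystemSpec) -> GRNModelParameters:
    """Draw kinetic parameters for a generating system.

    omega[i, j] = sign[i, j] * magnitude, so entries take only the values
    {-m, 0, +m}; alpha, beta, gamma (and Hill n for the Hill law) are drawn
    from the spec's kinetic sampler under its seed.
    """
    rng = np.random.default_rng(spec.seed)
    ks = spec.kinetic_sampler
    n = spec.topology.n_genes
    alpha = ks._draw(rng, ks.alpha, n)
    beta = ks._draw(rng, ks.beta, n)
    if spec.rate_law is RateLaw.HILL:
        gamma = ks._draw(rng, ks.hill_gamma, n)
        hill_n = ks._draw(rng, ks.hill_n, (n, n))
        if np.any(gamma <= 0) or np.any(hill_n <= 0):
            raise ValueError("kinetic sampler produced non-positive gamma or n for Hill")
    else:
        gamma = ks._draw(rng, ks.ann_gamma, n)
        hill_n = None
    if np.any(alpha <= 0) or np.any(beta <= 0):
        raise ValueError("kinetic sampler produced non-positive alpha or beta")
    omega = spec.topology.sign * spec.omega_magnitude
    return GRNModelParameters(
        rate_law=spec.rate_law,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        omega=omega,
        hill_n=hill_n,
        gene_names=spec.topology.gene_names,
    )


def add_noise(data: TimeCourseDataset, noise: NoiseSpec) -> TimeCourseDataset:
    """Perturb every value with independent zero-mean Gaussian noise.

    The scale is tied to the dataset's global range (see :class:`NoiseSpec`);
    results are clamped at zero from below and the returned metadata records
    the noise settings.
    """
    sigma = noise.sigma(data.value_range)
    if sigma == 0.0:
        return data.with_values(data.values.copy(), noisy=noise.level > 0)
    rng = np.random.default_rng(noise.seed)
    noisy = data.values + rng.normal(0.0, sigma, size=data.values.shape)
    return data.with_values(
        np.maximum(noisy, 0.0),
        noisy=True,
        noise_level=noise.level,
        noise_mode=noise.scale_mode,
        noise_sigma=sigma,
        noise_seed=noise.seed,
    )


def make_dataset_pair(
    spec: SystemSpec,
    n_timepoints: int = 16,
    noise: NoiseSpec | None = None,
    t_end: float = 15.0,
    max_retries: int = 10,
) -> tuple[TimeCourseDataset, TimeCourseDataset]:
    """Simulate one training and one validation series from a generating
    system, started from independently drawn initial conditions, then add
    noise.

    If the sampled kinetics produce an unintegrable system, the kinetics are
    re-drawn (up to ``max_retries`` times) under a perturbed seed.  Metadata
    carries the full ground-truth parameter set of the generating system.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    noise = noise if noise is not None else NoiseSpec(seed=spec.seed)
    times = default_time_grid(n_timepoints, t_end)

    last_err = None
    for attempt in range(max_retries):
        trial = dataclasses.replace(spec, seed=spec.seed + 1_000_003 * attempt)
        params = instantiate_system(trial)
        rng = np.random.default_rng(trial.seed + 17)
        ks = trial.kinetic_sampler
        x0_train = ks._draw(rng, ks.x0, params.n_genes)
        x0_val = ks._draw(rng, ks.x0, params.n_genes)
        while np.array_equal(x0_val, x0_train):  # validation must start elsewhere
            x0_val = ks._draw(rng, ks.x0, params.n_genes)
        base_meta = {
            "system_id": spec.system_id or "custom",
            "system_rate_law": spec.rate_law.value,
            "omega_magnitude": spec.omega_magnitude,
            "seed": trial.seed,
        }
        train = simulate(params, x0_train, times, meta={**base_meta, "role": "training"})
        val = simulate(params, x0_val, times, meta={**base_meta, "role": "validation"})
        if train.meta["failed"] or val.meta["failed"]:
            last_err = "integration failure"
            continue
        truth = params.to_dict()
        noisy_train = add_noise(
            train, dataclasses.replace(noise, seed=noise.seed + 2 * attempt)
        )
        noisy_val = add_noise(
            val, dataclasses.replace(noise, seed=noise.seed + 2 * attempt + 1)
        )
        for ds, clean in ((noisy_train, train), (noisy_val, val)):
            ds.meta["ground_truth"] = truth
            ds.meta["clean_values"] = clean.values
        return noisy_train, noisy_val
    raise RuntimeError(
        f"could not generate an integrable system after {max_retries} attempts: {last_err}"
    )
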