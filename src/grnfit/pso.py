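"""Multi-swarm particle swarm optimization over a box.

Several independent swarms explore the same search box; every
``migration_interval`` iterations each swarm swaps a few randomly chosen
particles (position, velocity and personal best) with the next swarm in a
ring, which maintains diversity without coupling the swarms' social
attractors.  Per-dimension velocities are clamped to half the box width and
positions are clipped to the bounds.

The default coefficients follow Pedersen's tuned-parameter guidelines
(inertia 0.3925, cognitive 2.5586, social 1.3358), which work well across
budgets of 10^4–10^5 function evaluations without per-problem tuning.  The
default geometry is 2 swarms of 40 particles: at these budgets fewer,
larger swarms give each particle more iterations and measurably better
final errors on the package's estimation problems than many small swarms,
while keeping the diversity benefit of migration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PSOConfig", "PSOResult", "pso_minimize"]


@dataclass(frozen=True)
class PSOConfig:
    n_swarms: int = 2
    particles_per_swarm: int = 40
    inertia: float = 0.3925
    cognitive: float = 2.5586
    social: float = 1.3358
    migration_interval: int = 50
    n_migrants: int = 2
    max_evaluations: int = 20_000
    error_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_swarms < 1 or self.particles_per_swarm < 1:
            raise ValueError("swarm and particle counts must be positive")
        if self.n_migrants < 0 or self.migration_interval < 1:
            raise ValueError("invalid migration settings")
        if self.max_evaluations < self.n_swarms * self.particles_per_swarm:
            raise ValueError("max_evaluations must cover at least one full batch")

    @property
    def population(self) -> int:
        return self.n_swarms * self.particles_per_swarm


@dataclass
class PSOResult:
    best_vector: np.ndarray
    best_value: float
    trace: np.ndarray  # best-so-far after each iteration (non-increasing)
    n_evaluations: int
    converged: bool  # best_value dropped below error_threshold


def pso_minimize(objective, bounds, config: PSOConfig | None = None, vectorized: bool = False) -> PSOResult:
    """Minimize ``objective`` over the box ``bounds``.

    Parameters
    ----------
    objective
        Maps a parameter vector to a finite value.  With
        ``vectorized=True`` it must instead accept an ``(N, d)`` array and
        return ``N`` values; the optimizer then evaluates the whole
        population in one call per iteration.
    bounds
        Sequence of ``(lo, hi)`` pairs, one per dimension.
    """
    config = config or PSOConfig()
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be a sequence of (lo, hi) pairs")
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(~np.isfinite(bounds)) or np.any(lo >= hi):
        raise ValueError("bounds must be finite with lo < hi")
    d = bounds.shape[0]
    rng = np.random.default_rng(config.seed)

    if vectorized:
        evaluate = lambda X: np.asarray(objective(X), dtype=float)
    else:
        evaluate = lambda X: np.array([float(objective(x)) for x in X])

    S, K = config.n_swarms, config.particles_per_swarm
    N = S * K
    vmax = 0.5 * (hi - lo)

    x = rng.uniform(lo, hi, size=(N, d))
    v = rng.uniform(-vmax, vmax, size=(N, d))
    swarm_of = np.repeat(np.arange(S), K)

    fx = evaluate(x)
    n_evals = N
    pbest_x, pbest_f = x.copy(), fx.copy()

    def swarm_best():
        gx = np.empty((S, d))
        gf = np.empty(S)
        for s in range(S):
            idx = np.where(swarm_of == s)[0]
            b = idx[np.argmin(pbest_f[idx])]
            gx[s], gf[s] = pbest_x[b], pbest_f[b]
        return gx, gf

    gbest_x, gbest_f = swarm_best()
    best = float(gbest_f.min())
    trace = [best]
    iteration = 0

    while best >= config.error_threshold and n_evals + N <= config.max_evaluations:
        iteration += 1
        r1 = rng.random((N, d))
        r2 = rng.random((N, d))
        v = (
            config.inertia * v
            + config.cognitive * r1 * (pbest_x - x)
            + config.social * r2 * (gbest_x[swarm_of] - x)
        )
        np.clip(v, -vmax, vmax, out=v)
        x = np.clip(x + v, lo, hi)

        fx = evaluate(x)
        n_evals += N
        improved = fx < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = fx[improved]

        if config.n_migrants and iteration % config.migration_interval == 0 and S > 1:
            for s in range(S):
                t = (s + 1) % S
                a = rng.choice(np.where(swarm_of == s)[0], config.n_migrants, replace=False)
                b = rng.choice(np.where(swarm_of == t)[0], config.n_migrants, replace=False)
                for arr in (x, v, pbest_x):
                    arr[a], arr[b] = arr[b].copy(), arr[a].copy()
                pbest_f[a], pbest_f[b] = pbest_f[b].copy(), pbest_f[a].copy()

        gbest_x, gbest_f = swarm_best()
        best = min(best, float(gbest_f.min()))
        trace.append(best)

    k = int(np.argmin(pbest_f))
    return PSOResult(
        best_vector=pbest_x[k].copy(),
        best_value=float(pbest_f[k]),
        trace=np.asarray(trace),
        n_evaluations=n_evals,
        converged=best < config.error_threshold,
    )
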