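"""Numerical integration of GRN models.

Two paths:

* :func:`simulate` — adaptive Runge–Kutta (scipy ``solve_ivp``) for a single
  parameter set; the reference integrator used for data generation and model
  validation.  Integration failures are flagged in the returned dataset's
  metadata rather than raised, so optimization loops can penalize them.
* :func:`simulate_batch` — fixed-step classical RK4 evaluated for a whole
  population of parameter sets at once.  This is the inference objective's
  workhorse: the regulation kernels broadcast over particles, so one step
  advances every candidate model simultaneously.  Candidates whose state
  blows up or turns non-finite are marked failed and frozen.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .data import TimeCourseDataset
from .rate_laws import (
    GRNModelParameters,
    RateLaw,
    ann_rhs_batch,
    hill_rhs_batch,
    rhs,
)

__all__ = ["simulate", "simulate_batch", "default_time_grid"]

# Default synthetic time grid: 16 uniform points on [0, 15] (arbitrary units).
DEFAULT_T_END = 15.0
DEFAULT_N_POINTS = 16

_STATE_CAP = 1e8  # batch states beyond this magnitude count as blow-up


def default_time_grid(n_points: int = DEFAULT_N_POINTS, t_end: float = DEFAULT_T_END) -> np.ndarray:
    return np.linspace(0.0, t_end, n_points)


def simulate(
    params: GRNModelParameters,
    x0: np.ndarray,
    times: np.ndarray,
    method: str = "RK45",
    rtol: float = 1e-6,
    atol: float = 1e-9,
    meta: dict | None = None,
) -> TimeCourseDataset:
    """Integrate ``params`` from ``x0`` over ``times``.

    The first output row equals ``x0`` exactly; later rows are the adaptive
    solution, with negative round-off clamped to zero.  On solver failure the
    returned dataset has ``meta['failed'] = True`` and the unreached rows
    hold the last valid state.
    """
    x0 = np.asarray(x0, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(~np.isfinite(x0)) or np.any(x0 < 0):
        raise ValueError("x0 must be finite and non-negative")
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    def fun(_t, x):
        # concentrations floor at zero: evaluate the rate at the clamped
        # state and forbid further decrease below the floor
        d = rhs(params, np.maximum(x, 0.0))
        return np.where((x <= 0.0) & (d < 0.0), 0.0, d)

    md = dict(meta or {})
    md.setdefault("rate_law", params.rate_law.value)
    values = np.empty((times.size, x0.size))
    values[0] = x0
    failed = False
    try:
        sol = solve_ivp(
            fun,
            (times[0], times[-1]),
            x0,
            method=method,
            t_eval=times,
            rtol=rtol,
            atol=atol,
        )
        ok = sol.success and sol.y.shape[1] == times.size and np.all(np.isfinite(sol.y))
        if ok:
            values[1:] = sol.y.T[1:]
        else:
            got = min(sol.y.shape[1], times.size)
            if got > 1 and np.all(np.isfinite(sol.y[:, :got])):
                values[1:got] = sol.y.T[1:got]
                values[got:] = sol.y.T[got - 1]
            else:
                values[1:] = x0
            failed = True
    except (ValueError, FloatingPointError, OverflowError):
        values[1:] = x0
        failed = True
    md["failed"] = failed
    return TimeCourseDataset(times, np.maximum(values, 0.0), params.gene_names, md)


def simulate_batch(
    rate_law: RateLaw | str,
    alpha: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
    omega: np.ndarray,
    hill_n: np.ndarray | None,
    x0: np.ndarray,
    times: np.ndarray,
    substeps: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 for a population of P parameter sets.

    Parameters are stacked along a leading particle axis: ``alpha``, ``beta``,
    ``gamma`` of shape (P, n); ``omega`` and ``hill_n`` of shape (P, n, n).
    ``x0`` is either a shared (n,) vector or per-particle (P, n).

    Returns ``(values, failed)`` with ``values`` of shape (P, T, n) (clamped
    at zero, first slice = x0) and a boolean failure mask of shape (P,).
    Failed particles keep whatever rows were computed before blow-up.
    """
    law = RateLaw.coerce(rate_law)
    batch_rhs = hill_rhs_batch if law is RateLaw.HILL else ann_rhs_batch
    alpha = np.asarray(alpha, float)
    P, n = alpha.shape
    times = np.asarray(times, float)
    x0 = np.asarray(x0, float)
    x = np.broadcast_to(x0, (P, n)).copy()

    values = np.empty((P, times.size, n))
    values[:, 0] = x
    failed = np.zeros(P, dtype=bool)

    def f(state):
        # same zero-floor convention as the adaptive path
        d = batch_rhs(state, alpha, beta, gamma, omega, hill_n)
        return np.where((state <= 0.0) & (d < 0.0), 0.0, d)

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for t_idx in range(1, times.size):
            h = (times[t_idx] - times[t_idx - 1]) / substeps
            for _ in range(substeps):
                k1 = f(x)
                k2 = f(x + 0.5 * h * k1)
                k3 = f(x + 0.5 * h * k2)
                k4 = f(x + h * k3)
                x = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
                bad = ~np.all(np.isfinite(x), axis=1) | (
                    np.max(np.abs(x), axis=1, initial=0.0) > _STATE_CAP
                )
                newly = bad & ~failed
                if newly.any():
                    failed |= newly
                if failed.any():
                    x[failed] = values[failed, t_idx - 1]  # freeze failed particles
                x = np.maximum(x, 0.0)
            values[:, t_idx] = x
    return values, failed


def params_to_batch(params_list: list[GRNModelParameters]) -> dict:
    """Stack homogeneous parameter sets into batch arrays."""
    law = params_list[0].rate_law
    out = {
        "rate_law": law,
        "alpha": np.stack([p.alpha for p in params_list]),
        "beta": np.stack([p.beta for p in params_list]),
        "gamma": np.stack([p.gamma for p in params_list]),
        "omega": np.stack([p.omega for p in params_list]),
        "hill_n": (
            np.stack([p.hill_n for p in params_list]) if law is RateLaw.HILL else None
        ),
    }
    return out
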