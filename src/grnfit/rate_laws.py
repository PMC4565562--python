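"""Semi-mechanistic transcription rate laws.

Two right-hand sides for gene-expression ODE models over *n* genes:

Hill law::

    dx_i/dt = alpha_i * sum_j omega_ij * r_ij(x_j)  -  beta_i * x_i
    r_ij(x) = x^n_ij / (x^n_ij + gamma_i^n_ij)    if omega_ij > 0   (activation)
            = 1 / (1 + (x / gamma_i)^n_ij)        if omega_ij < 0   (repression)

ANN (sigmoidal) law::

    dx_i/dt = alpha_i * sigma(sum_j omega_ij * x_j - gamma_i) - beta_i * x_i

with sigma the logistic function.  alpha_i is the maximal synthesis rate,
beta_i the first-order degradation constant, gamma_i the activation/
repression threshold, omega_ij the signed regulation weight of gene j on
gene i, and n_ij the Hill coefficient of the edge (i, j).  An omega_ij of 0
contributes exactly nothing, so sign(omega) encodes the network topology.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .topology import GeneNetworkTopology

__all__ = [
    "RateLaw",
    "GRNModelParameters",
    "hill_regulation",
    "hill_rhs",
    "ann_rhs",
    "rhs",
]

# Solver round-off can push concentrations marginally below zero; anything
# more negative than this is a genuine domain violation.
_NEG_TOL = 1e-9


class RateLaw(str, enum.Enum):
    HILL = "hill"
    ANN = "ann"

    @classmethod
    def coerce(cls, value: "RateLaw | str") -> "RateLaw":
        if isinstance(value, RateLaw):
            return value
        return cls(str(value).lower())


@dataclass
class GRNModelParameters:
    """Full parameter set of one rate law for an n-gene network.

    ``hill_n`` is required for (and only meaningful under) the Hill law;
    ``gamma`` must be positive under Hill and may be any real under ANN.
    """

    rate_law: RateLaw
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    omega: np.ndarray
    hill_n: np.ndarray | None = None
    gene_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.rate_law = RateLaw.coerce(self.rate_law)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        n = self.alpha.shape[0]
        if self.beta.shape != (n,) or self.gamma.shape != (n,):
            raise ValueError("alpha, beta, gamma must be n-vectors of equal length")
        if self.omega.shape != (n, n):
            raise ValueError("omega must be an (n, n) matrix")
        if not (np.all(self.alpha > 0) and np.all(self.beta > 0)):
            raise ValueError("alpha and beta must be strictly positive")
        if self.rate_law is RateLaw.HILL:
            if self.hill_n is None:
                raise ValueError("Hill law requires hill_n")
            self.hill_n = np.asarray(self.hill_n, dtype=float)
            if self.hill_n.shape != (n, n):
                raise ValueError("hill_n must be an (n, n) matrix")
            if not np.all(self.gamma > 0):
                raise ValueError("Hill law requires gamma > 0")
            if not np.all(self.hill_n > 0):
                raise ValueError("Hill coefficients must be > 0")
        if not self.gene_names:
            self.gene_names = tuple(f"g{k + 1}" for k in range(n))

    @property
    def n_genes(self) -> int:
        return self.alpha.shape[0]

    def topology(self) -> GeneNetworkTopology:
        """Network structure induced by sign(omega)."""
        return GeneNetworkTopology(np.sign(self.omega).astype(int), self.gene_names)

    def to_dict(self) -> dict:
        d = {
            "rate_law": self.rate_law.value,
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "gamma": self.gamma.tolist(),
            "omega": self.omega.tolist(),
            "gene_names": list(self.gene_names),
        }
        if self.hill_n is not None:
            d["hill_n"] = self.hill_n.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GRNModelParameters":
        return cls(
            rate_law=RateLaw.coerce(d["rate_law"]),
            alpha=np.array(d["alpha"], float),
            beta=np.array(d["beta"], float),
            gamma=np.array(d["gamma"], float),
            omega=np.array(d["omega"], float),
            hill_n=np.array(d["hill_n"], float) if "hill_n" in d else None,
            gene_names=tuple(d.get("gene_names", ())),
        )


def _clean_state(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < -_NEG_TOL):
        raise ValueError(f"negative concentration in state: min={x.min()}")
    return np.maximum(x, 0.0)


def hill_regulation(x_j, gamma_i, n_ij, activating: bool):
    """Hill regulation term, in [0, 1].

    Activating: ``x^n / (x^n + gamma^n)``; repressing: ``1 / (1 + (x/gamma)^n)``.
    Vectorized over broadcastable array inputs.
    """
    x = np.asarray(x_j, dtype=float)
    gamma = np.asarray(gamma_i, dtype=float)
    n = np.asarray(n_ij, dtype=float)
    if np.any(gamma <= 0):
        raise ValueError("gamma must be > 0")
    if np.any(n <= 0):
        raise ValueError("Hill coefficient must be > 0")
    if np.any(x < 0):
        raise ValueError("concentration must be >= 0")
    with np.errstate(over="ignore"):
        t = (x / gamma) ** n  # t in [0, inf]
        act = np.where(np.isinf(t), 1.0, t / (1.0 + t))
    out = act if activating else 1.0 - act
    return out if out.ndim else float(out)


def _hill_reg_matrix(x: np.ndarray, gamma: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Activating-form regulation for every (target i, regulator j) pair.

    ``x``: (..., n_genes) states; ``gamma``: (..., n_genes) per target;
    ``n``: (..., n_genes, n_genes) per edge.  Returns (..., n, n) with
    entry [i, j] = r_act(x_j; gamma_i, n_ij).  The repressing form is its
    complement 1 − r_act.
    """
    xr = x[..., None, :]          # broadcast regulators over targets
    gr = gamma[..., :, None]      # per-target threshold
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        t = (xr / gr) ** n
        act = np.where(np.isinf(t), 1.0, t / (1.0 + t))
    # x_j = 0 with any n gives t = 0 -> act 0; guard 0/0 from x=gamma=inf etc.
    return np.nan_to_num(act, nan=0.0, posinf=1.0, neginf=0.0)


def hill_rhs(params: GRNModelParameters, x: np.ndarray) -> np.ndarray:
    """Time derivative of all transcript concentrations under the Hill law."""
    if params.rate_law is not RateLaw.HILL:
        raise ValueError("params.rate_law must be HILL")
    x = _clean_state(x)
    act = _hill_reg_matrix(x, params.gamma, params.hill_n)
    reg = np.where(params.omega > 0, act, np.where(params.omega < 0, 1.0 - act, 0.0))
    synth = params.alpha * np.einsum("ij,ij->i", params.omega, reg)
    return synth - params.beta * x


def ann_rhs(params: GRNModelParameters, x: np.ndarray) -> np.ndarray:
    """Time derivative under the ANN (logistic) law; overflow-safe."""
    if params.rate_law is not RateLaw.ANN:
        raise ValueError("params.rate_law must be ANN")
    x = _clean_state(x)
    u = params.omega @ x - params.gamma
    return params.alpha * expit(u) - params.beta * x


def rhs(params: GRNModelParameters, x: np.ndarray) -> np.ndarray:
    """Dispatch to the rate law recorded in ``params``."""
    if params.rate_law is RateLaw.HILL:
        return hill_rhs(params, x)
    return ann_rhs(params, x)


# ---------------------------------------------------------------------------
# Batched kernels: the same right-hand sides evaluated for a whole population
# of parameter sets at once (one candidate per optimizer particle).  States
# are clamped at zero rather than validated, since the caller is an ODE
# stepper whose intermediate stages may undershoot.

def hill_rhs_batch(x, alpha, beta, gamma, omega, hill_n):
    """Hill RHS for ``x`` of shape (P, n) and per-particle parameter arrays
    alpha/beta/gamma (P, n), omega/hill_n (P, n, n)."""
    x = np.maximum(x, 0.0)
    act = _hill_reg_matrix(x, gamma, hill_n)
    reg = np.where(omega > 0, act, np.where(omega < 0, 1.0 - act, 0.0))
    synth = alpha * np.einsum("pij,pij->pi", omega, reg)
    return synth - beta * x


def ann_rhs_batch(x, alpha, beta, gamma, omega, hill_n=None):
    x = np.maximum(x, 0.0)
    u = np.einsum("pij,pj->pi", omega, x) - gamma
    return alpha * expit(u) - beta * x
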