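"""Signed network topologies for gene-regulatory network (GRN) models.

A topology records, for every ordered gene pair (i, j), whether gene j
activates (+1), represses (−1) or does not regulate (0) the synthesis of
gene i's transcript.  Rows index targets, columns index regulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneNetworkTopology", "builtin_topology", "random_topology", "BUILTIN_SYSTEMS"]


@dataclass(frozen=True)
class GeneNetworkTopology:
    """Signed adjacency over *n* genes.

    Parameters
    ----------
    sign
        ``(n, n)`` integer matrix with entries in ``{-1, 0, +1}``;
        ``sign[i, j]`` is the type of regulation of gene *i*'s synthesis by
        gene *j*.
    gene_names
        Optional identifiers; default ``g1 .. gn``.
    """

    sign: np.ndarray
    gene_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        sign = np.asarray(self.sign, dtype=int)
        if sign.ndim != 2 or sign.shape[0] != sign.shape[1]:
            raise ValueError("sign must be a square matrix")
        if not np.isin(sign, (-1, 0, 1)).all():
            raise ValueError("sign entries must be -1, 0 or +1")
        object.__setattr__(self, "sign", sign)
        names = tuple(self.gene_names) or tuple(f"g{k + 1}" for k in range(sign.shape[0]))
        if len(names) != sign.shape[0]:
            raise ValueError("gene_names length must match matrix size")
        object.__setattr__(self, "gene_names", names)

    @property
    def n_genes(self) -> int:
        return self.sign.shape[0]

    @property
    def n_activating(self) -> int:
        """Number of activating (+1) influences."""
        return int((self.sign == 1).sum())

    @property
    def n_repressing(self) -> int:
        """Number of repressing (−1) influences."""
        return int((self.sign == -1).sum())

    @property
    def n_edges(self) -> int:
        return self.n_activating + self.n_repressing

    def edges(self) -> list[tuple[int, int, int]]:
        """All regulatory influences as ``(target, regulator, sign)`` triples."""
        ti, rj = np.nonzero(self.sign)
        return [(int(i), int(j), int(self.sign[i, j])) for i, j in zip(ti, rj)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetworkTopology):
            return NotImplemented
        return np.array_equal(self.sign, other.sign) and self.gene_names == other.gene_names


def _from_edges(n: int, edges: list[tuple[int, int, int]], names: tuple[str, ...] = ()) -> GeneNetworkTopology:
    sign = np.zeros((n, n), dtype=int)
    for i, j, s in edges:
        sign[i, j] = s
    return GeneNetworkTopology(sign, names)


# Fixed representative edge sets.  The published figures of the three 5-gene
# benchmark systems give only the counts of activating/repressing influences,
# so these concrete edge lists are this package's canonical instantiations:
# A is a regulatory cycle with three repressive feedbacks (5+/3-), B and C are
# two distinct feed-forward/feedback structures with a single repression
# (6+/1-), and CC is an 11-gene cell-cycle-like network (15+/14-).
_SYSTEM_A = [
    (0, 4, 1), (1, 0, 1), (2, 1, 1), (3, 2, 1), (4, 3, 1),
    (0, 2, -1), (1, 3, -1), (2, 4, -1),
]
_SYSTEM_B = [
    (1, 0, 1), (2, 0, 1), (2, 1, 1), (3, 1, 1), (3, 2, 1), (4, 3, 1),
    (0, 4, -1),
]
_SYSTEM_C = [
    (1, 0, 1), (2, 1, 1), (3, 2, 1), (4, 2, 1), (4, 3, 1), (0, 3, 1),
    (1, 4, -1),
]
_SYSTEM_CC = [
    # 15 activating
    (1, 0, 1), (2, 1, 1), (3, 2, 1), (4, 3, 1), (5, 4, 1),
    (6, 5, 1), (7, 6, 1), (8, 7, 1), (9, 8, 1), (10, 9, 1),
    (0, 10, 1), (2, 0, 1), (5, 2, 1), (8, 5, 1), (10, 7, 1),
    # 14 repressing
    (0, 3, -1), (1, 4, -1), (2, 6, -1), (3, 7, -1), (4, 8, -1),
    (5, 9, -1), (6, 10, -1), (7, 0, -1), (8, 1, -1), (9, 2, -1),
    (10, 4, -1), (6, 1, -1), (9, 5, -1), (3, 10, -1),
]

BUILTIN_SYSTEMS = {
    "A": (5, _SYSTEM_A),
    "B": (5, _SYSTEM_B),
    "C": (5, _SYSTEM_C),
    "CC": (11, _SYSTEM_CC),
}


def builtin_topology(system_id: str) -> GeneNetworkTopology:
    """Return one of the built-in benchmark topologies.

    ``A``: 5 genes, 5 activating + 3 repressing influences (yeast-like).
    ``B``, ``C``: 5 genes, 6 activating + 1 repressing, distinct edge sets.
    ``CC``: 11 genes, 15 activating + 14 repressing (cell-cycle-like).
    """
    key = system_id.upper()
    if key not in BUILTIN_SYSTEMS:
        raise ValueError(
            f"unknown system id {system_id!r}; valid ids: {sorted(BUILTIN_SYSTEMS)}"
        )
    n, edges = BUILTIN_SYSTEMS[key]
    return _from_edges(n, edges)


def random_topology(
    n_genes: int,
    n_activating: int,
    n_repressing: int,
    allow_self: bool = False,
    seed: int | None = None,
) -> GeneNetworkTopology:
    """Place the requested edge counts uniformly at random without collision."""
    if n_genes < 1 or n_activating < 0 or n_repressing < 0:
        raise ValueError("counts must be non-negative and n_genes positive")
    capacity = n_genes * n_genes if allow_self else n_genes * (n_genes - 1)
    if n_activating + n_repressing > capacity:
        raise ValueError(
            f"cannot place {n_activating + n_repressing} edges in {capacity} cells"
        )
    rng = np.random.default_rng(seed)
    cells = [
        (i, j)
        for i in range(n_genes)
        for j in range(n_genes)
        if allow_self or i != j
    ]
    chosen = rng.choice(len(cells), size=n_activating + n_repressing, replace=False)
    edges = [
        (*cells[c], 1 if k < n_activating else -1) for k, c in enumerate(chosen)
    ]
    return _from_edges(n_genes, edges)
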