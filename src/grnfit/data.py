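"""Time-course gene-expression datasets and their CSV representation.

The on-disk format is a plain CSV with a ``time`` column followed by one
column per gene, preceded by ``#key=value`` comment lines carrying
provenance metadata (system id, rate law, omega variant, noise flag, seed,
role).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TimeCourseDataset"]


@dataclass
class TimeCourseDataset:
    """Gene-expression matrix over an ordered time grid.

    ``values`` has shape ``(len(times), n_genes)``; ``meta`` is a free-form
    provenance record (system id, rate law, omega magnitude, noise flag,
    seed, role in {training, validation}, ...).
    """

    times: np.ndarray
    values: np.ndarray
    gene_names: tuple[str, ...] = field(default=())
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("values must have one row per time point")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (time x gene)")
        if not self.gene_names:
            self.gene_names = tuple(f"g{k + 1}" for k in range(self.values.shape[1]))
        if len(self.gene_names) != self.values.shape[1]:
            raise ValueError("gene_names length must match number of columns")

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.times.shape[0]

    @property
    def x0(self) -> np.ndarray:
        """Initial condition (first row)."""
        return self.values[0].copy()

    @property
    def value_range(self) -> float:
        """Global max − min over all genes and time points."""
        return float(self.values.max() - self.values.min())

    def with_values(self, values: np.ndarray, **meta_updates) -> "TimeCourseDataset":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return TimeCourseDataset(self.times.copy(), np.asarray(values, float),
                                 self.gene_names, meta)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.gene_names))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            for key in sorted(self.meta):
                val = self.meta[key]
                if isinstance(val, (str, int, float, bool, np.integer, np.floating)):
                    fh.write(f"#{key}={val}\n")  # structured meta goes to sidecars
            self.to_dataframe().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeCourseDataset":
        path = Path(path)
        meta: dict = {}
        with path.open() as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key] = _coerce_meta(val)
                    pos = fh.tell()
                else:
                    fh.seek(pos)
                    break
            df = pd.read_csv(fh)
        if "time" not in df.columns:
            raise ValueError(f"{path}: missing 'time' column")
        genes = tuple(c for c in df.columns if c != "time")
        return cls(df["time"].to_numpy(float), df[list(genes)].to_numpy(float), genes, meta)

    def plot(self, ax=None, **kwargs):
        """Plot all gene trajectories on one axis (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for k, name in enumerate(self.gene_names):
            ax.plot(self.times, self.values[:, k], label=name, **kwargs)
        ax.set_xlabel("time")
        ax.set_ylabel("expression")
        ax.legend(fontsize="small")
        return ax


def _coerce_meta(val: str):
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    if val in ("True", "False"):
        return val == "True"
    return val
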