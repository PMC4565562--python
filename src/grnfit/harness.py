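"""Factorial experiment: systems x rate laws x omega magnitudes x omega
intervals x replications.

Every cell of the factorial is a pure function of the configuration and a
per-cell seed derived deterministically from the master seed, so cells can
be run in any order (or resumed after interruption) with identical results.
The report at the end checks the benchmark's central question: does
widening the omega search interval beyond [-1, +1] buy any model quality?
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import ErrorRecord, aggregate, records_frame, summary_table
from .inference import ParameterLimits, reverse_engineer
from .pso import PSOConfig
from .synthetic import KineticSampler, NoiseSpec, SystemSpec, make_dataset_pair
from .topology import builtin_topology

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "omega_invariance_report",
    "InvarianceReport",
    "PROFILES",
]

_LAW_INDEX = {"hill": 0, "ann": 1}


@dataclass(frozen=True)
class ExperimentConfig:
    systems: tuple[str, ...] = ("A", "B", "C")
    system_rate_laws: tuple[str, ...] = ("hill", "ann")
    magnitudes: tuple[float, ...] = (1.0, 5.0, 10.0, 20.0)
    model_rate_laws: tuple[str, ...] = ("hill", "ann")
    omega_intervals: tuple[tuple[float, float], ...] = (
        (-1.0, 1.0),
        (-5.0, 5.0),
        (-10.0, 10.0),
        (-20.0, 20.0),
    )
    n_replications: int = 1
    budget: int = 20_000
    n_timepoints: int = 16
    noise_level: float = 0.15
    noise_mode: str = "variance"
    seed: int = 0
    constrain_signs: bool = True
    known_topology: bool = True
    resample_noise: bool = False  # replications redraw the noise, not just PSO seeds
    substeps: int = 8
    kinetic_sampler: KineticSampler = field(default_factory=KineticSampler)

    def dataset_keys(self) -> list[tuple[str, str, float]]:
        """(system, system_rate_law, magnitude) triples — one dataset pair each."""
        return [
            (sys_id, law, mag)
            for sys_id in self.systems
            for law in self.system_rate_laws
            for mag in self.magnitudes
        ]

    def cell_keys(self) -> list[dict]:
        """Every inference cell of the factorial."""
        cells = []
        for sys_id, sys_law, mag in self.dataset_keys():
            for model_law in self.model_rate_laws:
                for interval in self.omega_intervals:
                    for rep in range(self.n_replications):
                        cells.append(
                            {
                                "system_id": sys_id,
                                "system_rate_law": sys_law,
                                "system_omega_magnitude": mag,
                                "model_rate_law": model_law,
                                "model_omega_interval": interval,
                                "replication_index": rep,
                            }
                        )
        return cells

    def n_dataset_pairs(self) -> int:
        return len(self.dataset_keys())

    def n_cells(self) -> int:
        return len(self.cell_keys())

    def _seed_for(self, *key_ints: int) -> int:
        ss = np.random.SeedSequence([int(self.seed), *[int(k) for k in key_ints]])
        return int(ss.generate_state(1)[0] % (2**31 - 1))

    def dataset_seed(self, sys_id: str, sys_law: str, mag: float) -> int:
        return self._seed_for(
            0, self.systems.index(sys_id), _LAW_INDEX[sys_law], int(mag * 10)
        )

    def cell_seed(self, cell: dict) -> int:
        return self._seed_for(
            1,
            self.systems.index(cell["system_id"]),
            _LAW_INDEX[cell["system_rate_law"]],
            int(cell["system_omega_magnitude"] * 10),
            _LAW_INDEX[cell["model_rate_law"]],
            int(abs(cell["model_omega_interval"][1]) * 10),
            cell["replication_index"],
        )


PROFILES: dict[str, dict] = {
    # Fast sanity run: one system, the two extreme conditions, tiny budget.
    "smoke": dict(
        systems=("A",),
        system_rate_laws=("hill",),
        magnitudes=(1.0,),
        model_rate_laws=("hill",),
        omega_intervals=((-1.0, 1.0), (-20.0, 20.0)),
        n_replications=1,
        budget=2_000,
    ),
    # Desk-scale hypothesis run: the factorial's extremes, minutes not hours.
    "desk": dict(
        systems=("A", "B", "C"),
        magnitudes=(1.0, 20.0),
        omega_intervals=((-1.0, 1.0), (-20.0, 20.0)),
        n_replications=2,
        budget=20_000,
    ),
    # Complete benchmark geometry: 24 dataset pairs, 192 inference cells.
    "full": dict(
        systems=("A", "B", "C"),
        magnitudes=(1.0, 5.0, 10.0, 20.0),
        omega_intervals=((-1.0, 1.0), (-5.0, 5.0), (-10.0, 10.0), (-20.0, 20.0)),
        n_replications=1,
        budget=50_000,
    ),
}


def profile_config(name: str, seed: int = 0, **overrides) -> ExperimentConfig:
    if name not in PROFILES:
        raise ValueError(f"unknown profile {name!r}; valid: {sorted(PROFILES)}")
    kw = {**PROFILES[name], "seed": seed, **overrides}
    return ExperimentConfig(**kw)


def _generate_pair(config: ExperimentConfig, sys_id: str, sys_law: str, mag: float, noise_seed_shift: int = 0):
    dseed = config.dataset_seed(sys_id, sys_law, mag)
    spec = SystemSpec.builtin(
        sys_id, mag, sys_law, seed=dseed, kinetic_sampler=config.kinetic_sampler
    )
    noise = NoiseSpec(
        level=config.noise_level,
        scale_mode=config.noise_mode,
        seed=dseed + 1 + noise_seed_shift,
    )
    return make_dataset_pair(spec, n_timepoints=config.n_timepoints, noise=noise)


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    resume: bool = False,
    progress=None,
) -> list[ErrorRecord]:
    """Run (or resume) the full factorial; returns one ErrorRecord per cell.

    With ``out_dir`` given, each finished cell is checkpointed as a small
    JSON file and ``resume=True`` skips cells that already have one.
    Failures inside a cell are recorded (penalty errors), never abort the
    sweep.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "cells").mkdir(parents=True, exist_ok=True)

    pair_cache: dict = {}

    def get_pair(sys_id, sys_law, mag, rep):
        shift = rep if config.resample_noise else 0
        key = (sys_id, sys_law, mag, shift)
        if key not in pair_cache:
            pair_cache[key] = _generate_pair(config, sys_id, sys_law, mag, shift)
        return pair_cache[key]

    records: list[ErrorRecord] = []
    cells = config.cell_keys()
    for idx, cell in enumerate(cells):
        cell_file = None
        if out_path is not None:
            iv = cell["model_omega_interval"]
            name = (
                f"{cell['system_id']}_{cell['system_rate_law']}"
                f"_m{cell['system_omega_magnitude']:g}_{cell['model_rate_law']}"
                f"_w{iv[1]:g}_r{cell['replication_index']}.json"
            )
            cell_file = out_path / "cells" / name
            if resume and cell_file.exists():
                d = json.loads(cell_file.read_text())
                d["model_omega_interval"] = tuple(d["model_omega_interval"])
                records.append(ErrorRecord(**d))
                continue

        import warnings

        seed = config.cell_seed(cell)
        try:
            train, val = get_pair(
                cell["system_id"],
                cell["system_rate_law"],
                cell["system_omega_magnitude"],
                cell["replication_index"],
            )
            limits = ParameterLimits.with_omega(*cell["model_omega_interval"])
            topology = (
                builtin_topology(cell["system_id"]) if config.known_topology else None
            )
            pso = PSOConfig(max_evaluations=config.budget, seed=seed)
            res = reverse_engineer(
                train,
                cell["model_rate_law"],
                limits=limits,
                topology=topology,
                pso=pso,
                constrain_signs=config.constrain_signs,
                substeps=config.substeps,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # failed validations become penalties
                val_err = res.validate(val)
            train_err, n_eval, conv = res.training_error, res.n_evaluations, res.converged
        except Exception as exc:  # a broken cell must not abort the sweep
            warnings.warn(f"cell {cell} failed: {exc}; recording penalty errors")
            from .evaluation import PENALTY_ERROR

            train_err = val_err = PENALTY_ERROR
            n_eval, conv = 0, False
        record = ErrorRecord(
            system_id=cell["system_id"],
            system_rate_law=cell["system_rate_law"],
            system_omega_magnitude=cell["system_omega_magnitude"],
            model_rate_law=cell["model_rate_law"],
            model_omega_interval=cell["model_omega_interval"],
            replication_index=cell["replication_index"],
            seed=seed,
            training_error=train_err,
            validation_error=val_err,
            n_evaluations=n_eval,
            converged=conv,
        )
        records.append(record)
        if cell_file is not None:
            d = record.__dict__.copy()
            d["model_omega_interval"] = list(d["model_omega_interval"])
            cell_file.write_text(json.dumps(d))
        if progress is not None:
            progress(idx + 1, len(cells), record)

    if out_path is not None:
        records_frame(records).to_csv(out_path / "records.tsv", sep="\t", index=False)
        for error in ("training_error", "validation_error"):
            summary_table(records, error=error).to_csv(
                out_path / f"summary_{error}.tsv", sep="\t"
            )
    return records


@dataclass
class InvarianceReport:
    """Per-configuration trend of mean validation error across omega
    intervals, and the overall verdict on the interval-invariance claim."""

    table: pd.DataFrame
    k: float

    @property
    def n_configurations(self) -> int:
        return len(self.table)

    @property
    def n_invariant(self) -> int:
        return int(self.table["invariant"].sum())

    @property
    def fraction_invariant(self) -> float:
        return self.n_invariant / max(self.n_configurations, 1)

    @property
    def verdict(self) -> str:
        return (
            "no systematic decrease"
            if self.fraction_invariant >= 0.75
            else "decrease detected"
        )

    def __str__(self) -> str:
        head = (
            f"omega-interval invariance report (k = {self.k:g})\n"
            f"configurations: {self.n_configurations}, invariant: "
            f"{self.n_invariant} ({100 * self.fraction_invariant:.0f}%)\n"
            f"overall verdict: {self.verdict}\n"
        )
        return head + self.table.to_string(index=False)


def omega_invariance_report(
    records: list[ErrorRecord],
    error: str = "validation_error",
    k: float = 2.0,
) -> InvarianceReport:
    """Does widening the omega interval reduce the error?

    For every configuration (system, system rate law, magnitude, model rate
    law) the records must span at least two omega intervals.  A
    configuration counts as *invariant* ("no systematic decrease") when the
    narrowest interval's mean error is within ``k`` within-cell standard
    deviations of every wider interval's mean.  The report also gives the
    trend sign and the largest pairwise mean difference relative to the
    within-cell spread.
    """
    group = ["system_id", "system_rate_law", "system_omega_magnitude", "model_rate_law"]
    df = records_frame(records)
    per_cell = aggregate(df, group + ["model_omega_interval"], error=error)
    # order intervals by their width encoded in the "[lo,hi]" label
    per_cell["_width"] = per_cell["model_omega_interval"].map(
        lambda s: float(s.strip("[]").split(",")[1])
    )

    rows = []
    for keys, sub in per_cell.groupby(group):
        sub = sub.sort_values("_width")
        if len(sub) < 2:
            raise ValueError(
                "invariance report needs >= 2 omega intervals per configuration"
            )
        means = sub["mean"].to_numpy()
        sds = sub["s"].to_numpy()
        floor = max(sds.max(), 1e-12)  # guard single-replication cells (s = 0)
        narrow_mean = means[0]
        wider_means = means[1:]
        tol = k * np.where(sds[1:] > 0, sds[1:], floor)
        invariant = bool(np.all(narrow_mean <= wider_means + tol))
        slope = np.polyfit(np.arange(len(means)), means, 1)[0]
        max_gap = float(means.max() - means.min())
        rows.append(
            dict(
                zip(group, keys),
                narrow_mean=float(narrow_mean),
                widest_mean=float(means[-1]),
                slope_sign=int(np.sign(slope)),
                max_gap=max_gap,
                max_gap_over_s=float(max_gap / floor) if floor > 0 else np.inf,
                invariant=invariant,
            )
        )
    return InvarianceReport(pd.DataFrame(rows), k)
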