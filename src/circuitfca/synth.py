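"""Synthetic flow-cytometry-style measurements with known ground truth.

Real readouts of these circuits are per-cell fluorescence populations
summarised by the geometric mean over ~10000 events, repeated over 3
biological replicates.  The generator emulates exactly that summary
chain: per-cell fluorescence is log-normal around the model's
steady-state output (geometric mean equal to the model value), each
replicate redraws its cell population (optionally with a between-day
log bias), and each well is reported as the geometric mean of its
cells.  Every draw is governed by an explicit seed — there is no
global RNG state — so experiments are bitwise reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NoiseModel",
    "SyntheticExperiment",
    "sample_population",
    "generate_experiment",
    "generate_ahl_sweep",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description of one cytometry experiment.

    ``log_cv`` is the standard deviation of natural-log fluorescence
    across cells (0.5 by default — a broad but realistic population
    spread); ``replicate_log_bias`` adds a per-replicate log-normal day
    effect (0 by default); ``autofluorescence`` an additive floor on
    every cell (0 by default).
    """

    log_cv: float = 0.5
    n_cells: int = 10000
    replicates: int = 3
    seed: int = 0
    replicate_log_bias: float = 0.0
    autofluorescence: float = 0.0

    def __post_init__(self) -> None:
        if self.log_cv < 0 or self.replicate_log_bias < 0 or self.autofluorescence < 0:
            raise ValueError("noise scales must be >= 0")
        if self.n_cells < 1 or self.replicates < 1:
            raise ValueError("n_cells and replicates must be >= 1")


def sample_population(
    mean_level: float, noise: NoiseModel, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, float]:
    """Draw one well: per-cell values and their geometric mean.

    Cells are log-normal with log-mean ``ln(mean_level)`` and log-sd
    ``log_cv``, so the population geometric mean estimates
    ``mean_level`` with log-space standard error ``log_cv/sqrt(n_cells)``.
    """
    if mean_level <= 0:
        raise ValueError("mean_level must be > 0")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    if noise.log_cv == 0.0:
        # exact limit: every cell equals the mean (exp(log(m)) would round)
        cells = np.full(noise.n_cells, mean_level + noise.autofluorescence)
        return cells, float(mean_level + noise.autofluorescence)
    logs = rng.normal(np.log(mean_level), noise.log_cv, size=noise.n_cells)
    cells = np.exp(logs) + noise.autofluorescence
    geomean = float(np.exp(np.mean(np.log(cells))))
    return cells, geomean


@dataclass(frozen=True)
class SyntheticExperiment:
    """Replicate geometric means per dose, with the generating truth."""

    doses: np.ndarray
    geomeans: np.ndarray  # shape (replicates, n_doses)
    ground_truth: dict
    seed: int
    condition: str = "synthetic"
    fs: float = 0.0
    n_cells: int = 10000

    @property
    def pooled_mean(self) -> np.ndarray:
        """Per-dose geometric mean across replicates."""
        pooled = np.exp(np.mean(np.log(self.geomeans), axis=0))
        # keep bitwise exactness where replicates agree (noiseless limit)
        same = np.all(self.geomeans == self.geomeans[0], axis=0)
        pooled[same] = self.geomeans[0][same]
        return pooled

    @property
    def pooled_sd(self) -> np.ndarray:
        """Per-dose standard deviation of the replicate geometric means."""
        return np.std(self.geomeans, axis=0, ddof=1) if self.geomeans.shape[0] > 1 \
            else np.zeros(self.doses.size)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.geomeans.shape[0]):
            for j, d in enumerate(self.doses):
                rows.append(
                    {
                        "condition": self.condition,
                        "fs": self.fs,
                        "dose": float(d),
                        "replicate": r + 1,
                        "geomean": float(self.geomeans[r, j]),
                        "n_cells": self.n_cells,
                        "seed": self.seed,
                    }
                )
        return pd.DataFrame(rows)

    def ground_truth_json(self) -> str:
        return json.dumps(
            {"ground_truth": self.ground_truth, "seed": self.seed,
             "condition": self.condition, "fs": self.fs},
            indent=2, sort_keys=True,
        )


def generate_experiment(
    model: Callable[[np.ndarray], np.ndarray],
    doses: Sequence[float],
    noise: NoiseModel,
    ground_truth: dict | None = None,
    condition: str = "synthetic",
    fs: float = 0.0,
) -> SyntheticExperiment:
    """Simulate one dose-response experiment through the cytometry chain.

    ``model`` maps the dose grid to noiseless steady-state outputs;
    each (replicate, dose) well then draws ``n_cells`` log-normal cells
    and reports their geometric mean.  With ``log_cv = 0`` the means
    equal the model curve exactly.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0 or np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be positive and strictly increasing")
    levels = np.asarray(model(doses), dtype=float)
    if np.any(levels <= 0):
        raise ValueError("model outputs must be > 0 to be measured on a log scale")
    rng = np.random.default_rng(noise.seed)
    geo = np.empty((noise.replicates, doses.size))
    for r in range(noise.replicates):
        bias = rng.normal(0.0, noise.replicate_log_bias) if noise.replicate_log_bias else 0.0
        for j, lvl in enumerate(levels):
            if noise.log_cv == 0.0 and noise.replicate_log_bias == 0.0:
                geo[r, j] = lvl + noise.autofluorescence
            else:
                _, geo[r, j] = sample_population(lvl * np.exp(bias), noise, rng)
    return SyntheticExperiment(
        doses=doses,
        geomeans=geo,
        ground_truth=dict(ground_truth or {}),
        seed=noise.seed,
        condition=condition,
        fs=fs,
        n_cells=noise.n_cells,
    )


def generate_ahl_sweep(
    family: Callable[[float], Callable[[np.ndarray], np.ndarray]],
    fs_values: Sequence[float],
    doses: Sequence[float],
    noise: NoiseModel,
    ground_truth: dict | None = None,
    condition: str = "synthetic",
) -> list[SyntheticExperiment]:
    """One experiment per loop strength (each AHL level = one curve).

    Seeds are derived deterministically per Fs from the base seed, so
    the sweep is reproducible as a whole and per member.
    """
    fs_values = list(fs_values)
    if any(fs < 0 for fs in fs_values):
        raise ValueError("fs values must be >= 0")
    out = []
    for i, fs in enumerate(fs_values):
        member_noise = NoiseModel(
            log_cv=noise.log_cv, n_cells=noise.n_cells, replicates=noise.replicates,
            seed=int((noise.seed + 7919 * i) % 2**31),
            replicate_log_bias=noise.replicate_log_bias,
            autofluorescence=noise.autofluorescence,
        )
        gt = dict(ground_truth or {})
        gt["fs"] = float(fs)
        out.append(
            generate_experiment(
                family(float(fs)), doses, member_noise,
                ground_truth=gt, condition=condition, fs=float(fs),
            )
        )
    return out
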