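"""Figures of merit for dose-response curves of gene circuits.

Given a measured or simulated input-output curve, this module computes:

* **FCA** — fold-change activation, the ratio of the ON state (output
  at the top of the input range) to the OFF state (basal output),
  with the OFF state clipped below at a noise floor.
* **Sensitivity** — the pointwise logarithmic gain
  S = (dOut/Out)/(dIn/In) = d ln(out)/d ln(in), evaluated by central
  differences on the log-log curve.
* **MDL** — minimum detection level, the input at which the
  sensitivity is maximal.
* **Th** — switching threshold, the input at which the output crosses
  the log-midpoint (geometric mean) of the OFF and ON levels.

plus loop-strength sweeps of these metrics and qualitative
(beta, Fs) design diagrams marking where FCA and MDL are optimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponse",
    "CircuitMetrics",
    "SweepResult",
    "compute_fca",
    "sensitivity_curve",
    "compute_mdl",
    "compute_threshold",
    "curve_metrics",
    "sweep_fs",
    "design_diagram",
]


@dataclass(frozen=True)
class DoseResponse:
    """One dose-response curve: paired input grid and output values."""

    inputs: np.ndarray
    outputs: np.ndarray
    input_label: str = "input"
    output_label: str = "output"

    def __post_init__(self) -> None:
        inputs = np.asarray(self.inputs, dtype=float)
        outputs = np.asarray(self.outputs, dtype=float)
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "outputs", outputs)
        if inputs.size == 0:
            raise ValueError("dose-response curve must not be empty")
        if inputs.shape != outputs.shape or inputs.ndim != 1:
            raise ValueError("inputs and outputs must be 1-D arrays of equal length")
        if np.any(np.diff(inputs) <= 0):
            raise ValueError("inputs must be strictly increasing")
        if np.any(inputs < 0):
            raise ValueError("inputs must be non-negative")
        if np.any(outputs < 0):
            raise ValueError("outputs must be non-negative")

    def __len__(self) -> int:
        return self.inputs.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.input_label: self.inputs, self.output_label: self.outputs})


def compute_fca(dr: DoseResponse, floor: float = 1e-3, mode: str = "endpoints") -> float:
    """Fold-change activation ON / max(OFF, floor).

    With ``mode='endpoints'`` (default, for monotone curves) ON is the
    output at the largest input and OFF at the smallest; with
    ``mode='extrema'`` ON/OFF are the max/min over the whole curve,
    for non-monotone data.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    if mode == "endpoints":
        on, off = float(dr.outputs[-1]), float(dr.outputs[0])
    elif mode == "extrema":
        on, off = float(dr.outputs.max()), float(dr.outputs.min())
    else:
        raise ValueError(f"mode must be 'endpoints' or 'extrema', got {mode!r}")
    denom = max(off, floor)
    if denom == 0.0:
        raise ZeroDivisionError("OFF state and floor are both zero; FCA undefined")
    return on / denom


def sensitivity_curve(dr: DoseResponse) -> np.ndarray:
    """Pointwise logarithmic sensitivity d ln(out)/d ln(in).

    Central differences on the log-log curve at interior points,
    one-sided at the two ends.  Requires strictly positive inputs and
    outputs (the logarithm must exist everywhere).
    """
    if len(dr) < 3:
        raise ValueError("sensitivity needs at least 3 points")
    if np.any(dr.inputs <= 0):
        raise ValueError("sensitivity requires strictly positive inputs")
    if np.any(dr.outputs <= 0):
        raise ValueError("sensitivity requires strictly positive outputs")
    return np.gradient(np.log(dr.outputs), np.log(dr.inputs))


def _argmax_first(s: np.ndarray) -> int:
    """First index attaining the maximum, robust to O(eps) gradient noise."""
    smax = float(s.max())
    tol = 1e-12 * (1.0 + abs(smax))
    return int(np.argmax(s >= smax - tol))


def compute_mdl(dr: DoseResponse) -> float:
    """Input at which the sensitivity is maximal (ties -> smallest input)."""
    s = sensitivity_curve(dr)
    return float(dr.inputs[_argmax_first(s)])


def compute_threshold(dr: DoseResponse, floor: float = 0.0) -> float:
    """Input at which the output crosses the log-midpoint of OFF and ON.

    The midpoint is the geometric mean sqrt(ON * OFF) — half the fold
    change on the logarithmic scale — with OFF clipped at ``floor``.
    Crossing is located by linear interpolation in log-log space.
    Returns ``nan`` if the curve never crosses the midpoint.
    """
    if np.any(dr.inputs <= 0) or np.any(dr.outputs <= 0):
        raise ValueError("threshold requires strictly positive inputs and outputs")
    on, off = float(dr.outputs[-1]), max(float(dr.outputs[0]), floor)
    mid = math.sqrt(on * off)
    logo = np.log(dr.outputs)
    logm = math.log(mid)
    above = logo >= logm
    if above.all() or not above.any():
        return float("nan")
    i = int(np.argmax(above))  # first point at/above the midpoint
    if i == 0:
        return float(dr.inputs[0])
    x0, x1 = math.log(dr.inputs[i - 1]), math.log(dr.inputs[i])
    y0, y1 = logo[i - 1], logo[i]
    t = (logm - y0) / (y1 - y0)
    return float(math.exp(x0 + t * (x1 - x0)))


@dataclass(frozen=True)
class CircuitMetrics:
    """All figures of merit for one dose-response curve."""

    fca: float
    s_curve: np.ndarray
    s_max: float
    mdl: float
    threshold: float

    def to_dict(self) -> dict:
        return {
            "fca": self.fca,
            "s_max": self.s_max,
            "mdl": self.mdl,
            "threshold": self.threshold,
        }


def curve_metrics(dr: DoseResponse, floor: float = 1e-3) -> CircuitMetrics:
    """Compute FCA, sensitivity curve/max, MDL and threshold for one curve."""
    s = sensitivity_curve(dr)
    return CircuitMetrics(
        fca=compute_fca(dr, floor=floor),
        s_curve=s,
        s_max=float(s.max()),
        mdl=float(dr.inputs[_argmax_first(s)]),
        threshold=compute_threshold(dr),
    )


@dataclass(frozen=True)
class SweepResult:
    """Metrics along a loop-strength grid."""

    fs_grid: np.ndarray
    metrics: tuple
    argmax_fca: float
    argmin_mdl: float

    @property
    def fca(self) -> np.ndarray:
        return np.array([m.fca for m in self.metrics])

    @property
    def mdl(self) -> np.ndarray:
        return np.array([m.mdl for m in self.metrics])

    @property
    def s_max(self) -> np.ndarray:
        return np.array([m.s_max for m in self.metrics])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fs": self.fs_grid,
                "fca": self.fca,
                "s_max": self.s_max,
                "mdl": self.mdl,
                "threshold": [m.threshold for m in self.metrics],
            }
        )


def sweep_fs(
    model_factory: Callable[[float], Callable[[np.ndarray], np.ndarray]],
    fs_grid: Sequence[float],
    x_grid: Sequence[float],
    floor: float = 1e-3,
) -> SweepResult:
    """Evaluate curve metrics for each loop strength on ``fs_grid``.

    ``model_factory(fs)`` must return a callable mapping the input grid
    to steady-state outputs.  Ties in argmax(FCA)/argmin(MDL) are
    broken toward the smallest Fs for determinism.
    """
    fs_grid = np.asarray(fs_grid, dtype=float)
    x_grid = np.asarray(x_grid, dtype=float)
    if fs_grid.size == 0 or x_grid.size == 0:
        raise ValueError("fs_grid and x_grid must not be empty")
    mets = []
    for fs in fs_grid:
        out = np.asarray(model_factory(float(fs))(x_grid), dtype=float)
        mets.append(curve_metrics(DoseResponse(x_grid, out), floor=floor))
    fca = np.array([m.fca for m in mets])
    mdl = np.array([m.mdl for m in mets])
    return SweepResult(
        fs_grid=fs_grid,
        metrics=tuple(mets),
        argmax_fca=float(fs_grid[int(np.argmax(fca))]),
        argmin_mdl=float(fs_grid[int(np.argmin(mdl))]),
    )


def design_diagram(
    family: Callable[[float, float], Callable[[np.ndarray], np.ndarray]],
    beta_grid: Sequence[float],
    fs_grid: Sequence[float],
    x_grid: Sequence[float],
    delta: float = 0.05,
    floor: float = 1e-3,
) -> pd.DataFrame:
    """Classify each (beta, Fs) cell of a design family.

    ``family(beta, fs)`` returns a dose-response callable.  Within each
    beta row, a cell is *optimal-FCA* if its FCA is at least
    ``(1 - delta)`` times the row maximum, and *optimal-MDL* if its MDL
    is at most ``1/(1 - delta)`` times the row minimum (the same
    relative tolerance applied on the other side; at ``delta = 1``
    every cell is optimal by both criteria).  Returns a long-format
    frame with columns beta, fs, fca, mdl, optimal_fca, optimal_mdl,
    region.
    """
    if not 0.0 < delta <= 1.0:
        raise ValueError("delta must be in (0, 1]")
    x_grid = np.asarray(x_grid, dtype=float)
    rows = []
    for beta in beta_grid:
        sweep = sweep_fs(lambda fs: family(float(beta), fs), fs_grid, x_grid, floor=floor)
        fca, mdl = sweep.fca, sweep.mdl
        ok_fca = fca >= (1.0 - delta) * fca.max()
        if delta >= 1.0:
            ok_mdl = np.ones_like(mdl, dtype=bool)
        else:
            ok_mdl = mdl <= mdl.min() / (1.0 - delta)
        for j, fs in enumerate(sweep.fs_grid):
            region = {
                (True, True): "both",
                (True, False): "fca",
                (False, True): "mdl",
                (False, False): "neither",
            }[(bool(ok_fca[j]), bool(ok_mdl[j]))]
            rows.append(
                {
                    "beta": float(beta),
                    "fs": float(fs),
                    "fca": float(fca[j]),
                    "mdl": float(mdl[j]),
                    "optimal_fca": bool(ok_fca[j]),
                    "optimal_mdl": bool(ok_mdl[j]),
                    "region": region,
                }
            )
    return pd.DataFrame(rows)
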