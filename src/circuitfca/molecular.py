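"""Three-node nonlinear steady-state circuit models.

Molecule Z (output) is activated by the input X through a Hill term
with basal leakage and repressed by the inhibitor Y:

    z = alpha * (x**n + beta)/(1 + x**n) * 1/(1 + y**m)

In the ICF wiring Y is repressed by X only,

    y = Fs / (1 + x**n)

so the steady state is an explicit feedforward evaluation.  In the DNF
wiring Y is repressed by Z instead,

    y = Fs / (1 + z**h)

which couples the two equations; the steady state is the root of a
scalar residual in z, bracketed in [0, A(x)] where
A(x) = alpha*(x**n + beta)/(1 + x**n) is the uninhibited activation.
For m = h = 1 that root is the positive solution of
z**2 + z*(1 + Fs - A) - A = 0 and the bracketed residual is monotone,
so the solver always converges.  For m*h > 1 the DNF motif can be
multistable; all roots on a scan grid are reported and the smallest is
returned with a flag.

All quantities are dimensionless (concentrations scaled by their
dissociation constants).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .metrics import DoseResponse

__all__ = [
    "MolecularParams",
    "SteadyState",
    "icf_steady_state",
    "dnf_steady_state",
    "dose_response",
]

#: Tolerance on the fixed-point residual |z - A/(1+y(z)^m)|.
DEFAULT_TOL = 1e-12
#: Number of scan points used to locate multiple fixed points when m*h > 1.
MULTISTABILITY_SCAN_POINTS = 400


@dataclass(frozen=True)
class MolecularParams:
    """Dimensionless parameters of the three-node models.

    Defaults are the reference simulation set: ``beta=0.1, alpha=10,
    n=1.5, m=1, h=1`` (loop strength ``fs`` defaults to 0, i.e. the
    bare activated promoter).
    """

    beta: float = 0.1
    alpha: float = 10.0
    n: float = 1.5
    m: float = 1.0
    h: float = 1.0
    fs: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.n <= 0:
            raise ValueError(f"n must be > 0, got {self.n}")
        if self.m < 1 or self.h < 1:
            raise ValueError("Hill coefficients m and h must be >= 1")
        if self.fs < 0:
            raise ValueError(f"fs must be >= 0, got {self.fs}")

    def with_fs(self, fs: float) -> "MolecularParams":
        return replace(self, fs=fs)


@dataclass(frozen=True)
class SteadyState:
    """Solution triple of the steady-state equations at one input."""

    x: float
    y: float
    z: float
    converged: bool = True
    residual: float = 0.0
    multistable: bool = False
    all_z: tuple = field(default_factory=tuple)


def _activation(x: float, p: MolecularParams) -> float:
    xn = x**p.n
    return p.alpha * (xn + p.beta) / (1.0 + xn)


def icf_steady_state(x: float, params: MolecularParams) -> SteadyState:
    """Exact ICF steady state (pure feedforward, no iteration)."""
    if x < 0:
        raise ValueError("input x must be non-negative")
    y = params.fs / (1.0 + x**params.n)
    z = _activation(x, params) / (1.0 + y**params.m)
    return SteadyState(x=float(x), y=float(y), z=float(z))


def _dnf_residual(z: float, A: float, params: MolecularParams) -> float:
    y = params.fs / (1.0 + z**params.h)
    return z - A / (1.0 + y**params.m)


def dnf_steady_state(
    x: float, params: MolecularParams, tol: float = DEFAULT_TOL
) -> SteadyState:
    """DNF steady state by root-finding the scalar residual in z.

    The residual ``z - A/(1 + y(z)**m)`` is negative at ``z = 0`` and
    positive at ``z = A``, so a root is always bracketed.  When
    ``m*h > 1`` the residual may cross zero several times; a 400-point
    scan locates every sign change, each root is refined, and the
    smallest is returned with ``multistable=True`` if more than one
    fixed point exists.
    """
    if x < 0:
        raise ValueError("input x must be non-negative")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    A = _activation(x, params)
    if params.fs == 0.0:
        return SteadyState(x=float(x), y=0.0, z=float(A))

    def f(z):
        return _dnf_residual(z, A, params)

    roots: list[float] = []
    if params.m * params.h <= 1.0 + 1e-12:
        # monotone residual: single root in [0, A]
        roots.append(brentq(f, 0.0, A, xtol=1e-15, rtol=8.9e-16, maxiter=200))
    else:
        zs = np.concatenate([[0.0], np.geomspace(A * 1e-9, A, MULTISTABILITY_SCAN_POINTS)])
        vals = np.array([f(z) for z in zs])
        for i in range(len(zs) - 1):
            if vals[i] == 0.0:
                roots.append(float(zs[i]))
            elif vals[i] * vals[i + 1] < 0:
                roots.append(
                    brentq(f, zs[i], zs[i + 1], xtol=1e-15, rtol=8.9e-16, maxiter=200)
                )
        if vals[-1] == 0.0:
            roots.append(float(zs[-1]))
        if not roots:  # scan missed the crossing; fall back to full bracket
            roots.append(brentq(f, 0.0, A, xtol=1e-15, rtol=8.9e-16, maxiter=200))

    z = min(roots)
    residual = abs(f(z))
    if residual > tol:
        raise RuntimeError(
            f"DNF fixed-point solver did not reach tolerance: residual={residual:.3e}"
        )
    y = params.fs / (1.0 + z**params.h)
    return SteadyState(
        x=float(x),
        y=float(y),
        z=float(z),
        converged=True,
        residual=float(residual),
        multistable=len(roots) > 1,
        all_z=tuple(sorted(roots)),
    )


def dose_response(
    topology: str,
    params: MolecularParams,
    x_grid,
    tol: float = DEFAULT_TOL,
) -> DoseResponse:
    """Vectorise a steady-state model over an increasing input grid."""
    x_grid = np.asarray(x_grid, dtype=float)
    if x_grid.size == 0:
        raise ValueError("x_grid must not be empty")
    if np.any(np.diff(x_grid) <= 0):
        raise ValueError("x_grid must be strictly increasing")
    if topology == "ICF":
        z = np.array([icf_steady_state(x, params).z for x in x_grid])
    elif topology == "DNF":
        z = np.array([dnf_steady_state(x, params, tol).z for x in x_grid])
    else:
        raise ValueError(f"topology must be 'ICF' or 'DNF', got {topology!r}")
    return DoseResponse(inputs=x_grid, outputs=z, input_label="x", output_label="z")
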