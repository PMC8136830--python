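"""Four-node steady-state models of the implemented genetic circuits.

The wet-lab realisation of the feedforward/feedback designs chains a
promoter under test (PUT) to a TetR inverting switch and a
LuxR-driven reverse promoter that interferes with the output:

    PUT --> TetR --| PtetO(LuxR) --> Plux(reverse) --| output

Node levels at input ``x``:

* ``p`` — PUT activity, the Hill transfer ``(x**n + beta)/(1 + x**n)``;
* ``t`` — TetR level, ``theta * p`` (ICF) or reduced by the reverse
  promoter in the DNF wiring; aTc lowers the *active* TetR to
  ``t / (1 + atc)``;
* ``L`` — LuxR level from the TetR-repressed PtetO promoter,
  ``lam / (1 + t_eff**q)``;
* ``w`` — reverse-promoter drive ``fs * L`` (AHL concentration and
  Plux strength folded into the single loop-strength knob ``fs``);
* ``z`` — reporter output.  The reverse promoter acts on it either
  *subtractively* (transcriptional interference / antisense
  transcription modelled as a subtraction, ``z = max(eps, alpha*p - w)``)
  or *divisively* (Hill repression ``z = alpha*p / (1 + w**m)``).

ICF: TetR sees only the PUT, so the chain is explicit.  DNF: TetR is
also reduced by the reverse promoter, giving a scalar fixed point in
``w`` on the bracket [0, fs*lam], solved by damped iteration with a
guaranteed bracketing fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .linear import HillPut, put_transfer
from .metrics import DoseResponse

__all__ = [
    "GeneticParams",
    "GeneticState",
    "genetic_icf_steady_state",
    "genetic_dnf_steady_state",
    "genetic_dose_response",
    "DEFAULT_GENETIC_PARAMS",
]

DEFAULT_TOL = 1e-10
_MAX_DAMPED_ITER = 500
_DAMPING = 0.5


@dataclass(frozen=True)
class GeneticParams:
    """Parameters of the four-node genetic circuit models."""

    put: HillPut
    alpha: float = 10.0  # output expression scale
    theta: float = 5.0  # TetR expression gain
    q: float = 2.0  # TetR-PtetO Hill coefficient
    lam: float = 1.0  # LuxR expression scale
    atc: float = 0.0  # aTc level; active TetR = t / (1 + atc)
    fs: float = 0.0  # reverse-promoter strength (AHL knob)
    mode: str = "subtractive"  # or "divisive"
    m: float = 1.0  # Hill coefficient of divisive interference
    floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.theta < 0 or self.lam <= 0:
            raise ValueError("alpha, lam must be > 0 and theta >= 0")
        if self.q <= 0 or self.m <= 0:
            raise ValueError("Hill coefficients q and m must be > 0")
        if self.atc < 0 or self.fs < 0 or self.floor < 0:
            raise ValueError("atc, fs and floor must be >= 0")
        if self.mode not in ("subtractive", "divisive"):
            raise ValueError(f"mode must be 'subtractive' or 'divisive', got {self.mode!r}")

    def with_fs(self, fs: float) -> "GeneticParams":
        return replace(self, fs=fs)


#: Shipped default parameter set; yields an interior FCA optimum over fs
#: for both the ICF and the DNF wiring in subtractive mode.
DEFAULT_GENETIC_PARAMS = GeneticParams(put=HillPut(beta=0.1, n=1.5))


@dataclass(frozen=True)
class GeneticState:
    """Node levels of the four-node circuit at one input."""

    x: float
    p: float
    t: float
    L: float
    w: float
    z: float
    converged: bool = True
    residual: float = 0.0


def _luxr(t: float, gp: GeneticParams) -> float:
    t_eff = t / (1.0 + gp.atc)
    return gp.lam / (1.0 + t_eff**gp.q)


def _output(p: float, w: float, gp: GeneticParams) -> float:
    if gp.mode == "subtractive":
        return max(gp.floor, gp.alpha * p - w)
    return gp.alpha * p / (1.0 + w**gp.m)


def genetic_icf_steady_state(x: float, params: GeneticParams) -> GeneticState:
    """ICF wiring: TetR is driven by the PUT only (explicit chain)."""
    if x < 0:
        raise ValueError("input x must be non-negative")
    p = float(put_transfer(x, params.put))
    t = params.theta * p
    L = _luxr(t, params)
    w = params.fs * L
    z = _output(p, w, params)
    return GeneticState(x=float(x), p=p, t=t, L=L, w=w, z=z)


def _tetr(p: float, w: float, gp: GeneticParams) -> float:
    if gp.mode == "subtractive":
        return max(0.0, gp.theta * p - w)
    return gp.theta * p / (1.0 + w**gp.m)


def genetic_dnf_steady_state(
    x: float, params: GeneticParams, tol: float = DEFAULT_TOL
) -> GeneticState:
    """DNF wiring: TetR is reduced by the reverse promoter too.

    Solves ``w = fs * lam / (1 + (t(p, w)/(1+atc))**q)`` on the bracket
    [0, fs*lam].  Damped fixed-point iteration (factor 0.5) is tried
    first; if it has not reached ``tol`` within the budget, the
    bracketing root-finder takes over (the residual changes sign across
    the bracket, so convergence is guaranteed).
    """
    if x < 0:
        raise ValueError("input x must be non-negative")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    p = float(put_transfer(x, params.put))
    w_max = params.fs * params.lam
    if w_max == 0.0:
        t = _tetr(p, 0.0, params)
        return GeneticState(x=float(x), p=p, t=t, L=_luxr(t, params), w=0.0,
                            z=_output(p, 0.0, params))

    def g(w: float) -> float:
        return params.fs * _luxr(_tetr(p, w, params), params)

    w = 0.5 * w_max
    converged = False
    for _ in range(_MAX_DAMPED_ITER):
        w_new = (1.0 - _DAMPING) * w + _DAMPING * g(w)
        if abs(w_new - g(w_new)) < tol:
            w, converged = w_new, True
            break
        w = w_new
    if not converged:
        w = brentq(lambda v: v - g(v), 0.0, w_max, xtol=1e-15, rtol=8.9e-16, maxiter=200)
        if abs(w - g(w)) > tol:
            raise RuntimeError(
                f"genetic DNF fixed point did not converge: residual={abs(w - g(w)):.3e}"
            )
    t = _tetr(p, w, params)
    return GeneticState(
        x=float(x), p=p, t=t, L=_luxr(t, params), w=w,
        z=_output(p, w, params), converged=True, residual=abs(w - g(w)),
    )


def genetic_dose_response(
    wiring: str, params: GeneticParams, x_grid, tol: float = DEFAULT_TOL
) -> DoseResponse:
    """Vectorise a genetic steady-state model over an input grid."""
    x_grid = np.asarray(x_grid, dtype=float)
    if x_grid.size == 0:
        raise ValueError("x_grid must not be empty")
    if np.any(np.diff(x_grid) <= 0):
        raise ValueError("x_grid must be strictly increasing")
    if wiring == "ICF":
        z = np.array([genetic_icf_steady_state(x, params).z for x in x_grid])
    elif wiring == "DNF":
        z = np.array([genetic_dnf_steady_state(x, params, tol).z for x in x_grid])
    else:
        raise ValueError(f"wiring must be 'ICF' or 'DNF', got {wiring!r}")
    return DoseResponse(inputs=x_grid, outputs=z, input_label="x", output_label="z")
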