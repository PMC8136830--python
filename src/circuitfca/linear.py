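"""Linear block models of fold-change-optimising circuit topologies.

Three algebraic steady-state designs act on a promoter-under-test (PUT)
with normalised basal level ``beta`` and maximum ``1``:

* **OL** (open loop): a constant subtraction ``out = p - Fs``.
* **ICF** (indirect coherent feedforward): the PUT drives the output
  directly and, through an inverter branch with gain ``Fs``, subtracts
  the complement of its own activity: ``out = p - Fs*(1 - p)``.
* **DNF** (double negative feedback / mutual inhibition): the output is
  fed back through an inverter of gain ``Fs``; the fixed point of
  ``out = p - Fs*(1 - out)`` is ``(p - Fs)/(1 - Fs)``.

All signals are clipped below at a configurable floor ``eps`` because
physical signals cannot go negative and any measurement has a noise
floor.  ICF and DNF both preserve the maximum (``out = 1`` at ``p = 1``)
while pushing the basal output toward the floor, which is what raises
the fold-change activation (FCA = ON/OFF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HillPut",
    "LinearCircuitParams",
    "put_transfer",
    "linear_response",
    "linear_optimal_fs",
    "linear_dose_response",
    "TOPOLOGIES",
]

TOPOLOGIES = ("OL", "ICF", "DNF")


@dataclass(frozen=True)
class HillPut:
    """Normalised Hill transfer function of the promoter under test.

    ``p(u) = (u**n + beta) / (1 + u**n)`` rises monotonically from the
    basal level ``beta`` at ``u = 0`` to ``1`` as ``u`` grows.

    Parameters
    ----------
    beta : float
        Basal (leaky) activity, ``0 < beta < 1``.
    n : float
        Hill coefficient, ``n > 0``.
    """

    beta: float
    n: float

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")
        if self.n <= 0.0:
            raise ValueError(f"Hill coefficient n must be > 0, got {self.n}")

    def __call__(self, u):
        return put_transfer(u, self)


def put_transfer(u, put: HillPut):
    """Evaluate the PUT transfer function ``(u**n + beta)/(1 + u**n)``.

    Accepts scalars or arrays; ``u`` must be non-negative.  The result
    lies in ``[beta, 1]`` and is monotone non-decreasing in ``u``.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("input u must be non-negative")
    un = u**put.n
    out = (un + put.beta) / (1.0 + un)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LinearCircuitParams:
    """Topology and loop strength of a linear circuit.

    ``floor`` is the output floor epsilon; a strictly-zero OFF state
    would make the fold change infinite, so outputs (and FCA
    denominators) are clipped at this level.
    """

    topology: str
    fs: float
    floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(
                f"topology must be one of {TOPOLOGIES}, got {self.topology!r}"
            )
        if self.fs < 0:
            raise ValueError(f"loop strength fs must be >= 0, got {self.fs}")
        if self.topology == "DNF" and self.fs >= 1.0:
            raise ValueError(
                "DNF feedback gain fs must be < 1 (the loop diverges at fs = 1)"
            )
        if self.floor < 0:
            raise ValueError(f"floor must be >= 0, got {self.floor}")


def linear_response(p, params: LinearCircuitParams):
    """Steady-state output of a linear topology for PUT activity ``p``.

    OL:  ``max(eps, p - Fs)``
    ICF: ``max(eps, p*(1 + Fs) - Fs)``  (direct branch minus ``Fs*(1-p)``)
    DNF: ``max(eps, (p - Fs)/(1 - Fs))``

    For ICF and DNF the output equals 1 exactly when ``p = 1``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("PUT activity p must lie in [0, 1]")
    fs = params.fs
    if params.topology == "OL":
        raw = p - fs
    elif params.topology == "ICF":
        raw = p * (1.0 + fs) - fs
    else:  # DNF; fs < 1 enforced by params
        raw = (p - fs) / (1.0 - fs)
    out = np.maximum(raw, params.floor)
    return out if out.ndim else float(out)


def linear_optimal_fs(topology: str, beta: float) -> float | None:
    """Loop strength giving maximal FCA and minimal MDL, if one exists.

    ICF: ``beta / (1 - beta)``; DNF: ``beta``.  These are the strengths
    at which the basal output just reaches zero while the maximum stays
    at 1.  The open loop has no FCA-improving optimum (subtraction
    lowers ON and OFF alike), so OL returns ``None``.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must be in (0, 1), got {beta}")
    if topology == "OL":
        return None
    if topology == "ICF":
        return beta / (1.0 - beta)
    if topology == "DNF":
        return beta
    raise ValueError(f"topology must be one of {TOPOLOGIES}, got {topology!r}")


def linear_dose_response(u_grid, put: HillPut, params: LinearCircuitParams):
    """Full input-to-output curve: PUT transfer followed by the topology."""
    return linear_response(put_transfer(u_grid, put), params)
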