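"""Mean-field firing-rate model of a population with dynamic synapses.

A single recurrently connected population with TM synapses is summarized by
the mean current h, mean depression x and mean facilitation u:

    tau h' = -h + A u x <nu> + I_ext
        x' = (1 - x)/tau_rec - u x <nu>
        u' = (U - u)/tau_facil + U (1 - u) <nu>

with a threshold-linear gain <nu> = a [h - theta]_+.  At equilibrium the
current satisfies h = F(<nu>) with

    F(nu) = A U (nu^-1 + tau_facil)
            / (nu^-2 + nu^-1 U tau_facil + nu^-1 U tau_rec + U tau_facil tau_rec)
            + I_ext,

whose nu -> inf limit gives the rate ceiling <nu> <= A/tau_rec + I_ext.  The
learning rules are gradients of the rate error through this bound (and its
heuristic U- and tau_facil-analogues); this module is the analytic surface
the rules are validated against.  Units: rates in Hz, time constants in
seconds, so A/tau_rec is a rate.

The gain constants a, theta are validation-only defaults (a=1, theta=0);
they never enter the network simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MeanFieldParams",
    "meanfield_rhs",
    "fixed_point_F",
    "rate_bound",
    "self_consistent_rate",
]


@dataclass
class MeanFieldParams:
    """Population-level synaptic and gain parameters (times in seconds)."""

    A: float = 0.5
    U: float = 0.5
    tau_rec: float = 0.5
    tau_facil: float = 0.45
    tau: float = 0.01  # current decay constant
    I_ext: float = 0.0
    a: float = 1.0  # gain slope (validation default)
    theta: float = 0.0  # gain threshold (validation default)

    def __post_init__(self) -> None:
        if min(self.tau, self.tau_rec, self.tau_facil) <= 0:
            raise ValueError("time constants must be positive")


def meanfield_rhs(p: MeanFieldParams, nu: float, h: float, x: float, u: float):
    """Time derivatives (h', x', u') of the mean-field equations."""
    if nu < 0:
        raise ValueError("nu must be non-negative")
    dh = (-h + p.A * u * x * nu + p.I_ext) / p.tau
    dx = (1.0 - x) / p.tau_rec - u * x * nu
    du = (p.U - u) / p.tau_facil + p.U * (1.0 - u) * nu
    return dh, dx, du


def fixed_point_F(p: MeanFieldParams, nu) -> np.ndarray:
    """Equilibrium current h = F(nu); requires nu > 0."""
    nu = np.asarray(nu, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("fixed_point_F requires nu > 0")
    inv = 1.0 / nu
    num = p.A * p.U * (inv + p.tau_facil)
    den = (
        inv**2
        + inv * p.U * p.tau_facil
        + inv * p.U * p.tau_rec
        + p.U * p.tau_facil * p.tau_rec
    )
    return num / den + p.I_ext


def rate_bound(p: MeanFieldParams) -> float:
    """High-rate ceiling <nu> = A/tau_rec + I_ext (the nu->inf limit of F)."""
    return p.A / p.tau_rec + p.I_ext


def self_consistent_rate(
    p: MeanFieldParams, bracket: tuple = (1e-6, 500.0)
) -> float:
    """Solve a*[F(nu) - theta]_+ = nu for nu by bisection.

    Raises ValueError when no sign change exists in the bracket (reported,
    never silently defaulted).
    """

    def resid(nu: float) -> float:
        return p.a * max(fixed_point_F(p, nu) - p.theta, 0.0) - nu

    lo, hi = bracket
    if resid(lo) * resid(hi) > 0:
        raise ValueError(f"no self-consistent rate in bracket {bracket}")
    return float(brentq(resid, lo, hi))
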