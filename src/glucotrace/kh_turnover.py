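"""Kinetic-heterogeneity (kh) model of lymphocyte DNA labeling.

A population of constant size proliferates at rate ``p`` (per day);
labeled cells disappear — by death, phenotype change or migration out of
the sampled compartment — at rate ``d*`` (per day), representative of
the labeled subpopulation only.  With plasma precursor enrichment U(t)
and normalization constant ``b`` (the maximum attainable fraction of
labeled deoxyadenosine at 100% precursor enrichment), the fraction X*
of labeled deoxyadenosine at the proliferation site obeys

    dX*/dt = b p U(t) - d* X*,   X*(0) = 0,

and the observed blood fraction lags by ``lag`` days with loss en route:

    L*(t) = X*(t - lag) exp(-lag d*).

The forward solver integrates the linear ODE exactly on a piecewise-
linear interpolation of U, so simulated and closed-form square-pulse
answers agree to solver-free precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .square_pulse import SquarePulse
from .tracer_simulator import EnrichmentProfile

__all__ = ["KhParams", "LabelCurve", "simulate_kh", "closed_form_square",
           "combine_subpops"]


@dataclass(frozen=True)
class KhParams:
    """Turnover parameters of the kh model (rates per day)."""

    p: float  # proliferation rate, 1/day
    d_star: float  # disappearance rate of labeled cells, 1/day
    b: float = 0.65  # max attainable label fraction
    lag: float = 0.5  # blood-appearance delay, day

    def __post_init__(self) -> None:
        if self.p < 0 or self.d_star < 0 or self.lag < 0:
            raise ValueError("rates and lag must be >= 0")
        if not 0.0 < self.b <= 1.0:
            raise ValueError("b must be in (0, 1]")


@dataclass(frozen=True)
class LabelCurve:
    """DNA label enrichment versus time (days)."""

    t: np.ndarray  # day
    l_star: np.ndarray  # observed blood fraction
    x_star: np.ndarray | None = None  # fraction at the proliferation site

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        l = np.asarray(self.l_star, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "l_star", l)
        if self.x_star is not None:
            object.__setattr__(self, "x_star",
                               np.asarray(self.x_star, dtype=float))
        if t.shape != l.shape:
            raise ValueError("t and l_star must have equal length")


def _phi(d: float, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """phi1 = (1-exp(-d h))/d and phi2 = (h - phi1)/d, stable for d h -> 0."""
    x = d * h
    small = x < 1e-8
    with np.errstate(divide="ignore", invalid="ignore"):
        phi1 = np.where(small, h * (1 - x / 2 + x * x / 6),
                        -np.expm1(-np.where(small, 1.0, x)) / max(d, 1e-300))
        phi2 = np.where(small, h * h * (0.5 - x / 6 + x * x / 24),
                        (h - phi1) / max(d, 1e-300))
    return phi1, phi2


def _integrate_xstar(t_nodes: np.ndarray, u_nodes: np.ndarray,
                     params: KhParams) -> np.ndarray:
    """Exact X* at ``t_nodes`` for piecewise-linear U between the nodes."""
    d = params.d_star
    bp = params.b * params.p
    h = np.diff(t_nodes)
    slope = np.diff(u_nodes) / h
    phi1, phi2 = _phi(d, h)
    decay = np.exp(-d * h)
    forcing = bp * (u_nodes[:-1] * phi1 + slope * phi2)
    x = np.empty_like(t_nodes)
    x[0] = 0.0
    for i in range(len(h)):
        x[i + 1] = x[i] * decay[i] + forcing[i]
    return x


def simulate_kh(u: EnrichmentProfile, params: KhParams,
                grid: np.ndarray) -> LabelCurve:
    """Forward-simulate DNA labeling on ``grid`` (days) under forcing U.

    ``u`` is a plasma enrichment profile on an hour grid; it must cover
    the requested window.  X*(t) = 0 for t <= 0 and U is interpolated
    linearly between profile nodes.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("grid times must be >= 0")
    t_u = u.t / 24.0
    if grid.max() > t_u.max() + 1e-9:
        raise ValueError("grid extends beyond the enrichment profile support")

    shifted = grid - params.lag
    nodes = np.concatenate([t_u, grid, shifted])
    nodes = np.unique(nodes[(nodes >= 0) & (nodes <= max(grid.max(), 0))])
    if len(nodes) == 0 or nodes[0] > 0:
        nodes = np.concatenate([[0.0], nodes])
    u_nodes = np.interp(nodes, t_u, u.u)
    x_nodes = _integrate_xstar(nodes, u_nodes, params)

    x_at = np.interp(grid, nodes, x_nodes)
    x_shift = np.where(shifted >= 0, np.interp(shifted, nodes, x_nodes), 0.0)
    l_star = x_shift * math.exp(-params.lag * params.d_star)
    return LabelCurve(t=grid, l_star=l_star, x_star=x_at)


def closed_form_square(pulse: SquarePulse, params: KhParams,
                       t: np.ndarray | float) -> np.ndarray | float:
    """Analytic L*(t) under a square-pulse U: the oracle for the solver.

    During the pulse (height u0, duration tau, in days):
    X*(s) = (b p u0 / d*) (1 - exp(-d* s)); afterwards it decays as
    exp(-d* (s - tau)).  The lag shift and en-route loss then give L*.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    d = params.d_star
    u0 = pulse.height
    t0 = pulse.start / 24.0
    tau = (pulse.end - pulse.start) / 24.0
    s = t - params.lag - t0  # time since pulse start, at the site
    bp = params.b * params.p * u0

    def x_of(s: np.ndarray) -> np.ndarray:
        s_on = np.clip(s, 0.0, tau)
        if d > 0:
            x_end = (bp / d) * (-np.expm1(-d * s_on))
        else:
            x_end = bp * s_on
        return x_end * np.exp(-d * np.maximum(s - tau, 0.0))

    l = np.where(s > 0, x_of(np.maximum(s, 0.0)), 0.0) * math.exp(-params.lag * d)
    return float(l[0]) if scalar else l


def combine_subpops(curves: list[LabelCurve],
                    weights: np.ndarray) -> LabelCurve:
    """Pointwise weighted mean of subpopulation label curves.

    Emulates pooling sorted subpopulations (e.g. naive and memory T
    cells) into a total-population enrichment, weighting each curve by
    the relative size of its blood pool.
    """
    weights = np.asarray(weights, dtype=float)
    if len(curves) != len(weights) or len(curves) == 0:
        raise ValueError("need one weight per curve")
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be >= 0 and sum to 1")
    t0 = curves[0].t
    for c in curves[1:]:
        if c.t.shape != t0.shape or not np.allclose(c.t, t0):
            raise ValueError("curves must share a common time grid")
    l = np.sum([w * c.l_star for c, w in zip(curves, weights)], axis=0)
    return LabelCurve(t=t0.copy(), l_star=l)
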