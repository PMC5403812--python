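"""The classical "square pulse" label-availability approximation.

Sparse plasma enrichment measurements taken during a labeling window are
summarized by a trapezoidal area under the curve, an exponential-washout
tail adjustment is added for residual label after end of infusion, and
the total exposure is rendered as a rectangle of equal area over the
labeling window: constant enrichment during labeling, zero afterwards.

AUC units follow the field's reporting convention of percent-times-day
(%·day) at the interface; sample enrichments are fractions internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracer_simulator import EnrichmentProfile

__all__ = [
    "EnrichmentSamples",
    "SquarePulse",
    "trapezoid_auc",
    "tail_adjustment",
    "build_square_pulse",
]

#: width of the numerical jump inserted when rendering a rectangle, h
_EDGE_EPS = 1e-12


@dataclass(frozen=True)
class EnrichmentSamples:
    """Sparse plasma enrichment measurements around a labeling window."""

    t: np.ndarray  # h, strictly increasing
    e: np.ndarray  # enrichment fraction
    label_start: float  # h
    label_end: float  # h

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        e = np.asarray(self.e, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "e", e)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("t and e must be 1-D arrays of equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(e < 0) or np.any(e > 1):
            raise ValueError("enrichment must be a fraction in [0, 1]")
        if self.label_end <= self.label_start:
            raise ValueError("label_end must be > label_start")


@dataclass(frozen=True)
class SquarePulse:
    """Rectangular label availability: constant ``height`` on [start, end]."""

    auc: float  # %·day
    start: float  # h
    end: float  # h

    def __post_init__(self) -> None:
        if self.auc < 0:
            raise ValueError("auc must be >= 0")
        if self.end <= self.start:
            raise ValueError("end must be > start")

    @property
    def duration_days(self) -> float:
        return (self.end - self.start) / 24.0

    @property
    def height(self) -> float:
        """Enrichment fraction during the pulse."""
        return self.auc / self.duration_days / 100.0

    def render(self, grid: np.ndarray) -> EnrichmentProfile:
        """Render the rectangle on ``grid`` (hours) as a linear profile.

        The pulse edges (with a vanishingly narrow ramp) are inserted
        into the grid so that trapezoidal integration of the rendered
        profile reproduces the AUC exactly under any grid refinement.
        """
        grid = np.asarray(grid, dtype=float)
        edges = []
        for edge in (self.start, self.end):
            edges.extend([edge - _EDGE_EPS, edge + _EDGE_EPS])
        t = np.unique(np.concatenate([grid, edges]))
        t = t[(t >= grid[0] - 1.0) & (t <= max(grid[-1], self.end) + 1.0)]
        u = np.where(
            (t >= self.start - _EDGE_EPS / 2) & (t <= self.end + _EDGE_EPS / 2),
            self.height, 0.0)
        return EnrichmentProfile(t=t, u=u)


def trapezoid_auc(samples: EnrichmentSamples) -> float:
    """Trapezoidal AUC of the samples over the labeling window, %·h.

    Window-boundary values are obtained by clamped interpolation (no
    extrapolation beyond the first/last sample).  Requires at least two
    samples inside the window.
    """
    s, e = samples.label_start, samples.label_end
    inside = (samples.t >= s) & (samples.t <= e)
    if inside.sum() < 2:
        raise ValueError("need >= 2 samples inside the labeling window")
    t = np.unique(np.concatenate([[s], samples.t[inside], [e]]))
    y = np.interp(t, samples.t, samples.e)
    return float(np.trapezoid(y, t)) * 100.0


def tail_adjustment(e_last: float, pool: float, rd: float) -> float:
    """Delabelling-tail AUC, %·h: exponential washout of the last sample.

    Residual label washes out of a glucose pool of mass ``pool`` (g)
    with disappearance rate ``rd`` (g/h), i.e. with time constant
    pool/rd; the integral of ``e_last * exp(-t*rd/pool)`` is
    ``e_last * pool / rd``.
    """
    if e_last < 0 or pool < 0:
        raise ValueError("e_last and pool must be >= 0")
    if rd <= 0:
        raise ValueError("rd must be > 0")
    return 100.0 * e_last * pool / rd


def build_square_pulse(total_auc: float, start: float, end: float) -> SquarePulse:
    """Square pulse over [start, end] hours with area ``total_auc`` %·day."""
    return SquarePulse(auc=total_auc, start=start, end=end)
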