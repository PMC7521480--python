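"""Analytic surfaces implied by a linear mean-variance relationship.

Across experimental conditions many genes show an empirically linear
relationship between the sample mean and variance of their mRNA counts,

    sigma^2 = alpha * mu + sigma_0.

Combining this constraint with the closed-form steady-state moments of the
two-allele telegraph model yields a surface in (k_off, k_on, k_t) rate
space on which the relationship holds exactly.  For zero intercept the
surface is explicit,

    k_t = (alpha - 1)(k_off + k_on + k_d)(1 + k_on/k_off),

and for a general intercept ``k_t`` solves a quadratic whose large root
converges to the explicit surface as ``sigma_0 -> 0``.  In the bursty
regime the burst size along the surface is pinned to ``b_k = alpha - 1``
while expression changes are carried purely by frequency modulation; away
from that regime, how much burst size can move is controlled by ``k_off``
(:func:`modulation_map`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import FrozenSet, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .estimators import kinetic_estimators, steady_state_moments
from .models import GeneModelSpec, Variant

__all__ = [
    "LinearTrend",
    "SurfacePoint",
    "ModulationBounds",
    "kt_on_surface",
    "kt_on_general_surface",
    "bursty_burst_curves",
    "modulation_map",
]

logger = logging.getLogger(__name__)

#: k_off grid used in the modulation analysis (min^-1).
DEFAULT_KOFF_VALUES: Tuple[float, ...] = (0.01, 0.02, 0.03, 0.05, 0.075, 0.1, 0.2)


@dataclass(frozen=True)
class LinearTrend:
    """Fitted linear mean-variance trend sigma^2 = alpha mu + sigma0."""

    alpha: float
    sigma0: float = 0.0
    r2: Optional[float] = None
    n_points: Optional[int] = None
    outlier_indices: FrozenSet[int] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.r2 is not None and not -1e-9 <= self.r2 <= 1 + 1e-9:
            raise ValueError(f"r2 must lie in [0, 1], got {self.r2}")

    @property
    def burst_size(self) -> float:
        """Asymptotic bursty-regime burst size alpha - 1."""
        return self.alpha - 1.0


@dataclass(frozen=True)
class SurfacePoint:
    """A point on the constraint surface with its implied burst statistics."""

    k_on: float
    k_off: float
    k_t: float
    mu: float
    b: float
    f: float

    @classmethod
    def from_rates(cls, alpha: float, k_on: float, k_off: float,
                   k_d: float, sigma0: float = 0.0) -> "SurfacePoint":
        if sigma0 == 0.0:
            k_t = kt_on_surface(alpha, k_on, k_off, k_d)
        else:
            roots = kt_on_general_surface(alpha, sigma0, k_on, k_off, k_d)
            if not roots:
                raise ValueError("no admissible k_t root for these rates")
            k_t = roots[-1]  # large root, continuous with the sigma0=0 surface
        spec = GeneModelSpec(Variant.ONE_STEP, k_on=k_on, k_off=k_off,
                             k_t=k_t, k_d=k_d)
        mu, var = steady_state_moments(spec)
        resid = abs(var - (alpha * mu + sigma0)) / max(abs(var), 1.0)
        if resid > 1e-9:
            raise ValueError(f"point off surface, relative residual {resid:.2e}")
        est = kinetic_estimators(spec)
        return cls(k_on=k_on, k_off=k_off, k_t=k_t, mu=mu,
                   b=est.size, f=est.frequency)


def kt_on_surface(alpha: float, k_on: float, k_off: float,
                  k_d: float) -> float:
    """Transcription rate putting a one-step model on sigma^2 = alpha mu.

    Substituting the result into the closed-form moments yields a Fano
    factor exactly equal to ``alpha``.  Requires ``alpha > 1`` (a bursty
    interpretation, b = alpha - 1 > 0) and positive rates.
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1 for a bursty interpretation")
    if min(k_on, k_off, k_d) <= 0:
        raise ValueError("rates must be > 0")
    return (alpha - 1.0) * (k_off + k_on + k_d) * (1.0 + k_on / k_off)


def kt_on_general_surface(alpha: float, sigma0: float, k_on: float,
                          k_off: float, k_d: float) -> Tuple[float, ...]:
    """Nonnegative k_t roots for the general trend sigma^2 = alpha mu + sigma0.

    Eliminating mu and sigma^2 with the steady-state closed forms leaves a
    quadratic ``A k_t^2 + B k_t - sigma0 = 0`` with

        A = 2 k_off k_on / (k_d (k_on+k_off)^2 (k_on+k_off+k_d))
        B = 2 (1 - alpha) k_on / (k_d (k_on+k_off)).

    Returns 0, 1 or 2 strictly positive real roots (ascending).  As
    ``sigma0 -> 0`` the large root converges to :func:`kt_on_surface` and
    the small root (a vanishing transcription rate) disappears.
    """
    if min(k_on, k_off, k_d) <= 0:
        raise ValueError("rates must be > 0")
    ks = k_on + k_off
    A = 2.0 * k_off * k_on / (k_d * ks * ks * (ks + k_d))
    B = 2.0 * (1.0 - alpha) * k_on / (k_d * ks)
    disc = B * B + 4.0 * A * sigma0
    if disc < 0:
        return ()
    sq = math.sqrt(disc)
    roots = sorted(((-B - sq) / (2 * A), (-B + sq) / (2 * A)))
    kept = tuple(r for r in roots if r > 1e-12)
    dropped = len(roots) - len(kept)
    if dropped:
        logger.debug("discarded %d non-positive k_t root(s) at "
                     "alpha=%g sigma0=%g k_on=%g k_off=%g",
                     dropped, alpha, sigma0, k_on, k_off)
    return kept


def bursty_burst_curves(trend: LinearTrend, mu_grid) -> Tuple[np.ndarray, np.ndarray]:
    """Bursty-regime burst size and frequency along a mean grid.

    b(mu) = (alpha - 1) + sigma0/mu, approaching the constant alpha - 1
    for large means; f(mu) = mu / b(mu).
    """
    if trend.alpha <= 1:
        raise ValueError("alpha must exceed 1")
    mu = np.asarray(mu_grid, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mean grid must be strictly positive")
    b = (trend.alpha - 1.0) + trend.sigma0 / mu
    f = mu / b
    return b, f


@dataclass(frozen=True)
class ModulationBounds:
    """Biologically plausible rate bounds for the modulation sweep."""

    k_off_max: float = 0.2
    k_on_max: float = 0.1
    k_on_min: float = 1e-4
    k_t_max: float = 30.0
    k_d: float = 0.014
    mu_max: float = 500.0


def modulation_map(trend: LinearTrend,
                   k_off_values: Sequence[float] = DEFAULT_KOFF_VALUES,
                   bounds: ModulationBounds = None,
                   n_kon: int = 200) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Burst size/frequency modulation attainable along the constraint surface.

    For each ``k_off``, sweeps ``k_on`` over a log-spaced grid, computes
    ``k_t`` from the surface, the implied steady-state mean and the
    kinetic burst statistics, keeping points admissible under ``bounds``.
    Returns ``(points, summary)``: a tidy per-point table
    (k_off, k_on, k_t, mu, b, f) and a per-k_off summary with the
    fold-changes ``delta_b = max b / min b`` and ``delta_f = max f /
    min f`` realized over the attained mean range.  Larger ``k_off``
    (closer to the bursty regime) yields smaller ``delta_b``: burst size
    is then pinned and expression is tuned by frequency alone.
    """
    bounds = bounds or ModulationBounds()
    kon_grid = np.geomspace(bounds.k_on_min, bounds.k_on_max, n_kon)
    rows = []
    for k_off in k_off_values:
        if k_off > bounds.k_off_max:
            logger.debug("k_off=%g outside bounds, skipped", k_off)
            continue
        for k_on in kon_grid:
            try:
                pt = SurfacePoint.from_rates(trend.alpha, k_on, k_off,
                                             bounds.k_d, trend.sigma0)
            except ValueError:
                continue
            if pt.k_t > bounds.k_t_max or pt.mu > bounds.mu_max or pt.mu <= 0:
                continue
            rows.append({"k_off": k_off, "k_on": k_on, "k_t": pt.k_t,
                         "mu": pt.mu, "b": pt.b, "f": pt.f})
    points = pd.DataFrame(rows, columns=["k_off", "k_on", "k_t", "mu", "b", "f"])
    summaries = []
    for k_off, grp in points.groupby("k_off"):
        summaries.append({
            "k_off": k_off,
            "n_points": len(grp),
            "mu_min": grp["mu"].min(), "mu_max": grp["mu"].max(),
            "delta_b": grp["b"].max() / grp["b"].min(),
            "delta_f": grp["f"].max() / grp["f"].min(),
        })
    summary = pd.DataFrame(
        summaries, columns=["k_off", "n_points", "mu_min", "mu_max",
                            "delta_b", "delta_f"])
    return points, summary
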