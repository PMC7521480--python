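"""Burst size and frequency estimators for the two-allele telegraph model.

Two families of estimators are provided:

* *kinetic* estimators, defined from the rate constants of a fitted
  one-step model: burst size ``b_k = k_t / k_off`` and burst frequency
  ``f_k = 2 k_on k_off / ((k_on + k_off) k_d)`` (bursts per mRNA
  lifetime, two alleles);
* *moment* estimators, computed from the sample (or theoretical) mean and
  variance of an mRNA count distribution: ``b_m = sigma^2 / mu`` (the
  Fano factor) and ``f_m = mu / (b_m - 1)``, with ``f_m = +inf`` in the
  Poisson case ``b_m <= 1``.

The steady-state moments of the two-allele telegraph model are available
in closed form (:func:`steady_state_moments`), which makes the discrepancy
between the two families exactly computable (:func:`estimator_errors`,
relative error ``(kinetic - moment) / kinetic``).  In the bursty regime
``k_off >> k_on`` (with ``k_t >> k_off >> k_d``) both errors vanish.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .models import GeneModelSpec, Variant

__all__ = [
    "EstimatorMethod",
    "BurstEstimate",
    "EstimatorError",
    "steady_state_moments",
    "moment_estimators",
    "kinetic_estimators",
    "estimator_errors",
]


class EstimatorMethod(str, enum.Enum):
    MOMENT = "moment"
    KINETIC = "kinetic"


@dataclass(frozen=True)
class BurstEstimate:
    """Burst size (mRNA per burst) and frequency (bursts per mRNA lifetime)."""

    size: float
    frequency: float
    method: EstimatorMethod


@dataclass(frozen=True)
class EstimatorError:
    """Relative error of moment vs kinetic estimators, (kin - mom)/kin."""

    b_error: float
    f_error: float


def _require_one_step(spec: GeneModelSpec, what: str) -> None:
    if Variant(spec.variant) is not Variant.ONE_STEP:
        raise ValueError(f"{what} is defined for the one_step variant only, "
                         f"got {Variant(spec.variant).value}")


def steady_state_moments(spec: GeneModelSpec) -> tuple:
    """Closed-form steady-state (mean, variance) of the two-allele telegraph model.

    mu = 2 k_on k_t / (k_d (k_on + k_off))
    sigma^2 = mu [1 + k_t k_off / ((k_on + k_off)(k_on + k_off + k_d))]

    The Fano factor is identical to the single-allele case because the two
    independent alleles contribute additively to both mean and variance.
    """
    _require_one_step(spec, "steady_state_moments")
    if spec.k_d <= 0:
        raise ValueError("steady-state moments require k_d > 0")
    ks = spec.k_on + spec.k_off
    mu = 2.0 * spec.k_on * spec.k_t / (spec.k_d * ks)
    fano = 1.0 + spec.k_t * spec.k_off / (ks * (ks + spec.k_d))
    return mu, mu * fano


def moment_estimators(mu: float, var: float) -> BurstEstimate:
    """Moment-based burst size and frequency from a mean and variance.

    ``b_m = var/mu``; ``f_m = mu/(b_m - 1)``, reported as ``+inf`` for
    Poisson-like data with ``b_m <= 1`` (no bursting signature).
    """
    if mu <= 0:
        raise ValueError("moment estimators are undefined at mu <= 0")
    if var < 0:
        raise ValueError("variance must be >= 0")
    b = var / mu
    f = mu / (b - 1.0) if b > 1.0 else math.inf
    return BurstEstimate(b, f, EstimatorMethod.MOMENT)


def kinetic_estimators(spec: GeneModelSpec) -> BurstEstimate:
    """Kinetic burst size k_t/k_off and frequency 2 k_on k_off/((k_on+k_off) k_d)."""
    _require_one_step(spec, "kinetic_estimators")
    if spec.k_off <= 0:
        raise ValueError("kinetic estimators require k_off > 0")
    if spec.k_d <= 0:
        raise ValueError("kinetic estimators require k_d > 0")
    b = spec.k_t / spec.k_off
    f = 2.0 * spec.k_on * spec.k_off / ((spec.k_on + spec.k_off) * spec.k_d)
    return BurstEstimate(b, f, EstimatorMethod.KINETIC)


def estimator_errors(spec: GeneModelSpec) -> EstimatorError:
    """Closed-form relative errors (kinetic - moment)/kinetic at steady state.

    b_error = 1 - k_off^2/((k_on+k_off)(k_on+k_off+k_d)) - k_off/k_t
    f_error = 1 - (k_off+k_on+k_d)(k_off+k_on)/k_off^2

    ``f_error`` does not involve ``k_t``; both errors tend to zero in the
    bursty limit ``k_off >> k_on``, ``k_off >> k_d``, ``k_t >> k_off``.
    """
    _require_one_step(spec, "estimator_errors")
    if spec.k_off <= 0 or spec.k_t <= 0 or spec.k_d <= 0:
        raise ValueError("estimator errors require k_off, k_t, k_d > 0")
    ks = spec.k_on + spec.k_off
    b_error = 1.0 - spec.k_off ** 2 / (ks * (ks + spec.k_d)) \
        - spec.k_off / spec.k_t
    f_error = 1.0 - (ks + spec.k_d) * ks / spec.k_off ** 2
    return EstimatorError(b_error=b_error, f_error=f_error)
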