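"""The two-sector (Scott-Hwa) proteome-allocation growth model.

Growth results from a metabolic sector (proteome fraction ``phi_n``,
efficiency ``kappa_n``) feeding precursors to a translational sector
(fraction ``phi_t``, efficiency ``kappa_t``), with a housekeeping fraction
``phi_o`` reserved, ``phi_t + phi_n + phi_o = 1``.  A growth-optimising
cell wastes no protein, so the two fluxes balance::

    lambda = kappa_t * phi_t = kappa_n * phi_n
           = (1 - phi_o) / (1/kappa_t + 1/kappa_n)

A mutation rescales one parameter, ``alpha' = theta * alpha``, and the cell
re-optimises its allocation.  For one mutation to ``kappa_t`` and one to
``kappa_n`` the double-mutant fitness has the closed form::

    W_xy = 1 / (1/W_x + 1/W_y - 1)

which is a Product law with a correction, sandwiched between Product and
Minimum on deleterious inputs.  The re-allocation feedback is essential:
with the proteome frozen at the wild-type optimum the double mutant obeys
the Minimum law exactly.  For beneficial mutations the closed form's
denominator can vanish (at ``W_x = W_y = 2``): the optimising feedback
compounds improvements, so the model's double-mutant fitness exceeds all
three simple laws in that regime.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .laws import DivergenceError, predict

__all__ = [
    "ScottHwaParams",
    "MutationSpec",
    "optimal_growth_rate",
    "optimal_allocation",
    "numeric_growth_rate",
    "closed_form_double_fitness",
    "equal_fitness_divergence_point",
    "no_feedback_growth_rate",
    "sample_double_mutants",
    "phi_o_multiplicativity_check",
]


@dataclass(frozen=True)
class ScottHwaParams:
    """Model parameters: sector efficiencies (1/time) and housekeeping
    fraction.  Absolute values of the kappas are immaterial to fitness
    ratios (only the rescaling factors theta matter), so the defaults are
    1."""

    kappa_t: float = 1.0
    kappa_n: float = 1.0
    phi_o: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa_t <= 0 or self.kappa_n <= 0:
            raise ValueError("kappa_t and kappa_n must be positive")
        if not 0 <= self.phi_o < 1:
            raise ValueError("phi_o must be in [0, 1)")


@dataclass(frozen=True)
class MutationSpec:
    """A multiplicative perturbation ``target' = factor * target``."""

    target: str
    factor: float

    def apply(self, params: ScottHwaParams) -> ScottHwaParams:
        if self.target not in ("kappa_t", "kappa_n", "phi_o"):
            raise ValueError(f"unknown target {self.target!r}")
        return replace(params, **{self.target: self.factor * getattr(params, self.target)})


def optimal_growth_rate(params: ScottHwaParams) -> float:
    """Growth rate at the growth-maximising allocation:
    ``(1 - phi_o) / (1/kappa_t + 1/kappa_n)``."""
    return (1.0 - params.phi_o) / (1.0 / params.kappa_t + 1.0 / params.kappa_n)


def optimal_allocation(params: ScottHwaParams) -> Tuple[float, float]:
    """Optimal ``(phi_t, phi_n)``; satisfies ``phi_t + phi_n + phi_o = 1``."""
    lam = optimal_growth_rate(params)
    return lam / params.kappa_t, lam / params.kappa_n


def _golden_max_rate(kappa_t, kappa_n, budget, n_iter: int = 90):
    """Vectorised golden-section maximisation of
    ``min(kappa_t * phi_t, kappa_n * (budget - phi_t))`` over
    ``phi_t in [0, budget]``.

    The objective is concave piecewise linear (a single kink at the
    flux-balance point), so golden section converges unconditionally; 90
    iterations shrink the bracket to machine precision.
    """
    kappa_t = np.asarray(kappa_t, dtype=float)
    kappa_n = np.asarray(kappa_n, dtype=float)
    lo = np.zeros(np.broadcast(kappa_t, kappa_n).shape)
    hi = np.full_like(lo, budget)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0

    def f(phi):
        return np.minimum(kappa_t * phi, kappa_n * (budget - phi))

    for _ in range(n_iter):
        x1 = hi - invphi * (hi - lo)
        x2 = lo + invphi * (hi - lo)
        left = f(x1) >= f(x2)
        hi = np.where(left, x2, hi)
        lo = np.where(left, lo, x1)
    return f(0.5 * (lo + hi))


def numeric_growth_rate(params: ScottHwaParams) -> float:
    """Growth rate by numerical maximisation of
    ``min(kappa_t * phi_t, kappa_n * (1 - phi_o - phi_t))`` over ``phi_t``.

    Independent of the closed form; used as the model evaluation in
    mutational scans so the closed form is checked against a genuine
    optimisation.
    """
    return float(
        _golden_max_rate(params.kappa_t, params.kappa_n, 1.0 - params.phi_o)
    )


def closed_form_double_fitness(w_x, w_y):
    """Closed-form double-mutant fitness ``1/(1/w_x + 1/w_y - 1)`` for one
    mutation to each sector efficiency.  Raises
    :class:`~neutrality.laws.DivergenceError` when the denominator is <= 0."""
    return predict("scott_hwa", w_x, w_y)


def equal_fitness_divergence_point(bracket: Tuple[float, float] = (1.0 + 1e-9, 100.0)) -> float:
    """The equal single-mutant fitness ``w > 1`` at which the closed form
    diverges, found by root-finding the denominator ``2/w - 1`` of
    ``W_xy = 1/(1/w + 1/w - 1)``."""
    lo, hi = bracket

    def denominator(w: float) -> float:
        return 1.0 / w + 1.0 / w - 1.0

    return float(brentq(denominator, lo, hi, xtol=1e-12))


def no_feedback_growth_rate(
    params: ScottHwaParams, wt_allocation: Tuple[float, float]
) -> float:
    """Growth with the allocation frozen at the wild-type optimum:
    ``min(kappa_t * phi_t, kappa_n * phi_n)``.  With unmutated parameters
    this equals :func:`optimal_growth_rate` (the fluxes balance at the
    optimum)."""
    phi_t, phi_n = wt_allocation
    return min(params.kappa_t * phi_t, params.kappa_n * phi_n)


def _fitness_triplet(
    params: ScottHwaParams,
    theta_t: np.ndarray,
    theta_n: np.ndarray,
    feedback: bool,
    numeric: bool,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single- and double-mutant fitnesses for mutations scaling kappa_t by
    theta_t and kappa_n by theta_n."""
    wt_rate = optimal_growth_rate(params)
    budget = 1.0 - params.phi_o
    if feedback:
        if numeric:
            def rate(kt_scale, kn_scale):
                return _golden_max_rate(
                    kt_scale * params.kappa_t, kn_scale * params.kappa_n, budget
                )
        else:
            def rate(kt_scale, kn_scale):
                return budget / (
                    1.0 / (kt_scale * params.kappa_t)
                    + 1.0 / (kn_scale * params.kappa_n)
                )
    else:
        phi_t, phi_n = optimal_allocation(params)

        def rate(kt_scale, kn_scale):
            return np.minimum(
                kt_scale * params.kappa_t * phi_t,
                kn_scale * params.kappa_n * phi_n,
            )

    ones = np.ones_like(theta_t)
    w_x = rate(theta_t, ones) / wt_rate
    w_y = rate(ones, theta_n) / wt_rate
    w_xy = rate(theta_t, theta_n) / wt_rate
    return w_x, w_y, w_xy


def sample_double_mutants(
    params: ScottHwaParams,
    n: int,
    regime: str = "deleterious",
    seed: Optional[int] = None,
    theta_max: float = 2.0,
    feedback: bool = True,
    numeric: bool = True,
) -> pd.DataFrame:
    """Sample ``n`` double mutants, one mutation to each sector efficiency.

    Deleterious regime: ``theta ~ U(0, 1]`` independently for ``kappa_t``
    and ``kappa_n`` (theta = 0 exactly is excluded to avoid undefined
    fitness ratios).  Beneficial regime: ``theta ~ U(1, theta_max)``.  The
    model fitness is obtained by (numerically) re-optimising the proteome
    allocation; ``feedback=False`` freezes the wild-type allocation
    instead.  Rows carry the four law predictions alongside the model and
    closed-form values; the closed form is evaluated only where it is
    finite (NaN where it diverges, which cannot happen in the deleterious
    regime).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if regime not in ("deleterious", "beneficial"):
        raise ValueError("regime must be 'deleterious' or 'beneficial'")
    rng = np.random.default_rng(seed)
    if regime == "deleterious":
        theta_t = 1.0 - rng.random(n)  # (0, 1]
        theta_n = 1.0 - rng.random(n)
    else:
        theta_t = rng.uniform(1.0, theta_max, n)
        theta_n = rng.uniform(1.0, theta_max, n)
    w_x, w_y, w_xy = _fitness_triplet(params, theta_t, theta_n, feedback, numeric)
    den = 1.0 / w_x + 1.0 / w_y - 1.0
    with np.errstate(divide="ignore"):
        closed = np.where(den > 0, 1.0 / np.where(den > 0, den, 1.0), np.nan)
    return pd.DataFrame(
        {
            "theta_x": theta_t,
            "theta_y": theta_n,
            "w_x": w_x,
            "w_y": w_y,
            "w_xy_model": w_xy,
            "w_xy_product": w_x * w_y,
            "w_xy_additive": w_x + w_y - 1.0,
            "w_xy_minimum": np.minimum(w_x, w_y),
            "w_xy_closed_form": closed,
        }
    )


def phi_o_multiplicativity_check(
    params: ScottHwaParams,
    theta_phi: float,
    theta_kappa: float,
    kappa_target: str = "kappa_t",
) -> Tuple[float, float, float]:
    """Fitnesses for one mutation to ``phi_o`` and one to a sector
    efficiency; these combine exactly multiplicatively
    (``w_xy = w_x * w_y``) because the ``(1 - phi_o)`` prefactor factors
    out of the optimal growth rate."""
    if kappa_target not in ("kappa_t", "kappa_n"):
        raise ValueError("kappa_target must be 'kappa_t' or 'kappa_n'")
    new_phi = theta_phi * params.phi_o
    if not 0 <= new_phi < 1:
        raise ValueError("mutated phi_o leaves [0, 1)")
    wt = optimal_growth_rate(params)
    p_x = replace(params, phi_o=new_phi)
    p_y = MutationSpec(kappa_target, theta_kappa).apply(params)
    p_xy = replace(p_y, phi_o=new_phi)
    return (
        optimal_growth_rate(p_x) / wt,
        optimal_growth_rate(p_y) / wt,
        optimal_growth_rate(p_xy) / wt,
    )
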