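"""Predicted species counts at the SAR phase transitions.

Species whose range centre lies within ``k * sigma_p`` of the focal point
(``k = 2`` for the Phase I-II boundary, ``k = 4`` for Phase II-III; heuristic
cut-offs, configurable) are the ones contributing to the earlier phase.  For
range centres distributed uniformly over a region of area ``A_T`` the
proportion of such species has the closed form

    S_MP = pi * (k * sigma_p)**2 / A_T,

and in general it is the polar double integral over the region of the centre
density times the probability that a species' range half-width ``w = k *
sigma_p`` exceeds its centre's distance ``r`` to the focal point:

    S_MP = int_0^{R_T} int_0^{2 pi} P(w > r | r, phi) f(r, phi) dphi dr.

Multiplying by the community size ``S_T`` gives the predicted species counts
``S_P`` at which the log-log curve changes slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import integrate

__all__ = [
    "TransitionModel",
    "TransitionPrediction",
    "uniform_disc_density",
    "transition_fraction_uniform",
    "transition_fraction_general",
    "transition_counts",
    "K_PHASE_I_II",
    "K_PHASE_II_III",
]

# heuristic range-width multipliers for the two transitions
K_PHASE_I_II = 2.0
K_PHASE_II_III = 4.0


@dataclass(frozen=True)
class TransitionModel:
    """Region geometry plus centre-density and range-width laws.

    ``centre_density(r, phi)`` is the probability density of range centres in
    polar measure ``dr dphi`` (it must already include the Jacobian ``r`` and
    integrate to 1 over ``[0, R_T] x [0, 2 pi]``).  ``width_law(r, phi)`` is
    the probability that a species centred at ``(r, phi)`` has range width
    ``w = k * sigma_p`` exceeding ``r``.  ``breakpoints`` lists radii where
    the integrand is non-smooth (e.g. a deterministic width cut-off), passed
    to the quadrature.
    """

    R_T: float
    centre_density: Callable[[float, float], float]
    width_law: Callable[[float, float], float]
    breakpoints: Sequence[float] = ()

    def __post_init__(self) -> None:
        if self.R_T <= 0:
            raise ValueError("R_T must be > 0")

    @property
    def A_T(self) -> float:
        return np.pi * self.R_T**2


@dataclass(frozen=True)
class TransitionPrediction:
    fraction_I_II: float
    fraction_II_III: float
    count_I_II: int
    count_II_III: int
    S_T: int


def uniform_disc_density(R_T: float) -> Callable[[float, float], float]:
    """Polar density of centres uniform over the disc of radius ``R_T``."""
    A_T = np.pi * R_T**2

    def f(r: float, phi: float) -> float:
        return r / A_T if 0.0 <= r <= R_T else 0.0

    return f


def transition_fraction_uniform(k: float, sigma_p: float, A_T: float) -> float:
    """Closed-form transition fraction ``pi (k sigma_p)**2 / A_T`` (clipped to 1)."""
    if k <= 0 or sigma_p <= 0 or A_T <= 0:
        raise ValueError("k, sigma_p and A_T must be > 0")
    raw = np.pi * (k * sigma_p) ** 2 / A_T
    if raw > 1.0:
        warnings.warn(
            f"transition fraction {raw:.3g} exceeds 1 (region smaller than the "
            "phase disc); clipped to 1", RuntimeWarning, stacklevel=2)
        return 1.0
    return float(raw)


def transition_fraction_general(
    model: TransitionModel,
    atol: float = 1e-8,
    density_check_tol: float = 1e-2,
) -> float:
    """Transition fraction by adaptive quadrature of the polar double integral.

    Raises if the supplied centre density does not integrate to 1 within
    ``density_check_tol``, or if the quadrature fails to converge.
    """
    pts = [b for b in model.breakpoints if 0.0 < b < model.R_T]

    def phi_integral(func: Callable[[float, float], float], r: float) -> float:
        val, _ = integrate.quad(lambda phi: func(r, phi), 0.0, 2.0 * np.pi,
                                epsabs=atol, limit=200)
        return val

    norm, norm_err = integrate.quad(
        lambda r: phi_integral(model.centre_density, r), 0.0, model.R_T,
        epsabs=atol, limit=200, points=pts or None)
    if abs(norm - 1.0) > density_check_tol:
        raise ValueError(
            f"centre density integrates to {norm:.4f} over the region, not 1")

    def integrand(r: float, phi: float) -> float:
        return model.width_law(r, phi) * model.centre_density(r, phi)

    val, err = integrate.quad(
        lambda r: phi_integral(integrand, r), 0.0, model.R_T,
        epsabs=atol, limit=200, points=pts or None)
    if not np.isfinite(val) or err > max(1e-6, 1e-3 * abs(val)):
        raise ArithmeticError(
            f"transition integral did not converge (value {val}, error estimate {err})")
    return float(min(max(val, 0.0), 1.0))


def transition_counts(
    fraction_I_II: float,
    fraction_II_III: float,
    S_T: int,
) -> tuple[int, int]:
    """Species counts at the transitions, rounded to the nearest integer."""
    for f in (fraction_I_II, fraction_II_III):
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    if fraction_I_II > fraction_II_III:
        raise ValueError("fraction_I_II must not exceed fraction_II_III")
    s12 = int(round(fraction_I_II * S_T))
    s23 = int(round(fraction_II_III * S_T))
    return s12, s23


def predict_transitions(
    sigma_p: float,
    A_T: float,
    S_T: int,
    k_I_II: float = K_PHASE_I_II,
    k_II_III: float = K_PHASE_II_III,
) -> TransitionPrediction:
    """Closed-form transition fractions and counts for uniform centres."""
    f12 = transition_fraction_uniform(k_I_II, sigma_p, A_T)
    f23 = transition_fraction_uniform(k_II_III, sigma_p, A_T)
    c12, c23 = transition_counts(f12, f23, S_T)
    return TransitionPrediction(fraction_I_II=f12, fraction_II_III=f23,
                                count_I_II=c12, count_II_III=c23, S_T=S_T)


__all__.append("predict_transitions")
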