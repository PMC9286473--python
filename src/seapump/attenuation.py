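"""Particle-flux attenuation mathematics.

This module holds the power-law flux profile, transfer efficiency,
the correspondence between the attenuation exponent ``b`` and the
depth-linear sinking-speed coefficient ``a`` (``w(z) = a z``,
``a = lam / b``), and the seasonal cosine parameterization of ``b``
with its hemisphere flip and closed-form annual means.

Conventions
-----------
* Time ``t`` is in days, with a 360-day default period.
* ``phi`` is latitude in degrees North.  In the Northern Hemisphere the
  seasonal exponent is ``b_ref - delta_b * cos(2 pi t / T + theta pi / 6)``;
  the Southern Hemisphere flips the sign of the cosine term; the equator
  sees the constant reference value.
* ``theta`` is a phase in months (12 months = one full cycle); it may be
  any real number, with {0, 3, 6, 9} the canonical experiment values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "LambdaSeasonal",
    "SeasonalAttenuation",
    "martin_flux",
    "martin_te",
    "sinking_coefficient",
    "seasonal_b",
    "seasonal_lambda",
    "seasonal_A",
    "mean_A",
    "equivalent_b",
    "sinking_speed",
    "transit_time",
]

DEFAULT_B_REF = 1.388
DEFAULT_LAMBDA = 0.05  # day^-1
DEFAULT_PERIOD = 360.0  # days


@dataclass(frozen=True)
class LambdaSeasonal:
    """Optional seasonal modulation of the remineralization rate.

    The time dependence mirrors the seasonal exponent: in the Northern
    Hemisphere ``lam(t) = lam - delta_lam * cos(2 pi t / T + theta pi / 6)``,
    with the sign flipped south of the equator.
    """

    delta_lam: float
    theta: float = 0.0  # months


@dataclass(frozen=True)
class SeasonalAttenuation:
    """Parameter bundle for the seasonally varying attenuation exponent.

    Parameters
    ----------
    b_ref
        Reference (annual-mean) attenuation exponent.
    delta_b
        Absolute seasonal amplitude; ``0 <= delta_b <= b_ref``.
    theta
        Phase in months.
    lam
        Detritus remineralization rate (day^-1).
    period
        Length of the seasonal cycle (days).
    lambda_seasonal
        Optional seasonal remineralization-rate variant.
    """

    b_ref: float = DEFAULT_B_REF
    delta_b: float = 0.6 * DEFAULT_B_REF
    theta: float = 0.0
    lam: float = DEFAULT_LAMBDA
    period: float = DEFAULT_PERIOD
    lambda_seasonal: Optional[LambdaSeasonal] = None

    def __post_init__(self) -> None:
        if self.b_ref <= 0:
            raise ValueError("b_ref must be positive")
        if not 0 <= self.delta_b <= self.b_ref:
            raise ValueError("delta_b must satisfy 0 <= delta_b <= b_ref")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.lambda_seasonal is not None:
            if not 0 <= self.lambda_seasonal.delta_lam < self.lam:
                raise ValueError("delta_lam must satisfy 0 <= delta_lam < lam")

    @classmethod
    def from_fraction(cls, b_ref: float = DEFAULT_B_REF, frac: float = 0.6,
                      theta: float = 0.0, **kwargs) -> "SeasonalAttenuation":
        """Amplitude given as a fraction of ``b_ref`` (the usual notation)."""
        return cls(b_ref=b_ref, delta_b=frac * b_ref, theta=theta, **kwargs)

    @classmethod
    def lambda_varying_preset(cls, frac: float = 0.6, theta: float = 0.0,
                              b_ref: float = DEFAULT_B_REF,
                              lam: float = DEFAULT_LAMBDA) -> "SeasonalAttenuation":
        """Variant: the remineralization rate varies while b stays constant."""
        return cls(b_ref=b_ref, delta_b=0.0, theta=theta, lam=lam,
                   lambda_seasonal=LambdaSeasonal(delta_lam=frac * lam, theta=theta))

    @classmethod
    def constant_a_preset(cls, frac: float = 0.6, theta: float = 0.0,
                          b_ref: float = DEFAULT_B_REF,
                          lam: float = DEFAULT_LAMBDA) -> "SeasonalAttenuation":
        """Variant: b and the remineralization rate vary in proportion so the
        sinking coefficient ``a = lam/b`` is constant in time."""
        return cls(b_ref=b_ref, delta_b=frac * b_ref, theta=theta, lam=lam,
                   lambda_seasonal=LambdaSeasonal(delta_lam=frac * lam, theta=theta))

    def require_finite_speed(self) -> None:
        if self.delta_b >= self.b_ref:
            raise ValueError(
                "delta_b = b_ref makes the sinking coefficient diverge; "
                "a strictly smaller amplitude is required for A(t)")


def martin_flux(F_z0, z0, z, b):
    """Power-law flux profile ``F(z) = F(z0) (z/z0)^-b``."""
    z0 = np.asarray(z0, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(z0 <= 0):
        raise ValueError("reference depth z0 must be positive")
    if np.any(z < z0):
        raise ValueError("z must be >= z0")
    if np.any(np.asarray(b) < 0):
        raise ValueError("b must be >= 0")
    out = np.asarray(F_z0, dtype=float) * (z / z0) ** (-np.asarray(b, dtype=float))
    return out if out.ndim else float(out)


def martin_te(b, z0: float = 120.0, z1: float = 1080.0):
    """Transfer efficiency ``(z1/z0)^-b`` between the export and transfer depths."""
    if not z1 > z0 > 0:
        raise ValueError("need z1 > z0 > 0")
    out = (z1 / z0) ** (-np.asarray(b, dtype=float))
    return out if out.ndim else float(out)


def sinking_coefficient(lam, b):
    """Depth-linear sinking-speed coefficient ``a = lam / b`` (day^-1)."""
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0):
        raise ValueError("b must be positive")
    out = np.asarray(lam, dtype=float) / b
    return out if out.ndim else float(out)


def _hemisphere_sign(phi):
    """-1 north of the equator, +1 south, 0 on it (sign applied to the cosine)."""
    return -np.sign(np.asarray(phi, dtype=float))


def seasonal_b(t, phi, params: SeasonalAttenuation):
    """Seasonal attenuation exponent ``b(t, phi)``.

    Northern Hemisphere: ``b_ref - delta_b cos(2 pi t/T + theta pi/6)``;
    Southern Hemisphere flips the cosine sign; the equator returns ``b_ref``.
    """
    t = np.asarray(t, dtype=float)
    osc = np.cos(2.0 * np.pi * t / params.period + params.theta * np.pi / 6.0)
    out = params.b_ref + _hemisphere_sign(phi) * params.delta_b * osc
    return out if out.ndim else float(out)


def seasonal_lambda(t, phi, params: SeasonalAttenuation):
    """Remineralization rate; seasonal only when the variant flag is set."""
    t = np.asarray(t, dtype=float)
    if params.lambda_seasonal is None:
        out = np.broadcast_to(params.lam, np.broadcast_shapes(t.shape, np.shape(phi)))
        return out.copy() if out.ndim else float(params.lam)
    ls = params.lambda_seasonal
    osc = np.cos(2.0 * np.pi * t / params.period + ls.theta * np.pi / 6.0)
    out = params.lam + _hemisphere_sign(phi) * ls.delta_lam * osc
    return out if out.ndim else float(out)


def seasonal_A(t, phi, params: SeasonalAttenuation):
    """Time-dependent sinking coefficient ``A(t) = lam(t) / b(t, phi)`` (day^-1)."""
    params.require_finite_speed()
    out = seasonal_lambda(t, phi, params) / seasonal_b(t, phi, params)
    return out if np.ndim(out) else float(out)


def mean_A(params: SeasonalAttenuation) -> float:
    """Annual mean of ``A(t)`` away from the equator.

    For a constant remineralization rate the closed form is
    ``lam / sqrt(b_ref**2 - delta_b**2)`` (the mean of 1/cosine-shifted b).
    Seasonal-lambda variants fall back to numerical quadrature.
    """
    params.require_finite_speed()
    if params.lambda_seasonal is None:
        return params.lam / np.sqrt(params.b_ref**2 - params.delta_b**2)
    from scipy.integrate import quad
    val, _ = quad(lambda t: seasonal_A(t, 45.0, params), 0.0, params.period,
                  limit=200)
    return val / params.period


def equivalent_b(params: SeasonalAttenuation) -> float:
    """Constant exponent with the same annual-mean sinking coefficient,
    ``lam / mean_A`` = ``sqrt(b_ref**2 - delta_b**2)`` for constant lam."""
    return params.lam / mean_A(params)


def sinking_speed(z, t, phi, params: SeasonalAttenuation):
    """Detritus sinking speed ``W(z, t) = A(t, phi) * z`` (m day^-1)."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be >= 0")
    out = seasonal_A(t, phi, params) * z
    return out if np.ndim(out) else float(out)


def transit_time(z1, z2, a):
    """Days for a particle to sink from ``z1`` to ``z2`` under ``dz/dt = a z``."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if np.any(z1 <= 0):
        raise ValueError("z1 must be positive (w = a z never leaves z = 0)")
    if np.any(z2 <= z1):
        raise ValueError("need z2 > z1")
    if np.any(np.asarray(a) <= 0):
        raise ValueError("a must be positive")
    out = np.log(z2 / z1) / np.asarray(a, dtype=float)
    return out if out.ndim else float(out)
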