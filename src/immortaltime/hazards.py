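"""Weibull baseline hazard under proportional hazards.

The Weibull family is parameterized here on the rate scale,

    h(t) = lam * ups * t**(ups - 1),        S(t) = exp(-lam * t**ups),

with ``lam > 0`` a rate-like scale parameter (units time**-ups) and
``ups > 0`` the dimensionless shape.  The shape controls the hazard
trend: decreasing for ``ups < 1``, constant (exponential) for
``ups == 1``, increasing for ``ups > 1``.

Exposure acts multiplicatively on the hazard (proportional hazards): a
subject who switches to the exposed state at time ``e`` has hazard
``rr_t * h(t)`` for ``t > e``.  Event times are drawn by inverting the
survival function, both unconditionally and conditionally on survival
to the switch time, so the proportional-hazards contract holds exactly
in simulated data.

Powers ``t**ups`` are evaluated in log space to stay stable for extreme
shapes (e.g. ups = 7 with lam = 1e-5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WeibullHazard",
    "ExposureEffect",
    "hazard_at",
    "survival_at",
    "sample_event_time",
    "sample_conditional_event_time",
]


def _power(t, ups):
    """t**ups via log space for positive t; exact 0.0 at t == 0."""
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(t > 0.0, np.exp(ups * np.log(np.where(t > 0.0, t, 1.0))), 0.0)
    return out


@dataclass(frozen=True)
class WeibullHazard:
    """Weibull baseline hazard, rate-scale parameterization.

    Parameters
    ----------
    lam : float
        Scale-like rate parameter, ``lam > 0`` (units time**-ups).
    ups : float
        Shape parameter, ``ups > 0``.  ``ups == 1`` gives the
        constant-hazard exponential with rate ``lam``.
    """

    lam: float
    ups: float

    def __post_init__(self) -> None:
        if not (self.lam > 0.0):
            raise ValueError(f"lam must be positive, got {self.lam}")
        if not (self.ups > 0.0):
            raise ValueError(f"ups must be positive, got {self.ups}")

    def hazard(self, t):
        """Instantaneous hazard h(t) = lam*ups*t**(ups-1) for t >= 0.

        For ``ups < 1`` the hazard diverges as t -> 0+; t must then be
        strictly positive.
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < 0.0):
            raise ValueError("t must be non-negative")
        if self.ups < 1.0 and np.any(t == 0.0):
            raise ValueError("hazard diverges at t=0 for ups < 1")
        out = self.lam * self.ups * _power(t, self.ups - 1.0)
        return out if out.ndim else float(out)

    def cumulative_hazard(self, t):
        """H(t) = lam * t**ups."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0.0):
            raise ValueError("t must be non-negative")
        out = self.lam * _power(t, self.ups)
        return out if out.ndim else float(out)

    def survival(self, t):
        """S(t) = exp(-lam * t**ups); S(0) = 1."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0.0):
            raise ValueError("t must be non-negative")
        out = np.exp(-self.lam * _power(t, self.ups))
        return out if out.ndim else float(out)

    def ppf_survival(self, u):
        """Invert S: the time T with S(T) == u, for u in (0, 1).

        This is the inverse-CDF sampler: feeding a Uniform(0,1) draw
        gives an event time with the Weibull law.
        """
        u = np.asarray(u, dtype=float)
        if np.any((u <= 0.0) | (u >= 1.0)):
            raise ValueError("u must lie strictly in (0, 1)")
        out = np.exp(np.log(-np.log(u) / self.lam) / self.ups)
        return out if out.ndim else float(out)

    def conditional_ppf_survival(self, u, e, rr_t=1.0):
        """Residual event time after an exposure switch at ``e``.

        Inverts the conditional survival of a subject alive at ``e``
        whose hazard is ``rr_t * h(t)`` from ``e`` onward:

            T = (e**ups - ln(u) / (rr_t * lam)) ** (1/ups)  > e.

        The clock is not reset, so proportional hazards holds exactly.
        """
        u = np.asarray(u, dtype=float)
        e = np.asarray(e, dtype=float)
        if np.any((u <= 0.0) | (u >= 1.0)):
            raise ValueError("u must lie strictly in (0, 1)")
        if np.any(e < 0.0):
            raise ValueError("exposure-switch time e must be non-negative")
        if not (rr_t > 0.0):
            raise ValueError("rr_t must be positive")
        arg = _power(e, self.ups) - np.log(u) / (rr_t * self.lam)
        out = np.exp(np.log(arg) / self.ups)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ExposureEffect:
    """Constant multiplicative effect of exposure on the hazard.

    ``rr_t`` is the true hazard ratio; under a constant hazard it
    coincides with the rate ratio the Poisson model targets.
    ``rr_t == 1`` means exposure is null.
    """

    rr_t: float

    def __post_init__(self) -> None:
        if not (self.rr_t > 0.0):
            raise ValueError(f"rr_t must be positive, got {self.rr_t}")


# -- thin functional surface ------------------------------------------------


def hazard_at(h: WeibullHazard, t):
    return h.hazard(t)


def survival_at(h: WeibullHazard, t):
    return h.survival(t)


def sample_event_time(h: WeibullHazard, u):
    """Event time from a Uniform(0,1) draw by inverting the survival."""
    return h.ppf_survival(u)


def sample_conditional_event_time(h: WeibullHazard, eff: ExposureEffect, e, u):
    """Event time conditional on survival to ``e``, hazard scaled by rr_t after."""
    return h.conditional_ppf_survival(u, e, rr_t=eff.rr_t)
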