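"""Closed-form response equations of the operational model of agonism (OMA).

The OMA describes the functional response ``E`` of a receptor system to an
agonist at concentration ``[A]`` with three parameters: the system maximum
``E_MAX``, the agonist equilibrium dissociation constant ``K_A`` (molar) and
the operational efficacy ``tau`` (the transducer ratio ``R_T/K_E``).  Two
slope-factor extensions are provided: the Black & Leff form, in which both
``[A]`` and ``tau`` are exponentiated to a factor ``n``, and the Hill form,
in which a Hill coefficient ``n_H`` changes the steepness of the curve
without moving its midpoint or asymptote.  The two are *not* equivalent:
exponentiating ``tau`` couples the observed maximum and potency to the slope
factor, which is the central pitfall this package quantifies.

All functions are pure, accept scalars or numpy arrays for concentrations
and work on a normalized response scale (``e_max`` defaults to 1).
Concentrations are molar; negative-log quantities use the conventional
``pX = -log10(X)`` form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "OperationalParams",
    "DerivedQuantities",
    "oma_response",
    "blackleff_response",
    "hill_response",
    "hill_oma_response",
    "two_slope_response",
    "observed_emax",
    "ec50_closed_form",
    "apparent_tau",
    "invert_apparent_tau",
    "invert_hill_to_operational",
    "ec50_exceeds_ka_region",
]


@dataclass(frozen=True)
class OperationalParams:
    """System/ligand parameters of a closed-form operational model.

    Parameters
    ----------
    k_a:
        Agonist equilibrium dissociation constant (molar, > 0).
    tau:
        Operational efficacy (dimensionless, >= 0).  ``tau = 0`` is a valid
        neutral ligand producing no response.
    e_max:
        Maximal possible response of the system (normalized units, > 0).
    slope:
        Slope factor (> 0): ``n`` for the Black & Leff model, ``n_H`` for the
        Hill model.  Ignored by the plain hyperbolic model.
    slope_binding:
        Optional second slope factor ``m`` (> 0) linking agonist
        concentration to the slope of the binding curve (two-slope variant).
    """

    k_a: float
    tau: float
    e_max: float = 1.0
    slope: float = 1.0
    slope_binding: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.k_a > 0:
            raise ValueError(f"k_a must be > 0, got {self.k_a}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if not self.e_max > 0:
            raise ValueError(f"e_max must be > 0, got {self.e_max}")
        if not self.slope > 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")
        if self.slope_binding is not None and not self.slope_binding > 0:
            raise ValueError(f"slope_binding must be > 0, got {self.slope_binding}")

    @property
    def p_k_a(self) -> float:
        """Negative decadic logarithm of ``k_a``."""
        return -math.log10(self.k_a)


@dataclass(frozen=True)
class DerivedQuantities:
    """Observable descriptors of a concentration-response curve.

    ``e_max_observed`` is the horizontal asymptote E'MAX (same units as the
    system maximum), ``ec50`` the half-effective agonist concentration
    (molar) and ``tau_apparent`` the apparent operational efficacy inferred
    from the observed maximum.  NaN marks quantities that cannot be
    determined (e.g. ``tau_apparent`` when E'MAX reaches the system maximum).
    """

    e_max_observed: float
    ec50: float
    tau_apparent: float = math.nan

    @property
    def p_ec50(self) -> float:
        return -math.log10(self.ec50)


def _conc(a):
    """Validate and convert concentrations; negative values are a domain error."""
    arr = np.asarray(a, dtype=float)
    if np.any(arr < 0):
        raise ValueError("agonist concentration must be >= 0")
    return arr


def oma_response(a, p: OperationalParams):
    """Hyperbolic operational-model response.

    ``E = E_MAX * [A] * tau / ([A] * (tau + 1) + K_A)``.  Monotone
    non-decreasing in ``a`` with horizontal asymptote ``E_MAX*tau/(tau+1)``.
    The slope fields of ``p`` are ignored.
    """
    a = _conc(a)
    return p.e_max * a * p.tau / (a * (p.tau + 1.0) + p.k_a)


def blackleff_response(a, p: OperationalParams):
    """Black & Leff response with slope factor ``n = p.slope``.

    ``E = [A]^n tau^n E_MAX / ([A]^n tau^n + ([A] + K_A)^n)``.  Both the
    agonist concentration and the operational efficacy are exponentiated, so
    the observed maximum ``E_MAX*tau^n/(1+tau^n)`` depends on ``n``.
    Reduces to :func:`oma_response` at ``n = 1``.
    """
    a = _conc(a)
    n = p.slope
    num = np.power(a, n) * p.tau**n * p.e_max
    den = np.power(a, n) * p.tau**n + np.power(a + p.k_a, n)
    return num / den


def hill_response(a, e_max_observed: float, ec50: float, n_h: float):
    """Hill equation parameterized by its observables.

    ``E = [A]^n_H E'MAX / ([A]^n_H + EC50^n_H)``.  The Hill coefficient
    changes steepness only: the response at ``a = ec50`` is ``E'MAX/2`` for
    every ``n_h``.
    """
    a = _conc(a)
    if not ec50 > 0:
        raise ValueError(f"ec50 must be > 0, got {ec50}")
    if not n_h > 0:
        raise ValueError(f"n_h must be > 0, got {n_h}")
    an = np.power(a, n_h)
    return an * e_max_observed / (an + ec50**n_h)


def hill_oma_response(a, p: OperationalParams):
    """Hill-based operational model with ``n_H = p.slope``.

    The Hill equation with its asymptote and midpoint pinned to the
    operational values ``E'MAX = E_MAX*tau/(tau+1)`` and
    ``EC50 = K_A/(tau+1)``, so the slope factor leaves both untouched.
    """
    a = _conc(a)
    if p.tau == 0:
        return np.zeros_like(a) if a.ndim else np.float64(0.0)
    e_obs = p.e_max * p.tau / (p.tau + 1.0)
    ec50 = p.k_a / (p.tau + 1.0)
    return hill_response(a, e_obs, ec50, p.slope)


def two_slope_response(a, p: OperationalParams):
    """Two-slope operational model for allosteric systems.

    ``E = [A]^(n*m) tau^n E_MAX / ([A]^(n*m) tau^n + ([A]^m + K_A^m)^n)``
    with ``n = p.slope`` (functional-response slope) and
    ``m = p.slope_binding`` (binding-curve slope).  Reduces to
    :func:`blackleff_response` at ``m = 1``.
    """
    if p.slope_binding is None:
        raise ValueError("two_slope_response requires slope_binding (m)")
    a = _conc(a)
    n, m = p.slope, p.slope_binding
    num = np.power(a, n * m) * p.tau**n * p.e_max
    den = np.power(a, n * m) * p.tau**n + np.power(
        np.power(a, m) + p.k_a**m, n
    )
    return num / den


def observed_emax(
    model_id: str,
    tau: float,
    e_max: float = 1.0,
    n: float = 1.0,
    sigma: Optional[float] = None,
    delta: Optional[float] = None,
) -> float:
    """Closed-form observed maximal response E'MAX (horizontal asymptote).

    Supported models: ``"oma"`` (``E_MAX*tau/(tau+1)``), ``"blackleff"``
    (``E_MAX*tau^n/(1+tau^n)``), ``"autoinhibition"``
    (``E_MAX * tau/(1+tau) * sigma/(1+sigma)``) and ``"feedback"``
    (``E_MAX * (tau^2+tau)/(delta*tau+tau^2+tau+1)``).  Always <= ``e_max``.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if model_id == "oma":
        return e_max * tau / (tau + 1.0)
    if model_id == "blackleff":
        return e_max * tau**n / (1.0 + tau**n)
    if model_id == "autoinhibition":
        if sigma is None or sigma <= 0:
            raise ValueError("autoinhibition requires sigma > 0")
        return e_max * tau / (1.0 + tau) * sigma / (1.0 + sigma)
    if model_id == "feedback":
        if delta is None or delta <= 0:
            raise ValueError("feedback requires delta > 0")
        return e_max * (tau**2 + tau) / (delta * tau + tau**2 + tau + 1.0)
    raise ValueError(f"unknown model_id {model_id!r}")


def ec50_closed_form(
    model_id: str,
    k_a: float,
    tau: float,
    n: float = 1.0,
    m: float = 1.0,
    sigma: Optional[float] = None,
) -> float:
    """Closed-form half-effective concentration EC50 (molar).

    * ``"oma"``: ``K_A/(tau+1)`` — always below ``K_A`` for ``tau > 0``.
    * ``"blackleff"``: ``K_A / ((2+tau^n)^(1/n) - 1)``.
    * ``"two_slope"``: ``K_A * (1/((2+tau^n)^(1/n) - 1))^(1/m)``.
    * ``"autoinhibition"``:
      ``K_A * (sqrt(sigma^2+6*sigma*tau+8*sigma+tau^2+8*tau+8)+sigma+tau+2)
      / (2*(1+sigma)*(1+tau))``.

    The feedback model has no practical closed form here; use
    :func:`omafit.fitting.numeric_ec50` on the simulated curve instead.
    """
    if not k_a > 0:
        raise ValueError("k_a must be > 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if model_id == "oma":
        return k_a / (tau + 1.0)
    if model_id == "blackleff":
        if not n > 0:
            raise ValueError("n must be > 0")
        return k_a / ((2.0 + tau**n) ** (1.0 / n) - 1.0)
    if model_id == "two_slope":
        if not (n > 0 and m > 0):
            raise ValueError("n and m must be > 0")
        return k_a * (1.0 / ((2.0 + tau**n) ** (1.0 / n) - 1.0)) ** (1.0 / m)
    if model_id == "autoinhibition":
        if sigma is None or sigma <= 0:
            raise ValueError("autoinhibition requires sigma > 0")
        s, t = sigma, tau
        root = math.sqrt(s**2 + 6 * s * t + 8 * s + t**2 + 8 * t + 8)
        return k_a * (root + s + t + 2.0) / (2.0 * (1.0 + s) * (1.0 + t))
    raise ValueError(f"unknown model_id {model_id!r}")


def apparent_tau(
    model_id: str,
    tau: float,
    sigma: Optional[float] = None,
    delta: Optional[float] = None,
) -> float:
    """Apparent operational efficacy tau' of a mechanistic model.

    For non-competitive auto-inhibition ``tau' = sigma*tau/(sigma+tau+1)``
    (symmetric in tau and sigma); for signalling feedback
    ``tau' = (tau^2+tau)/(delta*tau+1)`` (equal to tau at ``delta = 1``).
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if model_id == "autoinhibition":
        if sigma is None or sigma <= 0:
            raise ValueError("autoinhibition requires sigma > 0")
        return sigma * tau / (sigma + tau + 1.0)
    if model_id == "feedback":
        if delta is None or delta <= 0:
            raise ValueError("feedback requires delta > 0")
        return (tau**2 + tau) / (delta * tau + 1.0)
    raise ValueError(f"unknown model_id {model_id!r}")


def invert_apparent_tau(
    model_id: str,
    tau_apparent: float,
    sigma: Optional[float] = None,
    delta: Optional[float] = None,
) -> float:
    """Recover the modelled efficacy tau from an apparent tau'.

    Inverts the auto-inhibition relation (requires ``tau' < sigma``; above
    that bound no finite tau exists and NaN is returned) or the feedback
    relation (positive root of ``tau^2 + (1-tau'*delta)*tau - tau' = 0``).
    """
    tp = tau_apparent
    if tp < 0 or math.isnan(tp):
        return math.nan
    if model_id == "autoinhibition":
        if sigma is None or sigma <= 0:
            raise ValueError("autoinhibition requires sigma > 0")
        if tp >= sigma:
            return math.nan
        return tp * (sigma + 1.0) / (sigma - tp)
    if model_id == "feedback":
        if delta is None or delta <= 0:
            raise ValueError("feedback requires delta > 0")
        b = 1.0 - tp * delta
        return (-b + math.sqrt(b * b + 4.0 * tp)) / 2.0
    raise ValueError(f"unknown model_id {model_id!r}")


def invert_hill_to_operational(
    e_max_observed: float, ec50: float, e_max_system: float = 1.0
) -> tuple[float, float]:
    """Back-calculate ``(tau, K_A)`` from Hill-fit observables.

    ``tau = E'MAX/(E_MAX - E'MAX)`` and ``K_A = EC50*(tau+1)``.  When the
    observed maximum reaches (or exceeds) the system maximum, tau is
    unbounded and cannot be determined: ``(nan, nan)`` is returned as an
    explicit marker.
    """
    if not ec50 > 0:
        raise ValueError("ec50 must be > 0")
    if e_max_observed < 0:
        raise ValueError("e_max_observed must be >= 0")
    if e_max_observed >= e_max_system:
        return math.nan, math.nan
    tau = e_max_observed / (e_max_system - e_max_observed)
    return tau, ec50 * (tau + 1.0)


def ec50_exceeds_ka_region(n: float) -> Optional[float]:
    """Efficacy boundary below which the Black & Leff EC50 exceeds K_A.

    For slope factor ``n > 1`` returns ``tau* = (2^n - 2)^(1/n)``: curves
    with ``tau < tau*`` have EC50 > K_A, a biochemically counterintuitive
    regime (half-effect above half-occupancy).  The boundary crosses
    ``tau = 1`` at ``n = log2(3)`` and tends to 2 as ``n -> inf``.  For
    ``n <= 1`` the region is empty and ``None`` is returned.
    """
    if not n > 0:
        raise ValueError("n must be > 0")
    if n <= 1.0:
        return None
    return (2.0**n - 2.0) ** (1.0 / n)
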