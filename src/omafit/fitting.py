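"""Constrained nonlinear least-squares fitting of concentration-response curves.

Fits the Hill equation, the Black & Leff equation and the explicit
mechanistic models (auto-inhibition, feedback) to response curves.  The
conventions follow standard functional-assay practice: responses are
normalized so the system maximum is 1; the Hill fit constrains the observed
maximum E'MAX to at most the system maximum; the Black & Leff fit fixes the
system E_MAX.  Optimization runs in a positivity-preserving
parameterization (log10 tau, pK_A / pEC50, slope on the linear scale) with
deterministic multi-start, and non-convergence is flagged rather than
raised so panel pipelines keep running.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq, least_squares

from .models import (
    DerivedQuantities,
    OperationalParams,
    blackleff_response,
    ec50_closed_form,
    hill_response,
    invert_hill_to_operational,
    observed_emax,
)
from .simulate import MechanismParams, ResponseCurve, autoinhibition_response, feedback_response

__all__ = [
    "FitResult",
    "normalize_responses",
    "fit_hill",
    "fit_blackleff",
    "fit_mechanism",
    "numeric_ec50",
    "backcalc_ka",
    "SLOPE_BOUNDS",
    "LOG_TAU_BOUNDS",
    "PKA_BOUNDS",
]

# Bounds chosen to bracket, with margin, every efficacy/affinity/slope
# encountered in the mechanistic recovery scenarios and the synthetic panel.
SLOPE_BOUNDS = (0.2, 5.0)
LOG_TAU_BOUNDS = (-4.0, 7.0)
PKA_BOUNDS = (2.0, 12.0)

_EMAX_BOUND_TOL = 1e-6  # E'MAX this close to its cap => tau not determinable
_SPREAD_UNRELIABLE = 0.1


@dataclass
class FitResult:
    """Outcome of one least-squares fit.

    ``estimates`` are on the reporting scale (tau and sigma/delta linear,
    affinities as pK_A/pEC50); ``standard_errors`` are matched, obtained
    from the local curvature of the objective by the delta method.
    ``tau_exponentiated`` carries tau^n for Black & Leff fits (the quantity
    that tracks the apparent efficacy tau' on mechanistic data).
    ``multistart_spread`` is the relative dispersion of estimates across
    restarts; ``symmetry_flag`` marks a parameter-swap-equivalent optimum
    (auto-inhibition tau/sigma).  ``flags`` collects soft diagnostics such
    as ``"tau_not_determinable"`` or ``"se_unreliable"``.
    """

    model_id: str
    estimates: dict
    standard_errors: dict
    rss: float
    converged: bool
    n_points: int
    tau_exponentiated: Optional[float] = None
    derived: Optional[DerivedQuantities] = None
    multistart_spread: float = 0.0
    symmetry_flag: bool = False
    flags: tuple = ()

    def to_dict(self) -> dict:
        d = {
            "model_id": self.model_id,
            "rss": self.rss,
            "converged": self.converged,
            "n_points": self.n_points,
            "tau_exponentiated": self.tau_exponentiated,
            "multistart_spread": self.multistart_spread,
            "symmetry_flag": self.symmetry_flag,
            "flags": list(self.flags),
        }
        for k, v in self.estimates.items():
            d[k] = v
        for k, v in self.standard_errors.items():
            d[f"se_{k}"] = v
        if self.derived is not None:
            d["e_max_observed"] = self.derived.e_max_observed
            d["ec50"] = self.derived.ec50
            d["tau_apparent"] = self.derived.tau_apparent
        return d


CurveLike = Union[ResponseCurve, Sequence[ResponseCurve]]


def _pool(curve: CurveLike) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate one curve or a replicate set into (x, y) arrays."""
    if isinstance(curve, ResponseCurve):
        curves = [curve]
    else:
        curves = list(curve)
        if not curves:
            raise ValueError("no curves to fit")
    x = np.concatenate([c.concentrations for c in curves])
    y = np.concatenate([c.responses for c in curves])
    return x, y


def normalize_responses(
    curves: Iterable[ResponseCurve], basal: float, e_max_system: float
) -> list[ResponseCurve]:
    """Two-step normalization: subtract basal, express as fraction of E_MAX.

    ``response' = (response - basal)/(e_max_system - basal)``; afterwards
    the system maximum is 1.
    """
    if not e_max_system > basal:
        raise ValueError("e_max_system must exceed basal")
    span = e_max_system - basal
    out = []
    for c in curves:
        out.append(
            ResponseCurve(
                c.concentrations.copy(),
                (c.responses - basal) / span,
                replicate_id=c.replicate_id,
                meta=dict(c.meta, normalized=True, basal=basal, e_max_system=e_max_system),
            )
        )
    return out


def _run_multistart(residual: Callable, starts, lower, upper):
    """Run bounded least squares from each start; return best + all solutions."""
    solutions = []
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lower, upper)
        try:
            res = least_squares(residual, x0, bounds=(lower, upper), method="trf")
        except Exception:
            continue
        solutions.append(res)
    if not solutions:
        raise RuntimeError("all optimizer starts failed")
    best = min(solutions, key=lambda r: (r.cost, r.x[-1]))
    return best, solutions


def _spread(solutions, best, canonicalize=None) -> float:
    """Relative dispersion of near-optimal estimates across restarts."""
    xs = []
    cutoff = 2.0 * best.cost + 1e-12
    for r in solutions:
        if r.cost <= cutoff:
            x = np.array(r.x, dtype=float)
            if canonicalize is not None:
                x = canonicalize(x)
            xs.append(x)
    xs = np.array(xs)
    if len(xs) < 2:
        return 0.0
    ref = np.maximum(np.abs(xs.mean(axis=0)), 1e-12)
    return float(np.max((xs.max(axis=0) - xs.min(axis=0)) / ref))


def _standard_errors(res, n_points: int) -> np.ndarray:
    """Asymptotic SEs from the Jacobian at the optimum (pseudo-inverse)."""
    rss = 2.0 * res.cost
    dof = max(n_points - res.x.size, 1)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.pinv(jtj) * (rss / dof)
    except np.linalg.LinAlgError:
        return np.full(res.x.size, np.nan)
    return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))


def fit_hill(
    curve: CurveLike,
    e_max_cap: float = 1.0,
    e_max_system: Optional[float] = None,
    n_starts_slopes: Sequence[float] = (0.7, 1.0, 1.5),
) -> FitResult:
    """Fit the Hill equation with the observed maximum confined to a cap.

    Estimates ``(e_max_observed, p_ec50, n_h)``.  When ``e_max_system`` is
    given, the operational pair ``(tau, p_k_a)`` is derived by inverting the
    hyperbolic relations E'MAX = E_MAX*tau/(tau+1) and EC50 = K_A/(tau+1);
    if the fitted E'MAX sits at the cap, tau is unbounded and flagged
    ``"tau_not_determinable"``.
    """
    x, y = _pool(curve)
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 distinct concentrations")

    def residual(theta):
        e, pec50, n_h = theta
        return hill_response(x, e, 10.0**-pec50, n_h) - y

    ymax = float(np.max(y))
    e0 = min(max(ymax, 0.05), e_max_cap * 0.999)
    half_idx = int(np.argmin(np.abs(y - e0 / 2.0)))
    pec0 = -math.log10(x[half_idx])
    starts = [(e0, pec0, n) for n in n_starts_slopes]
    lower = np.array([0.0, PKA_BOUNDS[0], SLOPE_BOUNDS[0]])
    upper = np.array([e_max_cap, PKA_BOUNDS[1], SLOPE_BOUNDS[1]])
    best, sols = _run_multistart(residual, starts, lower, upper)

    e, pec50, n_h = best.x
    se = _standard_errors(best, x.size)
    spread = _spread(sols, best)
    flags = []
    if spread > _SPREAD_UNRELIABLE:
        flags.append("se_unreliable")
    estimates = {"e_max_observed": float(e), "p_ec50": float(pec50), "n_h": float(n_h)}
    errors = {"e_max_observed": float(se[0]), "p_ec50": float(se[1]), "n_h": float(se[2])}
    derived = None
    if e_max_system is not None:
        at_bound = e >= e_max_cap - _EMAX_BOUND_TOL * max(e_max_cap, 1.0)
        if at_bound:
            flags.append("tau_not_determinable")
            tau, k_a = math.nan, math.nan
        else:
            tau, k_a = invert_hill_to_operational(float(e), 10.0**-pec50, e_max_system)
        estimates["tau"] = tau
        estimates["p_k_a"] = -math.log10(k_a) if k_a == k_a else math.nan
        derived = DerivedQuantities(float(e), 10.0**-pec50, tau_apparent=tau)
    else:
        derived = DerivedQuantities(float(e), 10.0**-pec50)
    return FitResult(
        model_id="hill",
        estimates=estimates,
        standard_errors=errors,
        rss=float(2.0 * best.cost),
        converged=bool(best.status > 0),
        n_points=int(x.size),
        derived=derived,
        multistart_spread=spread,
        flags=tuple(flags),
    )


def fit_blackleff(curve: CurveLike, e_max: float = 1.0) -> FitResult:
    """Fit the Black & Leff equation with the system maximum fixed.

    Estimates ``(tau, p_k_a, n)`` plus the exponentiated efficacy
    ``tau^n``.  Multi-start: a deterministic grid over log10(tau) in
    {-1, 0, 1} x n in {0.7, 1, 1.5} plus a heuristic start from a Hill
    prefit; lowest residual sum of squares wins, ties broken by smaller
    slope.
    """
    x, y = _pool(curve)
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 distinct concentrations")

    def residual(theta):
        lt, pka, n = theta
        p = OperationalParams(k_a=10.0**-pka, tau=10.0**lt, e_max=e_max, slope=n)
        return blackleff_response(x, p) - y

    starts = []
    try:
        pre = fit_hill(curve, e_max_cap=e_max, e_max_system=e_max)
        tau0 = pre.estimates.get("tau", math.nan)
        if tau0 == tau0 and tau0 > 0:
            starts.append(
                (math.log10(tau0), pre.estimates["p_k_a"], pre.estimates["n_h"])
            )
    except Exception:
        pass
    half_idx = int(np.argmin(np.abs(y - np.max(y) / 2.0)))
    pec0 = -math.log10(x[half_idx])
    for lt in (-1.0, 0.0, 1.0):
        for n in (0.7, 1.0, 1.5):
            starts.append((lt, pec0, n))
    lower = np.array([LOG_TAU_BOUNDS[0], PKA_BOUNDS[0], SLOPE_BOUNDS[0]])
    upper = np.array([LOG_TAU_BOUNDS[1], PKA_BOUNDS[1], SLOPE_BOUNDS[1]])
    best, sols = _run_multistart(residual, starts, lower, upper)

    lt, pka, n = best.x
    tau = 10.0**lt
    se = _standard_errors(best, x.size)
    spread = _spread(sols, best)
    flags = []
    if spread > _SPREAD_UNRELIABLE:
        flags.append("se_unreliable")
    e_obs = observed_emax("blackleff", tau, e_max=e_max, n=n)
    ec50 = ec50_closed_form("blackleff", 10.0**-pka, tau, n=n)
    return FitResult(
        model_id="blackleff",
        estimates={"tau": float(tau), "p_k_a": float(pka), "n": float(n)},
        standard_errors={
            "tau": float(math.log(10.0) * tau * se[0]),
            "p_k_a": float(se[1]),
            "n": float(se[2]),
        },
        rss=float(2.0 * best.cost),
        converged=bool(best.status > 0),
        n_points=int(x.size),
        tau_exponentiated=float(tau**n),
        derived=DerivedQuantities(float(e_obs), float(ec50)),
        multistart_spread=spread,
        flags=tuple(flags),
    )


def fit_mechanism(
    curve: CurveLike,
    model_id: str,
    init: Optional[dict] = None,
    e_max: float = 1.0,
) -> FitResult:
    """Fit an explicit mechanistic model with the system maximum fixed.

    ``model_id`` is ``"autoinhibition"`` (parameters tau, sigma, pK_A) or
    ``"feedback"`` (tau, delta, pK_A).  The auto-inhibition response is
    exactly symmetric under exchange of tau and sigma; the fit detects this
    ridge, reports the canonical ordering ``tau <= sigma`` and sets
    ``symmetry_flag``.  ``init`` (dict with ``tau``, ``sigma``/``delta``,
    ``p_k_a``) replaces the default multi-start with a single start.
    """
    if model_id not in ("autoinhibition", "feedback"):
        raise ValueError(f"unknown mechanism {model_id!r}")
    x, y = _pool(curve)
    other = "sigma" if model_id == "autoinhibition" else "delta"

    if model_id == "autoinhibition":
        def predict(lt, lo, pka):
            return autoinhibition_response(x, 10.0**-pka, 10.0**lt, 10.0**lo, e_max)
    else:
        def predict(lt, lo, pka):
            return feedback_response(x, 10.0**-pka, 10.0**lt, 10.0**lo, e_max)

    def residual(theta):
        return predict(*theta) - y

    if init is not None:
        starts = [
            (math.log10(init["tau"]), math.log10(init[other]), init["p_k_a"])
        ]
    else:
        half_idx = int(np.argmin(np.abs(y - np.max(y) / 2.0)))
        pec0 = -math.log10(x[half_idx])
        starts = [
            (lt, lo, pec0)
            for lt in (-1.0, 0.0, 1.0)
            for lo in (-1.0, 0.0, 1.0)
        ]
    other_bounds = (-4.0, 7.0) if model_id == "autoinhibition" else (-2.0, 2.0)
    lower = np.array([LOG_TAU_BOUNDS[0], other_bounds[0], PKA_BOUNDS[0]])
    upper = np.array([LOG_TAU_BOUNDS[1], other_bounds[1], PKA_BOUNDS[1]])

    canonicalize = None
    if model_id == "autoinhibition":
        def canonicalize(xv):
            out = np.array(xv, dtype=float)
            if out[0] > out[1]:
                out[[0, 1]] = out[[1, 0]]
            return out

    best, sols = _run_multistart(residual, starts, lower, upper)
    theta = np.array(best.x, dtype=float)
    symmetry = False
    if model_id == "autoinhibition":
        swapped = theta[[1, 0, 2]]
        rss_swap = float(np.sum(residual(swapped) ** 2))
        rss_best = float(2.0 * best.cost)
        symmetry = abs(rss_swap - rss_best) <= 1e-9 * (1.0 + rss_best)
        theta = canonicalize(theta)
    se = _standard_errors(best, x.size)
    spread = _spread(sols, best, canonicalize=canonicalize)
    flags = []
    if spread > _SPREAD_UNRELIABLE:
        flags.append("se_unreliable")
    if symmetry:
        flags.append("tau_sigma_symmetric")
    lt, lo, pka = theta
    tau, oth = 10.0**lt, 10.0**lo
    kwargs = {other: oth}
    e_obs = observed_emax(model_id, tau, e_max=e_max, **kwargs)
    if model_id == "autoinhibition":
        ec50 = ec50_closed_form("autoinhibition", 10.0**-pka, tau, sigma=oth)
    else:
        ec50 = numeric_ec50(
            lambda a: feedback_response(a, 10.0**-pka, tau, oth, e_max), e_obs
        )
    return FitResult(
        model_id=model_id,
        estimates={"tau": float(tau), other: float(oth), "p_k_a": float(pka)},
        standard_errors={
            "tau": float(math.log(10.0) * tau * se[0]),
            other: float(math.log(10.0) * oth * se[1]),
            "p_k_a": float(se[2]),
        },
        rss=float(2.0 * best.cost),
        converged=bool(best.status > 0),
        n_points=int(x.size),
        derived=DerivedQuantities(float(e_obs), float(ec50)),
        multistart_spread=spread,
        symmetry_flag=symmetry,
        flags=tuple(flags),
    )


def numeric_ec50(
    response_callable: Callable,
    e_max_observed: float,
    bracket: tuple[float, float] = (1e-14, 1e-1),
) -> float:
    """Half-maximum concentration by root bracketing on the log10 axis.

    Solves ``E(a) = E'MAX/2`` for a monotone response callable; serves as
    the independent oracle for every closed-form EC50 and for the feedback
    model, whose EC50 has no convenient closed form.
    """
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ValueError("bracket must satisfy 0 < lo < hi")
    target = e_max_observed / 2.0

    def f(u):
        return float(response_callable(10.0**u)) - target

    flo, fhi = f(math.log10(lo)), f(math.log10(hi))
    if flo * fhi > 0:
        raise ValueError("bracket does not straddle the half-maximum")
    u = brentq(f, math.log10(lo), math.log10(hi), xtol=1e-10, rtol=8.9e-16)
    return 10.0**u


def backcalc_ka(
    model_id: str,
    ec50: float,
    tau: float,
    sigma_or_delta: Optional[float] = None,
) -> float:
    """Recover K_A from an observed EC50 under a known mechanism.

    Every supported mechanism has EC50 proportional to K_A at fixed shape
    parameters, so the inversion is a division by the EC50/K_A ratio:
    closed form for the plain operational model and auto-inhibition,
    numeric (unit-K_A root finding) for feedback.
    """
    if not ec50 > 0:
        raise ValueError("ec50 must be > 0")
    if model_id == "oma":
        return ec50 * (tau + 1.0)
    if model_id == "autoinhibition":
        ratio = ec50_closed_form("autoinhibition", 1.0, tau, sigma=sigma_or_delta)
        return ec50 / ratio
    if model_id == "feedback":
        if sigma_or_delta is None or sigma_or_delta <= 0:
            raise ValueError("feedback requires delta > 0")
        e_obs = observed_emax("feedback", tau, delta=sigma_or_delta)
        ratio = numeric_ec50(
            lambda a: feedback_response(a, 1.0, tau, sigma_or_delta), e_obs,
            bracket=(1e-8, 1e8),
        )
        return ec50 / ratio
    raise ValueError(f"unknown model_id {model_id!r}")
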