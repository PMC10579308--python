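"""Comparative experiments: slope-sensitivity surfaces, recovery tables, bias.

These routines orchestrate the package's diagnostic studies: how the
Black & Leff slope factor distorts the efficacy-maximum and potency-affinity
relations, how well each fitting equation recovers the parameters of known
mechanistic generators, and how agonist ranking and signalling-bias metrics
behave when curve slopes are heterogeneous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import fitting
from .models import (
    apparent_tau,
    ec50_exceeds_ka_region,
    invert_apparent_tau,
    observed_emax,
    ec50_closed_form,
)
from .simulate import (
    DEFAULT_RECOVERY_GRID,
    MechanismParams,
    ResponseCurve,
    make_log_grid,
    simulate_autoinhibition,
    simulate_depletion,
    simulate_feedback,
)

__all__ = [
    "RecoveryTable",
    "BiasReport",
    "slope_sensitivity",
    "boundary_table",
    "recovery_experiment",
    "rank_and_bias",
]

#: Sign convention for the between-pathway bias difference: for each metric,
#: ``delta = tested - reference`` within a pathway, and
#: ``delta_delta = delta(pathway_1) - delta(pathway_2)``.
DELTA_DELTA_CONVENTION = "delta(tested-reference, pathway_1) - delta(tested-reference, pathway_2)"


@dataclass
class RecoveryTable:
    """Machine-readable twin of a parameter-recovery experiment.

    One row per true-efficacy value: mechanism truth, the closed-form
    apparent efficacy tau', the Black & Leff fit (n, tau, tau^n, pK_A,
    E'MAX), the Hill fit (n_H, pEC50, E'MAX, derived tau and pK_A) and the
    mechanism-aware back-calculated pK_A.  NaN cells mark quantities that
    cannot be determined.
    """

    mechanism: str
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def round_sig(self, digits: int = 3) -> pd.DataFrame:
        """Table rounded to ``digits`` significant figures for export."""
        def r(v):
            if isinstance(v, float):
                if v == 0 or not math.isfinite(v):
                    return v
                return round(v, digits - 1 - int(math.floor(math.log10(abs(v)))))
            return v
        return self.table.map(r)


@dataclass
class BiasReport:
    """Signalling-bias metrics for an agonist panel.

    ``per_curve`` holds log10(tau/K_A) and log10(E'MAX/EC50) per
    (agonist, pathway, model); ``delta`` the within-pathway differences
    versus the reference agonist; ``delta_delta`` the between-pathway
    differences of those (antisymmetric under agonist swap).  Rows carry a
    ``slope_warning`` when Black & Leff slope factors differ between the
    compared curves, the condition under which the exponentiated-efficacy
    comparison is invalid.
    """

    reference_agonist: str
    per_curve: pd.DataFrame
    delta: pd.DataFrame
    delta_delta: pd.DataFrame
    convention: str = DELTA_DELTA_CONVENTION


def slope_sensitivity(
    tau_values: Sequence[float], n_values: Sequence[float]
) -> pd.DataFrame:
    """Tabulate E'MAX/E_MAX and EC50/K_A of the Black & Leff model.

    Over the grid of operational efficacies and slope factors, records the
    bidirectional effect of the slope factor on the observed maximum
    (increasing in n for tau > 1, decreasing for tau < 1) and the monotone
    increase of EC50 with n.
    """
    rows = []
    for tau in tau_values:
        for n in n_values:
            if not n > 0:
                raise ValueError("slope factors must be > 0")
            rows.append(
                {
                    "tau": tau,
                    "n": n,
                    "emax_ratio": observed_emax("blackleff", tau, n=n),
                    "ec50_ka_ratio": ec50_closed_form("blackleff", 1.0, tau, n=n),
                }
            )
    return pd.DataFrame(rows)


def boundary_table(n_values: Sequence[float]) -> pd.DataFrame:
    """EC50 > K_A boundary tau*(n); NaN where the region is empty (n <= 1)."""
    rows = []
    for n in n_values:
        b = ec50_exceeds_ka_region(n)
        rows.append({"n": n, "tau_boundary": math.nan if b is None else b})
    return pd.DataFrame(rows)


def _simulate_row(mechanism: str, row: dict, grid: np.ndarray) -> ResponseCurve:
    if mechanism == "autoinhibition":
        p = MechanismParams(
            "autoinhibition", k_a=10.0 ** -row["p_k_a"], tau=row["tau"], sigma=row["sigma"]
        )
        return simulate_autoinhibition(grid, p)
    if mechanism == "feedback":
        p = MechanismParams(
            "feedback", k_a=10.0 ** -row["p_k_a"], tau=row["tau"], delta=row["delta"]
        )
        return simulate_feedback(grid, p)
    if mechanism == "depletion":
        p = MechanismParams(
            "depletion",
            k_a=10.0 ** -row["p_k_a"],
            r_t=row["r_t"],
            g_t=row["g_t"],
            k_e=row["k_e"],
        )
        return simulate_depletion(grid, p)
    raise ValueError(f"unknown mechanism {mechanism!r}")


def recovery_experiment(
    mechanism: str,
    truth_rows: Iterable[dict],
    grid: Optional[np.ndarray] = None,
    e_max_system: float = 1.0,
) -> RecoveryTable:
    """Fit Black & Leff and Hill equations to noiseless mechanistic curves.

    Each truth row supplies ``tau`` (for depletion via ``r_t``/``k_e``),
    ``p_k_a`` and the mechanism constant (``sigma``, ``delta`` or the
    ``r_t``/``g_t``/``k_e`` triple).  Curves are generated noiselessly on
    ``grid`` (default: 61 log-spaced points over 1e-10 to 1e-2 M), the
    Black & Leff equation is fitted with the system maximum fixed and the
    Hill equation with the observed maximum capped, and the apparent
    efficacy and mechanism-aware back-calculated pK_A are appended.
    Deterministic for a fixed grid.
    """
    if grid is None:
        grid = make_log_grid(*DEFAULT_RECOVERY_GRID)
    rows = []
    for row in truth_rows:
        curve = _simulate_row(mechanism, row, grid)
        if mechanism == "depletion":
            tau_true = row["r_t"] / row["k_e"]
            tau_app = tau_true  # depletion leaves the apparent efficacy untouched
            constant = row["g_t"] / row["r_t"]
        elif mechanism == "autoinhibition":
            tau_true = row["tau"]
            constant = row["sigma"]
            tau_app = apparent_tau("autoinhibition", tau_true, sigma=constant)
        else:
            tau_true = row["tau"]
            constant = row["delta"]
            tau_app = apparent_tau("feedback", tau_true, delta=constant)

        bl = fitting.fit_blackleff(curve, e_max=e_max_system)
        hill = fitting.fit_hill(curve, e_max_cap=e_max_system, e_max_system=e_max_system)

        out = {
            "mechanism": mechanism,
            "tau_true": tau_true,
            "p_k_a_true": row["p_k_a"],
            "constant": constant,
            "tau_apparent_true": tau_app,
            "bl_n": bl.estimates["n"],
            "bl_tau": bl.estimates["tau"],
            "bl_tau_exp": bl.tau_exponentiated,
            "bl_p_k_a": bl.estimates["p_k_a"],
            "bl_e_max_obs": bl.derived.e_max_observed,
            "hill_n_h": hill.estimates["n_h"],
            "hill_p_ec50": hill.estimates["p_ec50"],
            "hill_e_max_obs": hill.estimates["e_max_observed"],
            "hill_tau": hill.estimates["tau"],
            "hill_p_k_a": hill.estimates["p_k_a"],
            "flags": ";".join(sorted(set(bl.flags) | set(hill.flags))),
        }
        # Mechanism-aware back-calculation: apparent tau from the Hill
        # maximum -> modelled tau via the mechanism relation -> K_A from
        # the fitted EC50.
        if mechanism in ("autoinhibition", "feedback"):
            tau_hat = hill.estimates["tau"]
            kw = {"sigma" if mechanism == "autoinhibition" else "delta": constant}
            tau_model = invert_apparent_tau(mechanism, tau_hat, **kw)
            if tau_model == tau_model:
                k_a = fitting.backcalc_ka(
                    mechanism, 10.0 ** -hill.estimates["p_ec50"], tau_model, constant
                )
                out["backcalc_p_k_a"] = -math.log10(k_a)
            else:
                out["backcalc_p_k_a"] = math.nan
        else:
            out["backcalc_p_k_a"] = math.nan
        rows.append(out)
    return RecoveryTable(mechanism=mechanism, table=pd.DataFrame(rows))


def rank_and_bias(
    fit_results: Iterable[tuple[str, str, "fitting.FitResult"]],
    reference_agonist: str,
    slope_tol: float = 0.1,
) -> BiasReport:
    """Signalling-bias metrics from fitted curves.

    ``fit_results`` yields ``(agonist, pathway, FitResult)`` triples from
    Hill and/or Black & Leff fits.  Per curve the report carries
    ``log10(tau/K_A)`` and ``log10(E'MAX/EC50)``; per pathway the
    difference of each metric versus the reference agonist; and between
    each ordered pathway pair the difference of differences.  Comparisons
    between Black & Leff fits whose slope factors differ by more than
    ``slope_tol`` are flagged: with unequal exponents the tau/K_A
    comparison is not valid.
    """
    records = []
    for agonist, pathway, fr in fit_results:
        tau = fr.estimates.get("tau", math.nan)
        p_k_a = fr.estimates.get("p_k_a", math.nan)
        log_tau_ka = (
            math.log10(tau) + p_k_a if tau == tau and tau > 0 and p_k_a == p_k_a else math.nan
        )
        if fr.derived is not None and fr.derived.e_max_observed > 0:
            log_ia = math.log10(fr.derived.e_max_observed) + fr.derived.p_ec50
        else:
            log_ia = math.nan
        records.append(
            {
                "agonist": agonist,
                "pathway": pathway,
                "model_id": fr.model_id,
                "slope": fr.estimates.get("n", fr.estimates.get("n_h", math.nan)),
                "log_tau_ka": log_tau_ka,
                "log_intrinsic_activity": log_ia,
            }
        )
    per_curve = pd.DataFrame(records)
    if reference_agonist not in set(per_curve["agonist"]):
        raise ValueError(f"reference agonist {reference_agonist!r} not in results")

    deltas = []
    for (pathway, model), grp in per_curve.groupby(["pathway", "model_id"]):
        ref = grp[grp["agonist"] == reference_agonist]
        if ref.empty:
            continue
        ref = ref.iloc[0]
        for _, r in grp.iterrows():
            slope_warning = bool(
                model == "blackleff"
                and abs(r["slope"] - ref["slope"]) > slope_tol
            )
            deltas.append(
                {
                    "agonist": r["agonist"],
                    "pathway": pathway,
                    "model_id": model,
                    "d_log_tau_ka": r["log_tau_ka"] - ref["log_tau_ka"],
                    "d_log_intrinsic_activity": r["log_intrinsic_activity"]
                    - ref["log_intrinsic_activity"],
                    "slope_warning": slope_warning,
                }
            )
    delta = pd.DataFrame(deltas)

    dd_rows = []
    if not delta.empty:
        for (agonist, model), grp in delta.groupby(["agonist", "model_id"]):
            paths = sorted(grp["pathway"].unique())
            for i, p1 in enumerate(paths):
                for p2 in paths[i + 1:]:
                    r1 = grp[grp["pathway"] == p1].iloc[0]
                    r2 = grp[grp["pathway"] == p2].iloc[0]
                    dd_rows.append(
                        {
                            "agonist": agonist,
                            "model_id": model,
                            "pathway_1": p1,
                            "pathway_2": p2,
                            "dd_log_tau_ka": r1["d_log_tau_ka"] - r2["d_log_tau_ka"],
                            "dd_log_intrinsic_activity": r1["d_log_intrinsic_activity"]
                            - r2["d_log_intrinsic_activity"],
                            "slope_warning": bool(
                                r1["slope_warning"] or r2["slope_warning"]
                            ),
                        }
                    )
    delta_delta = pd.DataFrame(dd_rows)
    return BiasReport(
        reference_agonist=reference_agonist,
        per_curve=per_curve,
        delta=delta,
        delta_delta=delta_delta,
    )
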