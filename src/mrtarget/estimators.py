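"""Causal-effect estimators and sensitivity diagnostics for cis-MR.

The workhorse is the fixed-effect inverse-variance-weighted (IVW)
estimator for *correlated* instruments: a generalized least squares fit
of the outcome associations on the exposure associations,

    theta_hat = (g' W g)^-1 g' W G,      W = Omega^-1,
    Omega_ij  = sigma_y_i * sigma_y_j * rho_ij,

where g (Gamma) are the per-variant exposure (outcome) betas, sigma_y the
outcome SEs and rho the signed LD correlation between the instruments.
With identity rho this reduces to the classical fixed-effect
meta-analysis of per-variant Wald ratios weighted by 1/SE^2, and with a
single variant to the Wald ratio itself. Cochran's Q, MR-Egger and
leave-one-out use the same Omega weighting so the diagnostics are
consistent with the estimator.

Inference uses the standard normal throughout (fixed-effect GLS
convention with Omega treated as known); p-values are two-sided and CIs
95% by default. For binary outcomes estimates live on the log-odds scale
and are also reported as odds ratios, conventionally per 1-unit
*decrease* of the exposure (e.g. 1 mmHg of blood pressure), which simply
negates the log-odds effect before exponentiating.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, stats

from .harmonization import InstrumentSet, orient_positive

logger = logging.getLogger(__name__)

EIGENVALUE_FLOOR = 1e-8

PER_UNIT_INCREASE = "per_unit_increase"
PER_UNIT_DECREASE = "per_unit_decrease"


@dataclass
class MREstimate:
    """A causal-effect estimate on the analysis scale.

    ``theta`` is in outcome units per 1-unit exposure change in the
    direction given by ``direction``; ``or_scale`` holds
    ``(or, or_ci_low, or_ci_high)`` and is populated only for binary
    (log-odds) outcomes.
    """

    method: str  # "wald" | "ivw_correlated" | "egger_slope"
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    direction: str = PER_UNIT_INCREASE
    or_scale: Optional[tuple[float, float, float]] = None


@dataclass
class SensitivityReport:
    q_stat: Optional[float] = None
    q_df: Optional[int] = None
    q_pvalue: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_pvalue: Optional[float] = None
    egger_slope: Optional[MREstimate] = None
    loo: list[tuple[str, MREstimate]] = field(default_factory=list)
    pleiotropy_detected: Optional[bool] = None


def _normal_interval(theta: float, se: float, alpha: float) -> tuple[float, float]:
    z = stats.norm.ppf(1 - alpha / 2)
    return theta - z * se, theta + z * se


def _two_sided_p(theta: float, se: float) -> float:
    return float(2 * stats.norm.sf(abs(theta) / se))


def _or_triplet(theta: float, lo: float, hi: float) -> tuple[float, float, float]:
    return (math.exp(theta), math.exp(lo), math.exp(hi))


def _finish(
    method: str,
    theta: float,
    se: float,
    n_snps: int,
    alpha: float,
    binary: bool,
) -> MREstimate:
    lo, hi = _normal_interval(theta, se, alpha)
    return MREstimate(
        method=method,
        theta=float(theta),
        se=float(se),
        ci_low=float(lo),
        ci_high=float(hi),
        pvalue=_two_sided_p(theta, se),
        n_snps=n_snps,
        direction=PER_UNIT_INCREASE,
        or_scale=_or_triplet(theta, lo, hi) if binary else None,
    )


def _omega_inverse(instr: InstrumentSet) -> np.ndarray:
    """Inverse of Omega = S_y rho S_y, with eigenvalue flooring on rho.

    Near-duplicate instruments (possible under the relaxed r^2 < 0.6
    clumping) can make rho numerically singular; eigenvalues below the
    floor are raised to it with a warning so the GLS stays defined.
    """
    rho = instr.rho
    w, v = np.linalg.eigh(rho)
    if w.min() < EIGENVALUE_FLOOR:
        logger.warning(
            "LD matrix nearly singular (min eigenvalue %.3g); flooring at %.0e — "
            "consider a stricter clump threshold",
            w.min(),
            EIGENVALUE_FLOOR,
        )
        w = np.maximum(w, EIGENVALUE_FLOOR)
        rho = (v * w) @ v.T
    omega = rho * np.outer(instr.sigma_y, instr.sigma_y)
    try:
        c, low = linalg.cho_factor(omega)
        return linalg.cho_solve((c, low), np.eye(instr.m))
    except linalg.LinAlgError as exc:  # pragma: no cover - floor should prevent this
        raise ValueError(
            "outcome covariance is numerically singular even after eigenvalue "
            "flooring; use a stricter clump threshold"
        ) from exc


def wald_ratio(
    gamma: float,
    sigma_x: float,
    Gamma: float,
    sigma_y: float,
    alpha: float = 0.05,
    binary: bool = False,
    second_order_se: bool = False,
) -> MREstimate:
    """Single-instrument causal estimate Gamma/gamma.

    The default SE is the first-order delta method ``sigma_y/|gamma|``,
    which ignores exposure-side uncertainty — the same no-measurement-
    error convention the correlated IVW weighting uses.
    ``second_order_se`` adds the exposure-noise term
    ``Gamma^2 sigma_x^2 / gamma^4`` under the square root. An instrument
    with ``|gamma|/sigma_x < 1`` triggers a weak-instrument warning;
    ``gamma = 0`` is an error (the ratio is undefined).
    """
    if gamma == 0:
        raise ValueError("Wald ratio undefined for gamma = 0")
    if abs(gamma) / sigma_x < 1:
        logger.warning(
            "weak instrument: |gamma|/sigma_x = %.3f < 1", abs(gamma) / sigma_x
        )
    theta = Gamma / gamma
    se = sigma_y / abs(gamma)
    if second_order_se:
        se = math.sqrt(sigma_y**2 / gamma**2 + Gamma**2 * sigma_x**2 / gamma**4)
    return _finish("wald", theta, se, 1, alpha, binary)


def ivw_correlated(instr: InstrumentSet, alpha: float = 0.05) -> MREstimate:
    """Fixed-effect IVW for LD-correlated instruments (GLS).

    ``theta = (g' Omega^-1 g)^-1 g' Omega^-1 Gamma`` with
    ``se = sqrt((g' Omega^-1 g)^-1)``. Reduces exactly to the Wald ratio
    for a single instrument and to the 1/SE^2-weighted fixed-effect
    meta-analysis of Wald ratios when instruments are independent.
    """
    binary = instr.outcome_kind == "binary"
    if instr.m == 1:
        # exact reduction; the method tag stays "wald" so reports show
        # single-instrument analyses for what they are
        return wald_ratio(
            float(instr.gamma[0]),
            float(instr.sigma_x[0]),
            float(instr.Gamma[0]),
            float(instr.sigma_y[0]),
            alpha=alpha,
            binary=binary,
        )
    w = _omega_inverse(instr)
    gwg = float(instr.gamma @ w @ instr.gamma)
    if gwg <= 0:
        raise ValueError("degenerate instrument set: g' Omega^-1 g <= 0")
    theta = float(instr.gamma @ w @ instr.Gamma) / gwg
    se = math.sqrt(1.0 / gwg)
    return _finish("ivw_correlated", theta, se, instr.m, alpha, binary)


def cochran_q(instr: InstrumentSet, theta: float) -> tuple[float, int, float]:
    """Generalized (correlation-aware) Cochran heterogeneity statistic.

    ``Q = e' Omega^-1 e`` with residuals ``e = Gamma - theta*g``; under
    instrument homogeneity Q ~ chi-square(m - 1). Reduces to the
    classical fixed-effect Q when rho is the identity. Requires m >= 2.
    """
    if instr.m < 2:
        raise ValueError("Cochran's Q requires at least two instruments")
    w = _omega_inverse(instr)
    e = instr.Gamma - theta * instr.gamma
    q = float(e @ w @ e)
    df = instr.m - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_correlated(
    instr: InstrumentSet, alpha: float = 0.05
) -> tuple[float, float, float, MREstimate]:
    """MR-Egger regression with correlated instruments.

    GLS fit of ``Gamma = alpha0 + theta*g`` with error covariance Omega,
    after orienting all exposure betas positive (the intercept — the
    average directional pleiotropy — is only identified in the
    exposure-increasing allele frame). Returns
    ``(intercept, intercept_se, intercept_pvalue, slope_estimate)``.
    Requires m >= 3 and non-degenerate spread in g.
    """
    if instr.m < 3:
        raise ValueError("MR-Egger requires at least three instruments")
    instr = orient_positive(instr)
    g = instr.gamma
    spread = g.max() - g.min()
    scale = max(abs(g).max(), 1.0)
    if spread / scale < 1e-6:
        raise ValueError(
            "exposure betas nearly constant; Egger intercept and slope are "
            "not separately identifiable"
        )
    w = _omega_inverse(instr)
    x = np.column_stack([np.ones(instr.m), g])
    xtwx = x.T @ w @ x
    cov = np.linalg.inv(xtwx)
    coef = cov @ (x.T @ w @ instr.Gamma)
    intercept, slope = float(coef[0]), float(coef[1])
    intercept_se = math.sqrt(cov[0, 0])
    slope_se = math.sqrt(cov[1, 1])
    slope_est = _finish(
        "egger_slope", slope, slope_se, instr.m, alpha,
        instr.outcome_kind == "binary",
    )
    return intercept, intercept_se, _two_sided_p(intercept, intercept_se), slope_est


def leave_one_out(
    instr: InstrumentSet, alpha: float = 0.05
) -> list[tuple[str, MREstimate]]:
    """Re-estimate IVW dropping each instrument in turn (outlier screen)."""
    if instr.m < 2:
        raise ValueError("leave-one-out requires at least two instruments")
    out = []
    for i in range(instr.m):
        keep = [j for j in range(instr.m) if j != i]
        out.append(
            (instr.variant_ids[i], ivw_correlated(instr.subset(keep), alpha=alpha))
        )
    return out


def sensitivity_analysis(
    instr: InstrumentSet,
    estimate: MREstimate | None = None,
    alpha: float = 0.05,
) -> SensitivityReport:
    """Run the full diagnostic battery appropriate for the instrument count.

    Q and leave-one-out need m >= 2, Egger m >= 3; unavailable diagnostics
    are left absent. ``pleiotropy_detected`` flags (at ``alpha``) either a
    significant Q or a significant Egger intercept; the recommended
    reporting rule is to fall back to the Egger slope when it is set,
    but no silent estimator switching is done here.
    """
    report = SensitivityReport()
    if instr.m < 2:
        return report
    if estimate is None:
        estimate = ivw_correlated(instr, alpha=alpha)
    q, df, qp = cochran_q(instr, estimate.theta)
    report.q_stat, report.q_df, report.q_pvalue = q, df, qp
    report.loo = leave_one_out(instr, alpha=alpha)
    detected = qp < alpha
    if instr.m >= 3:
        a0, a0_se, a0_p, slope = egger_correlated(instr, alpha=alpha)
        report.egger_intercept = a0
        report.egger_intercept_se = a0_se
        report.egger_intercept_pvalue = a0_p
        report.egger_slope = slope
        detected = detected or a0_p < alpha
    report.pleiotropy_detected = bool(detected)
    return report


def report_direction(est: MREstimate, direction: str) -> MREstimate:
    """Express an estimate per 1-unit increase or decrease of the exposure.

    Re-expressing in the opposite direction negates theta and swaps the
    (negated) CI bounds; the SE and p-value are unchanged. For binary
    outcomes the OR scale is recomputed from the re-expressed log-odds
    values. Requesting the direction the estimate already has is a no-op,
    so the operation is an involution.
    """
    if direction not in (PER_UNIT_INCREASE, PER_UNIT_DECREASE):
        raise ValueError(f"unknown direction {direction!r}")
    if direction == est.direction:
        return est
    theta, lo, hi = -est.theta, -est.ci_high, -est.ci_low
    return replace(
        est,
        theta=theta,
        ci_low=lo,
        ci_high=hi,
        direction=direction,
        or_scale=_or_triplet(theta, lo, hi) if est.or_scale is not None else None,
    )


def rescale_effect(est: MREstimate, units: float) -> MREstimate:
    """Rescale an estimate from per-1-unit to per-``units`` of exposure.

    Used e.g. to express a per-mmHg effect at the average blood-pressure
    reduction achieved by a drug class. theta, SE and CI bounds are
    multiplied by ``units`` (> 0); the z-score and p-value are invariant;
    the OR scale is recomputed from the scaled log-odds values.
    """
    if units <= 0:
        raise ValueError("units must be positive")
    theta, se = est.theta * units, est.se * units
    lo, hi = est.ci_low * units, est.ci_high * units
    return replace(
        est,
        theta=theta,
        se=se,
        ci_low=lo,
        ci_high=hi,
        or_scale=_or_triplet(theta, lo, hi) if est.or_scale is not None else None,
    )
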