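"""Liability-threshold prediction metrics for differential diagnosis.

A binary state ("having disorder A rather than disorder B", given that a
subject has exactly one of the two) arises when a standard-normal latent
liability exceeds the threshold ``T = Phi^-1(1 - K)``, where the
conditional prevalence is ``K = K_A / (K_A + K_B)`` and ``K_A``,
``K_B`` are the lifetime prevalences of the two disorders.  A polygenic
score ``G ~ N(0, v)`` explains a fraction ``v`` of the liability
variance, so the absolute risk of the case state at score ``g`` is

    risk(g) = Phi((g - T) / sqrt(1 - v)).

From this model the module computes the maximum attainable AUC for a
given SNP heritability, absolute risks by score percentile, relative
risks of top-vs-bottom percentile groups, the variance of predicted
risk, proportion of cases concentrated in the top k% of scores, and ROC
/ predictiveness curves.  The AUC integrator is cross-checked against a
closed-form normal approximation (:func:`auc_closed_form`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats


class RiskModelError(ValueError):
    pass


#: grid resolution of the numerical integrator (points over +-8 SD of G)
_N_GRID = 20001


@dataclass(frozen=True)
class LiabilityModel:
    """Liability-threshold model for the two-disorder contrast.

    ``K`` is the prevalence of the case state (for differential
    diagnosis: ``K_A / (K_A + K_B)``); ``v`` the liability variance
    explained by the score.
    """

    K: float
    v: float

    def __post_init__(self):
        if not 0.0 < self.K < 1.0:
            raise RiskModelError(f"prevalence K={self.K} outside (0, 1)")
        if not 0.0 <= self.v <= 1.0:
            raise RiskModelError(f"variance explained v={self.v} outside [0, 1]")

    @property
    def T(self) -> float:
        return float(stats.norm.ppf(1.0 - self.K))

    def risk(self, g):
        """Absolute risk of the case state at score value ``g``."""
        if self.v >= 1.0:
            return np.where(np.asarray(g, float) > self.T, 1.0, 0.0)
        return stats.norm.cdf((np.asarray(g, float) - self.T)
                              / np.sqrt(1.0 - self.v))

    def score_grid(self, n: int = _N_GRID):
        """Evaluation grid over the score distribution N(0, v) with the
        score pdf and the case/control conditional densities."""
        sd = np.sqrt(self.v) if self.v > 0 else 1.0
        g = np.linspace(-8.0 * sd, 8.0 * sd, n)
        pdf = stats.norm.pdf(g, scale=sd) if self.v > 0 else None
        return g, pdf


@dataclass
class RiskProfile:
    """Predictive indices of a liability model (see :func:`risk_profile`)."""

    model: LiabilityModel
    auc: float
    percentiles: np.ndarray
    risk_case: np.ndarray          # absolute risk of the case disorder
    risk_control: np.ndarray       # = 1 - risk_case in the DDx setting
    rr_top_bottom: dict            # x -> RR of case disorder, top-x vs bottom-x
    var_predicted_risk: float
    cases_in_top_k: dict           # k -> proportion of cases in top k% of risk
    roc_points: np.ndarray         # (n, 2) array of (FPR, TPR)
    predictiveness_points: np.ndarray  # (n, 2) array of (quantile, risk)
    bin_average: bool = False
    prior: dict = field(default_factory=dict)


def ddx_prior(K_case: float, K_control: float) -> tuple[float, float]:
    """Prior probability of the case disorder and the prior relative risk
    of the control disorder, from lifetime prevalences alone.

    Conditioning on having exactly one of the two disorders,
    ``prior_prob_case = K_case / (K_case + K_control)`` and the prior RR
    of control vs case is ``K_control / K_case``.
    """
    if not (0.0 < K_case < 1.0 and 0.0 < K_control < 1.0):
        raise RiskModelError("prevalences must lie in (0, 1)")
    return K_case / (K_case + K_control), K_control / K_case


def auc_from_model(model: LiabilityModel, n_grid: int = _N_GRID) -> float:
    """AUC = P(G_case > G_control) by numerical integration.

    The case/control score densities are ``f(g|case) ∝ risk(g) phi(g/sd)``
    and ``f(g|control) ∝ (1 - risk(g)) phi(g/sd)``; the AUC integrates
    the case density against the control CDF.
    """
    if model.v == 0.0:
        return 0.5
    if model.v >= 1.0:
        return 1.0
    g, pdf = model.score_grid(n_grid)
    risk = model.risk(g)
    case = risk * pdf
    ctrl = (1.0 - risk) * pdf
    case /= integrate.trapezoid(case, g)
    ctrl /= integrate.trapezoid(ctrl, g)
    ctrl_cdf = integrate.cumulative_trapezoid(ctrl, g, initial=0.0)
    return float(integrate.trapezoid(case * ctrl_cdf, g))


def max_auc(h2_liab: float, K_case: float, K_control: float) -> float:
    """Maximum AUC for discriminating the case from the control disorder
    when the score captures the full SNP heritability ``h2_liab`` of the
    differential liability.

    The conditional prevalence is ``K_case / (K_case + K_control)``.
    Values of ``h2_liab`` at 1 return the limit 1.0.
    """
    K = K_case / (K_case + K_control)
    if h2_liab >= 1.0:
        import logging
        logging.getLogger(__name__).warning(
            "v = 1: AUC returned as the limit 1.0")
        return 1.0
    return auc_from_model(LiabilityModel(K=K, v=h2_liab))


def auc_closed_form(model: LiabilityModel) -> float:
    """Normal approximation to the AUC of a liability-scale score.

    With ``i = phi(T)/K`` (mean liability of cases), ``i' = -K i /
    (1 - K)`` (mean liability of controls)::

        AUC = Phi( (i - i') v / sqrt(v [(1 - v i (i - T)) +
                                        (1 - v i' (i' - T))]) )
    """
    K, v, T = model.K, model.v, model.T
    if v == 0.0:
        return 0.5
    i = stats.norm.pdf(T) / K
    i2 = -K * i / (1.0 - K)
    num = (i - i2) * v
    den = np.sqrt(v * ((1.0 - v * i * (i - T)) + (1.0 - v * i2 * (i2 - T))))
    return float(stats.norm.cdf(num / den))


def invert_auc(target_auc: float, K: float, tol: float = 1e-6) -> float:
    """Variance explained ``v`` whose model AUC matches ``target_auc``.

    Bisection against the same integrator used by :func:`max_auc`;
    accurate to ``tol`` in AUC.
    """
    if not 0.5 <= target_auc < 1.0:
        raise RiskModelError("target AUC must lie in [0.5, 1)")
    if target_auc == 0.5:
        return 0.0

    def f(v):
        return auc_from_model(LiabilityModel(K=K, v=v)) - target_auc

    return float(optimize.brentq(f, 0.0, 1.0 - 1e-12, xtol=1e-12,
                                 rtol=8.9e-16, maxiter=200))


def risk_profile(
    model: LiabilityModel,
    percentiles=None,
    top_bottom_x=(5, 10, 20, 30),
    top_k=(1, 5, 10, 20, 30, 50),
    bin_average: bool = False,
    n_curve: int = 201,
) -> RiskProfile:
    """Absolute-risk and discrimination profile of a liability model.

    Percentile risks are point values at the percentile of the score
    distribution (``g_q = sqrt(v) Phi^-1(q)``); with
    ``bin_average=True`` the top/bottom relative risks instead compare
    mean risks within the tail bins.  In the differential-diagnosis
    setting the control-disorder risk at any percentile is one minus the
    case-disorder risk.
    """
    if percentiles is None:
        percentiles = [1, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 95, 99]
    percentiles = np.asarray(percentiles, float)
    K, v = model.K, model.v
    sd = np.sqrt(v) if v > 0 else 0.0

    q = percentiles / 100.0
    g_q = sd * stats.norm.ppf(q)
    risk_case = np.asarray(model.risk(g_q), float)

    g, pdf = model.score_grid()
    if v > 0:
        risk_g = model.risk(g)
        w = pdf / integrate.trapezoid(pdf, g)
        mean_risk = integrate.trapezoid(risk_g * w, g)
        var_risk = integrate.trapezoid((risk_g - mean_risk) ** 2 * w, g)
        cdf_g = stats.norm.cdf(g / sd)

        def tail_mean_risk(lo_q, hi_q):
            m = (cdf_g >= lo_q) & (cdf_g <= hi_q)
            return (integrate.trapezoid((risk_g * w)[m], g[m])
                    / integrate.trapezoid(w[m], g[m]))

        rr = {}
        for x in top_bottom_x:
            frac = x / 100.0
            if bin_average:
                top = tail_mean_risk(1.0 - frac, 1.0)
                bot = tail_mean_risk(0.0, frac)
            else:
                top = float(model.risk(sd * stats.norm.ppf(1.0 - frac)))
                bot = float(model.risk(sd * stats.norm.ppf(frac)))
            rr[x] = top / bot

        cases_top = {}
        for k in top_k:
            thr = sd * stats.norm.ppf(1.0 - k / 100.0)
            m = g >= thr
            cases_top[k] = float(
                integrate.trapezoid((risk_g * w)[m], g[m]) / K)

        # ROC by sweeping the score threshold
        case_d = risk_g * w / K
        ctrl_d = (1.0 - risk_g) * w / (1.0 - K)
        tpr = 1.0 - integrate.cumulative_trapezoid(case_d, g, initial=0.0)
        fpr = 1.0 - integrate.cumulative_trapezoid(ctrl_d, g, initial=0.0)
        sel = np.linspace(0, len(g) - 1, n_curve).astype(int)
        roc = np.column_stack([np.clip(fpr[sel], 0, 1),
                               np.clip(tpr[sel], 0, 1)])[::-1]
        roc[0] = (0.0, 0.0)
        roc[-1] = (1.0, 1.0)

        qq = np.linspace(0.001, 0.999, n_curve)
        pred = np.column_stack([qq, model.risk(sd * stats.norm.ppf(qq))])
        auc = auc_from_model(model)
    else:
        risk_case = np.full(len(percentiles), K)
        var_risk = 0.0
        rr = {x: 1.0 for x in top_bottom_x}
        cases_top = {k: k / 100.0 for k in top_k}
        uu = np.linspace(0, 1, n_curve)
        roc = np.column_stack([uu, uu])
        pred = np.column_stack([np.linspace(0.001, 0.999, n_curve),
                                np.full(n_curve, K)])
        auc = 0.5

    return RiskProfile(
        model=model, auc=auc, percentiles=percentiles,
        risk_case=risk_case, risk_control=1.0 - risk_case,
        rr_top_bottom=rr, var_predicted_risk=float(var_risk),
        cases_in_top_k=cases_top, roc_points=roc,
        predictiveness_points=pred, bin_average=bin_average,
    )
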