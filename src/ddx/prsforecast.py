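"""Forecasting the discriminative power of a P+T polygenic score.

Given (approximately independent) z-scores from the differential
case-case GWAS, the underlying mean effects are recovered by empirical
Bayes: the marginal z density ``f`` is estimated by Lindsey's method
(Poisson regression of histogram counts on a natural cubic spline
basis) and Tweedie's formula gives the posterior mean

    E[mu | z] = z + d/dz log f(z)

for unit sampling variance.  For each p-value threshold ``t`` of the
standard P+T construction the forecast variance explained on the
observed scale is the posterior signal energy of the selected SNPs,
``sum of E[mu^2 | z] / n_eff`` (the posterior second moment; summing
the squared posterior means alone would underestimate the energy by
the posterior variance); it is mapped to the liability scale and to an
AUC through the liability threshold model.  Eighteen conventional
thresholds from 1e-5 to 1 are scanned and the best one reported.

An optional greedy pruning step (keep the most significant SNP of any
correlated group) stands in for LD clumping; simulated panels of
independent SNPs pass through unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ldsc import liability_scale
from .riskmodel import LiabilityModel, auc_from_model

logger = logging.getLogger(__name__)

#: the 18 conventional p-value thresholds of the P+T scan
THRESHOLDS_18 = (1e-5, 1e-4, 5e-4, 1e-3, 5e-3, 0.01, 0.03, 0.05,
                 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


class PrsForecastError(ValueError):
    pass


@dataclass
class ShrinkageFit:
    """Observed z-scores, their posterior moments, and the density fit.

    ``z_post`` is the posterior mean ``E[mu | z]``; ``mu2_post`` the
    posterior second moment ``E[mu^2 | z] = z_post^2 + Var(mu | z)``
    with ``Var(mu | z) = 1 + d^2/dz^2 log f(z)``.  Summed over SNPs the
    second moment is an unbiased estimate of the total signal energy
    ``sum mu^2``, which the posterior mean squared alone underestimates.
    Individual ``mu2_post`` entries may fall below zero from
    density-estimation noise; only sums over SNP sets are meaningful.
    """

    z_obs: np.ndarray
    z_post: np.ndarray
    mu2_post: np.ndarray
    df: int
    n_bins: int
    method: str  # "lindsey" or "normal_fallback"


@dataclass
class ThresholdCurve:
    """Forecast variance explained and AUC across p-value thresholds."""

    table: pd.DataFrame  # threshold, n_snps, v_obs, v_liab, auc
    best_threshold: float
    best_auc: float


def _natural_spline_basis(x: np.ndarray, knots: np.ndarray):
    """Natural cubic spline basis (without intercept) plus its first and
    second derivatives.

    Uses the truncated-power construction: basis = [x, N_1..N_{K-2}]
    with ``N_k = d_k - d_{K-1}``, ``d_k(x) = ((x - xi_k)_+^3 -
    (x - xi_K)_+^3) / (xi_K - xi_k)``.  Linear beyond the boundary
    knots.
    """
    K = len(knots)

    def d(k, xx, deriv):
        num1 = np.clip(xx - knots[k], 0.0, None)
        num2 = np.clip(xx - knots[K - 1], 0.0, None)
        span = knots[K - 1] - knots[k]
        if deriv == 2:
            return (6 * num1 - 6 * num2) / span
        if deriv == 1:
            return (3 * num1 ** 2 - 3 * num2 ** 2) / span
        return (num1 ** 3 - num2 ** 3) / span

    cols, dcols, d2cols = [x], [np.ones_like(x)], [np.zeros_like(x)]
    for k in range(K - 2):
        cols.append(d(k, x, 0) - d(K - 2, x, 0))
        dcols.append(d(k, x, 1) - d(K - 2, x, 1))
        d2cols.append(d(k, x, 2) - d(K - 2, x, 2))
    return (np.column_stack(cols), np.column_stack(dcols),
            np.column_stack(d2cols))


def tweedie_shrink(z_obs, df: int = 7, n_bins: int = 199) -> ShrinkageFit:
    """Posterior-mean z-scores by Tweedie's formula.

    The marginal density is fitted by Lindsey's method: counts in
    ``n_bins`` equal-width bins spanning ``[min(z) - 0.1, max(z) + 0.1]``
    are modelled as Poisson with a log-linear natural-cubic-spline
    predictor of ``df`` degrees of freedom (knots at equally spaced
    quantiles of the data, boundary knots at the data range).  If the
    Poisson fit fails, a zero-mean normal fit is used instead
    (``z_post = z (s^2 - 1)/s^2`` with ``s^2`` the marginal variance),
    with a warning.
    """
    z = np.asarray(z_obs, float)
    if len(z) < 200:
        raise PrsForecastError(
            f"need >= 200 z-scores for density estimation, got {len(z)}")

    lo, hi = z.min() - 0.1, z.max() + 0.1
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(z, edges)
    mids = 0.5 * (edges[:-1] + edges[1:])

    qs = np.linspace(0.0, 1.0, df)
    knots = np.unique(np.quantile(z, qs))
    method = "lindsey"
    try:
        if len(knots) < 3:
            raise np.linalg.LinAlgError("degenerate knot sequence")
        B, _, _ = _natural_spline_basis(mids, knots)
        X = sm.add_constant(B)
        fit = sm.GLM(counts, X, family=sm.families.Poisson()).fit(maxiter=200)
        if not fit.converged or not np.all(np.isfinite(fit.params)):
            raise np.linalg.LinAlgError("Poisson fit did not converge")
        _, dB, d2B = _natural_spline_basis(z, knots)
        z_post = z + dB @ fit.params[1:]
        # per-SNP values are left unclipped: density-estimation noise
        # makes individual variances dip below zero, but clipping would
        # bias the summed signal energy upward (under the null the
        # noise must cancel in the sum)
        var_post = 1.0 + d2B @ fit.params[1:]
    except Exception as err:  # pragma: no cover - rare numerical failure
        logger.warning("Lindsey density fit failed (%s); falling back to "
                       "normal shrinkage", err)
        s2 = max(1.0, float(np.var(z)))
        z_post = z * (s2 - 1.0) / s2
        var_post = np.full_like(z, (s2 - 1.0) / s2 if s2 > 1 else 0.0)
        method = "normal_fallback"

    z_post = np.asarray(z_post, float)
    return ShrinkageFit(z_obs=z, z_post=z_post,
                        mu2_post=z_post ** 2 + np.asarray(var_post, float),
                        df=df, n_bins=n_bins, method=method)


def prune(
    table: pd.DataFrame,
    ld=None,
    r2_thresh: float = 0.1,
    window_kb: int = 1000,
) -> np.ndarray:
    """Greedy LD pruning; returns positional indices of retained rows.

    ``table`` needs columns ``P`` and, when ``ld`` is given, ``CHR`` and
    ``BP``.  ``ld`` is either ``None`` (input declared independent:
    pass-through) or a callable ``ld(i, j) -> r^2`` on positional row
    indices.  SNPs are visited by ascending p-value; a SNP is kept iff
    no already-kept SNP on the same chromosome within ``window_kb`` has
    ``r^2 > r2_thresh``.
    """
    n = len(table)
    if ld is None:
        return np.arange(n)
    order = np.argsort(table["P"].to_numpy(), kind="mergesort")
    chrom = table["CHR"].astype(str).to_numpy()
    bp = table["BP"].to_numpy(float)
    window = window_kb * 1000.0
    kept: list[int] = []
    for i in order:
        ok = True
        for j in kept:
            if chrom[i] == chrom[j] and abs(bp[i] - bp[j]) <= window \
                    and ld(i, j) > r2_thresh:
                ok = False
                break
        if ok:
            kept.append(i)
    return np.array(sorted(kept), dtype=int)


def forecast_auc(
    fit: ShrinkageFit,
    pvals,
    n_eff: float,
    K_case: float,
    K_control: float,
    sample_case_fraction: float = 0.5,
    thresholds=THRESHOLDS_18,
    pruned=None,
) -> ThresholdCurve:
    """Forecast the discriminative AUC of the P+T score per threshold.

    Parameters
    ----------
    fit
        Shrinkage fit of the differential z-scores.
    pvals
        Per-SNP p-values aligned with ``fit.z_obs``.
    n_eff
        Effective sample size of the differential contrast,
        ``4 / (1/N_case + 1/N_control)``.
    K_case, K_control
        Lifetime prevalences of the two disorders; the liability model
        uses the conditional prevalence ``K_case / (K_case + K_control)``.
    sample_case_fraction
        Case fraction of the contrast sample used for the
        observed-to-liability conversion (0.5 for a balanced effective
        design).
    pruned
        Positional indices from :func:`prune`; ``None`` keeps all SNPs.

    Thresholds with no selected SNP record AUC 0.5.
    """
    pvals = np.asarray(pvals, float)
    if len(pvals) != len(fit.z_obs):
        raise PrsForecastError("p-values not aligned with shrinkage fit")
    if pruned is None:
        pruned = np.arange(len(pvals))
    pruned = np.asarray(pruned, int)
    K = K_case / (K_case + K_control)

    energy = fit.mu2_post
    rows = []
    for t in thresholds:
        sel = pruned[pvals[pruned] <= t]
        if len(sel) == 0:
            rows.append((t, 0, 0.0, 0.0, 0.5))
            continue
        v_obs = float(np.clip(energy[sel].sum() / n_eff, 0.0, 1.0))
        v_liab = min(1.0, liability_scale(v_obs, K, sample_case_fraction))
        auc = auc_from_model(LiabilityModel(K=K, v=v_liab)) \
            if v_liab < 1.0 else 1.0
        rows.append((t, len(sel), v_obs, v_liab, auc))

    table = pd.DataFrame(rows, columns=["threshold", "n_snps", "v_obs",
                                        "v_liab", "auc"])
    best = table.loc[table["auc"].idxmax()]
    return ThresholdCurve(table=table, best_threshold=float(best["threshold"]),
                          best_auc=float(best["auc"]))


def effective_n(n_case: float, n_control: float) -> float:
    """Effective sample size ``4 / (1/n_case + 1/n_control)`` of a
    case-control contrast."""
    return 4.0 / (1.0 / n_case + 1.0 / n_control)
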