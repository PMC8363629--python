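"""Per-SNP differential association between two disorders.

Given harmonized summary statistics of disorder A ("case") and disorder
B ("pseudo-control"), the log-odds ratio of the implied case-case GWAS
is the difference of the two per-disorder log-odds ratios,

    beta_diff = beta_A - beta_B,

with variance

    Var(beta_diff) = Var(beta_A) + Var(beta_B) - 2 Cov(beta_A, beta_B).

The covariance term captures sample overlap between the two studies and
is obtained by multiplying the two standard errors with the cross-trait
LD-score-regression intercept (``r_int``), which estimates the
correlation of the two studies' test statistics under the null.
Genomic control can then divide the resulting chi-square statistics by
an inflation factor lambda to guard against residual stratification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedPair

logger = logging.getLogger(__name__)

#: conventional genome-wide significance level for per-SNP summaries
GENOME_WIDE_SIG = 5e-8

#: median of the chi-square distribution with 1 df
_CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))


class DiffGwasError(ValueError):
    """Fatal configuration or input problem in the differential test."""


@dataclass
class GcReport:
    """Record of the genomic-control correction applied."""

    lambda_used: float
    lambda_source: str  # ldsc_intercept | median_chi2 | user | none
    median_chi2_before: float
    median_chi2_after: float


def differential_effect(b1, se1, b2, se2, r_int: float):
    """Differential log-OR, SE, z and two-sided p for one or many SNPs.

    Parameters are array-like; ``r_int`` is the cross-trait intercept in
    (-1, 1).  Returns ``(beta13, se13, z, p_raw)`` as float arrays (or
    scalars for scalar input).  SNPs whose variance is non-positive
    (possible only when ``|r_int|`` is at the boundary) yield NaN.
    """
    if not np.isfinite(r_int) or abs(r_int) >= 1.0:
        raise DiffGwasError(
            f"cross-trait intercept r_int={r_int!r} must lie in (-1, 1)")
    b1 = np.asarray(b1, float)
    b2 = np.asarray(b2, float)
    se1 = np.asarray(se1, float)
    se2 = np.asarray(se2, float)
    if np.any(se1 <= 0) or np.any(se2 <= 0):
        raise DiffGwasError("standard errors must be positive")

    beta13 = b1 - b2
    var13 = se1 ** 2 + se2 ** 2 - 2.0 * r_int * se1 * se2
    bad = var13 <= 0
    var13 = np.where(bad, np.nan, var13)
    se13 = np.sqrt(var13)
    z = beta13 / se13
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    if np.ndim(beta13) == 0:
        return float(beta13), float(se13), float(z), float(p_raw)
    return beta13, se13, z, p_raw


def _chrom_key(chrom: pd.Series) -> pd.Series:
    """Natural sort key: numeric chromosomes first, then X/Y/MT/others."""
    s = chrom.astype(str).str.upper().str.replace("CHR", "", regex=False)
    num = pd.to_numeric(s, errors="coerce")
    special = s.map({"X": 23, "Y": 24, "MT": 25, "M": 25})
    rank = num.fillna(special)
    other = pd.Series(26.0 + s.factorize()[0], index=s.index)
    return rank.fillna(other)


def run_differential(
    pair: HarmonizedPair,
    r_int: float | object = 0.0,
    gc: str = "median",
    ld=None,
    lambda_user: float | None = None,
    sig_threshold: float = GENOME_WIDE_SIG,
) -> tuple[pd.DataFrame, GcReport]:
    """Run the differential test over a harmonized pair.

    Parameters
    ----------
    pair
        Output of :func:`ddx.sumstats.harmonize`; trait 1 plays the
        case role.
    r_int
        Cross-trait intercept (float) or a
        :class:`ddx.ldsc.CrossTraitFit`, whose ``intercept_xt`` is used.
    gc
        Source of the genomic-control inflation factor: ``"ldsc"``
        (intercept of an LD-score regression on the differential
        chi-square; needs ``ld``), ``"median"`` (median chi-square over
        its null expectation 0.4549), ``"none"`` or ``"user"`` (supply
        ``lambda_user``).  Lambda is clamped at >= 1; deflation is never
        applied.

    Returns the per-SNP result table sorted by (chromosome, position,
    SNP ID) together with a :class:`GcReport`.  Genomic control affects
    only the reported ``CHI2_GC``/``P_GC``; ``Z``/``P`` stay
    uncorrected.
    """
    if hasattr(r_int, "intercept_xt"):
        r_int = float(r_int.intercept_xt)
    if len(pair) == 0:
        raise DiffGwasError("harmonized pair is empty")

    df = pair.df
    beta13, se13, z, p_raw = differential_effect(
        df["BETA_T1"], df["SE_T1"], df["BETA_T2"], df["SE_T2"], r_int)

    out = pd.DataFrame({
        "SNP": df["SNP"].to_numpy(),
        "BETA13": beta13, "SE13": se13, "Z": z, "P": p_raw,
    })
    for col in ("CHR", "BP", "A1", "A2"):
        if col in df.columns:
            out[col] = df[col].to_numpy()
    for col in ("N_T1", "N_T2", "N_CASE_T1", "N_CONTROL_T1",
                "N_CASE_T2", "N_CONTROL_T2"):
        if col in df.columns:
            out[col] = df[col].to_numpy()

    degenerate = ~np.isfinite(out["SE13"].to_numpy())
    if degenerate.all():
        raise DiffGwasError("all SNPs have degenerate differential variance")
    if degenerate.any():
        logger.warning("%d SNP(s) dropped: degenerate_variance",
                       int(degenerate.sum()))
        out = out.loc[~degenerate]

    chi2 = out["Z"].to_numpy() ** 2
    median_before = float(np.median(chi2))

    if gc not in ("ldsc", "median", "none", "user"):
        raise DiffGwasError(f"unknown gc mode {gc!r}")
    if gc == "ldsc" and ld is None:
        logger.warning("gc='ldsc' requested but no LD scores available; "
                       "falling back to median chi-square")
        gc = "median"
    if gc == "ldsc":
        from .ldsc import fit_univariate
        n = out["N_T1"].to_numpy(float) if "N_T1" in out else \
            np.full(len(out), np.nan)
        fit = fit_univariate(chi2, n, ld)
        lam, source = fit.intercept, "ldsc_intercept"
    elif gc == "median":
        lam, source = median_before / _CHI2_MEDIAN_1DF, "median_chi2"
    elif gc == "none":
        lam, source = 1.0, "none"
    else:
        if lambda_user is None:
            raise DiffGwasError("gc='user' requires lambda_user")
        lam, source = float(lambda_user), "user"

    lam = max(1.0, float(lam))
    out["CHI2_GC"] = chi2 / lam
    out["P_GC"] = stats.chi2.sf(out["CHI2_GC"], 1)

    if {"CHR", "BP"} <= set(out.columns):
        out = out.assign(_ck=_chrom_key(out["CHR"])) \
                 .sort_values(["_ck", "BP", "SNP"], kind="mergesort") \
                 .drop(columns="_ck")
    else:
        out = out.sort_values("SNP", kind="mergesort")
    out = out.reset_index(drop=True)

    n_sig = int((out["P"] < sig_threshold).sum())
    logger.info("differential test: %d SNPs, %d below p=%.3g, lambda=%.4f (%s)",
                len(out), n_sig, sig_threshold, lam, source)

    report = GcReport(
        lambda_used=lam,
        lambda_source=source,
        median_chi2_before=median_before,
        median_chi2_after=float(np.median(out["CHI2_GC"])),
    )
    cols = [c for c in ("SNP", "CHR", "BP", "A1", "A2", "BETA13", "SE13",
                        "Z", "P", "CHI2_GC", "P_GC", "N_T1", "N_T2",
                        "N_CASE_T1", "N_CONTROL_T1", "N_CASE_T2",
                        "N_CONTROL_T2") if c in out.columns]
    return out[cols], report
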