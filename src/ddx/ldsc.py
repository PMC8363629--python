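"""Minimal LD-score regression.

Implements the two regressions needed by the differential-association
pipeline:

* univariate: ``chi2_j ~ intercept + (N_j l_j / M) * h2`` gives the
  observed-scale SNP heritability (slope) and a stratification/overlap
  intercept;
* cross-trait: ``z1_j z2_j ~ intercept + (sqrt(N1 N2) l_j / M) * gencov``
  whose intercept estimates the correlation of the two studies' test
  statistics under the null — the quantity that converts the two
  standard errors into Cov(beta_1, beta_2) for the differential test.

Standard errors come from a delete-a-block jackknife over
position-contiguous SNP blocks.  A "flat" LD-score mode (l_j = 1,
M = number of SNPs) supports simulated panels of independent SNPs: with
a constant regressor slope and intercept are not separable, so the
univariate fit constrains the intercept to its null value 1 (closed
form ``h2 = (mean chi2 - 1) M / N``) and the cross-trait fit reports
the mean of ``z1 z2`` as the intercept with no genetic-covariance
estimate.

Observed-scale heritability of a case-control trait is converted to the
liability scale with the standard prevalence transformation
(:func:`liability_scale`).
"""

from __future__ import annotations

import glob
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class LdscError(ValueError):
    pass


@dataclass
class LdScoreTable:
    """Per-SNP LD scores plus the reference panel size ``M``."""

    snp: np.ndarray
    chrom: np.ndarray
    l2: np.ndarray
    M: float
    flat: bool = False

    def __post_init__(self):
        self.l2 = np.asarray(self.l2, float)
        if np.any(self.l2 < 1.0 - 1e-6):
            logger.warning("LD scores below 1 present; clipping to 1 for "
                           "weighting only")
        if self.M < len(self.l2):
            raise LdscError("reference SNP count M smaller than scored SNPs")

    def __len__(self) -> int:
        return len(self.l2)

    @classmethod
    def flat_mode(cls, n_snp: int) -> "LdScoreTable":
        """Unit LD scores for a panel of independent SNPs (M = n_snp)."""
        return cls(
            snp=np.array([f"snp{i + 1}" for i in range(n_snp)]),
            chrom=np.ones(n_snp, dtype=int),
            l2=np.ones(n_snp),
            M=float(n_snp),
            flat=True,
        )

    @classmethod
    def read(cls, path: str) -> "LdScoreTable":
        """Read LD scores in the ``.l2.ldscore[.gz]`` tab dialect.

        ``path`` may be a single score file or a directory containing
        per-chromosome ``*.l2.ldscore(.gz)`` files.  A sibling
        ``.l2.M_5_50`` (or ``.l2.M``) count file supplies ``M``; when
        absent, M falls back to the number of scored SNPs.
        """
        if os.path.isdir(path):
            score_files = sorted(
                glob.glob(os.path.join(path, "*.l2.ldscore")) +
                glob.glob(os.path.join(path, "*.l2.ldscore.gz")))
            if not score_files:
                raise LdscError(f"no .l2.ldscore files under {path}")
        else:
            score_files = [path]
        frames = [pd.read_csv(f, sep=r"\s+") for f in score_files]
        df = pd.concat(frames, ignore_index=True)
        for col in ("CHR", "SNP", "L2"):
            if col not in df.columns:
                raise LdscError(f"LD-score file lacks column {col}")

        m_total = 0.0
        found_m = False
        for f in score_files:
            base = f[:-len(".gz")] if f.endswith(".gz") else f
            base = base[:-len(".l2.ldscore")]
            for suffix in (".l2.M_5_50", ".l2.M"):
                mf = base + suffix
                if os.path.exists(mf):
                    with open(mf) as fh:
                        m_total += float(fh.read().split()[0])
                    found_m = True
                    break
        M = m_total if found_m else float(len(df))
        return cls(snp=df["SNP"].astype(str).to_numpy(),
                   chrom=df["CHR"].to_numpy(),
                   l2=df["L2"].to_numpy(float), M=M)

    def aligned_to(self, snp_ids) -> "LdScoreTable":
        """Subset/reorder the scores to match ``snp_ids`` (inner join)."""
        idx = pd.Index(self.snp)
        pos = idx.get_indexer(pd.Index(np.asarray(snp_ids, dtype=str)))
        if np.any(pos < 0):
            raise LdscError(f"{int((pos < 0).sum())} SNP(s) missing from the "
                            "LD-score reference")
        return LdScoreTable(self.snp[pos], self.chrom[pos], self.l2[pos],
                            self.M, self.flat)


@dataclass
class LdscFit:
    h2_obs: float
    intercept: float
    se_h2: float
    se_intercept: float
    n_blocks: int
    n_snp: int
    mean_chi2: float


@dataclass
class CrossTraitFit:
    intercept_xt: float
    gencov: float
    rg: float
    se_intercept: float
    se_gencov: float
    n_blocks: int
    n_snp: int


def default_n_blocks(n_snp: int) -> int:
    """200 blocks as in common practice; fewer for small panels."""
    return 200 if n_snp >= 2000 else max(2, n_snp // 10)


def _block_bounds(n: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, n, n_blocks + 1).astype(int)


def _wls_jackknife(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                   n_blocks: int):
    """Weighted LS coefficients and delete-a-block jackknife SEs.

    Blocks are contiguous runs of rows (SNPs are assumed
    position-sorted).  Returns ``(coef, se, block_coefs)``.
    """
    n, p = X.shape
    n_blocks = min(n_blocks, n)
    Xw = X * w[:, None]
    xtx = X.T @ Xw
    xty = Xw.T @ y
    coef = np.linalg.solve(xtx, xty)

    bounds = _block_bounds(n, n_blocks)
    block_coefs = np.empty((n_blocks, p))
    for b in range(n_blocks):
        lo, hi = bounds[b], bounds[b + 1]
        Xb, yb, wb = X[lo:hi], y[lo:hi], w[lo:hi]
        xtx_b = xtx - Xb.T @ (Xb * wb[:, None])
        xty_b = xty - (Xb * wb[:, None]).T @ yb
        block_coefs[b] = np.linalg.solve(xtx_b, xty_b)
    mean_bc = block_coefs.mean(axis=0)
    se = np.sqrt((n_blocks - 1) / n_blocks *
                 ((block_coefs - mean_bc) ** 2).sum(axis=0))
    return coef, se, block_coefs


def fit_univariate(
    chi2,
    n,
    ld: LdScoreTable,
    n_blocks: int | None = None,
    chi2_max: float | None = -1.0,
) -> LdscFit:
    """Univariate LD-score regression of per-SNP chi-square statistics.

    ``chi2_max = -1`` applies the conventional outlier filter
    ``chi2 <= max(80, 0.001 N)``; pass ``None`` to disable (simulated
    panels).  Weights ``1 / (2 (1 + N h2 l/M)^2 l)`` are refined twice
    from an initial unweighted fit.  A negative fitted slope is reported
    as-is (no truncation), with a warning.
    """
    chi2 = np.asarray(chi2, float)
    n = np.asarray(n, float)
    if n.ndim == 0:
        n = np.full(len(chi2), float(n))
    if np.any(chi2 < 0):
        raise LdscError("chi-square statistics must be non-negative")
    if len(chi2) < 200 and not ld.flat:
        logger.warning("only %d SNPs for LD-score regression; estimates "
                       "will be unstable", len(chi2))

    if chi2_max is not None and chi2_max == -1.0:
        chi2_max = max(80.0, 0.001 * np.nanmax(n))
    keep = np.ones(len(chi2), bool)
    if chi2_max is not None:
        keep = chi2 <= chi2_max
    if len(ld.l2) != len(chi2):
        raise LdscError("LD-score table not aligned with statistics; use "
                        "LdScoreTable.aligned_to first")
    chi2, n = chi2[keep], n[keep]
    l2 = ld.l2[keep]
    M = ld.M
    n_snp = len(chi2)
    if n_blocks is None:
        n_blocks = default_n_blocks(n_snp)
    mean_n = float(np.mean(n))
    mean_chi2 = float(np.mean(chi2))

    if ld.flat:
        # constant regressor: constrain intercept to its null value 1
        per_block = np.empty(min(n_blocks, n_snp))
        bounds = _block_bounds(n_snp, len(per_block))
        total = chi2.sum()
        for b in range(len(per_block)):
            lo, hi = bounds[b], bounds[b + 1]
            per_block[b] = (total - chi2[lo:hi].sum()) / (n_snp - (hi - lo))
        h2_blocks = (per_block - 1.0) * M / mean_n
        h2 = (mean_chi2 - 1.0) * M / mean_n
        se_h2 = np.sqrt((len(per_block) - 1) / len(per_block) *
                        ((h2_blocks - h2_blocks.mean()) ** 2).sum())
        return LdscFit(h2_obs=h2, intercept=1.0, se_h2=float(se_h2),
                       se_intercept=0.0, n_blocks=len(per_block),
                       n_snp=n_snp, mean_chi2=mean_chi2)

    x = n * l2 / M
    X = np.column_stack([np.ones(n_snp), x])
    w = np.ones(n_snp)
    coef = None
    for _ in range(3):  # unweighted fit + two reweighted refinements
        coef, se, _ = _wls_jackknife(X, chi2, w, n_blocks)
        h2 = float(np.clip(coef[1], 0.0, 1.0))
        lw = np.maximum(l2, 1.0)
        w = 1.0 / (2.0 * (1.0 + n * h2 * lw / M) ** 2 * lw)
    h2 = float(coef[1])
    if h2 < 0:
        logger.warning("negative fitted heritability slope (h2_obs=%.4g); "
                       "reported as-is", h2)
    return LdscFit(h2_obs=h2, intercept=float(coef[0]),
                   se_h2=float(se[1]),
                   se_intercept=float(se[0]), n_blocks=n_blocks,
                   n_snp=n_snp, mean_chi2=mean_chi2)


def fit_crosstrait(
    z1,
    z2,
    n1,
    n2,
    ld: LdScoreTable,
    n_blocks: int | None = None,
) -> CrossTraitFit:
    """Cross-trait LD-score regression of ``z1 * z2``.

    The intercept estimates the null correlation of the two studies'
    z-scores (driven by sample overlap and phenotypic correlation); the
    slope gives the genetic covariance, and ``rg = gencov /
    sqrt(h2_1 h2_2)`` when both univariate heritabilities are positive
    (``rg`` may numerically exceed 1 and is reported as-is).  Inputs
    must be aligned to a common effect allele.
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    n1 = np.broadcast_to(np.asarray(n1, float), z1.shape).copy()
    n2 = np.broadcast_to(np.asarray(n2, float), z2.shape).copy()
    if z1.shape != z2.shape:
        raise LdscError("z-score vectors differ in length")
    n_snp = len(z1)
    if n_blocks is None:
        n_blocks = default_n_blocks(n_snp)
    y = z1 * z2
    M = ld.M

    if ld.flat:
        # constant regressor: the intercept absorbs everything
        nb = min(n_blocks, n_snp)
        bounds = _block_bounds(n_snp, nb)
        total = y.sum()
        per_block = np.array([
            (total - y[lo:hi].sum()) / (n_snp - (hi - lo))
            for lo, hi in zip(bounds[:-1], bounds[1:])])
        icpt = float(np.mean(y))
        se_icpt = np.sqrt((nb - 1) / nb *
                          ((per_block - per_block.mean()) ** 2).sum())
        return CrossTraitFit(intercept_xt=icpt, gencov=np.nan, rg=np.nan,
                             se_intercept=float(se_icpt), se_gencov=np.nan,
                             n_blocks=nb, n_snp=n_snp)

    fit1 = fit_univariate(z1 ** 2, n1, ld, n_blocks, chi2_max=None)
    fit2 = fit_univariate(z2 ** 2, n2, ld, n_blocks, chi2_max=None)
    h1 = float(np.clip(fit1.h2_obs, 0.0, 1.0))
    h2_ = float(np.clip(fit2.h2_obs, 0.0, 1.0))

    l2 = ld.l2
    lw = np.maximum(l2, 1.0)
    x = np.sqrt(n1 * n2) * l2 / M
    X = np.column_stack([np.ones(n_snp), x])
    w = np.ones(n_snp)
    coef = None
    for _ in range(3):
        coef, se, _ = _wls_jackknife(X, y, w, n_blocks)
        rho = float(np.clip(coef[1], -1.0, 1.0))
        icpt = float(np.clip(coef[0], -1.0, 1.0))
        a1 = 1.0 + n1 * h1 * lw / M
        a2 = 1.0 + n2 * h2_ * lw / M
        cross = np.sqrt(n1 * n2) * rho * lw / M + icpt
        w = 1.0 / ((a1 * a2 + cross ** 2) * lw)

    gencov = float(coef[1])
    rg = gencov / np.sqrt(fit1.h2_obs * fit2.h2_obs) \
        if fit1.h2_obs > 0 and fit2.h2_obs > 0 else np.nan
    if not np.isfinite(rg):
        logger.warning("rg undefined: a univariate h2_obs is non-positive")
    return CrossTraitFit(intercept_xt=float(coef[0]), gencov=gencov,
                         rg=float(rg), se_intercept=float(se[0]),
                         se_gencov=float(se[1]),
                         n_blocks=n_blocks, n_snp=n_snp)


def liability_scale(h2_obs: float, K: float, P: float) -> float:
    """Convert observed-scale heritability to the liability scale.

    ``K`` is the population prevalence of the (case) state and ``P``
    the case fraction of the study sample::

        h2_liab = h2_obs * K^2 (1-K)^2 / (P (1-P) phi(t)^2),
        t = Phi^-1(1 - K).
    """
    if not (0.0 < K < 1.0 and 0.0 < P < 1.0):
        raise LdscError("prevalences K, P must lie in (0, 1)")
    t = stats.norm.ppf(1.0 - K)
    phi_t = stats.norm.pdf(t)
    return h2_obs * K ** 2 * (1.0 - K) ** 2 / (P * (1.0 - P) * phi_t ** 2)
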