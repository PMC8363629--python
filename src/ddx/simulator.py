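"""Genotype-phenotype simulator for validating the differential test.

Simulates a population with two liability-threshold disorders sharing
part of their genetic basis, draws two overlapping case-control GWAS
from it, and compares the summary-statistics-based differential test
("inferred") against a direct case-vs-case GWAS of the same population
("real").

The default configuration: 300 independent biallelic SNPs with allele
frequencies Uniform(0.05, 0.95), disease prevalence K = 10% for both
disorders, SNP heritabilities 0.2 and 0.3 on the liability scale spread
over the causal SNPs, and four equal SNP classes — effects shared and
equal between the disorders, specific to A, specific to B, and null.
With these defaults the shared genetic component induces a liability
correlation of 0.1 and hence roughly 15% of the cases of one disorder
also qualify for the other; the ``comorbidity`` switch decides whether
such subjects keep both labels or are assigned to exactly one disorder.

Each case-control study takes all cases of its disorder plus screened
population controls (subjects with neither disorder); the two control
pools share a configurable fraction of subjects, mirroring the common
practice of re-using control panels.  Per-SNP logistic regressions
(IRLS, no covariates) produce the summary statistics.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from . import diffgwas, sumstats
from .prsforecast import effective_n

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions of the simulation harness.

    ``ncases`` is the *expected* number of cases of each disorder in the
    population, so the population size is ``ncases / K``.
    ``overlap_rate`` is the fraction of each study's sample shared with
    the other study (shared controls), ``P = N_shared / 2N``.
    ``class_fractions`` partitions the SNP panel into effects shared
    (equal on both disorders), A-specific, B-specific, and null.
    """

    n_snp: int = 300
    maf_range: tuple = (0.05, 0.95)
    ncases: int = 10_000
    K: float = 0.10
    h2_a: float = 0.2
    h2_b: float = 0.3
    overlap_rate: float = 0.15
    comorbidity: bool = False
    class_fractions: dict = field(default_factory=lambda: {
        "shared_equal": 0.25, "a_only": 0.25, "b_only": 0.25, "null": 0.25})
    allocation: str = "random"  # per-SNP effect variance: random | equal
    n_reps: int = 30
    seed: int = 0
    r_int_mode: str | float = "analytic"  # analytic | crosstrait | value
    gc: str = "none"

    def __post_init__(self):
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError("SNP class fractions must sum to 1")
        if not 0.0 < self.K < 1.0:
            raise SimulationError("prevalence K must lie in (0, 1)")
        if not 0.0 <= self.overlap_rate < 1.0:
            raise SimulationError("overlap rate must lie in [0, 1)")

    @property
    def ntotal(self) -> int:
        return int(round(self.ncases / self.K))


@dataclass
class Population:
    """Simulated cohort: genotypes, liabilities and disease states.

    ``status_a``/``status_b`` are the raw liability-threshold disease
    states; ``case_a``/``case_b`` are the study case pools after the
    comorbidity rule (identical to the raw states when comorbidity is
    allowed; restricted to single-disorder subjects otherwise).
    """

    cfg: SimConfig
    genotypes: np.ndarray  # (ntotal, n_snp) int8 allele counts
    maf: np.ndarray
    snp_class: np.ndarray  # labels per SNP
    beta_a: np.ndarray     # liability effects per standardized genotype
    beta_b: np.ndarray
    status_a: np.ndarray
    status_b: np.ndarray
    case_a: np.ndarray
    case_b: np.ndarray

    @property
    def comorbid_fraction_a(self) -> float:
        """Fraction of disorder-A subjects also qualifying for B."""
        na = int(self.status_a.sum())
        return float((self.status_a & self.status_b).sum()) / na if na else 0.0


def _allocate_effects(cfg: SimConfig, rng: np.random.Generator,
                      snp_class: np.ndarray):
    """Per-SNP liability effects (standardized-genotype scale).

    Shared SNPs receive identical effects on both disorders; each
    trait's effect variances sum exactly to its h2.  Under the default
    ``allocation="random"`` effects are Gaussian draws rescaled so the
    squared effects sum to h2 (heterogeneous per-SNP variances, the
    squared differential effects approximately chi-square distributed);
    ``"equal"`` gives every causal SNP of a trait the same squared
    effect.
    """
    shared = snp_class == "shared_equal"
    aonly = snp_class == "a_only"
    bonly = snp_class == "b_only"
    n_sh, n_a, n_b = int(shared.sum()), int(aonly.sum()), int(bonly.sum())

    if cfg.h2_a > 0 and n_sh + n_a == 0:
        raise SimulationError("h2_a > 0 but no causal SNPs for disorder A")
    if cfg.h2_b > 0 and n_sh + n_b == 0:
        raise SimulationError("h2_b > 0 but no causal SNPs for disorder B")

    n_snp = len(snp_class)
    beta_a = np.zeros(n_snp)
    beta_b = np.zeros(n_snp)
    signs = np.where(rng.random(n_snp) < 0.5, -1.0, 1.0)

    def _shares(k: int) -> np.ndarray:
        if cfg.allocation == "equal":
            return np.full(k, 1.0 / k)
        if cfg.allocation == "random":
            g = rng.standard_normal(k)
            return g ** 2 / (g ** 2).sum()
        raise SimulationError(f"unknown allocation {cfg.allocation!r}")

    var_a = np.zeros(n_snp)
    if n_sh + n_a:
        var_a[shared | aonly] = _shares(n_sh + n_a) * cfg.h2_a

    beta_a = signs * np.sqrt(var_a)
    beta_b[shared] = beta_a[shared]  # identical shared effects

    h2_b_resid = cfg.h2_b - float(var_a[shared].sum())
    if n_b == 0:
        if abs(h2_b_resid) > 1e-9:
            raise SimulationError(
                "no B-specific SNPs: h2_b must equal the shared "
                f"contribution {var_a[shared].sum():.4g}")
    else:
        if h2_b_resid < -1e-12:
            raise SimulationError(
                f"h2_b={cfg.h2_b} smaller than the variance already carried "
                f"by shared SNPs ({var_a[shared].sum():.4g})")
        beta_b[bonly] = signs[bonly] * np.sqrt(_shares(n_b) * max(h2_b_resid,
                                                                  0.0))
    return beta_a, beta_b


def simulate_population(cfg: SimConfig, rng: np.random.Generator) -> Population:
    """Draw genotypes and the two liability-threshold disease states."""
    n, m = cfg.ntotal, cfg.n_snp
    maf = rng.uniform(*cfg.maf_range, m)

    counts = {k: int(round(v * m)) for k, v in cfg.class_fractions.items()}
    drift = m - sum(counts.values())
    counts["null"] = counts.get("null", 0) + drift
    labels = np.concatenate([np.repeat(k, c) for k, c in counts.items()])
    snp_class = labels[rng.permutation(m)]

    beta_a, beta_b = _allocate_effects(cfg, rng, snp_class)

    # Binomial(2, maf) as two Bernoulli draws (much faster than the
    # generic binomial sampler for per-column probabilities)
    G = np.empty((n, m), np.int8)
    chunk = 200_000
    for lo in range(0, n, chunk):
        rows = G[lo:lo + chunk]
        np.add((rng.random(rows.shape) < maf).astype(np.int8),
               (rng.random(rows.shape) < maf), out=rows, casting="unsafe")

    sd = np.sqrt(2.0 * maf * (1.0 - maf))
    w_a = beta_a / sd
    w_b = beta_b / sd
    gen_a = np.empty(n)
    gen_b = np.empty(n)
    for lo in range(0, n, chunk):
        block = G[lo:lo + chunk].astype(np.float64)
        gen_a[lo:lo + chunk] = block @ w_a
        gen_b[lo:lo + chunk] = block @ w_b
    gen_a -= float(2.0 * maf @ w_a)
    gen_b -= float(2.0 * maf @ w_b)

    thr = stats.norm.ppf(1.0 - cfg.K)
    liab_a = gen_a + rng.normal(0.0, np.sqrt(1.0 - cfg.h2_a), n)
    liab_b = gen_b + rng.normal(0.0, np.sqrt(1.0 - cfg.h2_b), n)
    status_a = liab_a > thr
    status_b = liab_b > thr

    case_a = status_a.copy()
    case_b = status_b.copy()
    if not cfg.comorbidity:
        # cases with the other disorder are excluded, so each study's
        # case pool is its disorder's single-disorder subjects
        case_a &= ~status_b
        case_b &= ~status_a

    return Population(cfg=cfg, genotypes=G, maf=maf, snp_class=snp_class,
                      beta_a=beta_a, beta_b=beta_b,
                      status_a=status_a, status_b=status_b,
                      case_a=case_a, case_b=case_b)


def simulate_cohort_like(pop: Population, n_subjects: int,
                         rng: np.random.Generator) -> Population:
    """A fresh cohort drawn from the same genetic model (allele
    frequencies and true effects) as an existing population — e.g. an
    independent evaluation sample for a polygenic score."""
    cfg = dataclasses.replace(pop.cfg,
                              ncases=int(round(n_subjects * pop.cfg.K)))
    m = cfg.n_snp
    G = np.empty((n_subjects, m), np.int8)
    np.add((rng.random(G.shape) < pop.maf).astype(np.int8),
           (rng.random(G.shape) < pop.maf), out=G, casting="unsafe")
    sd = np.sqrt(2.0 * pop.maf * (1.0 - pop.maf))
    gen_a = G @ (pop.beta_a / sd) - float(2.0 * pop.maf @ (pop.beta_a / sd))
    gen_b = G @ (pop.beta_b / sd) - float(2.0 * pop.maf @ (pop.beta_b / sd))
    thr = stats.norm.ppf(1.0 - cfg.K)
    status_a = gen_a + rng.normal(0, np.sqrt(1 - cfg.h2_a), n_subjects) > thr
    status_b = gen_b + rng.normal(0, np.sqrt(1 - cfg.h2_b), n_subjects) > thr
    case_a, case_b = status_a.copy(), status_b.copy()
    if not cfg.comorbidity:
        case_a &= ~status_b
        case_b &= ~status_a
    return Population(cfg=cfg, genotypes=G, maf=pop.maf,
                      snp_class=pop.snp_class, beta_a=pop.beta_a,
                      beta_b=pop.beta_b, status_a=status_a,
                      status_b=status_b, case_a=case_a, case_b=case_b)


def logistic_gwas(G, y, chunk: int = 64, max_iter: int = 40,
                  tol: float = 1e-10):
    """Per-SNP logistic regression (intercept + allele count), vectorized.

    Newton/IRLS across SNP chunks.  Returns ``(beta, se, z, p)`` arrays
    on the per-allele log-odds scale.
    """
    G = np.asarray(G, np.float64)
    y = np.asarray(y, np.float64)
    n, m = G.shape
    ybar = y.mean()
    beta = np.empty(m)
    se = np.empty(m)
    for lo in range(0, m, chunk):
        Gc = G[:, lo:lo + chunk]
        G2 = Gc * Gc
        k = Gc.shape[1]
        a = np.full(k, logit(ybar))
        b = np.zeros(k)
        for _ in range(max_iter):
            p = expit(a[None, :] + Gc * b[None, :])
            r = y[:, None] - p
            W = p
            W *= 1.0 - p
            u1 = r.sum(axis=0)
            u2 = np.einsum("ij,ij->j", Gc, r)
            h11 = W.sum(axis=0)
            h12 = np.einsum("ij,ij->j", W, Gc)
            h22 = np.einsum("ij,ij->j", W, G2)
            det = h11 * h22 - h12 ** 2
            da = (h22 * u1 - h12 * u2) / det
            db = (h11 * u2 - h12 * u1) / det
            a += da
            b += db
            if max(np.abs(da).max(), np.abs(db).max()) < tol:
                break
        beta[lo:lo + chunk] = b
        se[lo:lo + chunk] = np.sqrt(h11 / det)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return beta, se, z, p


def _study_table(pop: Population, case_idx, ctrl_idx) -> pd.DataFrame:
    """Run the per-SNP logistic GWAS and format it in the sumstats dialect."""
    rows = np.concatenate([case_idx, ctrl_idx])
    y = np.concatenate([np.ones(len(case_idx)), np.zeros(len(ctrl_idx))])
    G = pop.genotypes[rows]
    beta, se, z, p = logistic_gwas(G, y)
    m = pop.cfg.n_snp
    return pd.DataFrame({
        "SNP": [f"rs{i + 1}" for i in range(m)],
        "CHR": 1,
        "BP": np.arange(1, m + 1) * 10_000,
        "A1": "A",
        "A2": "G",
        "BETA": beta, "SE": se, "P": p,
        "N": float(len(rows)),
        "N_CASE": float(len(case_idx)),
        "N_CONTROL": float(len(ctrl_idx)),
        "EAF": G.mean(axis=0) / 2.0,
    })


def expected_overlap_intercept(n_case1, n_ctrl1, n_case2, n_ctrl2,
                               n_shared_controls) -> float:
    """Null correlation of two studies' test statistics induced by
    shared controls.

    With case fractions ``P_i = n_case_i / n_i``::

        r = N_shared * sqrt(P1 P2 / ((1 - P1)(1 - P2))) / sqrt(n1 n2)

    This is the quantity the cross-trait LD-score-regression intercept
    estimates when the two phenotypes are otherwise independent.
    """
    n1 = n_case1 + n_ctrl1
    n2 = n_case2 + n_ctrl2
    p1, p2 = n_case1 / n1, n_case2 / n2
    return float(n_shared_controls *
                 np.sqrt(p1 * p2 / ((1.0 - p1) * (1.0 - p2))) /
                 np.sqrt(n1 * n2))


def build_casecontrol_studies(pop: Population, cfg: SimConfig,
                              rng: np.random.Generator):
    """Two overlapping case-control studies drawn from the population.

    Each study takes all its disorder's cases and ``2N - n_cases``
    screened controls (subjects with neither disorder), where ``N`` is
    the larger case count; the control pools share
    ``round(P * 2N)`` subjects.  Returns ``(study_a, study_b, report)``
    where the studies are sumstats-dialect DataFrames and the report
    records the realized overlap and its implied null test-statistic
    correlation.
    """
    case_a = np.flatnonzero(pop.case_a)
    case_b = np.flatnonzero(pop.case_b)
    neither = np.flatnonzero(~pop.status_a & ~pop.status_b)
    n_a, n_b = len(case_a), len(case_b)
    N = max(n_a, n_b)
    n_ctrl_a = 2 * N - n_a
    n_ctrl_b = 2 * N - n_b
    n_shared = int(round(cfg.overlap_rate * 2 * N))
    if n_shared > min(n_ctrl_a, n_ctrl_b):
        raise SimulationError(
            f"requested {n_shared} shared controls exceeds a control pool "
            f"({n_ctrl_a}, {n_ctrl_b})")
    needed = n_ctrl_a + n_ctrl_b - n_shared
    if needed > len(neither):
        raise SimulationError(
            f"need {needed} distinct controls but only {len(neither)} "
            "disorder-free subjects are available")

    perm = rng.permutation(neither)
    shared = perm[:n_shared]
    ua = perm[n_shared:n_ctrl_a]
    ub = perm[n_ctrl_a:n_ctrl_a + n_ctrl_b - n_shared]
    ctrl_a = np.concatenate([shared, ua])
    ctrl_b = np.concatenate([shared, ub])

    study_a = _study_table(pop, case_a, ctrl_a)
    study_b = _study_table(pop, case_b, ctrl_b)
    report = {
        "n_case_a": n_a, "n_ctrl_a": n_ctrl_a,
        "n_case_b": n_b, "n_ctrl_b": n_ctrl_b,
        "n_shared_controls": n_shared,
        "overlap_rate": n_shared / (2 * N),
        "r_int": expected_overlap_intercept(n_a, n_ctrl_a, n_b, n_ctrl_b,
                                            n_shared),
    }
    return study_a, study_b, report


def expected_logodds(beta_std: float, maf: float, K: float,
                     case_fraction: float) -> float:
    """Expected per-allele logistic slope in an ascertained case-control
    sample, for a SNP with liability effect ``beta_std`` per
    standardized genotype.

    Computed from the three genotype classes under Hardy-Weinberg:
    prospective risks follow the liability model, case-control sampling
    shifts the log-odds by a constant, and the slope is the
    information-weighted least-squares slope of the per-genotype
    log-odds on allele count.  Used as the "actual coefficient" against
    which estimated coefficients are judged.
    """
    g = np.array([0.0, 1.0, 2.0])
    w_pop = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])
    sd = np.sqrt(2.0 * maf * (1.0 - maf))
    x = (g - 2.0 * maf) / sd
    thr = stats.norm.ppf(1.0 - K)
    risk = stats.norm.cdf((beta_std * x - thr) /
                          np.sqrt(1.0 - beta_std ** 2))
    K_marg = float(w_pop @ risk)
    c = logit(case_fraction) - logit(K_marg)
    l_s = logit(risk) + c
    p_s = expit(l_s)
    w_s = w_pop * (case_fraction * risk / K_marg +
                   (1 - case_fraction) * (1 - risk) / (1 - K_marg))
    ww = w_s * p_s * (1 - p_s)
    gbar = float((ww @ g) / ww.sum())
    lbar = float((ww @ l_s) / ww.sum())
    return float((ww @ ((g - gbar) * (l_s - lbar))) /
                 (ww @ (g - gbar) ** 2))


@dataclass
class ReplicateResult:
    """All artifacts of one simulation replicate."""

    study_a: pd.DataFrame
    study_b: pd.DataFrame
    diff: pd.DataFrame          # differential test results
    gc_report: diffgwas.GcReport
    real: pd.DataFrame          # direct case-vs-case GWAS
    truth: pd.DataFrame
    overlap: dict
    r_int: float
    n_eff: float


def run_replicate(cfg: SimConfig, rng: np.random.Generator,
                  keep_population: bool = False):
    """Simulate one replicate: population, studies, differential test and
    the direct case-vs-case GWAS."""
    pop = simulate_population(cfg, rng)
    study_a, study_b, report = build_casecontrol_studies(pop, cfg, rng)

    pair = sumstats.harmonize(sumstats.SumstatTable(study_a),
                              sumstats.SumstatTable(study_b))
    if cfg.r_int_mode == "analytic":
        r_int = report["r_int"]
    elif cfg.r_int_mode == "crosstrait":
        from .ldsc import LdScoreTable, fit_crosstrait
        z1 = study_a["BETA"] / study_a["SE"]
        z2 = study_b["BETA"] / study_b["SE"]
        fit = fit_crosstrait(z1, z2, study_a["N"], study_b["N"],
                             LdScoreTable.flat_mode(cfg.n_snp))
        r_int = float(np.clip(fit.intercept_xt, -0.999, 0.999))
    else:
        r_int = float(cfg.r_int_mode)
    diff, gc_report = diffgwas.run_differential(pair, r_int=r_int, gc=cfg.gc)

    only_a = np.flatnonzero(pop.status_a & ~pop.status_b)
    only_b = np.flatnonzero(pop.status_b & ~pop.status_a)
    real = _study_table(pop, only_a, only_b)

    case_frac_a = report["n_case_a"] / (report["n_case_a"] + report["n_ctrl_a"])
    case_frac_b = report["n_case_b"] / (report["n_case_b"] + report["n_ctrl_b"])
    truth = pd.DataFrame({
        "SNP": study_a["SNP"],
        "class": pop.snp_class,
        "MAF": pop.maf,
        "BETA_LIAB_A": pop.beta_a,
        "BETA_LIAB_B": pop.beta_b,
        "BETA_LOGODDS_A": [expected_logodds(b, f, cfg.K, case_frac_a)
                           for b, f in zip(pop.beta_a, pop.maf)],
        "BETA_LOGODDS_B": [expected_logodds(b, f, cfg.K, case_frac_b)
                           for b, f in zip(pop.beta_b, pop.maf)],
        "DIFFERENTIAL_NULL": np.isin(pop.snp_class, ["shared_equal", "null"]),
        "R_INT_TRUE": report["r_int"],
    })
    n_eff = effective_n(len(only_a), len(only_b))
    result = ReplicateResult(study_a=study_a, study_b=study_b, diff=diff,
                             gc_report=gc_report, real=real, truth=truth,
                             overlap=report, r_int=r_int, n_eff=n_eff)
    if keep_population:
        return result, pop
    return result


@dataclass
class SimMetrics:
    """Pooled agreement and error-rate metrics across replicates."""

    corr_beta: float
    corr_se: float
    rmse_beta: float
    rmse_se: float
    power_inferred: float
    t1e_inferred: float
    power_real: float
    t1e_real: float
    n_reps: int
    n_snp_rep: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_validation(cfg: SimConfig, alpha: float = 0.05) -> SimMetrics:
    """Run ``cfg.n_reps`` replicates and pool the validation metrics.

    Correlations and RMSEs compare the inferred differential estimates
    with the direct case-vs-case GWAS over all SNPs x replicates.
    Power is the rejection rate (raw p < alpha) over SNPs with a
    nonzero true differential effect; type-I error is the rejection
    rate over differential-null SNPs (shared-effect and null classes).
    """
    if cfg.n_reps < 1:
        raise SimulationError("n_reps must be >= 1")
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_reps)
    inf_b, inf_s, inf_p = [], [], []
    real_b, real_s, real_p = [], [], []
    is_null = []
    for child in children:
        rng = np.random.default_rng(child)
        rep = run_replicate(cfg, rng)
        merged = rep.diff.merge(rep.real, on="SNP", suffixes=("", "_REAL")) \
                         .merge(rep.truth, on="SNP")
        inf_b.append(merged["BETA13"].to_numpy())
        inf_s.append(merged["SE13"].to_numpy())
        inf_p.append(merged["P"].to_numpy())
        real_b.append(merged["BETA"].to_numpy())
        real_s.append(merged["SE"].to_numpy())
        real_p.append(merged["P_REAL"].to_numpy())
        is_null.append(merged["DIFFERENTIAL_NULL"].to_numpy())

    inf_b, inf_s, inf_p = map(np.concatenate, (inf_b, inf_s, inf_p))
    real_b, real_s, real_p = map(np.concatenate, (real_b, real_s, real_p))
    is_null = np.concatenate(is_null)

    def _corr(x, y):
        return float(np.corrcoef(x, y)[0, 1])

    power_inf = float((inf_p[~is_null] < alpha).mean()) if (~is_null).any() \
        else float("nan")
    power_real = float((real_p[~is_null] < alpha).mean()) if (~is_null).any() \
        else float("nan")
    return SimMetrics(
        corr_beta=_corr(inf_b, real_b),
        corr_se=_corr(inf_s, real_s),
        rmse_beta=float(np.sqrt(np.mean((inf_b - real_b) ** 2))),
        rmse_se=float(np.sqrt(np.mean((inf_s - real_s) ** 2))),
        power_inferred=power_inf,
        t1e_inferred=float((inf_p[is_null] < alpha).mean()),
        power_real=power_real,
        t1e_real=float((real_p[is_null] < alpha).mean()),
        n_reps=cfg.n_reps,
        n_snp_rep=len(is_null),
    )


def evaluate_prs(pop: Population, weights) -> float:
    """Empirical AUC of a per-allele-weighted score for discriminating
    A-only from B-only subjects of a cohort (A-only ranked as cases)."""
    only_a = pop.genotypes[pop.status_a & ~pop.status_b].astype(float)
    only_b = pop.genotypes[pop.status_b & ~pop.status_a].astype(float)
    if not len(only_a) or not len(only_b):
        raise SimulationError("cohort lacks single-disorder subjects")
    w = np.asarray(weights, float)
    s_a = only_a @ w
    s_b = only_b @ w
    ranks = stats.rankdata(np.concatenate([s_a, s_b]))
    n1, n2 = len(s_a), len(s_b)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def generate_sumstats_fixture(cfg: SimConfig, rng: np.random.Generator,
                              outdir) -> dict:
    """Write one replicate's study summary statistics and truth table as
    TSV files usable as end-to-end test inputs.  Returns the paths."""
    import os

    rep = run_replicate(cfg, rng)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "study_a": os.path.join(outdir, "study_a.tsv"),
        "study_b": os.path.join(outdir, "study_b.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    rep.study_a.to_csv(paths["study_a"], sep="\t", index=False)
    rep.study_b.to_csv(paths["study_b"], sep="\t", index=False)
    rep.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
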