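"""Reading, validation and harmonization of GWAS summary statistics.

A summary-statistics table carries, per biallelic SNP, the estimated
log-odds ratio per effect allele (``BETA``), its standard error, a
two-sided p-value and the study sample sizes.  Before two studies can be
contrasted SNP-by-SNP they must share a variant set and an effect-allele
convention; :func:`harmonize` aligns the second study to the first,
flipping effect signs for swapped alleles and complementing alleles that
were reported on the opposite strand.  Strand-ambiguous (A/T, C/G)
variants are dropped by default because their orientation cannot be
resolved without allele-frequency information.

Continuous traits analysed with linear regression can be mapped onto a
case-control scale with :func:`dichotomize_continuous`, which treats the
top ``q`` fraction of the phenotype distribution as cases under a
threshold model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of the internal sumstats dialect
STANDARD_COLUMNS = [
    "SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P",
    "N", "N_CASE", "N_CONTROL", "EAF",
]

#: default mapping from standard names to common header spellings
DEFAULT_COLUMN_MAP = {
    "snp": "SNP", "chrom": "CHR", "pos": "BP",
    "effect_allele": "A1", "other_allele": "A2",
    "beta": "BETA", "se": "SE", "pval": "P",
    "n_total": "N", "n_case": "N_CASE", "n_control": "N_CONTROL",
    "eaf": "EAF",
}

ALIGN_ACTIONS = (
    "kept", "sign_flipped", "strand_flipped",
    "dropped_palindromic", "dropped_mismatch", "dropped_missing",
)


@dataclass
class SumstatTable:
    """A validated table of per-SNP association statistics.

    ``df`` uses the canonical columns of :data:`STANDARD_COLUMNS`
    (``N_CASE``/``N_CONTROL``/``EAF`` may be absent).  ``drop_log``
    records every input row removed during validation together with the
    reason.
    """

    df: pd.DataFrame
    drop_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["SNP", "reason"])
    )

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class HarmonizedPair:
    """Two studies joined on SNP ID and aligned to a common effect allele.

    ``df`` holds one row per retained SNP with ``*_T1`` / ``*_T2``
    suffixed statistics, the shared allele pair (trait 1's orientation)
    and the per-SNP ``ACTION`` taken during alignment.  ``drop_log``
    accounts for every input SNP that did not survive the join.
    """

    df: pd.DataFrame
    drop_log: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path, drop_log_path=None) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep="NA")
        if drop_log_path is not None:
            self.drop_log.to_csv(drop_log_path, sep="\t", index=False)


class SumstatError(ValueError):
    """Fatal problem with a summary-statistics input."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise SumstatError(msg)


def read_sumstats(
    path,
    column_map: dict | None = None,
    effect_scale: str = "logodds",
    n_total: float | None = None,
    n_case: float | None = None,
    n_control: float | None = None,
    sep: str | None = None,
) -> SumstatTable:
    """Read a whitespace/tab-delimited summary-statistics file.

    Parameters
    ----------
    path
        Text file with a header row; gzip is handled transparently by
        pandas.
    column_map
        Mapping from standard field names (``snp``, ``chrom``, ``pos``,
        ``effect_allele``, ``other_allele``, ``beta``, ``se``, ``pval``,
        ``n_total``, ``n_case``, ``n_control``, ``eaf``) to the column
        names used in the file.  Unspecified fields fall back to the
        conventional spellings in :data:`DEFAULT_COLUMN_MAP`.
    effect_scale
        ``"logodds"`` (``beta`` column holds log-OR), ``"oddsratio"``
        (converted via ``beta = ln(OR)``) or ``"zscore"`` (``beta``
        holds a z-score; SE is set to 1 so that ``beta/se`` is the test
        statistic).  OR columns are never auto-detected from value
        ranges; the scale must be declared.
    n_total, n_case, n_control
        Fixed sample sizes used when the file has no such columns.

    Records failing validation (non-positive SE or OR, invalid alleles,
    out-of-range p or EAF) are dropped and logged, never silently
    altered.  Row order is preserved.
    """
    _require(effect_scale in ("logodds", "oddsratio", "zscore"),
             f"unknown effect_scale {effect_scale!r}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path, sep=sep if sep is not None else r"\s+")
    mandatory = ["snp", "effect_allele", "other_allele", "beta"]
    if effect_scale != "zscore":
        mandatory.append("se")
    for key in mandatory:
        _require(cmap[key] in raw.columns,
                 f"mandatory column {cmap[key]!r} ({key}) not found in {path}")

    df = pd.DataFrame(index=raw.index)
    for key, std in [("snp", "SNP"), ("chrom", "CHR"), ("pos", "BP"),
                     ("effect_allele", "A1"), ("other_allele", "A2"),
                     ("beta", "BETA"), ("se", "SE"), ("pval", "P"),
                     ("n_total", "N"), ("n_case", "N_CASE"),
                     ("n_control", "N_CONTROL"), ("eaf", "EAF")]:
        if cmap[key] in raw.columns:
            df[std] = raw[cmap[key]]
    df["SNP"] = df["SNP"].astype(str)
    for col in ("A1", "A2"):
        df[col] = df[col].astype(str).str.upper()

    if n_case is not None and "N_CASE" not in df:
        df["N_CASE"] = float(n_case)
    if n_control is not None and "N_CONTROL" not in df:
        df["N_CONTROL"] = float(n_control)
    if "N" not in df:
        if n_total is not None:
            df["N"] = float(n_total)
        elif {"N_CASE", "N_CONTROL"} <= set(df.columns):
            df["N"] = df["N_CASE"] + df["N_CONTROL"]
        else:
            raise SumstatError("no sample-size columns and no fixed N supplied")

    drops = []

    def _drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        if mask.any():
            drops.append(pd.DataFrame(
                {"SNP": df.loc[mask, "SNP"], "reason": reason}))
            df = df.loc[~mask]

    if effect_scale == "oddsratio":
        _drop(~(df["BETA"] > 0), "nonpositive_or")
        df = df.assign(BETA=np.log(df["BETA"].to_numpy(float)))
    elif effect_scale == "zscore":
        if "SE" not in df:
            df["SE"] = 1.0

    _drop(df["BETA"].isna(), "missing_beta")
    _drop(~(df["SE"] > 0), "nonpositive_se")
    _drop(~df["A1"].isin(VALID_ALLELES) | ~df["A2"].isin(VALID_ALLELES)
          | (df["A1"] == df["A2"]), "invalid_alleles")
    if "P" in df:
        bad_p = df["P"].notna() & ~((df["P"] > 0) & (df["P"] <= 1))
        _drop(bad_p, "invalid_pval")
    else:
        df["P"] = 2.0 * stats.norm.sf(np.abs(df["BETA"] / df["SE"]))
    if "EAF" in df:
        bad = df["EAF"].notna() & ~df["EAF"].between(0.0, 1.0)
        _drop(bad, "invalid_eaf")

    # warn-only cross-checks
    with np.errstate(divide="ignore"):
        z = np.abs(df["BETA"].to_numpy(float) / df["SE"].to_numpy(float))
        p_implied = 2.0 * stats.norm.sf(z)
    p_obs = df["P"].to_numpy(float)
    ok = np.isfinite(p_obs) & (p_obs > 0) & (p_implied > 0)
    if ok.any():
        off = np.abs(np.log10(p_obs[ok]) - np.log10(p_implied[ok])) > 1.0
        if off.any():
            logger.warning(
                "%d record(s) have p-values inconsistent with beta/se "
                "by >1 order of magnitude", int(off.sum()))
    if {"N", "N_CASE", "N_CONTROL"} <= set(df.columns):
        full = df[["N", "N_CASE", "N_CONTROL"]].notna().all(axis=1)
        bad = full & (df["N_CASE"] + df["N_CONTROL"] != df["N"])
        if bad.any():
            logger.warning("%d record(s) have N_CASE + N_CONTROL != N",
                           int(bad.sum()))

    drop_log = (pd.concat(drops, ignore_index=True) if drops
                else pd.DataFrame(columns=["SNP", "reason"]))
    if len(drop_log):
        logger.info("read_sumstats: dropped %d of %d records",
                    len(drop_log), len(raw))
    cols = [c for c in STANDARD_COLUMNS if c in df.columns]
    return SumstatTable(df[cols].reset_index(drop=True), drop_log)


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return ((a1 == "A") & (a2 == "T")) | ((a1 == "T") & (a2 == "A")) | \
           ((a1 == "C") & (a2 == "G")) | ((a1 == "G") & (a2 == "C"))


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.map(COMPLEMENT)


def harmonize(
    t1: SumstatTable,
    t2: SumstatTable,
    palindromic_policy: str = "drop",
    eaf_window: float = 0.08,
    check_positions: bool = True,
) -> HarmonizedPair:
    """Join two studies on SNP ID and align trait 2 to trait 1's alleles.

    Trait 1's effect-allele orientation wins.  Where trait 2 reports the
    allele pair swapped, its beta sign is flipped and its EAF
    complemented; where its alleles are the strand complement of trait
    1's, they are complemented first.  Strand-ambiguous A/T and C/G
    variants are dropped under ``palindromic_policy="drop"``; under
    ``"keep_if_eaf_informative"`` they are retained only when both
    studies report an EAF outside ``[0.5 - eaf_window, 0.5 + eaf_window]``
    (the minor allele is then assumed to match between studies and
    trait 2 is oriented by frequency side).

    Every input SNP appears exactly once: either in the pair or in the
    drop log.
    """
    _require(palindromic_policy in ("drop", "keep_if_eaf_informative"),
             f"unknown palindromic_policy {palindromic_policy!r}")

    d1 = t1.df.set_index("SNP", drop=False)
    d2 = t2.df.set_index("SNP", drop=False)
    _require(d1.index.is_unique and d2.index.is_unique,
             "duplicate SNP IDs; deduplicate before harmonizing")

    common = d1.index.intersection(d2.index)
    drops = []
    for name, d in (("t1", d1), ("t2", d2)):
        missing = d.index.difference(common)
        if len(missing):
            drops.append(pd.DataFrame(
                {"SNP": missing, "reason": "dropped_missing", "table": name}))

    a = d1.loc[common].reset_index(drop=True)
    b = d2.loc[common].reset_index(drop=True)

    if check_positions and {"CHR", "BP"} <= set(a.columns) & set(b.columns):
        pos_mismatch = (a["CHR"].astype(str) != b["CHR"].astype(str)) | \
                       (a["BP"] != b["BP"])
        if pos_mismatch.any():
            logger.warning("%d SNP(s) joined on ID have inconsistent "
                           "positions between studies", int(pos_mismatch.sum()))

    b = b.copy()
    same = (b["A1"] == a["A1"]) & (b["A2"] == a["A2"])
    swap = (b["A1"] == a["A2"]) & (b["A2"] == a["A1"])
    b_c1, b_c2 = _complement(b["A1"]), _complement(b["A2"])
    comp = (b_c1 == a["A1"]) & (b_c2 == a["A2"])
    comp_swap = (b_c1 == a["A2"]) & (b_c2 == a["A1"])
    pal = _is_palindromic(a["A1"], a["A2"])

    action = pd.Series("dropped_mismatch", index=a.index)
    # For palindromic SNPs "same" and "comp_swap" (or "swap" and "comp")
    # coincide; orientation is decided by EAF below, not by allele labels.
    action[same & ~pal] = "kept"
    action[swap & ~pal] = "sign_flipped"
    action[comp & ~pal] = "strand_flipped"
    action[comp_swap & ~pal] = "sign_flipped"  # strand flip + swap

    flip_sign = (swap | comp_swap) & ~pal

    if palindromic_policy == "drop":
        action[pal] = "dropped_palindromic"
    else:
        have_eaf = ("EAF" in a.columns and "EAF" in b.columns)
        eaf1 = a["EAF"] if have_eaf else pd.Series(np.nan, index=a.index)
        eaf2 = b["EAF"] if have_eaf else pd.Series(np.nan, index=a.index)
        informative = (np.abs(eaf1 - 0.5) > eaf_window) & \
                      (np.abs(eaf2 - 0.5) > eaf_window)
        informative = informative.fillna(False) & (same | swap | comp | comp_swap)
        same_side = ((eaf1 - 0.5) * (eaf2 - 0.5)) > 0
        action[pal] = "dropped_palindromic"
        action[pal & informative & same_side] = "kept"
        pal_flip = pal & informative & ~same_side
        action[pal_flip] = "sign_flipped"
        flip_sign = flip_sign | pal_flip

    kept_mask = ~action.str.startswith("dropped")
    sign = np.where(flip_sign, -1.0, 1.0)
    b["BETA"] = b["BETA"].to_numpy(float) * sign
    if "EAF" in b.columns:
        eaf = b["EAF"].to_numpy(float)
        b["EAF"] = np.where(flip_sign, 1.0 - eaf, eaf)
    b["A1"], b["A2"] = a["A1"], a["A2"]

    if (~kept_mask).any():
        drops.append(pd.DataFrame({
            "SNP": a.loc[~kept_mask, "SNP"],
            "reason": action[~kept_mask],
            "table": "both",
        }))

    stat_cols = [c for c in ("BETA", "SE", "P", "N", "N_CASE", "N_CONTROL",
                             "EAF") if c in a.columns and c in b.columns]
    shared_cols = [c for c in ("SNP", "CHR", "BP", "A1", "A2")
                   if c in a.columns]
    out = a.loc[kept_mask, shared_cols].copy()
    for c in stat_cols:
        out[f"{c}_T1"] = a.loc[kept_mask, c]
        out[f"{c}_T2"] = b.loc[kept_mask, c]
    out["ACTION"] = action[kept_mask]

    drop_log = (pd.concat(drops, ignore_index=True) if drops
                else pd.DataFrame(columns=["SNP", "reason", "table"]))
    return HarmonizedPair(out.reset_index(drop=True), drop_log)


def dichotomize_continuous(t: SumstatTable, q: float = 0.20) -> SumstatTable:
    """Convert linear-scale statistics of a standardized continuous trait
    to case-control scale, treating the top ``q`` fraction as cases.

    Under a threshold model with cut-point ``T = Phi^-1(1 - q)`` the
    per-allele log-odds effect corresponding to a small linear effect
    ``beta_cont`` is ``beta_cont * phi(T) / (q (1 - q))``, and the
    asymptotic z-score of the dichotomized analysis is
    ``z_cont * phi(T) / sqrt(q (1 - q))``.  SE and p are recomputed from
    the converted beta and z, and effective case/control counts are
    ``q N`` and ``(1 - q) N``.
    """
    _require(0.0 < q < 1.0, "top fraction q must be in (0, 1)")
    T = stats.norm.ppf(1.0 - q)
    phi_t = stats.norm.pdf(T)
    beta_factor = phi_t / (q * (1.0 - q))
    z_factor = phi_t / np.sqrt(q * (1.0 - q))

    df = t.df.copy()
    beta = df["BETA"].to_numpy(float)
    se = df["SE"].to_numpy(float)
    z_bin = (beta / se) * z_factor
    df["BETA"] = beta * beta_factor
    with np.errstate(divide="ignore", invalid="ignore"):
        se_bin = np.where(z_bin != 0.0, df["BETA"] / z_bin,
                          se * beta_factor / z_factor)
    df["SE"] = se_bin
    df["P"] = 2.0 * stats.norm.sf(np.abs(z_bin))
    n = df["N"].to_numpy(float)
    df["N_CASE"] = q * n
    df["N_CONTROL"] = (1.0 - q) * n
    cols = [c for c in STANDARD_COLUMNS if c in df.columns]
    return SumstatTable(df[cols], t.drop_log.copy())
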