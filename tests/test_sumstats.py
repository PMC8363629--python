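"""Reading, harmonization and continuous-trait dichotomization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ddx.sumstats import (SumstatError, SumstatTable, dichotomize_continuous,
                          harmonize, read_sumstats)

from conftest import make_sumstats


def _write(tmp_path, df, name="ss.tsv"):
    path = tmp_path / name
    df.to_csv(path, sep="\t", index=False)
    return path


class TestReadSumstats:
    def test_odds_ratio_conversion_and_validation(self, tmp_path):
        df = pd.DataFrame({
            "SNP": ["rs1", "rs2", "rs3", "rs4"],
            "A1": ["A", "C", "G", "T"],
            "A2": ["G", "T", "A", "C"],
            "OR": [1.0, 1.105170918, 0.5, 1.2],
            "SE": [0.02, 0.02, 0.03, 0.0],
            "P": [1.0, 1e-6, 0.01, 0.5],
            "N": [1000.0] * 4,
        })
        t = read_sumstats(_write(tmp_path, df), column_map={"beta": "OR"},
                          effect_scale="oddsratio")
        assert len(t) == 3
        assert t.df["BETA"].iloc[0] == 0.0          # OR = 1 is the null
        assert t.df["BETA"].iloc[1] == pytest.approx(0.1, abs=1e-9)
        assert t.df["BETA"].iloc[2] == pytest.approx(np.log(0.5))
        assert list(t.drop_log["reason"]) == ["nonpositive_se"]
        assert list(t.drop_log["SNP"]) == ["rs4"]

    def test_nonpositive_or_dropped(self, tmp_path):
        df = pd.DataFrame({"SNP": ["rs1", "rs2"], "A1": ["A", "A"],
                           "A2": ["G", "G"], "OR": [-1.0, 1.1],
                           "SE": [0.02, 0.02], "N": [100.0, 100.0]})
        t = read_sumstats(_write(tmp_path, df), column_map={"beta": "OR"},
                          effect_scale="oddsratio")
        assert len(t) == 1
        assert list(t.drop_log["reason"]) == ["nonpositive_or"]

    def test_missing_mandatory_column_is_fatal(self, tmp_path):
        df = pd.DataFrame({"SNP": ["rs1"], "A1": ["A"], "A2": ["G"],
                           "SE": [0.1], "N": [10.0]})
        with pytest.raises(SumstatError, match="BETA"):
            read_sumstats(_write(tmp_path, df))

    def test_fixed_n_and_missing_p_recomputed(self, tmp_path):
        df = pd.DataFrame({"SNP": ["rs1"], "A1": ["A"], "A2": ["G"],
                           "BETA": [0.1], "SE": [0.05]})
        t = read_sumstats(_write(tmp_path, df), n_total=5000)
        assert t.df["N"].iloc[0] == 5000
        assert t.df["P"].iloc[0] == pytest.approx(2 * stats.norm.sf(2.0))

    def test_invalid_alleles_dropped(self, tmp_path):
        df = pd.DataFrame({"SNP": ["rs1", "rs2", "rs3"],
                           "A1": ["A", "I", "G"], "A2": ["A", "D", "C"],
                           "BETA": [0.1] * 3, "SE": [0.05] * 3,
                           "N": [100.0] * 3})
        t = read_sumstats(_write(tmp_path, df))
        assert list(t.df["SNP"]) == ["rs3"]
        assert set(t.drop_log["reason"]) == {"invalid_alleles"}

    def test_gzip_transparent(self, tmp_path):
        df = pd.DataFrame({"SNP": ["rs1"], "A1": ["A"], "A2": ["G"],
                           "BETA": [0.1], "SE": [0.05], "N": [100.0]})
        path = tmp_path / "ss.tsv.gz"
        df.to_csv(path, sep="\t", index=False)
        assert len(read_sumstats(path)) == 1


def _pair_tables(rows1, rows2):
    def mk(rows):
        df = pd.DataFrame(rows, columns=["SNP", "A1", "A2", "BETA", "EAF"])
        df["CHR"], df["BP"] = 1, np.arange(1, len(df) + 1) * 1000
        df["SE"], df["P"], df["N"] = 0.02, 0.5, 1000.0
        return SumstatTable(df)
    return mk(rows1), mk(rows2)


class TestHarmonize:
    @pytest.mark.parametrize("t2_alleles,t2_beta,action,out_beta", [
        (("A", "G"), 0.07, "kept", 0.07),
        (("G", "A"), -0.10, "sign_flipped", 0.10),     # swapped alleles
        (("T", "C"), 0.07, "strand_flipped", 0.07),    # strand complement
        (("C", "T"), 0.07, "sign_flipped", -0.07),     # complement + swap
    ])
    def test_allele_alignment(self, t2_alleles, t2_beta, action, out_beta):
        t1, t2 = _pair_tables([("rs1", "A", "G", 0.10, 0.3)],
                              [("rs1", *t2_alleles, t2_beta, 0.3)])
        pair = harmonize(t1, t2)
        assert len(pair) == 1
        row = pair.df.iloc[0]
        assert row["ACTION"] == action
        assert (row["A1"], row["A2"]) == ("A", "G")
        assert row["BETA_T2"] == pytest.approx(out_beta)

    def test_palindromic_dropped_by_default(self):
        t1, t2 = _pair_tables([("rs1", "A", "T", 0.05, 0.2)],
                              [("rs1", "A", "T", 0.05, 0.2)])
        pair = harmonize(t1, t2)
        assert len(pair) == 0
        assert list(pair.drop_log["reason"]) == ["dropped_palindromic"]

    def test_mismatch_and_missing(self):
        t1, t2 = _pair_tables(
            [("rs1", "A", "G", 0.1, 0.3), ("rs2", "A", "G", 0.1, 0.3)],
            [("rs1", "A", "C", 0.1, 0.3), ("rs3", "A", "G", 0.1, 0.3)])
        pair = harmonize(t1, t2)
        assert len(pair) == 0
        reasons = dict(zip(pair.drop_log["SNP"], pair.drop_log["reason"]))
        assert reasons["rs1"] == "dropped_mismatch"
        assert reasons["rs2"] == "dropped_missing"
        assert reasons["rs3"] == "dropped_missing"

    @pytest.mark.parametrize("eaf1,eaf2,kept,flipped", [
        (0.2, 0.25, True, False),   # informative, same side
        (0.2, 0.75, True, True),    # informative, opposite side: flip
        (0.48, 0.2, False, False),  # trait 1 frequency uninformative
    ])
    def test_palindromic_eaf_policy(self, eaf1, eaf2, kept, flipped):
        t1, t2 = _pair_tables([("rs1", "A", "T", 0.05, eaf1)],
                              [("rs1", "A", "T", 0.04, eaf2)])
        pair = harmonize(t1, t2, palindromic_policy="keep_if_eaf_informative")
        assert (len(pair) == 1) == kept
        if kept:
            expected = -0.04 if flipped else 0.04
            assert pair.df["BETA_T2"].iloc[0] == pytest.approx(expected)

    def test_idempotent(self, rng):
        t1 = make_sumstats(30, rng)
        t2 = make_sumstats(30, rng)
        first = harmonize(t1, t2)

        def tables_from(pair):
            cols = ["SNP", "CHR", "BP", "A1", "A2"]
            a = pair.df[cols].copy()
            b = pair.df[cols].copy()
            for c in ("BETA", "SE", "P", "N", "N_CASE", "N_CONTROL", "EAF"):
                a[c] = pair.df[f"{c}_T1"]
                b[c] = pair.df[f"{c}_T2"]
            return SumstatTable(a), SumstatTable(b)

        second = harmonize(*tables_from(first))
        assert (second.df["ACTION"] == "kept").all()
        pd.testing.assert_frame_equal(
            first.df.drop(columns="ACTION"),
            second.df.drop(columns="ACTION"), check_dtype=False)

    def test_sign_symmetry(self, rng):
        """Swapping one study's allele labels (and beta sign, EAF) is a
        pure relabeling and must not change the harmonized result."""
        t1 = make_sumstats(30, rng)
        t2 = make_sumstats(30, rng)
        flipped = t2.df.copy()
        flipped[["A1", "A2"]] = flipped[["A2", "A1"]].to_numpy()
        flipped["BETA"] = -flipped["BETA"]
        flipped["EAF"] = 1.0 - flipped["EAF"]
        p1 = harmonize(t1, t2)
        p2 = harmonize(t1, SumstatTable(flipped))
        pd.testing.assert_frame_equal(
            p1.df.drop(columns="ACTION"), p2.df.drop(columns="ACTION"),
            check_dtype=False)


class TestDichotomize:
    @pytest.mark.parametrize("q,factor", [
        (0.2, stats.norm.pdf(stats.norm.ppf(0.8)) / 0.16),
        (0.5, stats.norm.pdf(0.0) / 0.25),  # = 1.5958
    ])
    def test_beta_scale_factor(self, q, factor):
        t = make_sumstats(5, seed=3)
        out = dichotomize_continuous(t, q=q)
        np.testing.assert_allclose(out.df["BETA"], t.df["BETA"] * factor,
                                   rtol=1e-12)
        if q == 0.5:
            assert factor == pytest.approx(1.5958, abs=1e-4)

    @pytest.mark.parametrize("q", [0.05, 0.2, 0.5, 0.8])
    def test_z_ratio_identity(self, q):
        """z_bin / z_cont = phi(T) / sqrt(q (1 - q)) for every q."""
        t = make_sumstats(10, seed=4)
        out = dichotomize_continuous(t, q=q)
        z_cont = t.df["BETA"] / t.df["SE"]
        z_bin = out.df["BETA"] / out.df["SE"]
        T = stats.norm.ppf(1 - q)
        expected = stats.norm.pdf(T) / np.sqrt(q * (1 - q))
        np.testing.assert_allclose(z_bin / z_cont, expected, rtol=1e-9)

    def test_null_maps_to_null(self):
        t = make_sumstats(3, seed=5)
        t.df["BETA"] = 0.0
        out = dichotomize_continuous(t, q=0.2)
        assert (out.df["BETA"] == 0).all()
        assert (out.df["P"] == 1.0).all()

    def test_case_counts(self):
        t = make_sumstats(3, seed=6)
        out = dichotomize_continuous(t, q=0.2)
        assert (out.df["N_CASE"] == 0.2 * t.df["N"]).all()
        assert (out.df["N_CONTROL"] == 0.8 * t.df["N"]).all()

    def test_invalid_fraction_fatal(self):
        with pytest.raises(SumstatError):
            dichotomize_continuous(make_sumstats(3), q=1.5)

    def test_logistic_regression_oracle(self, rng):
        """A standardized trait with per-allele effect 0.02, dichotomized
        at the top 20%, must yield a logistic slope matching the
        threshold-model conversion within 5%."""
        n = 1_000_000
        maf = 0.3
        beta_cont = 0.02
        x = rng.binomial(2, maf, n).astype(float)
        e_sd = np.sqrt(1.0 - beta_cont ** 2 * 2 * maf * (1 - maf))
        y = beta_cont * x + rng.normal(0, e_sd, n)
        case = (y >= np.quantile(y, 0.8)).astype(float)

        import statsmodels.api as sm
        fit = sm.Logit(case, sm.add_constant(x)).fit(disp=0)
        slope = fit.params[1]

        t = make_sumstats(1, seed=7)
        t.df.loc[:, ["BETA", "SE"]] = [[beta_cont, 0.001]]
        expected = dichotomize_continuous(t, q=0.2).df["BETA"].iloc[0]
        assert expected == pytest.approx(0.0350, abs=2e-4)
        assert slope == pytest.approx(expected, rel=0.05)
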