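"""Population simulator, overlapping case-control studies and the
validation harness."""

import numpy as np
import pandas as pd
import pytest

from ddx.simulator import (Population, SimConfig, SimulationError,
                           build_casecontrol_studies, evaluate_prs,
                           expected_logodds, expected_overlap_intercept,
                           generate_sumstats_fixture, logistic_gwas,
                           run_replicate, simulate_population)
from ddx.sumstats import read_sumstats

SMALL = dict(ncases=1000, n_snp=100, n_reps=1)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestSimConfig:
    def test_population_size_follows_prevalence(self):
        assert SimConfig(ncases=10_000, K=0.1).ntotal == 100_000
        assert SimConfig(ncases=9_999, K=0.1).ntotal == 99_990

    def test_invalid_fractions_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(class_fractions={"shared_equal": 0.5, "a_only": 0.1,
                                       "b_only": 0.1, "null": 0.1})

    def test_infeasible_heritability_rejected(self):
        cfg = SimConfig(h2_a=0.3, h2_b=0.05, allocation="equal", **SMALL)
        with pytest.raises(SimulationError, match="h2_b"):
            simulate_population(cfg, _rng())


class TestSimulatePopulation:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(**SMALL)
        a = simulate_population(cfg, _rng(42))
        b = simulate_population(cfg, _rng(42))
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.status_a, b.status_a)
        np.testing.assert_allclose(a.beta_b, b.beta_b)

    def test_heritability_budget_and_shared_effects(self):
        cfg = SimConfig(**SMALL)
        pop = simulate_population(cfg, _rng(1))
        assert np.sum(pop.beta_a ** 2) == pytest.approx(cfg.h2_a)
        assert np.sum(pop.beta_b ** 2) == pytest.approx(cfg.h2_b)
        sh = pop.snp_class == "shared_equal"
        np.testing.assert_allclose(pop.beta_a[sh], pop.beta_b[sh])
        null = pop.snp_class == "null"
        assert (pop.beta_a[null] == 0).all() and (pop.beta_b[null] == 0).all()

    def test_realized_prevalence_matches_K(self):
        """Disease states follow the liability threshold: pooled
        prevalence within 3 binomial SEs of K."""
        cfg = SimConfig(ncases=2000, n_snp=100, K=0.1)
        hits_a = hits_b = total = 0
        for seed in range(8):
            pop = simulate_population(cfg, _rng(seed))
            hits_a += pop.status_a.sum()
            hits_b += pop.status_b.sum()
            total += cfg.ntotal
        se3 = 3 * np.sqrt(0.1 * 0.9 / total)
        assert hits_a / total == pytest.approx(0.1, abs=se3)
        assert hits_b / total == pytest.approx(0.1, abs=se3)

    def test_comorbid_fraction_near_fifteen_percent(self):
        """The default shared-effect fraction induces a liability
        correlation of ~0.1 and hence ~15% comorbidity among cases."""
        cfg = SimConfig(ncases=5000, comorbidity=True)
        fracs = [simulate_population(cfg, _rng(s)).comorbid_fraction_a
                 for s in range(4)]
        assert 0.10 < np.mean(fracs) < 0.20

    def test_no_comorbid_case_labels_when_disabled(self):
        pop = simulate_population(SimConfig(**SMALL), _rng(3))
        assert not (pop.case_a & pop.case_b).any()
        assert not (pop.case_a & pop.status_b).any()

    def test_null_trait_shows_no_association(self):
        """h2_a = 0: no SNP is associated with disorder A beyond chance."""
        cfg = SimConfig(ncases=2000, n_snp=150, h2_a=0.0, h2_b=0.2,
                        class_fractions={"shared_equal": 0.0, "a_only": 0.0,
                                         "b_only": 0.5, "null": 0.5})
        pop = simulate_population(cfg, _rng(11))
        study_a, _, _ = build_casecontrol_studies(pop, cfg, _rng(12))
        assert (study_a["P"] < 0.05).mean() < 0.12


class TestStudies:
    def test_sample_sizes_and_overlap_counts(self):
        cfg = SimConfig(ncases=2000, n_snp=50, overlap_rate=0.25)
        pop = simulate_population(cfg, _rng(5))
        a, b, rep = build_casecontrol_studies(pop, cfg, _rng(6))
        N = max(rep["n_case_a"], rep["n_case_b"])
        assert rep["n_case_a"] + rep["n_ctrl_a"] == 2 * N
        assert rep["n_case_b"] + rep["n_ctrl_b"] == 2 * N
        assert rep["n_shared_controls"] == round(0.25 * 2 * N)
        assert a["N"].iloc[0] == 2 * N

    def test_zero_overlap_has_zero_intercept(self):
        assert expected_overlap_intercept(5000, 5000, 5000, 5000, 0) == 0.0

    def test_balanced_overlap_intercept_equals_rate(self):
        # balanced studies sharing a fraction P of samples: r = P
        assert expected_overlap_intercept(10_000, 10_000, 10_000, 10_000,
                                          3000) == pytest.approx(0.15)

    def test_excessive_overlap_is_fatal(self):
        cfg = SimConfig(ncases=500, n_snp=20, overlap_rate=0.9, K=0.4)
        pop = simulate_population(cfg, _rng(7))
        with pytest.raises(SimulationError):
            build_casecontrol_studies(pop, cfg, _rng(8))


class TestLogisticGwas:
    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        n = 3000
        G = rng.binomial(2, [0.2, 0.5, 0.8], size=(n, 3)).astype(float)
        logits = -0.5 + G @ np.array([0.3, 0.0, -0.2])
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(float)
        beta, se, z, p = logistic_gwas(G, y)
        for j in range(3):
            ref = sm.Logit(y, sm.add_constant(G[:, j])).fit(disp=0)
            assert beta[j] == pytest.approx(ref.params[1], abs=1e-6)
            assert se[j] == pytest.approx(ref.bse[1], rel=1e-4)


class TestExpectedLogodds:
    def test_null_effect_gives_zero_slope(self):
        assert expected_logodds(0.0, 0.3, 0.1, 0.5) == pytest.approx(0.0)

    def test_sign_and_scale(self):
        up = expected_logodds(0.05, 0.3, 0.1, 0.5)
        down = expected_logodds(-0.05, 0.3, 0.1, 0.5)
        assert up > 0 > down
        # exact mirror symmetry holds at maf = 0.5 (symmetric genotypes)
        assert expected_logodds(0.05, 0.5, 0.1, 0.5) == pytest.approx(
            -expected_logodds(-0.05, 0.5, 0.1, 0.5), rel=1e-9)
        # at other frequencies the asymmetric weighting only perturbs it
        assert up == pytest.approx(-down, rel=0.02)


class TestReplicateAndFixture:
    def test_replicate_is_deterministic(self):
        cfg = SimConfig(**SMALL)
        r1 = run_replicate(cfg, _rng(9))
        r2 = run_replicate(cfg, _rng(9))
        pd.testing.assert_frame_equal(r1.study_a, r2.study_a)
        pd.testing.assert_frame_equal(r1.diff, r2.diff)

    def test_fixture_round_trips_through_reader(self, tmp_path):
        cfg = SimConfig(**SMALL)
        paths = generate_sumstats_fixture(cfg, _rng(10), tmp_path)
        t = read_sumstats(paths["study_a"])
        assert len(t) == cfg.n_snp
        assert len(t.drop_log) == 0
        truth = pd.read_csv(paths["truth"], sep="\t")
        sh = truth["class"] == "shared_equal"
        np.testing.assert_allclose(truth.loc[sh, "BETA_LIAB_A"],
                                   truth.loc[sh, "BETA_LIAB_B"])

    def test_estimated_betas_unbiased_at_large_n(self):
        """Regression of estimated on expected per-allele log-odds has
        slope ~1 in a large cohort."""
        cfg = SimConfig(ncases=50_000, n_snp=300, n_reps=1)
        rep = run_replicate(cfg, _rng(13))
        merged = rep.study_a.merge(rep.truth, on="SNP")
        x = merged["BETA_LOGODDS_A"].to_numpy()
        y = merged["BETA"].to_numpy()
        slope = (x @ y) / (x @ x)
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_prs_evaluation_detects_true_signal(self):
        cfg = SimConfig(ncases=2000, n_snp=100)
        rep, pop = run_replicate(cfg, _rng(14), keep_population=True)
        sd = np.sqrt(2 * pop.maf * (1 - pop.maf))
        w = (pop.beta_a - pop.beta_b) / sd   # true differential effects
        auc = evaluate_prs(pop, w)
        assert auc > 0.55
        assert evaluate_prs(pop, np.zeros_like(w)) == pytest.approx(0.5)
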