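import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from polyres.assoc import (LogisticFit, evaluate_score, fit_logistic,
                           liability_scale_r2, nagelkerke_r2,
                           run_resilience_gwas, variance_explained)
from polyres.io import GenotypeStudy
from polyres.stratify import StratifiedCohort

from conftest import make_study


def _cohort_for(study, resilient_idx, matched_idx):
    ids = study.samples["sample_id"]
    return StratifiedCohort(
        study_id=study.study_id, design=1,
        resilient_ids=ids.iloc[resilient_idx].tolist(),
        risk_matched_case_ids=ids.iloc[matched_idx].tolist(),
        control_cutoff_score=0.0, control_max_score=1.0,
        n_controls_total=len(resilient_idx), n_cases_total=len(matched_idx),
    )


def _binary_study(cells):
    """Study whose single variant forms a 2x2 table.

    ``cells = (a, b, c, d)``: a = resilient & dosage 1, b = resilient &
    dosage 0, c = case & dosage 1, d = case & dosage 0.
    """
    a, b, c, d = cells
    n = a + b + c + d
    dosage = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    status = np.array([1] * (a + b) + [2] * (c + d))
    study = GenotypeStudy(
        study_id="tab",
        variants=pd.DataFrame({"snp_id": ["rs0"], "chrom": ["1"], "pos": [5],
                               "effect_allele": ["A"], "other_allele": ["G"]}),
        dosages=dosage[:, None],
        samples=pd.DataFrame({
            "sample_id": [f"x{i}" for i in range(n)],
            "status": status, "sex": 1, "age": 70.0}),
    )
    cohort = _cohort_for(study, np.arange(a + b), np.arange(a + b, n))
    return study, cohort


class TestResilienceGwas:
    def test_monomorphic_skipped(self, rng):
        study = make_study(rng, n_samples=24, n_variants=3)
        study.dosages[:, 1] = 1.0
        cohort = _cohort_for(study, np.arange(12), np.arange(12, 24))
        stats = run_resilience_gwas(study, cohort)
        assert "rs1" not in set(stats["snp_id"])

    def test_woolf_oracle_printed_table(self):
        # closed-form 2x2 oracle: lnOR = ln(20*20/(10*10)), SE = sqrt(sum 1/cell)
        study, cohort = _binary_study((20, 10, 10, 20))
        stats = run_resilience_gwas(study, cohort)
        assert stats.loc[0, "beta"] == pytest.approx(np.log(4.0), abs=1e-6)
        assert stats.loc[0, "se"] == pytest.approx(
            np.sqrt(1 / 20 + 1 / 10 + 1 / 10 + 1 / 20), abs=1e-6)

    @pytest.mark.parametrize("cells", [(12, 8, 5, 15), (30, 10, 20, 20)])
    def test_woolf_oracle_other_tables(self, cells):
        a, b, c, d = cells
        study, cohort = _binary_study(cells)
        stats = run_resilience_gwas(study, cohort)
        assert stats.loc[0, "beta"] == pytest.approx(np.log(a * d / (b * c)),
                                                     abs=1e-6)
        assert stats.loc[0, "se"] == pytest.approx(
            np.sqrt(1 / a + 1 / b + 1 / c + 1 / d), abs=1e-6)

    def test_matches_statsmodels_with_covariates(self, rng):
        study = make_study(rng, n_samples=80, n_variants=4)
        cohort = _cohort_for(study, np.arange(40), np.arange(40, 80))
        stats = run_resilience_gwas(study, cohort,
                                    covariates=["age", "sex", "PC1", "PC2"])
        y = np.r_[np.ones(40), np.zeros(40)]
        for _, row in stats.iterrows():
            j = study.variant_indexer()[row["snp_id"]]
            X = sm.add_constant(np.column_stack([
                study.dosages[:, j],
                study.samples[["age", "sex", "PC1", "PC2"]].to_numpy(),
            ]))
            ref = sm.Logit(y, X).fit(disp=0)
            assert row["beta"] == pytest.approx(ref.params[1], abs=1e-6)
            assert row["se"] == pytest.approx(ref.bse[1], abs=1e-6)

    def test_permutation_null_p_uniform(self, rng):
        # one fixed genotype vector, labels permuted -> Wald P ~ U(0,1)
        n = 200
        study = make_study(rng, n_samples=n, n_variants=1)
        pvals = []
        for _ in range(200):
            perm = rng.permutation(n)
            cohort = _cohort_for(study, perm[: n // 2], perm[n // 2:])
            # continuous covariates break the discreteness of the
            # permutation lattice so the Wald P is comparable to U(0,1)
            stats = run_resilience_gwas(study, cohort,
                                        covariates=["age", "PC1", "PC2"])
            pvals.append(stats.loc[0, "p"])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_separation_skipped_not_fatal(self):
        study, cohort = _binary_study((15, 0, 0, 15))  # perfect separation
        with pytest.raises(ValueError, match="no variant"):
            run_resilience_gwas(study, cohort)


class TestEvaluateScore:
    def test_null_score_near_zero(self, rng):
        study = make_study(rng, n_samples=400, n_variants=2)
        cohort = _cohort_for(study, np.arange(200), np.arange(200, 400))
        scores = pd.Series(rng.normal(size=400),
                           index=study.samples["sample_id"])
        fit = evaluate_score(study, cohort, scores)
        beta, se, _ = fit.term("score")
        assert abs(beta / se) < 3.0

    def test_direction_convention(self, rng):
        # higher scores in the resilient group -> OR > 1
        study = make_study(rng, n_samples=100, n_variants=2)
        cohort = _cohort_for(study, np.arange(50), np.arange(50, 100))
        scores = pd.Series(np.r_[rng.normal(1, 1, 50), rng.normal(-1, 1, 50)],
                           index=study.samples["sample_id"])
        fit = evaluate_score(study, cohort, scores)
        assert fit.params["score"] > 0

    def test_matches_statsmodels_40_sample_fixture(self, rng):
        study = make_study(rng, n_samples=40, n_variants=2)
        cohort = _cohort_for(study, np.arange(20), np.arange(20, 40))
        raw = pd.Series(rng.normal(size=40), index=study.samples["sample_id"])
        fit = evaluate_score(study, cohort, raw, covariates=["age", "sex"])
        s = raw.to_numpy()
        s = (s - s.mean()) / s.std()
        X = sm.add_constant(np.column_stack([
            s, study.samples[["age", "sex"]].to_numpy()]))
        ref = sm.Logit(np.r_[np.ones(20), np.zeros(20)], X).fit(disp=0)
        assert fit.params["score"] == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.bse["score"] == pytest.approx(ref.bse[1], abs=1e-6)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-6)

    def test_zero_variance_fatal(self, rng):
        study = make_study(rng, n_samples=20, n_variants=2)
        cohort = _cohort_for(study, np.arange(10), np.arange(10, 20))
        scores = pd.Series(1.0, index=study.samples["sample_id"])
        with pytest.raises(ValueError, match="zero score variance"):
            evaluate_score(study, cohort, scores)

    def test_type_one_error_under_permutation(self, rng):
        study = make_study(rng, n_samples=120, n_variants=2)
        scores = pd.Series(rng.normal(size=120),
                           index=study.samples["sample_id"])
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            perm = rng.permutation(120)
            cohort = _cohort_for(study, perm[:60], perm[60:])
            fit = evaluate_score(study, cohort, scores)
            if fit.pvalues["score"] < 0.05:
                rejections += 1
        # binomial 99.9% band around 0.05 for 300 draws
        assert 2 <= rejections <= 29


class TestNagelkerke:
    def _fit(self, llf, llnull, n):
        return LogisticFit(params=pd.Series(dtype=float),
                           bse=pd.Series(dtype=float),
                           zvalues=pd.Series(dtype=float),
                           pvalues=pd.Series(dtype=float),
                           llf=llf, llnull=llnull, nobs=n, n_events=n // 2,
                           converged=True)

    def test_no_improvement_zero(self):
        assert nagelkerke_r2(self._fit(-5.0, -5.0, 10)) == 0.0

    def test_perfect_prediction_one(self):
        n = 10
        llnull = n * np.log(0.5)
        assert nagelkerke_r2(self._fit(0.0, llnull, n)) == pytest.approx(1.0)

    def test_hand_computed_ten_sample_fixture(self):
        llf, llnull, n = -4.2, -6.93, 10
        expected = (1 - np.exp(2 * (llnull - llf) / n)) / (1 - np.exp(2 * llnull / n))
        assert nagelkerke_r2(self._fit(llf, llnull, n)) == pytest.approx(expected)

    def test_affine_rescaling_invariance(self, rng):
        study = make_study(rng, n_samples=60, n_variants=2)
        cohort = _cohort_for(study, np.arange(30), np.arange(30, 60))
        raw = pd.Series(rng.normal(size=60), index=study.samples["sample_id"])
        r2a = nagelkerke_r2(evaluate_score(study, cohort, raw))
        r2b = nagelkerke_r2(evaluate_score(study, cohort, 5.0 * raw + 3.0))
        assert r2a == pytest.approx(r2b, abs=1e-9)


class TestLiabilityConversion:
    def test_zero_maps_to_zero(self):
        assert liability_scale_r2(0.0, 0.2, 0.5) == 0.0

    def test_monotone_increasing(self):
        vals = [liability_scale_r2(x, 0.1, 0.4) for x in (0.01, 0.05, 0.1, 0.3)]
        assert vals == sorted(vals)
        assert all(v > 0 for v in vals)

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            liability_scale_r2(0.1, 0.0, 0.5)
        with pytest.raises(ValueError):
            liability_scale_r2(0.1, 0.5, 1.0)

    def test_balanced_factor_against_simulation(self):
        # brute force: simulate liability, dichotomize at K = P = 0.5, regress
        rng = np.random.default_rng(7)
        n = 400_000
        a = 0.4                      # liability-scale effect of the score
        s = rng.standard_normal(n)
        liab = a * s + rng.standard_normal(n)
        y = (liab > 0).astype(float)         # K = 0.5, sample P = K
        obs_r2 = np.corrcoef(s, y)[0, 1] ** 2
        true_liab_r2 = a**2 / (a**2 + 1.0)
        got = liability_scale_r2(obs_r2, 0.5, 0.5)
        assert got == pytest.approx(true_liab_r2, rel=0.05)
        # at K = P the ascertainment term vanishes
        assert got == pytest.approx(
            liability_scale_r2(obs_r2, 0.5, 0.5, ascertainment_correction=False),
            rel=1e-12)

    def test_ascertained_sample_against_simulation(self):
        # K = 0.2 population, cases oversampled to P = 0.5
        rng = np.random.default_rng(8)
        n = 1_000_000
        a = 0.3
        s = rng.standard_normal(n)
        liab = a * s + rng.standard_normal(n)
        thr = np.sqrt(a**2 + 1) * sps.norm.isf(0.2)
        y = liab > thr
        case_idx = np.flatnonzero(y)
        ctrl_idx = np.flatnonzero(~y)[: case_idx.size]
        idx = np.r_[case_idx, ctrl_idx]
        obs_r2 = np.corrcoef(s[idx], y[idx].astype(float))[0, 1] ** 2
        true_liab_r2 = a**2 / (a**2 + 1.0)
        got = liability_scale_r2(obs_r2, 0.2, 0.5)
        assert got == pytest.approx(true_liab_r2, rel=0.10)

    def test_variance_explained_bundle(self, rng):
        study = make_study(rng, n_samples=80, n_variants=2)
        cohort = _cohort_for(study, np.arange(40), np.arange(40, 80))
        scores = pd.Series(rng.normal(size=80), index=study.samples["sample_id"])
        fit = evaluate_score(study, cohort, scores)
        ve = variance_explained(fit, K=0.1)
        assert ve.case_proportion_p == pytest.approx(0.5)
        assert ve.nagelkerke_r2 >= 0.0
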