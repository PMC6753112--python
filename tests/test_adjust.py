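import numpy as np
import pandas as pd
import pytest
from scipy.stats import boxcox_llf

from famh2.adjust import (adjust_trait, boxcox_loglik, boxcox_mle,
                          residualize, stepwise_select, treatment_adjust_bp)


class TestTreatmentAdjustment:
    def test_treated_offsets(self):
        assert treatment_adjust_bp(140.0, 85.0, True) == (155.0, 95.0)

    def test_untreated_identity(self):
        assert treatment_adjust_bp(140.0, 85.0, False) == (140.0, 85.0)

    def test_not_idempotent(self):
        once = treatment_adjust_bp(140.0, 85.0, True)
        twice = treatment_adjust_bp(*once, True)
        assert twice != once

    def test_vectorized(self):
        sbp, dbp = treatment_adjust_bp([140.0, 120.0], [85.0, 70.0],
                                       [True, False])
        np.testing.assert_allclose(sbp, [155.0, 120.0])
        np.testing.assert_allclose(dbp, [95.0, 70.0])


class TestBoxCox:
    def test_lognormal_lambda_near_zero(self, rng):
        y = np.exp(rng.normal(0.0, 0.5, 2000))
        fit = boxcox_mle(y)
        assert -0.1 <= fit.lmbda <= 0.1

    def test_normal_far_from_zero_lambda_near_one(self, rng):
        y = rng.normal(50.0, 1.0, 2000)
        fit = boxcox_mle(y)
        assert boxcox_loglik(y, 1.0) >= fit.loglik - 2.0

    def test_matches_grid_oracle(self, rng):
        for sigma in (0.3, 0.8):
            y = np.exp(rng.normal(1.0, sigma, 500))
            fit = boxcox_mle(y)
            grid = np.arange(-3.0, 3.0001, 0.001)
            oracle = grid[np.argmax([boxcox_loglik(y, lm) for lm in grid])]
            assert abs(fit.lmbda - oracle) <= 0.01

    def test_loglik_agrees_with_reference(self, rng):
        y = np.exp(rng.normal(0.0, 0.4, 300))
        for lm in (-1.0, 0.0, 0.5, 2.0):
            assert boxcox_loglik(y, lm) == pytest.approx(
                float(boxcox_llf(lm, y)), abs=1e-8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            boxcox_mle(np.full(50, 3.0))

    def test_nonpositive_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            boxcox_mle(np.r_[rng.uniform(1, 2, 50), -1.0])


class TestStepwise:
    def test_selects_true_covariate_only(self, rng):
        h = rng.normal(170.0, 7.0, 500)
        age = rng.normal(50.0, 10.0, 500)
        y = 0.5 * h + rng.normal(0.0, 0.1, 500)
        model = stepwise_select(y, pd.DataFrame({"height": h, "age": age}))
        assert model.selected == ["height"]
        assert (model.pvalues < 0.01).all()

    def test_threshold_one_enters_all(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        y = rng.normal(size=100)
        model = stepwise_select(y, X, threshold=1.0)
        assert set(model.selected) == {"a", "b", "c"}

    def test_null_entry_rate(self, rng):
        # pure-noise candidates enter with marginal probability ~ threshold
        k, reps = 3, 300
        entered = 0
        for _ in range(reps):
            X = pd.DataFrame(rng.normal(size=(100, k)), columns=list("abc"))
            y = rng.normal(size=100)
            entered += len(stepwise_select(y, X, threshold=0.01).selected)
        rate = entered / (reps * k)
        # binomial(900, 0.01): generous 99.9% bounds
        assert 0.001 <= rate <= 0.03

    def test_collinear_candidate_skipped(self, rng):
        h = rng.normal(170.0, 7.0, 200)
        X = pd.DataFrame({"height": h, "height2": 2.0 * h})
        y = 0.5 * h + rng.normal(0.0, 0.5, 200)
        with pytest.warns(UserWarning, match="collinear"):
            model = stepwise_select(y, X)
        assert len(model.selected) == 1


class TestResidualize:
    def test_empty_model_centres(self, rng):
        y = rng.normal(5.0, 2.0, 100)
        X = pd.DataFrame({"a": rng.normal(size=100)})
        model = stepwise_select(y, X, threshold=1e-12)
        r = residualize(y, model, X)
        np.testing.assert_allclose(r, y - y.mean())

    def test_orthogonality_and_variance(self, rng):
        h = rng.normal(170.0, 7.0, 400)
        y = 0.3 * h + rng.normal(0.0, 1.0, 400)
        X = pd.DataFrame({"height": h})
        model = stepwise_select(y, X)
        r = residualize(y, model, X)
        assert abs(r.mean()) < 1e-10
        assert abs(np.dot(r, h - h.mean())) / len(r) < 1e-8
        assert r.var() <= y.var()


class TestAdjustTrait:
    def test_casewise_deletion_and_report(self, small_cohort):
        from famh2.phenotypes import derive_phenotypes
        d = derive_phenotypes(small_cohort.phenotypes, voltage_scale=100.0)
        d["sex01"] = (d["sex"] == 2).astype(int)
        d["sbp_adj"], d["dbp_adj"] = treatment_adjust_bp(
            d["sbp"], d["dbp"], d["treated"])
        resid, report = adjust_trait(
            d, "ecg_lvm", ["age", "sex01", "weight_kg", "sbp_adj"])
        assert report["n"] == d["ecg_lvm"].notna().sum()
        assert len(resid) == report["n"]
        assert abs(resid.mean()) < 1e-8
        assert "lambda" in report

    def test_family_structure_preserved(self, rng):
        # adjustment with genotype-independent candidates leaves the
        # within-family correlation of a heritable trait intact
        from famh2.pedigree import extract_relative_pairs
        from famh2.simulate import (PedigreeSpec, simulate_pedigrees,
                                    simulate_polygenic)
        ped = simulate_pedigrees(PedigreeSpec(
            n_families=400, target_total_individuals=1500, seed=13))
        g = simulate_polygenic(ped, 0.8, seed=13)
        y = 50.0 + g[np.arange(len(ped))] + rng.normal(0, np.sqrt(0.2), len(ped))
        noise_cov = pd.DataFrame({"z1": rng.normal(size=len(ped)),
                                  "z2": rng.normal(size=len(ped))})
        model = stepwise_select(y, noise_cov, threshold=0.01)
        r = residualize(y, model, noise_cov)
        pairs = extract_relative_pairs(ped)["sibling"]
        pos = {k: i for i, k in enumerate(ped.ids)}
        before = np.corrcoef([y[pos[a]] for a, b in pairs],
                             [y[pos[b]] for a, b in pairs])[0, 1]
        after = np.corrcoef([r[pos[a]] for a, b in pairs],
                            [r[pos[b]] for a, b in pairs])[0, 1]
        assert after == pytest.approx(before, abs=0.02)
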