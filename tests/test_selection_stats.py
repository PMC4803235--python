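"""PCA, GLMM, dredge averaging, Moran's I and the decorrelating subsampler."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from stopover_rsf.geo import haversine_km
from stopover_rsf.selection_stats import (
    AveragedModel,
    NonDecorrelatableError,
    RankError,
    UndefinedMoranError,
    aicc,
    cropland_axis,
    decorrelate_subsample,
    dredge_average,
    fit_glmm,
    fit_pca,
    moran_i,
    pool_averaged_models,
    score,
)
from conftest import make_glmm_table


class TestPca:
    def test_single_varying_column_loads_pc1(self, rng):
        df = pd.DataFrame({"CRO2": rng.uniform(0, 100, 30)})
        df["BFO2"] = 100.0 - df["CRO2"]
        df["WATE"] = 0.0
        pc = fit_pca(df, k=1)
        assert pc.dropped_columns == ["WATE"]
        # the two complementary columns form one axis, loadings +-1/sqrt(2)
        assert abs(pc.loadings[:, 0]) == pytest.approx([1 / math.sqrt(2)] * 2, abs=1e-9)
        assert pc.eigenvalues[0] == pytest.approx(
            2 * np.var(df["CRO2"].to_numpy() / 100.0, ddof=1), rel=1e-9
        )

    def test_eigenvalue_sum_equals_trace(self, random_compositions):
        pc = fit_pca(random_compositions, k=3)
        X = random_compositions[pc.columns].to_numpy() / 100.0
        assert pc.eigenvalues.sum() == pytest.approx(np.trace(np.cov(X, rowvar=False)), rel=1e-10)

    def test_loadings_match_dense_eigensolver(self, random_compositions):
        pc = fit_pca(random_compositions, k=5)
        X = random_compositions[pc.columns].to_numpy() / 100.0
        # independent oracle: generic eigensolver on the hand-built covariance
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (len(X) - 1)
        evals, evecs = np.linalg.eig(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = np.real(evals[order]), np.real(evecs[:, order])
        assert pc.eigenvalues[:5] == pytest.approx(evals[:5], abs=1e-10)
        for j in range(5):
            dot = abs(float(pc.loadings[:, j] @ evecs[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_matches_sklearn_cross_check(self, random_compositions):
        sklearn = pytest.importorskip("sklearn.decomposition")
        pc = fit_pca(random_compositions, k=4)
        X = random_compositions[pc.columns].to_numpy() / 100.0
        sk = sklearn.PCA(n_components=4).fit(X)
        assert sk.explained_variance_ == pytest.approx(pc.eigenvalues[:4], rel=1e-9)

    def test_orthonormal_loadings(self, pca_model):
        gram = pca_model.loadings.T @ pca_model.loadings
        assert np.max(np.abs(gram - np.eye(pca_model.k))) < 1e-8

    def test_sign_convention_largest_element_positive(self, pca_model):
        for j in range(pca_model.k):
            col = pca_model.loadings[:, j]
            assert col[int(np.argmax(np.abs(col)))] > 0

    def test_score_of_column_means_is_zero_and_centred(self, random_compositions, pca_model):
        s = score(pca_model, random_compositions)
        assert np.max(np.abs(s.mean(axis=0))) < 1e-10
        mean_row = random_compositions.copy().iloc[[0]]
        for c in pca_model.columns:
            mean_row[c] = pca_model.means[list(pca_model.columns).index(c)] * 100.0
        assert np.max(np.abs(score(pca_model, mean_row).to_numpy())) < 1e-12

    def test_scores_match_direct_loop(self, random_compositions, pca_model):
        s = score(pca_model, random_compositions).to_numpy()
        X = random_compositions[pca_model.columns].to_numpy() / 100.0
        for i in (0, 7, 23):
            for j in range(pca_model.k):
                direct = sum(
                    (X[i, m] - pca_model.means[m]) * pca_model.loadings[m, j]
                    for m in range(X.shape[1])
                )
                assert s[i, j] == pytest.approx(direct, abs=1e-12)

    def test_schema_mismatch_rejected(self, pca_model):
        with pytest.raises(KeyError):
            score(pca_model, pd.DataFrame({"CRO2": [10.0]}))

    def test_k_beyond_rank_rejected(self, rng):
        df = pd.DataFrame({"CRO2": rng.uniform(0, 100, 20)})
        df["BFO2"] = 100 - df["CRO2"]  # rank 1
        with pytest.raises(RankError):
            fit_pca(df, k=2)

    def test_cropland_axis_orientation(self, rng):
        crop = rng.uniform(0, 100, 40)
        df = pd.DataFrame({"CRO2": crop, "BFO2": 100 - crop})
        name, sign = cropland_axis(fit_pca(df, k=1))
        assert name == "PC1"
        s = score(fit_pca(df, k=1), df)["PC1"] * sign
        assert np.corrcoef(s, crop)[0, 1] > 0.99


class TestGlmm:
    def test_neutral_intercept_matches_base_rate(self):
        # 1 use : 2 available with no covariate effect: b0 ~ ln(1/2)
        df = make_glmm_table(seed=3, n_birds=9, rows_per_bird=24, sigma_u=0.3)
        fit = fit_glmm(df, ("PC1", "PC2", "PC3", "PC4", "PC5"))
        assert abs(fit.beta["Intercept"] - math.log(0.5)) <= 2 * fit.se["Intercept"]

    def test_zero_variance_boundary_reduces_to_logistic(self):
        import statsmodels.api as sm

        df = make_glmm_table(seed=11, n_birds=6, rows_per_bird=30, sigma_u=0.0, beta=(0.8, -0.4))
        fit = fit_glmm(df, ("PC1", "PC2"), fix_sigma=0.0)
        X = sm.add_constant(df[["PC1", "PC2"]].to_numpy())
        ref = sm.Logit(df["y"].to_numpy(), X).fit(disp=0)
        got = np.array([fit.beta["Intercept"], fit.beta["PC1"], fit.beta["PC2"]])
        assert got == pytest.approx(ref.params, abs=1e-4)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_matches_lme4_oracle(self, tmp_path):
        # independent oracle: the reference mixed-model fitter the field uses
        import json
        import subprocess

        df = make_glmm_table(seed=42, n_birds=6, rows_per_bird=12, sigma_u=0.8, beta=(0.9, -0.5))
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        fit = fit_glmm(df, ("PC1", "PC2"), n_quad=25)
        rcode = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(y ~ PC1 + PC2 + (1|bird_id), data=d, family=binomial, nAGQ=25)
        cat(jsonlite::toJSON(list(beta=as.numeric(fixef(m)),
            sigma=as.numeric(sqrt(unlist(VarCorr(m))[1])),
            ll=as.numeric(logLik(m))), digits=12))
        """
        rfile = tmp_path / "fit.R"
        rfile.write_text(rcode)
        out = subprocess.run(["Rscript", str(rfile)], capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        assert fit.beta["Intercept"] == pytest.approx(ref["beta"][0], abs=5e-4)
        assert fit.beta["PC1"] == pytest.approx(ref["beta"][1], abs=5e-4)
        assert fit.beta["PC2"] == pytest.approx(ref["beta"][2], abs=5e-4)
        assert fit.sigma_re == pytest.approx(ref["sigma"][0], abs=5e-3)
        assert fit.loglik == pytest.approx(ref["ll"][0], abs=1e-4)

    def test_aicc_penalises_extra_parameters(self):
        assert aicc(-50.0, 4, 60) < aicc(-50.0, 5, 60)

    def test_aicc_matches_formula(self, glmm_table):
        fit = fit_glmm(glmm_table, ("PC1",))
        k, n = fit.k_params, fit.n_obs
        assert fit.aicc == pytest.approx(-2 * fit.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1))
        assert k == 3  # intercept + PC1 + random-intercept variance

    def test_separation_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        df = pd.DataFrame({
            "bird_id": np.repeat([f"B{i}" for i in range(4)], 10),
            "PC1": x,
            "y": (x > 0).astype(float),
            "lon": rng.uniform(0, 10, 40),
            "lat": rng.uniform(40, 50, 40),
        })
        fit = fit_glmm(df, ("PC1",))
        assert fit.separation


class TestDredgeAverage:
    def test_ranking_matches_independent_enumeration(self):
        df = make_glmm_table(seed=5, n_birds=6, rows_per_bird=12, sigma_u=0.4, beta=(0.7, 0, -0.5, 0, 0))
        pcs = ("PC1", "PC2", "PC3", "PC4", "PC5")
        avg = dredge_average(df, pcs)
        # independent loop over all 32 subsets
        oracle = []
        for r in range(6):
            for sub in itertools.combinations(pcs, r):
                f = fit_glmm(df, sub)
                oracle.append(("+".join(sub) if sub else "(intercept)", f.aicc))
        oracle.sort(key=lambda t: t[1])
        got = list(avg.candidates["model"])
        assert got == [m for m, _ in oracle]
        assert avg.candidates["aicc"].tolist() == pytest.approx([a for _, a in oracle], abs=1e-6)

    def test_weights_sum_to_one(self, glmm_table):
        avg = dredge_average(glmm_table)
        assert avg.candidates["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert avg.n_models_averaged == int((avg.candidates["weight"] > 0).sum())

    def test_single_model_subset_returns_exact_betas(self):
        # with a huge delta only relative ranking matters; with delta tiny
        # only the best model is averaged and betas match it exactly
        df = make_glmm_table(seed=9, n_birds=6, rows_per_bird=14, sigma_u=0.3, beta=(1.2,))
        avg = dredge_average(df, ("PC1",), delta=1e-9)
        best_terms = avg.candidates.iloc[0]["model"]
        terms = () if best_terms == "(intercept)" else tuple(best_terms.split("+"))
        best = fit_glmm(df, terms)
        for t in avg.terms:
            assert avg.beta[t] == pytest.approx(best.beta.get(t, 0.0), abs=1e-9)

    def test_full_averaging_shrinkage(self, glmm_table):
        avg = dredge_average(glmm_table)
        pcs = ("PC1", "PC2", "PC3", "PC4", "PC5")
        for t in pcs:
            caps = []
            for r in range(6):
                for sub in itertools.combinations(pcs, r):
                    if t in sub:
                        caps.append(abs(fit_glmm(glmm_table, sub).beta[t]))
            assert abs(avg.beta[t]) <= max(caps) + 1e-9

    def test_pooling_identical_replicates_is_identity(self, glmm_table):
        avg = dredge_average(glmm_table)
        pooled = pool_averaged_models([avg, avg, avg, avg])
        for t in avg.terms:
            assert pooled.beta[t] == pytest.approx(avg.beta[t], abs=1e-12)
            # identical replicates: between-variance 0, SE preserved
            assert pooled.se[t] == pytest.approx(avg.se[t], abs=1e-12)


class TestMoranI:
    def test_hand_computed_four_points(self):
        # 4 points on a line at 45N, residuals [1, 2, -1, -2]
        lons = np.array([0.0, 1.0, 2.0, 3.0])
        lats = np.full(4, 45.0)
        x = np.array([1.0, 2.0, -1.0, -2.0])
        res = moran_i(x, lons, lats, n_perm=999, rng=0)
        # independent hand computation with the same weights
        xc = x - x.mean()
        W = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i != j:
                    W[i, j] = 1.0 / haversine_km(lons[i], lats[i], lons[j], lats[j])
        expected = 4.0 / W.sum() * (xc @ W @ xc) / (xc @ xc)
        assert res.observed_i == pytest.approx(expected, abs=1e-12)
        assert res.expected_i == pytest.approx(-1.0 / 3.0)

    def test_spatially_sorted_residuals_highly_significant(self):
        n = 30
        lons = np.linspace(0, 10, n)
        lats = np.full(n, 45.0)
        x = np.sort(np.random.default_rng(1).normal(size=n))
        res = moran_i(x, lons, lats, n_perm=999, rng=2)
        # inverse-distance weights keep long-range pairs in play, so the
        # statistic stays well below its lattice ceiling even when the
        # residuals are perfectly sorted; significance is maximal
        assert res.observed_i > 0.3
        assert res.p_value <= 0.002

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedMoranError):
            moran_i(np.ones(5), np.arange(5.0), np.full(5, 45.0), rng=0)

    def test_duplicate_coordinates_jittered_not_fatal(self):
        x = np.array([1.0, -1.0, 2.0, -2.0])
        res = moran_i(x, np.array([0.0, 0.0, 1.0, 1.0]), np.full(4, 45.0), n_perm=99, rng=0)
        assert np.isfinite(res.observed_i)

    def test_null_rejection_rate_calibrated(self):
        # i.i.d. residuals: the permutation test should reject at ~alpha
        rng = np.random.default_rng(8)
        n = 20
        lons = rng.uniform(0, 10, n)
        lats = rng.uniform(44, 50, n)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            x = rng.normal(size=n)
            res = moran_i(x, lons, lats, n_perm=99, rng=rng)
            rejections += res.p_value <= 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestDecorrelateSubsample:
    def test_uncorrelated_residuals_keep_table(self):
        df = make_glmm_table(seed=21, n_birds=8, rows_per_bird=10)
        out, trace = decorrelate_subsample(df, ("PC1", "PC2"), rng=4, n_perm=199)
        assert len(trace) == 1
        assert len(out) == len(df)

    def test_planted_trend_terminates_with_fewer_rows(self):
        rng = np.random.default_rng(13)
        rows = []
        for g in range(8):
            for _ in range(12):
                lon = rng.uniform(0, 30)
                lat = rng.uniform(44, 54)
                # response sorted in space but independent of PC1: residual trend
                y = float(rng.random() < 1.0 / (1.0 + np.exp(-(lon / 7.5 - 2.0))))
                rows.append({"bird_id": f"B{g}", "y": y, "lon": lon, "lat": lat,
                             "PC1": rng.normal()})
        df = pd.DataFrame(rows)
        out, trace = decorrelate_subsample(df, ("PC1",), rng=5, n_perm=199, max_iter=60)
        assert trace[-1]["p"] > 0.05
        assert len(out) < len(df)

    def test_same_seed_identical_result(self):
        df = make_glmm_table(seed=22, n_birds=6, rows_per_bird=10)
        a, _ = decorrelate_subsample(df, ("PC1",), rng=9, n_perm=99)
        b, _ = decorrelate_subsample(df, ("PC1",), rng=9, n_perm=99)
        pd.testing.assert_frame_equal(a, b)

    def test_too_small_table_errors_with_trace(self):
        df = make_glmm_table(seed=23, n_birds=2, rows_per_bird=5)
        with pytest.raises((NonDecorrelatableError, ValueError)):
            decorrelate_subsample(df, ("PC1",), rng=1, n_perm=99)
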