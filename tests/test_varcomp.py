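"""REML variance components, ratios and BLUP prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, optimize

import holopred as hp
from holopred.varcomp import build_fixed_design, reml


def restricted_loglik(y, x, v):
    """Independent textbook evaluation of the restricted log-likelihood."""
    sign, logdet_v = np.linalg.slogdet(v)
    vinv = np.linalg.inv(v)
    xtvx = x.T @ vinv @ x
    _, logdet_x = np.linalg.slogdet(xtvx)
    beta = np.linalg.solve(xtvx, x.T @ vinv @ y)
    r = y - x @ beta
    return -0.5 * (logdet_v + logdet_x + r @ vinv @ r)


def make_one_kernel_problem(n=30, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n, n // 2))
    k = a @ a.T / (n // 2)
    k = k / np.mean(np.diag(k))
    x = np.column_stack([np.ones(n), rng.normal(size=n)])
    u = np.linalg.cholesky(k + 1e-10 * np.eye(n)) @ rng.normal(size=n)
    y = x @ np.array([1.0, 0.5]) + 0.8 * u + rng.normal(0, 0.7, n)
    return y, x, k


class TestRemlCore:
    def test_matches_grid_plus_refinement_oracle(self):
        """AI-REML finds the same optimum as brute-force maximization."""
        y, x, k = make_one_kernel_problem(n=30, seed=1)
        res = reml(y, x, {"animal": k})
        assert res["flag"] in ("converged", "boundary")

        identity = np.eye(len(y))

        def negll(theta):
            sg2, se2 = theta
            if sg2 < 0 or se2 <= 1e-8:
                return np.inf
            return -restricted_loglik(y, x, sg2 * k + se2 * identity)

        vy = np.var(y, ddof=1)
        grid = np.linspace(0.01, 2.5, 30) * vy
        best = min(
            ((sg, se) for sg in grid for se in grid), key=lambda t: negll(t)
        )
        opt = optimize.minimize(
            negll, best, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        assert abs(res["loglik"] - (-opt.fun)) < 1e-6
        # and the reported loglik is the loglik of the reported components
        v = res["theta"][0] * k + res["theta"][1] * identity
        assert restricted_loglik(y, x, v) == pytest.approx(res["loglik"], abs=1e-8)

    def test_loglik_never_decreases(self):
        y, x, k = make_one_kernel_problem(n=40, seed=2)
        # track by refitting with increasing iteration caps
        lls = [reml(y, x, {"animal": k}, max_iter=i)["loglik"] for i in (1, 2, 4, 8, 50)]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_identity_kernel_blup_shrinkage(self):
        rng = np.random.default_rng(3)
        n = 60
        x = np.ones((n, 1))
        y = rng.normal(2.0, 1.0, n)
        res = reml(y, x, {"animal": np.eye(n)})
        sg2, se2 = res["theta"]
        beta = res["beta"]
        shrink = sg2 / (sg2 + se2)
        u = sg2 * res["py"]
        assert np.allclose(u, shrink * (y - x @ beta), atol=1e-8)

    def test_identity_g_and_m_flagged_non_identifiable(self):
        rng = np.random.default_rng(4)
        n = 40
        y = rng.normal(size=n)
        x = np.ones((n, 1))
        res = reml(y, x, {"animal": np.eye(n), "metagenome": np.eye(n)})
        assert res["flag"] in ("singular", "boundary", "max-iter")

    def test_variance_floor_and_boundary_flag(self):
        # no genetic signal at all: component driven to the boundary
        rng = np.random.default_rng(5)
        n = 80
        k = np.eye(n)  # iid "genetic" effect indistinguishable -> boundary or tiny
        y = rng.normal(size=n)
        x = np.ones((n, 1))
        res = reml(y, x, {"animal": k})
        assert (res["theta"] >= 0).all()


class TestFitMixedModel:
    def test_components_sum_to_sigma_p2(self, small_dataset, small_matrices):
        G, M = small_matrices
        spec = hp.ModelSpec(trait="y", fixed=["brr", "aod", "bdev", "cg"])
        fit = hp.fit_mixed_model(small_dataset["pheno"], spec, G=G, M=M)
        assert fit.sigma_p2 == pytest.approx(sum(fit.components.values()))
        assert fit.h2 + fit.m2 <= 1 + 1e-8
        assert all(v >= 0 for v in fit.components.values())

    def test_single_effect_combined_equals_h2(self, small_dataset, small_matrices):
        G, _ = small_matrices
        spec = hp.ModelSpec(trait="y", fixed=["bdev"], random=("animal",))
        fit = hp.fit_mixed_model(small_dataset["pheno"], spec, G=G)
        assert "m2" not in fit.ratios
        assert fit.ratios["combined"][0] == pytest.approx(fit.h2)

    def test_missing_matrix_rejected(self, small_dataset):
        spec = hp.ModelSpec(trait="y", fixed=[], random=("animal",))
        with pytest.raises(ValueError, match="animal"):
            hp.fit_mixed_model(small_dataset["pheno"], spec, G=None)

    def test_delta_method_se_against_bootstrap(self):
        """SE of h2 from the AI matrix vs a parametric-bootstrap SE."""
        rng = np.random.default_rng(6)
        n = 500
        gt = hp.simulate_genotypes(n, 300, seed=6)
        G = hp.build_grm(gt.dosages)
        k = G.values
        sg2, se2 = 0.4, 0.6
        chol = np.linalg.cholesky(sg2 * k + se2 * np.eye(n) + 1e-10 * np.eye(n))
        x = np.ones((n, 1))

        y = chol @ rng.normal(size=n)
        res = reml(y, x, {"animal": k})
        ratios = hp.variance_ratios(
            dict(zip(res["names"], res["theta"])), res["ai_inv"], res["names"]
        )
        se_delta = ratios["h2"][1]

        boots = []
        for _ in range(30):
            yb = chol @ rng.normal(size=n)
            rb = reml(yb, x, {"animal": k})
            t = rb["theta"]
            boots.append(t[0] / t.sum())
        se_boot = np.std(boots, ddof=1)
        assert se_delta == pytest.approx(se_boot, rel=0.5)


class TestVarianceRatios:
    def test_arithmetic(self):
        out = hp.variance_ratios(
            {"animal": 1.0, "metagenome": 1.0, "residual": 2.0},
            None,
            ["animal", "metagenome", "residual"],
        )
        assert out["h2"][0] == pytest.approx(0.25)
        assert out["m2"][0] == pytest.approx(0.25)
        assert out["combined"][0] == pytest.approx(0.5)

    def test_zero_phenotypic_variance_rejected(self):
        with pytest.raises(ValueError):
            hp.variance_ratios({"animal": 0.0, "residual": 0.0}, None,
                               ["animal", "residual"])


class TestPredictBlup:
    @staticmethod
    def _train_fit(n=40, seed=7):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(n + 4, 30))
        k_full = a @ a.T / 30 + 0.05 * np.eye(n + 4)
        d = np.sqrt(np.diag(k_full))
        k_full = k_full / np.outer(d, d)
        ids = [f"A{i}" for i in range(n + 4)]
        train_ids, test_ids = ids[:n], ids[n:]
        u = np.linalg.cholesky(k_full) @ rng.normal(size=n + 4)
        y = 1.0 + 0.9 * u[:n] + rng.normal(0, 0.5, n)
        pheno = pd.DataFrame({"y": y}, index=train_ids)
        G = hp.RelationshipMatrix(values=k_full, ids=ids, kind="GRM")
        spec = hp.ModelSpec(trait="y", fixed=[], random=("animal",))
        fit = hp.fit_mixed_model(pheno, spec, G=hp.align_matrices(G, train_ids))
        return fit, G, train_ids, test_ids, y

    def test_matches_henderson_mme(self):
        fit, G, train_ids, test_ids, y = self._train_fit()
        n, t = len(train_ids), len(test_ids)
        k_full = G.values
        cross = k_full[n:, :n]
        pred = hp.predict_blup(fit, {"animal": cross}, test_ids)

        sg2 = fit.components["animal"]
        se2 = fit.components["residual"]
        x = np.ones((n, 1))
        z = np.hstack([np.eye(n), np.zeros((n, t))])
        kinv = np.linalg.inv(k_full)
        lam = se2 / sg2
        top = np.hstack([x.T @ x, x.T @ z])
        bot = np.hstack([z.T @ x, z.T @ z + lam * kinv])
        lhs = np.vstack([top, bot])
        rhs = np.concatenate([x.T @ y, z.T @ y])
        sol = np.linalg.solve(lhs, rhs)
        u_test = sol[1 + n:]
        assert np.allclose(pred["animal"].to_numpy(), u_test, atol=1e-8)

    def test_duplicate_relationship_row_duplicates_blup(self):
        fit, G, train_ids, test_ids, _ = self._train_fit()
        n = len(train_ids)
        # a "test animal" whose relationship row copies training animal 0
        cross = G.values[[0], :n]
        pred = hp.predict_blup(fit, {"animal": cross}, ["copy"])
        assert pred.loc["copy", "animal"] == pytest.approx(
            fit.blups["animal"].iloc[0]
        )

    def test_zero_variance_component_predicts_zero(self):
        fit, G, train_ids, test_ids, _ = self._train_fit()
        fit.components["animal"] = 0.0
        cross = G.values[len(train_ids):, :len(train_ids)]
        pred = hp.predict_blup(fit, {"animal": cross}, test_ids)
        assert (pred["animal"] == 0).all()

    def test_shape_mismatch_rejected(self):
        fit, G, train_ids, test_ids, _ = self._train_fit()
        with pytest.raises(ValueError):
            hp.predict_blup(fit, {"animal": np.ones((2, 3))}, test_ids)
        with pytest.raises(KeyError):
            hp.predict_blup(
                fit, {"metagenome": np.ones((4, len(train_ids)))}, test_ids
            )


class TestFixedDesign:
    def test_aliased_columns_dropped_with_warning(self):
        pheno = pd.DataFrame(
            {"a": ["x", "x", "y", "y"], "b": ["u", "u", "v", "v"],
             "y": [1.0, 2, 3, 4]}
        )
        with pytest.warns(UserWarning, match="aliased"):
            x, names = build_fixed_design(pheno, ["a", "b"])
        assert np.linalg.matrix_rank(x) == x.shape[1]

    def test_numeric_column_is_covariate(self):
        pheno = pd.DataFrame({"bdev": [0.1, -0.2, 0.3]})
        x, names = build_fixed_design(pheno, ["bdev"])
        assert names == ["mu", "bdev"]
        assert np.allclose(x[:, 1], pheno["bdev"])
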