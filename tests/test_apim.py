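import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm

from dyadema.apim import (ApimDesign, ApimParams, apim_loglik, build_design,
                          design_terms, fit_apim, p_stars, wald_tests)


def dense_loglik(design, beta, G, sm, sc, rho):
    """Independent oracle: dense multivariate-normal evaluation per dyad."""
    S = np.array([[sm ** 2, rho * sm * sc], [rho * sm * sc, sc ** 2]])
    total = 0.0
    row = 0
    for d in pd.unique(design.dyads):
        n = int((design.dyads == d).sum())
        idx = slice(row, row + 2 * n)
        Z = np.tile(np.eye(2), (n, 1))
        V = np.kron(np.eye(n), S) + Z @ np.asarray(G) @ Z.T
        total += multivariate_normal.logpdf(design.y[idx],
                                            mean=design.X[idx] @ beta, cov=V)
        row += 2 * n
    return total


def make_design(rng, D=40, n=8, G=None, sm=0.8, sc=1.1, rho=0.3, beta=None,
                p_extra=2):
    """Simulate a paired two-intercept design with known parameters."""
    if G is None:
        G = np.array([[0.30, 0.10], [0.10, 0.25]])
    cols = ["m:intercept", "c:intercept"] + \
        [f"m:x{i}" for i in range(p_extra)] + \
        [f"c:x{i}" for i in range(p_extra)]
    p = len(cols)
    if beta is None:
        beta = rng.normal(size=p)
    nw = D * n
    X = np.zeros((2 * nw, p))
    X[0::2, 0] = 1.0
    X[1::2, 1] = 1.0
    covs = rng.standard_normal((nw, p_extra))
    X[0::2, 2:2 + p_extra] = covs
    X[1::2, 2 + p_extra:] = rng.standard_normal((nw, p_extra))
    dyads = np.repeat(np.arange(D), n)
    b = (np.linalg.cholesky(G + 1e-12 * np.eye(2))
         @ rng.standard_normal((2, D))).T
    S = np.array([[sm ** 2, rho * sm * sc], [rho * sm * sc, sc ** 2]])
    eps = (np.linalg.cholesky(S) @ rng.standard_normal((2, nw))).T
    lp = X @ beta
    y = np.empty(2 * nw)
    y[0::2] = lp[0::2] + b[dyads, 0] + eps[:, 0]
    y[1::2] = lp[1::2] + b[dyads, 1] + eps[:, 1]
    des = ApimDesign(y=y, X=X, columns=cols, dyads=dyads,
                     window_ids=np.arange(nw))
    return des, beta, G


def analysis_frame_one_window():
    return pd.DataFrame([{
        "dyad_id": 7, "window_id": 0, "m_out": 1.5, "c_out": 2.5,
        "m_resp_hour": 17.5, "c_resp_hour": 18.0, "m_age_wave": 42.0,
        "c_age_wave": 10.0, "m_age_base": 41.0, "c_age_base": 9.5,
        "m_hispanic": 1, "c_hispanic": 0, "c_male": 1, "c_bmiz": 0.4,
        "prompt_diff": 31.0, "weekend": 1,
        "m_pa_pm": 2.6, "m_pa_dev": 0.2, "m_na_pm": 1.4, "m_na_dev": -0.1,
        "c_pa_pm": 3.1, "c_pa_dev": 0.3, "c_na_pm": 1.2, "c_na_dev": 0.05,
    }])


class TestBuildDesign:
    def test_two_rows_with_member_blocks(self):
        d = build_design(analysis_frame_one_window())
        assert d.X.shape == (2, 32)
        child_cols = [j for j, c in enumerate(d.columns) if c.startswith("c:")]
        mother_cols = [j for j, c in enumerate(d.columns) if c.startswith("m:")]
        assert np.all(d.X[0, child_cols] == 0.0)   # mother row
        assert np.all(d.X[1, mother_cols] == 0.0)  # child row

    def test_cells_match_hand_built_matrix(self):
        df = analysis_frame_one_window()
        d = build_design(df)
        get = lambda term: d.X[0 if term.startswith("m:") else 1,
                               d.columns.index(term)]
        assert get("m:intercept") == 1.0
        assert get("m:resp_time") == 17.5
        assert get("m:pa_dev") == 0.2
        assert get("m:partner_pa_dev") == 0.3      # child's deviation on mother row
        assert get("c:partner_na_pm") == 1.4       # mother's person mean on child row
        assert get("c:male") == 1.0
        assert get("c:prompt_diff") == 31.0
        assert d.y[0] == 1.5 and d.y[1] == 2.5

    def test_missing_column_named(self):
        df = analysis_frame_one_window().drop(columns=["c_bmiz"])
        with pytest.raises(KeyError, match="c_bmiz"):
            build_design(df)

    def test_true_affect_sources(self):
        mother, child = design_terms(use_true_affect=True)
        srcs = dict(mother + child)
        assert srcs["m:pa_dev"] == "m_pa_dev_true"
        assert srcs["c:partner_na_pm"] == "m_na_pm_true"


class TestLoglik:
    def test_matches_dense_oracle_on_small_instances(self, rng):
        for D, n in [(1, 1), (2, 3), (5, 4)]:
            des, beta, G = make_design(rng, D=D, n=n)
            ll = apim_loglik(des, beta, G, 0.8, 1.1, 0.3)
            assert ll == pytest.approx(dense_loglik(des, beta, G, 0.8, 1.1, 0.3),
                                       abs=1e-8)

    def test_independence_limit_is_univariate_sum(self, rng):
        des, beta, _ = make_design(rng, D=1, n=1)
        ll = apim_loglik(des, beta, np.zeros((2, 2)), 0.8, 1.1, 0.0)
        mu = des.X @ beta
        ref = norm.logpdf(des.y[0], mu[0], 0.8) + norm.logpdf(des.y[1], mu[1], 1.1)
        assert ll == pytest.approx(ref, abs=1e-10)

    def test_invariant_to_dyad_order(self, rng):
        des, beta, G = make_design(rng, D=4, n=3)
        perm = np.array([2, 0, 3, 1])
        order = np.concatenate([np.flatnonzero(des.dyads == d) for d in perm])
        rows = np.empty(2 * len(order), int)
        rows[0::2], rows[1::2] = 2 * order, 2 * order + 1
        des2 = ApimDesign(y=des.y[rows], X=des.X[rows], columns=des.columns,
                          dyads=des.dyads[order], window_ids=des.window_ids[order])
        assert apim_loglik(des2, beta, G, 0.8, 1.1, 0.3) == pytest.approx(
            apim_loglik(des, beta, G, 0.8, 1.1, 0.3), abs=1e-9)

    def test_invalid_parameters_rejected(self, rng):
        des, beta, G = make_design(rng, D=2, n=2)
        with pytest.raises(ValueError):
            apim_loglik(des, beta, G, -1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            apim_loglik(des, beta, G, 1.0, 1.0, 1.5)
        with pytest.raises(ValueError):
            apim_loglik(des, beta, np.array([[1.0, 2.0], [2.0, 1.0]]), 1, 1, 0)


class TestFit:
    def test_independence_factorization_cross_check(self, rng):
        """With rho=0 and diagonal G the joint fit must match per-member
        mixed models; statsmodels MixedLM is the independent engine."""
        import warnings

        import statsmodels.api as sm

        des, beta, G = make_design(rng, D=80, n=10,
                                   G=np.diag([0.3, 0.25]), rho=0.0)
        fit = fit_apim(des)
        for member, rows in (("m", slice(0, None, 2)), ("c", slice(1, None, 2))):
            cols = [j for j, c in enumerate(des.columns)
                    if c.startswith(f"{member}:")]
            exog = des.X[rows][:, cols]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(des.y[rows], exog, groups=des.dyads).fit(
                    reml=False)
            assert np.allclose(fit.beta[cols], np.asarray(res.fe_params),
                               atol=2e-3)
            k = 0 if member == "m" else 1
            assert fit.G[k, k] == pytest.approx(
                float(np.asarray(res.cov_re)[0, 0]), abs=5e-3)

    def test_loglik_at_optimum_beats_generating_parameters(self, rng):
        des, beta, G = make_design(rng, D=50, n=8)
        fit = fit_apim(des)
        ll_truth = apim_loglik(des, beta, G, 0.8, 1.1, 0.3)
        assert fit.loglik >= ll_truth - 1e-6

    def test_permuting_window_order_leaves_fit_unchanged(self, rng):
        des, *_ = make_design(rng, D=20, n=6)
        nw = len(des.dyads)
        perm = rng.permutation(nw)
        rows = np.empty(2 * nw, int)
        rows[0::2], rows[1::2] = 2 * perm, 2 * perm + 1
        des2 = ApimDesign(y=des.y[rows], X=des.X[rows], columns=des.columns,
                          dyads=des.dyads[perm], window_ids=des.window_ids[perm])
        f1, f2 = fit_apim(des), fit_apim(des2)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)
        assert np.allclose(np.sort(f1.beta), np.sort(f2.beta), atol=1e-6)

    def test_scale_equivariance(self, rng):
        des, *_ = make_design(rng, D=40, n=8)
        c = 3.0
        y2 = des.y.copy()
        y2[0::2] *= c
        des2 = ApimDesign(y=y2, X=des.X, columns=des.columns, dyads=des.dyads,
                          window_ids=des.window_ids)
        f1, f2 = fit_apim(des), fit_apim(des2)
        mcols = [j for j, col in enumerate(des.columns) if col.startswith("m:")]
        assert np.allclose(f2.beta[mcols], c * f1.beta[mcols], rtol=1e-3)
        assert f2.sigma_m == pytest.approx(c * f1.sigma_m, rel=1e-3)
        assert f2.sigma_c == pytest.approx(f1.sigma_c, rel=1e-3)
        assert f2.rho == pytest.approx(f1.rho, abs=5e-3)
        assert f2.r_intercepts == pytest.approx(f1.r_intercepts, abs=2e-2)

    def test_ml_and_reml_agree_on_beta(self, rng):
        des, *_ = make_design(rng, D=60, n=12)
        f_ml = fit_apim(des, method="ML")
        f_reml = fit_apim(des, method="REML")
        scale = np.maximum(np.abs(f_ml.beta), 0.1)
        assert np.all(np.abs(f_ml.beta - f_reml.beta) / scale < 0.01)

    def test_rank_deficient_design_rejected(self, rng):
        des, *_ = make_design(rng, D=10, n=4)
        X = des.X.copy()
        X[:, 3] = X[:, 2]
        bad = ApimDesign(y=des.y, X=X, columns=des.columns, dyads=des.dyads,
                         window_ids=des.window_ids)
        with pytest.raises(ValueError, match="rank"):
            fit_apim(bad)


class TestWald:
    def test_null_estimate_no_star(self, rng):
        assert p_stars(1.0) == ""
        des, *_ = make_design(rng, D=20, n=4)
        table = wald_tests(fit_apim(des))
        assert {"term", "estimate", "se", "z", "p", "stars"} <= set(table.columns)

    def test_z_and_p_reference_values(self):
        # z = 1.96 -> p ~ 0.05; z = 0.071/0.016 = 4.44 -> ***
        p_border = 2 * norm.sf(1.96)
        assert p_border == pytest.approx(0.05, abs=1e-3)
        z = 0.071 / 0.016
        assert z == pytest.approx(4.44, abs=0.01)
        assert p_stars(2 * norm.sf(z)) == "***"
        assert p_stars(p_border) == "*"
        assert p_stars(0.049) == "*" and p_stars(0.009) == "**"


class TestApimParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            ApimParams(fixed={}, G=np.array([[1.0, 2.0], [2.0, 1.0]]),
                       sigma_m=1, sigma_c=1, rho=0.0)
        with pytest.raises(ValueError):
            ApimParams(fixed={"nonsense": 1.0}, G=np.eye(2),
                       sigma_m=1, sigma_c=1, rho=0.0)
        p = ApimParams(fixed={"m:intercept": 1.0}, G=np.eye(2),
                       sigma_m=1.0, sigma_c=2.0, rho=0.5)
        assert p.intercept_corr == pytest.approx(0.0)
        assert p.beta_vector(["m:intercept", "c:intercept"]).tolist() == [1.0, 0.0]
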