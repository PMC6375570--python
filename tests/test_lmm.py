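import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from teloherit.lmm import MixedModel, ModelSpec, satterthwaite_df
from teloherit.pipeline import PRESETS


def _one_way(k=6, m=4, sd_b=2.0, sd_w=1.0, seed=0):
    rng = np.random.default_rng(seed)
    g = np.repeat([f"g{i}" for i in range(k)], m)
    y = 10.0 + rng.normal(0, sd_b, k).repeat(m) + rng.normal(0, sd_w, k * m)
    return pd.DataFrame({"y": y, "g": g})


# -- agreement with closed forms --------------------------------------------

def test_no_random_terms_equals_ols():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"x": rng.normal(size=40)})
    df["y"] = 1.0 + 2.0 * df.x + rng.normal(size=40)
    fit = MixedModel.from_dataframe(df, ModelSpec("y", ("x",))).fit()
    X = np.column_stack([np.ones(40), df.x])
    beta = np.linalg.lstsq(X, df.y, rcond=None)[0]
    assert np.allclose(fit.params.to_numpy(), beta, rtol=1e-10)
    resid = df.y - X @ beta
    s2 = resid @ resid / (40 - 2)
    se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
    assert np.allclose(fit.bse.to_numpy(), se, rtol=1e-10)
    assert (fit.df == 38.0).all()


def test_balanced_one_way_matches_anova_estimator():
    k, m = 8, 5
    df = _one_way(k=k, m=m, seed=3)
    fit = MixedModel.from_dataframe(df, ModelSpec("y", (), ("g",))).fit()
    ybar_g = df.groupby("g", sort=False)["y"].mean().to_numpy()
    msb = m * np.var(ybar_g, ddof=1)
    msw = (df.groupby("g")["y"].var(ddof=1).sum() * (m - 1)) / (k * (m - 1))
    expected_between = (msb - msw) / m
    assert fit.varcomps["g"] == pytest.approx(expected_between, rel=1e-5)
    assert fit.varcomps["residual"] == pytest.approx(msw, rel=1e-5)


def test_reml_optimum_matches_brute_force_grid():
    """On a <=30-row one-random-factor instance the REML maximum found by the
    optimizer agrees with a dense grid/profile search over the variance
    ratio to 1e-4."""
    df = _one_way(k=5, m=5, seed=7)
    model = MixedModel.from_dataframe(df, ModelSpec("y", (), ("g",)))
    fit = model.fit()

    # independent brute-force profile over gamma using raw dense algebra
    y = df["y"].to_numpy()
    X = np.ones((25, 1))
    Z = pd.get_dummies(df["g"]).to_numpy(dtype=float)
    n, p = 25, 1

    def m2ll(gamma):
        V = np.eye(n) + gamma * Z @ Z.T
        Vi = np.linalg.inv(V)
        XtVX = X.T @ Vi @ X
        beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
        r = y - X @ beta
        rss = r @ Vi @ r
        s2 = rss / (n - p)
        return ((n - p) * np.log(s2) + np.linalg.slogdet(V)[1]
                + np.linalg.slogdet(XtVX)[1] + (n - p)
                + (n - p) * np.log(2 * np.pi))

    grid = np.exp(np.linspace(np.log(1e-4), np.log(1e3), 20001))
    vals = np.array([m2ll(g) for g in grid])
    assert -2 * fit.reml_loglik == pytest.approx(vals.min(), abs=1e-4)
    best_gamma = grid[vals.argmin()]
    assert fit.varcomps["g"] / fit.varcomps["residual"] == pytest.approx(
        best_gamma, rel=1e-2)


def test_profiled_gradient_matches_finite_differences(default_table):
    data, spec = PRESETS["parental_age_father"](default_table.head(200))
    model = MixedModel.from_dataframe(data, spec)
    lg = np.log(np.array([0.3, 0.7, 0.2, 0.05]))
    _, grad = model._profiled(lg, want_grad=True)
    num = np.empty_like(grad)
    h = 1e-6
    for i in range(len(lg)):
        e = np.zeros_like(lg)
        e[i] = h
        num[i] = (model._profiled(lg + e) - model._profiled(lg - e)) / (2 * h)
    assert np.allclose(grad, num, rtol=1e-5, atol=1e-6)


# -- invariances ------------------------------------------------------------

@pytest.fixture(scope="module")
def crossed_data():
    rng = np.random.default_rng(12)
    n = 240
    f = rng.integers(0, 30, n)
    g = rng.integers(0, 12, n)
    x = rng.normal(size=n)
    y = (3.0 + 1.2 * x + rng.normal(0, 1.5, 30)[f]
         + rng.normal(0, 1.0, 12)[g] + rng.normal(0, 1.0, n))
    return pd.DataFrame({"y": y, "x": x,
                         "f": [f"f{i}" for i in f],
                         "g": [f"g{i}" for i in g]})


def test_estimates_invariant_to_random_term_order(crossed_data):
    a = MixedModel.from_dataframe(
        crossed_data, ModelSpec("y", ("x",), ("f", "g"))).fit()
    b = MixedModel.from_dataframe(
        crossed_data, ModelSpec("y", ("x",), ("g", "f"))).fit()
    assert np.allclose(a.params.to_numpy(), b.params.to_numpy(), rtol=1e-6)
    assert a.varcomps["f"] == pytest.approx(b.varcomps["f"], rel=1e-4)


def test_response_shift_moves_only_intercept(crossed_data):
    base = MixedModel.from_dataframe(
        crossed_data, ModelSpec("y", ("x",), ("f", "g"))).fit()
    shifted = crossed_data.assign(y=crossed_data.y + 100.0)
    shift = MixedModel.from_dataframe(
        shifted, ModelSpec("y", ("x",), ("f", "g"))).fit()
    assert shift.params["(intercept)"] - base.params["(intercept)"] == \
        pytest.approx(100.0, abs=1e-6)
    assert shift.params["x"] == pytest.approx(base.params["x"], abs=1e-8)


def test_row_permutation_leaves_estimates_unchanged(crossed_data):
    perm = crossed_data.sample(frac=1.0, random_state=5).reset_index(drop=True)
    a = MixedModel.from_dataframe(
        crossed_data, ModelSpec("y", ("x",), ("f", "g"))).fit()
    b = MixedModel.from_dataframe(
        perm, ModelSpec("y", ("x",), ("f", "g"))).fit()
    assert np.allclose(a.params.to_numpy(), b.params.to_numpy(), rtol=1e-7)
    assert a.varcomps["f"] == pytest.approx(b.varcomps["f"], rel=1e-5)


def test_rank_deficient_design_is_flagged():
    df = _one_way(k=5, m=5, seed=2)
    df["const"] = 1.0
    with pytest.raises(ValueError, match="rank-deficient"):
        MixedModel.from_dataframe(df, ModelSpec("y", ("const",), ("g",)))


# -- degrees of freedom -----------------------------------------------------

def test_satterthwaite_df_balanced_cases():
    rng = np.random.default_rng(7)
    k, m = 8, 5
    g = np.repeat(np.arange(k), m)
    xg = rng.normal(size=k)
    y = (2.0 + 1.5 * xg[g] + rng.normal(0, 1, size=k)[g]
         + rng.normal(0, 0.7, size=k * m))
    df = pd.DataFrame({"y": y, "x": xg[g], "g": [f"g{i}" for i in g]})
    with_cov = MixedModel.from_dataframe(df, ModelSpec("y", ("x",), ("g",))).fit()
    # group-level covariate in a balanced design: denominator df = k - 2
    assert satterthwaite_df(with_cov, "x") == pytest.approx(k - 2, rel=1e-3)
    mean_only = MixedModel.from_dataframe(df, ModelSpec("y", (), ("g",))).fit()
    assert satterthwaite_df(mean_only, "(intercept)") == pytest.approx(
        k - 1, rel=1e-3)


def test_satterthwaite_df_bounded_by_design(default_table):
    data, spec = PRESETS["parental_age_father"](default_table)
    fit = MixedModel.from_dataframe(data, spec).fit()
    n_multi = data.loc[data.delta_age_father != 0, "father_id"].nunique()
    df_delta = satterthwaite_df(fit, "delta_age_father")
    assert n_multi - 1 <= df_delta <= fit.nobs - len(fit.params)


# -- independent cross-check against lme4/lmerTest --------------------------

@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_matches_lmer_reference(tmp_path, default_table):
    """Coefficients, SEs, variance components and Satterthwaite df agree
    with the lme4/lmerTest reference implementation on one simulated
    parental-age dataset."""
    data, spec = PRESETS["parental_age_father"](default_table)
    fit = MixedModel.from_dataframe(data, spec).fit()
    csv = tmp_path / "d.csv"
    data.to_csv(csv, index=False)
    script = tmp_path / "m.R"
    script.write_text(f"""
suppressMessages({{library(lme4); library(lmerTest)}})
d <- read.csv('{csv}')
m <- lmer(offspring_tl_bp ~ offspring_age_d + mean_age_father + delta_age_father
          + (1|father_id) + (1|nest_id) + (1|gel_id)
          + (0 + delta_age_father|father_id),
          data=d, REML=TRUE, control=lmerControl(optimizer='bobyqa'))
co <- summary(m)$coefficients
write.csv(co, '{tmp_path}/coef.csv')
cat(logLik(m), file='{tmp_path}/ll.txt')
""")
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "coef.csv", index_col=0)
    ref.index = ["(intercept)", "offspring_age_d", "mean_age_father",
                 "delta_age_father"]
    est, se, dfcol = ref.columns[0], ref.columns[1], ref.columns[2]
    assert np.allclose(fit.params[ref.index], ref[est], rtol=1e-4)
    assert np.allclose(fit.bse[ref.index], ref[se], rtol=1e-3)
    assert np.allclose(fit.df[ref.index], ref[dfcol], rtol=1e-2)
    ll = float((tmp_path / "ll.txt").read_text())
    assert fit.reml_loglik == pytest.approx(ll, abs=1e-3)


# -- model-spec parsing -----------------------------------------------------

def test_spec_string_parsing_round_trip():
    spec = ModelSpec.from_string(
        "tl ~ age + mean_age, random = father_id/nest_id + gel_id, "
        "slope = delta_age|father_id")
    assert spec.response == "tl"
    assert spec.fixed_terms == ("age", "mean_age")
    assert spec.expanded_intercepts() == ["father_id", "father_id:nest_id",
                                          "gel_id"]
    assert spec.random_slopes == (("delta_age", "father_id"),)


def test_boundary_variance_reported_as_zero_not_error():
    rng = np.random.default_rng(9)
    df = pd.DataFrame({
        "y": rng.normal(size=60),
        "g": [f"g{i}" for i in rng.integers(0, 6, 60)],
    })  # no true group variance
    fit = MixedModel.from_dataframe(df, ModelSpec("y", (), ("g",))).fit()
    assert fit.converged
    if "g" in fit.boundary:
        assert fit.varcomps["g"] == 0.0
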