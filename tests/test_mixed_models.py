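import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from spraytrack.mixed_models import (
    ModelSpec,
    fit_glmm,
    fit_lmm,
    predict_response,
)


def _binomial_no_re(seed=2, n_groups=12, per_group=10, trials=15):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        for _ in range(per_group):
            x = rng.normal()
            p = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
            rows.append({"g": f"g{g}", "x": x, "dead": rng.binomial(trials, p), "n": trials})
    return pd.DataFrame(rows)


def _poisson_no_re(seed=1, n_groups=12, per_group=12):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        for _ in range(per_group):
            x = rng.normal()
            rows.append({"g": f"g{g}", "x": x, "y": rng.poisson(np.exp(0.5 + 0.6 * x))})
    return pd.DataFrame(rows)


class TestModelSpec:
    def test_binomial_requires_trials(self):
        with pytest.raises(ValueError, match="trials"):
            ModelSpec("binomial", "dead", ["x"], ["g"])

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="family"):
            ModelSpec("negbin", "y", ["x"], ["g"])

    def test_slash_nesting_expands(self):
        spec = ModelSpec("poisson", "y", ["x"], ["date/line"])
        assert spec.random_intercepts == ["date", "date:line"]


class TestGlmLimit:
    """Zero random-effect variance collapses the GLMM onto the GLM (IRLS oracle)."""

    def test_binomial_matches_glm(self):
        df = _binomial_no_re()
        fit = fit_glmm(ModelSpec("binomial", "dead", ["x"], ["g"], trials="n"), df)
        glm = sm.GLM(
            np.column_stack([df.dead, df.n - df.dead]),
            sm.add_constant(df[["x"]]),
            family=sm.families.Binomial(),
        ).fit()
        assert fit.random_sd["g"] == pytest.approx(0.0, abs=1e-3)
        assert np.abs(fit.beta - glm.params.values).max() < 1e-4
        assert np.abs(fit.coefficients["se"].values - glm.bse.values).max() < 1e-4

    def test_poisson_matches_glm(self):
        df = _poisson_no_re()
        fit = fit_glmm(ModelSpec("poisson", "y", ["x"], ["g"]), df)
        glm = sm.GLM(
            df.y, sm.add_constant(df[["x"]]), family=sm.families.Poisson()
        ).fit()
        assert np.abs(fit.beta - glm.params.values).max() < 1e-4


class TestOlsLimit:
    def test_matches_ols(self):
        rng = np.random.default_rng(1)
        rows = []
        for g in range(10):
            for _ in range(10):
                x = rng.normal()
                rows.append({"g": f"g{g}", "x": x, "y": 1.0 + 2.0 * x + rng.normal()})
        df = pd.DataFrame(rows)
        fit = fit_lmm(ModelSpec("gaussian", "y", ["x"], ["g"]), df)
        ols = sm.OLS(df.y, sm.add_constant(df[["x"]])).fit()
        assert fit.random_sd["g"] == pytest.approx(0.0, abs=1e-6)
        assert np.abs(fit.beta - ols.params.values).max() < 1e-6

    def test_balanced_anova_closed_form(self):
        """Balanced one-way REML equals the method-of-moments ANOVA estimators."""
        rng = np.random.default_rng(5)
        n_groups, per_group = 8, 6
        u = rng.normal(0, 1.2, n_groups)
        rows = [
            {"g": f"g{i}", "y": 2.0 + u[i] + rng.normal(0, 0.7)}
            for i in range(n_groups)
            for _ in range(per_group)
        ]
        df = pd.DataFrame(rows)
        fit = fit_lmm(ModelSpec("gaussian", "y", [], ["g"]), df)
        group_means = df.groupby("g")["y"].mean()
        msb = per_group * ((group_means - group_means.mean()) ** 2).sum() / (n_groups - 1)
        msw = (
            df.groupby("g")["y"].apply(lambda s: ((s - s.mean()) ** 2).sum()).sum()
            / (n_groups * (per_group - 1))
        )
        assert fit.scale**2 == pytest.approx(msw, abs=1e-6)
        assert fit.random_sd["g"] ** 2 == pytest.approx((msb - msw) / per_group, abs=1e-6)


class TestEquivariance:
    """Shifting a covariate by c moves only the intercept, by -c * slope."""

    @pytest.mark.parametrize("family", ["binomial", "poisson", "gaussian"])
    def test_covariate_shift(self, family):
        if family == "binomial":
            df = _binomial_no_re(seed=3)
            spec = ModelSpec(family, "dead", ["x"], ["g"], trials="n")
            fitter = fit_glmm
        elif family == "poisson":
            df = _poisson_no_re(seed=3)
            spec = ModelSpec(family, "y", ["x"], ["g"])
            fitter = fit_glmm
        else:
            rng = np.random.default_rng(3)
            rows = []
            for g in range(8):
                ug = rng.normal(0, 0.5)
                for _ in range(12):
                    x = rng.normal()
                    rows.append({"g": f"g{g}", "x": x, "y": 1 + 0.5 * x + ug + rng.normal()})
            df = pd.DataFrame(rows)
            spec = ModelSpec(family, "y", ["x"], ["g"])
            fitter = fit_lmm
        base = fitter(spec, df)
        shift = 3.7
        shifted = df.assign(x=df.x + shift)
        moved = fitter(spec, shifted)
        assert moved.coef("x") == pytest.approx(base.coef("x"), abs=1e-5)
        assert moved.coef("Intercept") == pytest.approx(
            base.coef("Intercept") - shift * base.coef("x"), abs=1e-5
        )


class TestPredict:
    def test_logit_zero_predictor_is_half(self):
        df = _binomial_no_re(seed=4)
        spec = ModelSpec("binomial", "dead", ["x"], ["g"], trials="n")
        fit = fit_glmm(spec, df)
        x_at_zero = -fit.coef("Intercept") / fit.coef("x")
        pred = predict_response(fit, pd.DataFrame({"x": [x_at_zero]}))
        assert pred[0] == pytest.approx(0.5, abs=1e-10)

    def test_unknown_random_level_errors(self):
        df = _poisson_no_re(seed=4)
        fit = fit_glmm(ModelSpec("poisson", "y", ["x"], ["g"]), df)
        with pytest.raises(ValueError, match="unknown level"):
            predict_response(
                fit, pd.DataFrame({"x": [0.0], "g": ["nonexistent"]}), include_random=True
            )

    def test_conditional_prediction_uses_modes(self):
        rng = np.random.default_rng(8)
        rows = []
        for g in range(10):
            ug = rng.normal(0, 1.0)
            for _ in range(20):
                rows.append({"g": f"g{g}", "y": rng.poisson(np.exp(1.0 + ug))})
        df = pd.DataFrame(rows)
        fit = fit_glmm(ModelSpec("poisson", "y", [], ["g"]), df)
        pred = predict_response(
            fit, pd.DataFrame({"g": [f"g{i}" for i in range(10)]}), include_random=True
        )
        observed = df.groupby("g")["y"].mean().to_numpy()
        # conditional means track group means (with shrinkage)
        assert np.corrcoef(pred, observed)[0, 1] > 0.98


class TestDegenerateDesigns:
    def test_rank_deficient_design_rejected(self):
        df = _poisson_no_re()
        df["x2"] = 2 * df["x"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_glmm(ModelSpec("poisson", "y", ["x", "x2"], ["g"]), df)

    def test_gaussian_family_routed_to_lmm(self):
        df = _poisson_no_re()
        with pytest.raises(ValueError, match="fit_lmm"):
            fit_glmm(ModelSpec("gaussian", "y", ["x"], ["g"]), df)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestReferenceImplementation:
    """Laplace fits agree with the reference mixed-model implementation (lme4)."""

    def _run_lme4(self, tmp_path, csv, script):
        (tmp_path / "fit.R").write_text(script)
        out = subprocess.run(
            ["Rscript", str(tmp_path / "fit.R")],
            capture_output=True,
            text=True,
            timeout=300,
        )
        assert out.returncode == 0, out.stderr
        return json.loads(out.stdout.strip().splitlines()[-1])

    def test_binomial_nested(self, tmp_path):
        rng = np.random.default_rng(42)
        rows = []
        for d in range(7):
            ud = rng.normal(0, 0.3)
            for l in range(3):
                ul = rng.normal(0, 0.9)
                for dist in (10, 30, 50, 70):
                    eta = 1.5 - 0.08 * dist + ud + ul
                    p = 1 / (1 + np.exp(-eta))
                    rows.append(
                        {
                            "date": f"d{d}",
                            "line": f"L{l}",
                            "distance": dist,
                            "dead": rng.binomial(20, p),
                            "n": 20,
                        }
                    )
        df = pd.DataFrame(rows)
        csv = tmp_path / "data.csv"
        df.to_csv(csv, index=False)
        ours = fit_glmm(
            ModelSpec("binomial", "dead", ["distance"], ["date/line"], trials="n"), df
        )
        ref = self._run_lme4(
            tmp_path,
            csv,
            f"""
            suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
            d <- read.csv("{csv}")
            f <- suppressWarnings(glmer(cbind(dead, n - dead) ~ distance +
                 (1|date) + (1|date:line), data = d, family = binomial))
            cat(toJSON(list(beta = unname(fixef(f)),
                            sd = unname(as.data.frame(VarCorr(f))$sdcor),
                            ll = as.numeric(logLik(f))), digits = 10))
            """,
        )
        assert np.abs(np.array(ref["beta"]) - ours.beta).max() < 1e-2
        assert ours.loglik == pytest.approx(ref["ll"][0], abs=1e-2)
        assert sorted(ref["sd"]) == pytest.approx(
            sorted(ours.random_sd.values()), abs=5e-2
        )

    def test_poisson_crossed(self, tmp_path):
        rng = np.random.default_rng(9)
        rows = []
        u_c = rng.normal(0, 0.6, 20)
        u_t = rng.normal(0, 0.4, 30)
        for c in range(20):
            for t in range(30):
                x = rng.normal()
                eta = 0.5 + 0.4 * x + u_c[c] + u_t[t]
                rows.append(
                    {"c": f"c{c}", "t": f"t{t}", "x": x, "y": rng.poisson(np.exp(eta))}
                )
        df = pd.DataFrame(rows)
        csv = tmp_path / "data.csv"
        df.to_csv(csv, index=False)
        ours = fit_glmm(ModelSpec("poisson", "y", ["x"], ["c", "t"]), df)
        ref = self._run_lme4(
            tmp_path,
            csv,
            f"""
            suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
            d <- read.csv("{csv}")
            f <- suppressWarnings(glmer(y ~ x + (1|c) + (1|t), data = d,
                 family = poisson))
            cat(toJSON(list(beta = unname(fixef(f)),
                            sd = unname(as.data.frame(VarCorr(f))$sdcor),
                            ll = as.numeric(logLik(f))), digits = 10))
            """,
        )
        assert np.abs(np.array(ref["beta"]) - ours.beta).max() < 1e-2
        assert sorted(ref["sd"]) == pytest.approx(
            sorted(ours.random_sd.values()), abs=5e-2
        )
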