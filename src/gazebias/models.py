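"""Linear mixed-effects moderation models for free-viewing dwell data.

The modelling layer is organised statsmodels-style: :class:`MixedModel` is
built from a formula and a tidy data frame, ``fit()`` returns a
:class:`MixedModelResults` carrying standardized fixed-effect estimates with
Satterthwaite degrees of freedom, type-III F lines, and the follow-up
machinery (range-averaged marginal means and simple slopes) used to unpack
interactions.

Estimation delegates to ``statsmodels`` ``MixedLM`` (Gaussian, subject
random intercept, maximum likelihood).  Satterthwaite df are computed here:
the profile log-likelihood in the two variance components
(sigma^2_subject, sigma^2_residual) is differentiated numerically to obtain
their asymptotic covariance, and for a contrast ``c`` the delta method on
``c' Cov(beta) c`` gives ``df = 2 (c'Vc)^2 / Var(c'Vc)``.  When the
random-intercept variance sits on the boundary or the information matrix is
not positive definite, a residual-df fallback is used and labeled in output.

``run_model_suite`` fits the four study models:

* M1  - dwell ~ image_emotion x condition x image_location on
        emotional-pair trials (two rows per trial: the emotional and the
        neutral image's dwell);
* M1b - dwell ~ image_location on neutral-neutral trials;
* M2  - bias ~ BDI x condition on per-trial emotional bias scores, with
        the condition contrast averaged over the BDI ranges observed in
        each group;
* M3  - dwell ~ age x condition x ERQ-preference, separately within the
        control and MDD groups, with age simple slopes at preference
        levels;
* M4  - dwell ~ age x condition x ERQ-preference x BDI across everyone.

Factors are sum-to-zero coded so the F lines are type-III marginal tests;
continuous outcome and predictors are standardized within each model's
analysis subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from . import scores as _scores

__all__ = [
    "ScalingRecord",
    "standardize",
    "MixedModel",
    "MixedModelResults",
    "ModelSpec",
    "fit_lmm",
    "run_model_suite",
    "ModelSuiteReport",
]


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Standardization


@dataclass(frozen=True)
class ScalingRecord:
    """Per-variable (mean, sd) pairs used to z-score an analysis subset."""

    scales: Mapping[str, tuple[float, float]]

    def transform(self, var: str, values):
        mean, sd = self.scales[var]
        return (np.asarray(values, dtype=float) - mean) / sd

    def inverse(self, var: str, values):
        mean, sd = self.scales[var]
        return np.asarray(values, dtype=float) * sd + mean


def standardize(data: pd.DataFrame, variables: Sequence[str]) -> tuple[pd.DataFrame, ScalingRecord]:
    """Center and scale the named columns by their sample mean and SD.

    Raises on zero variance, naming the offending variable.
    """
    out = data.copy()
    scales = {}
    for var in variables:
        x = out[var].to_numpy(dtype=float)
        mean = float(np.nanmean(x))
        sd = float(np.nanstd(x, ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise ModelError(f"cannot standardize {var!r}: zero variance")
        out[var] = (x - mean) / sd
        scales[var] = (mean, sd)
    return out, ScalingRecord(scales)


# ---------------------------------------------------------------------------
# Satterthwaite machinery for the random-intercept Gaussian LMM


class _RandomInterceptInfo:
    """Profile likelihood and contrast variances for a random-intercept LMM.

    Works from sufficient statistics (X'X, per-group sums), so evaluating
    the fixed-effect covariance at perturbed variance components is cheap.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.y = y
        self.X = X
        self.codes, self.n_i = np.unique(groups, return_inverse=False), None
        codes, inverse = np.unique(groups, return_inverse=True)
        self.inverse = inverse
        self.n_groups = len(codes)
        self.n_i = np.bincount(inverse).astype(float)
        self.N, self.p = X.shape
        self.xtx = X.T @ X
        self.xty = X.T @ y
        self.yty = float(y @ y)
        # per-group sums of columns of X and of y
        self.Sx = np.zeros((self.n_groups, self.p))
        for j in range(self.p):
            self.Sx[:, j] = np.bincount(inverse, weights=X[:, j])
        self.Sy = np.bincount(inverse, weights=y)

    def beta_cov(self, s2u: float, s2e: float) -> np.ndarray:
        w = s2u / (s2e + self.n_i * s2u)
        xvx = (self.xtx - (self.Sx.T * w) @ self.Sx) / s2e
        return np.linalg.inv(xvx)

    def _xvy(self, s2u: float, s2e: float) -> np.ndarray:
        w = s2u / (s2e + self.n_i * s2u)
        return (self.xty - self.Sx.T @ (w * self.Sy)) / s2e

    def profile_loglik(self, s2u: float, s2e: float) -> float:
        if s2e <= 0 or s2u < 0:
            return -np.inf
        w = s2u / (s2e + self.n_i * s2u)
        xvx_inv = self.beta_cov(s2u, s2e)
        beta = xvx_inv @ self._xvy(s2u, s2e)
        r = self.y - self.X @ beta
        Sr = np.bincount(self.inverse, weights=r, minlength=self.n_groups)
        quad = (float(r @ r) - float((w * Sr) @ Sr)) / s2e
        logdet = float(np.sum((self.n_i - 1) * np.log(s2e) + np.log(s2e + self.n_i * s2u)))
        return -0.5 * (logdet + quad + self.N * np.log(2 * np.pi))

    def theta_cov(self, s2u: float, s2e: float) -> np.ndarray | None:
        """Asymptotic covariance of (s2u, s2e) from the numerical Hessian of
        the profile log-likelihood; None when not positive definite."""
        h_u = max(1e-6, 1e-4 * max(s2u, s2e))
        h_e = max(1e-6, 1e-4 * s2e)
        f = self.profile_loglik

        def d2(fun, x, h):
            return (fun(x + h) - 2 * fun(x) + fun(x - h)) / h**2

        if s2u - h_u < 0:  # boundary: no curvature in the u direction
            return None
        H = np.empty((2, 2))
        H[0, 0] = d2(lambda v: f(v, s2e), s2u, h_u)
        H[1, 1] = d2(lambda v: f(s2u, v), s2e, h_e)
        fpp = f(s2u + h_u, s2e + h_e)
        fpm = f(s2u + h_u, s2e - h_e)
        fmp = f(s2u - h_u, s2e + h_e)
        fmm = f(s2u - h_u, s2e - h_e)
        H[0, 1] = H[1, 0] = (fpp - fpm - fmp + fmm) / (4 * h_u * h_e)
        info = -H
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.diag(cov) > 0):
            return None
        return cov

    def contrast_df(self, c: np.ndarray, s2u: float, s2e: float, theta_cov: np.ndarray | None) -> float | None:
        """Satterthwaite df for a single contrast; None -> caller falls back."""
        if theta_cov is None:
            return None
        f0 = float(c @ self.beta_cov(s2u, s2e) @ c)
        h_u = max(1e-6, 1e-4 * max(s2u, s2e))
        h_e = max(1e-6, 1e-4 * s2e)
        gu = (
            float(c @ self.beta_cov(s2u + h_u, s2e) @ c) - float(c @ self.beta_cov(max(s2u - h_u, 0.0), s2e) @ c)
        ) / (h_u + min(h_u, s2u))
        ge = (float(c @ self.beta_cov(s2u, s2e + h_e) @ c) - float(c @ self.beta_cov(s2u, s2e - h_e) @ c)) / (
            2 * h_e
        )
        g = np.array([gu, ge])
        var_f = float(g @ theta_cov @ g)
        if var_f <= 0:
            return None
        df = 2.0 * f0**2 / var_f
        if not np.isfinite(df) or df < 1.0:
            return None
        return df


# ---------------------------------------------------------------------------
# Model / Results


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description: formula, grouping, which variables to
    standardize, and an optional row filter applied before fitting."""

    formula: str
    standardize: tuple[str, ...] = ()
    groups: str = "subject_id"
    data_filter: Callable[[pd.DataFrame], pd.DataFrame] | None = None
    label: str = ""


class MixedModel:
    """Gaussian linear mixed model with a subject random intercept.

    Parameters
    ----------
    formula : patsy formula for the fixed effects, e.g.
        ``"bias ~ bdi * C(condition, Sum)"``.  Sum-code factors for
        type-III F lines.
    data : tidy per-observation data frame.
    groups : column holding the subject identifier (random intercept).
    standardize_vars : continuous columns (outcome and predictors) z-scored
        over this analysis subset before fitting; the scaling record is kept
        on the results for back-transformation.
    """

    def __init__(
        self,
        formula: str,
        data: pd.DataFrame,
        groups: str = "subject_id",
        standardize_vars: Sequence[str] = (),
    ):
        if groups not in data.columns:
            raise ModelError(f"grouping column {groups!r} not in data")
        data = data.dropna(subset=[groups]).reset_index(drop=True)
        if data[groups].nunique() < 2:
            raise ModelError("need at least 2 subjects to fit a random intercept")
        self.formula = formula
        self.groups_col = groups
        self.data, self.scaling = standardize(data, standardize_vars) if standardize_vars else (data.copy(), ScalingRecord({}))
        try:
            y_mat, x_mat = patsy.dmatrices(formula, self.data, return_type="dataframe", NA_action="raise")
        except patsy.PatsyError as err:
            raise ModelError(f"cannot build design matrix for {formula!r}: {err}") from err
        self.design_info = x_mat.design_info
        for factor, info in self.design_info.factor_infos.items():
            if info.type == "categorical" and len(info.categories) < 2:
                raise ModelError(f"factor {factor.name()} has a single level in the analysis subset")
        self.endog = y_mat.to_numpy(dtype=float).ravel()
        self.exog = x_mat.to_numpy(dtype=float)
        self.exog_names = list(x_mat.columns)
        self.group_labels = self.data[groups].to_numpy()

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, **kwargs) -> "MixedModel":
        return cls(formula, data, **kwargs)

    def fit(self) -> "MixedModelResults":
        """Maximum-likelihood fit; non-convergence is flagged, never silent."""
        exog = pd.DataFrame(self.exog, columns=self.exog_names)
        model = MixedLM(self.endog, exog, groups=self.group_labels)
        converged = True
        messages: list[str] = []
        # Optimizers can land on the sigma_u = 0 boundary (singular Hessian);
        # try several and keep the best converged log-likelihood.
        res, best_llf = None, -np.inf
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            for method in ("lbfgs", "bfgs", "powell", "cg", "nm"):
                if res is not None and method in ("cg", "nm"):
                    break  # a quasi-Newton or Powell fit already succeeded
                try:
                    cand = model.fit(reml=False, method=method)
                except (np.linalg.LinAlgError, ValueError) as err:
                    messages.append(f"{method}: {err}")
                    continue
                if np.isfinite(cand.llf) and cand.llf > best_llf + 1e-10:
                    res, best_llf = cand, float(cand.llf)
            for w in caught:
                messages.append(str(w.message))
        if res is None:
            # statsmodels can fail outright when sigma^2_u sits on the zero
            # boundary (singular Hessian); fall back to maximizing the
            # profile likelihood in the two variance components directly.
            res = self._profile_ml_fallback()
            messages.append("profile-likelihood fallback fit (boundary variance components)")
        if not getattr(res, "converged", True):
            converged = False
        if any("converge" in m.lower() for m in messages):
            converged = False
        s2u = float(np.atleast_2d(res.cov_re)[0, 0])
        s2e = float(res.scale)
        return MixedModelResults(self, res, s2u, s2e, converged, messages)

    def _profile_ml_fallback(self):
        from scipy import optimize
        from types import SimpleNamespace

        info = _RandomInterceptInfo(self.endog, self.exog, self.group_labels)
        var_y = float(np.var(self.endog)) or 1.0

        def neg_ll(log_theta):
            return -info.profile_loglik(np.exp(log_theta[0]), np.exp(log_theta[1]))

        best = None
        for s2u0 in (1e-6, 0.1 * var_y, 0.5 * var_y):
            opt = optimize.minimize(
                neg_ll,
                np.log([max(s2u0, 1e-8), 0.8 * var_y]),
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
            )
            if best is None or opt.fun < best.fun:
                best = opt
        s2u, s2e = np.exp(best.x)
        beta = info.beta_cov(s2u, s2e) @ info._xvy(s2u, s2e)
        return SimpleNamespace(
            fe_params=beta,
            cov_re=np.array([[s2u]]),
            scale=s2e,
            llf=-best.fun,
            converged=bool(best.success),
        )


@dataclass(frozen=True)
class ContrastEstimate:
    label: str
    estimate: float
    se: float
    df: float
    t: float
    p: float
    ci_low: float
    ci_high: float
    df_method: str  # "satterthwaite" or "residual"


class MixedModelResults:
    """Fitted fixed effects, their uncertainty, and follow-up machinery."""

    def __init__(self, model: MixedModel, sm_result, s2u: float, s2e: float, converged: bool, messages: list[str]):
        self.model = model
        self._sm = sm_result
        self.sigma2_subject = s2u
        self.sigma2_residual = s2e
        self.converged = converged
        self.messages = messages
        self.params = np.asarray(sm_result.fe_params, dtype=float)
        self.n_obs = len(model.endog)
        self.n_subjects = int(pd.unique(model.group_labels).size)
        self._info = _RandomInterceptInfo(model.endog, model.exog, model.group_labels)
        # Fixed-effect covariance at the ML variance components (model-based).
        self.cov_params = self._info.beta_cov(s2u, s2e)
        self._theta_cov = self._info.theta_cov(s2u, s2e)
        self._residual_df = max(self.n_obs - len(self.params), 1)

    # -- core linear-combination inference -------------------------------

    def contrast(self, c: np.ndarray, label: str = "contrast") -> ContrastEstimate:
        """Estimate, SE, Satterthwaite df, t, p and 95% CI for c'beta."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.params)
        se = float(np.sqrt(c @ self.cov_params @ c))
        df = self._info.contrast_df(c, self.sigma2_subject, self.sigma2_residual, self._theta_cov)
        method = "satterthwaite"
        if df is None:
            df, method = float(self._residual_df), "residual"
        t = est / se if se > 0 else np.inf * np.sign(est)
        p = float(2 * stats.t.sf(abs(t), df))
        half = float(stats.t.ppf(0.975, df) * se)
        return ContrastEstimate(label, est, se, float(df), float(t), p, est - half, est + half, method)

    def fixed_effects(self) -> pd.DataFrame:
        """Per-coefficient standardized estimates with SE, df, t, p and CI."""
        rows = []
        for i, name in enumerate(self.model.exog_names):
            c = np.zeros(len(self.params))
            c[i] = 1.0
            ce = self.contrast(c, label=name)
            rows.append(
                {
                    "term": name,
                    "estimate": ce.estimate,
                    "se": ce.se,
                    "df": ce.df,
                    "t": ce.t,
                    "p": ce.p,
                    "ci_low": ce.ci_low,
                    "ci_high": ce.ci_high,
                    "df_method": ce.df_method,
                }
            )
        return pd.DataFrame(rows)

    def anova(self) -> pd.DataFrame:
        """Type-III marginal F tests per model term (sum-coded factors).

        Multi-df terms combine per-eigencontrast Satterthwaite df the way
        lmerTest does; the fallback residual df is labeled.
        """
        rows = []
        for term, sl in self.model.design_info.term_slices.items():
            name = term.name()
            if name == "Intercept":
                continue
            idx = np.arange(sl.start, sl.stop)
            if len(idx) == 0:
                continue
            L = np.zeros((len(idx), len(self.params)))
            L[np.arange(len(idx)), idx] = 1.0
            est = L @ self.params
            M = L @ self.cov_params @ L.T
            q = len(idx)
            try:
                f_stat = float(est @ np.linalg.solve(M, est)) / q
            except np.linalg.LinAlgError:
                continue
            # eigencontrasts for the denominator df
            vals, vecs = np.linalg.eigh(M)
            df_method = "satterthwaite"
            dfs = []
            for j in range(q):
                if vals[j] <= 0:
                    dfs = []
                    break
                lj = (vecs[:, j] / np.sqrt(vals[j])) @ L
                dj = self._info.contrast_df(lj, self.sigma2_subject, self.sigma2_residual, self._theta_cov)
                if dj is None:
                    dfs = []
                    break
                dfs.append(dj)
            if dfs and all(d > 2 for d in dfs):
                E = sum(d / (d - 2) for d in dfs)
                df2 = 2 * E / (E - q) if E > q else float(self._residual_df)
            else:
                df2, df_method = float(self._residual_df), "residual"
            p = float(stats.f.sf(f_stat, q, df2))
            rows.append({"term": name, "F": f_stat, "df1": q, "df2": df2, "p": p, "df_method": df_method})
        return pd.DataFrame(rows)

    # -- reference grids and marginal estimates ---------------------------

    def _factor_levels(self) -> dict[str, list]:
        levels = {}
        for factor, info in self.model.design_info.factor_infos.items():
            if info.type == "categorical":
                levels[factor.name()] = list(info.categories)
        return levels

    def _variables(self) -> list[str]:
        return [f.name() for f in self.model.design_info.factor_infos]

    @staticmethod
    def _base_name(factor_name: str) -> str:
        # "C(condition, Sum)" -> "condition"
        if factor_name.startswith("C(") and factor_name.endswith(")"):
            return factor_name[2:-1].split(",")[0].strip()
        return factor_name

    def _grid_rows(self, overrides: Mapping[str, object]) -> np.ndarray:
        """Average design row over a reference grid.

        Factors not overridden are averaged over their levels with equal
        weight; continuous variables not overridden sit at their mean in the
        (standardized) analysis data.
        """
        levels = self._factor_levels()
        columns: dict[str, list] = {}
        grid = [dict()]
        for fname in self._variables():
            base = self._base_name(fname)
            key = base if base in overrides else (fname if fname in overrides else None)
            if key is not None:
                vals = overrides[key]
                vals = vals if isinstance(vals, (list, tuple, np.ndarray)) else [vals]
            elif fname in levels:
                vals = levels[fname]
            else:
                vals = [float(self.model.data[base].mean())]
            grid = [dict(g, **{base: v}) for g in grid for v in vals]
        frame = pd.DataFrame(grid)
        (mat,) = patsy.build_design_matrices([self.model.design_info], frame, return_type="dataframe")
        return mat.to_numpy(dtype=float).mean(axis=0)

    def emmeans_over_range(
        self,
        factor: str,
        level_a: str,
        level_b: str,
        covariate: str | None = None,
        covariate_values: Sequence[float] | None = None,
        label: str | None = None,
        adjustment_factor: int = 1,
    ) -> ContrastEstimate:
        """Factor contrast (level_a - level_b) with the covariate averaged
        with equal weight over the supplied grid of (model-scale) values.

        With no covariate the plain factor contrast is returned.
        """
        over: dict[str, object] = {}
        if covariate is not None:
            if covariate not in [self._base_name(v) for v in self._variables()]:
                raise ModelError(f"covariate {covariate!r} not in the model")
            over[covariate] = list(covariate_values if covariate_values is not None else [0.0])
        xa = self._grid_rows({**over, factor: level_a})
        xb = self._grid_rows({**over, factor: level_b})
        ce = self.contrast(xa - xb, label=label or f"{factor}: {level_a} - {level_b}")
        if adjustment_factor > 1:
            p_adj = min(1.0, ce.p * adjustment_factor)
            ce = ContrastEstimate(ce.label, ce.estimate, ce.se, ce.df, ce.t, p_adj, ce.ci_low, ce.ci_high, ce.df_method)
        return ce

    def simple_slopes(
        self,
        var: str,
        moderator: str,
        levels: Sequence[float],
        by_factor: str | None = None,
        level_labels: Sequence[str] | None = None,
    ) -> pd.DataFrame:
        """Slope of ``var`` (per model-scale unit) at each moderator level,
        optionally within each level of a factor.

        The slope is the difference of average design rows at ``var`` = 1
        vs 0, a linear combination of the fixed effects.
        """
        var_names = [self._base_name(v) for v in self._variables()]
        for v in (var, moderator):
            if v not in var_names:
                raise ModelError(f"variable {v!r} not in the model")
        factor_levels = self._factor_levels()
        if by_factor is not None:
            match = [f for f in factor_levels if self._base_name(f) == by_factor or f == by_factor]
            if not match:
                raise ModelError(f"factor {by_factor!r} not in the model")
            by_name = match[0]
            by_vals: list = factor_levels[by_name]
        else:
            by_name, by_vals = None, [None]

        rows = []
        for j, lev in enumerate(levels):
            for bv in by_vals:
                over: dict[str, object] = {moderator: lev}
                if by_name is not None:
                    over[self._base_name(by_name)] = bv
                x1 = self._grid_rows({**over, var: 1.0})
                x0 = self._grid_rows({**over, var: 0.0})
                lab = level_labels[j] if level_labels is not None else f"{moderator}={lev:g}"
                ce = self.contrast(x1 - x0, label=lab)
                rows.append(
                    {
                        "moderator_level": lev,
                        "level_label": lab,
                        **({"factor_level": bv} if by_name is not None else {}),
                        "slope": ce.estimate,
                        "se": ce.se,
                        "df": ce.df,
                        "t": ce.t,
                        "p": ce.p,
                        "ci_low": ce.ci_low,
                        "ci_high": ce.ci_high,
                        "df_method": ce.df_method,
                    }
                )
        return pd.DataFrame(rows)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        lines = [
            f"Linear mixed model (ML, random intercept by {self.model.groups_col})",
            f"  formula: {self.model.formula}",
            f"  observations: {self.n_obs}   subjects: {self.n_subjects}   converged: {self.converged}",
            f"  var(subject) = {self.sigma2_subject:.4f}   var(residual) = {self.sigma2_residual:.4f}",
            "",
            "Fixed effects (standardized):",
        ]
        fe = self.fixed_effects()
        lines.append(
            f"  {'term':<42}{'beta':>9}{'SE':>8}{'df':>9}{'t':>8}{'p':>8}  95% CI"
        )
        for row in fe.itertuples(index=False):
            lines.append(
                f"  {row.term:<42}{row.estimate:>9.3f}{row.se:>8.3f}{row.df:>9.1f}"
                f"{row.t:>8.3f}{row.p:>8.3f}  [{row.ci_low:.3f}, {row.ci_high:.3f}]"
            )
        an = self.anova()
        if len(an):
            lines += ["", "Type-III F tests:"]
            for row in an.itertuples(index=False):
                lines.append(
                    f"  {row.term:<52} F({row.df1:g}, {row.df2:.1f}) = {row.F:.3f}, p = {row.p:.3f}"
                )
        return "\n".join(lines)


def fit_lmm(spec: ModelSpec, data: pd.DataFrame) -> MixedModelResults:
    """Fit a :class:`ModelSpec`: filter, standardize within the subset, fit."""
    subset = spec.data_filter(data) if spec.data_filter is not None else data
    if len(subset) == 0:
        raise ModelError(f"empty analysis subset for model {spec.label or spec.formula!r}")
    model = MixedModel(spec.formula, subset.reset_index(drop=True), groups=spec.groups, standardize_vars=spec.standardize)
    return model.fit()


# ---------------------------------------------------------------------------
# The model suite


def build_model_frames(dwell: pd.DataFrame, participants: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Assemble the per-model data frames from kept trial dwell records and
    participant traits.

    Returns frames: ``dwell_long`` (two rows per emotional-pair trial, one
    per image), ``neutral_long`` (two rows per neutral-neutral trial),
    ``bias`` (one row per emotional-pair trial with a defined bias score),
    and ``emotional`` (one row per emotional-pair trial, dwell on the
    emotional image as DV).
    """
    erq = _scores.erq_table(participants)
    traits = participants[["subject_id", "group", "age", "bdi_sum"]].merge(erq, on="subject_id")
    traits = traits.rename(columns={"bdi_sum": "bdi"})

    emo = dwell.loc[dwell["condition"].isin(["positive-neutral", "negative-neutral"])].copy()
    long_rows = []
    for which, col in (("emotional", "dwell_emotional_ms"), ("neutral", "dwell_neutral_ms")):
        part = emo[["subject_id", "trial_id", "condition", "emotional_side"]].copy()
        part["image_emotion"] = which
        part["dwell"] = emo[col].to_numpy(dtype=float)
        long_rows.append(part)
    dwell_long = pd.concat(long_rows, ignore_index=True).rename(columns={"emotional_side": "image_location"})

    neu = dwell.loc[dwell["condition"] == "neutral-neutral"]
    neu_rows = []
    for side, col in (("left", "dwell_left_ms"), ("right", "dwell_right_ms")):
        part = neu[["subject_id", "trial_id", "condition"]].copy()
        part["image_location"] = side
        part["dwell"] = neu[col].to_numpy(dtype=float)
        neu_rows.append(part)
    neutral_long = pd.concat(neu_rows, ignore_index=True)

    bias = _scores.bias_table(dwell)
    emotional = emo[["subject_id", "trial_id", "condition"]].copy()
    emotional["dwell"] = emo["dwell_emotional_ms"].to_numpy(dtype=float)
    emotional["bias"] = (
        emo["dwell_emotional_ms"] / (emo["dwell_emotional_ms"] + emo["dwell_neutral_ms"])
    ).to_numpy(dtype=float)

    frames = {}
    for name, frame in (
        ("dwell_long", dwell_long),
        ("neutral_long", neutral_long),
        ("bias", bias),
        ("emotional", emotional),
    ):
        frames[name] = frame.merge(traits, on="subject_id", how="left")
    return frames


@dataclass
class ModelSuiteReport:
    """All fits and follow-up estimates from one run of the model suite."""

    fits: dict[str, MixedModelResults]
    bias_contrasts: dict[str, ContrastEstimate] = field(default_factory=dict)
    age_slopes: dict[str, pd.DataFrame] = field(default_factory=dict)
    preference_levels: dict[str, list[float]] = field(default_factory=dict)

    def summary(self) -> str:
        parts = []
        for name, fit in self.fits.items():
            parts.append(f"== {name} ==")
            parts.append(fit.summary())
            parts.append("")
        if self.bias_contrasts:
            parts.append("== Condition contrast (positive-neutral minus negative-neutral) averaged over BDI range ==")
            for label, ce in self.bias_contrasts.items():
                parts.append(
                    f"  {label:<16} beta = {ce.estimate:.3f}, t({ce.df:.0f}) = {ce.t:.3f}, "
                    f"p = {ce.p:.3f}, 95% CI [{ce.ci_low:.3f}, {ce.ci_high:.3f}]"
                )
            parts.append("")
        for group, tbl in self.age_slopes.items():
            parts.append(f"== Age slopes at ERQ-preference levels ({group}) ==")
            for row in tbl.itertuples(index=False):
                parts.append(
                    f"  {row.level_label:<24} {row.factor_level:<18} slope = {row.slope:.3f}, "
                    f"t({row.df:.0f}) = {row.t:.3f}, p = {row.p:.3f}"
                )
            parts.append("")
        return "\n".join(parts)

    def plot_age_slopes(self, group: str = "control", ax=None):
        """Diagnostic figure: age slope (with 95% CI) per condition across the
        ERQ-preference levels, mirroring the simple-slopes unpacking of the
        age x condition x preference interaction."""
        import matplotlib.pyplot as plt

        tbl = self.age_slopes[group]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        for cond, sub in tbl.groupby("factor_level"):
            sub = sub.sort_values("moderator_level")
            ax.errorbar(
                sub["moderator_level"],
                sub["slope"],
                yerr=[sub["slope"] - sub["ci_low"], sub["ci_high"] - sub["slope"]],
                marker="o",
                capsize=3,
                label=str(cond),
            )
        ax.axhline(0.0, color="gray", lw=0.8)
        ax.set_xlabel("ERQ preference level (SD units)")
        ax.set_ylabel("age slope on emotional dwell (standardized)")
        ax.set_title(f"Age slopes by reappraisal preference ({group})")
        ax.legend()
        return ax

    def to_frame(self) -> pd.DataFrame:
        """One tidy row per reported term/contrast across the suite."""
        rows = []
        for name, fit in self.fits.items():
            fe = fit.fixed_effects()
            fe.insert(0, "model", name)
            fe.insert(1, "kind", "coefficient")
            rows.append(fe)
            an = fit.anova()
            if len(an):
                an.insert(0, "model", name)
                an.insert(1, "kind", "anova")
                rows.append(an)
        for label, ce in self.bias_contrasts.items():
            rows.append(
                pd.DataFrame(
                    [
                        {
                            "model": "M2",
                            "kind": "range_contrast",
                            "term": label,
                            "estimate": ce.estimate,
                            "se": ce.se,
                            "df": ce.df,
                            "t": ce.t,
                            "p": ce.p,
                            "ci_low": ce.ci_low,
                            "ci_high": ce.ci_high,
                        }
                    ]
                )
            )
        for group, tbl in self.age_slopes.items():
            t = tbl.rename(columns={"slope": "estimate", "level_label": "term"}).copy()
            t.insert(0, "model", f"M3_{group}")
            t.insert(1, "kind", "simple_slope")
            rows.append(t)
        return pd.concat(rows, ignore_index=True)


DEFAULT_PREF_MULTIPLIERS = (-1.5, -1.0, 0.0, 1.0, 1.5)


def run_model_suite(
    dwell: pd.DataFrame,
    participants: pd.DataFrame,
    dv: str = "dwell",
    bdi_ranges: Mapping[str, tuple[int, int]] | None = None,
    pref_multipliers: Sequence[float] = DEFAULT_PREF_MULTIPLIERS,
) -> ModelSuiteReport:
    """Fit the four study models and their follow-ups.

    ``dv`` selects the DV for the moderation models M3/M4: ``"dwell"``
    (per-trial dwell on the emotional image, the default) or ``"bias"``.
    ``bdi_ranges`` gives the raw BDI ranges over which the M2 condition
    contrast is averaged (defaults control 0-8, MDD 10-47).
    """
    if dv not in ("dwell", "bias"):
        raise ModelError(f"dv must be 'dwell' or 'bias', got {dv!r}")
    frames = build_model_frames(dwell, participants)
    bdi_ranges = dict(bdi_ranges or {"control": (0, 8), "mdd": (10, 47)})

    fits: dict[str, MixedModelResults] = {}
    fits["M1"] = fit_lmm(
        ModelSpec(
            "dwell ~ C(image_emotion, Sum) * C(condition, Sum) * C(image_location, Sum)",
            standardize=("dwell",),
            label="M1 emotion x pair x location",
        ),
        frames["dwell_long"],
    )
    fits["M1b"] = fit_lmm(
        ModelSpec("dwell ~ C(image_location, Sum)", standardize=("dwell",), label="M1b neutral-neutral location"),
        frames["neutral_long"],
    )
    fits["M2"] = fit_lmm(
        ModelSpec("bias ~ bdi * C(condition, Sum)", standardize=("bias", "bdi"), label="M2 BDI x condition"),
        frames["bias"],
    )

    moderation = frames["emotional"].copy()
    moderation["dv"] = moderation[dv].astype(float)
    m3_formula = "dv ~ age * C(condition, Sum) * erq_preference"
    for group in ("control", "mdd"):
        fits[f"M3_{group}"] = fit_lmm(
            ModelSpec(
                m3_formula,
                standardize=("dv", "age", "erq_preference"),
                data_filter=lambda d, g=group: d.loc[d["group"] == g],
                label=f"M3 {group}",
            ),
            moderation,
        )
    fits["M4"] = fit_lmm(
        ModelSpec(
            "dv ~ age * C(condition, Sum) * erq_preference * bdi",
            standardize=("dv", "age", "erq_preference", "bdi"),
            label="M4 four-way",
        ),
        moderation,
    )

    report = ModelSuiteReport(fits=fits)

    # M2 follow-up: condition contrast averaged over each group's BDI range.
    m2 = fits["M2"]
    mean, sd = m2.model.scaling.scales["bdi"]
    for group, (lo, hi) in bdi_ranges.items():
        grid = [(v - mean) / sd for v in range(int(lo), int(hi) + 1)]
        report.bias_contrasts[group] = m2.emmeans_over_range(
            "condition", "positive-neutral", "negative-neutral", covariate="bdi", covariate_values=grid,
            label=f"{group} (BDI {lo}-{hi})",
        )

    # M3 follow-up: age slopes at ERQ-preference levels, per condition.
    for group in ("control", "mdd"):
        fit = fits[f"M3_{group}"]
        p_mean, p_sd = fit.model.scaling.scales["erq_preference"]
        raw_levels = _scores.sd_levels(p_mean, p_sd, pref_multipliers)
        labels = [f"{k:+g} SD ({v:.3f})" for k, v in zip(pref_multipliers, raw_levels)]
        report.age_slopes[group] = fit.simple_slopes(
            "age", "erq_preference", list(pref_multipliers), by_factor="condition", level_labels=labels
        )
        report.preference_levels[group] = raw_levels
    return report
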