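"""Factor analysis of cohort parameters, predictor screening, additive models, and trend tests.

The modeling layer follows the statsmodels convention: a model object is
built from a cohort-parameter table and ``fit()`` returns a results object
carrying estimates, uncertainties, and a ``summary()`` table.

* :func:`factor_model` — maximum-likelihood factor analysis (varimax
  rotation, Thomson regression scores) of the cohort parameter matrix.
* :func:`screen_predictors` — random-forest permutation-importance ranking
  of candidate covariates.
* :class:`CohortSizeModel` — negative-binomial additive model of cohort
  size N on smooths of previously existing adults and understory, with
  calendar decade as a parametric factor (reference 2000s).
* :class:`CohortLongevityModel` — the same machinery for cohort mean
  lifespan (rounded to days) on smooths of temperature, wave energy, and
  purple/red sea urchin density.
* :func:`trend_tests` — OLS of N on onset date and logistic regression of
  trickledness on onset date.

Smoothness is selected by a generalized-cross-validation grid search over
the penalty weight of each penalized B-spline term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg
from sklearn.decomposition import FactorAnalysis
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from statsmodels.gam.api import BSplines, GLMGam

__all__ = [
    "FactorResult",
    "factor_model",
    "varimax",
    "screen_predictors",
    "AdditiveModelResults",
    "CohortSizeModel",
    "CohortLongevityModel",
    "TrendResult",
    "trend_tests",
]

REFERENCE_DECADE = "2000s"


# ---------------------------------------------------------------------------
# factor analysis
# ---------------------------------------------------------------------------

def varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns (rotated loadings, orthogonal rotation matrix)."""
    p, k = loadings.shape
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        L = loadings @ R
        u, s, vt = linalg.svd(
            loadings.T @ (L**3 - (L @ np.diag((L**2).sum(axis=0))) / p)
        )
        R = u @ vt
        new_var = s.sum()
        if new_var - var < tol:
            break
        var = new_var
    return loadings @ R, R


@dataclass
class FactorResult:
    loadings: pd.DataFrame          # parameters x factors, varimax-rotated
    variance_share: np.ndarray      # fraction of total variance per factor
    scores: pd.DataFrame            # per-cohort regression (Thomson) scores
    rotation: str = "varimax"
    uniquenesses: pd.Series = field(default=None)

    def dominant_block(self, factor: int, threshold: float = 0.5) -> list[str]:
        """Parameter names loading above ``threshold`` in magnitude on a factor."""
        col = self.loadings.iloc[:, factor]
        return list(col.index[np.abs(col) >= threshold])


def factor_model(params: pd.DataFrame, n_factors: int = 2, seed: int = 0) -> FactorResult:
    """Maximum-likelihood factor analysis with varimax rotation and regression scores.

    Input columns are standardized internally; factors are ordered by the
    share of total (standardized) variance they explain.
    """
    cols = list(params.columns)
    if len(cols) < 3:
        raise ValueError("factor analysis needs at least 3 parameters")
    if len(params) < n_factors + 1:
        raise ValueError("too few cohorts for the requested number of factors")
    X = params.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"zero-variance parameters: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    fa = FactorAnalysis(n_components=n_factors, random_state=seed, max_iter=5000)
    fa.fit(Z)
    if fa.n_iter_ >= 5000:
        raise RuntimeError(f"factor analysis failed to converge in {fa.n_iter_} iterations")
    L, _ = varimax(fa.components_.T)
    # flip each factor so its largest-magnitude loading is positive
    for j in range(n_factors):
        if L[np.argmax(np.abs(L[:, j])), j] < 0:
            L[:, j] = -L[:, j]
    share = (L**2).sum(axis=0) / len(cols)
    order = np.argsort(share)[::-1]
    L, share = L[:, order], share[order]
    R = np.corrcoef(Z, rowvar=False)
    scores = Z @ linalg.solve(R, L)  # Thomson regression scores
    names = [f"factor{j + 1}" for j in range(n_factors)]
    return FactorResult(
        loadings=pd.DataFrame(L, index=cols, columns=names),
        variance_share=share,
        scores=pd.DataFrame(scores, index=params.index, columns=names),
        uniquenesses=pd.Series(fa.noise_variance_, index=cols),
    )


# ---------------------------------------------------------------------------
# random-forest screening
# ---------------------------------------------------------------------------

def screen_predictors(
    params: pd.DataFrame,
    response: str,
    candidates: list[str] | None = None,
    n_trees: int = 300,
    seed: int = 0,
    n_repeats: int = 10,
) -> pd.DataFrame:
    """Permutation-importance ranking of candidate predictors for one response.

    Importances are evaluated by permutation on a held-out 30% split (an
    in-sample evaluation would report spuriously positive importances for
    noise predictors because the forest overfits the training data).
    Returns a frame sorted by decreasing mean importance with columns
    importance_mean / importance_sd; flagged unstable below 10 cohorts.
    """
    if candidates is None:
        candidates = [c for c in params.columns if c != response and pd.api.types.is_numeric_dtype(params[c])]
    data = params[[response] + candidates].dropna()
    if len(data) < 10:
        warnings.warn("fewer than 10 cohorts: importance ranking is unstable")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(data))
    n_hold = max(len(data) // 3, 2)
    hold, train = data.iloc[idx[:n_hold]], data.iloc[idx[n_hold:]]
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    rf.fit(train[candidates], train[response])
    imp = permutation_importance(
        rf, hold[candidates], hold[response], n_repeats=n_repeats, random_state=seed
    )
    out = pd.DataFrame(
        {
            "predictor": candidates,
            "importance_mean": imp.importances_mean,
            "importance_sd": imp.importances_std,
        }
    ).sort_values("importance_mean", ascending=False).reset_index(drop=True)
    out.attrs["unstable"] = len(data) < 10
    return out


# ---------------------------------------------------------------------------
# negative-binomial additive models
# ---------------------------------------------------------------------------

def _decade_design(decades: pd.Series, reference: str = REFERENCE_DECADE) -> tuple[np.ndarray, list[str]]:
    levels = [d for d in sorted(decades.unique()) if d != reference]
    cols = [np.ones(len(decades))]
    names = ["(Intercept)"]
    for lv in levels:
        cols.append((decades == lv).to_numpy(float))
        names.append(f"decade{lv.rstrip('s')}")
    return np.column_stack(cols), names


def _estimate_nb_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB2 dispersion: Var = mu + alpha * mu^2."""
    num = ((y - mu) ** 2 - mu).sum()
    den = (mu**2).sum()
    return float(np.clip(num / den, 0.01, 10.0))


@dataclass
class AdditiveModelResults:
    """Fitted additive-model results: coefficient table, smooth-term table, fit statistics."""

    params_table: pd.DataFrame       # parametric coefficients: Estimate SE z p
    smooth_table: pd.DataFrame       # per-smooth: edf, chi2, p
    deviance_explained: float
    rsq_adj: float
    nb_alpha: float
    alpha_penalty: list[float]
    smooth_names: list[str]
    _res: object = field(repr=False, default=None)

    def smooth_values(self, term: str) -> pd.DataFrame:
        """Fitted partial smooth (linear-predictor scale) at the observed covariate values."""
        i = self.smooth_names.index(term)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            y, se = self._res.partial_values(i)
        x = self._res.model.smoother.smoothers[i].x
        order = np.argsort(x)
        return pd.DataFrame({term: x[order], "partial": y[order], "se": se[order]})

    def plot_smooths(self, axes=None):
        """Fitted partial smooths with +/- 2 SE bands, one panel per term."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, len(self.smooth_names),
                                   figsize=(4 * len(self.smooth_names), 3.2))
            axes = np.atleast_1d(axes)
        for ax, term in zip(axes, self.smooth_names):
            sv = self.smooth_values(term)
            ax.plot(sv[term], sv["partial"], color="k")
            ax.fill_between(sv[term], sv["partial"] - 2 * sv["se"],
                            sv["partial"] + 2 * sv["se"], alpha=0.25, color="grey")
            ax.set_xlabel(term)
            ax.set_ylabel("partial effect")
        return axes

    def summary(self) -> str:
        lines = ["Parametric coefficients", "=" * 62]
        lines.append(f"{'':14s}{'Estimate':>10s}{'SE':>9s}{'z':>8s}{'p':>12s}")
        for _, r in self.params_table.iterrows():
            lines.append(
                f"{r['term']:<14s}{r['Estimate']:>10.3f}{r['SE']:>9.3f}{r['z']:>8.2f}{r['p']:>12.2g}"
            )
        lines.append("Significance of smooth terms")
        lines.append(f"{'':14s}{'edf':>8s}{'chi2':>10s}{'p':>12s}")
        for _, r in self.smooth_table.iterrows():
            lines.append(f"{r['term']:<14s}{r['edf']:>8.2f}{r['chi2']:>10.2f}{r['p']:>12.2g}")
        lines.append(
            f"R-sq(adj) = {self.rsq_adj:.3f}; deviance explained = {100 * self.deviance_explained:.2f}%"
        )
        return "\n".join(lines)


class _NBAdditiveModel:
    """Count-family additive model: penalized B-spline smooths + decade factor.

    Subclasses define the response column and the smooth covariates.  The
    negative-binomial dispersion is estimated by moments from an initial
    Poisson fit; per-term penalty weights are selected on a GCV grid (a
    shared-alpha sweep followed by one per-term refinement pass).
    """

    response: str
    smooth_columns: list[str]
    smooth_labels: list[str]

    def __init__(self, table: pd.DataFrame, spline_df: int = 10, degree: int = 3):
        needed = [self.response] + self.smooth_columns + ["decade"]
        data = table.dropna(subset=[c for c in needed if c in table.columns]).copy()
        if "alive" in data.columns:
            data = data[~data["alive"].astype(bool)]  # living cohorts are excluded from modeling
        if len(data) < 30:
            warnings.warn(f"only {len(data)} cohorts available; additive-model fit may be fragile")
        self.data = data.reset_index(drop=True)
        self.y = self._make_response(self.data)
        self.exog, self.exog_names = _decade_design(self.data["decade"].astype(str))
        x = self.data[self.smooth_columns].to_numpy(float)
        # cap basis size on small data sets
        k = min(spline_df, max(5, len(self.data) // (3 * len(self.smooth_columns))))
        self.smoother = BSplines(x, df=[k] * len(self.smooth_columns),
                                 degree=[degree] * len(self.smooth_columns))

    def _make_response(self, data: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError

    def _gcv(self, res) -> float:
        n = len(self.y)
        edf = res.hat_matrix_trace
        return n * res.deviance / (n - edf) ** 2

    def fit(self, alphas: list[float] | None = None, select_penalty: bool = True) -> AdditiveModelResults:
        n_smooth = len(self.smooth_columns)
        # Poisson warm start for the NB dispersion
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            warm = GLMGam(self.y, exog=self.exog, smoother=self.smoother,
                          family=sm.families.Poisson(), alpha=[10.0] * n_smooth).fit()
        nb_alpha = _estimate_nb_alpha(self.y, warm.fittedvalues)
        family = sm.families.NegativeBinomial(alpha=nb_alpha)

        def _fit(alpha_vec):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return GLMGam(self.y, exog=self.exog, smoother=self.smoother,
                              family=family, alpha=list(alpha_vec)).fit()

        if alphas is not None:
            alpha_vec = list(alphas)
            res = _fit(alpha_vec)
        elif select_penalty:
            grid = [10.0**e for e in range(0, 7)]
            best = min(((self._gcv(_fit([a] * n_smooth)), a) for a in grid), key=lambda t: t[0])
            alpha_vec = [best[1]] * n_smooth
            for i in range(n_smooth):  # one per-term refinement pass
                scores = []
                for a in grid:
                    trial = list(alpha_vec)
                    trial[i] = a
                    scores.append((self._gcv(_fit(trial)), a))
                alpha_vec[i] = min(scores, key=lambda t: t[0])[1]
            res = _fit(alpha_vec)
        else:
            alpha_vec = [10.0] * n_smooth
            res = _fit(alpha_vec)

        k_par = self.exog.shape[1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            se = np.sqrt(np.diag(res.cov_params()))[:k_par]
        est = res.params[:k_par]
        z = est / se
        from scipy.stats import norm
        ptab = pd.DataFrame(
            {"term": self.exog_names, "Estimate": est, "SE": se, "z": z,
             "p": 2 * norm.sf(np.abs(z))}
        )
        rows = []
        edf_all = res.edf
        offset = k_par
        for i, name in enumerate(self.smooth_labels):
            ncol = self.smoother.smoothers[i].basis.shape[1]
            edf_i = float(edf_all[offset:offset + ncol].sum())
            offset += ncol
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                wt = res.test_significance(i)
            stat = float(np.squeeze(wt.statistic))
            pval = float(np.squeeze(wt.pvalue))
            rows.append({"term": f"s({name})", "edf": edf_i, "chi2": stat, "p": pval})
        stab = pd.DataFrame(rows)
        dev_expl = float(1.0 - res.deviance / res.null_deviance)
        n = len(self.y)
        edf_tot = res.hat_matrix_trace
        resid = self.y - res.fittedvalues
        tss = ((self.y - self.y.mean()) ** 2).sum()
        rsq = 1 - (resid**2).sum() / tss
        rsq_adj = float(1 - (1 - rsq) * (n - 1) / max(n - edf_tot - 1, 1))
        return AdditiveModelResults(
            params_table=ptab,
            smooth_table=stab,
            deviance_explained=dev_expl,
            rsq_adj=rsq_adj,
            nb_alpha=nb_alpha,
            alpha_penalty=list(np.atleast_1d(alpha_vec)),
            smooth_names=self.smooth_columns,
            _res=res,
        )


class CohortSizeModel(_NBAdditiveModel):
    """Cohort size N ~ s(Ad) + s(understory_1yr) + decade, negative-binomial family."""

    response = "N"
    smooth_columns = ["Ad", "understory_1yr"]
    smooth_labels = ["Adults", "Understory"]

    def _make_response(self, data: pd.DataFrame) -> np.ndarray:
        return data["N"].to_numpy(int)

    @classmethod
    def from_frame(cls, table: pd.DataFrame, **kw) -> "CohortSizeModel":
        return cls(table, **kw)


class CohortLongevityModel(_NBAdditiveModel):
    """Cohort mean lifespan (days) ~ s(Temp) + s(Waves) + s(PSU) + s(RSU) + decade.

    The response is mean lifespan in years rounded to integer days so a
    count family applies; pass ``response_scale="years"`` at construction to
    keep a continuous (Gaussian-on-log) check model instead.
    """

    response = "life_mn"
    smooth_columns = ["temp80", "wave80", "psu_density", "rsu_density"]
    smooth_labels = ["Temp", "Waves", "PSU", "RSU"]

    def __init__(self, table: pd.DataFrame, response_scale: str = "days", **kw):
        self.response_scale = response_scale
        super().__init__(table, **kw)

    def _make_response(self, data: pd.DataFrame) -> np.ndarray:
        days = np.round(data["life_mn"].to_numpy(float) * 365.25).astype(int)
        return np.maximum(days, 1)

    @classmethod
    def from_frame(cls, table: pd.DataFrame, **kw) -> "CohortLongevityModel":
        return cls(table, **kw)


# ---------------------------------------------------------------------------
# temporal trend tests
# ---------------------------------------------------------------------------

@dataclass
class TrendResult:
    slope: float
    intercept: float
    f_stat: float
    f_df: tuple[int, int]
    p_linear: float
    logit_coef: float
    logit_z: float
    p_logit: float
    degenerate_logit: bool = False

    def summary(self) -> str:
        out = (
            f"Cohort size over time: slope = {self.slope:.4g} / yr, "
            f"F[{self.f_df[0]},{self.f_df[1]}] = {self.f_stat:.2f}, p = {self.p_linear:.3g}\n"
        )
        if self.degenerate_logit:
            out += "Trickled-vs-pulsed logit: degenerate (single class)"
        else:
            out += (
                f"Trickled-vs-pulsed over time: coef = {self.logit_coef:.4g} / yr, "
                f"z = {self.logit_z:.2f}, p = {self.p_logit:.3g}"
            )
        return out


def trend_tests(table: pd.DataFrame) -> TrendResult:
    """OLS of cohort size N on onset date; logistic regression of trickledness on onset date."""
    data = table.dropna(subset=["N", "onset_date"])
    if len(data) < 10:
        raise ValueError("trend tests need at least 10 cohorts")
    X = sm.add_constant(data["onset_date"].to_numpy(float))
    ols = sm.OLS(data["N"].to_numpy(float), X).fit()
    trick = data["pulsed"].map({"pulsed": 0, "trickled": 1}) if data["pulsed"].dtype == object \
        else 1 - data["pulsed"].astype(int)
    degenerate = trick.nunique() < 2
    if degenerate:
        lc, lz, lp = np.nan, np.nan, np.nan
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            logit = sm.Logit(trick.to_numpy(float), X).fit(disp=0)
        lc, lz, lp = logit.params[1], logit.tvalues[1], logit.pvalues[1]
    return TrendResult(
        slope=float(ols.params[1]),
        intercept=float(ols.params[0]),
        f_stat=float(ols.fvalue),
        f_df=(int(ols.df_model), int(ols.df_resid)),
        p_linear=float(ols.f_pvalue),
        logit_coef=float(lc),
        logit_z=float(lz),
        p_logit=float(lp),
        degenerate_logit=degenerate,
    )
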