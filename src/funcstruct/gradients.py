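"""Soil predictor selection and mixed-effects tests of SES along gradients.

Predictor selection runs three screens in order: (1) iterative pairwise
correlation pruning at |r| > 0.70, (2) a PCA-loading screen keeping variables
with high maximum absolute loading on the first two components, and (3)
variance-inflation-factor pruning until every retained predictor has VIF below
threshold. Gradient tests fit SES ~ soil predictors with a random intercept
per site by maximum likelihood and judge each predictor with a likelihood
ratio test (chi-squared, 1 df) against the model without it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .datatypes import SoilTable
from .traits import iterative_correlation_prune

log = logging.getLogger(__name__)

REPORT_COLUMNS = (
    "trait",
    "metric",
    "predictor",
    "mode",
    "estimate",
    "se",
    "lrt_stat",
    "p_value",
    "site_var",
    "resid_var",
    "n_obs",
    "converged",
)


def log_transform_predictors(st: SoilTable, variables=None) -> SoilTable:
    """Natural log of the named soil variables (all if None).

    Non-positive values are a hard error identifying the plot and variable —
    no silent +epsilon offset is applied.
    """
    variables = list(variables) if variables is not None else st.variable_names
    values = st.values.copy()
    units = dict(st.units)
    for var in variables:
        if var not in values.columns:
            raise KeyError(f"soil variable {var!r} not present")
        col = values[var]
        bad = col[col <= 0]
        if len(bad):
            plot = bad.index[0]
            raise ValueError(
                f"cannot log-transform {var}: non-positive value {bad.iloc[0]} in plot {plot}"
            )
        values[var] = np.log(col)
        units[var] = f"log({units.get(var, '1')})"
    return SoilTable(values, units)


@dataclass
class PredictorSelection:
    """Audit record of the three-stage soil predictor screen."""

    correlation_survivors: list = field(default_factory=list)
    pca_loadings: pd.DataFrame | None = None
    selected: list = field(default_factory=list)
    vif: dict = field(default_factory=dict)
    audit: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "correlation_survivors": list(self.correlation_survivors),
            "pca_loadings": None
            if self.pca_loadings is None
            else self.pca_loadings.round(6).to_dict(),
            "selected": list(self.selected),
            "vif": {k: float(v) for k, v in self.vif.items()},
            "audit": list(self.audit),
        }


def _vif_table(X: pd.DataFrame) -> pd.Series:
    Xc = sm.add_constant((X - X.mean()) / X.std(ddof=1))
    arr = Xc.to_numpy()
    return pd.Series(
        [variance_inflation_factor(arr, i + 1) for i in range(X.shape[1])], index=X.columns
    )


class SoilVariableSelector(BaseEstimator, TransformerMixin):
    """Three-stage soil predictor screen as a feature-selection transformer.

    Parameters
    ----------
    cor_threshold : float, default 0.70
        Pairwise |Pearson r| above which one variable of a pair is pruned.
    n_components : int, default 2
        PCA components over which the maximum absolute loading is taken.
    loading_quantile : float, default 0.5
        Variables whose max |loading| falls below this quantile are cut
        (i.e. the top half survives by default).
    max_keep : int, default 6
        Hard cap on variables surviving the PCA screen.
    vif_threshold : float, default 5.0
        Iteratively drop the highest-VIF variable until all are below this.
    """

    def __init__(
        self,
        cor_threshold: float = 0.70,
        n_components: int = 2,
        loading_quantile: float = 0.5,
        max_keep: int = 6,
        vif_threshold: float = 5.0,
    ):
        self.cor_threshold = cor_threshold
        self.n_components = n_components
        self.loading_quantile = loading_quantile
        self.max_keep = max_keep
        self.vif_threshold = vif_threshold

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if X.shape[0] < 3:
            raise ValueError("predictor selection needs at least 3 plots")
        audit: list[str] = []

        # 1. correlation screen
        survivors, dropped = iterative_correlation_prune(X, self.cor_threshold)
        for victim, reason in dropped:
            audit.append(f"correlation screen dropped {victim}: {reason}")
        if len(survivors) < 2:
            raise ValueError("fewer than 2 variables survive the correlation screen")

        # 2. PCA loading screen on standardized survivors
        Z = X[survivors]
        Z = (Z - Z.mean()) / Z.std(ddof=1)
        n_comp = min(self.n_components, len(survivors), Z.shape[0])
        pca = PCA(n_components=n_comp).fit(Z.to_numpy())
        loadings = pd.DataFrame(
            pca.components_.T,
            index=survivors,
            columns=[f"PC{i + 1}" for i in range(n_comp)],
        )
        score = loadings.abs().max(axis=1)
        cutoff = score.quantile(self.loading_quantile)
        keep = score[score >= cutoff].sort_values(ascending=False).index.tolist()
        keep = keep[: self.max_keep]
        if len(keep) < 2:
            keep = score.sort_values(ascending=False).index[:2].tolist()
        for var in survivors:
            if var not in keep:
                audit.append(
                    f"PCA screen dropped {var}: max |loading| {score[var]:.3f} < cutoff {cutoff:.3f}"
                )

        # 3. VIF screen
        while len(keep) > 2:
            vif = _vif_table(X[keep])
            if vif.max() < self.vif_threshold:
                break
            victim = vif.idxmax()
            audit.append(f"VIF screen dropped {victim}: VIF {vif.max():.2f}")
            keep.remove(victim)
        vif = _vif_table(X[keep])

        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.selection_ = PredictorSelection(
            correlation_survivors=survivors,
            pca_loadings=loadings,
            selected=keep,
            vif=vif.to_dict(),
            audit=audit,
        )
        self.selected_ = keep
        return self

    def transform(self, X):
        return pd.DataFrame(X)[self.selected_]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.selected_, dtype=object)


def select_soil_variables(
    st: SoilTable,
    cor_threshold: float = 0.70,
    n_components: int = 2,
    vif_threshold: float = 5.0,
    loading_quantile: float = 0.5,
    max_keep: int = 6,
    log_variables: str | list | None = "auto",
) -> PredictorSelection:
    """Run the three-stage screen on a soil table.

    ``log_variables='auto'`` natural-log transforms every variable except pH
    before screening (pH is already a log-scale quantity); pass an explicit
    list or None to override.
    """
    if log_variables == "auto":
        log_variables = [v for v in st.variable_names if v != "pH"]
    if log_variables:
        st = log_transform_predictors(st, log_variables)
    selector = SoilVariableSelector(
        cor_threshold=cor_threshold,
        n_components=n_components,
        loading_quantile=loading_quantile,
        max_keep=max_keep,
        vif_threshold=vif_threshold,
    ).fit(st.values)
    return selector.selection_


# ---------------------------------------------------------------------------
# mixed models


@dataclass
class _LMMFit:
    """Uniform view of an ML mixed-model (or boundary OLS) fit."""

    params: pd.Series
    bse: pd.Series
    site_var: float
    resid_var: float
    llf: float
    converged: bool


def _fit_mixedlm(y: np.ndarray, X: pd.DataFrame | None, groups: np.ndarray) -> _LMMFit:
    """ML fit of y ~ const (+ X) with a random intercept per group.

    When the site variance collapses to the boundary the MixedLM Hessian can
    be singular; in that case an OLS fit — the exact boundary solution with
    zero random-intercept variance and the same ML likelihood — is used.
    """
    exog = pd.DataFrame({"const": np.ones(len(y))})
    if X is not None:
        exog = pd.concat([exog.reset_index(drop=True), X.reset_index(drop=True)], axis=1)
    names = exog.columns.tolist()
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)

    # single optimizers routinely stop short of the ML optimum on boundary-ish
    # likelihood surfaces; keep the best llf over several starts so nested
    # likelihood ratios are not inflated by under-maximized reduced models
    best: _LMMFit | None = None
    for method in ("lbfgs", "bfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                model = sm.MixedLM(y, exog.to_numpy(), groups=groups)
                result = model.fit(reml=False, method=method)
            converged = bool(getattr(result, "converged", True)) and not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
            candidate = _LMMFit(
                params=pd.Series(result.fe_params, index=names),
                bse=pd.Series(result.bse_fe, index=names),
                site_var=float(np.squeeze(result.cov_re)),
                resid_var=float(result.scale),
                llf=float(result.llf),
                converged=converged,
            )
        except (np.linalg.LinAlgError, ValueError):
            continue
        if best is None or candidate.llf > best.llf + 1e-10:
            best = candidate

    # the zero-site-variance boundary solution, which optimizers can miss
    ols = sm.OLS(y, exog.to_numpy()).fit()
    ols_fit = _LMMFit(
        params=pd.Series(ols.params, index=names),
        bse=pd.Series(ols.bse, index=names),
        site_var=0.0,
        resid_var=float(ols.scale * (len(y) - len(names)) / len(y)),  # ML variance
        llf=float(ols.llf),
        converged=True,
    )
    if best is None or ols_fit.llf > best.llf + 1e-8:
        if best is None:
            log.info("mixed model fits failed; using the OLS boundary solution")
        return ols_fit
    if abs(ols_fit.llf - best.llf) <= 1e-8 and best.site_var <= 1e-8:
        return ols_fit  # same optimum at the boundary, but cleanly converged
    return best


class MixedGradientModel(BaseEstimator):
    """SES-along-gradient linear mixed model with LRT inference.

    Fits ``y ~ predictors`` with a site-level random intercept by maximum
    likelihood and evaluates each predictor with a likelihood ratio test
    (chi-squared, 1 df) against the nested model dropping that predictor.
    ML rather than REML is used throughout because the compared models differ
    in their fixed effects; a REML fit of the full model is kept for variance
    reporting.

    Attributes (after ``fit(X, y, groups)``)
    ----------------------------------------
    params_, bse_ : Series of fixed-effect estimates and standard errors.
    site_var_, resid_var_ : random-intercept and residual variances (ML).
    llf_ : maximized log-likelihood of the full model.
    lrt_ : DataFrame (index predictor) with ``stat`` and ``p_value``.
    converged_ : bool; n_obs_ : int.
    """

    def __init__(self, reml_report: bool = True):
        self.reml_report = reml_report

    def fit(self, X, y, groups=None):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if groups is None:
            raise ValueError("groups (site identifiers per observation) are required")
        groups = np.asarray(groups)
        if len(np.unique(groups)) < 2:
            raise ValueError("mixed model needs at least 2 sites")
        mask = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
        X, y, groups = X[mask], y[mask], groups[mask]
        self.n_obs_ = int(mask.sum())
        if self.n_obs_ < 10:
            log.warning("only %d non-missing observations; estimates will be unstable", self.n_obs_)
        predictors = X.columns.tolist()

        if np.ptp(y) == 0:  # degenerate: constant response
            self.params_ = pd.Series(0.0, index=["const"] + predictors)
            self.params_["const"] = y[0] if len(y) else 0.0
            self.bse_ = pd.Series(0.0, index=self.params_.index)
            self.site_var_ = 0.0
            self.resid_var_ = 0.0
            self.llf_ = np.nan
            self.lrt_ = pd.DataFrame(
                {"stat": 0.0, "p_value": 1.0}, index=pd.Index(predictors, name="predictor")
            )
            self.converged_ = True
            return self

        full = _fit_mixedlm(y, X, groups)
        self.params_ = full.params
        self.bse_ = full.bse
        self.site_var_ = full.site_var
        self.resid_var_ = full.resid_var
        self.llf_ = full.llf
        self.converged_ = full.converged

        rows = {}
        for pred in predictors:
            rest = [p for p in predictors if p != pred]
            reduced = _fit_mixedlm(y, X[rest] if rest else None, groups)
            stat = max(0.0, 2.0 * (self.llf_ - reduced.llf))
            rows[pred] = {"stat": stat, "p_value": float(stats.chi2.sf(stat, df=1))}
            self.converged_ = self.converged_ and reduced.converged
        self.lrt_ = pd.DataFrame.from_dict(rows, orient="index").rename_axis("predictor")

        if self.reml_report:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    exog = sm.add_constant(X.to_numpy())
                    reml = sm.MixedLM(y, exog, groups=groups).fit(reml=True)
                self.reml_site_var_ = float(np.squeeze(reml.cov_re))
                self.reml_resid_var_ = float(reml.scale)
            except (np.linalg.LinAlgError, ValueError):
                self.reml_site_var_ = np.nan
                self.reml_resid_var_ = np.nan
        return self

    def predict(self, X):
        X = pd.DataFrame(X)
        beta = self.params_
        return beta["const"] + X[self.lrt_.index.tolist()].to_numpy() @ beta[
            self.lrt_.index
        ].to_numpy()


def fit_gradient_model(
    ses_table: pd.DataFrame,
    st: SoilTable,
    predictors,
    site_of=None,
    mode: str = "single",
) -> pd.DataFrame:
    """Gradient-model report over every (trait, metric) response in a SES table.

    ``mode='single'`` fits one model per predictor (matching per-panel
    regressions of SES against one soil gradient); ``mode='multi'`` fits all
    predictors jointly with per-predictor drop-one LRTs. Missing SES rows are
    excluded per response and counted in ``n_obs``.
    """
    if mode not in {"single", "multi"}:
        raise ValueError("mode must be 'single' or 'multi'")
    predictors = list(predictors)
    missing = [p for p in predictors if p not in st.variable_names]
    if missing:
        raise KeyError(f"predictors not in soil table: {missing}")

    rows = []
    for (trait, metric), group in ses_table.groupby(["trait", "metric"], sort=True):
        merged = group.dropna(subset=["ses"]).set_index("plot")
        merged = merged.join(st.values[predictors], how="inner")
        y = merged["ses"].to_numpy()
        groups = merged["site"].to_numpy() if site_of is None else (
            pd.Series(site_of).reindex(merged.index).to_numpy()
        )
        if len(merged) < 3 or len(np.unique(groups)) < 2:
            log.warning("skipping %s/%s: too few usable observations", trait, metric)
            continue
        if mode == "multi":
            model = MixedGradientModel().fit(merged[predictors], y, groups=groups)
            for pred in predictors:
                rows.append(
                    (
                        trait, metric, pred, mode,
                        model.params_[pred], model.bse_[pred],
                        model.lrt_.loc[pred, "stat"], model.lrt_.loc[pred, "p_value"],
                        model.site_var_, model.resid_var_, model.n_obs_, model.converged_,
                    )
                )
        else:
            for pred in predictors:
                model = MixedGradientModel().fit(merged[[pred]], y, groups=groups)
                rows.append(
                    (
                        trait, metric, pred, mode,
                        model.params_[pred], model.bse_[pred],
                        model.lrt_.loc[pred, "stat"], model.lrt_.loc[pred, "p_value"],
                        model.site_var_, model.resid_var_, model.n_obs_, model.converged_,
                    )
                )
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def panel_export(
    ses_table: pd.DataFrame, st: SoilTable, predictor: str, trait: str, metric: str
) -> pd.DataFrame:
    """Scatter data (SES vs one log predictor, with OLS line and 95% band)
    for external plotting of a single panel."""
    group = ses_table[(ses_table["trait"] == trait) & (ses_table["metric"] == metric)]
    merged = group.dropna(subset=["ses"]).set_index("plot").join(
        st.values[[predictor]], how="inner"
    )
    x = merged[predictor].to_numpy()
    y = merged["ses"].to_numpy()
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    pred = ols.get_prediction(sm.add_constant(x)).summary_frame(alpha=0.05)
    out = merged.reset_index()[["plot", "site", predictor, "ses"]]
    out["fit"] = pred["mean"].to_numpy()
    out["ci_low"] = pred["mean_ci_lower"].to_numpy()
    out["ci_high"] = pred["mean_ci_upper"].to_numpy()
    return out
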