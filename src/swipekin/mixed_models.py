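"""Final mixed-effects models, variance components and cohort tests.

The analysis models each swipe-level outcome as a function of target
distance (Dist, the centred 10-mm category index), participant age
(years, centred at 4.7) and diagnostic group (ASD vs TD), with a
correlated random intercept and Dist slope per subject:

* log MT, log PV, log TTPV — Gaussian, REML, with an ASD x age interaction;
* PV1-b — logistic, no interactions;
* MU-APV — Poisson log-link, with ASD x age and ASD x Dist interactions;
* MU — zero-truncated Poisson (counts are >= 1 by construction);
* PV1 and %Dec — Gaussian on the identity scale (secondary outcomes).

Coefficients are reported on the link scale and exponentiated
(multiplicative effects / odds ratios / incidence-rate ratios).  Variance
components follow the Nakagawa-Schielzeth conventions for intraclass
correlation and marginal/conditional R-squared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from swipekin import glmm
from swipekin.cohort_filter import ExclusionReport

__all__ = [
    "AGE_CENTER_YEARS",
    "DIST_CENTER_CATEGORY",
    "CORRELATION_OUTCOMES",
    "ModelSpec",
    "FitResult",
    "prepare_covariates",
    "final_model_specs",
    "fit_mixed",
    "variance_components",
    "dispersion_ratio",
    "pairwise_correlations",
    "cohort_tests",
    "chi_square_2x2",
    "t_from_summary",
]

AGE_CENTER_YEARS = 4.7
DIST_CENTER_CATEGORY = 3  # the "30-40" mm bin

#: Fixed-effect term names and the frame columns they map to.
_TERM_COLUMNS = {
    "Intercept": None,
    "Dist": "dist_c",
    "age": "age_c",
    "ASD": "asd",
    "ASD:age": ("asd", "age_c"),
    "ASD:Dist": ("asd", "dist_c"),
    "Dist:age": ("dist_c", "age_c"),
}

CORRELATION_OUTCOMES = ["TTPV", "MT", "MU", "pct_dec", "MU_APV", "PV1_b", "PV1", "PV"]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one outcome model."""

    outcome: str
    family: Literal["gaussian", "binomial", "poisson", "ztpoisson"] = "gaussian"
    transform: Literal["identity", "log"] = "identity"
    fixed: tuple[str, ...] = ("Dist", "age", "ASD")
    random: Literal["intercept_slope", "intercept", "none"] = "intercept_slope"

    @property
    def estimator(self) -> str:
        # REML for linear models, ML for generalised linear models
        return "REML" if self.family == "gaussian" else "ML"

    @property
    def terms(self) -> tuple[str, ...]:
        return ("Intercept",) + self.fixed


@dataclass
class FitResult:
    """Tidy fixed-effect estimates plus variance components."""

    spec: ModelSpec
    table: pd.DataFrame          # per term: coef, se, ci_low, ci_high, exp_*, p, df
    sigma2: float
    tau00: float
    tau11: float
    rho01: float
    loglik: float
    deviance: float
    aic: float
    n_obs: int
    n_subjects: int
    converged: bool
    singular: bool
    var_fixed: float = 0.0
    re_var_mean: float = 0.0
    _mu_conditional: np.ndarray = field(repr=False, default=None)
    _pearson_var: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "coef"])

    def exp_coef(self, term: str) -> float:
        return float(self.table.loc[term, "exp_coef"])

    def pvalue(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.table.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


def prepare_covariates(
    kin: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    age_center: float = AGE_CENTER_YEARS,
) -> pd.DataFrame:
    """Build the modelling frame from retained swipes.

    Adds ``asd`` (0/1), ``age_c`` (years, centred), ``dist_c`` (distance
    category centred at the median "30-40" bin, so values lie in -2..3)
    and natural-log transforms of MT, PV and TTPV.  ``participants`` must
    supply ``group`` and ``age_months`` for any subject not already
    carrying them on the swipe rows.
    """
    frame = kin.copy()
    if participants is not None:
        cols = [c for c in ("group", "age_months", "sex") if c in participants.columns
                and c not in frame.columns]
        if cols:
            frame = frame.merge(
                participants[["participant_id"] + cols],
                on="participant_id", how="left", validate="many_to_one",
            )
    missing = [c for c in ("group", "age_months") if c not in frame.columns]
    if missing:
        raise ValueError(f"cannot build covariates, missing {missing}")
    bad = frame["group"].isna() | frame["age_months"].isna()
    if bad.any():
        subjects = sorted(frame.loc[bad, "participant_id"].unique())
        raise ValueError(f"subjects missing group or age: {subjects}")
    if frame["dist_cat"].isna().any():
        raise ValueError("frame contains swipes without a distance category; "
                         "run the exclusion cascade first")
    frame["asd"] = (frame["group"].astype(str).str.upper() == "ASD").astype(int)
    frame["age_years"] = frame["age_months"] / 12.0
    frame["age_c"] = frame["age_years"] - age_center
    frame["dist_c"] = frame["dist_cat"].astype(int) - DIST_CENTER_CATEGORY
    for col in ("MT", "PV", "TTPV"):
        frame[f"log_{col}"] = np.log(frame[col].astype(float))
    frame["PV1_b"] = frame["PV1_b"].astype(int)
    return frame


def final_model_specs() -> dict[str, ModelSpec]:
    """The final model set, one spec per outcome.

    Interactions appear only where model comparison retained them: the
    ASD x age term for the three log-scale outcomes and MU-APV, plus
    ASD x Dist for MU-APV; the logistic PV1-b model keeps main effects
    only.  All models carry a per-subject random intercept and Dist slope.
    """
    log_terms = ("Dist", "age", "ASD", "ASD:age")
    return {
        "MT": ModelSpec("MT", "gaussian", "log", log_terms),
        "PV": ModelSpec("PV", "gaussian", "log", log_terms),
        "TTPV": ModelSpec("TTPV", "gaussian", "log", log_terms),
        "PV1_b": ModelSpec("PV1_b", "binomial", "identity", ("Dist", "age", "ASD")),
        "MU_APV": ModelSpec("MU_APV", "poisson", "identity",
                            ("Dist", "age", "ASD", "ASD:age", "ASD:Dist")),
        "MU": ModelSpec("MU", "ztpoisson", "identity", ("Dist", "age", "ASD")),
        "PV1": ModelSpec("PV1", "gaussian", "identity", ("Dist", "age", "ASD")),
        "pct_dec": ModelSpec("pct_dec", "gaussian", "identity", ("Dist", "age", "ASD")),
    }


def _design(frame: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    n = len(frame)
    cols = [np.ones(n)]
    for term in spec.fixed:
        mapping = _TERM_COLUMNS[term]
        if isinstance(mapping, tuple):
            cols.append(np.prod([frame[c].to_numpy(float) for c in mapping], axis=0))
        else:
            cols.append(frame[mapping].to_numpy(float))
    X = np.column_stack(cols)
    y_col = f"log_{spec.outcome}" if spec.transform == "log" else spec.outcome
    y = frame[y_col].to_numpy(float)
    return y, X


def fit_mixed(frame: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit one outcome model on a covariate frame.

    Gaussian outcomes use REML with Satterthwaite t-tests; count and
    binary outcomes use the Laplace-approximate ML fit with Wald z-tests.
    ``random="none"`` degrades to an ordinary (generalised) linear model,
    which is also the degenerate limit of the mixed fit.  Singular
    random-effect fits are returned flagged, not raised.
    """
    if frame["participant_id"].nunique() < 2 and spec.random != "none":
        raise ValueError("mixed fit needs at least 2 subjects")
    if frame["dist_c"].nunique() < 2:
        raise ValueError("mixed fit needs at least 2 distance categories")
    y, X = _design(frame, spec)
    groups = frame["participant_id"].to_numpy()
    if spec.random == "intercept_slope":
        Z = np.column_stack([np.ones(len(frame)), frame["dist_c"].to_numpy(float)])
    elif spec.random == "intercept":
        # vanishing-slope limit implemented as a near-zero slope column
        Z = np.column_stack([np.ones(len(frame)), np.zeros(len(frame))])
    else:
        Z = None

    if spec.family == "gaussian":
        if Z is None:
            fit = _ols_fit(y, X)
        else:
            fit = glmm.fit_lmm_reml(y, X, Z, groups, estimator=spec.estimator)
    else:
        if Z is None:
            raise ValueError("unreplicated GLM path not provided; use random effects")
        fit = glmm.fit_glmm_laplace(y, X, Z, groups, family=spec.family)
    if not fit.converged:
        raise RuntimeError(
            f"{spec.outcome} model did not converge "
            f"(loglik {fit.loglik:.3f}); inspect the frame for degeneracy"
        )

    crit = stats.t.ppf(0.975, fit.df) if np.all(np.isfinite(fit.df)) else \
        np.full(len(fit.beta), stats.norm.ppf(0.975))
    lo = fit.beta - crit * fit.se
    hi = fit.beta + crit * fit.se
    table = pd.DataFrame(
        {
            "coef": fit.beta,
            "se": fit.se,
            "ci_low": lo,
            "ci_high": hi,
            "exp_coef": np.exp(fit.beta),
            "exp_ci_low": np.exp(lo),
            "exp_ci_high": np.exp(hi),
            "df": fit.df,
            "p": fit.pvalues,
        },
        index=list(spec.terms),
    )
    return FitResult(
        spec=spec,
        table=table,
        sigma2=fit.sigma2,
        tau00=fit.tau00,
        tau11=fit.tau11,
        rho01=fit.rho01,
        loglik=fit.loglik,
        deviance=fit.deviance,
        aic=fit.aic,
        n_obs=fit.n_obs,
        n_subjects=fit.n_groups,
        converged=fit.converged,
        singular=fit.singular,
        var_fixed=fit.var_fixed,
        re_var_mean=fit.re_var_mean,
        _mu_conditional=fit.mu_conditional,
        _pearson_var=fit.pearson_var,
        _y=y,
    )


def _ols_fit(y: np.ndarray, X: np.ndarray) -> glmm.MixedFit:
    """Fixed-effects-only Gaussian fit (the no-random-effects limit)."""
    import statsmodels.api as sm

    res = sm.OLS(y, X).fit()
    n, p = X.shape
    return glmm.MixedFit(
        beta=res.params, se=res.bse, pvalues=res.pvalues,
        df=np.full(p, float(n - p)), sigma2=float(res.mse_resid),
        tau00=0.0, tau11=0.0, rho01=np.nan,
        loglik=float(res.llf), estimator="OLS",
        n_obs=n, n_groups=0, converged=True, singular=False,
        var_fixed=float(np.var(res.fittedvalues)), re_var_mean=0.0,
        mu_conditional=np.asarray(res.fittedvalues),
        pearson_var=np.full(n, float(res.mse_resid)),
    )


def variance_components(fit: FitResult) -> dict[str, float]:
    """Intraclass correlation and Nakagawa-Schielzeth R-squared.

    The between-subject variance is the mean of z' G z across
    observations (which reduces to the intercept variance when the slope
    variance vanishes).  The residual variance on the latent scale is the
    Gaussian residual variance, pi^2/3 for the logistic model, and the
    lognormal approximation ln(1 + 1/lambda0) for the count models, with
    lambda0 the rate at the fixed-effect intercept.
    """
    family = fit.spec.family
    if family == "gaussian":
        resid = fit.sigma2
    elif family == "binomial":
        resid = np.pi ** 2 / 3.0
    elif family in ("poisson", "ztpoisson"):
        lam0 = float(np.exp(fit.coef("Intercept")))
        resid = float(np.log1p(1.0 / lam0))
    else:  # pragma: no cover - family list is closed
        raise ValueError(f"no residual-variance convention for {family!r}")
    re_var = fit.re_var_mean
    total = fit.var_fixed + re_var + resid
    return {
        "icc": re_var / (re_var + resid),
        "r2_marginal": fit.var_fixed / total,
        "r2_conditional": (fit.var_fixed + re_var) / total,
        "residual_variance": resid,
    }


def dispersion_ratio(fit: FitResult) -> float:
    """Pearson dispersion ratio for count-family fits.

    Sum of squared Pearson residuals (conditional on the estimated random
    effects) over the residual degrees of freedom, n minus the number of
    fixed effects.  Values near 1 indicate no overdispersion.
    """
    if fit.spec.family not in ("poisson", "ztpoisson"):
        raise ValueError(f"dispersion ratio is defined for count families, "
                         f"not {fit.spec.family!r}")
    resid = (fit._y - fit._mu_conditional) / np.sqrt(fit._pearson_var)
    df = fit.n_obs - len(fit.table)
    return float(np.sum(resid ** 2) / df)


def pairwise_correlations(kin: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix over the eight kinematic outcomes.

    PV1-b enters as 0/1 (point-biserial).  Constant columns yield
    undefined off-diagonal entries (NaN) and are reported in a warning.
    """
    import warnings

    if len(kin) < 3:
        raise ValueError("need at least 3 swipes for correlations")
    cols = [c for c in CORRELATION_OUTCOMES if c in kin.columns]
    data = kin[cols].astype(float)
    constant = [c for c in cols if data[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant columns, correlations undefined: {constant}",
                      stacklevel=2)
    return data.corr(method="pearson")


def chi_square_2x2(table: np.ndarray, correction: bool = False) -> dict[str, float]:
    """Pearson chi-squared test on a contingency table.

    ``correction`` applies the Yates continuity correction (only
    meaningful for 2x2 tables, where it is R's default).
    """
    table = np.asarray(table, float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has an empty margin")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=correction)
    return {"statistic": float(chi2), "df": int(dof), "p": float(p)}


def t_from_summary(m1, s1, n1, m2, s2, n2) -> dict[str, float]:
    """Pooled-variance two-sample t-test from summary statistics."""
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
    t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return {"statistic": float(t), "df": int(df), "p": float(2 * stats.t.sf(abs(t), df))}


def cohort_tests(
    frame: pd.DataFrame,
    participants: pd.DataFrame,
    report: ExclusionReport | None = None,
) -> dict[str, dict[str, float]]:
    """Descriptive group comparisons of the analysis cohort.

    Returns, keyed by test name: chi-squared tests for excluded-vs-analysed
    swipes by group (when an exclusion report is supplied), sex by group
    and Dist-category distribution by group; pooled t-tests for age and
    swipes per participant; an F variance-ratio test for age; and a
    Mann-Whitney test on the Dist category.  Each entry carries
    ``statistic``, ``df`` (where defined) and ``p``.
    """
    out: dict[str, dict[str, float]] = {}
    pframe = participants.set_index("participant_id")
    subjects = frame["participant_id"].unique()
    pframe = pframe.loc[pframe.index.intersection(subjects)]
    grp = pframe["group"].astype(str).str.upper()
    is_asd = grp == "ASD"

    if report is not None and "ASD" in report.counts.columns:
        counts = report.counts
        excl = counts.loc[counts.index != "retained", ["TD", "ASD"]].sum()
        kept = counts.loc["retained", ["TD", "ASD"]]
        out["exclusion_by_group"] = chi_square_2x2(
            np.array([[excl["TD"], kept["TD"]], [excl["ASD"], kept["ASD"]]]),
            correction=True,
        )

    if "sex" in pframe.columns:
        tab = pd.crosstab(grp, pframe["sex"]).to_numpy()
        if tab.size == 4:
            out["sex_by_group"] = chi_square_2x2(tab, correction=False)

    age = pframe["age_months"] / 12.0
    a_td, a_asd = age[~is_asd], age[is_asd]
    t, p = stats.ttest_ind(a_td, a_asd, equal_var=True)
    out["age_t"] = {"statistic": float(t), "df": int(len(age) - 2), "p": float(p)}
    f = float(np.var(a_td, ddof=1) / np.var(a_asd, ddof=1))
    df1, df2 = len(a_td) - 1, len(a_asd) - 1
    pf = 2 * min(stats.f.cdf(f, df1, df2), stats.f.sf(f, df1, df2))
    out["age_var_f"] = {"statistic": f, "df1": df1, "df2": df2, "p": float(pf)}

    per_subject = frame.groupby("participant_id").size()
    s_td = per_subject[grp.reindex(per_subject.index) != "ASD"]
    s_asd = per_subject[grp.reindex(per_subject.index) == "ASD"]
    t, p = stats.ttest_ind(s_td, s_asd, equal_var=True)
    out["swipes_per_participant_t"] = {
        "statistic": float(t), "df": int(len(per_subject) - 2), "p": float(p)
    }

    dist = frame["dist_cat"].astype(int)
    swipe_is_asd = frame["group"].astype(str).str.upper() == "ASD"
    tab = pd.crosstab(swipe_is_asd, dist).to_numpy()
    chi2, p, dof, _ = stats.chi2_contingency(tab, correction=False)
    out["dist_by_group"] = {"statistic": float(chi2), "df": int(dof), "p": float(p)}
    u, p = stats.mannwhitneyu(dist[~swipe_is_asd.values], dist[swipe_is_asd.values],
                              alternative="two-sided")
    out["dist_mannwhitney"] = {"statistic": float(u), "p": float(p)}
    return out
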