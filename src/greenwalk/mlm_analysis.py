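"""Two-level random-intercept models of momentary affect.

Estimation is restricted maximum likelihood (REML) via statsmodels
MixedLM.  The level-1 predictors are the social-interaction dummies
(intensity 1 = reference) and viewshed greenness, the latter
person-mean-centered to isolate the within-person association; the
level-2 covariates (sex as a centered 0/1 indicator, age) are
grand-mean-centered.  Reported per term: the raw estimate, the
standardized coefficient (estimate x SD(term)/SD(outcome), realized
sample SDs), Wald 95% confidence limits, and a normal-approximation
p-value.  Variance components give the intraclass correlation
ICC = tau00/(tau00 + sigma2); marginal and conditional R2 follow the
fixed-versus-total variance decomposition
    R2_m = var(fixed)/(var(fixed) + tau00 + sigma2),
    R2_c = (var(fixed) + tau00)/(var(fixed) + tau00 + sigma2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

OUTCOMES = ("valence", "calmness", "energetic_arousal")
LEVEL1_TERMS = ("D1", "D2", "D3", "green_c")
LEVEL2_TERMS = ("sex_c", "age_c")


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    level1: tuple[str, ...] = LEVEL1_TERMS
    level2: tuple[str, ...] = LEVEL2_TERMS
    random_slope: str | None = None      # e.g. "green_c"
    interactions: bool = False           # SI x Green product terms
    reml: bool = True

    def __post_init__(self) -> None:
        if not self.outcome:
            raise ValueError("outcome is required")

    @property
    def terms(self) -> list[str]:
        out = list(self.level1) + list(self.level2)
        if self.interactions:
            out += [f"{d}:green_c" for d in ("D1", "D2", "D3")
                    if d in self.level1]
        return out


@dataclass
class MlmFit:
    outcome: str
    fixed: pd.DataFrame            # per-term estimates and inference
    sigma2: float
    tau00: float
    n_participants: int
    n_obs: int
    converged: bool
    loglike: float
    reml: bool
    spec: ModelSpec | None = None
    re_params: dict = field(default_factory=dict)
    var_fixed: float = 0.0

    @property
    def icc(self) -> float:
        total = self.tau00 + self.sigma2
        return self.tau00 / total if total > 0 else 0.0

    @property
    def within_person_pct(self) -> float:
        """Share of outcome variance at the situation level, in percent."""
        return 100.0 * (1.0 - self.icc)

    @property
    def r2(self) -> tuple[float, float]:
        return r_squared(self)


def center_predictors(obs: pd.DataFrame,
                      center_si_dummies: bool = False) -> pd.DataFrame:
    """Prepare the observation table for model fitting.

    Greenness is centered on each participant's own mean (and a
    sample-SD-standardized copy ``green_z`` added); age is grand-mean-
    centered; sex becomes a 0/1 indicator (female = 1) centered on its
    grand mean.  The social-interaction dummies stay uncentered by
    default so the reference-category interpretation survives; a switch
    person-mean-centers them too.  Participants with no greenness values
    are excluded (the count is recorded in ``df.attrs``).
    """
    df = obs.copy()
    missing_green = df.groupby("pid")["green_pct"].transform(
        lambda s: s.isna().all())
    n_dropped = int(missing_green.sum())
    df = df.loc[~missing_green].copy()
    df.attrs["n_dropped_all_missing_green"] = n_dropped

    df["green_c"] = df["green_pct"] - df.groupby("pid")["green_pct"].transform("mean")
    sd_g = df["green_c"].std()
    df["green_z"] = df["green_c"] / sd_g if sd_g > 0 else 0.0
    if np.issubdtype(df["sex"].dtype, np.number):
        sex01 = df["sex"].astype(float)
    else:
        sex01 = (df["sex"] == "female").astype(float)
    df["sex_c"] = sex01 - sex01.mean()
    df["age_c"] = df["age"] - df["age"].mean()
    if not {"D1", "D2", "D3"} <= set(df.columns):
        from greenwalk.scales_and_coding import add_si_dummies
        df = add_si_dummies(df)
    if center_si_dummies:
        for d in ("D1", "D2", "D3"):
            df[d] = df[d] - df.groupby("pid")[d].transform("mean")
    for d in ("D1", "D2", "D3"):
        df[f"{d}:green_c"] = df[d] * df["green_c"]
    return df


def _design(df: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    for t in terms:
        X[t] = df[t].to_numpy()
    if len(terms) and np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"collinear design among terms {terms}")
    return X


def _fit_mixed(df: pd.DataFrame, outcome: str, terms: list[str],
               random_slope: str | None, reml: bool):
    X = _design(df, terms)
    exog_re = None
    if random_slope is not None:
        exog_re = pd.DataFrame({"Intercept": np.ones(len(df)),
                                random_slope: df[random_slope].to_numpy()},
                               index=df.index)
    model = sm.MixedLM(df[outcome], X, groups=df["pid"], exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml, method="bfgs", gtol=1e-10)
            converged = bool(getattr(res, "converged", True))
        except Exception:
            res = model.fit(reml=reml, method="powell", maxiter=500)
            converged = False
    return res, X, converged


def _results_to_fit(res, X: pd.DataFrame, df: pd.DataFrame, outcome: str,
                    spec: ModelSpec, converged: bool) -> MlmFit:
    params = res.fe_params
    se = res.bse_fe
    sd_y = float(df[outcome].std())
    zcrit = stats.norm.ppf(0.975)
    rows = []
    for term in X.columns:
        est = float(params[term])
        s = float(se[term])
        if term == "Intercept":
            ratio = np.nan
        else:
            sd_x = float(df[term].std())
            ratio = sd_x / sd_y if sd_y > 0 else np.nan
        z = est / s if s > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({
            "term": term, "estimate": est, "se": s,
            "std_beta": est * ratio if np.isfinite(ratio) else np.nan,
            "ci_low": est - zcrit * s, "ci_high": est + zcrit * s,
            "std_ci_low": (est - zcrit * s) * ratio if np.isfinite(ratio) else np.nan,
            "std_ci_high": (est + zcrit * s) * ratio if np.isfinite(ratio) else np.nan,
            "p": p,
        })
    fixed = pd.DataFrame(rows).set_index("term")
    tau00 = max(float(np.asarray(res.cov_re)[0, 0]), 0.0)
    sigma2 = max(float(res.scale), 0.0)
    if np.asarray(res.cov_re).shape[0] > 1:
        re_params = {"cov_re": np.asarray(res.cov_re).tolist()}
    else:
        re_params = {}
    pred = X.to_numpy() @ params.to_numpy()
    return MlmFit(
        outcome=outcome, fixed=fixed, sigma2=sigma2, tau00=tau00,
        n_participants=int(df["pid"].nunique()), n_obs=len(df),
        converged=converged, loglike=float(res.llf), reml=spec.reml,
        spec=spec, re_params=re_params, var_fixed=float(np.var(pred)))


def fit_null_model(obs: pd.DataFrame, outcome: str,
                   reml: bool = True) -> MlmFit:
    """Intercept-only random-intercept model (variance decomposition/ICC)."""
    df = obs
    if df["pid"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    spec = ModelSpec(outcome=outcome, level1=(), level2=(), reml=reml)
    res, X, converged = _fit_mixed(df, outcome, [], None, reml)
    return _results_to_fit(res, X, df, outcome, spec, converged)


def fit_model(obs: pd.DataFrame, spec: ModelSpec) -> MlmFit:
    """REML fit of the configured two-level model on a prepared table."""
    res, X, converged = _fit_mixed(obs, spec.outcome, spec.terms,
                                   spec.random_slope, spec.reml)
    return _results_to_fit(res, X, obs, spec.outcome, spec, converged)


def r_squared(fit: MlmFit) -> tuple[float, float]:
    """(marginal, conditional) R2 from the fixed-vs-total decomposition."""
    total = fit.var_fixed + fit.tau00 + fit.sigma2
    if total <= 0:
        return 0.0, 0.0
    return fit.var_fixed / total, (fit.var_fixed + fit.tau00) / total


def _lrt(ll0: float, ll1: float, df: int) -> tuple[float, float]:
    chi2 = max(2.0 * (ll1 - ll0), 0.0)
    return chi2, float(stats.chi2.sf(chi2, df))


def step_up(obs: pd.DataFrame, outcome: str,
            alpha: float = 0.05) -> tuple[MlmFit, list[dict]]:
    """Sequential model building for one outcome.

    Order: null model; + social-interaction dummies; + greenness; test a
    random greenness slope (REML likelihood-ratio comparison, retained
    only when it improves fit); + sex and age; + SI x Green interactions
    (retained only when improving).  Main effects are kept regardless of
    significance — only the interaction block is dropped when
    non-significant — and every comparison is logged.
    """
    log: list[dict] = []
    null_fit = fit_null_model(obs, outcome, reml=False)
    log.append({"step": "null", "terms": [], "loglike": null_fit.loglike,
                "icc": null_fit.icc})

    ll_prev = null_fit.loglike
    terms: list[str] = []
    for name, block in (("si_dummies", ["D1", "D2", "D3"]),
                        ("greenness", ["green_c"])):
        terms += block
        fit_ml = fit_model(obs, ModelSpec(outcome, tuple(terms), (),
                                          reml=False))
        chi2, p = _lrt(ll_prev, fit_ml.loglike, len(block))
        log.append({"step": f"+{name}", "terms": list(terms),
                    "chi2": chi2, "df": len(block), "p": p,
                    "retained": True})
        ll_prev = fit_ml.loglike

    # random greenness slope, REML comparison at fixed mean structure
    base_reml = fit_model(obs, ModelSpec(outcome, tuple(terms), ()))
    slope_reml = fit_model(obs, ModelSpec(outcome, tuple(terms), (),
                                          random_slope="green_c"))
    chi2, p = _lrt(base_reml.loglike, slope_reml.loglike, 2)
    keep_slope = bool(p < alpha and slope_reml.converged)
    log.append({"step": "random_slope(green)", "chi2": chi2, "df": 2,
                "p": p, "retained": keep_slope})

    covariates = ("sex_c", "age_c")
    fit_cov = fit_model(obs, ModelSpec(outcome, tuple(terms), covariates,
                                       reml=False))
    chi2, p = _lrt(ll_prev, fit_cov.loglike, len(covariates))
    log.append({"step": "+covariates", "terms": list(terms) + list(covariates),
                "chi2": chi2, "df": 2, "p": p, "retained": True})
    ll_prev = fit_cov.loglike

    fit_int = fit_model(obs, ModelSpec(outcome, tuple(terms), covariates,
                                       interactions=True, reml=False))
    chi2, p = _lrt(ll_prev, fit_int.loglike, 3)
    keep_int = bool(p < alpha)
    log.append({"step": "+si_x_green", "chi2": chi2, "df": 3, "p": p,
                "retained": keep_int})

    final_spec = ModelSpec(outcome, tuple(terms), covariates,
                           random_slope="green_c" if keep_slope else None,
                           interactions=keep_int, reml=True)
    final = fit_model(obs, final_spec)
    log.append({"step": "final", "terms": final_spec.terms,
                "reml": True, "converged": final.converged})
    return final, log


def report_table(fit: MlmFit) -> pd.DataFrame:
    """One result table in the conventional layout (fixed block, random
    effects, sample sizes, R2)."""
    rows = fit.fixed.reset_index()[
        ["term", "estimate", "std_beta", "ci_low", "ci_high",
         "std_ci_low", "std_ci_high", "p"]]
    r2m, r2c = fit.r2
    extra = pd.DataFrame([
        {"term": "sigma2", "estimate": fit.sigma2},
        {"term": "tau00_participant", "estimate": fit.tau00},
        {"term": "ICC", "estimate": fit.icc},
        {"term": "N_participants", "estimate": fit.n_participants},
        {"term": "Observations", "estimate": fit.n_obs},
        {"term": "Marginal_R2", "estimate": r2m},
        {"term": "Conditional_R2", "estimate": r2c},
    ])
    return pd.concat([rows, extra], ignore_index=True)


def report_tables(fits: dict[str, MlmFit]) -> dict[str, pd.DataFrame]:
    if not fits:
        raise ValueError("need at least one fit")
    return {name: report_table(fit) for name, fit in fits.items()}


def table_to_markdown(table: pd.DataFrame) -> str:
    cols = list(table.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in table.iterrows():
        cells = ["" if pd.isna(v) else
                 (f"{v:.3f}" if isinstance(v, float) else str(v))
                 for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
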