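"""Descriptive statistics and mixed-effects synthesis of the study table.

Cross-sectional inference on the downturn-level table: random-intercept
linear mixed models (region as the grouping factor, controlling for
pseudoreplication of sequential downturns within a region) relate
resistance and resilience to the per-downturn frequency and candidate
covariates; forward stepwise selection on the information criterion
decides which fixed effects are worth keeping; a further model treats
log-frequency as the response with land use (hunter-gatherer as the
reference level), change, disturbance type, and pace as predictors.

Fitting is by REML through statsmodels' MixedLM; selection compares
marginal (ML-based) AIC, an adequate stand-in for the conditional AIC
when the question is only which terms survive. Standardized coefficients
are computed by refitting on the z-scored response and z-scored
continuous predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "MixedModelResult",
    "DescriptiveReport",
    "describe",
    "eta_squared",
    "fit_mixed",
    "stepwise_ic",
    "fit_frequency_model",
]

DURATION_CLASSES = [
    ("<=50", lambda d: d <= 50),
    ("50-100", lambda d: (d > 50) & (d <= 100)),
    ("100-500", lambda d: (d > 100) & (d <= 500)),
    (">500", lambda d: d > 500),
]

CONTINUOUS = {"frequency", "log_frequency", "pace", "duration", "time_to_min"}


@dataclass
class MixedModelResult:
    """Summary of one fitted random-intercept mixed model."""

    response: str
    fixed: list
    coefficients: pd.DataFrame  # index term; columns coef, se, stat, p
    standardized: pd.DataFrame | None
    random_intercept_var: float
    residual_var: float
    aic: float
    converged: bool
    n_obs: int
    formula: str = ""
    dropped_rows: int = 0

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "coef"])


@dataclass
class DescriptiveReport:
    """Medians, duration-class proportions, skewness, normality, ANOVA."""

    medians_overall: dict
    medians_by_category: pd.DataFrame
    medians_by_region: pd.DataFrame
    medians_by_dist_type: pd.DataFrame
    duration_classes: pd.DataFrame  # count and proportion per class
    skewness: dict
    shapiro_pace: tuple  # (W, p)
    anova: dict  # metric -> dict(F, p, df_between, df_within, eta_sq)
    extras: dict = field(default_factory=dict)


def _adjusted_skew(x) -> float:
    """Adjusted Fisher-Pearson skewness (bias-corrected g1)."""
    return float(st.skew(np.asarray(x, dtype=float), bias=False))


def eta_squared(values, groups) -> float:
    """Proportion of total variance between group means: SS_b / SS_t."""
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": np.asarray(groups)})
    grand = df["y"].mean()
    ss_total = ((df["y"] - grand) ** 2).sum()
    if ss_total == 0:
        return 0.0
    ss_between = df.groupby("g")["y"].agg(lambda v: len(v) * (v.mean() - grand) ** 2).sum()
    return float(ss_between / ss_total)


def _oneway(values, groups) -> dict:
    df = pd.DataFrame({"y": values, "g": groups}).dropna()
    samples = [grp["y"].values for _, grp in df.groupby("g")]
    if len(samples) < 2:
        return {"F": np.nan, "p": np.nan, "df_between": 0, "df_within": len(df) - 1, "eta_sq": np.nan}
    F, p = st.f_oneway(*samples)
    return {
        "F": float(F),
        "p": float(p),
        "df_between": len(samples) - 1,
        "df_within": len(df) - len(samples),
        "eta_sq": eta_squared(df["y"], df["g"]),
    }


def describe(table: pd.DataFrame) -> DescriptiveReport:
    """Descriptive summary of the downturn-level study table."""
    if len(table) < 3:
        raise ValueError("need at least 3 rows to describe")
    metrics = ["resistance", "resilience", "pace", "duration", "time_to_min", "frequency"]
    present = [m for m in metrics if m in table.columns]
    medians_overall = {m: float(table[m].median()) for m in present}
    by_cat = table.groupby("category")[present].median() if "category" in table else pd.DataFrame()
    by_region = table.groupby("region")[present].median()
    by_type = table.groupby("dist_type")[present].median() if "dist_type" in table else pd.DataFrame()
    dur = table["duration"]
    rows = []
    for name, pred in DURATION_CLASSES:
        n = int(pred(dur).sum())
        rows.append({"class": name, "count": n, "proportion": n / len(table)})
    dur_df = pd.DataFrame(rows).set_index("class")
    skewness = {
        "duration": _adjusted_skew(table["duration"]),
        "time_to_min": _adjusted_skew(table["time_to_min"]),
    }
    W, p_sw = st.shapiro(table["pace"].dropna())
    anova = {}
    if "category" in table:
        anova["resistance"] = _oneway(table["resistance"], table["category"])
        if table["resilience"].notna().sum() >= 3:
            sub = table.dropna(subset=["resilience"])
            anova["resilience"] = _oneway(sub["resilience"], sub["category"])
    return DescriptiveReport(
        medians_overall=medians_overall,
        medians_by_category=by_cat,
        medians_by_region=by_region,
        medians_by_dist_type=by_type,
        duration_classes=dur_df,
        skewness=skewness,
        shapiro_pace=(float(W), float(p_sw)),
        anova=anova,
    )


def _term_formula(terms: list) -> str:
    return " + ".join(terms) if terms else "1"


def _fit_one(data: pd.DataFrame, response: str, terms: list, reml: bool) -> tuple:
    """Fit one random-intercept model; returns (statsmodels result, formula)."""
    formula = f"{response} ~ {_term_formula(terms)}"
    model = smf.mixedlm(formula, data=data, groups=data["region"])
    last_exc = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # fall back across optimizers; near-zero random variance can make
        # the profiled objective singular for gradient methods
        for method in ("lbfgs", "powell", "nm"):
            try:
                res = model.fit(reml=reml, method=[method])
                if not np.isfinite(res.llf):  # lbfgs can collapse cov_re to 0 with llf=inf
                    raise RuntimeError(f"non-finite log-likelihood with {method}")
                return res, formula
            except Exception as exc:  # noqa: BLE001
                last_exc = exc
    raise last_exc


def _summarize(
    res,
    formula: str,
    response: str,
    terms: list,
    data: pd.DataFrame,
    dropped: int,
    aic_value: float | None = None,
) -> MixedModelResult:
    fe = res.fe_params
    coefs = pd.DataFrame(
        {
            "coef": fe,
            "se": res.bse_fe.reindex(fe.index),
            "stat": res.tvalues.reindex(fe.index),
            "p": res.pvalues.reindex(fe.index),
        }
    )
    converged = bool(getattr(res, "converged", True))
    # standardized refit: z-score response and continuous predictors
    std = None
    try:
        zdata = data.copy()
        for col in [response] + [t for t in terms if t in CONTINUOUS]:
            s = zdata[col].std(ddof=1)
            if s > 0:
                zdata[col] = (zdata[col] - zdata[col].mean()) / s
        zres, _ = _fit_one(zdata, response, terms, reml=True)
        zfe = zres.fe_params
        std = pd.DataFrame(
            {"coef": zfe, "se": zres.bse_fe.reindex(zfe.index), "p": zres.pvalues.reindex(zfe.index)}
        )
    except Exception:
        pass
    if aic_value is not None:
        aic = float(aic_value)
    else:
        try:
            aic = float(res.aic)
        except Exception:
            aic = np.nan
    return MixedModelResult(
        response=response,
        fixed=list(terms),
        coefficients=coefs,
        standardized=std,
        random_intercept_var=float(np.squeeze(res.cov_re.values)) if res.cov_re.size else 0.0,
        residual_var=float(res.scale),
        aic=aic,
        converged=converged,
        n_obs=len(data),
        formula=formula,
        dropped_rows=dropped,
    )


def _prepare(table: pd.DataFrame, response: str, terms: list) -> tuple:
    cols = {response, "region"}
    for t in terms:
        # pull the bare column name out of patsy-style terms like C(x, ...)
        name = t
        if name.startswith("C("):
            name = name[2:].split(",")[0].rstrip(")").strip()
        cols.add(name)
    data = table.copy()
    if "change" in data.columns:
        data["change"] = data["change"].astype(bool).astype(int)
    before = len(data)
    data = data.dropna(subset=[c for c in cols if c in data.columns])
    return data, before - len(data)


def fit_mixed(
    table: pd.DataFrame,
    response: str,
    fixed: list,
    reml: bool = True,
) -> MixedModelResult:
    """Random-intercept mixed model ``response ~ fixed + (1 | region)``.

    Rows with a missing response (e.g. the undefined-resilience guard)
    are dropped listwise and the count recorded. Non-convergence is
    flagged on the result, not raised.
    """
    data, dropped = _prepare(table, response, fixed)
    if data["region"].nunique() == 1:
        # degenerate single-group case: MixedLM is unstable, note it but fit anyway
        warnings.warn("single region: random-intercept variance is unidentified")
    res, formula = _fit_one(data, response, fixed, reml)
    return _summarize(res, formula, response, fixed, data, dropped)


def stepwise_ic(table: pd.DataFrame, response: str, candidate_fixed: list) -> MixedModelResult:
    """Forward stepwise selection of fixed effects by marginal AIC.

    Starting from the intercept-only model (region random intercept
    always retained), repeatedly adds the candidate with the largest AIC
    improvement until none improves; candidates are compared on ML fits
    and the selected model is refitted by REML. Deterministic given the
    data.
    """
    data, dropped = _prepare(table, response, candidate_fixed)
    selected: list = []
    remaining = list(candidate_fixed)
    res, _ = _fit_one(data, response, selected, reml=False)
    best_aic = float(res.aic)
    while remaining:
        trial_aics = {}
        for term in remaining:
            try:
                r, _ = _fit_one(data, response, selected + [term], reml=False)
                trial_aics[term] = float(r.aic)
            except Exception:
                continue
        if not trial_aics:
            break
        best_term = min(trial_aics, key=trial_aics.get)
        if trial_aics[best_term] < best_aic - 1e-9:
            selected.append(best_term)
            remaining.remove(best_term)
            best_aic = trial_aics[best_term]
        else:
            break
    res, formula = _fit_one(data, response, selected, reml=True)
    # report the ML AIC that drove selection (AIC is undefined under REML)
    return _summarize(res, formula, response, selected, data, dropped, aic_value=best_aic)


def fit_frequency_model(table: pd.DataFrame, min_level_rows: int = 2) -> MixedModelResult:
    """Mixed model of log-frequency on land use, change, type, and pace.

    Hunter-gatherer is the reference level for land use. Land-use levels
    with fewer than ``min_level_rows`` rows are merged into ``"mixed"``
    with a warning (they cannot support their own coefficient).
    """
    data = table.copy()
    counts = data["land_use"].value_counts()
    rare = counts[counts < min_level_rows].index.tolist()
    if rare:
        warnings.warn(f"land-use levels with < {min_level_rows} rows merged into 'mixed': {rare}")
        data.loc[data["land_use"].isin(rare), "land_use"] = "mixed"
    terms = [
        "C(land_use, Treatment(reference='hunter-gatherer'))",
        "change",
        "C(dist_type)",
        "pace",
    ]
    data, dropped = _prepare(data, "log_frequency", terms)
    res, formula = _fit_one(data, "log_frequency", terms, reml=True)
    return _summarize(res, formula, "log_frequency", terms, data, dropped)
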