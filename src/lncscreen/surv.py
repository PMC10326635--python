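"""Prognostic evaluation: Q3 dichotomization, Kaplan-Meier/log-rank, and
Gleason-stratified Cox regression with a proportional-hazards check.

Expression is split at the third quartile (linear-interpolation quantile,
strict > for "high"), clinical covariates are categorized (age at 62; PSA at
10 and 20 ng/mL; pT at the 5/6 split; Gleason <7 / =7 / >7), and the Cox
model includes expression group, PSA, age and pT categories while Gleason
enters only as a stratification variable (it violates proportional hazards
in prostatectomy cohorts). Tied event times use Breslow's method.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test

logger = logging.getLogger(__name__)

COVARIATE_LEVELS = {
    "expr": ("low", "high"),
    "psa_cat": ("psa_low", "psa_intermediate", "psa_high"),
    "age_cat": ("age_low", "age_high"),
    "pt_cat": ("pt_low", "pt_high"),
}


def dichotomize_q3(values: np.ndarray | pd.Series) -> np.ndarray:
    """Label values above the third quartile "high", the rest "low".

    The quartile is the linear-interpolation (type 7) quantile; a value equal
    to Q3 exactly is "low". A constant vector yields all "low" with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need >= 4 values to dichotomize at the third quartile")
    if np.all(v == v[0]):
        warnings.warn("all expression values identical; every sample labeled 'low'")
        return np.full(v.shape, "low", dtype=object)
    q3 = np.quantile(v, 0.75)
    return np.where(v > q3, "high", "low").astype(object)


def categorize_covariates(records: pd.DataFrame) -> pd.DataFrame:
    """Add categorical clinical covariates.

    age: <=62 low / >62 high; PSA: <=10 low, (10, 20) intermediate, >=20
    high; pT: codes 2-4 low, 5-6 high; Gleason: <7 low, =7 intermediate,
    >7 high.
    """
    out = records.copy()
    for col in ("age", "psa", "gleason", "pt"):
        if col not in out.columns:
            raise ValueError(f"clinical table missing covariate {col!r}")
    if out["pt"].lt(2).any() or out["pt"].gt(6).any():
        raise ValueError("pT codes must lie in 2..6")
    out["age_cat"] = np.where(out["age"] > 62, "age_high", "age_low")
    out["psa_cat"] = np.select(
        [out["psa"] >= 20, out["psa"] > 10], ["psa_high", "psa_intermediate"], "psa_low")
    out["pt_cat"] = np.where(out["pt"] >= 5, "pt_high", "pt_low")
    out["gs_cat"] = np.select(
        [out["gleason"] > 7, out["gleason"] == 7], ["gs_high", "gs_intermediate"], "gs_low")
    return out


def km_logrank(records: pd.DataFrame, groups: np.ndarray | pd.Series,
               ) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Product-limit survival per group plus the log-rank test.

    Returns ({group: table(time, at_risk, survival)}, chi2, p).
    """
    groups = np.asarray(groups, dtype=object)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    curves: dict[str, pd.DataFrame] = {}
    for lab in labels:
        mask = groups == lab
        if mask.sum() == 0:
            raise ValueError(f"group {lab!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(records.loc[mask, "time"], records.loc[mask, "event"])
        table = kmf.event_table
        curves[str(lab)] = pd.DataFrame({
            "time": table.index.to_numpy(),
            "at_risk": table["at_risk"].to_numpy(),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
        })
    res = multivariate_logrank_test(records["time"], groups, records["event"])
    return curves, float(res.test_statistic), float(res.p_value)


def cox_stratified(records: pd.DataFrame, strata: str | None = "gs_cat",
                   covariates: tuple[str, ...] = ("expr", "psa_cat", "age_cat", "pt_cat"),
                   ) -> tuple[pd.DataFrame, CoxPHFitter]:
    """Multivariate Cox PH fit with stratum-specific baseline hazards.

    Categorical covariates are dummy-coded against their reference level (the
    first level listed in COVARIATE_LEVELS); constant covariates are dropped
    with a warning. Returns the hazard-ratio table (with HR = 1 reference
    rows, Wald 95% CIs and p-values) and the fitted lifelines model.
    """
    if records["event"].sum() == 0:
        raise ValueError("no events in the data; Cox model cannot be fit")
    design = pd.DataFrame({"time": records["time"].to_numpy(),
                           "event": records["event"].to_numpy()})
    dummy_of: dict[str, tuple[str, str]] = {}  # column -> (covariate, level)
    for cov in covariates:
        levels = COVARIATE_LEVELS.get(cov)
        vals = records[cov].astype(str)
        if levels is None:
            levels = tuple(pd.unique(vals))
        if vals.nunique() < 2:
            warnings.warn(f"covariate {cov!r} is constant; dropped from the model")
            continue
        for level in levels[1:]:
            col = f"{cov}={level}"
            design[col] = (vals == level).astype(float).to_numpy()
            dummy_of[col] = (cov, level)
    if strata is not None:
        design["_stratum"] = records[strata].astype(str).to_numpy()

    cph = CoxPHFitter()
    cph.fit(design, duration_col="time", event_col="event",
            strata=["_stratum"] if strata is not None else None)
    cph._lncscreen_design = design

    rows = []
    summary = cph.summary
    for cov in covariates:
        levels = COVARIATE_LEVELS.get(cov, ())
        present = [c for c, (cv, _) in dummy_of.items() if cv == cov]
        if not present:
            continue
        ref = levels[0] if levels else "reference"
        rows.append((cov, str(ref), 1.0, np.nan, np.nan, np.nan, True))
        for col in present:
            s = summary.loc[col]
            rows.append((cov, dummy_of[col][1], float(np.exp(s["coef"])),
                         float(np.exp(s["coef lower 95%"])),
                         float(np.exp(s["coef upper 95%"])),
                         float(s["p"]), False))
    table = pd.DataFrame(rows, columns=["variable", "level", "hazard_ratio",
                                        "ci_low", "ci_high", "p_value", "is_reference"])
    return table, cph


def ph_check(cph: CoxPHFitter, design: pd.DataFrame | None = None,
             alpha: float = 0.05) -> pd.DataFrame:
    """Grambsch-Therneau scaled-Schoenfeld test of proportional hazards.

    Covariates with p < alpha are flagged as PH-violating (stratify on them).
    With fewer than five events the test is unreliable and returns NA.
    """
    if design is None:
        design = getattr(cph, "_lncscreen_design", None)
    if design is None:
        raise ValueError("pass the design frame the model was fitted on")
    n_events = int(np.asarray(cph.event_observed).sum())
    if n_events < 5:
        warnings.warn("fewer than 5 events; proportional-hazards test not computed")
        return pd.DataFrame({"covariate": cph.params_.index,
                             "p_value": np.nan, "violates_ph": pd.NA})
    res = proportional_hazard_test(cph, design, time_transform="rank")
    summ = res.summary
    names = summ.index.get_level_values(0) if isinstance(summ.index, pd.MultiIndex) \
        else summ.index
    return pd.DataFrame({
        "covariate": np.asarray(names),
        "p_value": summ["p"].to_numpy(),
        "violates_ph": summ["p"].to_numpy() < alpha,
    })


def evaluate_gene(records: pd.DataFrame, expression: np.ndarray | pd.Series,
                  strata: str | None = "gs_cat"):
    """Full prognostic evaluation of one gene: Q3 split, KM/log-rank,
    stratified Cox, PH check. Returns a dict of results."""
    rec = categorize_covariates(records)
    rec["expr"] = dichotomize_q3(expression)
    curves, chi2, p = km_logrank(rec, rec["expr"])
    cox_table, cph = cox_stratified(rec, strata=strata)
    ph = ph_check(cph)
    return {"km_curves": curves, "logrank_chi2": chi2, "logrank_p": p,
            "cox_table": cox_table, "cox_fit": cph, "ph_check": ph}
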