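"""Survival machinery shared by the discovery screen and cohort validation.

Cox proportional-hazards fits (Efron tie handling, Wald 95% CIs), the
Kaplan–Meier estimator, the log-rank test, Harrell's concordance index and
Benjamini–Hochberg FDR adjustment. Model fitting is delegated to lifelines;
this module fixes the conventions (tie handling, CI method, covariate
coding) and exposes plain result containers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from statsmodels.stats.multitest import multipletests

from .io_formats import ClinicalCohort
from .mutation_pathway import PathwayMutationProfile

__all__ = [
    "CoxFit",
    "KmCurve",
    "ScreenResult",
    "cox_fit",
    "km_estimate",
    "logrank_test",
    "concordance_index",
    "bh_fdr",
    "screen_pathways",
    "expand_covariates",
]

#: Sentinel for a median survival that is never reached.
NOT_REACHED = "NR"


@dataclass
class CoxFit:
    """Per-covariate Cox model estimates (log HR scale plus natural scale)."""

    summary: pd.DataFrame  # index = covariate; coef, hazard_ratio, ci_low, ci_high, se, p_value
    log_likelihood: float
    n: int
    n_events: int
    converged: bool

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hazard_ratio"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return float(row["ci_low"]), float(row["ci_high"])

    def p_value(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p_value"])


@dataclass
class KmCurve:
    """Product-limit survival estimate on the event-time grid."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float | str  # months, or "NR"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


@dataclass
class ScreenResult:
    """Per-pathway Cox screen with BH-FDR adjustment across pathways."""

    table: pd.DataFrame  # index = pathway; hazard_ratio, ci_low, ci_high, p_value, fdr, retained
    fdr_threshold: float
    skipped: list[str] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="pathway")


def expand_covariates(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Numeric columns pass through; categoricals become 0/1 indicators.

    The most frequent level is the (dropped) reference, so hazard ratios are
    relative to the modal category.
    """
    out = {}
    for col in columns:
        s = df[col]
        if pd.api.types.is_numeric_dtype(s):
            out[col] = s.astype(float)
        else:
            levels = s.value_counts().index.tolist()  # most frequent first
            for lev in levels[1:]:
                out[f"{col}[{lev}]"] = (s == lev).astype(float)
    return pd.DataFrame(out, index=df.index)


def cox_fit(
    time: Sequence[float],
    event: Sequence[int],
    covariates: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> CoxFit:
    """Fit a Cox proportional-hazards model (Efron ties, Wald 95% CI).

    Categorical covariates must be pre-expanded to indicators (see
    :func:`expand_covariates`). Constant covariates and zero-event inputs
    are rejected; non-convergence (e.g. monotone likelihood under perfect
    separation) raises a diagnostic error.
    """
    X = pd.DataFrame(covariates).astype(float).reset_index(drop=True)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no events: Cox model is undefined")
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise ValueError(f"constant covariate {col!r}")
    df = X.copy()
    df["__time"], df["__event"] = time, event
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            fitter.fit(df, duration_col="__time", event_col="__event")
        converged = True
    except ConvergenceError as exc:
        raise ValueError(f"Cox fit failed to converge (possible separation): {exc}") from exc
    except ConvergenceWarning:
        # refit without the warning trap; flag shaky convergence
        fitter = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="__time", event_col="__event")
        converged = False
    s = fitter.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hazard_ratio": np.exp(s["coef"]),
            "ci_low": np.exp(s["coef"] - 1.96 * s["se(coef)"]),
            "ci_high": np.exp(s["coef"] + 1.96 * s["se(coef)"]),
            "se": s["se(coef)"],
            "p_value": s["p"],
        }
    )
    summary.index = list(X.columns)
    return CoxFit(
        summary=summary,
        log_likelihood=float(fitter.log_likelihood_),
        n=len(time),
        n_events=int(event.sum()),
        converged=converged,
    )


def km_estimate(time: Sequence[float], event: Sequence[int]) -> KmCurve:
    """Kaplan–Meier product-limit estimate with median survival.

    The median is the smallest time with S(t) <= 0.5, or "NR" when the
    curve never drops that far (all-censored inputs stay flat at 1).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    km = KaplanMeierFitter()
    km.fit(time, event)
    grid = km.survival_function_.index.to_numpy(dtype=float)
    surv = km.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = km.event_table["at_risk"].reindex(km.survival_function_.index).to_numpy()
    med = km.median_survival_time_
    median: float | str = NOT_REACHED if math.isinf(med) else float(med)
    return KmCurve(times=grid, survival=surv, at_risk=at_risk, median=median)


def logrank_test(
    time: Sequence[float],
    event: Sequence[int],
    group: Sequence,
) -> tuple[float, float]:
    """Log-rank test across groups; returns (chi-square statistic, p).

    Two groups give the classic 1-df test; k groups give the k−1 df version
    used when stratifying by two biomarkers.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    if event.sum() == 0:
        raise ValueError("log-rank undefined: no events")
    if len(np.unique(group)) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    res = multivariate_logrank_test(time, group, event)
    return float(res.test_statistic), float(res.p_value)


def concordance_index(
    risk_score: Sequence[float],
    time: Sequence[float],
    event: Sequence[int],
) -> float:
    """Harrell's C: P(higher risk ⇒ earlier event) over comparable pairs."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    risk = np.asarray(risk_score, dtype=float)
    if event.sum() == 0:
        raise ValueError("no comparable pairs: no events")
    # lifelines scores *predicted survival time*; negate risk so higher risk
    # means shorter predicted survival.
    return float(_lifelines_cindex(time, -risk, event))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_pathways(
    profile: PathwayMutationProfile,
    cohort: ClinicalCohort,
    covariate_names: Sequence[str] = ("age", "sex", "cancer_type"),
    fdr_threshold: float = 0.05,
) -> ScreenResult:
    """Cox screen of every pathway's mutation status against survival.

    One multivariate Cox model per pathway (pathway status + clinical
    covariates); BH-FDR across the pathways actually fitted. Pathways that
    are all-mutated or all-wild-type in the shared samples are skipped with
    a warning and excluded from the FDR family.
    """
    shared = [s for s in profile.samples if s in set(cohort.ids)]
    if set(profile.samples) != set(cohort.ids):
        raise ValueError(
            "profile and cohort sample ids differ "
            f"(profile {len(profile.samples)}, cohort {len(cohort)}, shared {len(shared)})"
        )
    clin = cohort.data.loc[shared]
    covs = expand_covariates(clin, [c for c in covariate_names if c in clin.columns])
    rows, skipped = {}, []
    for pw in profile.pathways:
        status = profile.status.loc[pw, shared].astype(float)
        if status.nunique() <= 1:
            skipped.append(pw)
            warnings.warn(f"pathway {pw!r} constant across samples; skipped", stacklevel=2)
            continue
        X = covs.copy()
        X.insert(0, "pathway", status)
        fit = cox_fit(clin["time"], clin["event"], X)
        row = fit.summary.loc["pathway"]
        rows[pw] = (
            row["hazard_ratio"],
            row["ci_low"],
            row["ci_high"],
            row["p_value"],
        )
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["hazard_ratio", "ci_low", "ci_high", "p_value"]
    )
    if len(table):
        table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    else:
        table["fdr"] = []
    table["retained"] = table["fdr"] < fdr_threshold
    return ScreenResult(table=table, fdr_threshold=fdr_threshold, skipped=skipped)
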