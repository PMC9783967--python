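"""Discovery of the predictive comutated pathway pair.

The procedure: dichotomize TMB (and NAL) at the top quartile; pick the
comutation-count threshold that maximizes the Youden index on a ROC over
integer thresholds; regress TMB and NAL on the survival-retained pathways'
mutation indicators by ordinary least squares; keep pathways whose β is
positive for both responses; and among candidate pairs, select the pair
whose comutated carriers show the strongest rank-sum advantage in TMB and
NAL over the carriers of every competing pair.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .mutation_pathway import PathwayMutationProfile

__all__ = [
    "QuartileLabels",
    "RocCurve",
    "RegressionResult",
    "PairSelection",
    "quartile_split",
    "youden_threshold",
    "fit_multiple_regression",
    "wilcoxon_rank_sum",
    "select_pathway_pair",
    "run_discovery_chain",
]


@dataclass
class QuartileLabels:
    """Binary high/low split at the 75th percentile (ties go high)."""

    labels: pd.Series  # bool, True = high
    cutoff: float

    @property
    def n_high(self) -> int:
        return int(self.labels.sum())


@dataclass
class RocCurve:
    """ROC over integer score thresholds with the Youden operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    best_threshold: int
    best_sensitivity: float
    best_specificity: float
    youden: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


@dataclass
class RegressionResult:
    """OLS of a burden response on pathway mutation indicators."""

    response: str
    table: pd.DataFrame  # index = pathway; beta, se, p_value
    intercept: float

    def beta(self, pathway: str) -> float:
        return float(self.table.loc[pathway, "beta"])


@dataclass
class PairSelection:
    """Pairwise rank-sum comparison table and the selected pathway pair."""

    candidates: list[str]
    comparisons: pd.DataFrame  # per ordered pair: min standardized advantage, Wilcoxon p's
    selected: tuple[str, str]
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)


def quartile_split(values: Sequence[float]) -> QuartileLabels:
    """Label samples high/low at the top quartile of ``values``.

    The cutoff is the 75th percentile under NumPy's linear-interpolation
    convention; samples at or above the cutoff are "high".
    """
    s = pd.Series(values).astype(float)
    finite = s.dropna()
    if len(finite) < 4:
        raise ValueError("need at least 4 finite values for a quartile split")
    if finite.nunique() == 1:
        raise ValueError("all values identical: quartile split is degenerate")
    cutoff = float(np.percentile(finite, 75, method="linear"))
    labels = s >= cutoff
    return QuartileLabels(labels=labels, cutoff=cutoff)


def youden_threshold(score: Sequence[int], labels: QuartileLabels | Sequence[bool]) -> RocCurve:
    """ROC of an integer score against binary labels; pick max-Youden cutoff.

    Thresholds are every distinct score value with the rule "predict high if
    score >= t". Ties on the Youden index J = sensitivity + specificity − 1
    break toward the smaller (more sensitive) threshold. AUC is the
    trapezoidal area over the full curve including the (0,0)/(1,1) anchors.
    """
    y = np.asarray(labels.labels if isinstance(labels, QuartileLabels) else labels, dtype=bool)
    s = np.asarray(score, dtype=float)
    if len(s) != len(y):
        raise ValueError("score and labels differ in length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present")
    thresholds = np.unique(s).astype(int)
    sens = np.array([(s[y] >= t).mean() for t in thresholds])
    spec = np.array([(s[~y] < t).mean() for t in thresholds])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first maximum = smallest threshold
    # full curve for AUC: anchor at (FPR=1, TPR=1) for t = -inf and (0, 0) above max
    fpr = np.concatenate(([1.0], 1.0 - spec, [0.0]))
    tpr = np.concatenate(([1.0], sens, [0.0]))
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        best_threshold=int(thresholds[best]),
        best_sensitivity=float(sens[best]),
        best_specificity=float(spec[best]),
        youden=float(j[best]),
    )


def fit_multiple_regression(
    response: Sequence[float],
    pathway_status: pd.DataFrame,
    response_name: str = "TMB",
) -> RegressionResult:
    """OLS of TMB or NAL on pathway mutation indicators (with intercept)."""
    X = pd.DataFrame(pathway_status).astype(float)
    y = np.asarray(response, dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of pathways + 1")
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise ValueError(f"constant pathway column {col!r}")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; near-collinear columns e.g. {worst}")
    fit = sm.OLS(y, design).fit()
    table = pd.DataFrame(
        {
            "beta": fit.params[X.columns],
            "se": fit.bse[X.columns],
            "p_value": fit.pvalues[X.columns],
        }
    )
    return RegressionResult(
        response=response_name, table=table, intercept=float(fit.params["const"])
    )


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U statistic and p).

    Exact enumeration when m+n <= 20 with no ties; otherwise the normal
    approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    exact = (x.size + y.size) <= 20 and len(np.unique(pooled)) == pooled.size
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def _standardized_rank_advantage(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized Mann–Whitney z of a vs b (positive ⇒ a tends larger)."""
    m, n = len(a), len(b)
    u_stat = float(stats.mannwhitneyu(a, b, alternative="two-sided").statistic)
    mean_u = m * n / 2.0
    ranks = stats.rankdata(np.concatenate([a, b]))
    # tie-corrected variance
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / ((m + n) * (m + n - 1.0)) if m + n > 1 else 0.0
    var_u = m * n / 12.0 * ((m + n + 1) - tie_term)
    if var_u <= 0:
        return 0.0
    return (u_stat - mean_u) / np.sqrt(var_u)


def select_pathway_pair(
    candidates: Sequence[str],
    profile: PathwayMutationProfile,
    tmb: pd.Series,
    nal: pd.Series,
) -> PairSelection:
    """Select the comutated pair with the strongest TMB/NAL advantage.

    For every candidate pair, the samples comutated for that pair are
    compared against the samples comutated for each competing pair on TMB
    and on NAL by Wilcoxon rank-sum. A pair's score is the minimum, over
    competing pairs and both responses, of the standardized rank advantage;
    the selected pair maximizes this max-min score. Ties break
    lexicographically. Pairs with no comutated samples are excluded.
    """
    cand = sorted(dict.fromkeys(candidates))
    if len(cand) < 2:
        raise ValueError("need at least 2 candidate pathways")
    missing = [p for p in cand if p not in profile.pathways]
    if missing:
        raise KeyError(f"unknown candidate pathway(s): {missing}")
    samples = list(profile.samples)
    tmb = tmb.reindex(samples)
    nal = nal.reindex(samples)
    pairs = list(itertools.combinations(cand, 2))
    carriers: dict[tuple[str, str], np.ndarray] = {}
    excluded = []
    for p in pairs:
        mask = (profile.status.loc[p[0]] == 1) & (profile.status.loc[p[1]] == 1)
        if mask.sum() == 0:
            excluded.append(p)
            warnings.warn(f"pair {p} has no comutated samples; excluded", stacklevel=2)
        else:
            carriers[p] = mask.to_numpy(dtype=bool)
    live = [p for p in pairs if p in carriers]
    if len(live) < 1:
        raise ValueError("no candidate pair has comutated samples")
    if len(live) == 1:
        comp = pd.DataFrame(
            [], columns=["pair", "versus", "z_tmb", "z_nal", "p_tmb", "p_nal"]
        )
        return PairSelection(cand, comp, live[0], excluded)
    rows = []
    scores: dict[tuple[str, str], float] = {}
    for p in live:
        worst = np.inf
        for q in live:
            if q == p:
                continue
            # disjoint comparison: samples comutated for both pairs carry no
            # information about which pair drives the burden, so they are
            # excluded from both sides
            only_p = carriers[p] & ~carriers[q]
            only_q = carriers[q] & ~carriers[p]
            for resp_name, resp in (("tmb", tmb), ("nal", nal)):
                a = resp.to_numpy()[only_p]
                b = resp.to_numpy()[only_q]
                a, b = a[~np.isnan(a)], b[~np.isnan(b)]
                if a.size == 0 or b.size == 0:
                    continue
                z = _standardized_rank_advantage(a, b)
                _, pval = wilcoxon_rank_sum(a, b)
                rows.append(
                    {
                        "pair": "|".join(p),
                        "versus": "|".join(q),
                        "response": resp_name,
                        "z": z,
                        "p_value": pval,
                    }
                )
                worst = min(worst, z)
        scores[p] = worst if np.isfinite(worst) else -np.inf
    # deterministic lexicographic tie-break: among max scores pick smallest name
    best_score = max(scores.values())
    tied = sorted([p for p in live if scores[p] == best_score])
    selected = tied[0]
    comparisons = pd.DataFrame(rows)
    return PairSelection(cand, comparisons, selected, excluded)


def run_discovery_chain(
    profile: PathwayMutationProfile,
    cohort,
    tmb: pd.Series,
    nal: pd.Series,
    covariate_names: Sequence[str] = ("age", "sex", "cancer_type"),
    fdr_threshold: float = 0.05,
):
    """Full discovery: Cox screen → joint-β filter → pair selection.

    Returns (ScreenResult, RegressionResult for TMB, RegressionResult for
    NAL, candidate list, PairSelection or None). The candidate filter keeps
    screened pathways whose OLS β is positive against both TMB and NAL.
    """
    from .survival_stats import screen_pathways

    screen = screen_pathways(profile, cohort, covariate_names, fdr_threshold)
    retained = screen.retained
    if not retained:
        return screen, None, None, [], None
    status = profile.status.loc[retained].T.astype(float)  # samples × pathways
    usable = [c for c in status.columns if status[c].nunique() > 1]
    status = status[usable]
    if not usable:
        return screen, None, None, [], None
    samples = list(status.index)
    reg_tmb = fit_multiple_regression(tmb.reindex(samples), status, "TMB")
    reg_nal = fit_multiple_regression(nal.reindex(samples), status, "NAL")
    candidates = [
        p
        for p in usable
        if reg_tmb.beta(p) > 0 and reg_nal.beta(p) > 0
    ]
    if len(candidates) < 2:
        return screen, reg_tmb, reg_nal, candidates, None
    selection = select_pathway_pair(candidates, profile, tmb, nal)
    return screen, reg_tmb, reg_nal, candidates, selection
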