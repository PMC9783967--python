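"""Evaluation of a comutation classification in an immunotherapy cohort.

Response-rate contingency analysis (Fisher's exact test), survival
stratification by one or two biomarkers, confusion statistics against a
reference label such as MSI-H, and side-by-side biomarker performance
(Harrell's C and AUROC for response).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

from .io_formats import ClinicalCohort
from .survival_stats import KmCurve, concordance_index, km_estimate, logrank_test

__all__ = [
    "ContingencyTable",
    "ConfusionStats",
    "StratifiedGroups",
    "fisher_exact",
    "freeman_halton_2x3",
    "response_rates",
    "confusion_vs_reference",
    "stratify_two_biomarkers",
    "compare_biomarkers",
]


@dataclass
class ContingencyTable:
    """2×k nonnegative count table with labels and exact-fraction rates."""

    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def row_rates(self) -> list[Fraction]:
        """Per-row rate of the first column (e.g. responders) as fractions."""
        return [
            Fraction(int(r[0]), int(r.sum())) if r.sum() else Fraction(0)
            for r in self.counts
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass
class ConfusionStats:
    """Sensitivity/specificity/PPV/NPV with exact fraction provenance."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def sensitivity(self) -> Fraction:
        return Fraction(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Fraction:
        return Fraction(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Fraction:
        return Fraction(self.tp, self.tp + self.fp) if self.tp + self.fp else Fraction(0)

    @property
    def npv(self) -> Fraction:
        return Fraction(self.tn, self.tn + self.fn) if self.tn + self.fn else Fraction(0)

    def table(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass
class StratifiedGroups:
    """Three-way stratification by two binary biomarkers."""

    strata: pd.Series  # per patient: dual-positive | single-positive | dual-negative
    km: dict[str, KmCurve]
    logrank_statistic: float
    logrank_p: float
    response_table: ContingencyTable | None
    response_p: float | None
    dropped_strata: list[str] = field(default_factory=list)


def fisher_exact(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2×2 table.

    Two-sided p by the probability method: the sum of hypergeometric
    probabilities of tables (with the observed margins) no more probable
    than the observed one. Returns (conditional-MLE odds ratio, p).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin: Fisher's test undefined")
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    or_ = float(_cmle_odds_ratio(t, kind="conditional").statistic)
    return or_, p


def freeman_halton_2x3(table: Sequence[Sequence[int]], exact_max_total: int = 200) -> float:
    """Exact two-sided test of independence for a 2×3 table.

    Full enumeration of tables with the observed margins (probability
    method), feasible for totals up to a few hundred; larger tables fall
    back to the chi-square test with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 3):
        raise ValueError("table must be 2x3")
    n = int(t.sum())
    if n > exact_max_total:
        warnings.warn("table too large for exact enumeration; chi-square fallback", stacklevel=2)
        return float(stats.chi2_contingency(t, correction=False)[1])
    r1 = int(t[0].sum())
    c = t.sum(axis=0).astype(int)

    from math import comb

    def n_ways(x: tuple[int, int, int]) -> int:
        # multivariate hypergeometric numerator for a first row x
        return comb(c[0], x[0]) * comb(c[1], x[1]) * comb(c[2], x[2])

    denom = comb(n, r1)
    p_obs = n_ways(tuple(int(v) for v in t[0])) / denom
    total = 0.0
    for x0 in range(min(r1, c[0]) + 1):
        for x1 in range(min(r1 - x0, c[1]) + 1):
            x2 = r1 - x0 - x1
            if x2 < 0 or x2 > c[2]:
                continue
            pr = n_ways((x0, x1, x2)) / denom
            if pr <= p_obs * (1 + 1e-12):
                total += pr
    return float(min(total, 1.0))


def response_rates(
    cohort: ClinicalCohort,
    comut_labels: pd.Series,
    scheme: str = "ORR",
) -> tuple[ContingencyTable, dict]:
    """Response contingency of comut+ vs comut− with Fisher's exact test.

    ``scheme='ORR'``: responder = CR|PR, non-responder = SD|PD.
    ``scheme='DCB'``: durable-benefit column used directly. NA patients are
    excluded and counted in the returned summary.
    """
    df = cohort.data
    lab = comut_labels.reindex(df.index).astype(bool)
    if scheme.upper() == "ORR":
        if "response" not in df.columns:
            raise ValueError("cohort has no response column")
        col = df["response"]
        pos, neg = {"CR", "PR"}, {"SD", "PD"}
    elif scheme.upper() == "DCB":
        if "dcb" not in df.columns:
            raise ValueError("cohort has no dcb column")
        col = df["dcb"]
        pos, neg = {"DCB"}, {"NDB"}
    else:
        raise ValueError("scheme must be ORR or DCB")
    evaluable = col.isin(pos | neg)
    n_na = int((~evaluable).sum())
    responder = col.isin(pos)
    counts = np.array(
        [
            [int((lab & evaluable & responder).sum()), int((lab & evaluable & ~responder).sum())],
            [int((~lab & evaluable & responder).sum()), int((~lab & evaluable & ~responder).sum())],
        ]
    )
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("a comut group has zero evaluable patients")
    ct = ContingencyTable(
        counts, ["comut+", "comut-"], ["responder", "non-responder"]
    )
    or_, p = fisher_exact(counts)
    rates = ct.row_rates()
    summary = {
        "odds_ratio": or_,
        "p_value": p,
        "rate_pos": rates[0],
        "rate_neg": rates[1],
        "n_excluded_na": n_na,
        "scheme": scheme.upper(),
    }
    return ct, summary


def confusion_vs_reference(
    predicted: Sequence[bool] | pd.Series,
    reference: Sequence[bool] | pd.Series,
) -> tuple[ConfusionStats, dict]:
    """Confusion statistics of a binary prediction against a reference label.

    E.g. comut+ as a predictor of MSI-H. Also runs Fisher's exact test on
    the same 2×2 table.
    """
    pred = np.asarray(predicted, dtype=bool)
    ref = np.asarray(reference, dtype=bool)
    if len(pred) != len(ref):
        raise ValueError("length mismatch")
    if ref.all() or (~ref).all():
        raise ValueError("reference has a single class")
    cs = ConfusionStats(
        tp=int((pred & ref).sum()),
        fn=int((~pred & ref).sum()),
        fp=int((pred & ~ref).sum()),
        tn=int((~pred & ~ref).sum()),
    )
    or_, p = fisher_exact(cs.table())
    return cs, {"odds_ratio": or_, "p_value": p}


def stratify_two_biomarkers(
    cohort: ClinicalCohort,
    b1: pd.Series,
    b2: pd.Series,
    b2_cutoff: float | None = None,
    scheme: str | None = None,
) -> StratifiedGroups:
    """Stratify by two biomarkers into dual-positive / single / dual-negative.

    ``b1`` is binary (e.g. comut+). ``b2`` may be binary or numeric with a
    cutoff (PD-L1 convention: value >= cutoff is "high"; default cutoff 50).
    Per-stratum KM curves, a k-group log-rank across populated strata, and,
    when ``scheme`` is given, a response comparison (exact 2×3 test for
    totals <= 200, chi-square beyond).
    """
    df = cohort.data
    a = b1.reindex(df.index).astype(bool)
    b2 = b2.reindex(df.index)
    if b2_cutoff is None and not (b2.dropna().isin([0, 1, True, False]).all()):
        b2_cutoff = 50.0
    if b2_cutoff is not None:
        b = b2.astype(float) >= b2_cutoff
    else:
        b = b2.astype(bool)
    valid = b2.notna()
    strata = pd.Series(index=df.index, dtype=object)
    strata[valid & a & b] = "dual-positive"
    strata[valid & (a ^ b)] = "single-positive"
    strata[valid & ~a & ~b] = "dual-negative"
    populated = [
        s
        for s in ("dual-positive", "single-positive", "dual-negative")
        if (strata == s).any()
    ]
    dropped = [
        s
        for s in ("dual-positive", "single-positive", "dual-negative")
        if s not in populated
    ]
    if dropped:
        warnings.warn(f"empty strata dropped: {dropped}", stacklevel=2)
    mask = strata.isin(populated)
    km = {
        s: km_estimate(df.loc[strata == s, "time"], df.loc[strata == s, "event"])
        for s in populated
    }
    stat, p = logrank_test(df.loc[mask, "time"], df.loc[mask, "event"], strata[mask])
    resp_table = resp_p = None
    if scheme is not None:
        col = df["response"] if scheme.upper() == "ORR" else df["dcb"]
        pos = {"CR", "PR"} if scheme.upper() == "ORR" else {"DCB"}
        neg = {"SD", "PD"} if scheme.upper() == "ORR" else {"NDB"}
        evaluable = col.isin(pos | neg) & mask
        counts = np.array(
            [
                [
                    int((evaluable & (strata == s) & col.isin(pos)).sum()),
                    int((evaluable & (strata == s) & col.isin(neg)).sum()),
                ]
                for s in populated
            ]
        ).T  # 2 × k
        if counts.shape[1] == 3:
            resp_p = freeman_halton_2x3(counts)
        elif counts.shape[1] == 2:
            _, resp_p = fisher_exact(counts.T)
        else:
            resp_p = float(stats.chi2_contingency(counts, correction=False)[1])
        resp_table = ContingencyTable(counts.T, populated, ["responder", "non-responder"])
    return StratifiedGroups(
        strata=strata,
        km=km,
        logrank_statistic=stat,
        logrank_p=p,
        response_table=resp_table,
        response_p=resp_p,
        dropped_strata=dropped,
    )


def _binary_roc_auc(biomarker: np.ndarray, responder: np.ndarray) -> float:
    """AUROC of a binary biomarker = (sensitivity + specificity) / 2."""
    sens = (biomarker & responder).sum() / responder.sum()
    spec = (~biomarker & ~responder).sum() / (~responder).sum()
    return float((sens + spec) / 2.0)


def _numeric_roc_auc(score: np.ndarray, responder: np.ndarray) -> float:
    """Full-curve AUROC via the rank (Mann–Whitney) formulation."""
    n1, n0 = int(responder.sum()), int((~responder).sum())
    ranks = stats.rankdata(score)
    u = ranks[responder].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def compare_biomarkers(
    cohort: ClinicalCohort,
    biomarkers: Mapping[str, pd.Series],
    scheme: str = "ORR",
) -> pd.DataFrame:
    """Side-by-side C-index and response AUROC for several biomarkers.

    Binary biomarkers (e.g. comut status) yield the one-threshold ROC, whose
    AUROC equals (sensitivity + specificity)/2; numeric biomarkers (TMB)
    yield the full rank-based AUROC. The C-index treats each biomarker as a
    protective score (higher = lower risk), so C > 0.5 means the biomarker
    orders survival correctly.
    """
    df = cohort.data
    if scheme.upper() == "ORR":
        col, pos, neg = df.get("response"), {"CR", "PR"}, {"SD", "PD"}
    else:
        col, pos, neg = df.get("dcb"), {"DCB"}, {"NDB"}
    rows = {}
    for name, series in biomarkers.items():
        s = series.reindex(df.index)
        if s.dropna().nunique() <= 1:
            warnings.warn(f"biomarker {name!r} is constant; skipped", stacklevel=2)
            continue
        auroc = np.nan
        if col is not None:
            evaluable = col.isin(pos | neg) & s.notna()
            responder = col[evaluable].isin(pos).to_numpy()
            vals = s[evaluable]
            if vals.isin([0, 1, True, False]).all():
                auroc = _binary_roc_auc(vals.astype(bool).to_numpy(), responder)
            else:
                auroc = _numeric_roc_auc(vals.astype(float).to_numpy(), responder)
        ok = s.notna()
        cidx = concordance_index(
            -s[ok].astype(float), df.loc[ok, "time"], df.loc[ok, "event"]
        )
        rows[name] = {"c_index": cidx, "auroc": auroc}
    return pd.DataFrame.from_dict(rows, orient="index")
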