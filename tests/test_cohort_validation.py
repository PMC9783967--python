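from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from comutpath.cohort_validation import (
    compare_biomarkers,
    confusion_vs_reference,
    fisher_exact,
    freeman_halton_2x3,
    response_rates,
    stratify_two_biomarkers,
)
from comutpath.io_formats import ClinicalCohort


# --- independent oracle -------------------------------------------------------


def fisher_enumeration(table):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, r1)

    def prob(x):
        return comb(c1, x) * comb(n - c1, r1 - x) / denom

    p_obs = prob(a)
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def make_cohort(rng, n=200, with_msi=True):
    lab = rng.random(n) < 0.3
    df = pd.DataFrame(
        {
            "time": rng.exponential(20, n).round(3),
            "event": rng.integers(0, 2, n),
            "age": rng.normal(60, 10, n).round(1),
            "sex": rng.choice(["F", "M"], n),
            "cancer_type": rng.choice(["A", "B"], n),
            "response": rng.choice(["CR", "PR", "SD", "PD"], n),
            "dcb": rng.choice(["DCB", "NDB"], n),
            "tmb": rng.exponential(5, n).round(2),
            "pdl1": rng.uniform(0, 100, n).round(1),
        },
        index=[f"p{i}" for i in range(n)],
    )
    if with_msi:
        df["msi"] = rng.choice(["MSI-H", "MSS"], n, p=[0.2, 0.8])
    return ClinicalCohort(df), pd.Series(lab, index=df.index)


class TestFisherExact:
    def test_diagonal_two_by_two(self):
        _, p = fisher_exact([[2, 0], [0, 2]])
        assert p == pytest.approx(1 / 3)

    def test_balanced_table_p_one(self):
        _, p = fisher_exact([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(200):
            t = rng.integers(0, 11, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            _, p = fisher_exact(t)
            assert p == pytest.approx(fisher_enumeration(t), abs=1e-9)

    def test_invariant_to_label_swap(self, rng):
        t = np.array([[7, 2], [3, 9]])
        assert fisher_exact(t)[1] == pytest.approx(fisher_exact(t.T)[1])
        assert fisher_exact(t)[1] == pytest.approx(fisher_exact(t[::-1, ::-1])[1])

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact([[0, 0], [3, 4]])


class TestFreemanHalton:
    def test_reduces_to_null_for_balanced_table(self):
        assert freeman_halton_2x3([[5, 5, 5], [5, 5, 5]]) == pytest.approx(1.0)

    def test_matches_scipy_pmf_enumeration(self, rng):
        from scipy.stats import multivariate_hypergeom

        for _ in range(30):
            t = rng.integers(0, 8, size=(2, 3))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            cols = t.sum(axis=0)
            r1 = int(t[0].sum())
            p_obs = multivariate_hypergeom.pmf(t[0], cols, r1)
            total = 0.0
            for x0 in range(min(r1, cols[0]) + 1):
                for x1 in range(min(r1 - x0, cols[1]) + 1):
                    x2 = r1 - x0 - x1
                    if 0 <= x2 <= cols[2]:
                        pr = multivariate_hypergeom.pmf([x0, x1, x2], cols, r1)
                        if pr <= p_obs * (1 + 1e-9):
                            total += pr
            assert freeman_halton_2x3(t) == pytest.approx(min(total, 1.0), abs=1e-9)

    def test_large_table_falls_back_to_chisquare(self, rng):
        t = rng.integers(30, 60, size=(2, 3))
        from scipy import stats

        with pytest.warns(UserWarning, match="chi-square"):
            p = freeman_halton_2x3(t, exact_max_total=100)
        assert p == pytest.approx(stats.chi2_contingency(t, correction=False)[1])


class TestResponseRates:
    def test_orr_scheme_counts_cr_pr_as_responders(self):
        df = pd.DataFrame(
            {
                "time": [1.0] * 6,
                "event": [1] * 6,
                "response": ["CR", "PR", "SD", "PD", "NA", "PR"],
            },
            index=[f"p{i}" for i in range(6)],
        )
        cohort = ClinicalCohort(df)
        lab = pd.Series([True, True, True, False, False, False], index=df.index)
        table, summary = response_rates(cohort, lab, "ORR")
        assert table.counts.tolist() == [[2, 1], [1, 1]]
        assert summary["rate_pos"] == Fraction(2, 3)
        assert summary["n_excluded_na"] == 1

    def test_exact_fraction_rates_match_reconstructed_inova_shape(self):
        # 25 comut+ with 22 responders -> ORR 88.0%
        df = pd.DataFrame(
            {
                "time": [1.0] * 47,
                "event": [1] * 47,
                "response": ["PR"] * 22 + ["PD"] * 3 + ["PR"] * 13 + ["PD"] * 9,
            },
            index=[f"p{i}" for i in range(47)],
        )
        lab = pd.Series([True] * 25 + [False] * 22, index=df.index)
        table, summary = response_rates(ClinicalCohort(df), lab, "ORR")
        assert summary["rate_pos"] == Fraction(22, 25)
        assert float(summary["rate_pos"]) * 100 == pytest.approx(88.0)

    def test_all_na_rejected(self):
        df = pd.DataFrame(
            {"time": [1.0, 1.0], "event": [1, 1], "response": ["NA", "NA"]},
            index=["a", "b"],
        )
        lab = pd.Series([True, False], index=df.index)
        with pytest.raises(ValueError):
            response_rates(ClinicalCohort(df), lab, "ORR")

    def test_null_fisher_p_roughly_uniform(self):
        from scipy import stats

        pvals = []
        for rep in range(150):
            r = np.random.default_rng(900 + rep)
            cohort, lab = make_cohort(r, n=120, with_msi=False)
            _, summary = response_rates(cohort, lab, "ORR")
            pvals.append(summary["p_value"])
        # discrete p-values are conservative: check uniform-or-super-uniform
        assert stats.kstest(pvals, "uniform", alternative="greater").pvalue > 0.01
        assert np.mean(np.array(pvals) < 0.05) <= 0.07


class TestConfusion:
    def test_perfect_and_inverted_prediction(self, rng):
        ref = np.array([True] * 5 + [False] * 10)
        cs, _ = confusion_vs_reference(ref, ref)
        assert cs.sensitivity == 1 and cs.specificity == 1
        cs2, _ = confusion_vs_reference(~ref, ref)
        assert cs2.sensitivity == 0 and cs2.specificity == 0

    def test_random_predictions_track_prediction_prevalence(self, rng):
        n = 1000
        ref = np.tile([True, False], n // 2)
        pred = rng.random(n) < 0.4
        cs, _ = confusion_vs_reference(pred, ref)
        assert float(cs.sensitivity) == pytest.approx(0.4, abs=0.06)
        assert float(cs.specificity) == pytest.approx(0.6, abs=0.06)

    def test_fractions_recoverable_from_stored_counts(self, rng):
        pred = rng.random(50) < 0.5
        ref = rng.random(50) < 0.5
        if ref.all() or not ref.any():
            ref[0], ref[1] = True, False
        cs, _ = confusion_vs_reference(pred, ref)
        assert cs.sensitivity == Fraction(cs.tp, cs.tp + cs.fn)
        assert cs.table().sum() == 50

    def test_single_class_reference_rejected(self):
        with pytest.raises(ValueError):
            confusion_vs_reference([True, False], [True, True])


class TestStratifyTwoBiomarkers:
    def test_identical_biomarkers_yield_two_strata(self, rng):
        cohort, lab = make_cohort(rng)
        with pytest.warns(UserWarning, match="single-positive"):
            res = stratify_two_biomarkers(cohort, lab, lab.astype(float), b2_cutoff=0.5)
        assert res.dropped_strata == ["single-positive"]
        assert set(res.km) == {"dual-positive", "dual-negative"}

    def test_pdl1_exactly_at_cutoff_is_high(self, rng):
        cohort, lab = make_cohort(rng, n=60)
        pdl1 = cohort.data["pdl1"].copy()
        pdl1.iloc[0] = 50.0
        lab.iloc[0] = True
        res = stratify_two_biomarkers(cohort, lab, pdl1, b2_cutoff=50.0)
        assert res.strata.iloc[0] == "dual-positive"

    def test_partition_exhaustive_and_exclusive(self, rng):
        cohort, lab = make_cohort(rng)
        res = stratify_two_biomarkers(cohort, lab, cohort.data["pdl1"], 50.0, scheme="ORR")
        assert res.strata.notna().all()
        assert res.response_table.counts.sum() <= len(cohort)

    def test_planted_ordered_hazards_detected(self):
        detected = 0
        reps = 10
        for rep in range(reps):
            r = np.random.default_rng(40 + rep)
            n = 600
            b1 = r.random(n) < 0.5
            b2 = r.random(n) < 0.5
            rate = np.where(b1 & b2, 0.02, np.where(b1 | b2, 0.04, 0.08))
            t = r.exponential(1 / rate).round(4)
            df = pd.DataFrame(
                {"time": t, "event": np.ones(n, int)},
                index=[f"p{i}" for i in range(n)],
            )
            res = stratify_two_biomarkers(
                ClinicalCohort(df),
                pd.Series(b1, index=df.index),
                pd.Series(b2.astype(float), index=df.index),
                b2_cutoff=0.5,
            )
            if res.logrank_p < 0.01:
                detected += 1
        assert detected >= 9


class TestCompareBiomarkers:
    def test_biomarker_equal_to_response_has_auroc_one(self, rng):
        cohort, _ = make_cohort(rng)
        responder = cohort.data["response"].isin(["CR", "PR"])
        perf = compare_biomarkers(cohort, {"oracle": responder.astype(float)})
        assert perf.loc["oracle", "auroc"] == pytest.approx(1.0)

    def test_binary_auroc_equals_sens_spec_identity(self, rng):
        cohort, lab = make_cohort(rng)
        responder = cohort.data["response"].isin(["CR", "PR"])
        evaluable = cohort.data["response"].isin(["CR", "PR", "SD", "PD"])
        sens = (lab & responder & evaluable).sum() / (responder & evaluable).sum()
        spec = (~lab & ~responder & evaluable).sum() / (~responder & evaluable).sum()
        perf = compare_biomarkers(cohort, {"comut": lab.astype(float)})
        assert perf.loc["comut", "auroc"] == pytest.approx((sens + spec) / 2)

    def test_tmb_shift_in_responders_gives_normal_shift_auc(self):
        # one SD shift -> AUC = Phi(1/sqrt(2)) ~ 0.76
        aucs = []
        for rep in range(5):
            r = np.random.default_rng(60 + rep)
            n = 500
            responder = r.random(n) < 0.5
            tmb = r.normal(0, 1, n) + responder
            df = pd.DataFrame(
                {
                    "time": r.exponential(10, n),
                    "event": np.ones(n, int),
                    "response": np.where(responder, "PR", "PD"),
                    "tmb": tmb,
                },
                index=[f"p{i}" for i in range(n)],
            )
            perf = compare_biomarkers(ClinicalCohort(df), {"tmb": df["tmb"]})
            aucs.append(perf.loc["tmb", "auroc"])
        assert 0.70 <= np.mean(aucs) <= 0.82

    def test_constant_biomarker_skipped(self, rng):
        cohort, lab = make_cohort(rng)
        with pytest.warns(UserWarning, match="constant"):
            perf = compare_biomarkers(
                cohort, {"flat": pd.Series(1.0, index=cohort.ids), "comut": lab}
            )
        assert list(perf.index) == ["comut"]
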