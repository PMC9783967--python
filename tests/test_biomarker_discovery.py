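import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from comutpath.biomarker_discovery import (
    fit_multiple_regression,
    quartile_split,
    run_discovery_chain,
    select_pathway_pair,
    wilcoxon_rank_sum,
    youden_threshold,
)


# --- independent oracles ------------------------------------------------------


def youden_brute_force(score, labels):
    """Best J over every candidate threshold, by direct enumeration."""
    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    best = -np.inf
    for t in np.unique(score):
        sens = (score[labels] >= t).mean()
        spec = (score[~labels] < t).mean()
        best = max(best, sens + spec - 1)
    return best


def wilcoxon_enumeration(x, y):
    """Exact two-sided rank-sum p by full arrangement enumeration."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    m = len(x)
    obs = sum(pooled.index(v) + 1 for v in x)  # rank sum of x (no ties assumed)
    n_total = 0
    n_extreme = 0
    mean_w = m * (len(pooled) + 1) / 2
    for combo in itertools.combinations(range(len(pooled)), m):
        w = sum(i + 1 for i in combo)
        n_total += 1
        if abs(w - mean_w) >= abs(obs - mean_w) - 1e-12:
            n_extreme += 1
    return n_extreme / n_total


# --- quartile split -----------------------------------------------------------


class TestQuartileSplit:
    def test_top_quarter_of_one_to_eight(self):
        q = quartile_split(range(1, 9))
        assert q.labels.tolist() == [False] * 6 + [True, True]

    def test_ties_at_cutoff_go_high(self):
        q = quartile_split([5, 5, 5, 9])
        # cutoff = 6.0 by linear interpolation; only 9 is at/above it
        assert q.cutoff == pytest.approx(6.0)
        assert q.labels.tolist() == [False, False, False, True]

    def test_fewer_than_four_values_rejected(self):
        with pytest.raises(ValueError):
            quartile_split([1, 2, 3])

    def test_degenerate_constant_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            quartile_split([2, 2, 2, 2])

    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=4, max_size=60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_high_group_is_exactly_values_at_or_above_cutoff(self, values):
        if len(set(values)) == 1:
            return
        q = quartile_split(values)
        assert q.labels.tolist() == [v >= q.cutoff for v in values]


# --- Youden threshold ---------------------------------------------------------


class TestYoudenThreshold:
    def test_perfect_separation(self):
        roc = youden_threshold([0, 1, 2, 3], [False, False, True, True])
        assert roc.best_threshold == 2
        assert roc.best_sensitivity == 1.0 and roc.best_specificity == 1.0
        assert roc.youden == pytest.approx(1.0)

    def test_independent_labels_auc_near_half(self, rng):
        score = rng.integers(0, 6, 1000)
        labels = rng.random(1000) < 0.25
        roc = youden_threshold(score, labels)
        assert 0.45 <= roc.auc <= 0.55

    def test_best_j_equals_brute_force_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 51))
            score = rng.integers(0, 8, n)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            roc = youden_threshold(score, labels)
            assert roc.youden == pytest.approx(youden_brute_force(score, labels))

    def test_tie_on_j_breaks_to_smaller_threshold(self):
        # thresholds 1 and 2 both give J = 0.5 here; smaller must win
        score = np.array([0, 1, 2, 3])
        labels = np.array([False, True, False, True])
        roc = youden_threshold(score, labels)
        js = roc.sensitivity + roc.specificity - 1
        ties = roc.thresholds[js == js.max()]
        assert roc.best_threshold == ties.min()

    def test_invariant_to_monotone_score_transform(self, rng):
        score = rng.integers(0, 10, 200)
        labels = rng.random(200) < 0.3
        if not labels.any() or labels.all():
            labels[:5], labels[5:] = True, False
        base = youden_threshold(score, labels)
        trans = youden_threshold(3 * score + 7, labels)
        assert trans.youden == pytest.approx(base.youden)
        assert trans.best_threshold == 3 * base.best_threshold + 7

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold([1, 2], [True, True])


# --- multiple regression ------------------------------------------------------


class TestMultipleRegression:
    def test_noiseless_response_recovers_exact_beta(self):
        status = pd.DataFrame(
            {"P": [0, 1, 0, 1, 1, 0, 1, 0], "Q": [1, 1, 0, 0, 1, 0, 0, 1]}
        )
        y = 2.0 * status["P"]
        res = fit_multiple_regression(y, status)
        assert res.beta("P") == pytest.approx(2.0, abs=1e-10)
        assert res.beta("Q") == pytest.approx(0.0, abs=1e-10)

    def test_simulation_recovery_orthogonal_design(self, rng):
        n = 5000
        p1 = np.tile([0, 1], n // 2)
        p2 = np.repeat([0, 1], n // 2)  # orthogonal to p1
        y = 3 * p1 + 1 * p2 + rng.normal(0, 0.1, n)
        res = fit_multiple_regression(y, pd.DataFrame({"P1": p1, "P2": p2}))
        assert res.beta("P1") == pytest.approx(3, abs=0.05)
        assert res.beta("P2") == pytest.approx(1, abs=0.05)

    def test_orthogonal_beta_equals_simple_slopes(self, rng):
        n = 400
        p1 = np.tile([0, 1], n // 2)
        p2 = np.repeat([0, 1], n // 2)
        y = rng.normal(size=n) + p1
        multi = fit_multiple_regression(y, pd.DataFrame({"P1": p1, "P2": p2}))
        simple1 = fit_multiple_regression(y, pd.DataFrame({"P1": p1}))
        assert multi.beta("P1") == pytest.approx(simple1.beta("P1"), abs=1e-8)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_multiple_regression(
                [1.0, 2, 3, 4, 5], pd.DataFrame({"P": [1, 1, 1, 1, 1]})
            )

    def test_collinear_design_names_columns(self):
        p = np.array([0, 1, 0, 1, 1, 0, 0, 1])
        with pytest.raises(ValueError, match="collinear"):
            fit_multiple_regression(
                np.arange(8.0), pd.DataFrame({"A": p, "B": p})
            )


# --- Wilcoxon rank-sum --------------------------------------------------------


class TestWilcoxon:
    def test_exact_p_on_fully_separated_triples(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            x = rng.permutation(100)[:4].astype(float)
            y = rng.permutation(100)[50:56].astype(float)
            if set(x) & set(y):
                continue
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(wilcoxon_enumeration(x, y), abs=1e-9)

    def test_normal_approx_close_to_exact_at_n10(self, rng):
        for _ in range(5):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            _, p_exact = wilcoxon_rank_sum(x, y)  # m+n = 20 -> exact
            from scipy import stats

            p_approx = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert abs(p_exact - p_approx) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


# --- pair selection -----------------------------------------------------------


class TestSelectPathwayPair:
    def test_two_candidates_select_trivially(self, sim_profile):
        _, profile, tmb = sim_profile
        sel = select_pathway_pair(["PW01", "PW02"], profile, tmb.tmb, tmb.tmb)
        assert sel.selected == ("PW01", "PW02")

    def test_planted_pair_beats_null_competitors(self, sim_profile):
        _, profile, tmb = sim_profile
        sel = select_pathway_pair(
            ["PW01", "PW02", "PW03", "PW04"], profile, tmb.tmb, tmb.tmb
        )
        assert sel.selected == ("PW01", "PW02")

    def test_single_candidate_rejected(self, sim_profile):
        _, profile, tmb = sim_profile
        with pytest.raises(ValueError):
            select_pathway_pair(["PW01"], profile, tmb.tmb, tmb.tmb)

    def test_null_selection_close_to_uniform_over_pairs(self, rng):
        # no pathway affects the response: selection frequencies over the
        # 3 possible pairs should not reject uniformity (chi-square at 0.01)
        from comutpath.mutation_pathway import PathwayMutationProfile
        from scipy import stats

        counts = {}
        for rep in range(60):
            r = np.random.default_rng(1000 + rep)
            status = pd.DataFrame(
                r.integers(0, 2, size=(3, 80)),
                index=["A", "B", "C"],
                columns=[f"s{i}" for i in range(80)],
            )
            prof = PathwayMutationProfile(status=status, pathway_freq=status.mean(axis=1))
            resp = pd.Series(r.normal(size=80), index=status.columns)
            sel = select_pathway_pair(["A", "B", "C"], prof, resp, resp)
            counts[sel.selected] = counts.get(sel.selected, 0) + 1
        observed = [counts.get(p, 0) for p in [("A", "B"), ("A", "C"), ("B", "C")]]
        assert stats.chisquare(observed).pvalue > 0.01


def test_discovery_chain_recovers_planted_pair(sim_cohort, sim_profile):
    _, profile, tmb = sim_profile
    screen, reg_tmb, reg_nal, candidates, selection = run_discovery_chain(
        profile, sim_cohort.clinical, tmb.tmb, sim_cohort.clinical.data["nal"]
    )
    assert {"PW01", "PW02"} <= set(screen.retained)
    assert selection is not None and selection.selected == ("PW01", "PW02")
    assert reg_tmb.beta("PW01") > 0 and reg_nal.beta("PW02") > 0
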