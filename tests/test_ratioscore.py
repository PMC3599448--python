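import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gxratio as gx
from gxratio.ratioscore import greedy_cover
from conftest import random_expression


class TestSeparationCount:
    def test_direct_count(self):
        assert gx.separation_count([2.5, 3.5, 4.0], [1.0, 2.0, 3.0]) == 2

    def test_cases_inside_control_range(self):
        assert gx.separation_count([1.5, 2.0], [1.0, 2.5]) == 0

    def test_empty_control_errors(self):
        with pytest.raises(ValueError, match="control"):
            gx.separation_count([1.0], [])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        cases = rng.uniform(0.1, 5.0, 10)
        controls = rng.uniform(0.1, 5.0, 10)
        brute = sum(1 for c in cases if all(c > k for k in controls))
        assert gx.separation_count(cases, controls) == brute


def exhaustive_top_pairs(expr, case_label, control_label, top_k):
    """Independent plain-loop enumeration of top separating ordered pairs."""
    cases = expr.subjects_in(case_label)
    controls = expr.subjects_in(control_label)
    scored = []
    for num, den in itertools.permutations(expr.probe_ids, 2):
        case_vals = [gx.ratio_value(expr, num, den, s) for s in cases]
        ctrl_vals = [gx.ratio_value(expr, num, den, s) for s in controls]
        count = sum(v > max(ctrl_vals) for v in case_vals)
        if count > 0:
            scored.append((count, num, den))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    return scored[:top_k]


class TestSearchCandidates:
    def test_seed_required(self, tiny_expr):
        with pytest.raises(ValueError, match="seed"):
            gx.search_candidates(tiny_expr, "CD", "CTRL")

    def test_groups_too_small(self, tiny_expr):
        with pytest.raises(ValueError, match="too small"):
            gx.search_candidates(tiny_expr, "CD", "CTRL", seed=0)

    def test_planted_strong_ratio_has_frequency_one(self):
        effects = (gx.EffectSpec("PGK1", "up", 8.0, 1.0),
                   gx.EffectSpec("POU6F1", "down", 8.0, 1.0))
        config = gx.SyntheticConfig(
            cohorts=(gx.CohortSpec("CTRL", 30), gx.CohortSpec("CD", 30, effects)),
            seed=5)
        expr = gx.ct_to_relative(gx.generate_cohorts(config))
        # both probes are planted, so ~90 ratios separate perfectly; top_k must
        # be wide enough to keep the whole tie group
        candidates = gx.search_candidates(expr, "CD", "CTRL", reps=20, top_k=200, seed=5)
        by_name = {c.ratio.name: c for c in candidates}
        assert by_name["PGK1/POU6F1"].selection_frequency == 1.0
        assert by_name["PGK1/POU6F1"].separation_count == 30

    def test_full_fraction_resampling_matches_enumeration_oracle(self):
        # resample_frac=1 makes every rep the full data, so the search reduces
        # to one exhaustive ranking that plain loops can reproduce.
        rng = np.random.default_rng(8)
        groups = {f"S{i}": ("CD" if i < 6 else "CTRL") for i in range(12)}
        expr = random_expression(rng, 12, ["A", "B", "C", "D", "E"], groups)
        candidates = gx.search_candidates(expr, "CD", "CTRL", resample_frac=1.0,
                                          reps=3, top_k=4, seed=0)
        expected = exhaustive_top_pairs(expr, "CD", "CTRL", top_k=4)
        got = [(c.separation_count, c.ratio.numerator_probe,
                c.ratio.denominator_probe) for c in candidates]
        assert got == expected
        assert all(c.selection_frequency == 1.0 for c in candidates)

    def test_full_data_separation_counts_match_brute_force(self):
        rng = np.random.default_rng(21)
        groups = {f"S{i}": ("CD" if i < 8 else "CTRL") for i in range(20)}
        expr = random_expression(rng, 20, ["A", "B", "C", "D"], groups)
        candidates = gx.search_candidates(expr, "CD", "CTRL", reps=10, top_k=6, seed=3)
        for cand in candidates:
            case_vals = [gx.ratio_value(expr, cand.ratio.numerator_probe,
                                        cand.ratio.denominator_probe, s)
                         for s in expr.subjects_in("CD")]
            ctrl_vals = [gx.ratio_value(expr, cand.ratio.numerator_probe,
                                        cand.ratio.denominator_probe, s)
                         for s in expr.subjects_in("CTRL")]
            assert cand.separation_count == sum(v > max(ctrl_vals) for v in case_vals)

    def test_deterministic_given_seed(self, paperlike_expr):
        keep = [s for s in paperlike_expr.subject_ids
                if paperlike_expr.groups[s] in ("CD", "CTRL")]
        sub = paperlike_expr.subset(keep)
        a = gx.search_candidates(sub, "CD", "CTRL", reps=10, top_k=30, seed=4)
        b = gx.search_candidates(sub, "CD", "CTRL", reps=10, top_k=30, seed=4)
        assert a == b

    def test_zero_effect_frequencies_look_like_permutation_null(self):
        # no planted signal: the top full-data separation count should sit in
        # the range produced by label permutations of the same data.
        config = gx.SyntheticConfig(
            cohorts=(gx.CohortSpec("CTRL", 30), gx.CohortSpec("CD", 30)), seed=9)
        expr = gx.ct_to_relative(gx.generate_cohorts(config))
        observed = gx.search_candidates(expr, "CD", "CTRL", reps=10, top_k=30,
                                        seed=9)[0].separation_count
        perm_tops = []
        for k in range(8):
            expr.groups = gx.permute_labels(expr.groups, 100 + k)
            perm_tops.append(gx.search_candidates(expr, "CD", "CTRL", reps=10,
                                                  top_k=30, seed=9)[0].separation_count)
        assert observed <= max(perm_tops) + 2


def panel_from_sets(sets, n_cases=None):
    """Build an expression matrix + candidates realising given coverage sets.

    Cases covered by candidate i get ratio value 4 on ratio Ni/Di, everyone
    else 1; control subjects sit at 1, so the control max is 1.
    """
    if n_cases is None:
        n_cases = max((max(s) for s in sets if s), default=-1) + 1
    probes = []
    for i in range(len(sets)):
        probes += [f"N{i}", f"D{i}"]
    subjects = [f"CASE{j}" for j in range(n_cases)] + ["CTRL0", "CTRL1"]
    levels = np.ones((len(subjects), len(probes)))
    for i, covered in enumerate(sets):
        for j in covered:
            levels[j, 2 * i] = 4.0
    groups = {s: ("CD" if s.startswith("CASE") else "CTRL") for s in subjects}
    expr = gx.ExpressionMatrix(subject_ids=subjects, probe_ids=probes,
                               levels=levels, groups=groups)
    candidates = [
        gx.RatioCandidate(gx.GeneRatio(f"N{i}", f"D{i}"), len(s), 1.0)
        for i, s in enumerate(sets)
    ]
    return expr, candidates


def exhaustive_best_coverage(sets):
    """Oracle: maximum coverage attainable by any subset of the sets."""
    best = 0
    for r in range(len(sets) + 1):
        for combo in itertools.combinations(sets, r):
            covered = set().union(*combo) if combo else set()
            best = max(best, len(covered))
    return best


class TestSelectPanel:
    def test_set_cover_example(self):
        sets = [frozenset({0, 1}), frozenset({1, 2}), frozenset({0})]
        expr, candidates = panel_from_sets(sets)
        panel = gx.select_panel(candidates, expr, "CD", "CTRL")
        assert len(panel) == 2
        assert panel.ratio_names == ["N0/D0", "N1/D1"]
        results = gx.score_subjects(panel, expr, expr.subjects_in("CD"))
        assert gx.coverage(results) == 1.0

    def test_single_covering_ratio_gives_singleton_panel(self):
        sets = [frozenset({0, 1, 2}), frozenset({0}), frozenset({1})]
        expr, candidates = panel_from_sets(sets)
        panel = gx.select_panel(candidates, expr, "CD", "CTRL")
        assert len(panel) == 1 and panel.ratio_names == ["N0/D0"]

    def test_greedy_dominates_single_best(self, cd_ctrl_panelled):
        panel, sub = cd_ctrl_panelled
        case_subjects = sub.subjects_in("CD")
        full_cov = gx.coverage(gx.score_subjects(panel, sub, case_subjects))
        for k in range(len(panel)):
            single = gx.RatioPanel(ratios=[panel.ratios[k]],
                                   thresholds=[panel.thresholds[k]],
                                   case_label="CD", control_label="CTRL")
            single_cov = gx.coverage(gx.score_subjects(single, sub, case_subjects))
            assert full_cov >= single_cov

    def test_no_candidates_errors(self, tiny_expr):
        with pytest.raises(ValueError, match="no candidates"):
            gx.select_panel([], tiny_expr, "CD", "CTRL")

    def test_no_coverage_returns_empty_panel(self):
        sets = [frozenset(), frozenset()]
        expr, candidates = panel_from_sets(sets, n_cases=2)
        panel = gx.select_panel(candidates, expr, "CD", "CTRL")
        assert len(panel) == 0

    @settings(max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_greedy_coverage_equals_exhaustive_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_sets = int(rng.integers(1, 7))
        n_cases = int(rng.integers(1, 11))
        sets = [frozenset(int(j) for j in np.where(rng.random(n_cases) < 0.35)[0])
                for _ in range(n_sets)]
        chosen = greedy_cover(sets)
        greedy_covered = len(set().union(*[sets[i] for i in chosen])) if chosen else 0
        assert greedy_covered == exhaustive_best_coverage(sets)


class TestScoreSubjects:
    def test_worked_six_tuple(self):
        # Printed worked example: indicator 6-tuple {1,1,0,0,1,0} -> score 3.
        probes = [p for i in range(6) for p in (f"N{i}", f"D{i}")]
        indicators = (1, 1, 0, 0, 1, 0)
        case_levels = np.ones(12)
        for i, flag in enumerate(indicators):
            case_levels[2 * i] = 4.0 if flag else 0.5
        levels = np.vstack([np.ones(12), np.ones(12), case_levels])
        expr = gx.ExpressionMatrix(
            subject_ids=["CTRL0", "CTRL1", "CASE0"], probe_ids=probes,
            levels=levels,
            groups={"CTRL0": "CTRL", "CTRL1": "CTRL", "CASE0": "CD"})
        panel = gx.RatioPanel(
            ratios=[gx.GeneRatio(f"N{i}", f"D{i}") for i in range(6)],
            thresholds=[1.0] * 6, case_label="CD", control_label="CTRL")
        result = gx.score_subjects(panel, expr, ["CASE0"])[0]
        assert result.indicator_tuple == indicators
        assert result.ratioscore == 3
        assert result.call == "positive"

    def test_training_controls_all_score_zero(self, cd_ctrl_panelled):
        panel, sub = cd_ctrl_panelled
        results = gx.score_subjects(panel, sub, sub.subjects_in("CTRL"))
        assert all(r.ratioscore == 0 for r in results)
        assert all(r.call == "negative" for r in results)

    def test_all_below_threshold_negative(self):
        expr = gx.ExpressionMatrix(
            subject_ids=["S0"], probe_ids=["A", "B"],
            levels=np.array([[1.0, 2.0]]), groups={"S0": "CD"})
        panel = gx.RatioPanel(ratios=[gx.GeneRatio("A", "B")], thresholds=[5.0],
                              case_label="CD", control_label="CTRL")
        result = gx.score_subjects(panel, expr)[0]
        assert result.indicator_tuple == (0,)
        assert result.ratioscore == 0 and result.call == "negative"

    def test_missing_probe_errors_with_name(self, tiny_expr):
        panel = gx.RatioPanel(ratios=[gx.GeneRatio("A", "ZZZ")], thresholds=[1.0],
                              case_label="CD", control_label="CTRL")
        with pytest.raises(KeyError, match="ZZZ"):
            gx.score_subjects(panel, tiny_expr)

    def test_ratioscore_equals_indicator_sum(self, cd_ctrl_panelled):
        panel, sub = cd_ctrl_panelled
        for r in gx.score_subjects(panel, sub):
            assert r.ratioscore == sum(r.indicator_tuple)
            assert (r.call == "positive") == (r.ratioscore >= 1)


class TestCoverage:
    def make(self, scores):
        return [gx.ScoreResult(f"S{i}", (1,) if s else (0,), s,
                               "positive" if s else "negative")
                for i, s in enumerate(scores)]

    def test_all_positive(self):
        assert gx.coverage(self.make([1] * 5)) == 1.0

    def test_none_positive(self):
        assert gx.coverage(self.make([0] * 5)) == 0.0

    def test_forty_seven_of_fifty(self):
        assert gx.coverage(self.make([1] * 47 + [0] * 3)) == pytest.approx(0.94)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gx.coverage([])


class TestInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_training_specificity_is_one_for_any_data(self, seed):
        # Holds for pure-noise data too: thresholds are training-control
        # maxima with strict exceedance.
        config = gx.SyntheticConfig(
            cohorts=(gx.CohortSpec("CTRL", 20), gx.CohortSpec("CD", 20)), seed=seed)
        expr = gx.ct_to_relative(gx.generate_cohorts(config))
        cands = gx.search_candidates(expr, "CD", "CTRL", reps=5, top_k=20, seed=seed)
        if not cands:
            return
        panel = gx.select_panel(cands[:50], expr, "CD", "CTRL")
        ctrl_results = gx.score_subjects(panel, expr, expr.subjects_in("CTRL"))
        assert all(r.ratioscore == 0 for r in ctrl_results)

    def test_threshold_monotone_in_control_group(self):
        # Adding control subjects can only raise thresholds, hence shrink (or
        # keep) each ratio's case exceedance set.
        rng = np.random.default_rng(33)
        groups = {f"S{i}": ("CD" if i < 10 else "CTRL") for i in range(30)}
        expr = random_expression(rng, 30, ["A", "B", "C"], groups)
        ratio = gx.GeneRatio("A", "B")
        vals = gx.ratio_values(expr, ratio)
        ctrl_rows = [i for i, s in enumerate(expr.subject_ids)
                     if expr.groups[s] == "CTRL"]
        case_rows = [i for i, s in enumerate(expr.subject_ids)
                     if expr.groups[s] == "CD"]
        small = vals[ctrl_rows[:8]].max()
        large = vals[ctrl_rows].max()
        exceed_small = {i for i in case_rows if vals[i] > small}
        exceed_large = {i for i in case_rows if vals[i] > large}
        assert exceed_large <= exceed_small

    def test_parameter_recovery_panel_uses_planted_probes(self):
        planted = {"PGK1", "ANAPC1", "ASL"}
        effects = (gx.EffectSpec("PGK1", "up", 8.0, 1.0),
                   gx.EffectSpec("ANAPC1", "down", 8.0, 1.0),
                   gx.EffectSpec("ASL", "down", 8.0, 1.0))
        config = gx.SyntheticConfig(
            cohorts=(gx.CohortSpec("CTRL", 40), gx.CohortSpec("CD", 40, effects)),
            seed=13)
        expr = gx.ct_to_relative(gx.generate_cohorts(config))
        cands = gx.search_candidates(expr, "CD", "CTRL", reps=20, top_k=50, seed=13)
        panel = gx.select_panel(cands[:50], expr, "CD", "CTRL")
        assert len(panel) >= 1
        for ratio in panel.ratios:
            assert planted & {ratio.numerator_probe, ratio.denominator_probe}


def test_panel_json_round_trip(cd_ctrl_panelled, tmp_path):
    panel, _ = cd_ctrl_panelled
    back = gx.RatioPanel.from_json(panel.to_json())
    assert back.ratios == panel.ratios
    assert back.thresholds == pytest.approx(panel.thresholds)
    assert (back.case_label, back.control_label) == ("CD", "CTRL")


def test_gene_ratio_rejects_self_ratio():
    with pytest.raises(ValueError, match="self-ratio"):
        gx.GeneRatio("A", "A")


def test_scores_frame_layout(cd_ctrl_panelled):
    panel, sub = cd_ctrl_panelled
    frame = gx.ratioscore.scores_frame(gx.score_subjects(panel, sub))
    assert list(frame.columns) == ["subject_id", "indicator_tuple", "ratioscore", "call"]
    assert len(frame) == sub.n_subjects
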