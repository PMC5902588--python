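"""Category transformations, EDGE formulas, rankings and summaries."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from edgetree.scoring import (
    GE_INDEX,
    ISAAC,
    IUCN50,
    IUCNCategory,
    TransformationScheme,
    build_score_table,
    edge_score,
    effective_category,
    extinction_probability,
    rank_competition,
    round_half_up,
    scheme_from_config,
    summarize_assessments,
    summarize_coverage,
    threatened_ed_ranking,
)


class TestCategories:
    @pytest.mark.parametrize(
        "raw,expected",
        [("DD", "CR"), ("NE", "CR"), ("EW", "CR"), ("LC", "LC"), ("EN", "EN")],
    )
    def test_effective_category(self, raw, expected):
        assert effective_category(raw) is IUCNCategory(expected)

    @pytest.mark.parametrize(
        "cat,scheme,p",
        [
            ("EN", IUCN50, 0.42),
            ("LC", ISAAC, 0.025),
            ("CR", IUCN50, 0.97),
            ("NT", IUCN50, 0.004),
        ],
    )
    def test_extinction_probability(self, cat, scheme, p):
        assert extinction_probability(cat, scheme) == p

    def test_unconverted_dd_rejected(self):
        with pytest.raises(KeyError):
            extinction_probability("DD", IUCN50)

    def test_scheme_must_be_monotone(self):
        with pytest.raises(ValueError):
            TransformationScheme(
                name="bad",
                p_ext={
                    IUCNCategory.LC: 0.5,
                    IUCNCategory.NT: 0.1,
                    IUCNCategory.VU: 0.2,
                    IUCNCategory.EN: 0.3,
                    IUCNCategory.CR: 0.4,
                },
            )

    def test_scheme_from_config_round_trip(self):
        spec = {
            "name": "CUSTOM",
            "p_ext": {"LC": 0.01, "NT": 0.02, "VU": 0.1, "EN": 0.3, "CR": 0.6},
        }
        scheme = scheme_from_config(spec)
        assert extinction_probability("VU", scheme) == 0.1
        assert scheme.formula == "probability"


class TestEdgeScore:
    def test_ginkgo_worked_example(self):
        # ED 315.00, EN under the 50-year probabilities: ln(1 + 132.30)
        score = edge_score(315.00, "EN", IUCN50)
        assert round(score, 2) == 4.89

    def test_zero_ed_zero_score(self):
        assert edge_score(0.0, "CR", IUCN50) == 0.0

    def test_isaac_closed_form(self):
        assert edge_score(1.5, "LC", ISAAC) == pytest.approx(math.log(2.5))
        assert edge_score(1.5, "EN", ISAAC) == pytest.approx(
            math.log(2.5) + 3 * math.log(2)
        )

    def test_isaac_ge_equals_probability_ratio(self):
        # ln(1+ED) + GE*ln2 == ln(1+ED) + ln(p/0.025) for the ISAAC table
        for cat, p in ISAAC.p_ext.items():
            assert GE_INDEX[cat] * math.log(2) == pytest.approx(
                math.log(p / 0.025), abs=1e-12
            )

    def test_monotone_in_ed_and_category(self):
        for scheme in (ISAAC, IUCN50):
            assert edge_score(10.0, "EN", scheme) < edge_score(11.0, "EN", scheme)
            order = ["LC", "NT", "VU", "EN", "CR"]
            scores = [edge_score(10.0, c, scheme) for c in order]
            assert scores == sorted(scores)
            assert len(set(scores)) == len(scores)

    def test_negative_ed_rejected(self):
        with pytest.raises(ValueError):
            edge_score(-1.0, "EN", IUCN50)


class TestRanking:
    def test_competition_pattern_1_2_2_4(self):
        ranks = rank_competition({"a": 5.0, "b": 3.0, "c": 3.0, "d": 1.0})
        assert ranks == {"a": 1, "b": 2, "c": 2, "d": 4}

    def test_distinct_scores_are_permutation(self):
        scores = {f"s{i}": float(i) for i in range(20)}
        ranks = rank_competition(scores)
        assert sorted(ranks.values()) == list(range(1, 21))

    def test_sister_species_share_rank(self):
        # same ED and category => same EDGE score => same rank
        eds = {"Sequoia": 47.81, "Sequoiadendron": 47.81, "Other": 100.0}
        cats = {"Sequoia": "EN", "Sequoiadendron": "EN", "Other": "LC"}
        table = build_score_table(eds, cats)
        by = table.set_index("species")
        assert (
            by.loc["Sequoia", "edge_iucn50_rank"]
            == by.loc["Sequoiadendron", "edge_iucn50_rank"]
        )

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_ranking_is_total_preorder_consistent_with_scores(self, values):
        scores = {f"s{i}": v for i, v in enumerate(values)}
        ranks = rank_competition(scores)
        assert min(ranks.values()) == 1
        for a in scores:
            for b in scores:
                if scores[a] > scores[b]:
                    assert ranks[a] < ranks[b]
                elif scores[a] == scores[b]:
                    assert ranks[a] == ranks[b]
        # each rank equals 1 + number of strictly better species
        for sp, r in ranks.items():
            better = sum(1 for v in values if v > scores[sp])
            assert r == better + 1

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.floats(min_value=0.0, max_value=1e4, allow_nan=False),
        st.floats(min_value=1e-6, max_value=1e2, allow_nan=False),
    )
    def test_edge_score_strictly_increasing_in_ed(self, ed, bump):
        for scheme in (ISAAC, IUCN50):
            for cat in ("LC", "NT", "VU", "EN", "CR"):
                assert edge_score(ed + bump, cat, scheme) > edge_score(
                    ed, cat, scheme
                )

    def test_rank_group_sizes_sum_to_n(self):
        scores = {"a": 1.0, "b": 1.0, "c": 0.5, "d": 0.5, "e": 0.1}
        ranks = rank_competition(scores)
        groups = pd.Series(list(ranks.values())).value_counts()
        assert groups.sum() == len(scores)
        # next distinct rank skips by tie-group size
        assert sorted(set(ranks.values())) == [1, 3, 5]


class TestThreatenedRanking:
    def test_filter_and_order(self):
        eds = {"a": 10.0, "b": 30.0, "c": 20.0, "d": 50.0}
        cats = {"a": "LC", "b": "VU", "c": "CR", "d": "NT"}
        table = build_score_table(eds, cats)
        ranked = threatened_ed_ranking(table)
        assert list(ranked["species"]) == ["b", "c"]
        assert list(ranked["threatened_ed_rank"]) == [1, 2]

    def test_dd_ne_ew_included(self):
        eds = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        cats = {"a": "DD", "b": "NE", "c": "EW", "d": "LC"}
        ranked = threatened_ed_ranking(build_score_table(eds, cats))
        assert set(ranked["species"]) == {"a", "b", "c"}

    def test_equal_ed_shares_rank(self):
        eds = {"x": 47.81, "y": 47.81, "z": 60.0}
        cats = {"x": "EN", "y": "EN", "z": "CR"}
        ranked = threatened_ed_ranking(build_score_table(eds, cats))
        by = ranked.set_index("species")["threatened_ed_rank"]
        assert by["x"] == by["y"] == 2 and by["z"] == 1

    def test_empty_subset(self):
        table = build_score_table({"a": 1.0}, {"a": "LC"})
        assert threatened_ed_ranking(table).empty


class TestSummaries:
    def test_gymnosperm_assessment_accounting(self):
        counts = {
            "VU": 156, "EN": 161, "CR": 80, "EW": 4,
            "NT": 167, "LC": 416, "DD": 20, "NE": 86,
        }
        records = [c for c, n in counts.items() for _ in range(n)]
        summary = summarize_assessments(records)
        assert summary.total == 1090
        assert summary.assessed == 1004
        assert summary.threatened == 401
        assert summary.non_threatened == 583
        assert summary.pct_threatened_of_assessed == 39.9
        assert summary.pct_assessed_of_total == 92.1

    def test_order_invariance(self):
        cats = ["LC", "CR", "NE", "VU", "VU", "DD"]
        a = summarize_assessments(cats)
        b = summarize_assessments(list(reversed(cats)))
        assert a == b

    def test_empty_input(self):
        summary = summarize_assessments([])
        assert summary.total == 0
        assert summary.pct_assessed_of_total is None
        assert summary.pct_threatened_of_assessed is None

    def test_coverage_accounting(self):
        class Rec:
            def __init__(self, sampled, cat):
                self.sampled = sampled
                self.iucn_category = cat

        records = (
            [Rec(1, "LC")] * 897          # sampled and assessed
            + [Rec(1, "NE")] * 26         # sampled, not evaluated
            + [Rec(0, "LC")] * 107        # unsampled, assessed
            + [Rec(0, "NE")] * 60         # unsampled, not evaluated
        )
        cov = summarize_coverage(records)
        assert cov.n_total == 1090
        assert cov.n_sampled == 923
        assert cov.n_missing == 167
        assert cov.pct_sampled_of_total == 84.7
        assert cov.n_assessed == 1004
        assert cov.n_sampled_assessed == 897
        assert cov.pct_sampled_of_assessed == 89.3

    def test_round_half_up(self):
        assert round_half_up(39.94, 1) == 39.9
        assert round_half_up(39.95, 1) == 40.0
        assert round_half_up(92.11, 1) == 92.1
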