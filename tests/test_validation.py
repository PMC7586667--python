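"""Toxicity/half-life parsing, group comparison, and HITD graph filtering."""

import numpy as np
import pandas as pd
import pytest

from herbsub.datasets import GROUP_MEANS, load_antidepressant_profiles
from herbsub.validation import (
    DrugProfile,
    InsufficientDataError,
    build_hitd_graph,
    common_targets,
    group_comparison,
    parse_numeric_range,
)


class TestParseNumericRange:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("2–4 h", 3.0),
            ("6–8 h", 7.0),
            ("20–40 h", 30.0),
            ("7.3 +/− 0.8 h.", 7.3),
            ("26 h", 26.0),
            ("12.5 h", 12.5),
            ("1–3 days", 48.0),
            ("5 to 7 hours", 6.0),
            ("2 days", 48.0),
            ("", None),
            ("rapidly eliminated", None),
        ],
    )
    def test_half_life(self, text, expected):
        assert parse_numeric_range(text, kind="half_life") == expected

    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Oral LD50 rat: 780 mg/kg", 780.0),
            ("Oral LD50 rat:179 mg/kg", 179.0),
            ("500–700 mg/kg", 600.0),
            ("Cases of life-threatening hepatic failure have been reported.", None),
            ("Fatalities have been reported with doses of 1000 mg", None),
        ],
    )
    def test_toxicity(self, text, expected):
        assert parse_numeric_range(text, kind="toxicity") == expected

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            parse_numeric_range("26 h", kind="dose")

    def test_narrative_profiles_excluded_from_toxicity(self):
        profiles = load_antidepressant_profiles()
        parseable = [p for p in profiles if p.ld50_mg_per_kg is not None]
        # only the six profiles with an explicit oral LD50 figure parse
        assert sorted(p.drug for p in parseable) == sorted(
            ["Milnacipran", "Mianserin", "Trazodone", "Nortriptyline", "Mirtazapine", "Citalopram"]
        )
        # every profile has a parseable half-life
        assert all(p.half_life_hours is not None for p in profiles)


class TestGroupComparison:
    def test_published_style_group_means_ratio(self):
        selected = [DrugProfile("s", f"{GROUP_MEANS['selected']['toxicity']} mg/kg",
                                f"{GROUP_MEANS['selected']['half_life']} h")]
        unselected = [DrugProfile("u", f"{GROUP_MEANS['unselected']['toxicity']} mg/kg",
                                  f"{GROUP_MEANS['unselected']['half_life']} h")]
        comparison = group_comparison(selected, unselected)
        assert comparison.toxicity_ratio == pytest.approx(1.56, abs=0.01)

    def test_identical_groups_ratio_one(self):
        group = [DrugProfile("a", "100 mg/kg", "5 h"), DrugProfile("b", "300 mg/kg", "7 h")]
        assert group_comparison(group, group).toxicity_ratio == 1.0

    def test_means_equal_hand_computation(self):
        selected = [
            DrugProfile("a", "100 mg/kg", "2–4 h"),
            DrugProfile("b", "300 mg/kg", "1 days"),
        ]
        unselected = [DrugProfile("c", "500 mg/kg", "10 h")]
        comparison = group_comparison(selected, unselected)
        assert comparison.selected_toxicity == pytest.approx(200.0)
        assert comparison.selected_half_life == pytest.approx((3 + 24) / 2)
        assert comparison.unselected_toxicity == pytest.approx(500.0)
        assert comparison.toxicity_ratio == pytest.approx(2.5)

    def test_invariant_to_order_and_unparseable_insertion(self):
        a = [DrugProfile("a", "100 mg/kg", "5 h"), DrugProfile("b", "300 mg/kg", "7 h")]
        b = [DrugProfile("c", "200 mg/kg", "9 h")]
        base = group_comparison(a, b)
        noisy = group_comparison(
            [DrugProfile("x", "narrative only", "see text")] + a[::-1], b
        )
        assert noisy.selected_toxicity == base.selected_toxicity
        assert noisy.selected_half_life == base.selected_half_life

    def test_empty_parseable_group_raises(self):
        with pytest.raises(InsufficientDataError):
            group_comparison(
                [DrugProfile("a", "no numbers", "none")],
                [DrugProfile("b", "100 mg/kg", "5 h")],
            )


def frames(herb_ingredients, ingredient_targets, target_diseases):
    return (
        pd.DataFrame(herb_ingredients, columns=["herb", "ingredient", "ob", "dl"]),
        pd.DataFrame(ingredient_targets, columns=["ingredient", "target"]),
        pd.DataFrame(target_diseases, columns=["target", "disease"]),
    )


class TestHitdGraph:
    def test_low_ob_ingredient_excluded(self):
        hi, it, td = frames([("h", "i", 25.0, 0.5)], [("i", "t")], [("t", "d")])
        graph = build_hitd_graph(hi, it, td, {"d"})
        assert graph.number_of_nodes() == 0

    def test_passing_ingredient_keeps_full_path(self):
        hi, it, td = frames([("h", "i", 35.0, 0.2)], [("i", "t")], [("t", "d")])
        graph = build_hitd_graph(hi, it, td, {"d"})
        assert set(graph.nodes) == {"h", "i", "t", "d"}
        assert graph.has_edge("h", "i") and graph.has_edge("i", "t") and graph.has_edge("t", "d")

    @pytest.mark.parametrize("ob,dl", [(30.0, 0.5), (35.0, 0.18)])
    def test_boundary_values_excluded(self, ob, dl):
        hi, it, td = frames([("h", "i", ob, dl)], [("i", "t")], [("t", "d")])
        assert build_hitd_graph(hi, it, td, {"d"}).number_of_nodes() == 0

    def test_disease_outside_drug_set_dropped(self):
        hi, it, td = frames([("h", "i", 35.0, 0.2)], [("i", "t")], [("t", "other")])
        graph = build_hitd_graph(hi, it, td, {"d"})
        assert "other" not in graph.nodes
        assert "t" in graph.nodes  # target keeps its ingredient edge

    def test_matches_bruteforce_filter_and_join(self):
        rng = np.random.default_rng(5)
        herbs = [f"h{i}" for i in range(3)]
        ingredients = [f"i{i}" for i in range(8)]
        targets = [f"t{i}" for i in range(6)]
        diseases = [f"d{i}" for i in range(5)]
        hi_rows = [
            (rng.choice(herbs), ing, float(rng.uniform(10, 60)), float(rng.uniform(0.05, 0.4)))
            for ing in ingredients
        ]
        it_rows = [(rng.choice(ingredients), t) for t in targets for _ in range(2)]
        td_rows = [(rng.choice(targets), d) for d in diseases for _ in range(2)]
        drug_diseases = {"d0", "d1", "d2"}
        graph = build_hitd_graph(*frames(hi_rows, it_rows, td_rows), drug_diseases)

        kept_ing = {ing for _, ing, ob, dl in hi_rows if ob > 30 and dl > 0.18}
        expected_edges = set()
        for h, ing, ob, dl in hi_rows:
            if ing in kept_ing:
                expected_edges.add((h, ing))
        retained_targets = {t for ing, t in it_rows if ing in kept_ing}
        expected_edges |= {(ing, t) for ing, t in it_rows if ing in kept_ing}
        expected_edges |= {
            (t, d) for t, d in td_rows if t in retained_targets and d in drug_diseases
        }
        assert set(graph.edges) == expected_edges
        # node post-conditions
        for node, data in graph.nodes(data=True):
            assert graph.degree(node) > 0
            if data["node_type"] == "ingredient":
                assert node in kept_ing

    def test_no_edge_references_dropped_node(self):
        hi, it, td = frames(
            [("h1", "i1", 35.0, 0.2), ("h2", "i2", 20.0, 0.2)],
            [("i1", "t1"), ("i2", "t2")],
            [("t1", "d1"), ("t2", "d1")],
        )
        graph = build_hitd_graph(hi, it, td, {"d1"})
        for a, b in graph.edges:
            assert a in graph.nodes and b in graph.nodes
        assert "i2" not in graph.nodes and "t2" not in graph.nodes


class TestCommonTargets:
    def test_disjoint_sets_empty(self):
        assert common_targets({"t1"}, {"i1": {"t2"}}) == {}

    def test_shared_target_via_two_ingredients(self):
        out = common_targets({"SERT"}, {"beta-sitosterol": {"SERT"}, "boldine": {"SERT", "other"}})
        assert out == {"SERT": ["beta-sitosterol", "boldine"]}

    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(9)
        targets = [f"t{i}" for i in range(10)]
        drug_targets = set(rng.choice(targets, size=5, replace=False))
        mapping = {
            f"i{i}": set(rng.choice(targets, size=int(rng.integers(1, 4)), replace=False))
            for i in range(6)
        }
        out = common_targets(drug_targets, mapping)
        for t in targets:
            expected = sorted(i for i, ts in mapping.items() if t in ts) if t in drug_targets else []
            if expected:
                assert out.get(t) == expected
            else:
                assert t not in out
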