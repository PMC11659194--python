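import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sweetspots as sw
from sweetspots.spots import BreakMethod, SpotCategory


def make_table(registry, **columns):
    n = len(next(iter(columns.values())))
    df = pd.DataFrame(columns, index=pd.Index([f"D{i}" for i in range(n)], name="da_id"))
    return sw.DATable(df, 2006, registry, demo_groups=[])


class TestComputeBreaks:
    def test_even_breaks_quarter_the_range(self, registry):
        t = make_table(registry, no2=[0.0, 10.0, 60.0, 100.0])
        b = sw.compute_breaks(t, "no2", BreakMethod.EVEN_BREAKS)
        assert b.cutpoints == pytest.approx((25.0, 50.0, 75.0))

    def test_quartiles_split_one_through_eight_evenly(self, registry):
        t = make_table(registry, walkability=list(map(float, range(1, 9))))
        b = sw.compute_breaks(t, "walkability", BreakMethod.QUARTILE)
        classes = sw.assign_classes(t.env("walkability"), b)
        assert sorted(np.bincount(classes)[1:]) == [2, 2, 2, 2]

    def test_degenerate_variable_raises(self, registry):
        t = make_table(registry, no2=[5.0] * 6)
        with pytest.raises(sw.DegenerateVariableError):
            sw.compute_breaks(t, "no2", BreakMethod.QUARTILE)

    def test_few_distinct_values_warns_but_proceeds(self, registry):
        t = make_table(registry, no2=[1.0, 1.0, 2.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="fewer than 4 distinct"):
            b = sw.compute_breaks(t, "no2", BreakMethod.QUARTILE)
        assert b.cutpoints[0] <= b.cutpoints[2]

    def test_quartile_class_sizes_match_sort_and_split_oracle(self, registry, rng):
        for _ in range(50):
            n = int(rng.integers(8, 80))
            vals = rng.normal(0, 1, n)
            if np.unique(vals).size < n:
                continue
            t = make_table(registry, walkability=vals)
            b = sw.compute_breaks(t, "walkability", BreakMethod.QUARTILE)
            classes = sw.assign_classes(vals, b)
            sizes = np.bincount(classes, minlength=5)[1:]
            # oracle: sorting and splitting into four nearly equal runs
            oracle_sizes = sorted(len(s) for s in np.array_split(np.sort(vals), 4))
            assert max(sizes) - min(sizes) <= 1
            assert sorted(sizes) == oracle_sizes


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(
        st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
        min_size=8,
        max_size=60,
        unique=True,
    )
)
def test_quartile_balance_and_direction_are_universal(values):
    """For any tie-free sample, quartile class sizes differ by at most one
    and higher values of a benefit never get a lower class."""
    registry = sw.default_registry()
    t = make_table(registry, walkability=values)
    breaks = sw.compute_breaks(t, "walkability", BreakMethod.QUARTILE)
    classes = sw.assign_classes(np.asarray(values), breaks)
    sizes = np.bincount(classes, minlength=5)[1:]
    assert max(sizes) - min(sizes) <= 1
    order = np.argsort(values)
    assert np.all(np.diff(classes[order]) >= 0)


class TestAssignClass:
    breaks_high = sw.ClassBreaks(
        "walkability", BreakMethod.QUARTILE, (1.0, 2.0, 3.0), sw.Direction.HIGH_IS_GOOD
    )
    breaks_low = sw.ClassBreaks(
        "no2", BreakMethod.QUARTILE, (1.0, 2.0, 3.0), sw.Direction.LOW_IS_GOOD
    )

    def test_top_quartile_of_a_burden_is_class_1(self):
        assert sw.assign_class(9.0, self.breaks_low) == 1

    def test_top_quartile_of_a_benefit_is_class_4(self):
        assert sw.assign_class(9.0, self.breaks_high) == 4

    @pytest.mark.parametrize("value, expected", [(1.0, 1), (2.0, 2), (3.0, 3)])
    def test_value_on_cutpoint_falls_in_lower_bin(self, value, expected):
        assert sw.assign_class(value, self.breaks_high) == expected

    def test_direction_monotonicity(self, rng):
        vals = np.sort(rng.uniform(-1, 5, 40))
        up = sw.assign_classes(vals, self.breaks_high)
        down = sw.assign_classes(vals, self.breaks_low)
        assert np.all(np.diff(up) >= 0)
        assert np.all(np.diff(down) <= 0)
        assert np.all(up + down == 5)

    def test_missing_value_has_no_class(self):
        assert sw.assign_classes(np.array([np.nan]), self.breaks_high)[0] == 0
        with pytest.raises(sw.UsageError):
            sw.assign_class(float("nan"), self.breaks_high)


class TestRuleSets:
    def test_walkability_no2_high_walk_high_no2_is_risky(self, walk_no2_rules):
        assert sw.classify_pair(4, 1, walk_no2_rules) is SpotCategory.RISKY

    def test_vegetation_no2_offset_sweet_cells(self):
        rules = {r.name: r for r in sw.builtin_rulesets()}["ndvi_no2"]
        assert sw.classify_pair(3, 4, rules) is SpotCategory.SWEET
        assert sw.classify_pair(4, 3, rules) is SpotCategory.SWEET

    def test_heat_no2_wide_sour_corner(self):
        rules = {r.name: r for r in sw.builtin_rulesets()}["heat_no2"]
        assert sw.classify_pair(2, 1, rules) is SpotCategory.SOUR
        assert sw.classify_pair(1, 2, rules) is SpotCategory.SOUR

    def test_middle_cells_default_to_medium(self):
        for rules in sw.builtin_rulesets():
            assert sw.classify_pair(2, 2, rules) is SpotCategory.MEDIUM

    def test_only_walkability_no2_has_a_risky_cell(self):
        for rules in sw.builtin_rulesets():
            expected = 1 if rules.name == "walkability_no2" else 0
            assert len(rules.risky_pairs) == expected

    def test_every_cell_maps_to_exactly_one_label(self):
        for rules in sw.builtin_rulesets():
            for a in range(1, 5):
                for b in range(1, 5):
                    assert isinstance(sw.classify_pair(a, b, rules), SpotCategory)

    def test_symmetric_rulesets_commute(self):
        for rules in sw.builtin_rulesets():
            sym = all(
                (b, a) in pairs
                for pairs in (rules.sour_pairs, rules.risky_pairs, rules.sweet_pairs)
                for a, b in pairs
            )
            if sym:
                for a in range(1, 5):
                    for b in range(1, 5):
                        assert sw.classify_pair(a, b, rules) == sw.classify_pair(
                            b, a, rules
                        )

    def test_class_outside_range_raises(self, walk_no2_rules):
        with pytest.raises(sw.UsageError):
            sw.classify_pair(0, 1, walk_no2_rules)

    def test_overlapping_rule_sets_rejected(self):
        with pytest.raises(sw.ValidationError):
            sw.RuleSet(
                "bad",
                "a",
                "b",
                sour_pairs=frozenset({(1, 1)}),
                sweet_pairs=frozenset({(1, 1)}),
            )

    def test_rulesets_load_from_config_mapping(self, walk_no2_rules):
        cfg = {
            "rulesets": [
                {
                    "name": "walkability_no2",
                    "var_first": "walkability",
                    "var_second": "no2",
                    "sour": [[1, 1]],
                    "risky": [[4, 1]],
                    "sweet": [[4, 4]],
                }
            ]
        }
        (loaded,) = sw.rulesets_from_config(cfg)
        assert loaded == walk_no2_rules


class TestClassifyTable:
    def test_hand_derived_labels_on_eight_da_fixture(
        self, eight_da_table, walk_no2_rules
    ):
        a = sw.classify_table(eight_da_table, walk_no2_rules, BreakMethod.QUARTILE)
        expected = {
            "D0": "SOUR",
            "D1": "SOUR",
            "D2": "MEDIUM",
            "D3": "MEDIUM",
            "D4": "MEDIUM",
            "D5": "MEDIUM",
            "D6": "SWEET",
            "D7": "SWEET",
        }
        assert a.frame["category"].to_dict() == expected
        assert a.n_classified == 8

    def test_uniformly_favorable_table_is_all_sweet_under_even_breaks(self, registry):
        # both variables in their top even-break quartile for 6 of 8 DAs,
        # anchored by one unfavorable DA defining the range
        t = make_table(
            registry,
            walkability=[0.0, 97, 98, 99, 96, 95, 94, 100],
            no2=[100.0, 2, 1, 3, 2.5, 1.5, 0.5, 0.0],
        )
        rules = {r.name: r for r in sw.builtin_rulesets()}["walkability_no2"]
        a = sw.classify_table(t, rules, BreakMethod.EVEN_BREAKS)
        assert (a.frame.drop(index="D0")["category"] == "SWEET").all()

    def test_da_missing_one_variable_is_excluded(self, eight_da_table, walk_no2_rules):
        t = eight_da_table.copy()
        t.df.loc["D3", "no2"] = np.nan
        a = sw.classify_table(t, walk_no2_rules)
        assert a.n_classified == 7
        assert "D3" not in a.frame.index

    def test_labels_invariant_to_row_order(self, registry, rng, walk_no2_rules):
        vals = rng.normal(10, 3, 40)
        t = make_table(registry, walkability=vals, no2=rng.lognormal(2, 0.4, 40))
        a1 = sw.classify_table(t, walk_no2_rules)
        shuffled = sw.DATable(
            t.df.sample(frac=1, random_state=7), 2006, registry, demo_groups=[]
        )
        a2 = sw.classify_table(shuffled, walk_no2_rules)
        assert a1.frame["code"].sort_index().equals(a2.frame["code"].sort_index())


class TestAggregation:
    def test_count_spots_conserves_classified_combinations(
        self, registry, rng
    ):
        n = 60
        t = make_table(
            registry,
            walkability=rng.gamma(2, 1.2, n),
            no2=rng.lognormal(2.5, 0.4, n),
            ndvi=rng.uniform(0.05, 0.6, n),
            heat=rng.normal(26, 0.7, n),
            park_distance=rng.exponential(300, n),
        )
        t.df.loc["D0", "ndvi"] = np.nan  # D0 unclassifiable for 2 of 6 combos
        assignments = [sw.classify_table(t, r) for r in sw.builtin_rulesets()]
        counts = sw.count_spots(assignments)
        totals = counts.sum(axis=1)
        assert totals["D0"] == 4
        assert (totals.drop("D0") == 6).all()

    def test_count_spots_empty_input(self):
        assert sw.count_spots([]).empty

    def test_spot_proportions_sum_to_100(self, eight_da_table, walk_no2_rules):
        a = sw.classify_table(eight_da_table, walk_no2_rules)
        props = sw.spot_proportions(a)
        assert sum(props.values()) == pytest.approx(100.0, abs=1e-9)
        assert props[SpotCategory.SOUR] == pytest.approx(25.0)
        assert props[SpotCategory.SWEET] == pytest.approx(25.0)

    def test_spot_proportions_undefined_on_empty_assignment(self, walk_no2_rules):
        empty = sw.SpotAssignment(
            combination="walkability_no2",
            frame=pd.DataFrame(
                columns=["class_first", "class_second", "code", "category"]
            ),
            rules=walk_no2_rules,
            method=BreakMethod.QUARTILE,
        )
        with pytest.raises(sw.UndefinedResultError):
            sw.spot_proportions(empty)
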