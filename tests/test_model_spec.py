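"""Layout and model-specification behaviour: parameter counts, AR
topologies, constraint schemes, degrees-of-freedom bookkeeping."""

import pytest

import arcfa
from arcfa.layout import Item, ItemLayout
from arcfa.model import AR, RESIDUAL_COV, ParameterEntry, assert_nested


def blocked_layout(n_traits=2, per_trait=3):
    """Items administered in trait blocks (e1,e2,e3,a1,a2,a3,...)."""
    items, pos = [], 1
    for t in "eacno"[:n_traits]:
        for k in range(1, per_trait + 1):
            items.append(Item(name=f"{t}{k}", trait=t.upper(), position=pos))
            pos += 1
    return ItemLayout(items=tuple(items))


class TestLayout:
    def test_minipip_structure(self, layout):
        assert layout.p == 20
        assert layout.m == 5
        # cycled administration: position 6 is the second extraversion item
        assert layout.items[5].name == "e2"
        assert layout.names[:5] == ("e1", "a1", "c1", "n1", "o1")

    @pytest.mark.parametrize(
        "name,scoring",
        [("o3", "reversed"), ("n3", "normal"), ("e2", "reversed"), ("a1", "normal")],
    )
    def test_minipip_scoring_flags(self, layout, name, scoring):
        assert layout.item(name).scoring == scoring

    def test_minipip_reversed_set(self, layout):
        reversed_items = {it.name for it in layout.items if it.scoring == "reversed"}
        assert reversed_items == {"e2", "e4", "a2", "a4", "c2", "c4", "n2", "n4", "o2", "o3", "o4"}

    def test_invalid_layouts_rejected(self):
        with pytest.raises(ValueError):
            ItemLayout(items=(Item("x", "T", 1), Item("y", "T", 3)))  # gap
        with pytest.raises(ValueError):
            ItemLayout(items=(Item("x", "T", 1), Item("x", "T", 2)))  # dup name


class TestBuilders:
    def test_ic_cfa_free_parameter_count(self, layout):
        spec = arcfa.build_ic_cfa(layout)
        assert spec.n_free_distinct == 20 + 10 + 20
        assert not spec.select(AR)

    def test_ic_cfa_single_trait(self):
        lay = ItemLayout(items=tuple(Item(f"x{i}", "T", i) for i in (1, 2, 3)))
        assert arcfa.build_ic_cfa(lay).n_free_distinct == 6

    def test_ar_topologies(self, layout):
        adj = arcfa.build_ar_cfa(layout, "adjacent")
        assert len(adj.select(AR)) == 19
        full = arcfa.build_ar_cfa(layout, "adjacent_plus_construct")
        # 19 between-construct + 15 within-construct terms
        assert len(full.select(AR)) == 34
        within = [
            (s, t) for s, t in full.ar_pairs() if s[0] == t[0]
        ]
        assert len(within) == 15

    def test_blocked_layout_deduplicates(self):
        lay = blocked_layout()
        adj = arcfa.build_ar_cfa(lay, "adjacent")
        both = arcfa.build_ar_cfa(lay, "adjacent_plus_construct")
        # within-trait neighbours are already adjacent: one entry, not two
        assert len(adj.select(AR)) == len(both.select(AR)) == lay.p - 1

    def test_ar_strictly_forward(self, layout):
        spec = arcfa.build_ar_cfa(layout, "adjacent_plus_construct")
        for e in spec.select(AR):
            assert layout.items[e.col].position < layout.items[e.row].position

    def test_rc_cfa_preserves_df(self, layout):
        ar = arcfa.build_ar_cfa(layout, "adjacent_plus_construct")
        rc = arcfa.build_rc_cfa(ar)
        assert len(rc.select(RESIDUAL_COV)) == 34
        assert not rc.select(AR)
        assert arcfa.model_df(rc) == arcfa.model_df(ar)
        # entries map one-to-one through the reparameterization
        assert {(e.row, e.col) for e in rc.select(RESIDUAL_COV)} == {
            (e.row, e.col) for e in ar.select(AR)
        }

    def test_rc_cfa_no_ar_is_identity(self, layout):
        ic = arcfa.build_ic_cfa(layout)
        assert arcfa.build_rc_cfa(ic).entries == ic.entries


class TestDegreesOfFreedom:
    def test_minipip_df(self, layout):
        assert arcfa.model_df(arcfa.build_ic_cfa(layout)) == 160
        assert arcfa.model_df(arcfa.build_ar_cfa(layout, "adjacent_plus_construct")) == 126

    def test_df_drop_equals_ar_count(self):
        lay = blocked_layout(3, 4)
        ic = arcfa.build_ic_cfa(lay)
        ar = arcfa.build_ar_cfa(lay, "adjacent_plus_construct")
        assert arcfa.model_df(ic) - arcfa.model_df(ar) == len(ar.select(AR))

    def test_saturated_model_zero_df(self):
        lay = blocked_layout(1, 3)
        entries = [ParameterEntry("residual_var", i, i) for i in range(3)]
        entries += [ParameterEntry("residual_cov", i, j) for i in range(3) for j in range(i)]
        spec = arcfa.ModelSpec(layout=lay, entries=tuple(entries))
        assert arcfa.model_df(spec) == 0

    def test_overparameterized_rejected(self):
        lay = blocked_layout(1, 2)
        entries = [ParameterEntry("residual_var", i, i) for i in range(2)]
        entries += [ParameterEntry("residual_cov", 1, 0)]
        entries += [ParameterEntry("loading", i, 0) for i in range(2)]
        spec = arcfa.ModelSpec(layout=lay, entries=tuple(entries))
        with pytest.raises(ValueError, match="over-parameterized"):
            arcfa.model_df(spec)


class TestEqualityConstraints:
    def test_by_type_pools_to_14(self, layout):
        ar = arcfa.build_ar_cfa(layout, "adjacent_plus_construct")
        bt = arcfa.apply_equality_constraints(ar, "by_type")
        free_ar = {e.eq_label for e in bt.select(AR) if e.eq_label} | {
            None for e in bt.select(AR) if e.eq_label is None
        }
        n_groups = len({e.eq_label for e in bt.select(AR) if e.eq_label})
        n_exempt = sum(1 for e in bt.select(AR) if e.eq_label is None)
        assert (n_groups, n_exempt) == (10, 4)
        assert arcfa.model_df(bt) - arcfa.model_df(ar) == 20

    def test_by_type_and_scoring_pools_to_17(self, layout):
        ar = arcfa.build_ar_cfa(layout, "adjacent_plus_construct")
        bts = arcfa.apply_equality_constraints(ar, "by_type_and_scoring")
        cells = {e.eq_label for e in bts.select(AR) if e.eq_label}
        assert len(cells) == 13
        similar = {c for c in cells if c.endswith("similar")}
        assert len(similar) == 6  # the rest are different-scoring cells
        assert arcfa.model_df(bts) - arcfa.model_df(ar) == 17

    def test_exempt_terms_are_first_cycle(self, layout):
        ar = arcfa.build_ar_cfa(layout, "adjacent_plus_construct")
        bt = arcfa.apply_equality_constraints(ar, "by_type")
        names = layout.names
        exempt = {
            (names[e.col], names[e.row]) for e in bt.select(AR) if e.eq_label is None
        }
        assert exempt == {("e1", "a1"), ("a1", "c1"), ("c1", "n1"), ("n1", "o1")}

    def test_singleton_groups_change_nothing(self):
        lay = blocked_layout(2, 2)  # one non-exempt term per type group
        ar = arcfa.build_ar_cfa(lay, "adjacent_plus_construct")
        bt = arcfa.apply_equality_constraints(ar, "by_type")
        assert bt.n_free_distinct == ar.n_free_distinct

    def test_monotone_pooling(self, layout):
        ar = arcfa.build_ar_cfa(layout, "adjacent_plus_construct")
        bt = arcfa.apply_equality_constraints(ar, "by_type")
        bts = arcfa.apply_equality_constraints(ar, "by_type_and_scoring")
        assert bt.n_free_distinct <= bts.n_free_distinct <= ar.n_free_distinct
        # constraints touch eq_labels only, never matrix membership
        assert [(e.matrix, e.row, e.col) for e in bt.entries] == [
            (e.matrix, e.row, e.col) for e in ar.entries
        ]

    def test_requires_ar_entries(self, layout):
        with pytest.raises(ValueError):
            arcfa.apply_equality_constraints(arcfa.build_ic_cfa(layout), "by_type")


class TestNesting:
    def test_constrained_is_nested_in_free(self, layout):
        ar = arcfa.build_ar_cfa(layout, "adjacent_plus_construct")
        bt = arcfa.apply_equality_constraints(ar, "by_type")
        assert_nested(bt, ar)
        assert_nested(arcfa.build_ic_cfa(layout), ar)

    def test_rc_not_nested_in_ar(self, layout):
        ar = arcfa.build_ar_cfa(layout, "adjacent_plus_construct")
        rc = arcfa.build_rc_cfa(ar)
        with pytest.raises(ValueError):
            assert_nested(rc, ar)
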