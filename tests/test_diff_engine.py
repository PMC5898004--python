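import random

import pytest
from hypothesis import given, settings, strategies as st

from modelevo.diff_engine import (
    Delta,
    DiffOp,
    InconsistentDeltaError,
    ModelIdMismatchError,
    apply_delta,
    diff,
    line_diff,
    match_trees,
)
from modelevo.model_io import canonical_equal, iter_elements, parse_model
from modelevo.synthetic import EditSpec, generate_history, generate_seed_model

from conftest import SBML_SMALL
from oracles import lcs_line_counts


def _variant(old: str, new: str):
    assert old in SBML_SMALL
    return parse_model(SBML_SMALL.replace(old, new), model_id="m1", version_id="v2")


def _flat_nodes(root):
    """Independent (path, kind, value/label) table used as a brute-force
    oracle for the single-edit fixtures."""
    out = set()
    for el in iter_elements(root):
        out.add((el.path, "element", el.label))
        for a in el.attributes:
            out.add((a.path, "attribute", a.value))
        for t in el.text_children():
            out.add((t.path, "text", t.value))
    return out


class TestMatchTrees:
    def test_identical_trees_total_mapping(self, sbml_small):
        other = parse_model(SBML_SMALL, model_id="m1", version_id="v2")
        m = match_trees(sbml_small.root, other.root)
        n = sum(1 for _ in iter_elements(sbml_small.root))
        assert len(m.pairs()) == n

    def test_disjoint_trees_only_roots(self):
        a = parse_model(SBML_SMALL, model_id="m1")
        b = parse_model(
            '<sbml xmlns="http://www.sbml.org/sbml/level2/version4">'
            "<listOfNothing><thing id='q'/></listOfNothing></sbml>",
            model_id="m1",
        )
        m = match_trees(a.root, b.root)
        assert len(m.pairs()) == 1
        assert m.pairs()[0][0] is a.root

    def test_renamed_species_matched_structurally(self):
        # rename forces the similarity pass; with five attributes the
        # renamed pair shares 5 of 7 tokens (Jaccard 0.71 >= 0.7)
        rich = SBML_SMALL.replace(
            '<species id="s1" compartment="c1" initialConcentration="1"/>',
            '<species id="s1" name="one" compartment="c1"'
            ' initialConcentration="1" boundaryCondition="false"/>')
        a = parse_model(rich, model_id="m1", version_id="v1")
        b = parse_model(rich.replace('id="s1"', 'id="sX"'),
                        model_id="m1", version_id="v2")
        m = match_trees(a.root, b.root)
        s1 = next(e for e in iter_elements(a.root) if e.attr("id") == "s1")
        img = m.image(s1)
        assert img is not None and img.attr("id") == "sX"
        # and the diff reports the rename as a single attribute update
        d = diff(a, b)
        assert [o.key()[:2] for o in d.ops] == [("update", "attribute")]


class TestDiff:
    def test_identity_empty(self, sbml_small):
        other = parse_model(SBML_SMALL, model_id="m1", version_id="v2")
        d = diff(sbml_small, other)
        assert d.ops == [] and d.line_inserts == 0 and d.line_deletes == 0
        assert d.is_empty()

    def test_model_id_mismatch_refused(self, sbml_small, cellml_small):
        with pytest.raises(ModelIdMismatchError):
            diff(sbml_small, cellml_small)

    def test_single_attribute_update(self, sbml_small):
        b = _variant('initialConcentration="1"', 'initialConcentration="3"')
        # oracle: exactly one node-level difference between the flat tables
        delta_paths = _flat_nodes(sbml_small.root) ^ _flat_nodes(b.root)
        assert len(delta_paths) == 2  # one path, two values
        d = diff(sbml_small, b)
        assert len(d.ops) == 1
        (op,) = d.ops
        assert (op.op_type, op.entity_kind) == ("update", "attribute")
        assert op.old_value == "1" and op.new_value == "3"
        assert not op.triggered

    def test_element_move_single_op(self):
        base = SBML_SMALL.replace(
            '<species id="s2" compartment="c1" initialConcentration="2"/>',
            '<species id="s2" compartment="c1" initialConcentration="2"/>\n'
            '      <species id="s3" compartment="c1" initialConcentration="3"/>',
        )
        a = parse_model(base, model_id="m1", version_id="v1")
        # move s1 to the end of the list (jumps over two stable siblings)
        moved = base.replace(
            '<species id="s1" compartment="c1" initialConcentration="1"/>\n      ', "")
        moved = moved.replace(
            '<species id="s3" compartment="c1" initialConcentration="3"/>',
            '<species id="s3" compartment="c1" initialConcentration="3"/>\n'
            '      <species id="s1" compartment="c1" initialConcentration="1"/>',
        )
        b = parse_model(moved, model_id="m1", version_id="v2")
        d = diff(a, b)
        assert len(d.ops) == 1
        (op,) = d.ops
        assert (op.op_type, op.entity_kind, op.triggered) == ("move", "element", False)
        assert op.old_path.endswith("species[1]")
        assert op.new_path.endswith("species[3]")

    def test_subtree_delete_triggered_counts(self, sbml_small):
        b = parse_model(
            SBML_SMALL[:SBML_SMALL.index("<reaction")]
            + SBML_SMALL[SBML_SMALL.index("</reaction>") + len("</reaction>"):],
            model_id="m1", version_id="v2",
        )
        reaction = next(e for e in iter_elements(sbml_small.root)
                        if e.attr("id") == "r1")
        # oracle: count every node strictly inside the deleted subtree
        flat = _flat_nodes(reaction)
        n_descendants = len(flat) - 1  # minus the reaction element itself
        d = diff(sbml_small, b)
        non_trig = [o for o in d.ops if not o.triggered]
        trig = [o for o in d.ops if o.triggered]
        assert len(non_trig) == 1
        assert non_trig[0].op_type == "delete"
        assert non_trig[0].old_path == reaction.path
        assert len(trig) == n_descendants
        assert all(o.op_type == "delete" for o in trig)

    def test_attribute_insert_delete(self, sbml_small):
        b = _variant('<parameter id="p1" value="0.1"/>', '<parameter id="p1"/>')
        d = diff(sbml_small, b)
        assert [o.key()[:2] for o in d.ops] == [("delete", "attribute")]
        d2 = diff(b, sbml_small)
        assert [o.key()[:2] for o in d2.ops] == [("insert", "attribute")]

    def test_cosmetic_changes_empty_delta(self, sbml_small):
        reordered = parse_model(
            "".join(line.strip() for line in SBML_SMALL.replace(
                '<species id="s1" compartment="c1" initialConcentration="1"/>',
                '<species initialConcentration="1" id="s1" compartment="c1"/>',
            ).splitlines()),
            model_id="m1", version_id="v2",
        )
        d = diff(sbml_small, reordered)
        assert d.is_empty()

    def test_summary_tallies_ops(self, sbml_small):
        b = _variant('initialConcentration="1"', 'initialConcentration="3"')
        s = diff(sbml_small, b).summary
        assert s["update"] == 1 and s["update_attribute"] == 1
        assert s["total"] == 1 and s["triggered"] == 0

    def test_determinism(self, sbml_small):
        b = _variant('id="s2" compartment="c1"', 'id="s2" compartment="cX"')
        d1 = diff(sbml_small, b)
        d2 = diff(sbml_small, b)
        assert d1.to_json() == d2.to_json()


class TestLineDiff:
    def test_identical(self):
        assert line_diff("a\nb", "a\nb") == (0, 0)

    def test_appended_lines(self):
        assert line_diff("a\nb", "a\nb\nc\nd\ne") == (3, 0)

    def test_empty_inputs(self):
        assert line_diff("", "") == (0, 0)
        assert line_diff("a\nb", "") == (0, 2)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_pairs_match_lcs_oracle(self, seed):
        rng = random.Random(seed)
        alpha = [f"l{i}" for i in range(8)]
        a = "\n".join(rng.choice(alpha) for _ in range(rng.randint(0, 40)))
        b = "\n".join(rng.choice(alpha) for _ in range(rng.randint(0, 40)))
        assert line_diff(a, b) == lcs_line_counts(a, b)

    @given(st.lists(st.integers(0, 5), max_size=30),
           st.lists(st.integers(0, 5), max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_property_matches_oracle(self, xs, ys):
        a = "\n".join(map(str, xs))
        b = "\n".join(map(str, ys))
        assert line_diff(a, b) == lcs_line_counts(a, b)


class TestApplyDelta:
    def test_identity_round_trip(self, sbml_small):
        other = parse_model(SBML_SMALL, model_id="m1", version_id="v2")
        out = apply_delta(sbml_small, diff(sbml_small, other))
        assert canonical_equal(out, sbml_small)

    @pytest.mark.parametrize("old,new", [
        ('initialConcentration="1"', 'initialConcentration="3"'),
        ('<parameter id="p1" value="0.1"/>', '<parameter id="p1"/>'),
        ('<species id="s2" compartment="c1" initialConcentration="2"/>', ''),
        ('<listOfParameters>', '<listOfParameters>\n      <parameter id="pZ" value="7"/>'),
    ])
    def test_round_trip_fixture_pairs(self, sbml_small, old, new):
        b = _variant(old, new)
        out = apply_delta(sbml_small, diff(sbml_small, b))
        assert canonical_equal(out, b)

    def test_wrong_base_raises(self, sbml_small):
        b = _variant('initialConcentration="1"', 'initialConcentration="3"')
        d = diff(sbml_small, b)
        with pytest.raises(InconsistentDeltaError):
            apply_delta(b, d)  # base already carries the new value

    def test_unknown_path_raises(self, sbml_small):
        d = Delta("m1", "v1", "v2", ops=[
            DiffOp("delete", "element", old_path="/sbml[1]/model[1]/listOfEvents[1]")
        ])
        with pytest.raises(InconsistentDeltaError):
            apply_delta(sbml_small, d)

    def test_version_id_advanced(self, sbml_small):
        b = _variant('initialConcentration="1"', 'initialConcentration="3"')
        out = apply_delta(sbml_small, diff(sbml_small, b))
        assert out.version_id == "v2"


class TestSymmetry:
    @pytest.mark.parametrize("fmt,seed", [("SBML", 0), ("SBML", 1),
                                          ("CellML", 0), ("CellML", 1)])
    def test_insert_delete_symmetry(self, fmt, seed):
        doc = generate_seed_model(fmt, None, seed, model_id="sym")
        versions, _ = generate_history(doc, 4, EditSpec(n_edits=6), rng_seed=seed)
        for a, b in zip(versions, versions[1:]):
            ab, ba = diff(a, b).summary, diff(b, a).summary
            assert ab["insert"] == ba["delete"]
            assert ab["delete"] == ba["insert"]
            assert ab["update"] == ba["update"]
            assert ab["move"] == ba["move"]


class TestExports:
    @pytest.fixture
    def delta(self, sbml_small):
        b = _variant('initialConcentration="1"', 'initialConcentration="3"')
        return diff(sbml_small, b)

    def test_json_round_trip(self, delta):
        back = Delta.from_json(delta.to_json())
        assert [o.key() for o in back.ops] == [o.key() for o in delta.ops]
        assert back.model_id == delta.model_id

    def test_xml_patch_contains_ops(self, delta):
        text = delta.to_xml_patch()
        assert '<operation op="update" kind="attribute"' in text
        assert 'triggered="false"' in text

    def test_text_report(self, delta):
        rep = delta.to_text()
        assert "1 operations" in rep
        assert "update attribute" in rep

    def test_text_report_excludes_triggered(self, sbml_small):
        b = parse_model(
            SBML_SMALL[:SBML_SMALL.index("<reaction")]
            + SBML_SMALL[SBML_SMALL.index("</reaction>") + len("</reaction>"):],
            model_id="m1", version_id="v2",
        )
        d = diff(sbml_small, b)
        full = d.to_text(include_triggered=True)
        slim = d.to_text(include_triggered=False)
        assert full.count("delete") > slim.count("delete")
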