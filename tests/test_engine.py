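"""Decision engine: fidelity to the answer key, safety, tree auditing."""

import json

import pytest

import woundcdss as w
from woundcdss.engine import DecisionTree, TreeError


def _state(q, question_states):
    return w.parse_state(question_states[q]["state"])


@pytest.mark.parametrize(
    "q, ointment, dressing",
    [(3, 1, 5), (9, 2, 6), (6, 5, 4)],
)
def test_key_scenarios(q, ointment, dressing, tree, question_states):
    """Black necrosis, infected wound and acute ulcer map to their printed keys."""
    rec = w.recommend(_state(q, question_states), tree)
    assert (rec.ointment.code, rec.dressing.code) == (ointment, dressing)


def test_all_ten_scenarios_match_key(tree, key, question_states):
    for q, info in question_states.items():
        rec = w.recommend(w.parse_state(info["state"]), tree)
        assert (rec.ointment.code, rec.dressing.code) == key.entries[q], f"question {q}"


def test_trace_is_root_to_leaf_path(tree, all_states):
    for state in all_states:
        rec = w.recommend(state, tree)
        assert rec.trace[0] == tree.root
        for parent_id, child_id in zip(rec.trace, rec.trace[1:]):
            assert child_id in tree.nodes[parent_id].branches.values()
        assert tree.nodes[rec.trace[-1]].is_leaf


def test_safety_check_rules():
    occlusive = w.DRESSINGS[1]
    hydrogel = w.DRESSINGS[5]
    none_dressing = w.DRESSINGS[6]
    infected = w.parse_state({"phase": "chronic", "infection": "present"})
    pocketed = w.parse_state({"phase": "chronic", "depth": "deep", "pocket": "present_with_necrosis"})
    clean = w.parse_state({"phase": "chronic"})
    assert not w.safety_check(infected, occlusive)
    assert not w.safety_check(pocketed, w.DRESSINGS[3])
    assert w.safety_check(clean, hydrogel)
    assert w.safety_check(infected, none_dressing)  # "no dressing" is always safe


def test_totality_and_safety_over_entire_space(tree, all_states):
    """Every enumerable state reaches a leaf whose dressing passes the safety rule."""
    for state in all_states:
        rec = w.recommend(state, tree)
        assert w.safety_check(state, rec.dressing), state.to_dict()


def test_recommend_is_deterministic(tree, all_states):
    for state in all_states[::17]:
        assert w.recommend(state, tree) == w.recommend(state, tree)


def test_moist_healing_monotonicity(tree, all_states):
    """Clean deep chronic wound beds: moisture-donating dressings at minimal
    exudate, absorptive at high exudate; the printed dry-black-necrosis
    scenario also gets a moisture donor (hydrogel)."""
    for state in all_states:
        if (
            state.phase.value == "chronic"
            and state.depth.value == "deep"
            and state.infection.value == "absent"
            and state.pocket.value == "absent"
            and state.necrosis.value == "none"
        ):
            d = w.recommend(state, tree).dressing.code
            if state.exudate.value == "minimal":
                assert d in (3, 5)
            else:
                assert d == 1
    q3 = w.parse_state(
        {"phase": "chronic", "depth": "deep", "necrosis": "black_dry", "exudate": "minimal"}
    )
    assert w.recommend(q3, tree).dressing.code == 5


def test_validate_default_tree_is_clean(tree):
    report = w.validate_tree(tree)
    assert report.ok
    assert report.to_dict()["uncovered_states"] == []


def _tree_doc(tree):
    return json.loads(tree.to_json())


def test_validate_flags_unsafe_leaf(tree):
    doc = _tree_doc(tree)
    doc["nodes"]["leaf_infected"]["payload"] = {"ointment": 2, "dressing": 1}
    bad = DecisionTree.from_json(json.dumps(doc))
    report = w.validate_tree(bad)
    assert not report.ok
    assert "leaf_infected" in report.unsafe_leaves


def test_validate_flags_missing_branch(tree):
    doc = _tree_doc(tree)
    del doc["nodes"]["phase"]["branches"]["acute"]
    bad = DecisionTree.from_json(json.dumps(doc))
    report = w.validate_tree(bad)
    assert report.uncovered_states  # every acute state is now unreachable
    assert "phase" in report.non_exhaustive_nodes


def test_uncovered_state_raises_structured_error(tree):
    doc = _tree_doc(tree)
    del doc["nodes"]["phase"]["branches"]["acute"]
    bad = DecisionTree.from_json(json.dumps(doc))
    with pytest.raises(w.UncoveredStateError, match="acute"):
        w.recommend(w.parse_state({"phase": "acute"}), bad)


def test_json_round_trip_is_byte_identical(tree):
    text = tree.to_json()
    assert DecisionTree.from_json(text).to_json() == text


def test_malformed_trees_rejected():
    with pytest.raises(TreeError):
        DecisionTree.from_json(json.dumps({"root": "a", "nodes": {"a": {}}}))
    with pytest.raises(TreeError):
        DecisionTree.from_json(
            json.dumps(
                {"root": "a", "nodes": {"a": {"payload": {"ointment": 9, "dressing": 1}}}}
            )
        )
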