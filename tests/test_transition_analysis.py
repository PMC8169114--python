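import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from songctx import (
    CollapseRules,
    TransitionModel,
    branch_points,
    build_transition_model,
    collapse_sequences,
    context_difference,
    default_diagram,
    generate_bout,
    specificity,
    targeted_branch_states,
    transition_entropy,
)
from songctx.transition_analysis import (
    DifferenceMatrix,
    END,
    INTRO,
)


def make_model(rows: dict[str, dict[str, float]], freq: dict[str, float]) -> TransitionModel:
    cols = sorted({y for out in rows.values() for y in out})
    mat = pd.DataFrame(0.0, index=sorted(rows), columns=cols)
    for x, out in rows.items():
        for y, p in out.items():
            mat.loc[x, y] = p
    return TransitionModel(
        states=tuple(sorted(rows)),
        matrix=mat,
        state_freq=pd.Series(freq),
        counts=(mat * 1000).astype(int),
    )


class TestCollapse:
    def test_fixed_sequence_becomes_single_chunk(self):
        # 'abbc' must not fake a 50/50 branch at the duplicated 'b'
        seqs = collapse_sequences([tuple("abbc")] * 20, CollapseRules())
        assert all(len(s) == 1 for s in seqs)
        model = build_transition_model(seqs)
        assert set(model.matrix.index) == {seqs[0][0]}
        assert branch_points(model) == set()

    def test_intro_notes_summarized(self):
        rules = CollapseRules(intro_labels=frozenset("i"))
        seqs = collapse_sequences(
            [tuple("iiabc"), tuple("iabc")], rules
        )
        assert seqs[0] == seqs[1]
        assert seqs[0][0] == INTRO

    def test_variable_corpus_identity_at_threshold_one(self):
        corpus = [tuple("ab"), tuple("ac"), tuple("ba"), tuple("ca")]
        rules = CollapseRules(chunk_threshold=1.0, repeat_collapse=False)
        assert collapse_sequences(corpus, rules) == [list(s) for s in corpus]

    def test_repeat_phrases_single_state(self):
        corpus = [tuple("xeey"), tuple("xey"), tuple("xeeez"), tuple("xq")]
        seqs = collapse_sequences(corpus, CollapseRules())
        # every run of e, including length 1, is the same repeat state
        assert [s[1] for s in seqs[:3]] == ["e+", "e+", "e+"]
        assert seqs[3] == ["x", "q"]

    def test_explicit_chunks_override_detection(self):
        rules = CollapseRules(explicit_chunks=(("a", "b"),))
        seqs = collapse_sequences(
            [tuple("abx"), tuple("aby")], rules
        )
        assert seqs[0][0] == "ab" and seqs[1][0] == "ab"

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            collapse_sequences([], CollapseRules())


class TestTransitionModel:
    def test_deterministic_pair(self):
        m = build_transition_model([tuple("ab"), tuple("ab")])
        assert m.p("a", "b") == 1.0

    def test_count_and_normalize(self):
        m = build_transition_model(
            [tuple("ab"), tuple("ac"), tuple("ab"), tuple("ad")]
        )
        assert m.p("a", "b") == pytest.approx(0.5)
        assert m.p("a", "c") == pytest.approx(0.25)
        assert m.p("a", "d") == pytest.approx(0.25)

    def test_bout_boundaries_terminate(self):
        m = build_transition_model([tuple("ab"), tuple("ba")])
        assert m.p("b", "a") == pytest.approx(0.5)  # b->END and b->a
        assert m.p("b", END) == pytest.approx(0.5)

    def test_rows_stochastic_and_freq_normalized(self, trained_log):
        log, _ = trained_log
        seqs = collapse_sequences(
            log.bouts[:500], CollapseRules(intro_labels=frozenset("i"))
        )
        m = build_transition_model(seqs)
        assert np.allclose(m.matrix.sum(axis=1), 1.0, atol=1e-9)
        assert m.state_freq.sum() == pytest.approx(1.0, abs=1e-9)
        assert (m.counts.sum(axis=1) > 0).all()

    def test_generator_edge_recovery(self):
        rng = np.random.default_rng(5)
        d = default_diagram()
        bouts = [generate_bout(d, 0.7, rng) for _ in range(5000)]
        seqs = collapse_sequences(
            bouts, CollapseRules(intro_labels=frozenset("i"))
        )
        m = build_transition_model(seqs)
        # the branch chunk ends in 'b'; its successors are the two motif
        # chunks beginning with 'd' (yellow) and 'c' (green)
        branch = next(s for s in m.matrix.index if s.endswith("b"))
        to_d = next(s for s in m.matrix.columns if s.startswith("d"))
        to_c = next(s for s in m.matrix.columns if s.startswith("c"))
        assert m.p(branch, to_d) == pytest.approx(0.7, abs=0.02)
        assert m.p(branch, to_c) == pytest.approx(0.3, abs=0.02)
        assert m.p(to_d, "g") == pytest.approx(0.6, abs=0.02)
        assert m.p("g", END) == pytest.approx(0.15, abs=0.02)


class TestBranchPoints:
    def test_deterministic_not_branch(self):
        m = make_model({"a": {"b": 1.0}}, {"a": 1.0})
        assert branch_points(m) == set()

    def test_near_deterministic_not_branch(self):
        m = make_model({"a": {"b": 0.98, "c": 0.02}}, {"a": 1.0})
        assert branch_points(m) == set()

    def test_typical_branch(self):
        m = make_model({"a": {"b": 0.64, "c": 0.36}}, {"a": 1.0})
        assert branch_points(m) == {"a"}

    def test_threshold_is_open_interval(self):
        m = make_model({"a": {"b": 0.97, "c": 0.03}}, {"a": 1.0})
        assert branch_points(m) == set()


class TestContextDifference:
    def test_identical_models_zero(self):
        m = make_model({"a": {"b": 0.6, "c": 0.4}}, {"a": 1.0})
        d = context_difference(m, m)
        assert (d.diff.to_numpy() == 0).all()

    def test_signed_difference(self):
        g = make_model({"ab": {"c": 0.8, "d": 0.2}}, {"ab": 1.0})
        y = make_model({"ab": {"c": 0.36, "d": 0.64}}, {"ab": 1.0})
        d = context_difference(g, y)
        assert d.diff.loc["ab", "c"] == pytest.approx(0.44)
        assert d.diff.loc["ab", "d"] == pytest.approx(-0.44)

    def test_branch_rows_sum_to_zero(self):
        g = make_model({"a": {"b": 0.7, "c": 0.3}}, {"a": 1.0})
        y = make_model({"a": {"b": 0.4, "c": 0.6}}, {"a": 1.0})
        d = context_difference(g, y)
        assert d.branch_cells().sum(axis=1).abs().max() < 1e-9

    def test_disjoint_state_sets_rejected(self):
        a = make_model({"a": {"b": 1.0}}, {"a": 1.0})
        b = make_model({"x": {"y": 1.0}}, {"x": 1.0})
        with pytest.raises(ValueError):
            context_difference(a, b)


def _diff_from_magnitudes(targeted: dict, others: dict) -> DifferenceMatrix:
    """Build a difference matrix with given |diff| magnitudes per row."""
    rows = {}
    for name, vals in {**targeted, **others}.items():
        rows[name] = {f"s{i}": v * (-1) ** i for i, v in enumerate(vals)}
    cols = sorted({c for r in rows.values() for c in r})
    diff = pd.DataFrame(0.0, index=sorted(rows), columns=cols)
    for r, out in rows.items():
        for c, v in out.items():
            diff.loc[r, c] = v
    return DifferenceMatrix(diff=diff, branch_rows=tuple(sorted(rows)))


class TestSpecificity:
    def test_worked_example(self):
        d = _diff_from_magnitudes(
            {"aab": [0.44, 0.45]},
            {"i": [0.06, 0.06], "wr": [0.01, 0.01], "cr": [0.02, 0.02]},
        )
        assert specificity(d, ["aab"]) == pytest.approx(0.832, abs=5e-4)

    def test_all_difference_at_target(self):
        d = _diff_from_magnitudes({"aab": [0.3, 0.3]}, {"i": [0.0, 0.0]})
        assert specificity(d, ["aab"]) == 1.0

    def test_equal_mass_four_branch_points(self):
        d = _diff_from_magnitudes(
            {"t": [0.1, 0.1]},
            {"u": [0.1, 0.1], "v": [0.1, 0.1], "w": [0.1, 0.1]},
        )
        assert specificity(d, ["t"]) == pytest.approx(0.25)

    def test_swap_invariance(self):
        g = make_model({"a": {"b": 0.7, "c": 0.3}, "x": {"y": 0.5, "z": 0.5}},
                       {"a": 0.5, "x": 0.5})
        y = make_model({"a": {"b": 0.4, "c": 0.6}, "x": {"y": 0.6, "z": 0.4}},
                       {"a": 0.5, "x": 0.5})
        s1 = specificity(context_difference(g, y), ["a"])
        s2 = specificity(context_difference(y, g), ["a"])
        assert s1 == pytest.approx(s2)
        assert 0.0 <= s1 <= 1.0

    def test_no_difference_is_error(self):
        m = make_model({"a": {"b": 0.6, "c": 0.4}}, {"a": 1.0})
        with pytest.raises(ValueError, match="no contextual difference"):
            specificity(context_difference(m, m), ["a"])

    def test_non_branch_target_rejected(self):
        d = _diff_from_magnitudes({"t": [0.1, 0.1]}, {})
        with pytest.raises(ValueError):
            specificity(d, ["nope"])


class TestTargetedBranchStates:
    def test_chunk_boundary_target(self):
        d = _diff_from_magnitudes({"a+b": [0.4, 0.4]}, {"f": [0.1, 0.1]})
        d.diff["d"] = [0.0, 0.4]
        d.diff.loc["a+b", "d"] = 0.4
        found = targeted_branch_states(
            d, [tuple("abd"), tuple("abc")]
        )
        assert found == {"a+b"}

    def test_first_token_branch(self):
        # branch at 'f' or 'n' preceding targets f-ab / n-ab
        rows = {"f": {"ab": 0.3, "n": -0.3}, "n": {"ab": -0.3, "f": 0.3}}
        diff = pd.DataFrame(0.0, index=["f", "n"], columns=["ab", "f", "n"])
        for r, out in rows.items():
            for c, v in out.items():
                diff.loc[r, c] = v
        d = DifferenceMatrix(diff=diff, branch_rows=("f", "n"))
        found = targeted_branch_states(
            d, [tuple("fab"), tuple("nab")]
        )
        assert found == {"f", "n"}


class TestEntropy:
    def test_deterministic_chain_zero(self):
        m = make_model({"a": {"b": 1.0}, "b": {"c": 1.0}}, {"a": 0.5, "b": 0.5})
        assert transition_entropy(m) == 0.0

    def test_uniform_binary_one_bit(self):
        m = make_model({"a": {"b": 0.5, "c": 0.5}}, {"a": 1.0})
        assert transition_entropy(m) == pytest.approx(1.0)

    def test_weighted_sum_by_hand(self):
        m = make_model(
            {"a": {"b": 0.5, "c": 0.5}, "b": {"c": 1.0}},
            {"a": 0.5, "b": 0.5},
        )
        assert transition_entropy(m) == pytest.approx(0.5)

    @pytest.mark.parametrize("k", [2, 3, 5, 8])
    def test_uniform_k_way_is_log2k(self, k):
        m = make_model(
            {"x": {f"y{i}": 1.0 / k for i in range(k)}}, {"x": 1.0}
        )
        assert transition_entropy(m) == pytest.approx(math.log2(k), abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    def test_entropy_bounds(self, weights):
        w = np.array(weights) / sum(weights)
        m = make_model(
            {"x": {f"y{i}": float(p) for i, p in enumerate(w)}}, {"x": 1.0}
        )
        h = transition_entropy(m)
        assert -1e-12 <= h <= math.log2(len(w)) + 1e-9
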