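"""Summaries: node pies, majority transitions, rates, age bounds."""

import numpy as np
import pytest

import nodulemap as nm
from nodulemap.ctmc_core import FT, NON, SYM
from nodulemap.stochastic_mapper import Event, MappedHistory
from nodulemap.transition_summary import majority_transitions, summarize
from nodulemap.treedata_io import TipObservations


def make_history(tree, states, events=()):
    return MappedHistory(
        tree=tree, node_state=np.asarray(states, dtype=np.int64), events=list(events)
    )


@pytest.fixture
def toy_tree():
    # ((A:1,B:1)n:1,C:2) in preorder: 0=root, 1=internal, 2=A, 3=B, 4=C
    return nm.read_chronogram("((A:1,B:1):1,C:2);")


class TestNodeFrequencies:
    def test_counting(self, toy_tree):
        hists = [make_history(toy_tree, [FT, FT, NON, NON, FT]) for _ in range(4)]
        hists += [make_history(toy_tree, [FT, SYM, NON, NON, FT])]
        freqs = nm.node_state_frequencies(hists)
        assert freqs[1, FT] == pytest.approx(0.8)
        assert freqs[1, SYM] == pytest.approx(0.2)
        np.testing.assert_allclose(freqs.sum(axis=1), 1.0)

    def test_unambiguous_tip_clamped(self, toy_tree):
        hists = [make_history(toy_tree, [FT, FT, FT, NON, FT]) for _ in range(3)]
        freqs = nm.node_state_frequencies(hists)
        np.testing.assert_array_equal(freqs[2], [0, 1, 0])

    def test_mismatched_trees_rejected(self, toy_tree):
        other = nm.read_chronogram("((A:1,X:1):1,C:2);")
        hists = [
            make_history(toy_tree, [FT] * 5),
            make_history(other, [FT] * 5),
        ]
        with pytest.raises(ValueError, match="different trees"):
            nm.node_state_frequencies(hists)


class TestMajorityTransitions:
    def test_single_loss_on_internal_branch(self, toy_tree):
        # root FT, internal NON, tips A,B NON, C FT
        freqs = np.zeros((5, 3))
        freqs[0, FT] = 1.0
        freqs[1, NON] = 1.0
        freqs[2, NON] = freqs[3, NON] = 1.0
        freqs[4, FT] = 1.0
        trans, counts, unresolved = majority_transitions(freqs, toy_tree)
        assert len(trans) == 1 and not unresolved
        t = trans[0]
        assert (t.from_state, t.to_state) == (FT, NON)
        assert t.branch == 1
        assert counts == {"FT->NON": 1}

    def test_double_loss_counts_both_branches(self, toy_tree):
        # parent FT with both child tips NON: two simultaneous losses
        freqs = np.zeros((5, 3))
        freqs[0, FT] = freqs[1, FT] = 1.0
        freqs[2, NON] = freqs[3, NON] = 1.0
        freqs[4, FT] = 1.0
        trans, counts, _ = majority_transitions(freqs, toy_tree)
        assert counts == {"FT->NON": 2}
        assert {t.branch for t in trans} == {2, 3}

    def test_tie_flags_incident_branches(self, toy_tree):
        freqs = np.zeros((5, 3))
        freqs[0, FT] = 1.0
        freqs[1, FT] = freqs[1, NON] = 0.5  # exact tie at the internal node
        freqs[2, NON] = freqs[3, NON] = 1.0
        freqs[4, FT] = 1.0
        trans, _, unresolved = majority_transitions(freqs, toy_tree)
        assert set(unresolved) == {1, 2, 3}
        assert all(t.branch not in unresolved for t in trans)

    def test_parent_age_exceeds_child_age(self, toy_tree, default_model):
        obs = TipObservations({"A": "nonnodulating", "B": "ft", "C": "sym"})
        maps = nm.stochastic_maps(toy_tree, obs, default_model, 51, seed=2)
        trans, _, _ = majority_transitions(nm.node_state_frequencies(maps), toy_tree)
        for t in trans:
            assert t.parent_age > t.child_age

    def test_counts_invariant_to_history_order(self, toy_tree, default_model):
        obs = TipObservations({"A": "nonnodulating", "B": "ft", "C": "sym"})
        maps = nm.stochastic_maps(toy_tree, obs, default_model, 51, seed=2)
        _, c1, _ = majority_transitions(nm.node_state_frequencies(maps), toy_tree)
        _, c2, _ = majority_transitions(
            nm.node_state_frequencies(maps[::-1]), toy_tree
        )
        assert c1 == c2


class TestEventCounts:
    def test_distribution(self, toy_tree):
        def hist(n_events):
            evs = [Event(4, 0.1 * (k + 1), FT, NON) for k in range(n_events)]
            return make_history(toy_tree, [FT, FT, FT, FT, NON], evs)

        # counts per history: 2, 3, 2  (chain validity irrelevant here)
        dist = nm.event_count_distribution([hist(2), hist(3), hist(2)])
        assert dist["FT->NON"] == {2: pytest.approx(2 / 3), 3: pytest.approx(1 / 3)}
        assert dist["SYM->NON"] == {0: 1.0}
        for d in dist.values():
            assert sum(d.values()) == pytest.approx(1.0)


class TestLossRates:
    def test_realized_rate_arithmetic(self):
        # one 100 Myr branch fully in FT, two FT->NON events... construct:
        tree = nm.read_chronogram("(X:100,Y:100);")
        hist = make_history(
            tree,
            [FT, NON, FT],
            [Event(1, 40.0, FT, NON), Event(1, 70.0, NON, FT), Event(1, 90.0, FT, NON)],
        )
        # dwelling in FT: 40 + (90-70) + 100 (branch Y) = 160; 2 FT->NON events
        m = nm.build_rate_matrix({"FT->NON": 0.0174, "FT->SYM": 0.0, "SYM->NON": 0.0028})
        rates = nm.loss_rates(m, [hist])
        assert rates["realized_rates"]["FT->NON"]["mean"] == pytest.approx(2 / 160)

    def test_q_reading_and_ratio(self, toy_tree):
        m = nm.build_rate_matrix(
            {"FT->NON": 0.0174, "FT->SYM": 0.01, "SYM->NON": 0.0028}
        )
        hist = make_history(toy_tree, [FT] * 5)
        rates = nm.loss_rates(m, [hist])
        assert rates["q_rates"]["FT->NON"] == pytest.approx(0.0174)
        assert rates["q_rates"]["SYM->NON"] == pytest.approx(0.0028)
        assert rates["ft_to_sym_loss_ratio"] == pytest.approx(0.0174 / 0.0028)

    def test_zero_rate_never_realized(self, toy_tree):
        m = nm.build_rate_matrix({"FT->NON": 0.02, "FT->SYM": 0.01, "SYM->NON": 0.0})
        obs = TipObservations({"A": "nonnodulating", "B": "ft", "C": "sym"})
        maps = nm.stochastic_maps(toy_tree, obs, m, 40, seed=3)
        rates = nm.loss_rates(m, maps)
        assert rates["realized_rates"]["SYM->NON"]["mean"] == pytest.approx(0.0)

    def test_zero_dwell_excluded(self, toy_tree):
        m = nm.build_rate_matrix({"FT->NON": 0.02, "FT->SYM": 0.01, "SYM->NON": 0.001})
        # all-NON nodes except forced-FT root never dwell in SYM
        hist = make_history(toy_tree, [FT, FT, FT, FT, FT])
        rates = nm.loss_rates(m, [hist])
        assert rates["realized_rates"]["SYM->NON"]["n_excluded"] == 1


class TestAgeBounds:
    def test_bounds_and_spans(self):
        from nodulemap.transition_summary import TransitionRecord, transition_age_bounds

        trans = [
            TransitionRecord(1, "b1", FT, SYM, 46.0, 41.0),
            TransitionRecord(2, "b2", FT, NON, 59.0, 30.0),
            TransitionRecord(3, "b3", FT, NON, 24.0, 0.0),
        ]
        per, spans = transition_age_bounds(trans)
        assert per[0] == {"branch": "b1", "class": "FT->SYM", "max_age": 46.0, "min_age": 41.0}
        assert per[2]["min_age"] == 0.0  # pendant branch reaches the present
        assert spans["FT->NON"] == {"oldest_max_age": 59.0, "youngest_max_age": 24.0}
        # single-transition class: span degenerates to that age
        assert spans["FT->SYM"] == {"oldest_max_age": 46.0, "youngest_max_age": 46.0}


class TestSummaryReport:
    def test_end_to_end_report(self, default_model):
        tree = nm.simulate_chronogram(25, 0.3, 0.0, seed=5, crown_height=60.0)
        hist, tips = nm.simulate_history_forward(tree, default_model, FT, seed=6)
        obs = nm.mask_observations(tips, 0.0, 0.0, seed=7)
        maps = nm.stochastic_maps(tree, obs, default_model, 60, seed=8)
        rep = summarize(maps, default_model)
        np.testing.assert_allclose(rep.node_state_proportions.sum(axis=1), 1.0)
        assert sum(rep.counts_by_class.values()) == len(rep.transitions)
        assert rep.n_losses == rep.losses_by_source["FT"] + rep.losses_by_source["SYM"]
        d = rep.to_json_dict()
        assert d["n_histories"] == 60
        # annotated newick must re-parse with the same tip set
        t2 = nm.read_chronogram(rep.annotated_newick())
        assert sorted(t2.tip_labels) == sorted(tree.tip_labels)
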