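"""Summaries of mapped histories: node pies, branch transitions, rates, ages.

Collapses a set of stochastic maps into the quantities reported in a
comparative analysis of nodule-type evolution:

* per-node state proportions across histories (the "pie charts");
* majority-rule branch transitions — one transition on every branch whose
  parent and child have different modal states, with its age bounds (the
  event lies somewhere on the branch, between the parent's and the child's
  age); sibling branches count separately, so a parent in FT with both
  children in NON yields two simultaneous "double losses";
* per-history event-count distributions by transition class;
* loss rates per Myr under two readings: the fitted Q entries (primary)
  and realized per-history rates (events divided by dwelling time in the
  source state).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctmc_core import NON, STATES, TransitionModel
from .stochastic_mapper import MappedHistory, dwelling_times
from .treedata_io import Chronogram, write_newick

__all__ = [
    "TransitionRecord",
    "SummaryReport",
    "node_state_frequencies",
    "majority_transitions",
    "event_count_distribution",
    "loss_rates",
    "transition_age_bounds",
    "summarize",
]

CLASSES = ("FT->NON", "SYM->NON", "FT->SYM")


def _class_label(a: int, b: int) -> str:
    lab = f"{STATES[a]}->{STATES[b]}"
    return lab if lab in CLASSES else "other"


@dataclass
class TransitionRecord:
    """A majority-rule transition on one branch, with its age bounds."""

    branch: int  # child node index
    branch_label: str
    from_state: int
    to_state: int
    parent_age: float  # max age of the event (Myr)
    child_age: float  # min age of the event (Myr)

    @property
    def klass(self) -> str:
        return _class_label(self.from_state, self.to_state)


def _check_same_tree(histories: list[MappedHistory]) -> Chronogram:
    if not histories:
        raise ValueError("need at least one history")
    tree = histories[0].tree
    for h in histories[1:]:
        if h.tree is not tree and (
            h.tree.n_nodes != tree.n_nodes or h.tree.labels != tree.labels
        ):
            raise ValueError("histories were mapped on different trees")
    return tree


def node_state_frequencies(histories: list[MappedHistory]) -> np.ndarray:
    """(n_nodes, 3) fraction of histories in which each node is in each state."""
    tree = _check_same_tree(histories)
    counts = np.zeros((tree.n_nodes, 3))
    for h in histories:
        counts[np.arange(tree.n_nodes), h.node_state] += 1.0
    return counts / len(histories)


def _modal_states(freqs: np.ndarray, tie_tol: float = 1e-12) -> tuple[np.ndarray, list[int]]:
    """Modal state per node; nodes whose top two proportions tie are flagged."""
    order = np.argsort(freqs, axis=1)
    modal = order[:, -1]
    ties = [
        i
        for i in range(freqs.shape[0])
        if abs(freqs[i, order[i, -1]] - freqs[i, order[i, -2]]) <= tie_tol
    ]
    return modal, ties


def majority_transitions(
    freqs: np.ndarray,
    tree: Chronogram,
) -> tuple[list[TransitionRecord], dict[str, int], list[int]]:
    """Branch transitions between majority (modal) node states.

    Returns ``(transitions, counts_by_class, unresolved_branches)``.  A node
    whose top two state proportions are exactly tied is treated as ambiguous
    and its incident branches are reported unresolved rather than guessed.
    """
    modal, ties = _modal_states(freqs)
    tied = set(ties)
    transitions: list[TransitionRecord] = []
    unresolved: list[int] = []
    for c in range(1, tree.n_nodes):
        p = tree.parent[c]
        if c in tied or p in tied:
            unresolved.append(c)
            continue
        if modal[p] != modal[c]:
            transitions.append(
                TransitionRecord(
                    branch=c,
                    branch_label=tree.labels[c],
                    from_state=int(modal[p]),
                    to_state=int(modal[c]),
                    parent_age=float(tree.node_age[p]),
                    child_age=float(tree.node_age[c]),
                )
            )
    counts: dict[str, int] = {}
    for t in transitions:
        counts[t.klass] = counts.get(t.klass, 0) + 1
    return transitions, counts, unresolved


def event_count_distribution(
    histories: list[MappedHistory],
) -> dict[str, dict[int, float]]:
    """Per transition class, the empirical distribution of events per history."""
    _check_same_tree(histories)
    classes: set[str] = set(CLASSES)
    per_hist: list[dict[str, int]] = []
    for h in histories:
        counts: dict[str, int] = {}
        for e in h.events:
            k = _class_label(e.from_state, e.to_state)
            counts[k] = counts.get(k, 0) + 1
            classes.add(k)
        per_hist.append(counts)
    dist: dict[str, dict[int, float]] = {}
    n = len(histories)
    for k in sorted(classes):
        vals = [c.get(k, 0) for c in per_hist]
        uniq, cnt = np.unique(vals, return_counts=True)
        dist[k] = {int(u): float(c) / n for u, c in zip(uniq, cnt)}
    return dist


def loss_rates(
    model: TransitionModel,
    histories: list[MappedHistory],
) -> dict:
    """Loss rates per Myr under the two readings.

    ``q_rates`` (primary) are the fitted instantaneous rates from Q;
    ``realized_rates`` divide each history's event count by its dwelling
    time in the source state, summarized by mean and 2.5/97.5 percentiles.
    Histories with zero dwelling time in a source state are excluded from
    that class's realized rate, with the exclusion count reported.
    """
    _check_same_tree(histories)
    q_rates = {
        "FT->NON": model.rate("FT", "NON"),
        "SYM->NON": model.rate("SYM", "NON"),
        "FT->SYM": model.rate("FT", "SYM"),
    }
    ratio = (
        q_rates["FT->NON"] / q_rates["SYM->NON"]
        if q_rates["SYM->NON"] > 0
        else float("inf")
    )
    realized: dict[str, dict] = {}
    dwell = np.array([dwelling_times(h) for h in histories])
    for k in CLASSES:
        a, b = (STATES.index(s) for s in k.split("->"))
        vals = []
        excluded = 0
        for h, hist in enumerate(histories):
            d = dwell[h, a]
            if d <= 0.0:
                excluded += 1
                continue
            vals.append(hist.count_events(a, b) / d)
        arr = np.asarray(vals)
        realized[k] = {
            "mean": float(arr.mean()) if arr.size else float("nan"),
            "q2.5": float(np.percentile(arr, 2.5)) if arr.size else float("nan"),
            "q97.5": float(np.percentile(arr, 97.5)) if arr.size else float("nan"),
            "n_histories": int(arr.size),
            "n_excluded": excluded,
        }
    return {"q_rates": q_rates, "ft_to_sym_loss_ratio": ratio, "realized_rates": realized}


def transition_age_bounds(
    transitions: list[TransitionRecord],
) -> tuple[list[dict], dict[str, dict]]:
    """Per-transition (max_age, min_age) plus per-class spans of the max ages.

    A transition on a branch happened between the parent's age (max) and the
    child's age (min); a class's span runs from the oldest to the youngest
    maximum age across its branches.
    """
    per_transition = [
        {
            "branch": t.branch_label,
            "class": t.klass,
            "max_age": t.parent_age,
            "min_age": t.child_age,
        }
        for t in transitions
    ]
    spans: dict[str, dict] = {}
    for t in transitions:
        s = spans.setdefault(t.klass, {"oldest_max_age": -np.inf, "youngest_max_age": np.inf})
        s["oldest_max_age"] = max(s["oldest_max_age"], t.parent_age)
        s["youngest_max_age"] = min(s["youngest_max_age"], t.parent_age)
    return per_transition, spans


@dataclass
class SummaryReport:
    """Machine-readable analogue of the headline trait-evolution results."""

    tree: Chronogram
    n_histories: int
    node_state_proportions: np.ndarray
    transitions: list[TransitionRecord]
    counts_by_class: dict[str, int]
    unresolved_branches: list[int]
    event_counts: dict[str, dict[int, float]]
    rates: dict
    age_bounds: list[dict] = field(default_factory=list)
    age_spans: dict[str, dict] = field(default_factory=dict)

    @property
    def n_losses(self) -> int:
        """Transitions into the nonnodulating state, from any ancestry."""
        return sum(1 for t in self.transitions if t.to_state == NON)

    @property
    def losses_by_source(self) -> dict[str, int]:
        out = {"FT": 0, "SYM": 0}
        for t in self.transitions:
            if t.to_state == NON:
                out[STATES[t.from_state]] = out.get(STATES[t.from_state], 0) + 1
        return out

    @property
    def n_ft_to_sym(self) -> int:
        return self.counts_by_class.get("FT->SYM", 0)

    def to_json_dict(self) -> dict:
        return {
            "n_histories": self.n_histories,
            "counts_by_class": self.counts_by_class,
            "n_losses": self.n_losses,
            "losses_by_source": self.losses_by_source,
            "n_ft_to_sym": self.n_ft_to_sym,
            "unresolved_branches": [self.tree.labels[i] for i in self.unresolved_branches],
            "rates": self.rates,
            "event_count_distribution": {
                k: {str(c): f for c, f in d.items()}
                for k, d in self.event_counts.items()
            },
            "transitions": self.age_bounds,
            "age_spans": self.age_spans,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_json_dict(), indent=2, **kwargs)

    def node_proportions_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.node_state_proportions, columns=list(STATES))
        df.insert(0, "node_id", self.tree.labels)
        df.insert(1, "node_age", self.tree.node_age)
        return df

    def transitions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "branch_id": t.branch_label,
                    "from_state": STATES[t.from_state],
                    "to_state": STATES[t.to_state],
                    "class": t.klass,
                    "max_age": t.parent_age,
                    "min_age": t.child_age,
                }
                for t in self.transitions
            ],
            columns=["branch_id", "from_state", "to_state", "class", "max_age", "min_age"],
        )

    def annotated_newick(self) -> str:
        """Newick with modal states appended to internal node labels."""
        modal, _ = _modal_states(self.node_state_proportions)
        labels = {
            i: f"{self.tree.labels[i]}_{STATES[modal[i]]}"
            for i in range(self.tree.n_nodes)
            if not self.tree.is_tip[i]
        }
        return write_newick(self.tree, node_labels=labels)


def summarize(
    histories: list[MappedHistory],
    model: TransitionModel,
) -> SummaryReport:
    """Full summary of a set of mapped histories under their fitted model."""
    tree = _check_same_tree(histories)
    freqs = node_state_frequencies(histories)
    transitions, counts, unresolved = majority_transitions(freqs, tree)
    per_transition, spans = transition_age_bounds(transitions)
    return SummaryReport(
        tree=tree,
        n_histories=len(histories),
        node_state_proportions=freqs,
        transitions=transitions,
        counts_by_class=counts,
        unresolved_branches=unresolved,
        event_counts=event_count_distribution(histories),
        rates=loss_rates(model, histories),
        age_bounds=per_transition,
        age_spans=spans,
    )
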