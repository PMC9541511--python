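"""Synthetic chronograms and trait data for testing the whole pipeline.

The generator emulates the statistical structure the analysis assumes: an
ultrametric birth-death chronogram in Myr, tip states produced by forward
simulation of the three-state nodulation CTMC from a known root state, and
random masking of tips into the two partially observed categories
("unknown" status, "nodulating but of unknown type").  The true history is
retained before masking, so recovery of states, transitions and rates can
be scored against ground truth.

The default scenario mirrors the scale of the empirical study system: 150
genus-level tips, ~60 Myr crown age, root in the fixation-thread state, and
loss rates of 0.0174 (FT) and 0.0028 (SYM) events/Myr with a small FT->SYM
gain rate of 0.002/Myr chosen to yield on the order of one or two gains per
tree.  These defaults are a construction for testing, not estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .ctmc_core import FT, NON, SYM, STATES, TransitionModel, build_rate_matrix
from .stochastic_mapper import Event, MappedHistory, histories_to_tables
from .treedata_io import (
    Chronogram,
    TipObservations,
    read_chronogram,
    write_newick,
)

__all__ = [
    "SyntheticScenario",
    "simulate_chronogram",
    "simulate_history_forward",
    "mask_observations",
    "make_benchmark",
    "true_branch_transitions",
]

_STATE_TO_CATEGORY = {NON: "nonnodulating", FT: "ft", SYM: "sym"}


@dataclass
class SyntheticScenario:
    """Everything needed to generate one benchmark dataset."""

    n_tips: int = 150
    birth: float = 0.15  # lineages per lineage per Myr
    death: float = 0.05
    crown_height: float | None = 60.0  # rescale tree to this crown age (Myr)
    rates: dict = field(
        default_factory=lambda: {
            "FT->NON": 0.0174,
            "FT->SYM": 0.002,
            "SYM->NON": 0.0028,
        }
    )
    root_state: int = FT
    p_unknown: float = 0.10
    p_type_unknown: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if not self.birth > self.death >= 0:
            raise ValueError("need birth > death >= 0")
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("rates must be non-negative")
        for p in (self.p_unknown, self.p_type_unknown):
            if not 0.0 <= p <= 1.0:
                raise ValueError("masking fractions must lie in [0, 1]")
        if self.p_unknown + self.p_type_unknown > 1.0:
            raise ValueError("p_unknown + p_type_unknown must be <= 1")

    def model(self) -> TransitionModel:
        prior = np.zeros(3)
        prior[self.root_state] = 1.0
        return build_rate_matrix(self.rates, root_prior=prior)


def simulate_chronogram(
    n_tips: int,
    birth: float,
    death: float,
    seed: int,
    *,
    crown_height: float | None = None,
    max_restarts: int = 10_000,
) -> Chronogram:
    """Birth-death chronogram with exactly ``n_tips`` extant tips.

    Gillespie simulation from a crown pair of lineages, stopped the moment
    the extant count reaches ``n_tips``; runs that go extinct are discarded
    and regenerated (simple rejection, adequate at these scales).  Extinct
    lineages are pruned, so the result is ultrametric.  ``crown_height``
    optionally rescales all branch lengths to a target crown age in Myr.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not birth > death >= 0:
        raise ValueError("birth rate must exceed death rate (death >= 0)")
    rng = np.random.default_rng(seed)

    for _ in range(max_restarts):
        # node records: parent, birth time, death time (None while extant)
        parent = [-1, 0, 0]
        t_birth = [0.0, 0.0, 0.0]
        t_end: list[float | None] = [0.0, None, None]
        extant = [1, 2]
        t = 0.0
        failed = False
        while len(extant) < n_tips:
            k = len(extant)
            if k == 0:
                failed = True
                break
            t += rng.exponential(1.0 / (k * (birth + death)))
            idx = extant[rng.integers(k)]
            if rng.random() < birth / (birth + death):
                t_end[idx] = t
                extant.remove(idx)
                for _ in range(2):
                    parent.append(idx)
                    t_birth.append(t)
                    t_end.append(None)
                    extant.append(len(parent) - 1)
            else:
                t_end[idx] = t
                extant.remove(idx)
        if failed:
            continue
        # observe the tree just before the next event would occur, so the
        # n-tip interval has positive duration (needed e.g. for n_tips = 2)
        t_present = t + rng.exponential(1.0 / (n_tips * (birth + death)))
        extant_set = set(extant)
        for i in extant:
            t_end[i] = t_present

        # keep only nodes with extant descendants; collapse unifurcations
        children: list[list[int]] = [[] for _ in parent]
        for i, p in enumerate(parent):
            if p >= 0:
                children[p].append(i)

        labels = iter(f"t{i}" for i in range(1, n_tips + 1))

        def render(i: int, start: float) -> str | None:
            if not children[i]:
                if i not in extant_set:
                    return None
                return f"{next(labels)}:{t_end[i] - start:.12g}"
            subs = [render(c, t_end[i]) for c in children[i]]
            subs = [s for s in subs if s is not None]
            if not subs:
                return None
            if len(subs) == 1:  # unifurcation: extend the child branch
                name, _, rest = subs[0].rpartition(":")
                return f"{name}:{float(rest) + (t_end[i] - start):.12g}"
            return f"({','.join(subs)}):{t_end[i] - start:.12g}"

        body = render(0, 0.0)
        assert body is not None
        newick = body.rsplit(":", 1)[0] + ";"
        tree = read_chronogram(newick, ultrametric_tol=1e-6)
        if crown_height is not None:
            scale = crown_height / tree.height
            tree = Chronogram(
                tree.parent,
                tree.children,
                tree.branch_length * scale,
                tree.labels,
                tree.is_tip,
            )
        return tree
    raise RuntimeError(
        f"no surviving tree with {n_tips} tips in {max_restarts} attempts"
    )


def simulate_history_forward(
    tree: Chronogram,
    model: TransitionModel,
    root_state: int,
    seed: int,
) -> tuple[MappedHistory, dict[str, int]]:
    """Unconditioned forward CTMC realization from ``root_state`` down the tree.

    Exponential waiting times at the current state's total exit rate, jump
    targets proportional to the off-diagonal rates.  Returns the full true
    history and the resulting tip states (taxon -> state index).
    """
    if model.root_prior[root_state] <= 0:
        raise ValueError("root_state has zero prior support under the model")
    rng = np.random.default_rng(seed)
    Q = model.Q
    states = np.empty(tree.n_nodes, dtype=np.int64)
    states[0] = root_state
    events: list[Event] = []
    for c in range(1, tree.n_nodes):
        s = int(states[tree.parent[c]])
        bl = float(tree.branch_length[c])
        t = 0.0
        while True:
            exit_rate = -Q[s, s]
            if exit_rate <= 0.0:
                break
            t += rng.exponential(1.0 / exit_rate)
            if t >= bl:
                break
            w = Q[s].copy()
            w[s] = 0.0
            cw = np.cumsum(w)
            nxt = int(np.searchsorted(cw, rng.random() * cw[-1], side="right"))
            events.append(Event(c, t, s, nxt))
            s = nxt
        states[c] = s
    history = MappedHistory(tree=tree, node_state=states, events=events)
    tip_states = {tree.labels[i]: int(states[i]) for i in tree.tip_indices}
    return history, tip_states


def mask_observations(
    tip_states: dict[str, int],
    p_unknown: float,
    p_type_unknown: float,
    seed: int,
) -> TipObservations:
    """Randomly degrade true tip states into observation categories.

    Each tip independently becomes ``unknown`` with probability
    ``p_unknown``; otherwise, if its true state is a nodulating one (FT or
    SYM), it becomes ``nodulating_unknown_type`` with probability
    ``p_type_unknown``; otherwise it keeps its true category.  Masking never
    touches the underlying truth, only the observation layer.
    """
    rng = np.random.default_rng(seed)
    cats: dict[str, str] = {}
    for taxon in sorted(tip_states):
        s = tip_states[taxon]
        u = rng.random(2)
        if u[0] < p_unknown:
            cats[taxon] = "unknown"
        elif s in (FT, SYM) and u[1] < p_type_unknown:
            cats[taxon] = "nodulating_unknown_type"
        else:
            cats[taxon] = _STATE_TO_CATEGORY[s]
    return TipObservations(cats)


def true_branch_transitions(history: MappedHistory) -> set[tuple[int, int, int]]:
    """Branch-level truth: (branch, parent_state, child_state) where they differ."""
    tree = history.tree
    return {
        (c, int(history.node_state[tree.parent[c]]), int(history.node_state[c]))
        for c in range(1, tree.n_nodes)
        if history.node_state[tree.parent[c]] != history.node_state[c]
    }


def make_benchmark(scenario: SyntheticScenario, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete benchmark bundle to ``out_dir``.

    Files: scenario.json, tree.nwk, traits.csv, truth_events.csv,
    truth_node_states.csv, model.json — enough to run the full pipeline and
    score recovery against truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree, history, obs = generate(scenario)
    paths = {
        "scenario": out / "scenario.json",
        "tree": out / "tree.nwk",
        "traits": out / "traits.csv",
        "truth_events": out / "truth_events.csv",
        "truth_node_states": out / "truth_node_states.csv",
        "model": out / "model.json",
    }
    paths["scenario"].write_text(json.dumps(asdict(scenario), indent=2))
    paths["tree"].write_text(write_newick(tree) + "\n")
    lines = ["taxon,status"]
    for taxon in sorted(obs.categories):
        lines.append(f"{taxon},{obs.categories[taxon]}")
    paths["traits"].write_text("\n".join(lines) + "\n")
    events, states = histories_to_tables([history])
    events.to_csv(paths["truth_events"], index=False)
    states.to_csv(paths["truth_node_states"], index=False)
    paths["model"].write_text(json.dumps(scenario.model().to_json_dict(), indent=2))
    return paths


def generate(
    scenario: SyntheticScenario,
) -> tuple[Chronogram, MappedHistory, TipObservations]:
    """In-memory benchmark: (tree, true history, masked observations).

    Sub-seeds for the tree, the trait history and the masking are derived
    deterministically from the scenario seed.
    """
    ss = np.random.SeedSequence(scenario.seed)
    s_tree, s_hist, s_mask = (int(s) % (2**31) for s in ss.generate_state(3))
    tree = simulate_chronogram(
        scenario.n_tips,
        scenario.birth,
        scenario.death,
        s_tree,
        crown_height=scenario.crown_height,
    )
    model = scenario.model()
    history, tip_states = simulate_history_forward(
        tree, model, scenario.root_state, s_hist
    )
    obs = mask_observations(
        tip_states, scenario.p_unknown, scenario.p_type_unknown, s_mask
    )
    return tree, history, obs
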