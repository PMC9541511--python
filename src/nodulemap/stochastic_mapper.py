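"""Stochastic character mapping: full trait histories conditional on tip data.

Each mapped history is one draw from the joint posterior of the character
process given the tips, the fitted rate matrix and the root prior:

1. node states are sampled jointly by a pre-order pass over the conditional
   likelihoods from the pruning recursion (root ~ prior x partial, each
   child ~ P[parent_state, .](branch) x partial);
2. each branch is then filled in with an endpoint-conditioned CTMC path
   sampled by uniformization, which is exact and stays efficient when the
   conditioned transition is rare (plain rejection sampling can become
   arbitrarily slow there, so it is kept only as a test oracle).

Histories are reproducible: the random stream for history ``i`` and branch
``b`` is keyed by ``(master_seed, i, b)``, independent of traversal order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .ctmc_core import (
    ImpossibleDataError,
    Partials,
    TransitionModel,
    compute_partials,
    expm_qt,
)
from .treedata_io import Chronogram, TipObservations

__all__ = [
    "Event",
    "MappedHistory",
    "PathSampler",
    "UnreachableEndpointError",
    "sample_joint_node_states",
    "sample_path",
    "stochastic_maps",
    "dwelling_times",
    "histories_to_tables",
]


class UnreachableEndpointError(ValueError):
    """Requested endpoint pair has zero probability under the model."""


class Event(NamedTuple):
    """One state change on a branch; ``time`` is Myr from the branch start."""

    node: int  # child node index identifying the branch
    time: float
    from_state: int
    to_state: int


@dataclass
class MappedHistory:
    """One full realization of the trait process on a tree."""

    tree: Chronogram
    node_state: np.ndarray  # int state per node
    events: list[Event]

    def events_on_branch(self, node: int) -> list[Event]:
        return [e for e in self.events if e.node == node]

    def count_events(self, a: int, b: int) -> int:
        return sum(1 for e in self.events if e.from_state == a and e.to_state == b)

    def validate(self, model: TransitionModel, atol: float = 1e-9) -> None:
        """Check chaining, ordering, allowed transitions and dwell balance."""
        per_branch: dict[int, list[Event]] = {}
        for e in self.events:
            per_branch.setdefault(e.node, []).append(e)
        for node, evs in per_branch.items():
            times = [e.time for e in evs]
            if times != sorted(times) or len(set(times)) != len(times):
                raise ValueError(f"events on branch {node} not strictly ordered")
            state = self.node_state[self.tree.parent[node]]
            for e in evs:
                if e.from_state != state:
                    raise ValueError(f"event chain broken on branch {node}")
                if not model.mask[e.from_state, e.to_state]:
                    raise ValueError(f"disallowed transition on branch {node}")
                state = e.to_state
            if state != self.node_state[node]:
                raise ValueError(f"final state mismatch on branch {node}")
        dwell = dwelling_times(self)
        if abs(dwell.sum() - self.tree.total_branch_length) > atol:
            raise ValueError("dwelling times do not sum to total tree length")


def sample_joint_node_states(
    tree: Chronogram,
    obs: TipObservations,
    model: TransitionModel,
    rng: np.random.Generator,
    partials: Partials | None = None,
) -> np.ndarray:
    """One exact draw from the joint posterior of node states given all tips.

    Ambiguous tips (unknown status or unknown nodule type) receive a concrete
    sampled state like any other node.
    """
    if partials is None:
        partials = compute_partials(tree, obs, model)
    L, pmats = partials.L, partials.pmats
    states = np.empty(tree.n_nodes, dtype=np.int64)
    u = rng.random(tree.n_nodes)
    w = model.root_prior * L[0]
    tot = w.sum()
    if tot <= 0.0:
        raise ImpossibleDataError("zero posterior mass at the root")
    states[0] = np.searchsorted(np.cumsum(w), u[0] * tot, side="right")
    for i in range(1, tree.n_nodes):
        w = pmats[i][states[tree.parent[i]]] * L[i]
        tot = w.sum()
        if tot <= 0.0:
            raise ImpossibleDataError(
                f"zero posterior mass at node '{tree.labels[i]}'"
            )
        states[i] = np.searchsorted(np.cumsum(w), u[i] * tot, side="right")
    return states


class PathSampler:
    """Endpoint-conditioned path sampler for one model, via uniformization.

    The CTMC is represented as a Poisson(mu*t) number of candidate jumps of
    the discrete chain R = I + Q/mu with mu = headroom * max_i |q_ii|; the
    jump count is drawn from its exact conditional distribution given the
    endpoints, jump states by a forward-backward pass over powers of R, and
    self-jumps (virtual events) are discarded.
    """

    def __init__(
        self,
        model: TransitionModel,
        *,
        headroom: float = 1.05,
        tail_mass: float = 1e-12,
    ) -> None:
        self.model = model
        self.tail_mass = tail_mass
        qmax = float(-model.Q.diagonal().min())
        self.mu = headroom * qmax
        if self.mu > 0.0:
            self.R = np.eye(3) + model.Q / self.mu
        else:
            self.R = np.eye(3)
        self._rpow = [np.eye(3), self.R]
        # states that can leave and later return; if a state cannot, an
        # a -> a branch is forced to carry zero events (fast path below)
        self._can_excurse = np.array(
            [
                any(model.mask[a, j] and model.reach[j, a] for j in range(3) if j != a)
                for a in range(3)
            ]
        )

    def rpow(self, n: int) -> np.ndarray:
        while len(self._rpow) <= n:
            self._rpow.append(self._rpow[-1] @ self.R)
        return self._rpow[n]

    def sample(self, a: int, b: int, t: float, rng: np.random.Generator) -> list[Event]:
        """Sample a path on [0, t] from state ``a`` to state ``b``.

        Returns timed (time, from, to) changes with ``node`` left as -1;
        callers attach the branch id.
        """
        if t < 0:
            raise ValueError("duration must be non-negative")
        if self.mu == 0.0 or t == 0.0:
            if a != b:
                raise UnreachableEndpointError(
                    f"{STATES_[a]}->{STATES_[b]} impossible "
                    f"(no rates or zero duration)"
                )
            return []
        if a == b and not self._can_excurse[a]:
            return []  # irreversibility forbids any excursion
        mu_t = self.mu * t
        # conditional jump-count weights: Poisson(mu t) pmf x R^n[a, b]
        weights = []
        pois = np.exp(-mu_t)  # pmf at n = 0
        cum_pois = pois
        n = 0
        while True:
            weights.append(pois * self.rpow(n)[a, b])
            if cum_pois >= 1.0 - self.tail_mass:
                break
            n += 1
            pois *= mu_t / n
            cum_pois += pois
        weights = np.asarray(weights)
        total = weights.sum()
        if total <= 0.0:
            raise UnreachableEndpointError(
                f"P[{STATES_[a]}, {STATES_[b]}]({t}) = 0: endpoint unreachable"
            )
        n_jumps = int(
            np.searchsorted(np.cumsum(weights), rng.random() * total, side="right")
        )
        if n_jumps == 0:
            return []
        # jump states by forward sampling against backward R powers
        seq = np.empty(n_jumps + 1, dtype=np.int64)
        seq[0] = a
        seq[n_jumps] = b
        for k in range(1, n_jumps):
            w = self.R[seq[k - 1]] * self.rpow(n_jumps - k)[:, b]
            cw = np.cumsum(w)
            seq[k] = np.searchsorted(cw, rng.random() * cw[-1], side="right")
        times = np.sort(rng.uniform(0.0, t, size=n_jumps))
        return [
            Event(-1, float(times[k]), int(seq[k]), int(seq[k + 1]))
            for k in range(n_jumps)
            if seq[k] != seq[k + 1]  # drop virtual self-jumps
        ]


STATES_ = ("NON", "FT", "SYM")


def sample_path(
    a: int,
    b: int,
    t: float,
    model: TransitionModel,
    rng: np.random.Generator,
) -> list[Event]:
    """Convenience wrapper: one endpoint-conditioned path draw."""
    return PathSampler(model).sample(a, b, t, rng)


def stochastic_maps(
    tree: Chronogram,
    obs: TipObservations,
    model: TransitionModel,
    n: int,
    seed: int,
) -> list[MappedHistory]:
    """Draw ``n`` independent mapped histories conditional on the tip data.

    Each history uses substreams keyed by (seed, history index) for node
    states and (seed, history index, branch id) for branch paths, so reruns
    with the same seed reproduce histories exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    partials = compute_partials(tree, obs, model)
    sampler = PathSampler(model)
    histories: list[MappedHistory] = []
    for h in range(n):
        rng_nodes = np.random.default_rng([seed, h])
        states = sample_joint_node_states(tree, obs, model, rng_nodes, partials)
        events: list[Event] = []
        for c in range(1, tree.n_nodes):
            a, b = int(states[tree.parent[c]]), int(states[c])
            bl = float(tree.branch_length[c])
            if a == b and not sampler._can_excurse[a]:
                continue  # forced empty; skip substream construction
            rng_branch = np.random.default_rng([seed, h, c])
            for e in sampler.sample(a, b, bl, rng_branch):
                events.append(Event(c, e.time, e.from_state, e.to_state))
        histories.append(MappedHistory(tree=tree, node_state=states, events=events))
    return histories


def dwelling_times(history: MappedHistory) -> np.ndarray:
    """Total time spent in each state, summed over branches (Myr).

    Sums to the total tree branch length.
    """
    tree = history.tree
    dwell = np.zeros(3)
    per_branch: dict[int, list[Event]] = {}
    for e in history.events:
        per_branch.setdefault(e.node, []).append(e)
    for c in range(1, tree.n_nodes):
        bl = float(tree.branch_length[c])
        state = int(history.node_state[tree.parent[c]])
        t0 = 0.0
        for e in sorted(per_branch.get(c, []), key=lambda e: e.time):
            dwell[state] += e.time - t0
            t0 = e.time
            state = e.to_state
        dwell[state] += bl - t0
    return dwell


def histories_to_tables(
    histories: list[MappedHistory],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize histories to (events, node_states) tables.

    Events: history_id, branch_id, time_from_branch_start, from_state,
    to_state.  Node states: history_id, node_id, state.  Branch and node ids
    are node labels of the shared tree.
    """
    tree = histories[0].tree
    ev_rows = []
    st_rows = []
    for h, hist in enumerate(histories):
        for e in hist.events:
            ev_rows.append(
                (h, tree.labels[e.node], e.time, STATES_[e.from_state],
                 STATES_[e.to_state])
            )
        for i in range(tree.n_nodes):
            st_rows.append((h, tree.labels[i], STATES_[hist.node_state[i]]))
    events = pd.DataFrame(
        ev_rows,
        columns=[
            "history_id",
            "branch_id",
            "time_from_branch_start",
            "from_state",
            "to_state",
        ],
    )
    states = pd.DataFrame(st_rows, columns=["history_id", "node_id", "state"])
    return events, states
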