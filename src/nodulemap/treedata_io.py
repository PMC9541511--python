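"""Chronogram and tip-trait input/output.

Trees are rooted, ultrametric chronograms with branch lengths in millions
of years (Myr); node ages are measured backwards from the present, so tips
sit at age 0.  Tip traits are one of five observation categories per taxon,
each mapped to a state-likelihood vector over the ordered state space
(NON, FT, SYM):

=========================  ===========
category                   vector
=========================  ===========
nonnodulating              (1, 0, 0)
ft                         (0, 1, 0)
sym                        (0, 0, 1)
nodulating_unknown_type    (0, 1, 1)
unknown                    (1, 1, 1)
=========================  ===========

``nodulating_unknown_type`` covers taxa known to nodulate but whose nodule
anatomy (fixation-thread vs symbiosome) is unrecorded; ``unknown`` covers
taxa whose nodulation status itself is unrecorded and places equal weight
on all three states.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Chronogram",
    "TipObservations",
    "ChronogramError",
    "TraitTableError",
    "DEFAULT_CATEGORY_VECTORS",
    "CATEGORY_ALIASES",
    "read_chronogram",
    "write_newick",
    "prune_to_representatives",
    "read_trait_table",
    "match_tips",
    "normalize_taxon",
]


class ChronogramError(ValueError):
    """Malformed or invalid input tree."""


class TraitTableError(ValueError):
    """Malformed or invalid trait table."""


def normalize_taxon(name: str) -> str:
    """Canonical taxon key: strip, collapse whitespace runs to underscores."""
    return "_".join(str(name).strip().split())


@dataclass
class Chronogram:
    """Rooted ultrametric tree stored as flat preorder arrays.

    Node 0 is the root and every child has a larger index than its parent,
    so iterating indices in reverse visits nodes in postorder.  Polytomies
    are permitted and handled natively downstream.
    """

    parent: np.ndarray  # int, -1 at the root
    children: list[list[int]]
    branch_length: np.ndarray  # Myr; 0.0 at the root
    labels: list[str]
    is_tip: np.ndarray  # bool
    node_age: np.ndarray = field(init=False)  # Myr before present

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.branch_length = np.asarray(self.branch_length, dtype=float)
        self.is_tip = np.asarray(self.is_tip, dtype=bool)
        self._recompute_ages()

    def _recompute_ages(self) -> None:
        n = self.n_nodes
        depth = np.zeros(n)
        for i in range(1, n):
            depth[i] = depth[self.parent[i]] + self.branch_length[i]
        height = depth[self.is_tip].max() if self.is_tip.any() else 0.0
        age = height - depth
        age[self.is_tip] = 0.0  # tips pinned at the present
        self.node_age = age

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def height(self) -> float:
        """Root age = tree height in Myr."""
        return float(self.node_age[0])

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_length[1:].sum())

    def postorder(self) -> range:
        return range(self.n_nodes - 1, -1, -1)

    def preorder(self) -> range:
        return range(self.n_nodes)

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths, in tip order."""
        n = self.n_nodes
        depth = np.zeros(n)
        for i in range(1, n):
            depth[i] = depth[self.parent[i]] + self.branch_length[i]
        return depth[self.is_tip]


def _from_dendropy(tree: dendropy.Tree) -> Chronogram:
    nodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    blen = np.zeros(n)
    children: list[list[int]] = [[] for _ in range(n)]
    labels: list[str] = [""] * n
    is_tip = np.zeros(n, dtype=bool)
    auto = 0
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            if nd.edge.length is None:
                raise ChronogramError(
                    "branch without a length encountered; chronograms require "
                    "branch lengths on every edge"
                )
            blen[i] = float(nd.edge.length)
        if nd.is_leaf():
            is_tip[i] = True
            labels[i] = normalize_taxon(nd.taxon.label)
        elif nd.label:
            labels[i] = normalize_taxon(nd.label)
        else:
            labels[i] = f"node{auto}"
            auto += 1
        if blen[i] < 0:
            raise ChronogramError(
                f"negative branch length {blen[i]} on the branch above "
                f"node '{labels[i]}'"
            )
    dup = pd.Series(np.array(labels)[is_tip])
    dups = dup[dup.duplicated()].tolist()
    if dups:
        raise ChronogramError(f"duplicate tip labels: {sorted(set(dups))}")
    return Chronogram(parent, children, blen, labels, is_tip)


def read_chronogram(newick_text: str, *, ultrametric_tol: float = 1e-3) -> Chronogram:
    """Parse a Newick chronogram and validate its invariants.

    Parameters
    ----------
    newick_text
        Newick string (or the contents of a Newick file).  Branch lengths
        are required; a basal polytomy is kept as a hard polytomy.
    ultrametric_tol
        Relative tolerance on root-to-tip path lengths: all tip depths must
        agree within ``ultrametric_tol * tree_height``.  Dating pipelines
        emit rounded lengths, hence the permissive default.

    Raises
    ------
    ChronogramError
        On parse failure, a negative branch length (naming the node), or a
        non-ultrametric tree (reporting the worst deviation).
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick_text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ChronogramError(f"could not parse Newick input: {exc}") from exc
    tree = _from_dendropy(dtree)
    if tree.n_tips < 2:
        raise ChronogramError("tree must have at least two tips")
    depths = tree.tip_depths()
    height = depths.max()
    if height <= 0:
        raise ChronogramError("tree has zero height")
    worst = float(np.max(np.abs(depths - height)))
    if worst > ultrametric_tol * height:
        raise ChronogramError(
            f"tree is not ultrametric: root-to-tip paths deviate by up to "
            f"{worst:.6g} Myr against height {height:.6g} "
            f"(tolerance {ultrametric_tol:g} x height)"
        )
    return tree


def write_newick(tree: Chronogram, *, node_labels: dict[int, str] | None = None) -> str:
    """Serialize to Newick.  ``node_labels`` overrides internal-node labels
    (used e.g. to annotate modal ancestral states)."""

    def render(i: int) -> str:
        if tree.is_tip[i]:
            body = tree.labels[i]
        else:
            inner = ",".join(render(c) for c in tree.children[i])
            lab = (node_labels or {}).get(i, tree.labels[i])
            body = f"({inner}){lab}"
        if tree.parent[i] < 0:
            return body
        return f"{body}:{tree.branch_length[i]:.12g}"

    return render(0) + ";"


def prune_to_representatives(tree: Chronogram, keep: set[str]) -> Chronogram:
    """Restrict the tree to the taxa in ``keep``.

    Unifurcating internal nodes left behind are collapsed by summing branch
    lengths, so all pairwise path lengths among kept tips are preserved.
    This mirrors pruning a densely sampled chronogram down to one
    representative per genus.
    """
    keep_norm = {normalize_taxon(k) for k in keep}
    tips = set(tree.tip_labels)
    missing = sorted(keep_norm - tips)
    if missing:
        raise ChronogramError(f"taxa not present in the tree: {missing}")
    if len(keep_norm) < 2:
        raise ChronogramError("need at least two taxa to keep")

    dtree = dendropy.Tree.get(
        data=write_newick(tree), schema="newick", preserve_underscores=True
    )
    dtree.retain_taxa_with_labels(sorted(keep_norm))
    out = io.StringIO()
    dtree.write(file=out, schema="newick", suppress_rooting=True,
                unquoted_underscores=True)
    return read_chronogram(out.getvalue(), ultrametric_tol=np.inf)


# --- tip traits -------------------------------------------------------------

DEFAULT_CATEGORY_VECTORS: dict[str, tuple[float, float, float]] = {
    "nonnodulating": (1.0, 0.0, 0.0),
    "ft": (0.0, 1.0, 0.0),
    "sym": (0.0, 0.0, 1.0),
    "nodulating_unknown_type": (0.0, 1.0, 1.0),
    "unknown": (1.0, 1.0, 1.0),
}

CATEGORY_ALIASES: dict[str, str] = {
    "non": "nonnodulating",
    "nonnodulating": "nonnodulating",
    "non-nodulating": "nonnodulating",
    "ft": "ft",
    "fixation_thread": "ft",
    "sym": "sym",
    "symbiosome": "sym",
    "nodulating_unknown_type": "nodulating_unknown_type",
    "nodulating": "nodulating_unknown_type",
    "unknown": "unknown",
    "uncertain": "unknown",
}


@dataclass
class TipObservations:
    """Per-taxon observation categories with derived likelihood vectors."""

    categories: dict[str, str]
    category_vectors: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_VECTORS)
    )

    def __post_init__(self) -> None:
        for cat in self.categories.values():
            if cat not in self.category_vectors:
                raise TraitTableError(f"unknown observation category '{cat}'")
        for cat, vec in self.category_vectors.items():
            v = np.asarray(vec, dtype=float)
            if v.shape != (3,) or (v < 0).any() or not v.any():
                raise TraitTableError(
                    f"category '{cat}' must map to a non-negative length-3 "
                    f"vector with at least one positive entry"
                )

    def __len__(self) -> int:
        return len(self.categories)

    def __contains__(self, taxon: str) -> bool:
        return normalize_taxon(taxon) in self.categories

    def vector(self, taxon: str) -> np.ndarray:
        return np.asarray(
            self.category_vectors[self.categories[normalize_taxon(taxon)]],
            dtype=float,
        )

    def likelihood_matrix(self, tree: Chronogram) -> np.ndarray:
        """(n_nodes, 3) tip conditional likelihoods; internal rows are 1."""
        L = np.ones((tree.n_nodes, 3))
        for i in tree.tip_indices:
            L[i] = self.vector(tree.labels[i])
        return L


def read_trait_table(
    csv_text: str,
    *,
    aliases: dict[str, str] | None = None,
    category_vectors: dict[str, tuple[float, float, float]] | None = None,
) -> TipObservations:
    """Read a taxon,status CSV into :class:`TipObservations`.

    ``status`` tokens are matched case-insensitively against the five-category
    vocabulary plus ``aliases``; ``category_vectors`` overrides the
    category-to-likelihood mapping (e.g. to give unknown-status taxa equal
    weight on nodulating vs nonnodulating instead of equal weight per state).
    """
    alias_map = dict(CATEGORY_ALIASES)
    if aliases:
        alias_map.update({k.strip().lower(): v for k, v in aliases.items()})
    try:
        df = pd.read_csv(io.StringIO(csv_text), dtype=str)
    except Exception as exc:
        raise TraitTableError(f"could not parse trait CSV: {exc}") from exc
    cols = {c.strip().lower() for c in df.columns}
    if not {"taxon", "status"} <= cols:
        raise TraitTableError(
            f"trait table must have 'taxon' and 'status' columns, got {sorted(cols)}"
        )
    df.columns = [c.strip().lower() for c in df.columns]
    categories: dict[str, str] = {}
    for row in df.itertuples(index=False):
        taxon = normalize_taxon(row.taxon)
        token = str(row.status).strip().lower().replace(" ", "_")
        if token not in alias_map:
            raise TraitTableError(
                f"unknown status '{row.status}' for taxon '{row.taxon}'"
            )
        if taxon in categories:
            raise TraitTableError(f"duplicate taxon '{taxon}' in trait table")
        categories[taxon] = alias_map[token]
    kwargs = {}
    if category_vectors is not None:
        merged = dict(DEFAULT_CATEGORY_VECTORS)
        merged.update(category_vectors)
        kwargs["category_vectors"] = merged
    return TipObservations(categories, **kwargs)


def match_tips(
    tree: Chronogram,
    obs: TipObservations,
    *,
    fill_unknown: bool = False,
) -> tuple[Chronogram, TipObservations, list[str]]:
    """Validate that every tip has an observation.

    Returns ``(tree, obs, unmatched_rows)`` where ``unmatched_rows`` lists
    table taxa absent from the tree (reported, never silently dropped).
    Tips without an observation raise unless ``fill_unknown`` is set, in
    which case they are scored ``unknown``.
    """
    tips = set(tree.tip_labels)
    have = set(obs.categories)
    missing = sorted(tips - have)
    unmatched = sorted(have - tips)
    if missing and not fill_unknown:
        raise TraitTableError(
            f"{len(missing)} tips lack a trait observation: {missing}"
        )
    if missing:
        cats = dict(obs.categories)
        for t in missing:
            cats[t] = "unknown"
        obs = TipObservations(cats, category_vectors=dict(obs.category_vectors))
    return tree, obs, unmatched
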