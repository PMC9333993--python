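"""Phylogeny representation, phylogenetic covariance matrices, and regime painting.

A :class:`Phylogeny` is a rooted tree with non-negative branch lengths in time
units. Every statistical module in the package consumes covariance structures
built here: the Brownian-motion matrix of shared path times, its Pagel's
:math:`\\lambda` transform, and the root-conditioned multi-optimum
Ornstein--Uhlenbeck covariance. Regime paintings map shift locations on
branches to a per-segment regime index, from which the Hansen-model weight
matrix (the expected contribution of each regime's optimum to each tip) is
computed.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "RegimePainting",
    "NewickFormatError",
    "TreeValidationError",
    "read_newick",
    "shared_path_times",
    "bm_vcv",
    "lambda_transform",
    "paint_regimes",
    "ou_weights",
    "ou_vcv",
    "prune_tree",
]


class NewickFormatError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


@dataclass
class Phylogeny:
    """Rooted tree stored as flat parent/length arrays.

    Nodes are indexed ``0 .. n_nodes-1`` in preorder with the root at index 0.
    ``parent[0] == -1``. ``length[i]`` is the branch length of the edge above
    node ``i`` (``length[0]`` is the root stem, usually 0). Tips carry labels;
    internal labels are preserved but unused.
    """

    parent: np.ndarray
    length: np.ndarray
    labels: dict[int, str]          # node index -> label (tips always present)
    children: list[list[int]] = field(repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.length = np.asarray(self.length, dtype=float)
        if not np.all(np.isfinite(self.length)) or np.any(self.length < 0):
            raise TreeValidationError("branch lengths must be finite and non-negative")
        if int(np.sum(self.parent < 0)) != 1 or self.parent[0] != -1:
            raise TreeValidationError("exactly one root (node 0) required")
        tips = self.tip_indices
        if len(tips) < 2:
            raise TreeValidationError("tree must have at least 2 tips")
        tip_labels = [self.labels[i] for i in tips]
        dupes = {l for l in tip_labels if tip_labels.count(l) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")

    # -- basic structure -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return 0

    @property
    def tip_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node (root stem excluded)."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):  # preorder: parent before child
            d[i] = d[self.parent[i]] + self.length[i]
        return d

    def ultrametricity(self) -> float:
        """Max relative spread of root-to-tip depths (0 for ultrametric trees)."""
        d = self.depths()[self.tip_indices]
        dmax = d.max()
        return float((d.max() - d.min()) / dmax) if dmax > 0 else 0.0

    def preorder(self) -> range:
        return range(self.n_nodes)

    def postorder(self) -> range:
        return range(self.n_nodes - 1, -1, -1)

    def path_to_root(self, node: int) -> list[int]:
        out = []
        while node != -1:
            out.append(node)
            node = self.parent[node]
        return out

    def tips_below(self) -> list[list[int]]:
        """For every node, the tip indices in its subtree."""
        below: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in self.postorder():
            if not self.children[i]:
                below[i] = [i]
            else:
                for c in self.children[i]:
                    below[i].extend(below[c])
        return below

    def branch_ids(self, include_root_stem: bool = False) -> list[int]:
        """Branch identifiers (a branch is named by the node below it)."""
        start = 0 if include_root_stem else 1
        return list(range(start, self.n_nodes))

    def to_newick(self, precision: int = 12) -> str:
        def fmt(i: int) -> str:
            lab = self.labels.get(i, "")
            if self.children[i]:
                inner = ",".join(fmt(c) for c in self.children[i])
                return f"({inner}){lab}:{self.length[i]:.{precision}g}"
            return f"{lab}:{self.length[i]:.{precision}g}"

        return fmt(self.root) + ";"


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Branch lengths absent from the string default to 0 with a warning.
    Comments (``[...]``) are ignored. Raises :class:`NewickFormatError` on
    malformed input and :class:`TreeValidationError` on duplicate tip labels.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickFormatError("empty Newick string")
    if text.count("(") != text.count(")"):
        raise NewickFormatError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,  # duplicates caught by our own validation
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy reports line/column in its message
        raise NewickFormatError(f"Newick parse failure: {exc}") from exc

    # flatten to preorder arrays
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    length = np.zeros(len(nodes))
    labels: dict[int, str] = {}
    children: list[list[int]] = [[] for _ in nodes]
    missing = 0
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
        if nd.edge.length is None:
            if nd.parent_node is not None:
                missing += 1
        else:
            length[i] = float(nd.edge.length)
        lab = nd.taxon.label if nd.taxon is not None else nd.label
        if lab:
            labels[i] = str(lab)
    if missing:
        warnings.warn(
            f"{missing} branch length(s) absent; defaulting to 0", stacklevel=2
        )
    tips = [i for i, ch in enumerate(children) if not ch]
    unlabeled = [i for i in tips if i not in labels]
    if unlabeled:
        raise NewickFormatError(f"{len(unlabeled)} tip(s) without labels")
    return Phylogeny(parent=parent, length=length, labels=labels, children=children)


# ---------------------------------------------------------------------------
# covariance construction


def _shared_times_arr(tree: Phylogeny) -> tuple[np.ndarray, list[str]]:
    tips = tree.tip_indices
    pos = {t: j for j, t in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))
    below = tree.tips_below()
    for node in range(1, tree.n_nodes):  # root stem contributes to nobody's depth
        idx = np.fromiter((pos[t] for t in below[node]), dtype=int)
        C[np.ix_(idx, idx)] += tree.length[node]
    return C, [tree.labels[t] for t in tips]


def shared_path_times(tree: Phylogeny) -> pd.DataFrame:
    """Matrix of shared root-to-MRCA path times t_ij; diagonal is tip depth T_i."""
    C, labels = _shared_times_arr(tree)
    return pd.DataFrame(C, index=labels, columns=labels)


def bm_vcv(tree: Phylogeny, rate: float = 1.0) -> pd.DataFrame:
    """Brownian-motion covariance: ``rate`` (variance per unit time) x shared times."""
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    return rate * shared_path_times(tree)


def lambda_transform(C: pd.DataFrame | np.ndarray, lam: float) -> pd.DataFrame | np.ndarray:
    """Pagel's lambda transform: multiply off-diagonal entries by lam in [0, 1].

    lam = 0 is the star-tree (no signal) limit; lam = 1 leaves the Brownian
    structure unchanged.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    arr = C.to_numpy() if isinstance(C, pd.DataFrame) else np.asarray(C, dtype=float)
    out = lam * arr
    np.fill_diagonal(out, np.diag(arr))
    if isinstance(C, pd.DataFrame):
        return pd.DataFrame(out, index=C.index, columns=C.columns)
    return out


# ---------------------------------------------------------------------------
# regime painting and OU structures


@dataclass
class RegimePainting:
    """Assignment of regimes to branch segments.

    ``shifts`` is a list of ``(branch_id, relative_position)`` pairs, at most
    one per branch; shift *i* opens regime *i + 1*. The regime at the root is
    regime 0 and every root-to-tip path induces a contiguous regime sequence.
    ``start_regime[b]`` / ``end_regime[b]`` give the regime at the rootward
    and tipward ends of branch *b*.
    """

    tree: Phylogeny
    shifts: list[tuple[int, float]]
    start_regime: np.ndarray
    end_regime: np.ndarray

    @property
    def k(self) -> int:
        return len(self.shifts)

    @property
    def n_regimes(self) -> int:
        return self.k + 1

    def tip_regimes(self) -> dict[str, int]:
        return {
            self.tree.labels[t]: int(self.end_regime[t]) for t in self.tree.tip_indices
        }

    def segments(self, tip: int) -> list[tuple[float, float, int]]:
        """Root-to-tip path as (t_start, t_end, regime) segments in absolute time."""
        depths = self.tree.depths()
        shift_on = {b: p for b, p in self.shifts}
        segs: list[tuple[float, float, int]] = []
        for node in reversed(self.tree.path_to_root(tip)):
            if node == self.tree.root:
                continue
            t0 = depths[self.tree.parent[node]]
            t1 = depths[node]
            if node in shift_on and t1 > t0:
                tm = t0 + shift_on[node] * (t1 - t0)
                segs.append((t0, tm, int(self.start_regime[node])))
                segs.append((tm, t1, int(self.end_regime[node])))
            else:
                segs.append((t0, t1, int(self.end_regime[node])))
        return segs


def paint_regimes(
    tree: Phylogeny, shifts: list[tuple[int, float]] | list[int]
) -> RegimePainting:
    """Paint regimes on a tree from a set of shifts.

    ``shifts`` may be branch ids (relative position defaults to 0.5) or
    ``(branch_id, position)`` pairs with position in [0, 1] measured from the
    rootward end. At most one shift per branch; the root stem cannot shift.
    """
    norm: list[tuple[int, float]] = []
    for s in shifts:
        if isinstance(s, (tuple, list)):
            b, p = int(s[0]), float(s[1])
        else:
            b, p = int(s), 0.5
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"shift position must be in [0, 1], got {p}")
        norm.append((b, p))
    branches = set(tree.branch_ids())
    seen: set[int] = set()
    for b, _ in norm:
        if b == tree.root:
            raise ValueError("shift on the root stem is not allowed")
        if b not in branches:
            raise ValueError(f"branch {b} does not exist")
        if b in seen:
            raise ValueError(f"two shifts on branch {b}")
        seen.add(b)

    regime_of = {b: i + 1 for i, (b, _) in enumerate(norm)}
    start = np.zeros(tree.n_nodes, dtype=int)
    end = np.zeros(tree.n_nodes, dtype=int)
    for node in tree.preorder():
        if node == tree.root:
            continue
        start[node] = end[tree.parent[node]]
        end[node] = regime_of.get(node, start[node])
    return RegimePainting(tree=tree, shifts=norm, start_regime=start, end_regime=end)


def ou_weights(
    tree: Phylogeny, painting: RegimePainting, alpha: float
) -> np.ndarray:
    """Hansen-model weight matrix W (tips x regimes).

    Row *i* gives the weight of each regime's optimum in the expectation of
    tip *i* under an OU process with attraction ``alpha``: the contribution of
    a path segment [a, b] is exp(-alpha (T_i - b)) - exp(-alpha (T_i - a)),
    and the residual root-state weight exp(-alpha T_i) is assigned to regime
    0 (the root is taken to sit at its regime's optimum). Rows sum to 1.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    tips = tree.tip_indices
    depths = tree.depths()
    W = np.zeros((len(tips), painting.n_regimes))
    for i, tip in enumerate(tips):
        T = depths[tip]
        for a, b, r in painting.segments(tip):
            W[i, r] += np.exp(-alpha * (T - b)) - np.exp(-alpha * (T - a))
        W[i, 0] += np.exp(-alpha * T)
    return W


def _ou_vcv_arr(C: np.ndarray, alpha: float, sigma2: float) -> np.ndarray:
    """Root-conditioned OU covariance from a shared-path-time matrix."""
    T = np.diag(C)
    D = T[:, None] + T[None, :] - 2.0 * C  # phylogenetic distance between tips
    V = (sigma2 / (2.0 * alpha)) * np.exp(-alpha * D) * (-np.expm1(-2.0 * alpha * C))
    return V


def ou_vcv(tree: Phylogeny, alpha: float, sigma2: float) -> pd.DataFrame:
    """Non-stationary (root-conditioned) OU covariance among tips.

    Cov(i, j) = sigma2/(2 alpha) exp(-alpha (T_i + T_j - 2 t_ij))
                (1 - exp(-2 alpha t_ij)).

    As alpha -> 0 this converges to sigma2 x shared path times (the Brownian
    limit); as alpha -> infinity tips decorrelate with variance
    sigma2 / (2 alpha).
    """
    if alpha <= 0 or sigma2 <= 0:
        raise ValueError(f"alpha and sigma2 must be > 0, got {alpha}, {sigma2}")
    C, labels = _shared_times_arr(tree)
    return pd.DataFrame(_ou_vcv_arr(C, alpha, sigma2), index=labels, columns=labels)


# ---------------------------------------------------------------------------
# pruning


def prune_tree(tree: Phylogeny, keep: set[str] | list[str]) -> Phylogeny:
    """Restrict a tree to a subset of tips.

    Degree-2 internal nodes created by the restriction are suppressed with
    branch lengths summed, so all pairwise shared path times among the kept
    tips — and their root-to-tip depths — are preserved exactly. The original
    root is retained (possibly with a single child) so that depths do not
    change.
    """
    keep = set(keep)
    have = set(tree.tip_labels)
    unknown = keep - have
    if unknown:
        raise ValueError(f"unknown tip labels: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("must keep at least 2 tips")

    keep_node = np.zeros(tree.n_nodes, dtype=bool)
    for i in tree.postorder():
        if not tree.children[i]:
            keep_node[i] = tree.labels.get(i) in keep
        else:
            keep_node[i] = any(keep_node[c] for c in tree.children[i])

    # new preorder over kept nodes, suppressing unary non-root nodes
    parent_new: list[int] = []
    length_new: list[float] = []
    labels_new: dict[int, str] = {}
    children_new: list[list[int]] = []

    def add(node: int, parent_idx: int, carried: float) -> None:
        kept_children = [c for c in tree.children[node] if keep_node[c]]
        is_root = parent_idx == -1
        if len(kept_children) == 1 and not is_root:
            # suppress: pass accumulated length to the single kept child
            add(kept_children[0], parent_idx, carried + tree.length[kept_children[0]])
            return
        idx = len(parent_new)
        parent_new.append(parent_idx)
        length_new.append(carried)
        children_new.append([])
        if parent_idx >= 0:
            children_new[parent_idx].append(idx)
        if node in tree.labels:
            labels_new[idx] = tree.labels[node]
        for c in kept_children:
            add(c, idx, tree.length[c])

    add(tree.root, -1, tree.length[tree.root])
    return Phylogeny(
        parent=np.array(parent_new),
        length=np.array(length_new),
        labels=labels_new,
        children=children_new,
    )
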