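"""Quartet topology weighting over window genealogies.

For three ingroup populations (Tapajos, Xingu, Belem) plus an outgroup
there are exactly three unrooted quartet topologies:

* topology 1 — Tapajos and Xingu sisters: (outgroup, Belem (Xingu, Tapajos))
* topology 2 — Xingu and Belem sisters:   (outgroup, Tapajos (Xingu, Belem))
* topology 3 — Tapajos and Belem sisters: (outgroup, Xingu (Belem, Tapajos))

A window genealogy is weighted by the fraction of one-tip-per-group
quartets whose induced subtree matches each topology.  Quartets are
resolved structurally: pairwise *topological* (unit-branch-length)
distances are computed after collapsing zero-length branches, and the
four-point condition on integers then identifies the split exactly.
Tied (star) quartets split their vote equally by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .matrix import MISSING, GenotypeMatrix

#: group order expected everywhere: (T, X, B, outgroup)
GROUP_ORDER = ("Tapajos", "Xingu", "Belem", "Outgroup")

# pairing of sample-1 with each other sample, in topology order:
# topology 1 pairs (g0,g1); topology 2 pairs (g1,g2); topology 3 pairs (g0,g2)


@dataclass
class TopologyWeights:
    weights: np.ndarray  # (w1, w2, w3), sums to 1
    n_quartets: int
    method: str  # "exact" | "montecarlo"


# ---------------------------------------------------------------------------
# quartet resolution
# ---------------------------------------------------------------------------
def quartet_from_distances(dm: np.ndarray) -> set[int]:
    """Four-point condition on a 4x4 matrix ordered (T, X, B, O).

    Returns the set of minimising topologies: a single topology when the
    within-pair sum is strictly minimal, a tie set otherwise.
    """
    s1 = dm[0, 1] + dm[2, 3]  # (T,X) | (B,O)
    s2 = dm[1, 2] + dm[0, 3]  # (X,B) | (T,O)
    s3 = dm[0, 2] + dm[1, 3]  # (T,B) | (X,O)
    sums = np.array([s1, s2, s3])
    lo = sums.min()
    return {i + 1 for i in range(3) if sums[i] <= lo + 1e-12}


def _collapse_zero_branches(tree: dendropy.Tree, eps: float = 1e-12) -> None:
    for edge in list(tree.preorder_edge_iter()):
        if edge.head_node is None or edge.tail_node is None:
            continue
        if edge.head_node.is_leaf():
            continue
        if edge.length is not None and edge.length <= eps:
            edge.collapse()


def topological_distances(
    tree: dendropy.Tree, collapse_eps: float | None = 1e-12
) -> tuple[np.ndarray, list[str]]:
    """Leaf x leaf path lengths counting every (non-collapsed) edge as 1."""
    t = tree.clone(depth=1)
    if collapse_eps is not None:
        _collapse_zero_branches(t, collapse_eps)
    adj: dict[int, list[int]] = {}
    leaf_of: dict[int, str] = {}
    ids: dict[dendropy.Node, int] = {}
    for node in t.preorder_node_iter():
        ids[node] = len(ids)
        adj[ids[node]] = []
    for node in t.preorder_node_iter():
        for child in node.child_nodes():
            adj[ids[node]].append(ids[child])
            adj[ids[child]].append(ids[node])
        if node.is_leaf():
            leaf_of[ids[node]] = node.taxon.label
    labels = sorted(leaf_of.values())
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n), dtype=np.int32)
    for src, lab in leaf_of.items():
        dist = {src: 0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    stack.append(v)
        for dst, lab2 in leaf_of.items():
            out[index[lab], index[lab2]] = dist[dst]
    return out, labels


def quartet_topology(
    tree_or_dm: dendropy.Tree | np.ndarray,
    labels: tuple[str, str, str, str] | None = None,
) -> set[int]:
    """Topology of a single quartet, from a 4-leaf tree or a 4x4 matrix.

    For trees, ``labels`` orders the four tips as (T, X, B, outgroup);
    with 4 tips the unit-distance four-point condition recovers the
    unique unrooted split, and a star quartet ties all three.
    """
    if isinstance(tree_or_dm, dendropy.Tree):
        dm, labs = topological_distances(tree_or_dm)
        if len(labs) != 4:
            raise ValueError("quartet tree must have exactly 4 leaves")
        order = labels if labels is not None else tuple(labs)
        idx = [labs.index(l) for l in order]
        dm = dm[np.ix_(idx, idx)]
    else:
        dm = np.asarray(tree_or_dm, dtype=float)
        if dm.shape != (4, 4):
            raise ValueError("distance matrix must be 4x4")
    return quartet_from_distances(dm)


# ---------------------------------------------------------------------------
# weights over a multi-tip tree
# ---------------------------------------------------------------------------
def _resolve_groups(
    tree: dendropy.Tree, groups: dict[str, list[str]], order: tuple[str, ...]
) -> tuple[np.ndarray, list[list[int]]]:
    dm, labels = topological_distances(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    members = []
    for g in order:
        if g not in groups or not groups[g]:
            raise ValueError(f"group {g!r} empty or absent")
        try:
            members.append([index[t] for t in groups[g]])
        except KeyError as e:
            raise ValueError(f"tip {e.args[0]!r} not in tree") from None
    return dm, members


def _tally(dm: np.ndarray, combos: np.ndarray, tie_mode: str) -> tuple[np.ndarray, int]:
    t, x, b, o = combos.T
    s = np.stack(
        [dm[t, x] + dm[b, o], dm[x, b] + dm[t, o], dm[t, b] + dm[x, o]]
    ).T.astype(float)
    lo = s.min(axis=1, keepdims=True)
    is_min = s <= lo + 1e-12
    n_min = is_min.sum(axis=1)
    votes = np.zeros(3)
    used = combos.shape[0]
    if tie_mode == "split":
        votes = (is_min / n_min[:, None]).sum(axis=0)
    elif tie_mode == "discard":
        keep = n_min == 1
        votes = is_min[keep].sum(axis=0).astype(float)
        used = int(keep.sum())
    else:
        raise ValueError("tie_mode must be 'split' or 'discard'")
    return votes, used


def weights_exact(
    tree: dendropy.Tree,
    groups: dict[str, list[str]],
    order: tuple[str, ...] = GROUP_ORDER,
    tie_mode: str = "split",
) -> TopologyWeights:
    """Enumerate every one-tip-per-group quartet and tally the votes."""
    dm, members = _resolve_groups(tree, groups, order)
    combos = np.array(list(itertools.product(*members)), dtype=np.int64)
    votes, used = _tally(dm, combos, tie_mode)
    total = votes.sum()
    w = votes / total if total > 0 else np.full(3, 1 / 3)
    return TopologyWeights(w, used, "exact")


def weights_mc(
    tree: dendropy.Tree,
    groups: dict[str, list[str]],
    n_samples: int,
    seed: int,
    order: tuple[str, ...] = GROUP_ORDER,
    tie_mode: str = "split",
) -> TopologyWeights:
    """Monte-Carlo weights: uniform quartet sampling with replacement."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    dm, members = _resolve_groups(tree, groups, order)
    combos = np.stack(
        [rng.choice(m, size=n_samples) for m in members], axis=1
    ).astype(np.int64)
    votes, used = _tally(dm, combos, tie_mode)
    total = votes.sum()
    w = votes / total if total > 0 else np.full(3, 1 / 3)
    return TopologyWeights(w, used, "montecarlo")


def weights_auto(
    tree: dendropy.Tree,
    groups: dict[str, list[str]],
    order: tuple[str, ...] = GROUP_ORDER,
    exact_limit: int = 50_000,
    mc_samples: int = 10_000,
    seed: int = 1,
) -> TopologyWeights:
    n_comb = int(np.prod([len(groups[g]) for g in order]))
    if n_comb <= exact_limit:
        return weights_exact(tree, groups, order)
    return weights_mc(tree, groups, mc_samples, seed, order)


# ---------------------------------------------------------------------------
# distance-based window trees
# ---------------------------------------------------------------------------
def hamming_distances(gm: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """Pairwise haplotype Hamming proportion over jointly called sites."""
    a = gm.alleles
    n = gm.n_haplotypes
    labels = [f"{gm.pops[i] if gm.pops else 'h'}:{i}" for i in range(n)]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (a[i] != MISSING) & (a[j] != MISSING)
            if ok.any():
                dm[i, j] = dm[j, i] = float(np.mean(a[i, ok] != a[j, ok]))
    return dm, labels


def nj_tree(gm_or_dm, labels: list[str] | None = None) -> dendropy.Tree:
    """Neighbor-joining window tree on Hamming distances.

    Accepts a :class:`GenotypeMatrix` (distances computed here) or a
    precomputed square matrix with ``labels``.  Negative branch lengths
    are clamped to zero.  An asymmetric matrix is an error.
    """
    if isinstance(gm_or_dm, GenotypeMatrix):
        if gm_or_dm.n_haplotypes < 4:
            raise ValueError("need at least 4 haplotypes")
        dm, labels = hamming_distances(gm_or_dm)
    else:
        dm = np.asarray(gm_or_dm, dtype=float)
        if labels is None:
            raise ValueError("labels required with a raw matrix")
        if not np.allclose(dm, dm.T):
            raise ValueError("distance matrix must be symmetric")
    sk = _skbio_nj(DistanceMatrix(dm, ids=labels), neg_as_zero=True)
    tree = dendropy.Tree.get(data=str(sk), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


def groups_from_matrix(gm: GenotypeMatrix) -> dict[str, list[str]]:
    """Tip-label groups matching :func:`nj_tree`'s labelling."""
    out: dict[str, list[str]] = {}
    for i, p in enumerate(gm.pops):
        out.setdefault(p, []).append(f"{p}:{i}")
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------
def weights_by_subset(
    weights: np.ndarray,
    subsets: dict[str, np.ndarray],
    n_boot: int = 1000,
    seed: int = 1,
) -> "pd.DataFrame":
    """Mean weight per topology per window subset with bootstrap CIs."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    w = np.asarray(weights, dtype=float)
    rows = []
    for name, idx in subsets.items():
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            raise ValueError(f"subset {name!r} is empty")
        sub = w[idx]
        boots = np.empty((n_boot, 3))
        for bi in range(n_boot):
            take = rng.integers(0, idx.size, size=idx.size)
            boots[bi] = sub[take].mean(axis=0)
        lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
        for t in range(3):
            rows.append(
                {
                    "subset": name,
                    "topology": t + 1,
                    "mean_weight": float(sub[:, t].mean()),
                    "ci_lo": float(lo[t]),
                    "ci_hi": float(hi[t]),
                    "n_windows": int(idx.size),
                }
            )
    return pd.DataFrame(rows)
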