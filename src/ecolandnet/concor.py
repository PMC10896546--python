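"""CONCOR blockmodelling: cohesive subgroups by convergence of iterated correlations.

Each node's structural profile is the concatenation of its row (ties sent)
and column (ties received) of the adjacency matrix. CONCOR correlates
profiles pairwise (excluding the self and mutual-tie positions of the pair,
the standard treatment), then repeatedly replaces the matrix with the
correlation matrix of its own rows until every off-diagonal entry converges
to +/-1; the sign pattern of the first row yields a bipartition. Recursive
application to depth 2 gives the four cohesive subgroups, summarized by a
block density matrix and its binary image under the alpha-density criterion
(alpha defaults to the overall network density).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gravity import TieNetwork

__all__ = [
    "ConcorError",
    "ConcorResult",
    "concor_split",
    "concor_tree",
    "subgroup_density",
    "image_matrix",
]

CONVERGENCE_TOL = 1e-6
MAX_ITER = 200


class ConcorError(RuntimeError):
    pass


@dataclass(frozen=True)
class ConcorResult:
    cities: Sequence[str]
    membership: dict[str, int]          # city -> subgroup id (1..2^depth)
    split_tree: tuple                   # nested tuples of city_id leaves
    density_matrix: np.ndarray
    image_matrix: np.ndarray
    alpha: float

    @property
    def n_groups(self) -> int:
        return len(set(self.membership.values()))

    def group_members(self, g: int) -> list[str]:
        return [c for c in self.cities if self.membership[c] == g]


def _pairwise_profile_corr(A: np.ndarray, nodes: Sequence[int]) -> np.ndarray:
    """Initial correlation matrix of send+receive profiles.

    For each pair (i, j) the profile positions belonging to i and j
    themselves (diagonal and mutual ties) are dropped before correlating.
    """
    n = A.shape[0]
    k = len(nodes)
    profiles = np.concatenate([A[nodes, :], A[:, nodes].T], axis=1).astype(float)
    C = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            i, j = nodes[a], nodes[b]
            mask = np.ones(2 * n, dtype=bool)
            mask[[i, j, n + i, n + j]] = False
            u, v = profiles[a][mask], profiles[b][mask]
            su, sv = u.std(), v.std()
            if su == 0 or sv == 0:
                C[a, b] = C[b, a] = np.nan
            else:
                C[a, b] = C[b, a] = float(np.corrcoef(u, v)[0, 1])
    return C


def _profile_degenerate(A: np.ndarray, node: int) -> bool:
    n = A.shape[0]
    prof = np.concatenate([A[node, :], A[:, node]]).astype(float)
    mask = np.ones(2 * n, dtype=bool)
    mask[[node, n + node]] = False
    return prof[mask].std() == 0


def _refine_bipartition(C0: np.ndarray, left: list[int], right: list[int],
                        max_pass: int = 20) -> tuple[list[int], list[int]]:
    """Move nodes whose mean initial-profile correlation favors the other block.

    The convergence of iterated correlations can strand individual nodes on
    the side of the dominant contrast even when their profile correlations
    clearly favor the other block; this deterministic consistency pass
    restores agreement with the initial correlation structure.
    """
    left, right = list(left), list(right)
    for _ in range(max_pass):
        moved = False
        for v in list(left) + list(right):
            own, other = (left, right) if v in left else (right, left)
            if len(own) == 1:
                continue
            own_c = np.mean([C0[v, w] for w in own if w != v])
            oth_c = np.mean([C0[v, w] for w in other])
            if oth_c > own_c:
                own.remove(v)
                other.append(v)
                moved = True
        if not moved:
            break
    return left, right


def concor_split(A: np.ndarray | TieNetwork,
                 nodes: Sequence[int] | None = None,
                 refine: bool = True) -> tuple[list[int], list[int]]:
    """One CONCOR bipartition of ``nodes`` (defaults to all) of the network.

    Returns two node-index lists; the block containing the lowest node index
    comes first. With ``refine`` (default) a consistency pass against the
    initial profile correlations reassigns nodes the sign convergence
    stranded on the wrong side. Zero-variance profiles are assigned by
    fallback (most correlated non-degenerate node's block, else the larger
    block) with a warning; non-convergence raises :class:`ConcorError`.
    """
    if isinstance(A, TieNetwork):
        A = A.A
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    nodes = list(range(n)) if nodes is None else list(nodes)
    if len(nodes) < 2:
        raise ConcorError("need at least two nodes to split")
    if len(nodes) == 2:
        return [nodes[0]], [nodes[1]]

    degenerate = [v for v in nodes if _profile_degenerate(A, v)]
    active = [v for v in nodes if v not in degenerate]
    if degenerate:
        warnings.warn(
            f"zero-variance profiles for nodes {degenerate}; "
            "assigned by fallback rule", stacklevel=2)
    if len(active) < 2:
        # nothing to correlate: split degenerates arbitrarily but deterministically
        half = len(nodes) // 2
        return nodes[:half], nodes[half:]

    C0 = _pairwise_profile_corr(A, active)
    # identical profiles give nan against everything only when constant;
    # within active set correlations are defined
    C = np.nan_to_num(C0, nan=0.0)
    for _ in range(MAX_ITER):
        if np.all(np.abs(np.abs(C - np.diag(np.diag(C))
                                + np.eye(len(active))) - 1) <= CONVERGENCE_TOL):
            break
        rows_std = C.std(axis=1)
        if np.any(rows_std == 0):
            raise ConcorError("constant row during CONCOR iteration")
        C = np.corrcoef(C)
    else:
        raise ConcorError(f"CONCOR did not converge within {MAX_ITER} iterations")

    left_pos = [a for a in range(len(active)) if C[0, a] > 0]
    right_pos = [a for a in range(len(active)) if C[0, a] <= 0]
    if refine and left_pos and right_pos:
        left_pos, right_pos = _refine_bipartition(
            np.nan_to_num(C0, nan=0.0), left_pos, right_pos)
    block1 = [active[a] for a in left_pos]
    block2 = [active[a] for a in right_pos]

    for v in degenerate:
        # most-correlated non-degenerate partner on the initial profiles
        best, best_corr = None, -np.inf
        n_full = A.shape[0]
        maskv = np.ones(2 * n_full, dtype=bool)
        profv = np.concatenate([A[v, :], A[:, v]])
        for w in active:
            mask = maskv.copy()
            mask[[v, w, n_full + v, n_full + w]] = False
            u, x = profv[mask], np.concatenate([A[w, :], A[:, w]])[mask]
            if u.std() == 0 or x.std() == 0:
                continue
            c = float(np.corrcoef(u, x)[0, 1])
            if c > best_corr:
                best, best_corr = w, c
        if best is not None:
            (block1 if best in block1 else block2).append(v)
        else:
            (block1 if len(block1) >= len(block2) else block2).append(v)

    block1.sort()
    block2.sort()
    if not block1 or not block2:
        raise ConcorError("CONCOR produced an empty block")
    if block2[0] < block1[0]:
        block1, block2 = block2, block1
    return block1, block2


def _tree(A: np.ndarray, nodes: list[int], depth: int):
    if depth == 0 or len(nodes) < 2:
        return tuple(nodes)
    try:
        left, right = concor_split(A, nodes)
    except ConcorError:
        if len(nodes) <= 3:  # tiny blocks may be structurally unsplittable
            return tuple(nodes)
        raise
    return (_tree(A, left, depth - 1), _tree(A, right, depth - 1))


def _leaves(tree) -> list[tuple]:
    if tree and isinstance(tree[0], tuple):
        return _leaves(tree[0]) + _leaves(tree[1])
    return [tree]


def _polish_groups(C0: np.ndarray, groups: list[list[int]],
                   max_pass: int = 20) -> list[list[int]]:
    """Leaf-level analogue of the bipartition refinement across all groups."""
    groups = [list(g) for g in groups]
    for _ in range(max_pass):
        moved = False
        for gi, g in enumerate(groups):
            for v in list(g):
                if len(g) == 1:
                    continue
                best_g = gi
                best_c = np.mean([C0[v, w] for w in g if w != v])
                for hj, h in enumerate(groups):
                    if hj == gi or not h:
                        continue
                    c = np.mean([C0[v, w] for w in h])
                    if c > best_c:
                        best_g, best_c = hj, c
                if best_g != gi:
                    g.remove(v)
                    groups[best_g].append(v)
                    moved = True
        if not moved:
            break
    return [sorted(g) for g in groups]


def concor_tree(net: TieNetwork, depth: int = 2,
                polish: bool = True) -> ConcorResult:
    """Recursive CONCOR to the given depth; groups labelled in canonical order.

    Leaf groups are numbered 1..2^depth by their smallest member city_id.
    With ``polish`` (default) the leaf partition gets the same
    initial-correlation consistency pass as each split, across all groups.
    The result carries the subgroup density matrix and its image under
    alpha = overall network density.
    """
    A = net.A
    n = net.n
    if n < 2 ** depth:
        raise ConcorError(f"need at least {2 ** depth} nodes for depth {depth}")
    cities = list(net.cities)
    tree = _tree(A.astype(float), list(range(n)), depth)
    leaves = _leaves(tree)
    if polish and len(leaves) > 1:
        C0 = np.nan_to_num(
            _pairwise_profile_corr(A.astype(float), list(range(n))), nan=0.0)
        polished = _polish_groups(C0, [list(leaf) for leaf in leaves])
        leaves = [tuple(g) for g in polished if g]
    leaves = sorted(leaves, key=lambda leaf: cities[min(leaf)])
    membership = {}
    for g, leaf in enumerate(leaves, start=1):
        for v in leaf:
            membership[cities[v]] = g
    dens = subgroup_density(net, membership)
    m = net.tie_count
    alpha = m / (n * (n - 1))
    img = image_matrix(dens, alpha)
    tree_cities = _map_tree(tree, cities)
    return ConcorResult(cities=cities, membership=membership,
                        split_tree=tree_cities, density_matrix=dens,
                        image_matrix=img, alpha=alpha)


def _map_tree(tree, cities):
    if tree and isinstance(tree[0], tuple):
        return (_map_tree(tree[0], cities), _map_tree(tree[1], cities))
    return tuple(cities[v] for v in tree)


def subgroup_density(net: TieNetwork, membership: dict[str, int]) -> np.ndarray:
    """Block density matrix: ties from group g to h over possible ties.

    Diagonal cells use n_g(n_g - 1) possible ties; a singleton diagonal cell
    is recorded as 0 (no possible ties).
    """
    cities = list(net.cities)
    groups = sorted(set(membership.values()))
    idx = {g: [i for i, c in enumerate(cities) if membership[c] == g]
           for g in groups}
    k = len(groups)
    D = np.zeros((k, k))
    for a, g in enumerate(groups):
        for b, h in enumerate(groups):
            block = net.A[np.ix_(idx[g], idx[h])]
            possible = (len(idx[g]) * (len(idx[g]) - 1) if g == h
                        else len(idx[g]) * len(idx[h]))
            D[a, b] = block.sum() / possible if possible else 0.0
    return D


def image_matrix(density: np.ndarray, alpha: float) -> np.ndarray:
    """Binary block image: 1 where block density >= alpha."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return (np.asarray(density) >= alpha).astype(int)
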