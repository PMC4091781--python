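"""Cell phylogenies from genotype matrices.

Somatic-variant genotypes are reduced to binary characters (reference vs.
variant allele present) — the biologically meaningful signal at validated
SNV sites. Distances between cells are mismatch fractions over sites
callable in both (pairwise deletion, since ~45% of sites are below the
coverage gate in WGA libraries). Trees are built by standard neighbor
joining (Saitou-Nei Q-criterion) with negative branch lengths clamped to
zero, branch support comes from a nonparametric bootstrap over loci, and a
symmetric two-state likelihood (Felsenstein pruning) scores fixed trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix
from .simulate import HET, HOMREF, HOMVAR

__all__ = [
    "DistanceMatrix",
    "Tree",
    "pairwise_distance",
    "neighbor_joining",
    "bootstrap_support",
    "two_state_loglik",
]


@dataclass
class DistanceMatrix:
    """Symmetric cell-by-cell distances with per-pair co-callable counts."""

    values: pd.DataFrame
    shared_sites: pd.DataFrame
    min_shared: int = 20

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def labels(self) -> list[str]:
        return [str(x) for x in self.values.index]

    def low_support_pairs(self) -> list[tuple[str, str]]:
        """Pairs whose co-callable site count fell below ``min_shared``."""
        out = []
        labels = self.labels
        s = self.shared_sites.to_numpy()
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                if s[i, j] < self.min_shared:
                    out.append((labels[i], labels[j]))
        return out


def _binary_states(matrix: GenotypeMatrix) -> np.ndarray:
    """Cells x loci array: 0 = reference, 1 = variant allele present,
    -1 = missing (no call)."""
    calls = matrix.calls.to_numpy()
    out = np.full(calls.shape, -1, dtype=np.int8)
    out[calls == HOMREF] = 0
    out[(calls == HET) | (calls == HOMVAR)] = 1
    return out


def pairwise_distance(matrix: GenotypeMatrix, min_shared: int = 20) -> DistanceMatrix:
    """Mismatch-fraction distances over sites callable in both cells."""
    if len(matrix.cells) < 3:
        raise ValueError("need >= 3 cells")
    states = _binary_states(matrix)
    present = states >= 0
    labels = [str(c) for c in matrix.cells]
    n = len(labels)
    dist = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        shared[i, i] = int(present[i].sum())
        for j in range(i + 1, n):
            both = present[i] & present[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"cells {labels[i]!r} and {labels[j]!r} share no callable sites"
                )
            d = float(np.mean(states[i, both] != states[j, both]))
            dist[i, j] = dist[j, i] = d
            shared[i, j] = shared[j, i] = m
    idx = pd.Index(labels)
    return DistanceMatrix(
        values=pd.DataFrame(dist, index=idx, columns=idx),
        shared_sites=pd.DataFrame(shared, index=idx, columns=idx),
        min_shared=min_shared,
    )


@dataclass
class Tree:
    """Unrooted tree over cell leaves.

    ``adjacency`` maps node -> neighbor -> branch length. Internal nodes
    have generated names; ``support`` maps a canonical leaf bipartition
    (the side not containing the alphabetically first leaf) to a bootstrap
    percentage in [0, 100].
    """

    adjacency: dict[str, dict[str, float]]
    leaves: frozenset[str]
    support: dict[frozenset, float] = field(default_factory=dict)

    def nodes(self) -> list[str]:
        return list(self.adjacency)

    def _split_leaves(self, node: str, away_from: str) -> frozenset:
        """Leaves on ``node``'s side of the edge (node, away_from)."""
        out: set[str] = set()
        stack = [(node, away_from)]
        while stack:
            cur, parent = stack.pop()
            if cur in self.leaves:
                out.add(cur)
            for nbr in self.adjacency[cur]:
                if nbr != parent:
                    stack.append((nbr, cur))
        return frozenset(out)

    def canonical_bipartition(self, leaf_side: Iterable[str]) -> frozenset:
        side = frozenset(leaf_side)
        anchor = min(self.leaves)
        return side if anchor not in side else self.leaves - side

    def bipartitions(self) -> set[frozenset]:
        """Canonical bipartitions of all internal edges (both sides >= 2)."""
        out: set[frozenset] = set()
        seen: set[frozenset] = set()
        for u, nbrs in self.adjacency.items():
            for v in nbrs:
                edge = frozenset((u, v))
                if edge in seen:
                    continue
                seen.add(edge)
                side = self._split_leaves(u, v)
                if 2 <= len(side) <= len(self.leaves) - 2:
                    out.add(self.canonical_bipartition(side))
        return out

    def to_newick(self, with_support: bool = False) -> str:
        """Serialize to Newick, rooted at an arbitrary internal node;
        bootstrap supports (if any) become internal node labels."""
        root = next(
            (n for n in self.adjacency if n not in self.leaves), next(iter(self.adjacency))
        )

        def fmt(node: str, parent: str | None) -> str:
            children = [n for n in self.adjacency[node] if n != parent]
            if not children:
                length = self.adjacency[node][parent] if parent is not None else 0.0
                return f"{node}:{length:.6g}"
            inner = ",".join(fmt(c, node) for c in sorted(children))
            label = ""
            if with_support and parent is not None:
                side = self._split_leaves(node, parent)
                key = self.canonical_bipartition(side)
                if key in self.support:
                    label = f"{self.support[key]:g}"
            if parent is None:
                return f"({inner}){label}"
            return f"({inner}){label}:{self.adjacency[node][parent]:.6g}"

        return fmt(root, None) + ";"


def neighbor_joining(dist: DistanceMatrix) -> Tree:
    """Standard neighbor joining with deterministic lexicographic tie-breaks.

    Negative branch-length estimates are clamped to zero. Internal nodes are
    ordered (for tie-breaking) by the alphabetically smallest leaf beneath
    them, so the result is invariant to input row order.
    """
    labels = dist.labels
    D = dist.values.to_numpy().astype(float)
    if not np.isfinite(D).all():
        raise ValueError("non-finite distances")
    n0 = len(labels)
    if n0 < 3:
        raise ValueError("need >= 3 taxa")

    # active nodes: id -> representative leaf (for deterministic ordering)
    ids = list(labels)
    rep = {l: l for l in labels}
    d: dict[tuple[str, str], float] = {}
    for i in range(n0):
        for j in range(i + 1, n0):
            d[(ids[i], ids[j])] = d[(ids[j], ids[i])] = D[i, j]

    adjacency: dict[str, dict[str, float]] = {l: {} for l in labels}
    counter = 0

    def add_edge(a: str, b: str, length: float) -> None:
        length = max(0.0, length)
        adjacency.setdefault(a, {})[b] = length
        adjacency.setdefault(b, {})[a] = length

    active = list(ids)
    while len(active) > 3:
        m = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best_key: tuple | None = None
        best_pair: tuple[str, str] | None = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * d[(a, b)] - r[a] - r[b]
                key = (q, *sorted((rep[a], rep[b])))
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (a, b)
        a, b = best_pair  # type: ignore[misc]
        counter += 1
        u = f"_nj{counter}"
        la = 0.5 * d[(a, b)] + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = d[(a, b)] - la
        add_edge(a, u, la)
        add_edge(b, u, lb)
        rep[u] = min(rep[a], rep[b])
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
            d[(u, c)] = d[(c, u)] = duc
        active = [c for c in active if c not in (a, b)] + [u]

    a, b, c = sorted(active, key=lambda x: rep[x])
    counter += 1
    center = f"_nj{counter}"
    add_edge(a, center, 0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)]))
    add_edge(b, center, 0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)]))
    add_edge(c, center, 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)]))
    return Tree(adjacency=adjacency, leaves=frozenset(labels))


def bootstrap_support(
    matrix: GenotypeMatrix,
    n_iter: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    min_shared: int = 1,
) -> Tree:
    """Neighbor-joining tree with nonparametric bootstrap branch support.

    Loci are resampled with replacement ``n_iter`` times; each replicate
    tree's bipartitions are tallied and reported as percentages on the tree
    built from the full matrix. Edges with support >= 75 are conventionally
    considered strong. Replicates in which some cell pair shares no callable
    resampled site are skipped (the denominator is successful replicates).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if len(matrix.cells) < 4:
        raise ValueError("need >= 4 cells for meaningful bipartition support")
    rng = np.random.default_rng(seed)
    main = neighbor_joining(pairwise_distance(matrix, min_shared=min_shared))
    counts: dict[frozenset, int] = {bp: 0 for bp in main.bipartitions()}
    n_loci = len(matrix.loci)
    successful = 0
    for _ in range(n_iter):
        cols = rng.integers(0, n_loci, size=n_loci)
        resampled = GenotypeMatrix(
            matrix.calls.iloc[:, cols], callable_threshold=matrix.callable_threshold
        )
        try:
            rep_tree = neighbor_joining(pairwise_distance(resampled, min_shared=min_shared))
        except ValueError:
            continue
        successful += 1
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    if successful == 0:
        raise ValueError("all bootstrap replicates failed")
    main.support = {bp: 100.0 * c / successful for bp, c in counts.items()}
    return main


def two_state_loglik(matrix: GenotypeMatrix, tree: Tree, rate: float) -> float:
    """Log-likelihood of the genotype matrix on a fixed tree under a
    symmetric two-state model (Felsenstein pruning).

    Branch transition probability is (1 - exp(-2*rate*t))/2 with stationary
    frequencies (0.5, 0.5); missing calls are marginalized. Characters are
    reference (0) vs. variant present (1).
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    leaf_order = {str(c): i for i, c in enumerate(matrix.cells)}
    if frozenset(leaf_order) != tree.leaves:
        raise ValueError("tree leaves do not match matrix cells")
    states = _binary_states(matrix)
    n_sites = states.shape[1]

    def transition(t: float) -> np.ndarray:
        change = 0.5 * (1.0 - np.exp(-2.0 * rate * t))
        stay = 1.0 - change
        return np.array([[stay, change], [change, stay]])

    root = next((n for n in tree.adjacency if n not in tree.leaves), None)
    if root is None:  # degenerate 2-leaf tree
        root = next(iter(tree.adjacency))

    def partial(node: str, parent: str | None) -> np.ndarray:
        if node in tree.leaves:
            obs = states[leaf_order[node]]
            L = np.ones((2, n_sites))
            L[0, obs == 1] = 0.0
            L[1, obs == 0] = 0.0
        else:
            L = np.ones((2, n_sites))
        for child, length in tree.adjacency[node].items():
            if child == parent:
                continue
            Lc = partial(child, node)
            L = L * (transition(length) @ Lc)
        return L

    L_root = partial(root, None)
    site_lik = 0.5 * L_root[0] + 0.5 * L_root[1]
    return float(np.sum(np.log(site_lik)))
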