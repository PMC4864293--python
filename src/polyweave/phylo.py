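"""SNP distance matrices, neighbor joining, and bootstrap consensus trees.

Distances are the proportion of co-covered SNP sites at which two taxa
carry different haploid calls. Trees come from standard neighbor joining
(Saitou-Nei Q-criterion) with seed-controlled randomization of the taxon
input order, since NJ tie-breaking on non-additive matrices is
order-dependent. Support values come from resampling subsamples of SNP
sites without replacement (default 1000 replicates of 5% of sites — a
deliberate departure from the classical with-replacement bootstrap) and a
majority-rule consensus greedily extended with compatible minority splits,
mirroring the PHYLIP consense default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .snpcall import calls_to_codes


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray
    pair_sites: np.ndarray | None = None  # co-covered site counts


def distance_matrix(
    matrix: pd.DataFrame, group: list[tuple[str, str]] | None = None
) -> DistanceMatrix:
    """Pairwise SNP distances over a genotype matrix.

    ``group`` selects (accession, subgenome) columns; taxa are labeled by
    accession name. A pair with zero co-covered sites is an error naming
    the pair.
    """
    if group is None:
        group = list(matrix.columns)
    if len(group) < 3:
        raise ValueError("distance matrix needs >= 3 taxa")
    codes = calls_to_codes(matrix[group].to_numpy())
    taxa = [g[0] if isinstance(g, tuple) else g for g in group]
    return distance_matrix_from_codes(codes, taxa)


def distance_matrix_from_codes(
    codes: np.ndarray, taxa: list[str]
) -> DistanceMatrix:
    n = len(taxa)
    valid = codes >= 0
    D = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            co = valid[:, i] & valid[:, j]
            m = int(co.sum())
            if m == 0:
                raise ValueError(
                    f"taxa {taxa[i]!r} and {taxa[j]!r} share no covered "
                    "sites")
            d = float((codes[co, i] != codes[co, j]).sum()) / m
            D[i, j] = D[j, i] = d
            counts[i, j] = counts[j, i] = m
    return DistanceMatrix(taxa, D, counts)


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary root (the final NJ join)."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaves())

    def splits(self) -> set[frozenset]:
        """Nontrivial bipartitions, each canonicalized to the side not
        containing the alphabetically first taxon."""
        all_taxa = frozenset(self.leaf_names())
        ref = min(all_taxa)
        out: set[frozenset] = set()

        def walk(node: TreeNode):
            below = frozenset(node.leaves())
            side = below if ref not in below else all_taxa - below
            if 1 < len(side) < len(all_taxa) - 1:
                out.add(side)
            for child, _ in node.children:
                walk(child)

        for child, _ in self.root.children:
            walk(child)
        return out

    def split_supports(self) -> dict[frozenset, float]:
        all_taxa = frozenset(self.leaf_names())
        ref = min(all_taxa)
        out: dict[frozenset, float] = {}

        def walk(node: TreeNode):
            below = frozenset(node.leaves())
            side = below if ref not in below else all_taxa - below
            if 1 < len(side) < len(all_taxa) - 1 and \
                    node.support is not None:
                out[side] = node.support
            for child, _ in node.children:
                walk(child)

        for child, _ in self.root.children:
            walk(child)
        return out

    def leaf_distances(self) -> DistanceMatrix:
        """Path-length distances between all leaf pairs."""
        taxa = self.leaf_names()
        idx = {t: i for i, t in enumerate(taxa)}
        n = len(taxa)
        D = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[int, float]:
            if node.is_leaf():
                return {idx[node.name]: 0.0}
            below: dict[int, float] = {}
            child_maps = []
            for child, length in node.children:
                cm = {k: v + length for k, v in walk(child).items()}
                child_maps.append(cm)
            for a in range(len(child_maps)):
                for b in range(a + 1, len(child_maps)):
                    for i, di in child_maps[a].items():
                        for j, dj in child_maps[b].items():
                            D[i, j] = D[j, i] = di + dj
                below = {k: v for cm in child_maps for k, v in cm.items()}
            return below

        walk(self.root)
        return DistanceMatrix(taxa, D)

    def to_newick(self) -> str:
        def fmt(node: TreeNode, length: float | None) -> str:
            if node.is_leaf():
                body = node.name
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                label = ""
                if node.support is not None:
                    label = f"{node.support:.0f}"
                body = f"({inner}){label}"
            if length is None:
                return body
            return f"{body}:{length:.6g}"

        return fmt(self.root, None) + ";"


def neighbor_joining(
    dm: DistanceMatrix, join_order_seed: int | None = None
) -> PhyloTree:
    """Standard neighbor joining with seeded input-order randomization.

    Negative branch lengths are floored at zero with the deficit moved to
    the sibling branch, preserving the pairwise path length.
    """
    D = np.asarray(dm.matrix, dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    n = D.shape[0]
    order = np.arange(n)
    if join_order_seed is not None:
        order = np.random.default_rng(join_order_seed).permutation(n)
    D = D[np.ix_(order, order)].copy()
    nodes: list[TreeNode] = [TreeNode(dm.taxa[i]) for i in order]
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
    if len(nodes) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        l0 = max(0.0, (d01 + d02 - d12) / 2)
        l1 = max(0.0, (d01 + d12 - d02) / 2)
        l2 = max(0.0, (d02 + d12 - d01) / 2)
        root = TreeNode(children=[(nodes[0], l0), (nodes[1], l1),
                                  (nodes[2], l2)])
    elif len(nodes) == 2:
        root = TreeNode(children=[(nodes[0], D[0, 1] / 2),
                                  (nodes[1], D[0, 1] / 2)])
    else:
        root = nodes[0]
    return PhyloTree(root)


def splits_compatible(a: frozenset, b: frozenset) -> bool:
    """Clusters (canonicalized away from the reference taxon) are
    compatible iff nested or disjoint."""
    return a <= b or b <= a or not (a & b)


def consensus_from_splits(
    taxa: list[str],
    split_counts: dict[frozenset, int],
    n_reps: int,
    majority: float = 0.5,
) -> PhyloTree:
    """Majority-rule consensus greedily extended with compatible splits."""
    accepted: list[tuple[frozenset, float]] = []
    items = sorted(split_counts.items(),
                   key=lambda kv: (-kv[1], sorted(kv[0])))
    for split, count in items:
        frac = count / n_reps
        if frac > majority or all(
            splits_compatible(split, s) for s, _ in accepted
        ):
            if frac > majority or frac * 100 >= 1:
                accepted.append((split, 100.0 * frac))
    # build the rooted-cluster hierarchy
    clusters = sorted(accepted, key=lambda kv: -len(kv[0]))

    def build(members: frozenset, pool: list) -> list[tuple[TreeNode, float]]:
        children: list[tuple[TreeNode, float]] = []
        used: set[str] = set()
        for k, (cl, support) in enumerate(pool):
            if cl <= members and not (cl & used):
                node = TreeNode(support=support)
                rest = [(c, s) for c, s in pool[k + 1:] if c < cl]
                node.children = build(cl, rest)
                children.append((node, 1.0))
                used |= cl
        for t in sorted(members - used):
            children.append((TreeNode(t), 1.0))
        return children

    root = TreeNode()
    root.children = build(frozenset(taxa), clusters)
    return PhyloTree(root)


def bootstrap_consensus(
    matrix: pd.DataFrame | np.ndarray,
    group: list | None = None,
    taxa: list[str] | None = None,
    n_reps: int = 1000,
    frac: float = 0.05,
    seed: int | None = 0,
) -> PhyloTree:
    """Consensus of NJ trees over without-replacement site subsamples.

    Each replicate draws ``frac`` of the SNP sites without replacement,
    rebuilds the distance matrix and an NJ tree with shuffled input order,
    and the consensus carries split supports as percentages of replicates.
    """
    if isinstance(matrix, pd.DataFrame):
        cols = group if group is not None else list(matrix.columns)
        codes = calls_to_codes(matrix[cols].to_numpy())
        taxa = [c[0] if isinstance(c, tuple) else c for c in cols]
    else:
        codes = np.asarray(matrix)
        if taxa is None:
            raise ValueError("taxa required with a code-matrix input")
    S = codes.shape[0]
    m = int(round(frac * S))
    if m < 10:
        raise ValueError(
            f"subsample of {m} sites is too small (need frac*sites >= 10)")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for rep in range(n_reps):
        sites = rng.choice(S, size=m, replace=False)
        dm = distance_matrix_from_codes(codes[sites], taxa)
        tree = neighbor_joining(dm, join_order_seed=int(rng.integers(2**31)))
        for split in tree.splits():
            counts[split] = counts.get(split, 0) + 1
    return consensus_from_splits(sorted(taxa), counts, n_reps)
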