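"""TVD/NJ ancestry geometry and admixture-proportion estimators.

Population copy profiles (normalized donor-group vectors from the painting
step) are compared with the total variation distance TVD(x, y) =
0.5 * sum |x_k - y_k|; the TVD matrix is summarized by a Neighbor-Joining
tree whose splits are supported by bootstrap over individuals. Three
estimators convert this geometry (or cluster/PCA summaries) into two-way
admixture proportions: Bernstein's linear interpolation of cluster
components, orthogonal projection onto a PCA centroid-centroid axis, and a
ratio of patristic distances on the NJ tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "UnrootedTree",
    "tvd",
    "tvd_matrix",
    "nj_tree",
    "bootstrap_support",
    "bernstein",
    "bernstein_components",
    "pca_projection_ancestry",
    "nj_geometry_ancestry",
]


def tvd(x, y) -> float:
    """Total variation distance between two normalized copy profiles."""
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        if list(x.index) != list(y.index):
            raise ValueError("profiles are on different donor-group bases")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles are on different donor-group bases")
    return float(0.5 * np.abs(x - y).sum())


def tvd_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise TVD between the rows of a profile matrix."""
    labels = list(profiles.index)
    arr = profiles.to_numpy(dtype=float)
    d = 0.5 * np.abs(arr[:, None, :] - arr[None, :, :]).sum(axis=2)
    return pd.DataFrame(d, index=labels, columns=labels)


@dataclass
class UnrootedTree:
    """Unrooted tree with branch lengths and optional split supports.

    Backed by a networkx graph; leaves carry their taxon labels, internal
    nodes are integers. A split is the frozenset of leaf labels on the side
    of an edge not containing the reference (first sorted) leaf.
    """

    graph: nx.Graph
    leaves: list[str]
    supports: dict = field(default_factory=dict)

    def attachment(self, leaf: str):
        """Internal node where the leaf's pendant branch attaches."""
        nbrs = list(self.graph.neighbors(leaf))
        if len(nbrs) != 1:
            raise ValueError(f"{leaf!r} is not a leaf")
        return nbrs[0]

    def patristic(self, u, v) -> float:
        """Along-branch distance between two nodes (leaves or internal)."""
        return float(
            nx.shortest_path_length(self.graph, u, v, weight="length")
        )

    def patristic_matrix(self) -> pd.DataFrame:
        d = pd.DataFrame(0.0, index=self.leaves, columns=self.leaves)
        for i, a in enumerate(self.leaves):
            for b in self.leaves[i + 1 :]:
                d.loc[a, b] = d.loc[b, a] = self.patristic(a, b)
        return d

    def splits(self) -> set[frozenset]:
        """Non-trivial splits, canonicalized away from the reference leaf."""
        ref = sorted(self.leaves)[0]
        out = set()
        for u, v in self.graph.edges:
            g = self.graph.copy()
            g.remove_edge(u, v)
            side = {
                n for n in nx.node_connected_component(g, u) if n in set(self.leaves)
            }
            if ref in side:
                side = set(self.leaves) - side
            if 2 <= len(side) <= len(self.leaves) - 2:
                out.add(frozenset(side))
        return out

    def to_newick(self) -> str:
        """Newick string with supports as internal-node labels."""
        ref = self.leaves[0]
        root = self.attachment(ref)
        splits = {}
        for s in self.supports:
            splits[s] = self.supports[s]

        def support_label(node, parent) -> str:
            g = self.graph.copy()
            g.remove_edge(node, parent)
            side = {
                n
                for n in nx.node_connected_component(g, node)
                if n in set(self.leaves)
            }
            refleaf = sorted(self.leaves)[0]
            if refleaf in side:
                side = set(self.leaves) - side
            key = frozenset(side)
            return f"{splits[key]:.3f}" if key in splits else ""

        def rec(node, parent) -> str:
            children = [n for n in self.graph.neighbors(node) if n != parent]
            if not children:
                return str(node)
            inner = ",".join(
                f"{rec(c, node)}:{self.graph[node][c]['length']:.6g}"
                for c in children
            )
            label = support_label(node, parent) if parent is not None else ""
            return f"({inner}){label}"

        return rec(root, None) + ";"


def nj_tree(d) -> UnrootedTree:
    """Saitou-Nei Neighbor-Joining with the standard Q-criterion.

    Negative branch lengths are truncated to zero with the deficit moved to
    the sibling branch (their sum is preserved). Additive distance matrices
    are reconstructed exactly.
    """
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        mat = d.to_numpy(dtype=float)
    else:
        mat = np.asarray(d, dtype=float)
        labels = [f"T{i}" for i in range(mat.shape[0])]
    n = mat.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if np.any(np.isnan(mat)):
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(mat, mat.T) or np.any(np.diag(mat) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    g = nx.Graph()
    active: list = list(labels)
    dist = {a: {b: float(mat[i, j]) for j, b in enumerate(labels)} for i, a in enumerate(labels)}
    next_id = 0
    while len(active) > 2:
        m = len(active)
        r = {a: sum(dist[a][b] for b in active if b != a) for a in active}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * dist[a][b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-15:
                    best = (q, a, b)
        _, a, b = best
        la = 0.5 * dist[a][b] + (r[a] - r[b]) / (2 * (m - 2))
        lb = dist[a][b] - la
        if la < 0:
            la, lb = 0.0, dist[a][b]
        if lb < 0:
            lb, la = 0.0, dist[a][b]
        u = ("I", next_id)
        next_id += 1
        g.add_edge(u, a, length=la)
        g.add_edge(u, b, length=lb)
        dist[u] = {}
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist[a][c] + dist[b][c] - dist[a][b])
            dist[u][c] = duc
            dist[c][u] = duc
        active = [c for c in active if c not in (a, b)] + [u]
    a, b = active
    g.add_edge(a, b, length=max(dist[a][b], 0.0))
    return UnrootedTree(graph=g, leaves=list(labels))


def bootstrap_support(
    profiles: pd.DataFrame,
    labels,
    n_reps: int = 1000,
    seed: int = 0,
) -> UnrootedTree:
    """NJ tree of population-averaged profiles with bootstrap split support.

    Each replica resamples individuals with replacement within populations,
    re-averages profiles, recomputes the TVD matrix and NJ tree; the
    support of a split is the fraction of replicas containing it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels = pd.Series(np.asarray(labels, dtype=object), index=profiles.index)
    rng = np.random.default_rng(seed)

    def averaged(df: pd.DataFrame) -> pd.DataFrame:
        return df.groupby(labels.loc[df.index]).mean()

    main_tree = nj_tree(tvd_matrix(averaged(profiles)))
    counts: dict[frozenset, int] = {s: 0 for s in main_tree.splits()}
    pop_rows = {p: profiles.index[labels == p] for p in labels.unique()}
    for _ in range(n_reps):
        rows = []
        for p, idx in pop_rows.items():
            pick = rng.choice(idx, size=idx.size, replace=True)
            sub = profiles.loc[pick].mean(axis=0)
            rows.append(pd.Series(sub, name=p))
        rep_profiles = pd.DataFrame(rows)
        rep_tree = nj_tree(tvd_matrix(rep_profiles))
        for s in rep_tree.splits():
            if s in counts:
                counts[s] += 1
    main_tree.supports = {s: c / n_reps for s, c in counts.items()}
    return main_tree


def bernstein(q_hybrid: float, q_source_a: float, q_source_b: float) -> float:
    """Two-way admixture proportion by linear interpolation.

    m_a = (q_hybrid - q_b) / (q_a - q_b), clamped to [0, 1] (a warning is
    emitted when clamping occurs).
    """
    if q_source_a == q_source_b:
        raise ZeroDivisionError("source components are equal")
    m = (q_hybrid - q_source_b) / (q_source_a - q_source_b)
    if not (0 <= m <= 1):
        warnings.warn(f"Bernstein estimate {m:.4f} clamped to [0, 1]", stacklevel=2)
        m = min(max(m, 0.0), 1.0)
    return float(m)


def bernstein_components(triples) -> float:
    """Average Bernstein estimates over marker components.

    ``triples`` is an iterable of (q_hybrid, q_source_a, q_source_b), one
    per cluster component (e.g. the two African components of a K=4
    clustering); per-component estimates get equal weight.
    """
    vals = [bernstein(*t) for t in triples]
    if not vals:
        raise ValueError("no components supplied")
    return float(np.mean(vals))


def pca_projection_ancestry(
    pca_result,
    group_a: list[str],
    group_b: list[str],
    targets: list[str],
    pc_pair: tuple[int, int] = (1, 3),
) -> pd.Series:
    """Ancestry from orthogonal projection onto the centroid-centroid line.

    Each target is projected onto the line joining the centroids of groups
    A and B in the chosen principal-component plane; the contribution of A
    is 1 - d(projection, centroid_A) / d(centroid_A, centroid_B), clamped
    to [0, 1].
    """
    coords = pca_result.coordinates if hasattr(pca_result, "coordinates") else pca_result
    cols = [f"PC{pc_pair[0]}", f"PC{pc_pair[1]}"]
    x = coords[cols]
    ca = x.loc[group_a].mean(axis=0).to_numpy()
    cb = x.loc[group_b].mean(axis=0).to_numpy()
    v = cb - ca
    norm2 = float(v @ v)
    if norm2 == 0:
        raise ValueError("group centroids coincide")
    out = {}
    for t in targets:
        p = x.loc[t].to_numpy()
        tt = float((p - ca) @ v) / norm2  # projection coordinate along the axis
        contribution = 1.0 - abs(tt)
        out[t] = min(max(contribution, 0.0), 1.0)
    return pd.Series(out, name="proportion_a")


def nj_geometry_ancestry(
    tree: UnrootedTree,
    target: str,
    ref_gog: str,
    ref_ang_pair: tuple[str, str],
    reading: str = "complement",
    node_mode: str = "attachment",
    gog_node_mode: str = "leaf",
) -> dict:
    """Two-way ancestry from the position of a population in the NJ tree.

    The ratio r = d(target_root, gog) / d(gog, angolan_midpoint) is
    measured patristically. A population's "root" is the internal node
    where its pendant branch attaches (``node_mode='leaf'`` uses the leaf
    itself); the Gulf-of-Guinea reference is taken as its leaf by default
    (``gog_node_mode``), matching a formula phrased as distance *to* that
    population, and avoiding a degeneracy where colinear copy profiles put
    the target's and the reference's attachment nodes at the same point.
    The Angolan reference point is the midpoint of the path between the
    two Angolan population roots. Under the default
    ``reading='complement'`` the Gulf-of-Guinea proportion is 1 - r, so a
    target coinciding with the Gulf-of-Guinea reference is 100% GoG;
    ``reading='direct'`` returns r itself as the GoG proportion.
    """
    for leaf in (target, ref_gog, *ref_ang_pair):
        if leaf not in tree.leaves:
            raise ValueError(f"{leaf!r} is not a leaf of the tree")

    def node(leaf, mode):
        return tree.attachment(leaf) if mode == "attachment" else leaf

    t, gog = node(target, node_mode), node(ref_gog, gog_node_mode)
    a1, a2 = node(ref_ang_pair[0], node_mode), node(ref_ang_pair[1], node_mode)

    def dist_to_angolan_midpoint(x) -> float:
        d_x_a1 = tree.patristic(x, a1)
        d_x_a2 = tree.patristic(x, a2)
        d_a = tree.patristic(a1, a2)
        # junction of x onto the a1-a2 path, then walk to the path midpoint
        d_x_j = 0.5 * (d_x_a1 + d_x_a2 - d_a)
        d_j_a1 = d_x_a1 - d_x_j
        return d_x_j + abs(d_j_a1 - 0.5 * d_a)

    num = tree.patristic(t, gog)
    den = dist_to_angolan_midpoint(gog)
    if den == 0:
        raise ValueError("Gulf-of-Guinea and Angolan references coincide")
    r = num / den
    if r > 1.25:
        warnings.warn(
            f"distance ratio {r:.3f} > 1.25: target lies outside the "
            "reference axis",
            stacklevel=2,
        )
    gog_prop = (1.0 - r) if reading == "complement" else r
    clamped = not (0.0 <= gog_prop <= 1.0)
    gog_prop = min(max(gog_prop, 0.0), 1.0)
    return {
        "population": target,
        "gulf_of_guinea": gog_prop,
        "angola": 1.0 - gog_prop,
        "ratio": r,
        "clamped": clamped,
        "method": "nj_geometry",
    }
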