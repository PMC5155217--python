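"""Distance-based trees, lineage-through-time curves and the gamma statistic.

Supports the diversification-rate side of a duplicate-gene analysis:
pairwise distances (p, JC69, K2P, and Nei-Gojobori synonymous-only /
nonsynonymous-only proportions), Saitou-Nei neighbor joining with
deterministic tie-breaking, extraction of lineage-through-time curves,
and the constant-rate diversification test statistic

    gamma = [ mean_i T_i  -  T/2 ] / ( T sqrt(1/(12(n-2))) ),

with T_i = sum_{k=2..i} k g_k, T = T_n, and g_k the duration during
which the reconstructed tree has exactly k lineages.  Under a pure-birth
process gamma is asymptotically standard normal; strongly positive
values indicate a late acceleration of diversification.

Substitution-scaled trees (such as NJ trees on synonymous-only
distances) are not ultrametric; by default they are made ultrametric by
node-depth averaging before gamma is computed (raw depths available
behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .seqio import Alignment, CodonAlignment, parse_newick

__all__ = [
    "DistanceMatrix",
    "SaturationError",
    "distance_matrix",
    "neighbor_joining",
    "gamma_statistic",
    "gamma_p_value",
    "ltt_curve",
    "node_depth_ultrametricize",
]


class SaturationError(ArithmeticError):
    """A distance correction is undefined (log of a non-positive value)."""


@dataclass
class DistanceMatrix:
    labels: list
    matrix: np.ndarray
    method: str
    saturated: list  # label pairs whose correction overflowed (inf entries)

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("diagonal must be zero")
        finite = m[np.isfinite(m)]
        if np.any(finite < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")


def _p_counts(a: np.ndarray, b: np.ndarray, miss_a, miss_b):
    ok = ~(miss_a | miss_b)
    n_ok = int(np.count_nonzero(ok))
    nd = int(np.count_nonzero(a[ok] != b[ok]))
    return nd, n_ok, ok


def distance_matrix(aln, method: str = "p") -> DistanceMatrix:
    """Pairwise distances under the requested model.

    ``p``/``jc69``/``k2p`` act on a nucleotide (or amino-acid, for p)
    :class:`Alignment`; ``ng-syn``/``ng-nonsyn`` act on a
    :class:`CodonAlignment` and give the Nei-Gojobori proportions of
    synonymous (pS) resp. nonsynonymous (pN) differences per site.
    Saturated corrections are stored as inf and flagged.
    """
    method = method.lower()
    if method in ("ng-syn", "ng-nonsyn"):
        if not isinstance(aln, CodonAlignment):
            raise TypeError("ng-syn/ng-nonsyn require a CodonAlignment")
        from .codonml import ng86_counts

        ids = list(aln.ids)
        N = len(ids)
        mat = np.zeros((N, N))
        cods = aln.codon_matrix()
        for i in range(N):
            for j in range(i + 1, N):
                c = ng86_counts(cods[i], cods[j], aln.code)
                d = c.pS if method == "ng-syn" else c.pN
                mat[i, j] = mat[j, i] = d
        return DistanceMatrix(ids, mat, method, [])

    if not isinstance(aln, Alignment):
        raise TypeError("p/jc69/k2p require an Alignment")
    ids = list(aln.ids)
    N = len(ids)
    m = aln.matrix
    miss = aln.missing_mask()
    mat = np.zeros((N, N))
    saturated = []
    for i in range(N):
        for j in range(i + 1, N):
            nd, n_ok, ok = _p_counts(m[i], m[j], miss[i], miss[j])
            if n_ok == 0:
                raise ValueError(f"no comparable sites between {ids[i]} and {ids[j]}")
            p = nd / n_ok
            if method == "p":
                d = p
            elif method == "jc69":
                arg = 1.0 - 4.0 * p / 3.0
                if arg <= 0:
                    d = np.inf
                    saturated.append((ids[i], ids[j]))
                else:
                    d = -0.75 * np.log(arg)
            elif method == "k2p":
                ai, bj = m[i][ok], m[j][ok]
                diff = ai != bj
                purines = np.isin(ai, ["A", "G"]) == np.isin(bj, ["A", "G"])
                P = np.count_nonzero(diff & purines) / n_ok  # transitions
                Q = np.count_nonzero(diff & ~purines) / n_ok  # transversions
                a1, a2 = 1.0 - 2 * P - Q, 1.0 - 2 * Q
                if a1 <= 0 or a2 <= 0:
                    d = np.inf
                    saturated.append((ids[i], ids[j]))
                else:
                    d = -0.5 * np.log(a1) - 0.25 * np.log(a2)
            else:
                raise ValueError(f"unknown distance method {method!r}")
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(ids, mat, method, saturated)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Ties in the Q-criterion are broken by label order (lexicographically
    smallest joined pair), so the output is deterministic.  Negative
    branch-length estimates are clamped to zero with the deficit moved to
    the sister branch, preserving the pair's summed length.
    """
    labels = list(dm.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.matrix)):
        raise SaturationError("distance matrix contains saturated (inf) entries")
    D = {a: {b: float(dm.matrix[i, j]) for j, b in enumerate(labels)}
         for i, a in enumerate(labels)}
    newick = {a: a for a in labels}  # cluster -> newick fragment
    active = sorted(labels)
    counter = 0
    while len(active) > 3:
        r = len(active)
        R = {a: sum(D[a][b] for b in active if b != a) for a in active}
        best, best_q = None, np.inf
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (r - 2) * D[a][b] - R[a] - R[b]
                key = tuple(sorted((a, b)))
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12
                                          and (best is None or key < best)):
                    best_q, best = q, key
        a, b = best
        va = 0.5 * D[a][b] + (R[a] - R[b]) / (2.0 * (r - 2))
        vb = D[a][b] - va
        if va < 0:
            vb += va
            va = 0.0
        if vb < 0:
            va += vb
            vb = 0.0
        va, vb = max(va, 0.0), max(vb, 0.0)
        counter += 1
        new = f"__nj{counter}"
        newick[new] = f"({newick[a]}:{va:.12g},{newick[b]}:{vb:.12g})"
        D[new] = {}
        for c in active:
            if c in (a, b):
                continue
            d = 0.5 * (D[a][c] + D[b][c] - D[a][b])
            D[new][c] = D[c][new] = max(d, 0.0)
        for c in (a, b):
            active.remove(c)
        active.append(new)
        active.sort()
    # final three-point resolution
    x, y, z = active
    vx = 0.5 * (D[x][y] + D[x][z] - D[y][z])
    vy = 0.5 * (D[x][y] + D[y][z] - D[x][z])
    vz = 0.5 * (D[x][z] + D[y][z] - D[x][y])
    vx, vy, vz = (max(v, 0.0) for v in (vx, vy, vz))
    s = (f"({newick[x]}:{vx:.12g},{newick[y]}:{vy:.12g},"
         f"{newick[z]}:{vz:.12g});")
    return parse_newick(s)


# ---------------------------------------------------------------------------
# Ultrametricization and gamma
# ---------------------------------------------------------------------------

def node_depth_ultrametricize(tree: dendropy.Tree) -> dendropy.Tree:
    """Make a rooted tree ultrametric by node-depth averaging.

    Each node's height above the present is replaced by the mean of its
    root-to-tip path remainders; child heights are capped at the parent's
    so depths stay monotone.  Operates on (and returns) a clone.
    """
    t = tree.clone(depth=1)
    heights = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            heights[node] = 0.0
        else:
            vals = []
            for ch in node.child_nodes():
                vals.append(heights[ch] + (ch.edge.length or 0.0))
            heights[node] = float(np.mean(vals))
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        hp = heights[node.parent_node]
        h = min(heights[node], hp)
        heights[node] = h
        node.edge.length = hp - h
    return t


def _ensure_rooted(tree: dendropy.Tree, outgroup: str | None):
    t = tree.clone(depth=1)
    if outgroup is not None:
        og = t.find_node_with_taxon_label(outgroup)
        if og is None:
            raise ValueError(f"outgroup {outgroup!r} not in tree")
        t.to_outgroup_position(og, update_bipartitions=False)
    elif len(t.seed_node.child_nodes()) > 2:
        t.reroot_at_midpoint(update_bipartitions=False)
    return t


def _internode_intervals(tree: dendropy.Tree):
    """g_k intervals (k = 2..n) from a rooted ultrametric tree.

    A node of out-degree c contributes c-1 coincident lineage-birth
    events at its depth.
    """
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    events = []  # (depth, lineages added)
    tip_depths = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            tip_depths.append(node.root_distance)
        else:
            events.append((node.root_distance, len(node.child_nodes()) - 1))
    T_tip = float(np.max(tip_depths))
    events.sort()
    n = len(tip_depths)
    # lineage count after the root event is (root out-degree); walk events
    g = np.zeros(n + 1)  # g[k] = duration with k lineages
    k = 0
    t_prev = events[0][0]
    for depth, added in events:
        if k >= 2:
            g[k] += depth - t_prev
        t_prev = depth
        k += added + (1 if k == 0 else 0)  # root: 1 lineage splits into >=2
    g[n] += T_tip - t_prev
    return g, n


def gamma_statistic(
    tree: dendropy.Tree,
    *,
    outgroup: str | None = None,
    ultrametricize: bool = True,
) -> float:
    """Constant-rate diversification test statistic on a rooted tree.

    Non-ultrametric (substitution-scaled) trees are made ultrametric by
    node-depth averaging unless ``ultrametricize=False``, in which case
    raw node depths are used directly.
    """
    t = _ensure_rooted(tree, outgroup)
    n = len(t.leaf_nodes())
    if n < 3:
        raise ValueError("gamma requires at least 3 tips")
    if ultrametricize:
        t = node_depth_ultrametricize(t)
    g, n = _internode_intervals(t)
    kk = np.arange(len(g))
    T = float(np.sum(kk * g))
    if T <= 0:
        raise ArithmeticError("zero total tree depth")
    cum = np.cumsum(kk * g)  # cum[i] = sum_{k<=i} k g_k
    mean_ti = float(np.mean(cum[2:n]))  # i = 2..n-1
    return (mean_ti - T / 2.0) / (T * np.sqrt(1.0 / (12.0 * (n - 2))))


def gamma_p_value(gamma: float, *, two_sided: bool = False) -> float:
    """Normal-approximation p-value for gamma (one-sided: late burst)."""
    from scipy.stats import norm

    p = norm.sf(gamma)
    return float(2 * min(p, 1 - p)) if two_sided else float(p)


def ltt_curve(tree: dendropy.Tree, *, outgroup: str | None = None):
    """Lineage-through-time curve: sorted node depths and lineage counts.

    Returns (depths, counts) arrays; counts[i] is the number of lineages
    immediately after the event at depths[i].  The curve starts at the
    root (count = root out-degree) and ends at n.
    """
    t = _ensure_rooted(tree, outgroup)
    t.calc_node_root_distances(return_leaf_distances_only=False)
    events = []
    for node in t.preorder_node_iter():
        if not node.is_leaf():
            events.append((float(node.root_distance), len(node.child_nodes()) - 1))
    events.sort()
    depths, counts = [], []
    k = 1
    for depth, added in events:
        k += added
        depths.append(depth)
        counts.append(k)
    return np.asarray(depths), np.asarray(counts)
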