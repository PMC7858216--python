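"""Tree building and support estimation.

Engines
-------
* p-distance / Jukes-Cantor distances and neighbor-joining (NJ).
* Fitch parsimony scoring and a heuristic maximum-parsimony (MP) search:
  seeded random stepwise addition followed by subtree-prune-regraft (SPR)
  swapping with first-improvement acceptance.
* Strict consensus, nonparametric (column-resampling) bootstrap, and
  outgroup rooting.

Trees are :class:`dendropy.Tree` objects; bootstrap supports are integer
percentages stored as internal-node labels.  All scoring runs on compressed
site patterns (unique alignment columns with multiplicities), which is what
makes bootstrap resampling cheap: a replicate is just a new weight vector
over patterns.

The stepwise-addition and SPR scoring use directional Fitch state sets: for
an edge e with side sets D1, D2, attaching a subtree with root set S on e
costs ``base + sum_p w_p * [S_p ∩ E_p = ∅]`` where ``E = D1 ∩ D2`` if
non-empty else ``D1 ∪ D2``.  Because the Fitch length is invariant to root
placement this insertion score is exact, giving O(n^2) additions per
replicate instead of O(n^3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import DataError
from .seqio import Alignment

# ---------------------------------------------------------------------------
# site patterns
# ---------------------------------------------------------------------------

def site_patterns(aln: Alignment, ids: Sequence[str] | None = None):
    """Compress an alignment into unique columns.

    Returns ``(taxa, pat, weights, col_to_pat)`` where ``pat`` is an
    (n_taxa, n_patterns) uint8 bitmask matrix, ``weights`` the column
    multiplicities and ``col_to_pat`` maps original columns to patterns.
    """
    sub = aln if ids is None else aln.subset(list(ids))
    codes = sub.codes()  # (n, L)
    cols, col_to_pat, counts = np.unique(
        codes.T, axis=0, return_inverse=True, return_counts=True
    )
    return list(sub.ids), cols.T.copy(), counts.astype(float), col_to_pat


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise DataError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-9):
            raise DataError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise DataError("distance matrix diagonal must be zero")
        if np.any(m < 0):
            raise DataError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)


def _weighted_pdist(ids, pat, w, model="p") -> DistanceMatrix:
    det = (pat & (pat - 1)) == 0  # (n, P) unambiguous base
    bits = np.array([1, 2, 4, 8], dtype=np.uint8)
    onehot = (pat[:, :, None] == bits[None, None, :]).astype(float)  # (n,P,4)
    matches = np.einsum("ips,jps->ij", onehot * w[None, :, None], onehot)
    detw = det * w
    comparable = detw @ det.T
    if np.any((comparable == 0) & ~np.eye(len(ids), dtype=bool)):
        i, j = np.argwhere((comparable == 0) & ~np.eye(len(ids), dtype=bool))[0]
        raise DataError(
            f"sequences {ids[i]!r} and {ids[j]!r} share no comparable column"
        )
    with np.errstate(invalid="ignore"):
        p = 1.0 - matches / comparable
    np.fill_diagonal(p, 0.0)
    p = np.clip((p + p.T) / 2.0, 0.0, 1.0)
    if model == "p":
        return DistanceMatrix(tuple(ids), p)
    if model == "jc":
        capped = p >= 0.75
        if np.any(capped):
            warnings.warn("p-distance >= 0.75: Jukes-Cantor distance capped")
            p = np.where(capped, 0.7499999, p)
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(tuple(ids), d)
    raise DataError(f"unknown distance model {model!r}")


def p_distance_matrix(aln: Alignment, model: str = "p") -> DistanceMatrix:
    """Pairwise p- or Jukes-Cantor distances over pairwise-complete columns."""
    if aln.n_sequences < 2:
        raise DataError("need >= 2 sequences for distances")
    ids, pat, w, _ = site_patterns(aln)
    return _weighted_pdist(ids, pat, w, model=model)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; deterministic, ties broken by the
    lexicographically smallest pair of (merged) taxon labels."""
    if d.n < 3:
        raise DataError("neighbor joining needs >= 3 taxa")
    ns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    labels: list[str] = []  # tie-break label = min leaf label in the cluster
    for sid in d.ids:
        lf = dendropy.Node(taxon=ns.new_taxon(label=sid))
        nodes.append(lf)
        labels.append(sid)
    D = d.matrix.astype(float).copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-10))
        i, j = min(
            ((int(a), int(b)) for a, b in cand if a < b),
            key=lambda ij: tuple(sorted((labels[ij[0]], labels[ij[1]]))),
        )
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        nodes[i].edge.length = float(li)
        nodes[j].edge.length = float(lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.empty((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]
        D = D2

    # join the last three clusters at one internal node
    (a, b, c) = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    center = dendropy.Node()
    for node, ln in ((a, la), (b, lb), (c, lc)):
        node.edge.length = float(ln)
        center.add_child(node)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=center)
    tree.is_rooted = False
    _collapse_zero_internal_edges(tree)
    return tree


def _collapse_zero_internal_edges(tree: dendropy.Tree, tol: float = 1e-12) -> None:
    """Collapse internal edges of (near-)zero length into polytomies.

    Without this, deterministic tie-breaking would resolve signal-free
    groups into an arbitrary but reproducible binary shape, and the
    bootstrap would then certify those arbitrary edges at 100%.
    """
    for nd in list(tree.postorder_internal_node_iter()):
        if nd.parent_node is None:
            continue
        if nd.edge.length is not None and abs(nd.edge.length) < tol:
            parent = nd.parent_node
            for ch in nd.child_nodes():
                nd.remove_child(ch)
                parent.add_child(ch)
            parent.remove_child(nd)


# ---------------------------------------------------------------------------
# Fitch machinery on an adjacency representation
# ---------------------------------------------------------------------------

def _combine(a: np.ndarray, b: np.ndarray, w: np.ndarray):
    inter = a & b
    empty = inter == 0
    return np.where(empty, a | b, inter), float(w[empty].sum())


def _postorder(adj: dict[int, list[int]], root: int):
    """(node, parent) pairs, children before parents."""
    order, stack = [], [(root, -1)]
    while stack:
        u, p = stack.pop()
        order.append((u, p))
        for v in adj[u]:
            if v != p:
                stack.append((v, u))
    return order[::-1]


def _full_fitch(adj, pat, w, root: int | None = None) -> float:
    """Weighted Fitch length; tolerates multifurcations (sequential fold)."""
    if root is None:
        root = min(adj)
    cost = 0.0
    sets: dict[int, np.ndarray] = {}
    n_taxa = pat.shape[0]
    for u, p in _postorder(adj, root):
        kids = [v for v in adj[u] if v != p]
        if not kids:
            sets[u] = pat[u]
            continue
        cur = sets.pop(kids[0])
        for k in kids[1:]:
            cur, c = _combine(cur, sets.pop(k), w)
            cost += c
        if u < n_taxa:  # rooting at a leaf: fold the leaf's own state in
            cur, c = _combine(cur, pat[u], w)
            cost += c
        sets[u] = cur
    return cost


def _directional_sets(adj, pat, w, root: int | None = None):
    """Fitch state set and internal cost for every directed edge.

    ``down[(u, v)]`` is the (set, cost) of the component containing ``u``
    when edge (u, v) is removed.  Internal nodes must have degree 3 (binary
    unrooted tree); leaves are nodes < pat.shape[0] present in ``adj``.
    """
    n_taxa = pat.shape[0]
    if root is None:
        root = min(u for u in adj if u < n_taxa and len(adj[u]) == 1)
    down: dict[tuple[int, int], tuple[np.ndarray, float]] = {}
    post = _postorder(adj, root)
    for u, p in post:
        if p < 0:
            continue
        kids = [v for v in adj[u] if v != p]
        if not kids:
            down[(u, p)] = (pat[u], 0.0)
        else:
            (s1, c1), (s2, c2) = down[(kids[0], u)], down[(kids[1], u)]
            s, c = _combine(s1, s2, w)
            down[(u, p)] = (s, c + c1 + c2)
    # top-down pass for the reverse directions
    for u, p in post[::-1]:
        kids = [v for v in adj[u] if v != p]
        if not kids:
            continue
        if p < 0:  # root leaf: unique neighbour
            assert len(kids) == 1
            down[(u, kids[0])] = (pat[u], 0.0)
            continue
        for c in kids:
            other = kids[0] if kids[1] == c else kids[1]
            (s1, c1) = down[(p, u)]
            (s2, c2) = down[(other, u)]
            s, cc = _combine(s1, s2, w)
            down[(u, c)] = (s, cc + c1 + c2)
    return down


def _edge_sets(adj, down, w):
    """{(u, v) u<v: (E, base_cost)} for every edge; base_cost is the tree
    length, identical on every edge (root invariance) -- kept per edge only
    to avoid a second pass."""
    out = {}
    for u in adj:
        for v in adj[u]:
            if u < v:
                (s1, c1), (s2, c2) = down[(u, v)], down[(v, u)]
                e, c = _combine(s1, s2, w)
                out[(u, v)] = (e, c + c1 + c2)
    return out


class _AdjTree:
    """Mutable unrooted binary tree over taxa 0..n-1 plus internal ids."""

    def __init__(self, n_taxa: int):
        self.n_taxa = n_taxa
        self.adj: dict[int, list[int]] = {}
        self._next = n_taxa

    def new_internal(self) -> int:
        m = self._next
        self._next += 1
        self.adj[m] = []
        return m

    def connect(self, a: int, b: int) -> None:
        self.adj.setdefault(a, []).append(b)
        self.adj.setdefault(b, []).append(a)

    def disconnect(self, a: int, b: int) -> None:
        self.adj[a].remove(b)
        self.adj[b].remove(a)

    def edges(self):
        return sorted(
            (u, v) for u in self.adj for v in self.adj[u] if u < v
        )

    def insert_leaf(self, x: int, u: int, v: int) -> int:
        """Attach leaf x on edge (u, v) via a fresh internal node."""
        m = self.new_internal()
        self.disconnect(u, v)
        self.connect(u, m)
        self.connect(m, v)
        self.connect(m, x)
        return m

    def copy(self) -> "_AdjTree":
        t = _AdjTree(self.n_taxa)
        t.adj = {u: list(vs) for u, vs in self.adj.items()}
        t._next = self._next
        return t

    def bipartitions(self) -> frozenset[frozenset[int]]:
        """Non-trivial splits as frozensets of taxa on the side away from
        taxon 0."""
        out = []
        root = 0
        below: dict[int, set[int]] = {}
        for u, p in _postorder(self.adj, root):
            if len(self.adj[u]) == 1 and u != root:
                below[u] = {u}
            else:
                below[u] = set().union(
                    *(below[v] for v in self.adj[u] if v != p)
                )
            if p >= 0 and 2 <= len(below[u]) <= self.n_taxa - 2:
                out.append(frozenset(below[u]))
        return frozenset(out)

    def to_dendropy(self, taxa: Sequence[str], ns=None) -> dendropy.Tree:
        ns = ns or dendropy.TaxonNamespace()
        taxon_of = {i: ns.require_taxon(label=label) for i, label in enumerate(taxa)}
        start = next(u for u in self.adj if u >= self.n_taxa)
        nodes = {start: dendropy.Node()}
        for u, p in reversed(_postorder(self.adj, start)):
            if p < 0:
                continue
            node = dendropy.Node()
            if u < self.n_taxa:
                node.taxon = taxon_of[u]
            nodes[u] = node
            nodes[p].add_child(node)
        tree = dendropy.Tree(taxon_namespace=ns, seed_node=nodes[start])
        tree.is_rooted = False
        return tree


# ---------------------------------------------------------------------------
# public Fitch score
# ---------------------------------------------------------------------------

def fitch_score(tree: dendropy.Tree, aln: Alignment) -> int:
    """Fitch parsimony length of ``tree`` on ``aln``.

    Gaps, N and ambiguity codes are wildcards (match anything at no cost).
    Multifurcating nodes are scored by sequential state-set folding.
    """
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    if set(leaves) != set(aln.ids):
        raise DataError("tree leaves and alignment ids differ")
    _, pat, w, _ = site_patterns(aln, ids=leaves)
    index = {label: i for i, label in enumerate(leaves)}
    adj: dict[int, list[int]] = {}
    counter = [len(leaves)]
    ids: dict[int, int] = {}

    def node_id(nd):
        key = id(nd)
        if key not in ids:
            if nd.is_leaf():
                ids[key] = index[nd.taxon.label]
            else:
                ids[key] = counter[0]
                counter[0] += 1
        return ids[key]

    for nd in tree.preorder_node_iter():
        u = node_id(nd)
        adj.setdefault(u, [])
        for ch in nd.child_nodes():
            v = node_id(ch)
            adj.setdefault(v, [])
            adj[u].append(v)
            adj[v].append(u)
    # suppress a degree-2 root so scoring sees the unrooted shape
    for u in list(adj):
        if len(adj[u]) == 2 and u >= len(leaves):
            a, b = adj[u]
            adj[a].remove(u)
            adj[b].remove(u)
            adj[a].append(b)
            adj[b].append(a)
            del adj[u]
    root = min(u for u in adj if u < len(leaves))
    return int(round(_full_fitch(adj, pat, w, root=root)))


# ---------------------------------------------------------------------------
# maximum parsimony search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchParams:
    """Heuristic MP search settings: number of random-addition replicates,
    branch-swapping mode and the cap on retained equally-best trees."""

    n_addition_replicates: int = 10
    swap: str = "spr"  # none | nni | spr  (nni is run as restricted spr)
    max_trees_kept: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_addition_replicates < 1:
            raise DataError("n_addition_replicates must be >= 1")
        if self.swap not in {"none", "nni", "spr"}:
            raise DataError(f"unknown swap mode {self.swap!r}")


def _stepwise_addition(order: np.ndarray, pat, w) -> _AdjTree:
    n = pat.shape[0]
    t = _AdjTree(n)
    a, b, c = (int(x) for x in order[:3])
    hub = t.new_internal()
    for leaf in (a, b, c):
        t.connect(hub, leaf)
    for x in order[3:]:
        x = int(x)
        down = _directional_sets(t.adj, pat, w)
        esets = _edge_sets(t.adj, down, w)
        best, best_edge = np.inf, None
        for (u, v), (E, _base) in sorted(esets.items()):
            delta = float(w[(pat[x] & E) == 0].sum())
            if delta < best - 1e-9:
                best, best_edge = delta, (u, v)
        t.insert_leaf(x, *best_edge)
    return t


def _spr_swap(t: _AdjTree, pat, w, nni_only: bool = False):
    """First-improvement SPR; returns (tree, score).

    ``nni_only`` restricts regrafting to edges incident to the original
    attachment point, which reproduces the NNI neighbourhood.
    """
    score = _full_fitch(t.adj, pat, w)
    improved = True
    while improved:
        improved = False
        down_full = _directional_sets(t.adj, pat, w)
        directed = [e for uv in t.edges() for e in (uv, uv[::-1])]
        for a, b in directed:
            # prune the component containing `a`; `b` must be internal so it
            # can be smoothed out of the remaining tree
            if b < t.n_taxa:
                continue
            D_S, cost_S = down_full[(a, b)]
            rem = t.copy()
            rem.disconnect(a, b)
            x, y = rem.adj[b]
            rem.disconnect(x, b)
            rem.disconnect(y, b)
            del rem.adj[b]
            rem.connect(x, y)
            # drop the pruned side from the remaining adjacency
            keep = {u for u, _ in _postorder(rem.adj, x)}
            pruned_side = {u: vs for u, vs in rem.adj.items() if u not in keep}
            rem.adj = {u: vs for u, vs in rem.adj.items() if u in keep}
            if len(rem.adj) < 2:
                continue
            down_r = _directional_sets(rem.adj, pat, w)
            esets = _edge_sets(rem.adj, down_r, w)
            base = next(iter(esets.values()))[1]
            for (u, v), (E, _b) in sorted(esets.items()):
                if nni_only and u not in (x, y) and v not in (x, y):
                    continue
                cand = base + cost_S + float(w[(D_S & E) == 0].sum())
                if cand < score - 1e-9:
                    # graft the pruned component back, then subdivide (u, v)
                    for p, qs in pruned_side.items():
                        rem.adj[p] = list(qs)
                    m = rem.new_internal()
                    rem.disconnect(u, v)
                    rem.connect(u, m)
                    rem.connect(m, v)
                    rem.connect(m, a)
                    t = rem
                    score = cand
                    improved = True
                    break
            if improved:
                break
    return t, score


def mp_search(aln: Alignment, params: SearchParams | None = None) -> list[dendropy.Tree]:
    """Heuristic maximum-parsimony search.

    Runs ``n_addition_replicates`` random stepwise-addition replicates, each
    followed by branch swapping, and returns the distinct best-score trees
    (at most ``max_trees_kept``), all on one shared taxon namespace.
    """
    params = params or SearchParams()
    if aln.n_sequences < 4:
        raise DataError("MP search needs >= 4 taxa")
    taxa, pat, w, _ = site_patterns(aln)
    trees, scores = _mp_search_patterns(pat, w, params)
    ns = dendropy.TaxonNamespace()
    return [t.to_dendropy(taxa, ns=ns) for t in trees]


def _mp_search_patterns(pat, w, params: SearchParams):
    n = pat.shape[0]
    rng = np.random.default_rng(params.seed)
    best_score = np.inf
    kept: dict[frozenset, _AdjTree] = {}
    for _rep in range(params.n_addition_replicates):
        order = rng.permutation(n)
        t = _stepwise_addition(order, pat, w)
        if params.swap == "none":
            score = _full_fitch(t.adj, pat, w)
        else:
            t, score = _spr_swap(t, pat, w, nni_only=(params.swap == "nni"))
        if score < best_score - 1e-9:
            best_score = score
            kept = {t.bipartitions(): t}
        elif abs(score - best_score) <= 1e-9 and len(kept) < params.max_trees_kept:
            kept.setdefault(t.bipartitions(), t)
    return list(kept.values()), best_score


def mp_best_score(aln: Alignment, params: SearchParams | None = None) -> int:
    params = params or SearchParams()
    _, pat, w, _ = site_patterns(aln)
    _, score = _mp_search_patterns(pat, w, params)
    return int(round(score))


# ---------------------------------------------------------------------------
# bipartitions, consensus, supports
# ---------------------------------------------------------------------------

def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits as leaf-label sets on the side away from the
    lexicographically smallest leaf (root-invariant canonical form)."""
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = labels[0]
    n = len(labels)
    out = set()
    for nd in tree.postorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if ref in side:
            side = frozenset(labels) - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def strict_consensus(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Tree containing exactly the splits shared by every input tree."""
    if not trees:
        raise DataError("no trees given")
    leafsets = [frozenset(lf.taxon.label for lf in t.leaf_node_iter()) for t in trees]
    if len(set(leafsets)) != 1:
        raise DataError("trees have different leaf sets")
    shared = set.intersection(*(bipartitions(t) for t in trees))
    return tree_from_bipartitions(sorted(leafsets[0]), shared)


def tree_from_bipartitions(
    labels: Sequence[str], splits: Iterable[frozenset[str]]
) -> dendropy.Tree:
    """Build an unrooted tree from mutually compatible canonical splits."""
    labels = sorted(labels)
    ref = labels[0]
    ns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    root.add_child(dendropy.Node(taxon=ns.new_taxon(label=ref)))
    clades = sorted(splits, key=lambda s: (-len(s), sorted(s)))
    node_of: list[tuple[frozenset, dendropy.Node]] = []
    for cl in clades:
        parent = root
        for other, nd in node_of:
            if cl < other:
                parent = nd  # node_of is sorted big->small: last hit is smallest
        nd = dendropy.Node()
        parent.add_child(nd)
        node_of.append((cl, nd))
    for label in labels[1:]:
        parent = root
        for other, nd in node_of:
            if label in other:
                parent = nd
        parent.add_child(dendropy.Node(taxon=ns.new_taxon(label=label)))
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


def support_of(node: dendropy.Node) -> int | None:
    """Bootstrap support stored on a node label, if any."""
    if node.label is None:
        return None
    try:
        return int(node.label)
    except ValueError:
        return None


def _apply_supports(tree: dendropy.Tree, table: dict[frozenset, int]) -> None:
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    full, ref = frozenset(labels), labels[0]
    for nd in tree.postorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if ref in side:
            side = full - side
        if side in table:
            nd.label = str(table[side])


def supports_by_bipartition(tree: dendropy.Tree) -> dict[frozenset, int]:
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    full, ref = frozenset(labels), labels[0]
    out = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        s = support_of(nd)
        if s is None:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if ref in side:
            side = full - side
        out[side] = s
    return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _build_tree_from_weights(taxa, pat, weights, builder, params: SearchParams):
    if builder == "nj":
        d = _weighted_pdist(taxa, pat, weights, model="p")
        return [nj_tree(d)]
    if builder == "mp":
        trees, _ = _mp_search_patterns(pat, weights, params)
        return [t.to_dendropy(taxa) for t in trees]
    raise DataError(f"unknown tree builder {builder!r}")


def bootstrap(
    aln: Alignment,
    builder: str = "nj",
    n_reps: int = 1000,
    seed: int = 0,
    search_params: SearchParams | None = None,
) -> dendropy.Tree:
    """Point-estimate tree with nonparametric bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; the support of
    each internal edge of the point tree is the percentage of replicate
    trees containing that split, rounded half-up to an integer.  With the MP
    builder the point estimate (and each replicate's contribution) is the
    strict consensus of the equally-best trees.
    """
    if n_reps < 1:
        raise DataError("n_reps must be >= 1")
    params = search_params or SearchParams(n_addition_replicates=2)
    taxa, pat, w, col_to_pat = site_patterns(aln)
    L = aln.length

    point_trees = _build_tree_from_weights(taxa, pat, w, builder, params)
    point = point_trees[0] if len(point_trees) == 1 else strict_consensus(point_trees)

    counts: dict[frozenset, int] = {b: 0 for b in bipartitions(point)}
    rng = np.random.default_rng(seed)
    for rep in range(n_reps):
        col_counts = rng.multinomial(L, np.full(L, 1.0 / L))
        wrep = np.bincount(col_to_pat, weights=col_counts, minlength=pat.shape[1])
        keep = wrep > 0
        rep_params = replace(params, seed=int(rng.integers(0, 2**31 - 1)))
        rep_trees = _build_tree_from_weights(
            taxa, pat[:, keep], wrep[keep], builder, rep_params
        )
        rep_bips = (
            bipartitions(rep_trees[0])
            if len(rep_trees) == 1
            else set.intersection(*(bipartitions(t) for t in rep_trees))
        )
        for b in counts:
            if b in rep_bips:
                counts[b] += 1

    supports = {
        b: int(np.floor(100.0 * c / n_reps + 0.5)) for b, c in counts.items()
    }
    _apply_supports(point, supports)
    return point


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def root_with_outgroup(tree: dendropy.Tree, outgroup_ids: Sequence[str]) -> dendropy.Tree:
    """Root on the edge separating the outgroup taxa from the ingroup.

    Multi-taxon outgroups must be monophyletic on the unrooted tree,
    otherwise a :class:`DataError` is raised.
    """
    og = set(outgroup_ids)
    if not og:
        raise DataError("no outgroup ids given")
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = og - labels
    if missing:
        raise DataError(f"outgroup id(s) not on tree: {sorted(missing)}")
    saved = supports_by_bipartition(tree)
    tree = tree.clone(depth=1)
    target = None
    for nd in tree.postorder_node_iter():
        if nd.parent_node is None:
            continue
        side = {lf.taxon.label for lf in nd.leaf_iter()}
        if side == og or side == labels - og:
            target = nd
            break
    if target is None:
        raise DataError("outgroup is not monophyletic on this tree")
    edge = target.edge
    half = None if edge.length is None else edge.length / 2.0
    tree.is_rooted = True
    tree.reroot_at_edge(edge, length1=half, length2=half)
    # rerooting reshuffles which clade sits below which node: wipe the old
    # labels and re-attach supports by bipartition
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf():
            nd.label = None
    _apply_supports(tree, saved)
    return tree
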