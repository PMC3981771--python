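"""SNP-matrix phylogenetics: Fitch parsimony, JC69 maximum likelihood with
NNI search, nonparametric bootstrap, and the incongruence length difference
(ILD) permutation test.

The character matrix codes each taxon at each SNP site with its called
alternate allele, or the reference allele where the taxon has no SNP; the
reference accession is included as its own taxon.  With a few dozen sites
nothing richer than Jukes-Cantor is identifiable, so JC69 is the only
substitution model offered.  Searches are deterministic given the seed:
candidate order follows taxon order, and the incumbent is kept on ties.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .cohort import CohortTable

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_BASE = "ACGT"


# ---------------------------------------------------------------------------
# Character matrix

@dataclass
class CharacterMatrix:
    """Taxa x SNP-site nucleotide matrix (no missing data)."""

    taxa: list[str]
    sites: list  # site identifiers (genome positions or arbitrary labels)
    states: np.ndarray  # (n_taxa, n_sites) of single characters

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype="<U1")
        if self.states.shape != (len(self.taxa), len(self.sites)):
            raise ValueError("matrix shape does not match taxa/sites")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def masks(self) -> np.ndarray:
        """Per-cell 4-bit state masks for Fitch bookkeeping (cached)."""
        cached = getattr(self, "_masks", None)
        if cached is None:
            out = np.zeros(self.states.shape, dtype=np.uint8)
            for b, bit in _BASE_BIT.items():
                out[self.states == b] = bit
            if (out == 0).any():
                raise ValueError("matrix contains non-ACGT states")
            self._masks = cached = out
        return cached

    def onehot(self) -> np.ndarray:
        """Per-taxon (n_sites, 4) indicator arrays for pruning (cached)."""
        cached = getattr(self, "_onehot", None)
        if cached is None:
            idx = np.full(self.states.shape, -1, dtype=np.int64)
            for b, i in _BASE_IDX.items():
                idx[self.states == b] = i
            cached = np.zeros((self.n_taxa, self.n_sites, 4))
            rows = np.repeat(np.arange(self.n_taxa), self.n_sites)
            cols = np.tile(np.arange(self.n_sites), self.n_taxa)
            cached[rows, cols, idx.ravel()] = 1.0
            self._onehot = cached
        return cached

    def column_variable(self) -> np.ndarray:
        return np.array(
            [len(set(self.states[:, j])) > 1 for j in range(self.n_sites)]
        )

    def subset_taxa(self, taxa: list[str]) -> "CharacterMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return CharacterMatrix(list(taxa), list(self.sites), self.states[idx])

    def take_sites(self, idx) -> "CharacterMatrix":
        idx = np.asarray(idx)
        return CharacterMatrix(
            list(self.taxa), [self.sites[i] for i in idx], self.states[:, idx]
        )

    def concatenate(self, other: "CharacterMatrix") -> "CharacterMatrix":
        if self.taxa != other.taxa:
            raise ValueError("taxa differ between matrices")
        return CharacterMatrix(
            list(self.taxa),
            list(self.sites) + list(other.sites),
            np.concatenate([self.states, other.states], axis=1),
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\t" + "\t".join(str(s) for s in self.sites) + "\n")
            for i, t in enumerate(self.taxa):
                fh.write(t + "\t" + "\t".join(self.states[i]) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "CharacterMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            taxa, rows = [], []
            for ln in fh:
                parts = ln.rstrip("\n").split("\t")
                taxa.append(parts[0])
                rows.append(parts[1:])
        return cls(taxa, header, np.array(rows))


def build_matrix(
    table: CohortTable, reference_taxon: str = "KHA"
) -> CharacterMatrix:
    """Supermatrix from cohort calls: cultivar rows plus the reference row.

    Each cultivar is coded with its primary alternate allele at sites where
    it has a SNP and the reference allele elsewhere; the reference taxon
    carries the reference allele everywhere.
    """
    refs: dict[int, str] = {}
    alts: dict[tuple[str, int], str] = {}
    for r in table.records:
        if refs.setdefault(r.position, r.ref_base) != r.ref_base:
            raise ValueError(f"conflicting reference alleles at {r.position}")
        key = (r.cultivar, r.position)
        if alts.setdefault(key, r.alt_base) != r.alt_base:
            raise ValueError(f"conflicting alternate alleles for {key}")
    sites = sorted(refs)
    taxa = list(table.cultivars) + [reference_taxon]
    states = np.empty((len(taxa), len(sites)), dtype="<U1")
    for j, pos in enumerate(sites):
        states[-1, j] = refs[pos]
        for i, c in enumerate(table.cultivars):
            states[i, j] = alts.get((c, pos), refs[pos])
    return CharacterMatrix(taxa, sites, states)


# ---------------------------------------------------------------------------
# Unrooted trees

class Tree:
    """Unrooted tree over labelled leaves; integer node ids internally."""

    def __init__(self):
        self.adj: dict[int, set[int]] = {}
        self.labels: dict[int, str] = {}
        self.lengths: dict[frozenset, float] = {}
        self._next = 0

    # -- construction ------------------------------------------------------
    def add_node(self, label: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = set()
        if label is not None:
            self.labels[nid] = label
        return nid

    def add_edge(self, u: int, v: int, length: float = 0.0) -> None:
        self.adj[u].add(v)
        self.adj[v].add(u)
        self.lengths[frozenset((u, v))] = length

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self.lengths.pop(frozenset((u, v)), None)

    def copy(self) -> "Tree":
        t = Tree()
        t.adj = {n: set(s) for n, s in self.adj.items()}
        t.labels = dict(self.labels)
        t.lengths = dict(self.lengths)
        t._next = self._next
        return t

    @classmethod
    def star(cls, taxa: list[str]) -> "Tree":
        t = cls()
        hub = t.add_node()
        for name in taxa:
            leaf = t.add_node(name)
            t.add_edge(hub, leaf)
        return t

    def insert_leaf(self, u: int, v: int, label: str,
                    length: float = 0.0) -> int:
        """Subdivide edge (u,v) and attach a new labelled leaf."""
        old = self.lengths.get(frozenset((u, v)), 0.0)
        self.remove_edge(u, v)
        mid = self.add_node()
        leaf = self.add_node(label)
        self.add_edge(u, mid, old / 2)
        self.add_edge(mid, v, old / 2)
        self.add_edge(mid, leaf, length)
        return leaf

    # -- queries -----------------------------------------------------------
    def leaves(self) -> dict[int, str]:
        return dict(self.labels)

    def taxa(self) -> list[str]:
        return sorted(self.labels.values())

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (min(u, v), max(u, v))
            for u in self.adj for v in self.adj[u] if u < v
        )

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v) for u, v in self.edges()
            if u not in self.labels and v not in self.labels
        ]

    def side_labels(self, u: int, v: int) -> frozenset:
        """Leaf labels reachable from u when edge (u,v) is cut."""
        seen, stack, out = {v, u}, [u], []
        while stack:
            n = stack.pop()
            if n in self.labels:
                out.append(self.labels[n])
            for m in self.adj[n]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return frozenset(out)

    def bipartitions(self) -> set[frozenset]:
        """Nontrivial splits, each coded as the side NOT holding the first
        taxon in sorted order (a canonical representation)."""
        anchor = self.taxa()[0]
        out = set()
        for u, v in self.edges():
            side = self.side_labels(u, v)
            if len(side) < 2 or len(side) > len(self.labels) - 2:
                continue
            if anchor in side:
                side = frozenset(self.labels.values()) - side
            out.add(side)
        return out

    # -- rearrangement -----------------------------------------------------
    def nni_variants(self, edge: tuple[int, int]) -> list["Tree"]:
        """The two nearest-neighbour interchanges across an internal edge."""
        u, v = edge
        a, b = sorted(n for n in self.adj[u] if n != v)
        c, d = sorted(n for n in self.adj[v] if n != u)
        variants = []
        for swap in (c, d):
            t = self.copy()
            lb = t.lengths[frozenset((u, b))]
            ls = t.lengths[frozenset((v, swap))]
            t.remove_edge(u, b)
            t.remove_edge(v, swap)
            t.add_edge(u, swap, ls)
            t.add_edge(v, b, lb)
            variants.append(t)
        return variants

    # -- newick ------------------------------------------------------------
    def to_newick(
        self,
        lengths: bool = True,
        supports: dict[frozenset, float] | None = None,
    ) -> str:
        if not self.adj:
            return ";"
        root = max(self.adj, key=lambda n: (len(self.adj[n]), -n))
        anchor = self.taxa()[0]
        all_taxa = frozenset(self.labels.values())

        def fmt(node, parent):
            parts = []
            for child in sorted(self.adj[node]):
                if child == parent:
                    continue
                sub = fmt(child, node)
                if lengths:
                    sub += f":{self.lengths[frozenset((node, child))]:.6g}"
                parts.append(sub)
            if not parts:
                return self.labels[node]
            label = ""
            if supports is not None and parent is not None:
                side = self.side_labels(node, parent)
                key = side if anchor not in side else all_taxa - side
                if key in supports:
                    label = f"{supports[key]:g}"
            return "(" + ",".join(parts) + ")" + label

        return fmt(root, None) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        import dendropy

        dtree = dendropy.Tree.get(data=newick, schema="newick")
        t = cls()

        def build(dnode):
            label = dnode.taxon.label if dnode.taxon else None
            nid = t.add_node(label if not dnode.child_nodes() else None)
            for child in dnode.child_nodes():
                cid = build(child)
                t.add_edge(nid, cid, child.edge.length or 0.0)
            return nid

        root_id = build(dtree.seed_node)
        # splice out a degree-2 root left by rooted newick
        if len(t.adj[root_id]) == 2:
            a, b = sorted(t.adj[root_id])
            total = (t.lengths[frozenset((root_id, a))]
                     + t.lengths[frozenset((root_id, b))])
            t.remove_edge(root_id, a)
            t.remove_edge(root_id, b)
            del t.adj[root_id]
            t.add_edge(a, b, total)
        return t


# ---------------------------------------------------------------------------
# Fitch parsimony

def fitch_length(matrix: CharacterMatrix, tree: Tree) -> int:
    """Minimum number of state changes over all sites (Fitch 1971)."""
    if set(tree.labels.values()) != set(matrix.taxa):
        raise ValueError("tree leaves do not match matrix taxa")
    masks = matrix.masks()
    taxon_row = {t: i for i, t in enumerate(matrix.taxa)}
    root = next(iter(tree.labels))  # root at an arbitrary leaf
    # iterative postorder
    order, stack = [], [(root, None)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for child in tree.adj[node]:
            if child != parent:
                stack.append((child, node))
    node_mask: dict[int, np.ndarray] = {}
    changes = np.zeros(matrix.n_sites, dtype=np.int64)
    for node, parent in reversed(order):
        if node in tree.labels and node != root:
            node_mask[node] = masks[taxon_row[tree.labels[node]]]
            continue
        children = [c for c in tree.adj[node] if c != parent]
        if node == root:
            children = [c for c in tree.adj[node]]
        acc = None
        for c in children:
            m = node_mask.pop(c)
            if acc is None:
                acc = m
                continue
            inter = acc & m
            empty = inter == 0
            changes += empty
            acc = np.where(empty, acc | m, inter)
        if node == root:
            leaf = masks[taxon_row[tree.labels[root]]]
            changes += (acc & leaf) == 0
        else:
            node_mask[node] = acc
    return int(changes.sum())


def enumerate_topologies(taxa: list[str]):
    """Yield every unrooted binary topology on the given taxa."""
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    base = Tree.star(taxa[:3])

    def grow(tree, remaining):
        if not remaining:
            yield tree
            return
        name, rest = remaining[0], remaining[1:]
        for u, v in tree.edges():
            t = tree.copy()
            t.insert_leaf(u, v, name)
            yield from grow(t, rest)

    yield from grow(base, taxa[3:])


def parsimony_search(
    matrix: CharacterMatrix, seed: int = 0
) -> tuple[int, Tree]:
    """Heuristic best Fitch length: stepwise addition then NNI to a local
    optimum.  Taxon addition order is a seed-determined permutation."""
    rng = np.random.default_rng(seed)
    taxa = list(matrix.taxa)
    order = [taxa[i] for i in rng.permutation(len(taxa))]
    if len(taxa) < 4:
        tree = Tree.star(taxa)
        return fitch_length(matrix, tree), tree
    tree = Tree.star(order[:3])
    for step, name in enumerate(order[3:], start=4):
        sub = matrix.subset_taxa(order[:step])
        best, best_tree = None, None
        for u, v in tree.edges():
            t = tree.copy()
            t.insert_leaf(u, v, name)
            score = fitch_length(sub, t)
            if best is None or score < best:
                best, best_tree = score, t
        tree = best_tree
    best = fitch_length(matrix, tree)
    improved = True
    while improved:
        improved = False
        for edge in tree.internal_edges():
            for cand in tree.nni_variants(edge):
                score = fitch_length(matrix, cand)
                if score < best:
                    best, tree, improved = score, cand, True
                    break
            if improved:
                break
    return best, tree


# ---------------------------------------------------------------------------
# JC69 likelihood

def jc69_distance(p: float) -> float:
    """Closed-form JC69 distance for observed difference proportion p."""
    if not 0 <= p < 0.75:
        raise ValueError("p must be in [0, 0.75)")
    return -0.75 * np.log(1 - 4 * p / 3)


def _jc_transform(cp: np.ndarray, t: float) -> np.ndarray:
    """Propagate a conditional-likelihood array across a JC69 branch."""
    e = np.exp(-4.0 * max(t, 0.0) / 3.0)
    s = cp.sum(axis=1, keepdims=True)
    return 0.25 * (1 - e) * s + e * cp


def _cond_partial(matrix: CharacterMatrix, tree: Tree, taxon_row: dict,
                  node: int, away_from: int | None) -> np.ndarray:
    """Conditional likelihood of the component at ``node`` (excluding the
    ``away_from`` side), conditional on the state at ``node``."""
    if node in tree.labels:
        leaf = matrix.onehot()[taxon_row[tree.labels[node]]]
        if all(c == away_from for c in tree.adj[node]):
            return leaf
        P = leaf.copy()
    else:
        P = np.ones((matrix.n_sites, 4))
    for child in tree.adj[node]:
        if child == away_from:
            continue
        cp = _cond_partial(matrix, tree, taxon_row, child, node)
        P = P * _jc_transform(cp, tree.lengths[frozenset((node, child))])
    return P


def log_likelihood(matrix: CharacterMatrix, tree: Tree) -> float:
    """Felsenstein-pruning log likelihood under JC69 (uniform base priors)."""
    taxon_row = {t: i for i, t in enumerate(matrix.taxa)}
    u, v = tree.edges()[0]
    A = _cond_partial(matrix, tree, taxon_row, u, v)
    B = _cond_partial(matrix, tree, taxon_row, v, u)
    t = tree.lengths[frozenset((u, v))]
    site_lik = 0.25 * (A * _jc_transform(B, t)).sum(axis=1)
    return float(np.sum(np.log(np.maximum(site_lik, 1e-300))))


def optimize_branch_lengths(
    matrix: CharacterMatrix, tree: Tree, tol: float = 1e-6, max_passes: int = 12
) -> float:
    """Optimize each branch length in turn (Brent) until converged.

    For each edge the two flanking conditional-likelihood arrays are
    computed once, making every Brent iteration O(sites)."""
    taxon_row = {t: i for i, t in enumerate(matrix.taxa)}
    prev = log_likelihood(matrix, tree)
    for _ in range(max_passes):
        for edge in tree.edges():
            key = frozenset(edge)
            u, v = edge
            A = _cond_partial(matrix, tree, taxon_row, u, v)
            B = _cond_partial(matrix, tree, taxon_row, v, u)

            def neg(t):
                site_lik = 0.25 * (A * _jc_transform(B, t)).sum(axis=1)
                return -float(np.sum(np.log(np.maximum(site_lik, 1e-300))))

            res = minimize_scalar(
                neg, bounds=(0.0, 10.0), method="bounded",
                options={"xatol": 1e-8},
            )
            if neg(float(res.x)) < neg(tree.lengths[key]):
                tree.lengths[key] = float(res.x)
        cur = log_likelihood(matrix, tree)
        if cur - prev < tol:
            return cur
        prev = cur
    return prev


def ml_tree(matrix: CharacterMatrix, seed: int = 0) -> tuple[Tree, float]:
    """JC69 maximum-likelihood tree via parsimony start + NNI search.

    Returns (tree, log_likelihood); branch lengths are in expected
    substitutions per site.
    """
    if matrix.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    if not matrix.column_variable().any():
        warnings.warn(
            "all columns invariant: topology is arbitrary (star-like data)"
        )
    _, tree = parsimony_search(matrix, seed=seed)
    for key in tree.lengths:
        tree.lengths[key] = max(tree.lengths[key], 0.05)
    best_ll = optimize_branch_lengths(matrix, tree)
    improved = True
    while improved:
        improved = False
        for edge in tree.internal_edges():
            for cand in tree.nni_variants(edge):
                # cheap screen, then full optimisation on acceptance
                ll = optimize_branch_lengths(matrix, cand, max_passes=2)
                if ll > best_ll + 1e-9:
                    best_ll = optimize_branch_lengths(matrix, cand)
                    tree, improved = cand, True
                    break
            if improved:
                break
    return tree, best_ll


def bootstrap(
    matrix: CharacterMatrix,
    tree: Tree | None = None,
    n_replicates: int = 1000,
    seed: int = 0,
) -> dict[frozenset, float]:
    """Percent of site-resampled ML replicates containing each bipartition
    of the reference ML tree."""
    if tree is None:
        tree, _ = ml_tree(matrix, seed=seed)
    ref_splits = tree.bipartitions()
    counts = {s: 0 for s in ref_splits}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        idx = rng.integers(0, matrix.n_sites, size=matrix.n_sites)
        rep, _ = ml_tree(matrix.take_sites(idx),
                         seed=int(rng.integers(0, 2**31 - 1)))
        rep_splits = rep.bipartitions()
        for s in ref_splits:
            if s in rep_splits:
                counts[s] += 1
    return {s: 100.0 * c / n_replicates for s, c in counts.items()}


# ---------------------------------------------------------------------------
# ILD permutation test

def ild_test(
    matrix_a: CharacterMatrix,
    matrix_b: CharacterMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[int, float]:
    """Incongruence length difference test between two character partitions.

    D = L(A+B) - [L(A) + L(B)] with L the heuristic-best Fitch length; the
    null repartitions the pooled sites into pseudo-partitions of the original
    sizes.  Returns (D, p) with p = (1 + #{D_perm >= D_obs}) / (1 + n_perm).
    """
    if matrix_a.taxa != matrix_b.taxa:
        raise ValueError("matrices must share the same taxa")
    if matrix_a.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    pooled = matrix_a.concatenate(matrix_b)
    l_pool, _ = parsimony_search(pooled, seed=seed)
    l_a, _ = parsimony_search(matrix_a, seed=seed)
    l_b, _ = parsimony_search(matrix_b, seed=seed)
    d_obs = l_pool - (l_a + l_b)
    rng = np.random.default_rng(seed)
    n_a = matrix_a.n_sites
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled.n_sites)
        la, _ = parsimony_search(pooled.take_sites(perm[:n_a]), seed=seed)
        lb, _ = parsimony_search(pooled.take_sites(perm[n_a:]), seed=seed)
        if l_pool - (la + lb) >= d_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return d_obs, p


# ---------------------------------------------------------------------------
# Character simulation (for property tests and power analyses)

def simulate_characters(
    tree: Tree, n_sites: int, seed: int = 0
) -> CharacterMatrix:
    """Evolve independent sites along ``tree`` under JC69."""
    rng = np.random.default_rng(seed)
    internal = [n for n in tree.adj if n not in tree.labels]
    root = internal[0] if internal else next(iter(tree.adj))
    states = {root: rng.integers(0, 4, size=n_sites)}
    order, stack = [], [(root, None)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for child in tree.adj[node]:
            if child != parent:
                stack.append((child, node))
    for node, parent in order:
        if parent is None:
            continue
        t = tree.lengths[frozenset((node, parent))]
        p_change = 0.75 * (1 - np.exp(-4.0 * t / 3.0))
        cur = states[parent].copy()
        flip = rng.random(n_sites) < p_change
        if flip.any():
            # draw one of the three other states uniformly
            shift = rng.integers(1, 4, size=int(flip.sum()))
            cur[flip] = (cur[flip] + shift) % 4
        states[node] = cur
    taxa = sorted(tree.labels.values())
    label_node = {v: k for k, v in tree.labels.items()}
    mat = np.empty((len(taxa), n_sites), dtype="<U1")
    for i, taxon in enumerate(taxa):
        mat[i] = np.array(list(_IDX_BASE))[states[label_node[taxon]]]
    return CharacterMatrix(taxa, list(range(1, n_sites + 1)), mat)
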