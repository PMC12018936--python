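"""Maximum parsimony on discrete morphological characters.

Tree length is computed with the generalized Sankoff dynamic program, which
covers both unordered (Fitch) characters, where any change costs 1, and
ordered morphocline (Wagner) characters, where a change from state *i* to *j*
costs ``|i - j|``.  Missing cells are free to take any state and therefore
contribute nothing to the length.  Polytomies are scored as hard polytomies.

Ancestral states are reported as full MPR sets: for each node, every state it
takes in at least one minimum-length labeling (no ACCTRAN/DELTRAN choice is
made).

Tree search is deliberately simple and reproducible: random-addition starting
trees followed by SPR (or NNI) hill climbing, optionally under a molecular
scaffold that fixes the relationships of a constrained (extant) taxon subset
while letting all other (fossil) taxa attach anywhere compatible.  All
equally best trees found are retained, and ties are broken by a canonical
lexicographic tree order so runs are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Mapping, Sequence

import dendropy
import numpy as np

from .io_formats import MISSING, CharacterMatrix

INF = np.int64(10**9)


class ParsimonyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cost model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CostModel:
    """Per-character step costs: unordered (0/1) or ordered (|i-j|)."""

    n_states: tuple[int, ...]
    ordered: tuple[bool, ...]

    @classmethod
    def from_matrix(cls, matrix: CharacterMatrix) -> "CostModel":
        n_states = []
        for j in range(matrix.n_chars):
            # include states mentioned in ambiguity sets beyond the per-column max
            n_states.append(max(matrix.n_states(j), 1))
        return cls(n_states=tuple(n_states), ordered=tuple(matrix.ordered))

    def cost_matrix(self, j: int) -> np.ndarray:
        return _step_matrix(self.n_states[j], self.ordered[j])


@lru_cache(maxsize=256)
def _step_matrix(n_states: int, ordered: bool) -> np.ndarray:
    idx = np.arange(n_states)
    if ordered:
        mat = np.abs(idx[:, None] - idx[None, :])
    else:
        mat = (idx[:, None] != idx[None, :]).astype(np.int64)
    return mat.astype(np.int64)


# ---------------------------------------------------------------------------
# internal tree structure
#
# Scoring works on a flat postorder representation so the same code serves
# dendropy trees (possibly with polytomies) and the search's nested-tuple
# binary trees.
# ---------------------------------------------------------------------------


def _structure_from_dendropy(tree: dendropy.Tree) -> tuple[list[list[int]], list[str | None]]:
    nodes = list(tree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    children = [[index[id(c)] for c in nd.child_nodes()] for nd in nodes]
    labels: list[str | None] = [
        (nd.taxon.label if nd.taxon is not None else nd.label) if nd.is_leaf() else None
        for nd in nodes
    ]
    for nd, lab in zip(nodes, labels):
        if nd.is_leaf() and lab is None:
            raise ParsimonyError("tree has an unlabeled tip")
    return children, labels


# nested-tuple trees: a leaf is a string, an internal node a tuple of subtrees
def _structure_from_tuple(tree) -> tuple[list[list[int]], list[str | None]]:
    children: list[list[int]] = []
    labels: list[str | None] = []

    def walk(node) -> int:
        if isinstance(node, str):
            children.append([])
            labels.append(node)
            return len(children) - 1
        idx = [walk(c) for c in node]
        children.append(idx)
        labels.append(None)
        return len(children) - 1

    walk(tree)
    return children, labels


def _as_structure(tree) -> tuple[list[list[int]], list[str | None]]:
    if isinstance(tree, dendropy.Tree):
        return _structure_from_dendropy(tree)
    return _structure_from_tuple(tree)


def _tip_rows(labels: Sequence[str | None], matrix: CharacterMatrix) -> dict[int, int]:
    taxon_index = {t: i for i, t in enumerate(matrix.taxa)}
    rows: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab is not None:
            if lab not in taxon_index:
                raise ParsimonyError(f"tip {lab!r} absent from character matrix")
            rows[i] = taxon_index[lab]
    return rows


def _char_groups(costs: CostModel) -> dict[tuple[int, bool], list[int]]:
    groups: dict[tuple[int, bool], list[int]] = {}
    for j, (s, o) in enumerate(zip(costs.n_states, costs.ordered)):
        groups.setdefault((s, o), []).append(j)
    return groups


def _down_pass_group(
    children: Sequence[Sequence[int]],
    labels: Sequence[str | None],
    tip_row: Mapping[int, int],
    matrix: CharacterMatrix,
    chars: Sequence[int],
    n_states: int,
    cost: np.ndarray,
) -> list[np.ndarray | None]:
    """Sankoff down-pass for one (n_states, ordered) character class.

    Returns, per node, an array of shape (len(chars), n_states) with the
    minimal subtree cost conditional on the node's state.
    """
    k = len(chars)
    down: list[np.ndarray | None] = [None] * len(children)
    for i, kids in enumerate(children):
        if not kids:
            row = matrix.cells[tip_row[i]]
            arr = np.full((k, n_states), INF, dtype=np.int64)
            for c, j in enumerate(chars):
                cell = row[j]
                if cell is MISSING or not cell:
                    arr[c, :] = 0
                else:
                    for s in cell:
                        if s < n_states:
                            arr[c, s] = 0
            down[i] = arr
        else:
            acc = np.zeros((k, n_states), dtype=np.int64)
            for c_idx in kids:
                d = down[c_idx]
                # min over child state t of cost[s, t] + d[:, t]
                acc = acc + (d[:, None, :] + cost[None, :, :]).min(axis=2)
            down[i] = acc
    return down


class MatrixScorer:
    """Precomputed Sankoff machinery for one (matrix, cost model) pair.

    All characters are padded to a common state count; padded states carry
    infinite cost so they never enter a minimum.  Scoring a tree is then one
    vectorized min-plus per node over all characters at once.
    """

    def __init__(self, matrix: CharacterMatrix, costs: CostModel | None = None) -> None:
        if costs is None:
            costs = CostModel.from_matrix(matrix)
        self.matrix = matrix
        self.costs = costs
        n_chars = matrix.n_chars
        S = max(costs.n_states) if n_chars else 1
        C = np.full((n_chars, S, S), INF, dtype=np.int64)
        for j in range(n_chars):
            s = costs.n_states[j]
            C[j, :s, :s] = _step_matrix(s, costs.ordered[j])
        self.C = C
        self.tip: dict[str, np.ndarray] = {}
        for i, taxon in enumerate(matrix.taxa):
            arr = np.full((n_chars, S), INF, dtype=np.int64)
            for j, cell in enumerate(matrix.cells[i]):
                s = costs.n_states[j]
                if not cell:
                    arr[j, :s] = 0
                else:
                    for st in cell:
                        if st < s:
                            arr[j, st] = 0
            self.tip[taxon] = arr

    def _down(self, node) -> np.ndarray:
        if isinstance(node, str):
            try:
                return self.tip[node]
            except KeyError:
                raise ParsimonyError(f"tip {node!r} absent from character matrix") from None
        acc = None
        for child in node:
            d = self._down(child)
            md = (self.C + d[:, None, :]).min(axis=2)
            acc = md if acc is None else acc + md
        return acc

    def length(self, tree) -> int:
        """Parsimony length of a tuple tree or dendropy tree."""
        if isinstance(tree, dendropy.Tree):
            tree = dendropy_to_tuple(tree)
        if isinstance(tree, str):
            return 0
        return int(self._down(tree).min(axis=1).sum())


def tree_length(tree, matrix: CharacterMatrix, costs: CostModel | None = None) -> int:
    """Parsimony length of *tree* (dendropy Tree or nested tuples) on *matrix*."""
    return MatrixScorer(matrix, costs).length(tree)


def mpr_states(
    tree, matrix: CharacterMatrix, costs: CostModel | None = None, char_index: int = 0
) -> dict:
    """Full MPR state sets for one character.

    Returns a mapping from node to the frozenset of states that node takes in
    at least one minimum-length labeling.  For a dendropy tree the keys are
    the tree's nodes; for a tuple tree, postorder node indices.
    """
    if costs is None:
        costs = CostModel.from_matrix(matrix)
    children, labels = _as_structure(tree)
    tip_row = _tip_rows(labels, matrix)
    n_states = costs.n_states[char_index]
    cost = _step_matrix(n_states, costs.ordered[char_index])
    down_l = _down_pass_group(
        children, labels, tip_row, matrix, [char_index], n_states, cost
    )
    down = [d[0] for d in down_l]  # (n_states,) per node
    n_nodes = len(children)
    root = n_nodes - 1
    up: list[np.ndarray | None] = [None] * n_nodes
    up[root] = np.zeros(n_states, dtype=np.int64)
    parent = [-1] * n_nodes
    for i, kids in enumerate(children):
        for c in kids:
            parent[c] = i
    # preorder = reversed postorder
    for i in range(n_nodes - 1, -1, -1):
        for c in children[i]:
            # contribution of child c to down[i], per parent state t
            contrib = (down[c][None, :] + cost).min(axis=1)
            rest = up[i] + down[i] - contrib
            up[c] = (rest[:, None] + cost).min(axis=0)
    best = int((down[root] + up[root]).min())
    result: dict = {}
    for i in range(n_nodes):
        total = down[i] + up[i]
        states = frozenset(int(s) for s in np.nonzero(total == best)[0])
        if not states:
            raise ParsimonyError("empty MPR set (internal error)")
        result[i] = states
    if isinstance(tree, dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        return {nodes[i]: result[i] for i in range(n_nodes)}
    return result


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def _leafset(tree) -> frozenset[str]:
    if isinstance(tree, dendropy.Tree):
        return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    return frozenset(_tuple_leaves(tree))


def rooted_clades(tree, *, include_trivial: bool = False) -> set[frozenset[str]]:
    """Rooted clades (leaf-label sets of internal nodes) of *tree*."""
    clades: set[frozenset[str]] = set()
    if isinstance(tree, dendropy.Tree):
        for nd in tree.postorder_node_iter():
            leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            if len(leaves) >= 2 or include_trivial:
                clades.add(leaves)
    else:
        def walk(node) -> frozenset[str]:
            if isinstance(node, str):
                s = frozenset([node])
                if include_trivial:
                    clades.add(s)
                return s
            s = frozenset().union(*(walk(c) for c in node))
            clades.add(s)
            return s

        walk(tree)
    return clades


def tree_from_clades(taxa: Sequence[str], clades: set[frozenset[str]]) -> dendropy.Tree:
    """Build the rooted tree whose internal nodes are exactly *clades*.

    *clades* must be pairwise compatible (nested or disjoint) and include the
    full taxon set.
    """
    full = frozenset(taxa)
    all_sets = {full} | {c for c in clades if len(c) >= 2}
    ns = dendropy.TaxonNamespace([str(t) for t in sorted(taxa)])
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    nodes: dict[frozenset[str], dendropy.Node] = {}
    ordered_sets = sorted(all_sets, key=lambda s: (-len(s), sorted(s)))
    for s in ordered_sets:
        nodes[s] = tree.seed_node if s == full else dendropy.Node()
    # attach each clade (and each tip) to its smallest proper superset
    def smallest_superset(s: frozenset[str]) -> frozenset[str]:
        best = full
        for t in all_sets:
            if s < t and len(t) < len(best):
                best = t
        return best

    for s in ordered_sets:
        if s != full:
            nodes[smallest_superset(s)].add_child(nodes[s])
    for taxon in sorted(taxa):
        leaf = dendropy.Node(taxon=ns.get_taxon(str(taxon)))
        nodes[smallest_superset(frozenset([taxon]))].add_child(leaf)
    return tree


def strict_consensus(trees: Sequence) -> dendropy.Tree:
    """Strict consensus: exactly the rooted clades present in every input tree."""
    if not trees:
        raise ParsimonyError("strict_consensus requires at least one tree")
    leafsets = {_leafset(t) for t in trees}
    if len(leafsets) != 1:
        raise ParsimonyError("strict_consensus requires identical taxon sets")
    taxa = sorted(next(iter(leafsets)))
    common = rooted_clades(trees[0])
    for t in trees[1:]:
        common &= rooted_clades(t)
    return tree_from_clades(taxa, common)


def _prune_tuple(tree, keep: frozenset[str]):
    if isinstance(tree, str):
        return tree if tree in keep else None
    kids = [p for p in (_prune_tuple(c, keep) for c in tree) if p is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    return tuple(kids)


def restrict_tree(tree, keep: frozenset[str]) -> dendropy.Tree:
    """Copy of *tree* restricted to the tip labels in *keep* (degree-2 nodes suppressed)."""
    if not isinstance(tree, dendropy.Tree):
        pruned = _prune_tuple(tree, keep)
        if pruned is None:
            raise ParsimonyError("restriction removed all taxa")
        return pruned
    clone = tree.clone(depth=1)
    clone.retain_taxa_with_labels(sorted(keep & _leafset(tree)))
    return clone


def reduced_consensus(trees: Sequence, prune: Sequence[str]) -> dendropy.Tree:
    """Strict consensus after deleting the *prune* (rogue) taxa from every tree."""
    if not trees:
        raise ParsimonyError("reduced_consensus requires at least one tree")
    full = _leafset(trees[0])
    keep = full - set(prune)
    if not keep:
        raise ParsimonyError("cannot prune all taxa")
    pruned = [restrict_tree(t, frozenset(keep)) for t in trees]
    return strict_consensus(pruned)


# ---------------------------------------------------------------------------
# scaffold constraint
# ---------------------------------------------------------------------------


@dataclass
class ScaffoldConstraint:
    """Backbone topology fixing relationships among a constrained taxon subset.

    In the molecular-scaffold approach the backbone carries the extant taxa
    arranged by molecular phylogeny; all other (fossil) taxa float and may
    attach anywhere that keeps the restricted tree a refinement of the
    backbone.
    """

    backbone: dendropy.Tree | None = None

    @property
    def constrained_taxa(self) -> frozenset[str]:
        if self.backbone is None:
            return frozenset()
        return _leafset(self.backbone)

    def required_clades(self, present: frozenset[str] | None = None) -> set[frozenset[str]]:
        """Backbone clades, optionally restricted to the taxa in *present*."""
        if self.backbone is None:
            return set()
        if present is None:
            return {c for c in rooted_clades(self.backbone) if len(c) >= 2}
        clades = set()
        for c in rooted_clades(self.backbone):
            r = frozenset(c & present)
            if len(r) >= 2:
                clades.add(r)
        return clades


def satisfies_scaffold(tree, constraint: ScaffoldConstraint | None) -> bool:
    """True iff *tree* restricted to the constrained taxa refines the backbone."""
    if constraint is None or constraint.backbone is None:
        return True
    present = _leafset(tree)
    required = constraint.required_clades(frozenset(present))
    if not required:
        return True
    keep = constraint.constrained_taxa & present
    restricted = restrict_tree(tree, frozenset(keep))
    have = rooted_clades(restricted)
    return required <= have


# ---------------------------------------------------------------------------
# tuple-tree utilities for search
# ---------------------------------------------------------------------------


def _tuple_leaves(tree) -> list[str]:
    if isinstance(tree, str):
        return [tree]
    out: list[str] = []
    for c in tree:
        out.extend(_tuple_leaves(c))
    return out


def canonical(tree):
    """Canonical form of a tuple tree: children sorted by smallest leaf label."""
    if isinstance(tree, str):
        return tree
    kids = sorted((canonical(c) for c in tree), key=_min_leaf)
    return tuple(kids)


def _min_leaf(tree) -> str:
    while not isinstance(tree, str):
        tree = min(tree, key=_min_leaf)
    return tree


def _tree_key(tree):
    """Total order on tuple trees (leaves before internals, then recursive)."""
    if isinstance(tree, str):
        return (0, tree)
    return (1, tuple(_tree_key(c) for c in canonical(tree)))


def tuple_to_newick(tree) -> str:
    def fmt(node) -> str:
        if isinstance(node, str):
            return node
        return "(" + ",".join(fmt(c) for c in node) + ")"

    return fmt(tree) + ";"


def tuple_to_dendropy(tree, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    t = dendropy.Tree.get(
        data=tuple_to_newick(tree),
        schema="newick",
        preserve_underscores=True,
        rooting="force-rooted",
        taxon_namespace=taxon_namespace,
    )
    return t


def dendropy_to_tuple(tree: dendropy.Tree):
    def walk(nd):
        if nd.is_leaf():
            return nd.taxon.label if nd.taxon else nd.label
        return tuple(walk(c) for c in nd.child_nodes())

    return walk(tree.seed_node)


def _insertions(subtree, leaf: str) -> Iterator:
    """All trees from attaching *leaf* on each edge of *subtree* (incl. its root edge)."""
    yield (leaf, subtree)
    if not isinstance(subtree, str):
        for i, child in enumerate(subtree):
            for new_child in _insertions(child, leaf):
                yield subtree[:i] + (new_child,) + subtree[i + 1 :]


def _subtrees_with_removal(tree) -> Iterator[tuple[object, object]]:
    """Yield (pruned_subtree, remainder) for every proper subtree of *tree*.

    The remainder has the pruned subtree's parent suppressed.  *tree* must be
    binary.
    """
    if isinstance(tree, str):
        return
    a, b = tree
    yield a, b
    yield b, a
    for sub, rem in _subtrees_with_removal(a):
        yield sub, (rem, b)
    for sub, rem in _subtrees_with_removal(b):
        yield sub, (a, rem)


def _attachments(tree, subtree) -> Iterator:
    """All trees from attaching *subtree* on each edge of *tree* (incl. root edge)."""
    yield (subtree, tree)
    if not isinstance(tree, str):
        for i, child in enumerate(tree):
            for new_child in _attachments(child, subtree):
                yield tree[:i] + (new_child,) + tree[i + 1 :]


def spr_neighbors(ingroup) -> Iterator:
    """SPR neighborhood of a binary tuple tree (ingroup side only)."""
    for sub, rem in _subtrees_with_removal(ingroup):
        for t in _attachments(rem, sub):
            yield t


def nni_neighbors(ingroup) -> Iterator:
    """NNI neighborhood: swap subtrees across each internal edge."""
    if isinstance(ingroup, str):
        return
    a, b = ingroup
    if not isinstance(a, str):
        a0, a1 = a
        yield ((a0, b), a1)
        yield ((a1, b), a0)
        for na in nni_neighbors(a):
            yield (na, b)
    if not isinstance(b, str):
        b0, b1 = b
        yield ((b0, a), b1)
        yield ((b1, a), b0)
        for nb in nni_neighbors(b):
            yield (a, nb)


# ---------------------------------------------------------------------------
# heuristic search
# ---------------------------------------------------------------------------


@dataclass
class SearchConfig:
    """Settings for the random-addition + rearrangement search."""

    n_replicates: int = 10
    rearrangement: str = "SPR"
    max_trees_retained: int = 100
    seed: int = 0
    outgroup: str | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.max_trees_retained < 1:
            raise ValueError("n_replicates and max_trees_retained must be positive")
        if self.rearrangement not in ("SPR", "NNI"):
            raise ValueError("rearrangement must be 'SPR' or 'NNI'")


class _Pool:
    """Collects all distinct equally best trees seen so far."""

    def __init__(self, max_trees: int) -> None:
        self.best: int | None = None
        self.trees: dict = {}
        self.max_trees = max_trees

    def offer(self, tree, length: int) -> None:
        if self.best is None or length < self.best:
            self.best = length
            self.trees = {canonical(tree): tree}
        elif length == self.best and len(self.trees) < self.max_trees:
            self.trees.setdefault(canonical(tree), tree)


def _scaffold_ok(ingroup, outgroup: str, constraint: ScaffoldConstraint | None) -> bool:
    if constraint is None or constraint.backbone is None:
        return True
    return satisfies_scaffold((outgroup, ingroup), constraint)


def heuristic_search(
    matrix: CharacterMatrix,
    costs: CostModel | None = None,
    constraint: ScaffoldConstraint | None = None,
    config: SearchConfig | None = None,
) -> list[dendropy.Tree]:
    """Random-addition + hill-climbing parsimony search.

    Returns all distinct best-length trees found (up to
    ``config.max_trees_retained``), as rooted dendropy trees with the
    outgroup (``config.outgroup``, default: lexicographically first taxon)
    attached at the root.  Deterministic given ``config.seed``.
    """
    if config is None:
        config = SearchConfig()
    if costs is None:
        costs = CostModel.from_matrix(matrix)
    taxa = list(matrix.taxa)
    if len(taxa) < 2:
        raise ParsimonyError("need at least two taxa to search")
    outgroup = config.outgroup or min(taxa)
    if outgroup not in taxa:
        raise ParsimonyError(f"outgroup {outgroup!r} not in matrix")
    ingroup_taxa = sorted(t for t in taxa if t != outgroup)
    if constraint is not None and constraint.backbone is not None:
        missing = constraint.constrained_taxa - set(taxa)
        if missing:
            raise ParsimonyError(f"scaffold taxa absent from matrix: {sorted(missing)}")

    scorer = MatrixScorer(matrix, costs)
    memo: dict = {}

    def length_of(ingroup) -> int:
        key = canonical(ingroup)
        ln = memo.get(key)
        if ln is None:
            ln = scorer.length((outgroup, ingroup) if ingroup_taxa else outgroup)
            memo[key] = ln
        return ln

    pool = _Pool(config.max_trees_retained)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    neighbor_fn = spr_neighbors if config.rearrangement == "SPR" else nni_neighbors

    for rep_seed in seeds:
        rng = np.random.default_rng(rep_seed)
        order = list(ingroup_taxa)
        rng.shuffle(order)
        current = _random_addition(order, outgroup, constraint, length_of)
        if current is None:
            raise ParsimonyError("no constraint-satisfying tree could be constructed")
        cur_len = length_of(current)
        pool.offer(current, cur_len)
        improved = True
        while improved:
            improved = False
            best_nb, best_len = None, cur_len
            for nb in neighbor_fn(current):
                if not _scaffold_ok(nb, outgroup, constraint):
                    continue
                ln = length_of(nb)
                pool.offer(nb, ln)
                if ln < best_len or (
                    ln == best_len and best_nb is not None and _tree_key(nb) < _tree_key(best_nb)
                ):
                    if ln < cur_len:
                        best_nb, best_len = nb, ln
            if best_nb is not None:
                current, cur_len = best_nb, best_len
                improved = True

    ns = dendropy.TaxonNamespace(sorted(taxa))
    out = []
    for key in sorted(pool.trees, key=_tree_key):
        ingroup = pool.trees[key]
        full = (outgroup, ingroup) if ingroup_taxa else outgroup
        out.append(tuple_to_dendropy(canonical(full), ns))
    return out


def _random_addition(order, outgroup, constraint, length_of):
    """Stepwise addition: insert each taxon at the best scaffold-compatible edge."""
    if not order:
        return None
    current = order[0]
    for leaf in order[1:]:
        best, best_len = None, None
        for cand in _insertions(current, leaf):
            if not _scaffold_ok(cand, outgroup, constraint):
                continue
            ln = length_of(cand)
            if best_len is None or ln < best_len or (
                ln == best_len and _tree_key(cand) < _tree_key(best)
            ):
                best, best_len = cand, ln
        if best is None:
            return None
        current = best
    return current


# ---------------------------------------------------------------------------
# exhaustive enumeration (for tiny problems and as a search baseline)
# ---------------------------------------------------------------------------


def all_rooted_shapes(leaves: Sequence[str]) -> list:
    """All (2n-3)!! rooted binary tuple trees on *leaves*, by stepwise insertion."""
    leaves = list(leaves)
    if not leaves:
        raise ParsimonyError("need at least one leaf")
    trees = [leaves[0]]
    for leaf in leaves[1:]:
        trees = [t for base in trees for t in _insertions(base, leaf)]
    return trees


def all_unrooted_topologies(taxa: Sequence[str], outgroup: str | None = None) -> list:
    """All (2n-5)!! unrooted topologies on *taxa*, each as a rooted tuple tree
    ``(outgroup, ingroup_shape)`` so every unrooted topology appears exactly once."""
    taxa = sorted(taxa)
    out = outgroup or taxa[0]
    rest = [t for t in taxa if t != out]
    if not rest:
        raise ParsimonyError("need at least two taxa")
    return [(out, shape) for shape in all_rooted_shapes(rest)]
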