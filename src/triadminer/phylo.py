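"""Distance-based phylogenetics and the HGT nesting test.

The evolutionary claim under test is topological: streptophyte (plant)
LPR1-like sequences form a single monophyletic clade *nested inside* a
bacterial radiation — the signature of one horizontal gene transfer from
bacteria into the streptophyte stem, rather than vertical descent (which
would place plants as a sister group to all bacterial sequences) or
repeated transfers (which would scatter them).

Tree inference here is deliberately simple and fully deterministic:
p-distances (optionally Poisson-corrected), neighbor joining with
label-order tie-breaking, midpoint rooting, and nonparametric bootstrap
over alignment columns.  The nesting test itself is method-agnostic and
works on any rooted tree with labelled leaves.

Trees are dendropy ``Tree`` objects throughout; Newick is the on-disk
format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np



@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered leaf labels."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("diagonal must be zero")
        if (self.d < 0).any() or not np.isfinite(self.d).all():
            raise ValueError("distances must be finite and non-negative")


@dataclass(frozen=True)
class CladeTest:
    """Outcome of the HGT topology test for a query leaf set."""

    taxa: frozenset[str]
    monophyletic: bool
    nesting: bool
    support: float | None = None


# ---------------------------------------------------------------------------
# pairwise alignment


def global_align(
    a: str,
    b: str,
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[tuple[str, str], float]:
    """Optimal global alignment under affine gap penalties.

    Returns the aligned pair and percent identity (identical aligned
    positions over total alignment columns x 100).  Penalties are given
    as positive magnitudes.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    ident = sum(x == y and x != "-" for x, y in zip(sa, sb))
    return (sa, sb), ident / len(sa) * 100.0


# ---------------------------------------------------------------------------
# distances


def distance_matrix(
    msa: Sequence[tuple[str, str]], correction: str = "none"
) -> DistanceMatrix:
    """p-distance matrix over shared non-gap columns (pairwise deletion).

    ``correction='poisson'`` applies d = -ln(1 - p).  Saturated pairs
    (p = 1, which would give an infinite corrected distance) are clamped
    to p = 1 - 1/(2 L) over the L shared columns; pairs with zero shared
    columns raise.
    """
    if correction not in ("none", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    labels = tuple(sid for sid, _ in msa)
    seqs = [s for _, s in msa]
    n = len(seqs)
    if len(set(labels)) != n:
        raise ValueError("duplicate labels in alignment")
    L = len(seqs[0]) if seqs else 0
    if any(len(s) != L for s in seqs):
        raise ValueError("ragged alignment")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = diff = 0
            for x, y in zip(seqs[i], seqs[j]):
                if x in "-." or y in "-.":
                    continue
                shared += 1
                diff += x != y
            if shared == 0:
                raise ValueError(
                    f"no shared non-gap columns between {labels[i]!r} and {labels[j]!r}"
                )
            p = diff / shared
            if correction == "poisson":
                if p >= 1:
                    p = 1 - 1 / (2 * shared)
                dij = -math.log(1 - p)
            else:
                dij = p
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# neighbor joining

class _Cluster:
    __slots__ = ("newick", "min_label")

    def __init__(self, newick: str, min_label: str):
        self.newick = newick
        self.min_label = min_label


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor-joining agglomeration.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of cluster representative labels, so the result is deterministic
    and invariant to input row order.  Negative intermediate branch
    lengths are clamped to 0 with the deficit shifted onto the sister
    branch; the final unrooted tree has a trifurcating root node.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 leaves")

    active = list(range(n))
    clusters: dict[int, _Cluster] = {
        i: _Cluster(lab, lab) for i, lab in enumerate(D.labels)
    }
    dist = {(i, j): float(D.d[i, j]) for i in range(n) for j in range(i + 1, n)}
    next_id = n

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        best_pair = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                lab = tuple(sorted((clusters[i].min_label, clusters[j].min_label)))
                key = (q, lab)
                if best is None or key < best:
                    best, best_pair = key, (i, j)
        i, j = best_pair
        dij = get(i, j)
        bi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        bj = dij - bi
        # clamp negatives, shifting the deficit to the sister branch
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        ci, cj = clusters.pop(i), clusters.pop(j)
        merged = _Cluster(
            f"({ci.newick}:{bi:.10g},{cj.newick}:{bj:.10g})",
            min(ci.min_label, cj.min_label),
        )
        new_dists = {}
        for k in active:
            if k in (i, j):
                continue
            new_dists[k] = max(0.0, 0.5 * (get(i, k) + get(j, k) - dij))
        active = [k for k in active if k not in (i, j)]
        clusters[next_id] = merged
        for k, v in new_dists.items():
            dist[(k, next_id) if k < next_id else (next_id, k)] = v
        active.append(next_id)
        next_id += 1

    # resolve the last three clusters with the three-point formulas
    x, y, z = sorted(active, key=lambda k: clusters[k].min_label)
    dxy, dxz, dyz = get(x, y), get(x, z), get(y, z)
    bx = max(0.0, 0.5 * (dxy + dxz - dyz))
    by = max(0.0, 0.5 * (dxy + dyz - dxz))
    bz = max(0.0, 0.5 * (dxz + dyz - dxy))
    newick = (
        f"({clusters[x].newick}:{bx:.10g},"
        f"{clusters[y].newick}:{by:.10g},"
        f"{clusters[z].newick}:{bz:.10g});"
    )
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# rooting and clade queries


def _path_edges(tree: dendropy.Tree, a, b):
    """Edges along the path leaf a -> leaf b, in walk order from a."""
    anc_a = [a] + [n for n in a.ancestor_iter()]
    anc_b = [b] + [n for n in b.ancestor_iter()]
    in_a = set(id(n) for n in anc_a)
    mrca = next(n for n in anc_b if id(n) in in_a)
    up = []
    node = a
    while node is not mrca:
        up.append((node.edge, node))  # walk child -> parent: enter at head
        node = node.parent_node
    down = []
    node = b
    while node is not mrca:
        down.append((node.edge, node.parent_node))  # walk parent -> child
        node = node.parent_node
    return up + list(reversed(down))


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    Ties between equally long paths are broken by the lexicographically
    smallest leaf-label pair.  Leaf-to-leaf path lengths are unchanged by
    the rerooting.
    """
    rooted = tree.clone(depth=1)
    leaves = sorted(rooted.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    if len(leaves) < 2:
        rooted.is_rooted = True
        return rooted
    pdm = rooted.phylogenetic_distance_matrix()
    best = None
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            d = pdm.distance(leaves[i].taxon, leaves[j].taxon)
            key = (-d, leaves[i].taxon.label, leaves[j].taxon.label)
            if best is None or key < best:
                best = key
                pair = (leaves[i], leaves[j])
    half = -best[0] / 2.0
    walk = _path_edges(rooted, *pair)
    cum = 0.0
    for edge, entered_from in walk:
        elen = edge.length or 0.0
        if cum + elen >= half - 1e-12:
            rem = half - cum  # distance into this edge, from the end nearer leaf a
            # dendropy lengths: length1 -> tail (parent) side, length2 -> head (child)
            if entered_from is edge.head_node:  # walking child -> parent
                length2, length1 = rem, elen - rem
            else:  # walking parent -> child
                length1, length2 = rem, elen - rem
            rooted.reroot_at_edge(
                edge,
                length1=max(0.0, length1),
                length2=max(0.0, length2),
                update_bipartitions=False,
            )
            rooted.is_rooted = True
            return rooted
        cum += elen
    raise RuntimeError("midpoint not found on the longest path")  # pragma: no cover


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def is_monophyletic(rooted_tree: dendropy.Tree, taxa: Iterable[str]) -> bool:
    """True iff some node's leaf set equals *taxa* exactly (rooted test)."""
    query = frozenset(taxa)
    if not query:
        raise ValueError("empty taxon set")
    all_leaves = leaf_labels(rooted_tree)
    if not query <= all_leaves:
        raise ValueError(f"taxa not in tree: {sorted(query - all_leaves)}")
    for node in rooted_tree.preorder_node_iter():
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if leaves == query:
            return True
        if len(leaves) < len(query):
            continue
    return False


def hgt_consistency(
    rooted_tree: dendropy.Tree,
    labels: Mapping[str, str],
    ingroup: str = "plant",
    outgroup: str = "bacteria",
    support: float | None = None,
) -> CladeTest:
    """Test the single-HGT topology: ingroup monophyletic and nested.

    *monophyletic*: the ingroup leaves form a clade.  *nesting*: the
    outgroup leaves do NOT themselves form a single clade on the rooted
    tree — i.e. the ingroup clade sits inside the outgroup radiation
    rather than as its sister.  Both true is the one-transfer signature.
    """
    plants = frozenset(l for l, c in labels.items() if c == ingroup)
    bacteria = frozenset(l for l, c in labels.items() if c == outgroup)
    if not plants or not bacteria:
        raise ValueError("both label classes must be non-empty")
    mono = is_monophyletic(rooted_tree, plants)
    nested = not is_monophyletic(rooted_tree, bacteria)
    return CladeTest(taxa=plants, monophyletic=mono, nesting=nested, support=support)


# ---------------------------------------------------------------------------
# bootstrap


def _splits(tree: dendropy.Tree, ref: str) -> set[frozenset[str]]:
    """Unrooted bipartitions, each encoded as the leaf set not containing *ref*."""
    all_leaves = leaf_labels(tree)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        if side:
            out.add(side)
    out.add(all_leaves)
    return out


def bootstrap_support(
    msa: Sequence[tuple[str, str]],
    n_replicates: int = 100,
    seed: int = 0,
    correction: str = "none",
) -> dict[frozenset[str], float]:
    """Column-resampling bootstrap proportions for the NJ tree's bipartitions.

    Resamples alignment columns with replacement, rebuilds the NJ tree per
    replicate, and reports the frequency of each original-tree bipartition
    among the replicates.  Bipartitions are keyed by the leaf set on the
    side not containing the alphabetically first taxon; trivial splits
    (single leaves, full taxon set) always have support 1.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels = [sid for sid, _ in msa]
    ref = min(labels)
    base_tree = neighbor_joining(distance_matrix(msa, correction))
    base_splits = _splits(base_tree, ref)

    seqs = [s for _, s in msa]
    L = len(seqs[0])
    arr = np.array([list(s) for s in seqs])
    rng = np.random.default_rng(seed)
    counts = {s: 0 for s in base_splits}
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep = [(lab, "".join(row)) for lab, row in zip(labels, arr[:, cols])]
        rep_splits = _splits(neighbor_joining(distance_matrix(rep, correction)), ref)
        for s in base_splits:
            if s in rep_splits:
                counts[s] += 1
    support = {s: c / n_replicates for s, c in counts.items()}
    full = frozenset(labels)
    support[full] = 1.0
    for lab in labels:
        if lab != ref:
            support[frozenset([lab])] = 1.0
    return support


# ---------------------------------------------------------------------------
# Newick IO


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


def to_newick(tree: dendropy.Tree) -> str:
    """Newick string with branch lengths to 6 decimal places."""
    return tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".6f",
    ).strip()
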