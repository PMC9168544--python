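"""Synthetic fixtures with the statistical structure the analysis assumes.

Every generator is a pure function of its parameters and seed: rerunning
with the same arguments is byte-identical.  Each emits a truth table
recording what was planted, so downstream expectations can be computed
without re-reading sequence content.

The generators emulate, in order: proteins with 0-3 planted acidic-triad
motifs on a background of i.i.d. residues; homology hit tables with
controlled per-criterion pass probabilities; a single-HGT phylogenetic
scenario (compact plant clade grafted inside a deeper bacterial
radiation); sequence evolution along a tree under a 20-state equal-rates
substitution process; and Michaelis-Menten initial-rate data with
multiplicative Gaussian noise on a 0-200 uM substrate grid.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .kinetics import RateSeries
from .motifs import (
    DEFAULT_MOTIF_SPECS,
    MotifPattern,
    call_triad,
    compile_pattern,
    default_motifs,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _sample_background(rng: np.random.Generator, n: int, freqs=None) -> str:
    p = None if freqs is None else np.asarray(freqs, dtype=float)
    return "".join(rng.choice(list(AA), size=n, p=p))


def _instantiate_motif(
    pattern: MotifPattern,
    rng: np.random.Generator,
    gap_len_range: tuple[int, int],
    background_freqs=None,
) -> tuple[str, int]:
    """Concrete residue string matching *pattern*; returns (string, anchor offset 0-based)."""
    out = []
    anchor_off = -1
    for k, e in enumerate(pattern.elements):
        if e.kind == "class":
            if k == pattern.anchor_index:
                anchor_off = sum(len(x) for x in out)
            out.append(str(rng.choice(sorted(e.residues))))
        elif e.kind == "wildcard":
            out.append(_sample_background(rng, 1, background_freqs))
        else:
            lo = max(e.gap_min, gap_len_range[0])
            hi = min(e.gap_max, gap_len_range[1])
            if lo > hi:
                lo, hi = e.gap_min, e.gap_max
            glen = int(rng.integers(lo, hi + 1))
            out.append(_sample_background(rng, glen, background_freqs))
    return "".join(out), anchor_off


_SUBSET_CHOICES = {
    3: [("M1", "M2", "M3")],
    2: [("M1", "M2"), ("M1", "M3"), ("M2", "M3")],
    1: [("M1",), ("M2",), ("M3",)],
    0: [()],
}


def _allocate_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment so class counts are exact."""
    props = np.asarray(proportions, dtype=float)
    if props.sum() <= 0 or (props < 0).any():
        raise ValueError("proportions must be non-negative and sum > 0")
    props = props / props.sum()
    raw = props * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def gen_triad_sequences(
    n: int,
    completeness_mix: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    length: int = 550,
    gap_len_range: tuple[int, int] = (5, 10),
    background_freqs: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Proteins with planted triad motifs plus background decoys.

    ``completeness_mix`` gives the proportions of sequences with 3, 2, 1
    and 0 planted motifs (exact counts by largest-remainder rounding).
    Planted motifs appear in M1 < M2 < M3 order at non-overlapping
    random positions; which motifs a partial sequence carries is drawn
    uniformly among the subsets of that size.  For sequences with at
    least one planted motif the background is resampled (bounded
    retries) until the triad call equals the planted completeness, so
    truth labels are exact; background-only (0/3) sequences are emitted
    raw so spurious-call rates can be measured against them.

    Returns ``(records, truth)`` where records are (id, sequence) pairs
    and truth has one row per record.
    """
    if len(completeness_mix) != 4:
        raise ValueError("completeness_mix must have 4 entries for {3,2,1,0}")
    rng = np.random.default_rng(seed)
    counts = _allocate_counts(n, completeness_mix)
    patterns = {p.id: p for p in default_motifs()}
    min_needed = sum(p.min_length for p in patterns.values()) + 4
    if length < min_needed:
        raise ValueError(f"length {length} too short to host all motifs ({min_needed})")

    records, rows = [], []
    idx = 0
    for completeness, count in zip((3, 2, 1, 0), counts):
        for _ in range(count):
            sid = f"seq{idx:04d}"
            idx += 1
            subset = _SUBSET_CHOICES[completeness][
                int(rng.integers(len(_SUBSET_CHOICES[completeness])))
            ]
            seq, anchors = _plant(
                rng, length, [patterns[m] for m in subset], gap_len_range,
                background_freqs,
            )
            if completeness > 0:
                for _retry in range(50):
                    got = call_triad(seq, list(patterns.values()), seq_id=sid)
                    if got.completeness == completeness:
                        break
                    seq, anchors = _plant(
                        rng, length, [patterns[m] for m in subset], gap_len_range,
                        background_freqs,
                    )
                else:  # pragma: no cover - astronomically unlikely
                    raise RuntimeError(f"could not plant clean motifs for {sid}")
            records.append((sid, seq))
            rows.append(
                {
                    "seq_id": sid,
                    "planted_completeness": completeness,
                    "planted_motifs": ";".join(subset),
                    "anchor_positions": ";".join(str(a) for a in anchors),
                    "seed": seed,
                }
            )
    return records, pd.DataFrame(rows)


def _plant(rng, length, patterns, gap_len_range, background_freqs):
    """One sequence with the given motifs embedded left-to-right."""
    pieces = [_instantiate_motif(p, rng, gap_len_range, background_freqs) for p in patterns]
    total = sum(len(s) for s, _ in pieces)
    spare = length - total
    if spare < 0:
        raise ValueError("sequence length too short for requested motifs")
    # distribute spare background across k+1 slots
    k = len(pieces)
    cuts = np.sort(rng.integers(0, spare + 1, size=k)) if k else np.array([], dtype=int)
    fills = np.diff(np.concatenate(([0], cuts, [spare])))
    seq_parts = []
    anchors = []
    pos = 0
    for i, fill in enumerate(fills):
        bg = _sample_background(rng, int(fill), background_freqs)
        seq_parts.append(bg)
        pos += len(bg)
        if i < k:
            s, aoff = pieces[i]
            anchors.append(pos + aoff + 1)  # 1-based
            seq_parts.append(s)
            pos += len(s)
    return "".join(seq_parts), anchors


def synthetic_lpr1_like(length: int = 580, seed: int = 2010) -> str:
    """A synthetic LPR1-like protein standing in for the real accession.

    This is NOT the Arabidopsis LPR1 (At1g23010) sequence: it is a
    background-sampled 580-residue protein with the three triad motifs
    planted so that their acidic anchors fall at exactly the documented
    LPR1 coordinates — E at 269 (motif 1), D at 370 (motif 2, inside a
    realized 8-residue linker) and D at 462 (motif 3).  It exercises the
    coordinate arithmetic of the scanner at full protein scale; it makes
    no claim about the real sequence's residues elsewhere.

    The background seed is advanced until the leftmost maximal ordered
    triad chain anchors exactly at (269, 370, 462), so the planted truth
    is unambiguous.
    """
    # concrete instantiations; anchor offsets within each block: 3, 10, 4
    m1 = "WAPEYAG"                               # anchor E at offset 3
    m2 = "NDAGLPYPAGD" + "GLSAKTVN" + "VMAF"     # anchor D at offset 10, gap 8
    m3 = "NGTADGHP"                              # anchor D at offset 4
    starts = {m1: 266, m2: 360, m3: 458}         # 1-based block starts
    target = {"M1": 269, "M2": 370, "M3": 462}
    for s in range(seed, seed + 100):
        rng = np.random.default_rng(s)
        residues = list(_sample_background(rng, length))
        for block, start1 in starts.items():
            residues[start1 - 1 : start1 - 1 + len(block)] = block
        seq = "".join(residues)
        call = call_triad(seq, default_motifs())
        if call.completeness == 3 and all(
            call.anchors[m][0] == pos for m, pos in target.items()
        ):
            return seq
    raise RuntimeError("could not construct a clean stand-in sequence")


def gen_hit_table(
    n: int,
    pass_fractions: Sequence[float] = (0.5, 0.5, 0.5),
    seed: int = 0,
) -> tuple[list, pd.DataFrame]:
    """Homology hit tables with independent per-criterion pass draws.

    ``pass_fractions`` are the probabilities that a hit passes the
    coverage (>60), e-value (<=1e-40) and identity (>30) criteria,
    respectively.  Values are drawn uniformly from the passing or
    failing side of each threshold; the truth table marks per-criterion
    and overall pass.
    """
    from .homology import HitRecord

    if len(pass_fractions) != 3:
        raise ValueError("pass_fractions must be (coverage, evalue, identity)")
    rng = np.random.default_rng(seed)
    hits, rows = [], []
    for i in range(n):
        ok = rng.random(3) < np.asarray(pass_fractions)
        cov = rng.uniform(60.5, 100.0) if ok[0] else rng.uniform(0.0, 59.5)
        ev = 10.0 ** rng.uniform(-200, -41) if ok[1] else 10.0 ** rng.uniform(-39, 0)
        ident = rng.uniform(30.5, 100.0) if ok[2] else rng.uniform(0.0, 29.5)
        hits.append(
            HitRecord(
                query_id="LPR1",
                subject_id=f"hit{i:05d}",
                percent_identity=float(ident),
                alignment_length=int(rng.integers(50, 600)),
                evalue=float(ev),
                query_coverage=float(cov),
            )
        )
        rows.append(
            {
                "subject_id": f"hit{i:05d}",
                "pass_coverage": bool(ok[0]),
                "pass_evalue": bool(ok[1]),
                "pass_identity": bool(ok[2]),
                "pass_all": bool(ok.all()),
                "seed": seed,
            }
        )
    return hits, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# HGT scenario


def _random_binary_topology(labels: list[str], rng) -> list:
    """Random rooted binary topology as nested lists, by sequential joins."""
    nodes: list = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append([a, b])
    return nodes[0]


def _to_newick(node, rng, blen_sampler) -> str:
    if isinstance(node, str):
        return f"{node}:{blen_sampler():.6f}"
    parts = ",".join(_to_newick(c, rng, blen_sampler) for c in node)
    return f"({parts}):{blen_sampler():.6f}"


def gen_hgt_scenario(
    n_bacterial_clades: int = 3,
    leaves_per_clade: int = 4,
    n_plants: int = 4,
    branch_scale: float = 0.1,
    seed: int = 0,
) -> tuple[dendropy.Tree, dict[str, str]]:
    """A single-HGT true tree: plant clade grafted inside a bacterial radiation.

    The bacterial backbone is a random binary tree over
    ``n_bacterial_clades x leaves_per_clade`` leaves with branch lengths
    Uniform(0.5, 1.5) x ``branch_scale``.  The plant clade is compact
    (branches Uniform(0.2, 0.5) x scale — a recent radiation following a
    single transfer) and is grafted mid-edge onto a random internal,
    non-root bacterial edge, so on the returned rooted tree the plants
    are monophyletic and the bacteria are paraphyletic by construction.

    Returns the rooted true tree and a leaf -> {'plant','bacteria'} map.
    """
    if n_bacterial_clades < 2:
        raise ValueError("need >= 2 bacterial clades for a radiation")
    rng = np.random.default_rng(seed)

    bact_leaves = [
        f"b{c}x{i}" for c in range(n_bacterial_clades) for i in range(leaves_per_clade)
    ]
    plant_leaves = [f"p{i}" for i in range(n_plants)]

    clades = []
    for c in range(n_bacterial_clades):
        labs = [f"b{c}x{i}" for i in range(leaves_per_clade)]
        topo = _random_binary_topology(labs, rng) if len(labs) > 1 else labs[0]
        clades.append(topo)
    backbone = _random_binary_topology(list(range(len(clades))), rng)

    def expand(node):
        if isinstance(node, int):
            return clades[node]
        return [expand(c) for c in node]

    full = expand(backbone)
    newick = (
        "("
        + ",".join(
            _to_newick(c, rng, lambda: rng.uniform(0.5, 1.5) * branch_scale)
            for c in (full if isinstance(full, list) else [full])
        )
        + ");"
    )
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True

    # candidate graft edges: internal, below the root, not the root's children
    candidates = [
        nd
        for nd in tree.preorder_node_iter()
        if not nd.is_leaf()
        and nd.parent_node is not None
        and nd.parent_node.parent_node is not None
    ]
    if not candidates:
        candidates = [
            nd
            for nd in tree.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        ]
    graft_below = candidates[int(rng.integers(len(candidates)))]

    if n_plants > 1:
        plant_topo = _random_binary_topology(plant_leaves, rng)
        plant_nwk = (
            "("
            + ",".join(
                _to_newick(c, rng, lambda: rng.uniform(0.2, 0.5) * branch_scale)
                for c in plant_topo
            )
            + ")"
        )
    else:
        plant_nwk = plant_leaves[0]
    stem = rng.uniform(0.8, 1.2) * branch_scale
    plant_tree = dendropy.Tree.get(
        data=f"{plant_nwk}:{stem:.6f};", schema="newick", preserve_underscores=True,
        taxon_namespace=tree.taxon_namespace,
    )

    # split the chosen edge at its midpoint and hang the plant clade there
    edge_len = graft_below.edge.length or branch_scale
    parent = graft_below.parent_node
    mid = dendropy.Node()
    parent.remove_child(graft_below)
    parent.add_child(mid)
    mid.edge.length = edge_len / 2
    mid.add_child(graft_below)
    graft_below.edge.length = edge_len / 2
    plant_root = plant_tree.seed_node
    mid.add_child(plant_root)
    plant_root.edge.length = stem
    tree.update_taxon_namespace()

    labels = {l: "bacteria" for l in bact_leaves}
    labels.update({l: "plant" for l in plant_leaves})
    return tree, labels


def evolve_msa(
    tree: dendropy.Tree,
    length: int = 500,
    root_seq: str | None = None,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Evolve an ungapped alignment along a tree.

    Sites are i.i.d.; along a branch of length t each site is replaced,
    with probability 1 - exp(-t), by a residue drawn uniformly from the
    20 standard amino acids (possibly the same one).  This is the
    20-state equal-rates model: the simplest substitution process with
    closed-form expectations, a deliberate simplification of empirical
    exchangeability matrices.
    """
    rng = np.random.default_rng(seed)
    if root_seq is None:
        root = rng.integers(0, 20, size=length)
    else:
        if len(root_seq) != length:
            raise ValueError("root_seq length mismatch")
        root = np.array([AA.index(ch) for ch in root_seq])

    aa_arr = np.array(list(AA))
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root}
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_seq = seqs[id(node.parent_node)]
        t = node.edge.length or 0.0
        p_sub = 1 - math.exp(-t)
        hit = rng.random(length) < p_sub
        child = parent_seq.copy()
        child[hit] = rng.integers(0, 20, size=int(hit.sum()))
        seqs[id(node)] = child
        if node.is_leaf():
            out.append((node.taxon.label, "".join(aa_arr[child])))
    return out


def gen_kinetics(
    km_uM: float,
    vmax: float,
    S_grid: Sequence[float] = (0, 0.5, 1, 2, 5, 10, 25, 50, 100, 200),
    replicates: int = 3,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> tuple[RateSeries, pd.DataFrame]:
    """Michaelis-Menten initial rates with multiplicative Gaussian noise.

    v = vmax*S/(km+S) * (1 + eps), eps ~ Normal(0, noise_cv); negative
    draws are clamped to 0.  S = 0 rows are always exactly 0.
    """
    if km_uM <= 0 or vmax <= 0:
        raise ValueError("km and vmax must be positive")
    rng = np.random.default_rng(seed)
    S = np.tile(np.asarray(S_grid, dtype=float), replicates)
    group = np.repeat(np.arange(replicates), len(S_grid))
    v_true = vmax * S / (km_uM + S)
    eps = rng.normal(0.0, noise_cv, size=len(S)) if noise_cv > 0 else np.zeros(len(S))
    v = np.clip(v_true * (1 + eps), 0.0, None)
    truth = pd.DataFrame(
        [{"km_uM": km_uM, "vmax": vmax, "noise_cv": noise_cv, "seed": seed,
          "replicates": replicates, "n_points": len(S)}]
    )
    return RateSeries(S=S, v=v, grouping=group), truth
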