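"""Degenerate consensus-motif scanning and acidic-triad classification.

LPR1-type multicopper-oxidase (MCO) ferroxidases carry a high-affinity
Fe(II)-binding site built from three acidic residues (the *acidic triad*;
E269, D370 and D462 in Arabidopsis LPR1), each embedded in a short
conserved sequence motif.  This module compiles those degenerate consensus
motifs, scans protein sequences for them, and classifies each sequence by
how many of the three motifs it carries (its *triad completeness*,
0/3 .. 3/3).  Sequences covering at least two of the three motifs are
flagged as candidate ferroxidases ("considered").

Motif grammar
-------------
``[ABC]``   residue class (any of the bracketed letters)
``A``       single uppercase letter: a one-letter class
``X``       wildcard (any residue)
``X(m-n)``  bounded gap: between m and n wildcard positions

Coordinates are 1-based with inclusive ends throughout, matching the
residue numbering conventions of the ferroxidase literature.
"""

from __future__ import annotations

import gzip
import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: The three printed consensus motifs flanking the acidic triad.
DEFAULT_MOTIF_SPECS: dict[str, str] = {
    "M1": "[WVI]XP[EA][YAF]X[GA]",
    "M2": "N[DTS][AG]XXP[YF]PXG[DE]X(5-10)[VI][ML]XF",
    "M3": "NXTX[DEG]XHP",
}

#: Default MCO hallmark signatures (T1 Cu site; T2/T3 Cu cluster).
#: These are canonical His/Cys copper-ligand spacings of the MCO fold,
#: shipped as a documented, configurable extension: the hallmark
#: inspection step is defined operationally, not by printed patterns.
DEFAULT_HALLMARK_SPECS: dict[str, str] = {
    "t1_site": "HCH",
    "t23_cluster": "HXXHXH",
}


class PatternSyntaxError(ValueError):
    """Raised when a consensus string violates the motif grammar."""


@dataclass(frozen=True)
class Element:
    """One position (or bounded gap) of a compiled motif."""

    kind: str  # 'class' | 'wildcard' | 'gap'
    residues: frozenset[str] = frozenset()
    gap_min: int = 0
    gap_max: int = 0

    def accepts(self, aa: str) -> bool:
        if self.kind == "class":
            return aa in self.residues
        # wildcard / gap positions accept any uppercase letter, including
        # non-standard codes (B, J, O, U, Z, X, *-free ambiguity codes)
        return aa.isalpha() and aa.isupper()


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate consensus motif with a designated anchor.

    The *anchor* is the element that holds the triad residue: the unique
    acidic-class element of the motif ([EA], [DE] or [DEG] in the three
    built-in motifs).
    """

    id: str
    elements: tuple[Element, ...]
    anchor_index: int
    source_text: str

    @property
    def fixed_length(self) -> int:
        """Number of non-gap positions."""
        return sum(1 for e in self.elements if e.kind != "gap")

    @property
    def gap_element(self) -> Element | None:
        for e in self.elements:
            if e.kind == "gap":
                return e
        return None

    @property
    def min_length(self) -> int:
        g = self.gap_element
        return self.fixed_length + (g.gap_min if g else 0)


@dataclass(frozen=True)
class MotifMatch:
    """One placement of a motif on a sequence (1-based, inclusive)."""

    seq_id: str
    motif_id: str
    start: int
    end: int
    anchor_pos: int
    anchor_residue: str
    gap_len: int = 0

    @property
    def is_acidic(self) -> bool:
        """Whether the anchored residue is a true acid (D or E).

        Motif 3's printed class is [DEG]; a glycine anchor still counts
        toward completeness but is not acidic.
        """
        return self.anchor_residue in ("D", "E")


_TRIAD_LABELS = {3: "complete", 2: "partial_2", 1: "partial_1", 0: "absent"}


@dataclass(frozen=True)
class TriadCall:
    """Per-sequence triad completeness call."""

    seq_id: str
    matched_motifs: frozenset[str]
    completeness: int
    anchors: Mapping[str, tuple[int, str]]
    ordered: bool
    label: str
    considered: bool


@dataclass(frozen=True)
class HallmarkReport:
    """Occurrences of the configured MCO Cu-ligand signatures."""

    seq_id: str
    t1_site: tuple[bool, tuple[int, ...]]
    t23_cluster: tuple[bool, tuple[int, ...]]
    patterns_used: Mapping[str, str]


_TOKEN_RE = re.compile(
    r"\[(?P<cls>[A-Z]*)\]"        # residue class
    r"|(?P<gap>X\((?P<m>\d+)-(?P<n>\d+)\))"  # bounded gap
    r"|(?P<wild>X)"               # wildcard
    r"|(?P<lit>[A-Z])"            # literal (X is reserved; validated below)
)


def _is_anchor_candidate(e: Element) -> bool:
    # the triad element: contains an acid (D/E) and otherwise only the
    # small degenerate substitutes A/G — selects [EA], [DE], [DEG]
    if e.kind != "class":
        return False
    return bool(e.residues & {"D", "E"}) and e.residues <= {"D", "E", "A", "G"}


def compile_pattern(spec: str, motif_id: str | None = None) -> MotifPattern:
    """Compile a consensus string into a :class:`MotifPattern`.

    Parameters
    ----------
    spec
        Consensus string in the motif grammar, e.g. ``"NXTX[DEG]XHP"``.
    motif_id
        Identifier for the pattern; defaults to the spec string itself.

    Raises
    ------
    PatternSyntaxError
        On unbalanced brackets, empty classes, inverted gap bounds,
        multiple gaps, or zero/multiple anchor candidates.
    """
    elements: list[Element] = []
    pos = 0
    while pos < len(spec):
        m = _TOKEN_RE.match(spec, pos)
        if m is None:
            raise PatternSyntaxError(
                f"{spec!r}: unrecognised token at position {pos + 1}: "
                f"{spec[pos:pos + 8]!r}"
            )
        if m.lastgroup == "cls" or m.group("cls") is not None:
            letters = m.group("cls")
            if not letters:
                raise PatternSyntaxError(f"{spec!r}: empty class at position {pos + 1}")
            bad = set(letters) - STANDARD_AA
            if bad:
                raise PatternSyntaxError(
                    f"{spec!r}: non-standard letters {sorted(bad)} in class"
                )
            elements.append(Element("class", frozenset(letters)))
        elif m.group("gap") is not None:
            lo, hi = int(m.group("m")), int(m.group("n"))
            if lo > hi:
                raise PatternSyntaxError(
                    f"{spec!r}: gap bounds inverted in {m.group('gap')!r}"
                )
            if any(e.kind == "gap" for e in elements):
                raise PatternSyntaxError(f"{spec!r}: more than one gap element")
            elements.append(Element("gap", gap_min=lo, gap_max=hi))
        elif m.group("wild") is not None:
            elements.append(Element("wildcard"))
        else:
            lit = m.group("lit")
            if lit not in STANDARD_AA:
                raise PatternSyntaxError(f"{spec!r}: non-standard literal {lit!r}")
            elements.append(Element("class", frozenset(lit)))
        pos = m.end()

    if not elements:
        raise PatternSyntaxError(f"{spec!r}: empty pattern")
    if "[" in spec and spec.count("[") != spec.count("]"):
        # _TOKEN_RE would have failed already for most cases; belt-and-braces
        raise PatternSyntaxError(f"{spec!r}: unbalanced bracket")

    anchors = [i for i, e in enumerate(elements) if _is_anchor_candidate(e)]
    if len(anchors) != 1:
        raise PatternSyntaxError(
            f"{spec!r}: expected exactly one acidic anchor element, "
            f"found {len(anchors)}"
        )
    return MotifPattern(
        id=motif_id or spec,
        elements=tuple(elements),
        anchor_index=anchors[0],
        source_text=spec,
    )


def default_motifs() -> list[MotifPattern]:
    """The three built-in triad motifs, compiled, in M1 < M2 < M3 order."""
    return [compile_pattern(s, mid) for mid, s in DEFAULT_MOTIF_SPECS.items()]


def _try_window(
    seq: str, pattern: MotifPattern, start0: int, gap_len: int
) -> tuple[int, str] | None:
    """Check one (start, gap length) placement; return (anchor_pos0, residue)."""
    i = start0
    anchor0 = -1
    for k, e in enumerate(pattern.elements):
        if e.kind == "gap":
            for j in range(gap_len):
                if i + j >= len(seq) or not e.accepts(seq[i + j]):
                    return None
            i += gap_len
            continue
        if i >= len(seq) or not e.accepts(seq[i]):
            return None
        if k == pattern.anchor_index:
            anchor0 = i
        i += 1
    return anchor0, seq[anchor0]


def scan_sequence(seq: str, pattern: MotifPattern, seq_id: str = "") -> list[MotifMatch]:
    """Report every placement of *pattern* on *seq*.

    All matches are returned, overlaps included, sorted by
    (start ascending, gap length ascending).  Sequences shorter than the
    minimal pattern length yield an empty list.
    """
    g = pattern.gap_element
    gap_lens = range(g.gap_min, g.gap_max + 1) if g else (0,)
    out: list[MotifMatch] = []
    for start0 in range(len(seq) - pattern.min_length + 1):
        for gl in gap_lens:
            total = pattern.fixed_length + gl
            if start0 + total > len(seq):
                continue
            hit = _try_window(seq, pattern, start0, gl)
            if hit is not None:
                anchor0, res = hit
                out.append(
                    MotifMatch(
                        seq_id=seq_id,
                        motif_id=pattern.id,
                        start=start0 + 1,
                        end=start0 + total,
                        anchor_pos=anchor0 + 1,
                        anchor_residue=res,
                        gap_len=gl,
                    )
                )
    return out


def _best_ordered_chain(
    per_motif: Sequence[list[MotifMatch]],
) -> list[MotifMatch | None]:
    """Maximum-cardinality selection of at most one match per motif with
    strictly increasing anchor positions in motif order; among maxima the
    lexicographically smallest anchor tuple (leftmost) wins."""
    best: tuple[int, tuple[int, ...]] | None = None
    best_choice: list[MotifMatch | None] = [None] * len(per_motif)
    indices = [[None, *ms] for ms in per_motif]
    for combo in itertools.product(*indices):
        anchors = [m.anchor_pos for m in combo if m is not None]
        if any(b <= a for a, b in zip(anchors, anchors[1:])):
            continue
        key = (-len(anchors), tuple(anchors))
        if best is None or key < best:
            best = key
            best_choice = list(combo)
    return best_choice


def call_triad(
    seq: str,
    patterns: Sequence[MotifPattern] | None = None,
    min_motifs: int = 2,
    enforce_order: bool = True,
    seq_id: str = "",
) -> TriadCall:
    """Classify one sequence's acidic-triad completeness.

    With ``enforce_order=True`` (default) the chosen matches must have
    strictly increasing anchor positions in M1 < M2 < M3 order — the triad
    is positional in the MCO fold.  The maximum-cardinality ordered chain
    is selected, ties broken by leftmost anchors.  A sequence is
    *considered* a candidate ferroxidase when completeness >= ``min_motifs``
    (default 2: at least two of the three motifs).
    """
    if patterns is None:
        patterns = default_motifs()
    if not patterns:
        raise ValueError("call_triad requires at least one compiled pattern")

    per_motif = [scan_sequence(seq, p, seq_id) for p in patterns]
    if enforce_order:
        chosen = _best_ordered_chain(per_motif)
    else:
        chosen = [ms[0] if ms else None for ms in per_motif]

    anchors = {
        p.id: (m.anchor_pos, m.anchor_residue)
        for p, m in zip(patterns, chosen)
        if m is not None
    }
    completeness = len(anchors)
    positions = [m.anchor_pos for m in chosen if m is not None]
    ordered = all(b > a for a, b in zip(positions, positions[1:]))
    return TriadCall(
        seq_id=seq_id,
        matched_motifs=frozenset(anchors),
        completeness=completeness,
        anchors=anchors,
        ordered=ordered,
        label=_TRIAD_LABELS[completeness],
        considered=completeness >= min_motifs,
    )


def detect_mco_hallmarks(
    seq: str,
    hallmark_patterns: Mapping[str, str] | None = None,
    seq_id: str = "",
) -> HallmarkReport:
    """Locate MCO Cu-ligand hallmark signatures (T1 site; T2/T3 cluster).

    The defaults are canonical His/Cys copper-ligand spacings and are a
    documented extension: hallmark inspection is configurable, and any
    pattern in the motif grammar may be supplied per group.
    """
    specs = dict(DEFAULT_HALLMARK_SPECS if hallmark_patterns is None else hallmark_patterns)
    found: dict[str, tuple[bool, tuple[int, ...]]] = {}
    for group, spec in specs.items():
        pat = _compile_hallmark(spec)
        positions = tuple(m.start for m in scan_sequence(seq, pat, seq_id))
        found[group] = (bool(positions), positions)
    return HallmarkReport(
        seq_id=seq_id,
        t1_site=found.get("t1_site", (False, ())),
        t23_cluster=found.get("t23_cluster", (False, ())),
        patterns_used=specs,
    )


def _compile_hallmark(spec: str) -> MotifPattern:
    # hallmark patterns have no acidic anchor; reuse the grammar but anchor
    # arbitrarily at element 0
    try:
        return compile_pattern(spec)
    except PatternSyntaxError:
        elements: list[Element] = []
        pos = 0
        while pos < len(spec):
            m = _TOKEN_RE.match(spec, pos)
            if m is None:
                raise PatternSyntaxError(
                    f"{spec!r}: unrecognised token at position {pos + 1}"
                )
            if m.group("cls") is not None:
                elements.append(Element("class", frozenset(m.group("cls"))))
            elif m.group("gap") is not None:
                elements.append(
                    Element("gap", gap_min=int(m.group("m")), gap_max=int(m.group("n")))
                )
            elif m.group("wild") is not None:
                elements.append(Element("wildcard"))
            else:
                elements.append(Element("class", frozenset(m.group("lit"))))
            pos = m.end()
        return MotifPattern(spec, tuple(elements), 0, spec)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file (plain or gzip) into (id, sequence) pairs."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def classify_collection(
    fasta: str | Path | Iterable[tuple[str, str]],
    patterns: Sequence[MotifPattern] | None = None,
    min_motifs: int = 2,
    enforce_order: bool = True,
) -> pd.DataFrame:
    """Classify every sequence of a FASTA file (or (id, seq) iterable).

    Returns one row per input sequence, in input order, with columns
    ``seq_id, completeness, label, anchors, considered``.  The ``anchors``
    column is a ``motif:pos:residue`` semicolon-joined string.

    Raises
    ------
    ValueError
        If identifiers are duplicated (duplicates listed in the message).
    """
    if isinstance(fasta, (str, Path)):
        records = read_fasta(fasta)
    else:
        records = list(fasta)

    ids = [sid for sid, _ in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate sequence identifiers: {dupes}")

    rows = []
    for sid, seq in records:
        call = call_triad(seq, patterns, min_motifs, enforce_order, seq_id=sid)
        anchor_str = ";".join(
            f"{mid}:{pos}:{res}" for mid, (pos, res) in sorted(call.anchors.items())
        )
        rows.append(
            {
                "seq_id": sid,
                "completeness": call.completeness,
                "label": call.label,
                "anchors": anchor_str,
                "considered": call.considered,
            }
        )
    return pd.DataFrame(
        rows, columns=["seq_id", "completeness", "label", "anchors", "considered"]
    )
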