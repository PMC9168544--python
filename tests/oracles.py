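"""Independent brute-force oracles used to cross-check the implementation.

These re-derive expected results from first principles (exhaustive
enumeration, naive predicate evaluation, closed forms) without touching
the code paths they verify.
"""

from __future__ import annotations

import itertools
import re

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


def parse_consensus(spec: str) -> list:
    """Minimal independent parser: list of ('class', set) / ('wild',) / ('gap', m, n)."""
    out = []
    i = 0
    while i < len(spec):
        ch = spec[i]
        if ch == "[":
            j = spec.index("]", i)
            out.append(("class", set(spec[i + 1 : j])))
            i = j + 1
        elif ch == "X":
            m = re.match(r"X\((\d+)-(\d+)\)", spec[i:])
            if m:
                out.append(("gap", int(m.group(1)), int(m.group(2))))
                i += m.end()
            else:
                out.append(("wild",))
                i += 1
        else:
            out.append(("class", {ch}))
            i += 1
    return out


def brute_force_matches(seq: str, spec: str) -> list[tuple[int, int, int]]:
    """All (start, gap_len, anchor_pos) placements, 1-based, by window checking.

    The anchor is the element whose class holds D or E plus at most A/G.
    """
    elems = parse_consensus(spec)
    anchor_idx = next(
        i
        for i, e in enumerate(elems)
        if e[0] == "class" and e[1] & {"D", "E"} and e[1] <= {"D", "E", "A", "G"}
    )
    gaps = [(i, e[1], e[2]) for i, e in enumerate(elems) if e[0] == "gap"]
    gap_ranges = [range(m, n + 1) for _, m, n in gaps] or [range(0, 1)]
    results = []
    for start in range(len(seq)):
        for gls in itertools.product(*gap_ranges):
            gl_map = {gaps[k][0]: gls[k] for k in range(len(gaps))}
            pos = start
            ok = True
            anchor_pos = None
            for i, e in enumerate(elems):
                if e[0] == "gap":
                    width = gl_map[i]
                    if pos + width > len(seq) or any(
                        not seq[pos + w].isalpha() for w in range(width)
                    ):
                        ok = False
                        break
                    pos += width
                    continue
                if pos >= len(seq):
                    ok = False
                    break
                ch = seq[pos]
                if e[0] == "class":
                    if ch not in e[1]:
                        ok = False
                        break
                else:  # wildcard
                    if not ch.isalpha():
                        ok = False
                        break
                if i == anchor_idx:
                    anchor_pos = pos + 1
                pos += 1
            if ok:
                results.append((start + 1, gls[0] if gaps else 0, anchor_pos))
    return sorted(results)


def best_ordered_chain_size(anchor_lists: list[list[int]]) -> int:
    """Exhaustive search for the largest one-per-motif strictly increasing chain."""
    best = 0
    options = [[None, *a] for a in anchor_lists]
    for combo in itertools.product(*options):
        chosen = [c for c in combo if c is not None]
        if all(b > a for a, b in zip(chosen, chosen[1:])):
            best = max(best, len(chosen))
    return best


def naive_hit_pass(hit, mode: str = "tblastn") -> bool:
    if mode == "tblastn":
        return (
            hit.query_coverage > 60
            and hit.evalue <= 1e-40
            and hit.percent_identity > 30
        )
    return hit.alignment_length > 175 and hit.query_coverage > 30


def enumerate_global_alignments(a: str, b: str):
    """All global alignments of a and b as lists of column pairs ('-' = gap)."""
    if not a and not b:
        yield []
        return
    if a:
        for rest in enumerate_global_alignments(a[1:], b):
            yield [(a[0], "-")] + rest
    if b:
        for rest in enumerate_global_alignments(a, b[1:]):
            yield [("-", b[0])] + rest
    if a and b:
        for rest in enumerate_global_alignments(a[1:], b[1:]):
            yield [(a[0], b[0])] + rest


def affine_score(columns, sub, gap_open: float, gap_extend: float) -> float:
    """Score one alignment under affine gaps (open cost charged per gap run)."""
    score = 0.0
    prev_gap_a = prev_gap_b = False
    for x, y in columns:
        if x == "-":
            score -= gap_extend if prev_gap_a else gap_open
            prev_gap_a, prev_gap_b = True, False
        elif y == "-":
            score -= gap_extend if prev_gap_b else gap_open
            prev_gap_a, prev_gap_b = False, True
        else:
            score += sub[x, y]
            prev_gap_a = prev_gap_b = False
    return score
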