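"""Homology-hit filtering and profile-based candidate screening.

Candidate LPR1-like ferroxidases are gathered in two sweeps: a
translated-BLAST (tblastn) search whose tabular hits are filtered on
query coverage, e-value and percent identity, and a profile screen over
whole genomes/transcriptomes.  The profile screen here is an ungapped
position-specific scoring matrix (PSSM) built from an alignment of
LPR1-like proteins — a documented, testable stand-in for an external
profile-HMM tool; it shares the training input (a vascular-plant LPR1
alignment) and the downstream length rule, but makes no claim of score
equivalence with hmmer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


@dataclass(frozen=True)
class HitRecord:
    """One row of a BLAST-outfmt-6-like hit table (plus query coverage)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    query_coverage: float

    def __post_init__(self):
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(f"percent_identity out of [0,100]: {self.percent_identity}")
        if not 0 <= self.query_coverage <= 100:
            raise ValueError(f"query_coverage out of [0,100]: {self.query_coverage}")
        if self.alignment_length < 0:
            raise ValueError("alignment_length must be >= 0")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class FilterConfig:
    """Hit-filter thresholds.

    tblastn mode applies coverage (strict >), e-value (inclusive <=) and
    identity (strict >); profile mode applies alignment length (strict >)
    and coverage (strict >).  The printed ">" thresholds are read as
    strict and the e-value "cutoff" as inclusive.
    """

    min_query_coverage: float = 60.0
    max_evalue: float = 1e-40
    min_identity: float = 30.0
    min_alignment_length: int = 175
    mode: str = "tblastn"

    def __post_init__(self):
        if self.mode not in ("tblastn", "profile"):
            raise ValueError(f"unknown filter mode {self.mode!r}")

    @classmethod
    def tblastn(cls, **kw) -> "FilterConfig":
        return cls(mode="tblastn", **kw)

    @classmethod
    def profile(cls, min_query_coverage: float = 30.0, **kw) -> "FilterConfig":
        """Profile-screen length rule: >175 residues (>30% query coverage)."""
        return cls(mode="profile", min_query_coverage=min_query_coverage, **kw)

    def reasons(self, hit: HitRecord) -> list[str]:
        """Failure reasons for *hit* under the active criteria (empty = pass)."""
        out = []
        if self.mode == "tblastn":
            if not hit.query_coverage > self.min_query_coverage:
                out.append(f"query_coverage {hit.query_coverage} <= {self.min_query_coverage}")
            if not hit.evalue <= self.max_evalue:
                out.append(f"evalue {hit.evalue} > {self.max_evalue}")
            if not hit.percent_identity > self.min_identity:
                out.append(f"percent_identity {hit.percent_identity} <= {self.min_identity}")
        else:
            if not hit.alignment_length > self.min_alignment_length:
                out.append(
                    f"alignment_length {hit.alignment_length} <= {self.min_alignment_length}"
                )
            if not hit.query_coverage > self.min_query_coverage:
                out.append(f"query_coverage {hit.query_coverage} <= {self.min_query_coverage}")
        return out

    def passes(self, hit: HitRecord) -> bool:
        return not self.reasons(hit)


def filter_hits(
    hits: Sequence[HitRecord], config: FilterConfig | None = None
) -> tuple[list[HitRecord], list[tuple[HitRecord, list[str]]]]:
    """Apply the hit filter; returns (survivors, rejections-with-reasons).

    Survivors keep input order.
    """
    config = config or FilterConfig()
    survivors, rejected = [], []
    for h in hits:
        why = config.reasons(h)
        if why:
            rejected.append((h, why))
        else:
            survivors.append(h)
    return survivors, rejected


HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "evalue",
    "query_coverage",
]


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a tab-separated hit table (header row optional)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "query_id":
                continue
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            try:
                rows.append(
                    HitRecord(
                        query_id=parts[0],
                        subject_id=parts[1],
                        percent_identity=float(parts[2]),
                        alignment_length=int(parts[3]),
                        evalue=float(parts[4]),
                        query_coverage=float(parts[5]),
                    )
                )
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from e
    return rows


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:g}\t"
                f"{h.alignment_length}\t{h.evalue:g}\t{h.query_coverage:g}\n"
            )


@dataclass(frozen=True)
class ProfileModel:
    """Ungapped per-column log-odds profile (PSSM).

    Column scores are ``log((count + pc*bg) / (n + pc) / bg)`` with
    pseudocount weight ``pc`` and background frequency ``bg`` — a
    Laplace-style smoothed log-odds against the background composition.
    """

    length: int
    log_odds: np.ndarray  # (length, 20)
    background: np.ndarray  # (20,)
    pseudocount: float
    source_n: int

    def __post_init__(self):
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError("log-odds must be finite (is pseudocount > 0?)")

    def consensus(self) -> str:
        return "".join(AA_ORDER[i] for i in self.log_odds.argmax(axis=1))


def build_profile(
    msa: Sequence[str] | Sequence[tuple[str, str]],
    background: Sequence[float] | None = None,
    pseudocount: float = 1.0,
    max_gap_fraction: float = 0.5,
) -> ProfileModel:
    """Build a PSSM from an aligned set of sequences.

    Columns whose gap fraction exceeds ``max_gap_fraction`` are dropped.
    Gap characters within retained columns do not contribute counts but
    the column denominator stays at the per-column residue count.
    """
    seqs = [s[1] if isinstance(s, tuple) else s for s in msa]
    if len(seqs) < 2:
        raise ValueError("profile building requires >= 2 aligned sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("ragged alignment: sequences have unequal lengths")

    bg = (
        np.full(20, 1 / 20.0)
        if background is None
        else np.asarray(background, dtype=float)
    )
    if bg.shape != (20,) or abs(bg.sum() - 1) > 1e-9 or (bg <= 0).any():
        raise ValueError("background must be 20 positive frequencies summing to 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")

    kept_cols = []
    for c in range(L):
        col = [s[c].upper() for s in seqs]
        gapfrac = sum(ch in "-." for ch in col) / len(col)
        if gapfrac <= max_gap_fraction:
            kept_cols.append(col)
    if not kept_cols:
        raise ValueError("alignment is all gaps after column filtering")

    n = len(seqs)
    lo = np.empty((len(kept_cols), 20))
    for r, col in enumerate(kept_cols):
        counts = np.zeros(20)
        for ch in col:
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
        freqs = (counts + pseudocount * bg) / (n + pseudocount)
        lo[r] = np.log(freqs / bg)
    return ProfileModel(
        length=len(kept_cols),
        log_odds=lo,
        background=bg,
        pseudocount=pseudocount,
        source_n=n,
    )


def score_sequence(profile: ProfileModel, seq: str) -> tuple[float, int]:
    """Best ungapped window score of *seq* under the profile.

    Returns ``(best_score, best_start)`` with a 1-based start; ties are
    broken leftmost.  Residues outside the 20 standard letters score the
    background expectation (0 log-odds).
    """
    L = profile.length
    if len(seq) < L:
        raise ValueError(f"sequence length {len(seq)} < profile length {L}")
    # per-position score lookup; unknown residues -> 0
    best_score, best_start = -math.inf, 1
    scores = np.zeros((len(seq), 20))
    idx = np.array([_AA_INDEX.get(ch, -1) for ch in seq.upper()])
    for start0 in range(len(seq) - L + 1):
        s = 0.0
        for k in range(L):
            j = idx[start0 + k]
            if j >= 0:
                s += profile.log_odds[k, j]
        if s > best_score:
            best_score, best_start = s, start0 + 1
    return best_score, best_start


def screen_candidates(
    fasta: Iterable[tuple[str, str]],
    profile: ProfileModel,
    score_threshold: float = 0.0,
    length_rule: FilterConfig | None = None,
) -> pd.DataFrame:
    """Score sequences against the profile and rank candidates.

    Each row carries the best window score, its location, and pass/fail
    of the alignment-length rule applied to the profile match region
    (window length must exceed ``min_alignment_length``, and query
    coverage — window length over profile length — must exceed the
    coverage threshold).  Output is sorted by descending score; sequences
    shorter than the profile are skipped.
    """
    rule = length_rule or FilterConfig.profile()
    rows = []
    for sid, seq in fasta:
        if len(seq) < profile.length:
            continue
        score, start = score_sequence(profile, seq)
        window_len = profile.length
        coverage = window_len / profile.length * 100.0
        length_ok = (
            window_len > rule.min_alignment_length
            and coverage > rule.min_query_coverage
        )
        rows.append(
            {
                "seq_id": sid,
                "score": score,
                "start": start,
                "end": start + window_len - 1,
                "above_threshold": score >= score_threshold,
                "length_rule_pass": length_ok,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["seq_id", "score", "start", "end", "above_threshold", "length_rule_pass"],
    )
    if not df.empty:
        df = df.sort_values("score", ascending=False, kind="mergesort").reset_index(
            drop=True
        )
    return df
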