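"""End-to-end orchestration of the screening and phylogeny stages.

The screening pipeline mirrors the published search order: homology-hit
filtering first, then the profile screen, then triad classification of
the surviving candidate sequences.  The phylogeny pipeline runs
distances -> neighbor joining -> midpoint rooting -> bootstrap -> HGT
nesting test and writes every intermediate artifact.

Configuration lives in a single TOML file; CLI flags override config
values.  One global seed fixes every stochastic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import io as tio
from .homology import FilterConfig, ProfileModel, build_profile, filter_hits, read_hit_table, screen_candidates, write_hit_table
from .motifs import DEFAULT_MOTIF_SPECS, classify_collection, compile_pattern
from .phylo import bootstrap_support, distance_matrix, hgt_consistency, midpoint_root, neighbor_joining, to_newick

log = logging.getLogger("triadminer")

_KNOWN_KEYS = {
    "fasta", "hits", "msa", "labels", "out_dir", "seed",
    "motifs", "min_motifs", "enforce_order",
    "filter_mode", "min_query_coverage", "max_evalue", "min_identity",
    "min_alignment_length",
    "profile_msa", "profile_pseudocount", "score_threshold",
    "bootstrap", "correction",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (TOML file or keyword overrides)."""

    fasta: Path | None = None
    hits: Path | None = None
    msa: Path | None = None
    labels: Path | None = None
    out_dir: Path = Path("triadminer_out")
    seed: int = 0
    motifs: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIF_SPECS))
    min_motifs: int = 2
    enforce_order: bool = True
    filter_mode: str = "tblastn"
    min_query_coverage: float = 60.0
    max_evalue: float = 1e-40
    min_identity: float = 30.0
    min_alignment_length: int = 175
    profile_msa: Path | None = None
    profile_pseudocount: float = 1.0
    score_threshold: float = 0.0
    bootstrap: int = 100
    correction: str = "none"

    @classmethod
    def from_toml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**{k: v for k, v in data.items() if k in _KNOWN_KEYS})
        cfg._coerce()
        return cfg

    def _coerce(self):
        for name in ("fasta", "hits", "msa", "labels", "profile_msa"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, Path(val))
        self.out_dir = Path(self.out_dir)

    def validate_inputs(self, required: list[str]) -> None:
        missing = []
        for name in required:
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                missing.append(name)
        if missing:
            raise FileNotFoundError(f"missing or absent inputs: {missing}")

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            min_query_coverage=self.min_query_coverage,
            max_evalue=self.max_evalue,
            min_identity=self.min_identity,
            min_alignment_length=self.min_alignment_length,
            mode=self.filter_mode,
        )

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(getattr(self, k)) for k in sorted(_KNOWN_KEYS) if hasattr(self, k)},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_log(cfg: PipelineConfig, stage: str) -> None:
    import triadminer

    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    with open(cfg.out_dir / f"{stage}.log.json", "w") as fh:
        json.dump(
            {
                "stage": stage,
                "version": triadminer.__version__,
                "config_hash": cfg.config_hash(),
                "seed": cfg.seed,
            },
            fh,
            indent=2,
        )


def run_screen(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Filter -> profile screen -> triad classification.

    Requires ``fasta``; ``hits`` and ``profile_msa`` stages run when
    configured.  All intermediate tables are written under ``out_dir``.
    """
    cfg.validate_inputs(["fasta"])
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    out: dict[str, pd.DataFrame] = {}

    records = tio.read_fasta(cfg.fasta)
    if not records:
        log.warning("empty FASTA input: %s", cfg.fasta)

    if cfg.hits is not None:
        cfg.validate_inputs(["hits"])
        survivors, _ = filter_hits(read_hit_table(cfg.hits), cfg.filter_config())
        write_hit_table(survivors, cfg.out_dir / "hits.filtered.tsv")
        out["hits"] = pd.DataFrame([h.__dict__ for h in survivors])

    surviving_ids = None
    if cfg.profile_msa is not None:
        cfg.validate_inputs(["profile_msa"])
        profile = build_profile(
            tio.read_fasta(cfg.profile_msa), pseudocount=cfg.profile_pseudocount
        )
        ranked = screen_candidates(records, profile, cfg.score_threshold)
        tio.write_table(ranked, cfg.out_dir / "candidates.ranked.tsv")
        out["candidates"] = ranked
        surviving_ids = set(
            ranked.loc[ranked.above_threshold & ranked.length_rule_pass, "seq_id"]
        )

    patterns = [compile_pattern(s, mid) for mid, s in cfg.motifs.items()]
    subset = (
        records
        if surviving_ids is None
        else [(sid, s) for sid, s in records if sid in surviving_ids]
    )
    calls = classify_collection(
        subset, patterns, min_motifs=cfg.min_motifs, enforce_order=cfg.enforce_order
    )
    tio.write_table(calls, cfg.out_dir / "triad_calls.tsv")
    calls.to_json(cfg.out_dir / "triad_calls.json", orient="records", indent=2)
    out["calls"] = calls
    _write_log(cfg, "screen")
    return out


def run_phylo(cfg: PipelineConfig) -> dict[str, Any]:
    """Distances -> NJ -> midpoint root -> bootstrap -> HGT test."""
    cfg.validate_inputs(["msa"])
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    msa = tio.read_fasta(cfg.msa)
    if len(msa) < 3:
        raise ValueError("phylogeny requires >= 3 aligned sequences")

    dm = distance_matrix(msa, correction=cfg.correction)
    tree = midpoint_root(neighbor_joining(dm))
    support = bootstrap_support(
        msa, n_replicates=cfg.bootstrap, seed=cfg.seed, correction=cfg.correction
    )
    with open(cfg.out_dir / "tree.nwk", "w") as fh:
        fh.write(to_newick(tree) + "\n")

    result: dict[str, Any] = {"tree": tree, "support": support}
    report: dict[str, Any] = {
        "method": "p-distance + neighbor joining, midpoint rooted "
                  "(distance-based stand-in for ML inference)",
        "bootstrap_replicates": cfg.bootstrap,
        "seed": cfg.seed,
    }
    if cfg.labels is not None:
        cfg.validate_inputs(["labels"])
        labels = tio.read_label_map(cfg.labels)
        plants = frozenset(l for l, c in labels.items() if c == "plant")
        clade_support = support.get(plants)
        test = hgt_consistency(tree, labels, support=clade_support)
        result["clade_test"] = test
        report["hgt_test"] = {
            "monophyletic": test.monophyletic,
            "nesting": test.nesting,
            "support": test.support,
            "n_plant_leaves": len(test.taxa),
        }
    with open(cfg.out_dir / "phylo_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _write_log(cfg, "phylo")
    return result
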