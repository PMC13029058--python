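"""End-to-end orchestration: mining, promoter discovery, IVT reporting.

Each run takes a single config (dict or YAML/JSON file), executes the
stage functions in the documented order, writes TSV/FASTA outputs plus a
JSON manifest with per-filter record counts, and is byte-deterministic for
a fixed config and seed (no timestamps in any output).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .genome import (
    SequenceRecord,
    find_orfs,
    longest_orfs,
    read_fasta,
    read_gff3,
    write_fasta,
    write_gff3,
)
from .ivt import fold_report, read_measurements, summarize_enzyme
from .mining import (
    MiningConfig,
    apply_mining_filters,
    build_candidates,
    check_catalytic_residues,
    classify_orfs,
    deduplicate,
    drop_unclonable,
    rank_into_blocks,
    retained,
)
from .promoters import build_consensus, enumerate_variants, scan_core_motif

log = logging.getLogger("phagemine")


class ConfigError(ValueError):
    """Raised when a run config is malformed (CLI exit code 2)."""


@dataclass
class PipelineRunManifest:
    config: dict
    input_digests: dict
    stage_counts: dict
    tool_version: str = __version__
    seed: Optional[int] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineRunManifest":
        return cls(**json.loads(text))


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return dict(config)
    path = Path(config)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config {path} is not valid YAML/JSON: {exc}") from exc
    if not isinstance(loaded, dict):
        raise ConfigError(f"config {path} must define a mapping")
    return loaded


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _require(config: dict, keys: list[str]) -> None:
    missing = [k for k in keys if k not in config]
    if missing:
        raise ConfigError(f"config lacks required keys: {missing}")


def run_mining(config) -> PipelineRunManifest:
    """ORF detection -> reference classification -> mining filters ->
    deduplication -> clone-failure exclusion -> block ranking/selection."""
    cfg = _load_config(config)
    _require(cfg, ["contigs", "rnap_refs", "capsid_refs", "out_dir"])
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    mcfg_keys = {f.name for f in MiningConfig.__dataclass_fields__.values()}
    mcfg = MiningConfig(**{k: v for k, v in cfg.items() if k in mcfg_keys})

    contigs = read_fasta(cfg["contigs"], "dna") if Path(cfg["contigs"]).stat().st_size else []
    rnap_refs = read_fasta(cfg["rnap_refs"], "protein")
    capsid_refs = read_fasta(cfg["capsid_refs"], "protein")
    known = (
        read_fasta(cfg["known_proteins"], "protein") if cfg.get("known_proteins") else []
    )
    unclonable_ids = set(cfg.get("unclonable_ids", []))
    digests = {
        key: _digest(cfg[key])
        for key in ("contigs", "rnap_refs", "capsid_refs", "known_proteins")
        if cfg.get(key)
    }

    orfs = []
    for contig in contigs:
        orfs.extend(
            find_orfs(contig, min_aa_length=int(cfg.get("orf_min_aa_length", 100)))
        )
    orfs = longest_orfs(orfs)
    log.info("mining: %d contigs, %d ORFs", len(contigs), len(orfs))
    classified = classify_orfs(orfs, rnap_refs, capsid_refs, mcfg) if orfs else []
    candidates = build_candidates(classified)
    for c in candidates:
        if c.id in unclonable_ids or c.contig_id in unclonable_ids:
            c.unclonable = True
    n_input = len(candidates)
    candidates = apply_mining_filters(candidates, known, mcfg)
    n_filtered = len(retained(candidates))
    candidates = deduplicate(candidates, mcfg.dedup_threshold)
    n_dedup = len(retained(candidates))
    candidates = drop_unclonable(candidates)
    n_clonable = len(retained(candidates))
    candidates = rank_into_blocks(candidates, mcfg)
    selected = [c for c in candidates if c.selected]
    counts = {
        "contigs": len(contigs),
        "orfs": len(orfs),
        "candidates": n_input,
        "after_filters": n_filtered,
        "after_dedup": n_dedup,
        "after_unclonable": n_clonable,
        "selected": len(selected),
    }
    for reason in ("no_capsid", "too_short", "identity_out_of_window", "not_novel",
                   "duplicate", "unclonable"):
        counts[f"excluded_{reason}"] = sum(
            1 for c in candidates if c.excluded_reason == reason
        )
    log.info("mining funnel: %s", counts)

    pd.DataFrame(
        [
            {
                "id": c.id,
                "contig_id": c.contig_id,
                "aa_length": c.aa_length,
                "identity_to_reference": round(c.identity_to_reference, 3),
                "best_reference": c.best_reference,
                "has_capsid_partner": c.has_capsid_partner,
                "is_novel": c.is_novel,
                "excluded_reason": c.excluded_reason or "",
                "block": c.block if c.block is not None else "",
                "selected": c.selected,
            }
            for c in candidates
        ]
    ).to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    write_fasta(
        [SequenceRecord(c.id, c.protein, "protein") for c in selected],
        out_dir / "selected.fasta",
    )
    cat_rows = []
    for c in selected:
        report = check_catalytic_residues(c.protein, rnap_refs[0].seq)
        for pos, res, cpos, cres, ok in report.residue_map:
            cat_rows.append(
                {
                    "candidate": c.id,
                    "reference_position": pos,
                    "reference_residue": res,
                    "candidate_position": cpos if cpos is not None else "",
                    "candidate_residue": cres if cres is not None else "",
                    "conserved": ok,
                }
            )
    pd.DataFrame(
        cat_rows,
        columns=[
            "candidate",
            "reference_position",
            "reference_residue",
            "candidate_position",
            "candidate_residue",
            "conserved",
        ],
    ).to_csv(out_dir / "catalytic_residues.tsv", sep="\t", index=False)

    manifest = PipelineRunManifest(
        config=cfg, input_digests=digests, stage_counts=counts, seed=cfg.get("seed")
    )
    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def run_promoters(config) -> PipelineRunManifest:
    """Core-motif scan -> consensus -> naturally occurring variants."""
    cfg = _load_config(config)
    _require(cfg, ["contigs", "genes_gff", "out_dir"])
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = read_fasta(cfg["contigs"], "dna")
    genes = read_gff3(cfg["genes_gff"])
    core = cfg.get("core", "CACTA")
    max_upstream = int(cfg.get("max_upstream", 150))
    window_span = tuple(cfg.get("window_span", (18, 6)))
    same_strand = bool(cfg.get("same_strand", True))
    digests = {k: _digest(cfg[k]) for k in ("contigs", "genes_gff")}

    hits = []
    for contig in contigs:
        contig_genes = [g for g in genes if g.contig_id == contig.id]
        hits.extend(
            scan_core_motif(contig, contig_genes, core, max_upstream, window_span, same_strand)
        )
    pd.DataFrame(
        [
            {
                "contig_id": h.contig_id,
                "plus_one": h.plus_one,
                "strand": h.strand,
                "window_seq": h.window_seq,
                "downstream_gene_id": h.downstream_gene_id,
                "distance_to_gene": h.distance_to_gene,
            }
            for h in hits
        ],
        columns=[
            "contig_id",
            "plus_one",
            "strand",
            "window_seq",
            "downstream_gene_id",
            "distance_to_gene",
        ],
    ).to_csv(out_dir / "hits.tsv", sep="\t", index=False)

    counts = {"contigs": len(contigs), "genes": len(genes), "hits": len(hits)}
    if hits:
        consensus = build_consensus(hits)
        write_fasta(
            [SequenceRecord("promoter_1_consensus", consensus.consensus_seq, "dna")],
            out_dir / "consensus.fasta",
        )
        up = consensus.window_span[0]
        from .promoters import index_to_coord

        pd.DataFrame(
            [
                {
                    "coordinate": index_to_coord(col, up),
                    **{b: counter.get(b, 0) for b in "ACGTN"},
                }
                for col, counter in enumerate(consensus.counts)
            ]
        ).to_csv(out_dir / "consensus_counts.tsv", sep="\t", index=False)
        variants = enumerate_variants(
            consensus, hits, max_variants=int(cfg.get("max_variants", 8))
        )
        pd.DataFrame(
            [
                {
                    "variant_seq": seq,
                    "substitutions": ",".join(str(s) for s in subs),
                    "support": support,
                }
                for seq, subs, support in variants
            ],
            columns=["variant_seq", "substitutions", "support"],
        ).to_csv(out_dir / "variants.tsv", sep="\t", index=False)
        counts["variants"] = len(variants)
    else:
        (out_dir / "NO_PROMOTER_FOUND.txt").write_text(
            "no promoter core hit satisfied the scan constraints\n"
        )
        log.warning("promoter scan: no hits")
        counts["variants"] = 0

    manifest = PipelineRunManifest(
        config=cfg, input_digests=digests, stage_counts=counts, seed=cfg.get("seed")
    )
    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def run_ivt_report(
    measurements_path: str | Path,
    reference: str = "T7",
    out_dir: str | Path = ".",
) -> dict:
    """Fold-reductions versus the reference enzyme plus per-enzyme summaries."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = read_measurements(measurements_path)
    folds = fold_report(df, reference=reference)
    folds.to_csv(out_dir / "fold_reductions.tsv", sep="\t", index=False)
    summaries = pd.DataFrame(
        [summarize_enzyme(df, enz) for enz in df["enzyme"].unique()]
    )
    summaries.to_csv(out_dir / "enzyme_summaries.tsv", sep="\t", index=False)
    return {"folds": folds, "summaries": summaries}
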