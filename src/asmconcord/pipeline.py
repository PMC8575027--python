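"""End-to-end orchestration: read inputs, run every analysis stage, and
emit per-stage TSVs plus one machine-readable JSON run report.

The report is the single source of truth: every number in it is the
direct output of a module operation on the same inputs, so a run is a
pure function of inputs plus configuration.  Stages whose optional
inputs (depth, hits, idxstats, peptides) are missing are marked
``skipped`` in the report, never silently omitted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clustering, concordance, coverage, frameshift, sketching
from .core_io import (
    AlignmentHit,
    CdsRecord,
    Contig,
    depth_dict,
    read_contigs,
    read_depth_table,
    read_hits_table,
    read_idxstats,
    read_peptide_evidence,
    read_prodigal_faa,
)

logger = logging.getLogger("asmconcord")


@dataclass
class AssemblyInputs:
    label: str
    contigs: str
    proteins: str
    depth: str | None = None
    hits: str | None = None
    idxstats: str | None = None


@dataclass
class RunConfig:
    assemblies: list[AssemblyInputs]
    peptides: str | None = None
    outdir: str = "asmconcord_out"
    seed: int = 0
    min_id: float = 0.9
    min_cov: float = 0.8
    metat_threshold: float = 10.0
    length_thresholds: tuple[int, ...] = coverage.DEFAULT_LENGTH_THRESHOLDS
    hc_mode: str = "auto"  # auto: metaT/metaP/either by available evidence
    protein_scope: str = "strict"
    max_gap: int = 100
    max_subject_overlap: float = 0.2
    min_subject_cover: float = 0.8
    require_same_strand: bool = True
    kmer: int = 31
    sketch_size: int = 100_000
    hash_seed: int = 42

    def __post_init__(self) -> None:
        labels = [a.label for a in self.assemblies]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate assembly labels in config")

    def validate_files(self) -> None:
        for a in self.assemblies:
            for attr in ("contigs", "proteins", "depth", "hits", "idxstats"):
                p = getattr(a, attr)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{a.label}.{attr}: {p} does not exist")
        if self.peptides is not None and not Path(self.peptides).exists():
            raise FileNotFoundError(f"peptides: {self.peptides} does not exist")


def load_config(path: str | Path, **overrides: Any) -> RunConfig:
    """Load a YAML config; keyword overrides take precedence over the file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    assemblies = [
        AssemblyInputs(label=lab, **spec)
        for lab, spec in sorted(raw.pop("assemblies", {}).items())
    ]
    raw.update({k: v for k, v in overrides.items() if v is not None})
    if "length_thresholds" in raw:
        raw["length_thresholds"] = tuple(raw["length_thresholds"])
    return RunConfig(assemblies=assemblies, **raw)


def config_for_bundle(bundle_dir: str | Path, outdir: str | Path, **overrides) -> RunConfig:
    """Build a RunConfig from a synthetic bundle's manifest.json."""
    bundle_dir = Path(bundle_dir)
    with open(bundle_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    assemblies = [
        AssemblyInputs(
            label=lab,
            contigs=str(bundle_dir / paths["contigs"]),
            proteins=str(bundle_dir / paths["proteins"]),
            depth=str(bundle_dir / paths["depth"]),
            hits=str(bundle_dir / paths["hits"]),
            idxstats=str(bundle_dir / paths["idxstats"]),
        )
        for lab, paths in sorted(manifest["assemblies"].items())
    ]
    peptides = manifest.get("peptides")
    return RunConfig(
        assemblies=assemblies,
        peptides=str(bundle_dir / peptides) if peptides else None,
        outdir=str(outdir),
        **overrides,
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis flow and write TSVs + report.json.

    Order: read -> cluster -> combination counts -> coverage/expression ->
    partial stats/best hits/length ratios -> high confidence ->
    frameshift -> sketch distances.
    """
    config.validate_files()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = [a.label for a in config.assemblies]
    report: dict[str, Any] = {
        "version": __version__,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "assemblies"
        },
        "inputs": {},
        "skipped": [],
        "stages": {},
    }

    # ---- read ------------------------------------------------------------
    contigs: dict[str, list[Contig]] = {}
    records: list[CdsRecord] = []
    tracks_by_label: dict[str, dict] = {}
    hits_by_label: dict[str, list[AlignmentHit]] = {}
    idx_by_label: dict[str, tuple] = {}
    for a in config.assemblies:
        checks = {}
        contigs[a.label] = read_contigs(a.contigs, a.label)
        checks["contigs"] = _sha256(a.contigs)
        recs = read_prodigal_faa(a.proteins, a.label)
        records.extend(recs)
        checks["proteins"] = _sha256(a.proteins)
        if a.depth:
            tracks_by_label[a.label] = depth_dict(read_depth_table(a.depth))
            checks["depth"] = _sha256(a.depth)
        if a.hits:
            lengths = {r.id: len(r.protein_seq) for r in recs}
            hits_by_label[a.label] = read_hits_table(a.hits, lengths)
            checks["hits"] = _sha256(a.hits)
        if a.idxstats:
            idx_by_label[a.label] = read_idxstats(a.idxstats)
            checks["idxstats"] = _sha256(a.idxstats)
        report["inputs"][a.label] = checks
    peptides = None
    if config.peptides:
        peptides = read_peptide_evidence(config.peptides)
        report["inputs"]["peptides"] = _sha256(config.peptides)

    # ---- clustering ------------------------------------------------------
    clusters = clustering.greedy_cluster(
        records, min_id=config.min_id, min_cov=config.min_cov
    )
    combos = clustering.combination_counts(clusters, all_labels=labels, records=records)
    _write_tsv(
        pd.DataFrame(
            [
                (c.cluster_id, c.representative_id, mid, lab)
                for c in clusters
                for mid, lab in c.members
            ],
            columns=["cluster_id", "representative_id", "member_id", "assembly_label"],
        ),
        outdir / "clusters.tsv",
    )
    _write_tsv(
        pd.DataFrame(
            [
                ("+".join(r.combination), r.n_clusters, r.n_proteins, r.n_proteins_dedup)
                for r in combos.rows
            ],
            columns=["combination", "n_clusters", "n_proteins", "n_proteins_dedup"],
        ),
        outdir / "combinations.tsv",
    )
    report["stages"]["clustering"] = {
        "n_proteins": combos.n_proteins_total,
        "n_clusters": combos.n_clusters_total,
        "n_core_clusters": combos.n_core_clusters,
        "n_core_proteins": combos.n_core_proteins,
        "n_exclusive_clusters": combos.n_exclusive_clusters,
        "n_exclusive_proteins": combos.n_exclusive_proteins,
        "combinations": [
            {
                "combination": list(r.combination),
                "n_clusters": r.n_clusters,
                "n_proteins": r.n_proteins,
            }
            for r in combos.rows
        ],
    }

    # ---- coverage / expression ------------------------------------------
    calls = None
    if tracks_by_label:
        calls = []
        for a in config.assemblies:
            recs = [r for r in records if r.assembly_label == a.label]
            tr = tracks_by_label.get(a.label, {})
            calls.extend(
                coverage.expression_calls(recs, tr, tau=config.metat_threshold)
            )
        _write_tsv(
            pd.DataFrame(
                [(c.protein_id, c.mean_depth, int(c.expressed)) for c in calls],
                columns=["protein_id", "mean_depth", "expressed"],
            ),
            outdir / "expression.tsv",
        )
        report["stages"]["expression"] = {
            "tau": config.metat_threshold,
            "n_proteins": len(calls),
            "n_expressed": sum(c.expressed for c in calls),
        }
    else:
        report["skipped"].append("expression")

    if idx_by_label:
        rows = []
        ret_report = {}
        for lab, (stats, unmapped) in idx_by_label.items():
            curve = coverage.retention_curve(stats, config.length_thresholds)
            for r in curve.rows:
                rows.append(
                    (lab, r.threshold, r.n_contigs, r.total_length,
                     r.mapped_reads, r.retention)
                )
            ret_report[lab] = {
                "unmapped_reads": unmapped,
                "retention": {str(r.threshold): r.retention for r in curve.rows},
            }
        _write_tsv(
            pd.DataFrame(
                rows,
                columns=["assembly_label", "threshold", "n_contigs",
                         "total_length", "mapped_reads", "retention"],
            ),
            outdir / "retention.tsv",
        )
        report["stages"]["retention"] = ret_report
    else:
        report["skipped"].append("retention")

    # ---- concordance -----------------------------------------------------
    pstats = concordance.partial_stats(records)
    _write_tsv(
        pd.DataFrame(
            [(s.assembly_label, s.n_total, s.n_partial, s.n_complete)
             for s in pstats.values()],
            columns=["assembly_label", "n_total", "n_partial", "n_complete"],
        ),
        outdir / "partial_stats.tsv",
    )
    report["stages"]["partial"] = {
        lab: dataclasses.asdict(s) for lab, s in pstats.items()
    }

    best = None
    if hits_by_label:
        all_hits = [h for hs in hits_by_label.values() for h in hs]
        best = concordance.best_hits(all_hits)
        ratios = concordance.length_ratios(best)
        _write_tsv(
            pd.DataFrame(
                sorted(ratios.ratios.items()), columns=["protein_id", "length_ratio"]
            ),
            outdir / "length_ratios.tsv",
        )
        report["stages"]["length_ratios"] = {
            "n": ratios.n,
            "n_below_half": ratios.n_below_half,
            "n_near_one": ratios.n_near_one,
            "median": float(np.median(list(ratios.ratios.values()))) if ratios.n else None,
        }
    else:
        report["skipped"].append("length_ratios")

    if config.hc_mode != "auto":
        mode = config.hc_mode
    elif calls is not None and peptides is not None:
        mode = "either"
    elif calls is not None:
        mode = "metaT"
    elif peptides is not None:
        mode = "metaP"
    else:
        mode = "none"
    hc = concordance.high_confidence(
        clusters,
        expression_calls=calls,
        peptide_evidence=peptides,
        tau=config.metat_threshold,
        mode=mode,
        protein_scope=config.protein_scope,
        all_labels=labels,
    )
    expressed_ids = (
        {c.protein_id for c in calls if c.mean_depth >= config.metat_threshold}
        if calls
        else set()
    )
    peptide_ids = {p.protein_id for p in peptides if p.n_peptides >= 1} if peptides else set()
    cluster_of = {mid: c.cluster_id for c in clusters for mid, _ in c.members}
    _write_tsv(
        pd.DataFrame(
            [
                (
                    mid,
                    cluster_of[mid],
                    int(mid in hc.core_protein_ids),
                    int(mid in expressed_ids),
                    int(mid in peptide_ids),
                    int(mid in hc.hc_protein_ids),
                )
                for mid in sorted(cluster_of)
            ],
            columns=["protein_id", "cluster_id", "core", "metat_evidence",
                     "metap_evidence", "hc"],
        ),
        outdir / "high_confidence.tsv",
    )
    report["stages"]["high_confidence"] = {
        k: v
        for k, v in dataclasses.asdict(hc).items()
        if not k.endswith("_ids")
    }

    # ---- frameshift ------------------------------------------------------
    if best is not None:
        candidates = frameshift.find_split_candidates(
            records,
            best,
            max_gap=config.max_gap,
            max_subject_overlap=config.max_subject_overlap,
            min_subject_cover=config.min_subject_cover,
            require_same_strand=config.require_same_strand,
        )
        if tracks_by_label:
            verified = []
            cds_by_id = {r.id: r for r in records}
            for cand in candidates:
                verified.append(
                    frameshift.verify_with_coverage(
                        cand, tracks_by_label.get(cand.assembly_label, {}), cds_by_id
                    )
                )
            candidates = verified
        _write_tsv(
            pd.DataFrame(
                [
                    (
                        c.assembly_label, c.contig_id, c.cds_a_id, c.cds_b_id,
                        c.genomic_gap, c.subject_id,
                        round(c.subject_overlap_frac, 4),
                        round(c.subject_cover_frac, 4),
                        int(c.order_consistent),
                        c.junction.junction_min if c.junction else "",
                        c.junction.dip_width if c.junction else "",
                        c.verdict or "",
                    )
                    for c in candidates
                ],
                columns=["assembly_label", "contig_id", "cds_a_id", "cds_b_id",
                         "genomic_gap", "subject_id", "subject_overlap_frac",
                         "subject_cover_frac", "order_consistent",
                         "junction_min", "dip_width", "verdict"],
            ),
            outdir / "split_candidates.tsv",
        )
        verdicts: dict[str, int] = {}
        for c in candidates:
            key = c.verdict or "unverified"
            verdicts[key] = verdicts.get(key, 0) + 1
        report["stages"]["frameshift"] = {
            "n_candidates": len(candidates),
            "verdicts": verdicts,
        }
    else:
        report["skipped"].append("frameshift")

    # ---- sketch distances ------------------------------------------------
    if len(labels) >= 2:
        sk_labels, mat = sketching.pairwise_matrix(
            contigs, k=config.kmer, sketch_size=config.sketch_size,
            seed=config.hash_seed,
        )
        dist_df = pd.DataFrame(mat, index=sk_labels, columns=sk_labels)
        dist_df.to_csv(outdir / "distances.tsv", sep="\t", index_label="assembly")
        report["stages"]["sketch"] = {
            "k": config.kmer,
            "sketch_size": config.sketch_size,
            "labels": sk_labels,
            "matrix": [[float(x) for x in row] for row in mat],
        }
    else:
        report["skipped"].append("sketch")

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
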