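"""Partial-protein accounting, best-hit selection, query/subject length
ratios, and the reference-independent high-confidence protein procedure.

The high-confidence procedure works in two steps.  *Core* proteins are
members of clusters whose provenance covers every assembly — genes that
independent assembly approaches reconstructed concordantly.  The core is
then extended with proteins carrying orthogonal evidence: metaT (average
gene coverage at or above a threshold, 10x by default), metaP (at least
one identified peptide), or either.  Clusters containing an evidenced
protein join the high-confidence cluster set.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .clustering import ProteinCluster
from .core_io import AlignmentHit, CdsRecord, PeptideEvidence
from .coverage import ExpressionCall


def round_percent(x: float) -> float:
    """Percentage to two decimals with half-up rounding."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Partial-protein accounting
# ---------------------------------------------------------------------------


@dataclass
class PartialStats:
    assembly_label: str
    n_total: int
    n_partial: int
    n_complete: int


def partial_stats(cds_records: Sequence[CdsRecord]) -> dict[str, PartialStats]:
    """Per-assembly counts of total, partial and complete proteins."""
    totals: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for rec in cds_records:
        t = totals[rec.assembly_label]
        t[0] += 1
        t[1] += int(rec.is_partial)
    return {
        label: PartialStats(label, n_total, n_partial, n_total - n_partial)
        for label, (n_total, n_partial) in sorted(totals.items())
    }


# ---------------------------------------------------------------------------
# Best-hit selection
# ---------------------------------------------------------------------------


def best_hits(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Keep one hit per query: minimal e-value, ties broken by maximal
    bitscore, then lexicographically smallest subject id."""
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key_new = (h.evalue, -h.bitscore, h.subject_id)
        key_cur = (cur.evalue, -cur.bitscore, cur.subject_id)
        if key_new < key_cur:
            best[h.query_id] = h
    return best


# ---------------------------------------------------------------------------
# Query-to-subject length ratios
# ---------------------------------------------------------------------------


@dataclass
class LengthRatioSummary:
    """Distribution of qlen/slen over queries with a best hit.

    Bimodality of this ratio separates truncated predictions (a mode well
    below 1, e.g. fragments of split genes) from full-length ones (a mode
    around 1).
    """

    ratios: dict[str, float]
    bin_edges: np.ndarray  # 0..2 in steps of bin width; last bin is overflow
    counts: np.ndarray
    n_below_half: int
    n_near_one: int

    @property
    def n(self) -> int:
        return len(self.ratios)


def length_ratios(
    hits: Mapping[str, AlignmentHit] | Iterable[AlignmentHit],
    bin_width: float = 0.05,
) -> LengthRatioSummary:
    """Per-query qlen/slen ratios with a fixed-width histogram on [0, 2].

    Ratios above 2 land in an overflow bin.  ``n_below_half`` counts
    ratios < 0.5, ``n_near_one`` ratios in [0.9, 1.1].
    """
    if isinstance(hits, Mapping):
        hits = hits.values()
    ratios: dict[str, float] = {}
    bad: list[str] = []
    for h in hits:
        if h.qlen <= 0 or h.slen <= 0:
            bad.append(h.query_id)
            continue
        ratios[h.query_id] = h.qlen / h.slen
    if bad:
        raise ValueError(f"length_ratios: missing lengths for queries {bad[:10]}")
    edges = np.arange(0.0, 2.0 + bin_width / 2, bin_width)
    values = np.array(list(ratios.values()))
    counts = np.zeros(len(edges), dtype=int)  # last entry = overflow (> 2)
    if len(values):
        in_range = values <= 2.0
        counts[:-1], _ = np.histogram(values[in_range], bins=edges)
        counts[-1] = int((~in_range).sum())
    return LengthRatioSummary(
        ratios=ratios,
        bin_edges=edges,
        counts=counts,
        n_below_half=int((values < 0.5).sum()) if len(values) else 0,
        n_near_one=int(((values >= 0.9) & (values <= 1.1)).sum()) if len(values) else 0,
    )


# ---------------------------------------------------------------------------
# High-confidence proteins and clusters
# ---------------------------------------------------------------------------


@dataclass
class HighConfidenceReport:
    n_proteins_total: int
    n_clusters_total: int
    n_core_proteins: int
    n_core_clusters: int
    n_hc_proteins: int
    n_hc_clusters: int
    pct_core_proteins: float
    pct_core_clusters: float
    pct_hc_proteins: float
    pct_hc_clusters: float
    mode: str
    protein_scope: str
    core_protein_ids: frozenset[str]
    hc_protein_ids: frozenset[str]
    core_cluster_ids: frozenset[str]
    hc_cluster_ids: frozenset[str]
    evidenced_protein_ids: frozenset[str]


def high_confidence(
    clusters: Sequence[ProteinCluster],
    expression_calls: Sequence[ExpressionCall] | None = None,
    peptide_evidence: Sequence[PeptideEvidence] | None = None,
    tau: float = 10.0,
    mode: str = "metaT",
    protein_scope: str = "strict",
    all_labels: Iterable[str] | None = None,
) -> HighConfidenceReport:
    """Core and high-confidence protein/cluster sets with percentages.

    Core clusters have provenance equal to the full assembly-label set;
    core proteins are their members.  Evidence rescue adds proteins with
    metaT coverage >= ``tau`` (mode ``metaT``), >=1 peptide (``metaP``),
    or either (``either``); mode ``none`` disables rescue.  With
    ``protein_scope='strict'`` the high-confidence proteins are the core
    plus the individually evidenced proteins; with ``'cluster'`` they are
    all members of high-confidence clusters.
    """
    if mode not in ("metaT", "metaP", "either", "none"):
        raise ValueError(f"unknown high-confidence mode {mode!r}")
    if protein_scope not in ("strict", "cluster"):
        raise ValueError(f"unknown protein_scope {protein_scope!r}")
    all_proteins: set[str] = set()
    cluster_of: dict[str, str] = {}
    for c in clusters:
        for mid, _ in c.members:
            all_proteins.add(mid)
            cluster_of[mid] = c.cluster_id
    if all_labels is None:
        labels: set[str] = set()
        for c in clusters:
            labels |= c.provenance
        full = frozenset(labels)
    else:
        full = frozenset(all_labels)

    evid: set[str] = set()
    if mode in ("metaT", "either") and expression_calls:
        for call in expression_calls:
            if call.protein_id not in all_proteins:
                raise ValueError(
                    f"expression evidence for unknown protein {call.protein_id!r}"
                )
            if call.mean_depth >= tau:
                evid.add(call.protein_id)
    if mode in ("metaP", "either") and peptide_evidence:
        for pe in peptide_evidence:
            if pe.protein_id not in all_proteins:
                raise ValueError(
                    f"peptide evidence for unknown protein {pe.protein_id!r}"
                )
            if pe.n_peptides >= 1:
                evid.add(pe.protein_id)

    core_clusters = {c.cluster_id for c in clusters if c.provenance == full}
    core_proteins = {
        mid for c in clusters if c.cluster_id in core_clusters for mid, _ in c.members
    }
    rescued_clusters = {cluster_of[p] for p in evid}
    hc_clusters = core_clusters | rescued_clusters
    if protein_scope == "strict":
        hc_proteins = core_proteins | evid
    else:
        hc_proteins = {
            mid for c in clusters if c.cluster_id in hc_clusters for mid, _ in c.members
        }

    n_p, n_c = len(all_proteins), len(clusters)

    def pct(k: int, n: int) -> float:
        return round_percent(100.0 * k / n) if n else 0.0

    return HighConfidenceReport(
        n_proteins_total=n_p,
        n_clusters_total=n_c,
        n_core_proteins=len(core_proteins),
        n_core_clusters=len(core_clusters),
        n_hc_proteins=len(hc_proteins),
        n_hc_clusters=len(hc_clusters),
        pct_core_proteins=pct(len(core_proteins), n_p),
        pct_core_clusters=pct(len(core_clusters), n_c),
        pct_hc_proteins=pct(len(hc_proteins), n_p),
        pct_hc_clusters=pct(len(hc_clusters), n_c),
        mode=mode,
        protein_scope=protein_scope,
        core_protein_ids=frozenset(core_proteins),
        hc_protein_ids=frozenset(hc_proteins),
        core_cluster_ids=frozenset(core_clusters),
        hc_cluster_ids=frozenset(hc_clusters),
        evidenced_protein_ids=frozenset(evid),
    )
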