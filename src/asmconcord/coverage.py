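"""MetaT coverage of predicted genes, expression calls, junction profiles
and mapping-rate retention under contig-length cutoffs.

Expression of a predicted protein is called from the arithmetic mean of
the per-base metatranscriptomic depth over its gene interval; the default
threshold is an average coverage of 10x (boundary inclusive).  Retention
curves measure how many mapped reads survive when contigs below a length
cutoff are discarded — the standard quality view at cutoffs 0, 1000, 2000
and 5000 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_io import CdsRecord, ContigMapStats, DepthTrack

logger = logging.getLogger("asmconcord")

DEFAULT_METAT_THRESHOLD = 10.0
DEFAULT_LENGTH_THRESHOLDS = (0, 1000, 2000, 5000)


@dataclass
class ExpressionCall:
    protein_id: str
    mean_depth: float
    expressed: bool


@dataclass
class RetentionRow:
    threshold: int
    n_contigs: int
    total_length: int
    mapped_reads: int
    retention: float


@dataclass
class RetentionCurve:
    thresholds: tuple[int, ...]
    rows: list[RetentionRow]


@dataclass
class JunctionProfile:
    """Depth summary around the junction between two same-contig CDSs."""

    junction_min: float
    flank_mean_left: float
    flank_mean_right: float
    dip_width: int


def mean_cds_depth(track: DepthTrack, cds: CdsRecord) -> float:
    """Mean per-base depth over the CDS interval (1-based inclusive)."""
    if cds.contig_id != track.contig_id:
        raise ValueError(
            f"CDS {cds.id!r} is on contig {cds.contig_id!r}, track is {track.contig_id!r}"
        )
    if cds.start < 1 or cds.end > len(track):
        raise ValueError(
            f"CDS {cds.id!r} ({cds.contig_id}:{cds.start}-{cds.end}) "
            f"outside depth track of length {len(track)}"
        )
    return float(np.mean(track.depth[cds.start - 1 : cds.end]))


def call_expressed(
    protein_id: str, mean_depth: float, tau: float = DEFAULT_METAT_THRESHOLD
) -> ExpressionCall:
    """Expressed iff mean depth >= tau (an average coverage of >=10x by default)."""
    if tau <= 0:
        raise ValueError("expression threshold tau must be > 0")
    return ExpressionCall(
        protein_id=protein_id, mean_depth=float(mean_depth), expressed=mean_depth >= tau
    )


def expression_calls(
    records: Sequence[CdsRecord],
    tracks: dict[str, DepthTrack],
    tau: float = DEFAULT_METAT_THRESHOLD,
    missing_track: str = "zero",
) -> list[ExpressionCall]:
    """Expression calls for a batch of CDS records.

    A contig absent from the depth tables gets an all-zero track of
    sufficient length (``missing_track='zero'``, warning) or raises
    (``missing_track='error'``); genomecov emits every position, so
    absence normally means a truncated file.
    """
    calls = []
    missing: set[str] = set()
    for rec in records:
        track = tracks.get(rec.contig_id)
        if track is None:
            if missing_track == "error":
                raise ValueError(f"no depth track for contig {rec.contig_id!r}")
            missing.add(rec.contig_id)
            calls.append(call_expressed(rec.id, 0.0, tau))
            continue
        calls.append(call_expressed(rec.id, mean_cds_depth(track, rec), tau))
    if missing:
        logger.warning(
            "%d contigs had no depth track; their CDSs were given zero depth",
            len(missing),
        )
    return calls


def retention_curve(
    map_stats: Sequence[ContigMapStats],
    thresholds: Iterable[int] = DEFAULT_LENGTH_THRESHOLDS,
) -> RetentionCurve:
    """Read-weighted retention after dropping contigs below each cutoff.

    retention(L) = (mapped reads on contigs of length >= L) / (all mapped
    reads); 0 when no reads mapped at all.
    """
    if not map_stats:
        raise ValueError("retention_curve: no contigs")
    thresholds = tuple(int(t) for t in thresholds)
    if any(t < 0 for t in thresholds):
        raise ValueError("retention_curve: negative length threshold")
    lengths = np.array([s.length for s in map_stats])
    mapped = np.array([s.mapped_reads for s in map_stats])
    total = int(mapped.sum())
    rows = []
    for t in thresholds:
        keep = lengths >= t
        kept_reads = int(mapped[keep].sum())
        rows.append(
            RetentionRow(
                threshold=t,
                n_contigs=int(keep.sum()),
                total_length=int(lengths[keep].sum()),
                mapped_reads=kept_reads,
                retention=kept_reads / total if total else 0.0,
            )
        )
    return RetentionCurve(thresholds=thresholds, rows=rows)


def _below_runs(values: np.ndarray, threshold: float) -> list[int]:
    """Lengths of maximal runs of values strictly below ``threshold``."""
    below = values < threshold
    runs: list[int] = []
    n = 0
    for b in below:
        if b:
            n += 1
        elif n:
            runs.append(n)
            n = 0
    if n:
        runs.append(n)
    return runs


def _junction_window(
    track: DepthTrack, cds_a: CdsRecord, cds_b: CdsRecord, flank: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (window, inner, left-flank, right-flank) depth slices."""
    jl = min(cds_a.end, cds_b.start)
    jr = max(cds_a.end, cds_b.start)
    n = len(track)
    lo = max(1, jl - flank)
    hi = min(n, jr + flank)
    d = track.depth
    window = d[lo - 1 : hi]
    inner = d[jl - 1 : jr]
    left = d[max(1, jl - flank) - 1 : jl - 1]
    right = d[jr : min(n, jr + flank)]
    return window, inner, left, right


def junction_profile(
    track: DepthTrack, cds_a: CdsRecord, cds_b: CdsRecord, flank: int = 50
) -> JunctionProfile:
    """Profile depth across the junction between two CDSs on one contig.

    The junction spans from min(a.end, b.start) to max(a.end, b.start);
    the window extends ``flank`` bp on both sides, clipped to the contig.
    ``dip_width`` is the longest run of window positions strictly below
    half the smaller available flank mean.  Flank means are computed over
    the positions that exist (junctions near contig edges have shorter
    flanks); with no flank positions at all the window mean is used as
    the reference level.
    """
    if cds_a.contig_id != cds_b.contig_id:
        raise ValueError(
            f"junction_profile: CDSs on different contigs "
            f"({cds_a.contig_id!r} vs {cds_b.contig_id!r})"
        )
    if cds_a.contig_id != track.contig_id:
        raise ValueError("junction_profile: track does not match the CDS contig")
    if cds_a.start > cds_b.start:
        raise ValueError("junction_profile: cds_a must start at or before cds_b")
    window, inner, left, right = _junction_window(track, cds_a, cds_b, flank)
    fl = float(np.mean(left)) if len(left) else float("nan")
    fr = float(np.mean(right)) if len(right) else float("nan")
    available = [v for v in (fl, fr) if not np.isnan(v)]
    ref = min(available) if available else float(np.mean(window))
    runs = _below_runs(window, 0.5 * ref)
    return JunctionProfile(
        junction_min=float(inner.min()) if len(inner) else float(window.min()),
        flank_mean_left=fl,
        flank_mean_right=fr,
        dip_width=max(runs) if runs else 0,
    )


def smoothed(values: np.ndarray, width: int = 5) -> np.ndarray:
    """Centered moving average with edge-aware normalisation."""
    if width <= 1:
        return values.astype(float)
    kernel = np.ones(width)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones(len(values)), kernel, mode="same")
    return sums / counts
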