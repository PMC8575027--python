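"""Greedy cross-assembly protein clustering and provenance accounting.

Proteins predicted independently from several assemblies of the same
sample are clustered so that each cluster can be labelled with the set of
assemblies (its *provenance*) that contributed a member.  The clusterer is
a deterministic CD-HIT-style greedy algorithm: proteins are processed from
longest to shortest and either join the first earlier representative they
match (global identity and mutual coverage above thresholds) or found a
new cluster.  An exact amino-acid k-mer prefilter skips hopeless pairs; it
can only skip alignments, never change an accepted pair's identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_io import CdsRecord

_NEG = -(2**40)  # -inf sentinel safe for int64 additions


@dataclass(frozen=True)
class AlignScoring:
    """Global-alignment scoring; a gap of length L costs open + (L-1)*extend."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -5
    gap_extend: int = -1


# ---------------------------------------------------------------------------
# Pairwise global alignment (Gotoh, affine gaps), row-vectorised
# ---------------------------------------------------------------------------


def _gotoh_matrices(a: str, b: str, sc: AlignScoring):
    """Fill the three Gotoh state matrices.

    M ends in a substitution column, X in a gap-in-b column (consumes a
    residue of ``a``), Y in a gap-in-a column.  Y has a within-row
    dependency which is resolved with a running-max scan:
    Y[i,j] = e*j + max_{l<j}(max(M,X)[i,l] + open - e*(l+1)).
    """
    m, n = len(a), len(b)
    o, e = sc.gap_open, sc.gap_extend
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    M = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    X = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    Y = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    M[0, 0] = 0
    X[1:, 0] = o + np.arange(m) * e
    Y[0, 1:] = o + np.arange(n) * e
    jidx = np.arange(1, n + 1)
    for i in range(1, m + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        s = np.where(bv == av[i - 1], sc.match, sc.mismatch)
        M[i, 1:] = s + prev_best[:-1]
        X[i, 1:] = np.maximum(
            M[i - 1, 1:] + o, np.maximum(X[i - 1, 1:] + e, Y[i - 1, 1:] + o)
        )
        P = np.maximum(M[i], X[i])
        C = P + o - e * (np.arange(n + 1) + 1)
        Y[i, 1:] = e * jidx + np.maximum.accumulate(C[:-1])
    return M, X, Y


def _traceback(a: str, b: str, sc: AlignScoring, M, X, Y) -> str:
    """Recover one optimal alignment as a column string over {M,X,Y}.

    Ties are broken deterministically: substitution, then gap-in-b, then
    gap-in-a, both for the final state and at every step.
    """
    o, e = sc.gap_open, sc.gap_extend
    i, j = len(a), len(b)
    best = max(M[i, j], X[i, j], Y[i, j])
    state = "M"
    for st in "MXY":
        if {"M": M, "X": X, "Y": Y}[st][i, j] == best:
            state = st
            break
    cols: list[str] = []
    while i > 0 or j > 0:
        cols.append(state)
        if state == "M":
            target = M[i, j] - (sc.match if a[i - 1] == b[j - 1] else sc.mismatch)
            i, j = i - 1, j - 1
            for st, val in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
                if val == target:
                    state = st
                    break
        elif state == "X":
            target = X[i, j]
            i -= 1
            for st, val in (
                ("M", M[i, j] + o),
                ("X", X[i, j] + e),
                ("Y", Y[i, j] + o),
            ):
                if val == target:
                    state = st
                    break
        else:
            target = Y[i, j]
            j -= 1
            for st, val in (
                ("M", M[i, j] + o),
                ("X", X[i, j] + o),
                ("Y", Y[i, j] + e),
            ):
                if val == target:
                    state = st
                    break
    return "".join(reversed(cols))


def _identity_from_columns(a: str, b: str, cols: str) -> tuple[float, float, float]:
    matches = 0
    ia = ib = 0
    first_sub = last_sub = None
    a_in_core = b_in_core = 0
    for ci, c in enumerate(cols):
        if c == "M":
            if a[ia] == b[ib]:
                matches += 1
            if first_sub is None:
                first_sub = ci
            last_sub = ci
            ia += 1
            ib += 1
        elif c == "X":
            ia += 1
        else:
            ib += 1
    identity = matches / len(cols) if cols else 0.0
    if first_sub is None:
        return identity, 0.0, 0.0
    # residues of each sequence inside the core (first..last substitution column)
    ia = ib = 0
    for ci, c in enumerate(cols):
        in_core = first_sub <= ci <= last_sub
        if c in ("M", "X"):
            ia += 1
            if in_core:
                a_in_core += 1
        if c in ("M", "Y"):
            ib += 1
            if in_core:
                b_in_core += 1
    return identity, a_in_core / len(a), b_in_core / len(b)


def pairwise_identity(
    seq_a: str, seq_b: str, scoring: AlignScoring | None = None
) -> tuple[float, float, float]:
    """Globally align two proteins and report identity and coverages.

    Identity is matched columns over *all* alignment columns (gap columns
    included).  Coverage of a sequence is the fraction of its residues
    inside the aligned core, i.e. between the first and last
    substitution column (terminal overhangs excluded).
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity: empty sequence")
    sc = scoring or AlignScoring()
    M, X, Y = _gotoh_matrices(seq_a, seq_b, sc)
    cols = _traceback(seq_a, seq_b, sc, M, X, Y)
    return _identity_from_columns(seq_a, seq_b, cols)


def alignment_score(seq_a: str, seq_b: str, scoring: AlignScoring | None = None) -> int:
    """Optimal global alignment score (exposed for cross-checks)."""
    sc = scoring or AlignScoring()
    M, X, Y = _gotoh_matrices(seq_a, seq_b, sc)
    return int(max(M[-1, -1], X[-1, -1], Y[-1, -1]))


# ---------------------------------------------------------------------------
# Greedy clustering
# ---------------------------------------------------------------------------


@dataclass
class ProteinCluster:
    """A cluster of CDS proteins with cross-assembly provenance."""

    cluster_id: str
    representative_id: str
    members: list[tuple[str, str]]  # (cds_id, assembly_label), in join order

    @property
    def member_ids(self) -> frozenset[str]:
        return frozenset(m[0] for m in self.members)

    @property
    def provenance(self) -> frozenset[str]:
        return frozenset(m[1] for m in self.members)

    def __len__(self) -> int:
        return len(self.members)


def _kmer_set(seq: str, k: int) -> frozenset[str] | None:
    """Exact k-mer word set; None (= bypass prefilter) for sequences < k."""
    if len(seq) < k:
        return None
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def greedy_cluster(
    proteins: Sequence[CdsRecord],
    min_id: float = 0.9,
    min_cov: float = 0.8,
    k_prefilter: int = 5,
    min_shared_kmers: int = 1,
    scoring: AlignScoring | None = None,
    use_prefilter: bool = True,
) -> list[ProteinCluster]:
    """Cluster proteins greedily by global identity and mutual coverage.

    Proteins are ordered by (length descending, id ascending) and tried
    against representatives in cluster-creation order; the first
    representative with >= ``min_shared_kmers`` shared k-mers, identity
    >= ``min_id`` and both coverages >= ``min_cov`` absorbs the protein.
    The result is a deterministic partition independent of input order.
    """
    if not proteins:
        raise ValueError("greedy_cluster: no proteins")
    if not (0 < min_id <= 1) or not (0 < min_cov <= 1):
        raise ValueError("greedy_cluster: thresholds must be in (0, 1]")
    ordered = sorted(proteins, key=lambda r: (-len(r.protein_seq), r.id))
    reps: list[CdsRecord] = []
    rep_kmers: list[frozenset[str] | None] = []
    member_lists: list[list[tuple[str, str]]] = []
    for rec in ordered:
        km = _kmer_set(rec.protein_seq, k_prefilter)
        assigned = False
        for ri, rep in enumerate(reps):
            if use_prefilter and km is not None and rep_kmers[ri] is not None:
                if len(km & rep_kmers[ri]) < min_shared_kmers:
                    continue
            ident, cov_q, cov_r = pairwise_identity(
                rec.protein_seq, rep.protein_seq, scoring
            )
            if ident >= min_id and cov_q >= min_cov and cov_r >= min_cov:
                member_lists[ri].append((rec.id, rec.assembly_label))
                assigned = True
                break
        if not assigned:
            reps.append(rec)
            rep_kmers.append(km)
            member_lists.append([(rec.id, rec.assembly_label)])
    return [
        ProteinCluster(
            cluster_id=f"C{ri:06d}",
            representative_id=rep.id,
            members=members,
        )
        for ri, (rep, members) in enumerate(zip(reps, member_lists))
    ]


# ---------------------------------------------------------------------------
# Combination counting (provenance labels)
# ---------------------------------------------------------------------------


@dataclass
class CombinationRow:
    combination: tuple[str, ...]  # sorted assembly labels
    n_clusters: int
    n_proteins: int
    n_proteins_dedup: int


@dataclass
class CombinationTable:
    """Cluster/protein counts per distinct provenance combination.

    ``n_proteins`` counts member CDS records (the primary count);
    ``n_proteins_dedup`` collapses identical sequences within one assembly
    when CDS records are supplied.  ``n_core_proteins`` /
    ``n_exclusive_proteins`` are the two highlighted aggregates: members
    of clusters spanning every assembly, and members of single-assembly
    clusters.
    """

    rows: list[CombinationRow]
    all_labels: tuple[str, ...]
    n_clusters_total: int
    n_proteins_total: int
    n_core_clusters: int
    n_core_proteins: int
    n_exclusive_clusters: int
    n_exclusive_proteins: int


def combination_counts(
    clusters: Sequence[ProteinCluster],
    all_labels: Iterable[str] | None = None,
    records: Sequence[CdsRecord] | None = None,
) -> CombinationTable:
    """Tally clusters and member proteins per provenance combination."""
    if all_labels is None:
        labels: set[str] = set()
        for c in clusters:
            labels |= c.provenance
        all_labels = sorted(labels)
    else:
        all_labels = sorted(all_labels)
    seq_by_id = {r.id: r.protein_seq for r in records} if records else None
    agg: dict[tuple[str, ...], list[int]] = {}
    for c in clusters:
        combo = tuple(sorted(c.provenance))
        n_members = len(c.members)
        if seq_by_id is not None:
            dedup = len({(lab, seq_by_id[mid]) for mid, lab in c.members})
        else:
            dedup = n_members
        row = agg.setdefault(combo, [0, 0, 0])
        row[0] += 1
        row[1] += n_members
        row[2] += dedup
    rows = [
        CombinationRow(combo, nc, npr, nd)
        for combo, (nc, npr, nd) in agg.items()
    ]
    rows.sort(key=lambda r: (-r.n_proteins, r.combination))
    full = tuple(all_labels)
    n_core_c = sum(r.n_clusters for r in rows if r.combination == full)
    n_core_p = sum(r.n_proteins for r in rows if r.combination == full)
    n_excl_c = sum(r.n_clusters for r in rows if len(r.combination) == 1)
    n_excl_p = sum(r.n_proteins for r in rows if len(r.combination) == 1)
    return CombinationTable(
        rows=rows,
        all_labels=full,
        n_clusters_total=sum(r.n_clusters for r in rows),
        n_proteins_total=sum(r.n_proteins for r in rows),
        n_core_clusters=n_core_c,
        n_core_proteins=n_core_p,
        n_exclusive_clusters=n_excl_c,
        n_exclusive_proteins=n_excl_p,
    )
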