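"""Domain types and I/O for the formats the pipeline consumes and emits.

The pipeline compares several assemblies of the same metagenome through
their predicted proteins, per-base metatranscriptomic depth, per-contig
mapping statistics, and protein homology hits.  This module defines the
in-memory types for those objects and readers/writers for the on-disk
dialects:

* contig FASTA,
* protein FASTA with Prodigal-style headers
  (``<id> # <start> # <end> # <strand> # ID=..;partial=XY;..``),
* GFF3 CDS annotations (optional alternative CDS source),
* ``bedtools genomecov -d`` per-base depth tables,
* ``samtools idxstats`` per-contig mapping tables,
* BLAST/DIAMOND tabular hits (outfmt-6, 12 or 14 columns),
* two-column peptide-evidence tables.

All coordinates are 1-based and inclusive internally, which is the native
convention of every consumed dialect (FASTA headers, GFF3, genomecov ``-d``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("asmconcord")

_DNA_OK = set("ACGTN")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Contig:
    """One assembled contig."""

    id: str
    assembly_label: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"contig {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CdsRecord:
    """A predicted protein-coding gene on a contig.

    ``partial5``/``partial3`` flag truncation of the 5' (start) and 3'
    (stop) gene edge, i.e. the biological reading direction, not the
    contig's left/right edge.  ``protein_seq`` never carries the stop
    symbol ``*``.
    """

    id: str
    contig_id: str
    assembly_label: str
    start: int
    end: int
    strand: str
    partial5: bool
    partial3: bool
    protein_seq: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"CDS {self.id!r}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"CDS {self.id!r}: invalid strand {self.strand!r}")
        if not self.protein_seq:
            raise ValueError(f"CDS {self.id!r}: empty protein sequence")
        if "*" in self.protein_seq:
            raise ValueError(
                f"CDS {self.id!r}: internal stop symbol '*' in protein sequence"
            )
        if not (self.partial5 or self.partial3) and (self.end - self.start + 1) % 3:
            raise ValueError(
                f"CDS {self.id!r}: complete CDS length not divisible by 3"
            )

    @property
    def is_partial(self) -> bool:
        return self.partial5 or self.partial3

    @property
    def nt_length(self) -> int:
        return self.end - self.start + 1


@dataclass(eq=False)
class DepthTrack:
    """Per-base depth for one contig; index i of ``depth`` is base i+1."""

    contig_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1 or len(self.depth) == 0:
            raise ValueError(f"depth track {self.contig_id!r}: need a 1-D non-empty vector")
        if (self.depth < 0).any():
            raise ValueError(f"depth track {self.contig_id!r}: negative depth")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, DepthTrack)
            and self.contig_id == other.contig_id
            and np.array_equal(self.depth, other.depth)
        )

    def __len__(self) -> int:
        return len(self.depth)


@dataclass
class AlignmentHit:
    """One local protein alignment (BLAST outfmt-6 row, plus qlen/slen)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int
    slen: int

    def __post_init__(self) -> None:
        if not (1 <= self.qstart <= self.qend <= self.qlen):
            raise ValueError(
                f"hit {self.query_id!r}->{self.subject_id!r}: bad query coords"
            )
        if not (1 <= min(self.sstart, self.send)) or max(self.sstart, self.send) > self.slen:
            raise ValueError(
                f"hit {self.query_id!r}->{self.subject_id!r}: bad subject coords"
            )
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id!r}: negative e-value")

    @property
    def subject_interval(self) -> tuple[int, int]:
        """Subject span with orientation normalised away."""
        return (min(self.sstart, self.send), max(self.sstart, self.send))


@dataclass
class ContigMapStats:
    contig_id: str
    length: int
    mapped_reads: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"idxstats {self.contig_id!r}: non-positive length")
        if self.mapped_reads < 0:
            raise ValueError(f"idxstats {self.contig_id!r}: negative read count")


@dataclass
class PeptideEvidence:
    protein_id: str
    n_peptides: int

    def __post_init__(self) -> None:
        if self.n_peptides < 0:
            raise ValueError(f"peptide evidence {self.protein_id!r}: negative count")


# ---------------------------------------------------------------------------
# FASTA contigs
# ---------------------------------------------------------------------------


def read_contigs(path: str | Path, assembly_label: str) -> list[Contig]:
    """Read a contig FASTA.

    Sequences are upper-cased; characters outside ``ACGTN`` are replaced
    with ``N`` (one warning reporting the total replacement count).
    Duplicate record ids are an error.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    n_replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not set(seq) <= _DNA_OK:
            cleaned = "".join(c if c in _DNA_OK else "N" for c in seq)
            n_replaced += sum(a != b for a, b in zip(seq, cleaned))
            seq = cleaned
        contigs.append(Contig(id=rec.id, assembly_label=assembly_label, sequence=seq))
    if n_replaced:
        logger.warning("%s: replaced %d non-ACGTN characters with N", path, n_replaced)
    if not contigs:
        logger.warning("%s: empty FASTA, no contigs read", path)
    return contigs


def write_contigs(contigs: Iterable[Contig], path: str | Path) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Prodigal-dialect protein FASTA
# ---------------------------------------------------------------------------


def _header_line_numbers(path: str | Path) -> list[int]:
    """1-based line numbers of FASTA headers, for error messages."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                out.append(i)
    return out


def _parse_partial_digits(digits: str, strand: str) -> tuple[bool, bool]:
    """Map Prodigal ``partial=XY`` to (partial5, partial3).

    The first digit flags truncation at the contig's left edge, the second
    at the right edge; on the minus strand the left edge is the gene's 3'
    end, so the digits swap roles.
    """
    if len(digits) != 2 or any(d not in "01" for d in digits):
        raise ValueError(f"invalid partial attribute {digits!r}")
    left, right = digits[0] == "1", digits[1] == "1"
    if strand == "+":
        return left, right
    return right, left


def _partial_digits(rec: CdsRecord) -> str:
    if rec.strand == "+":
        left, right = rec.partial5, rec.partial3
    else:
        left, right = rec.partial3, rec.partial5
    return f"{int(left)}{int(right)}"


def read_prodigal_faa(path: str | Path, assembly_label: str) -> list[CdsRecord]:
    """Read a Prodigal-dialect protein FASTA.

    Headers carry ``<id> # <start> # <end> # <strand> # <attributes>``;
    strand is ``1``/``-1``; attributes include ``partial=XY``.  A missing
    partial attribute is treated as ``00`` (complete) with a warning.  A
    single trailing ``*`` is stripped from each sequence; an internal
    ``*`` is an error.
    """
    linenos = _header_line_numbers(path)
    records: list[CdsRecord] = []
    n_missing_partial = 0
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        lineno = linenos[idx] if idx < len(linenos) else -1
        header = rec.description
        parts = [p.strip() for p in header.split("#")]
        if len(parts) < 4:
            raise ValueError(
                f"{path}:{lineno}: header lacks '#'-separated fields: {header!r}"
            )
        cds_id = parts[0].split()[0]
        try:
            start, end = int(parts[1]), int(parts[2])
            strand_field = parts[3]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric coordinate field") from exc
        if strand_field == "1":
            strand = "+"
        elif strand_field == "-1":
            strand = "-"
        else:
            raise ValueError(f"{path}:{lineno}: invalid strand field {strand_field!r}")
        attrs: dict[str, str] = {}
        if len(parts) >= 5:
            for kv in parts[4].split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k.strip()] = v.strip()
        if "partial" in attrs:
            partial5, partial3 = _parse_partial_digits(attrs["partial"], strand)
        else:
            n_missing_partial += 1
            partial5 = partial3 = False
        seq = str(rec.seq)
        if seq.endswith("*"):
            seq = seq[:-1]
        records.append(
            CdsRecord(
                id=cds_id,
                contig_id=cds_id.rsplit("_", 1)[0],
                assembly_label=assembly_label,
                start=start,
                end=end,
                strand=strand,
                partial5=partial5,
                partial3=partial3,
                protein_seq=seq,
            )
        )
    if n_missing_partial:
        logger.warning(
            "%s: %d headers lacked a partial attribute; treated as complete (partial=00)",
            path,
            n_missing_partial,
        )
    if not records:
        logger.warning("%s: empty protein FASTA", path)
    return records


def write_prodigal_faa(records: Iterable[CdsRecord], path: str | Path) -> None:
    """Write proteins back in the Prodigal header dialect (round-trip safe)."""
    with open(path, "w") as fh:
        for i, rec in enumerate(records, start=1):
            strand = "1" if rec.strand == "+" else "-1"
            fh.write(
                f">{rec.id} # {rec.start} # {rec.end} # {strand} # "
                f"ID={i};partial={_partial_digits(rec)}\n"
            )
            seq = rec.protein_seq
            for j in range(0, len(seq), 70):
                fh.write(seq[j : j + 70] + "\n")


# ---------------------------------------------------------------------------
# GFF3 CDS (optional alternative source)
# ---------------------------------------------------------------------------


def read_cds_gff3(
    path: str | Path, assembly_label: str, contigs: Sequence[Contig]
) -> list[CdsRecord]:
    """Read CDS features from a GFF3 file and translate them.

    Needs the assembly contigs to extract and translate the coding
    sequence (translation table 11).  Recognised attributes: ``ID``
    (required) and ``partial`` (two digits, Prodigal semantics; default
    ``00``).
    """
    by_id = {c.id: c for c in contigs}
    records: list[CdsRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _, ftype, start_s, end_s, _, strand, _, attr_s = cols
            if ftype != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in attr_s.split(";") if "=" in kv
            )
            if "ID" not in attrs:
                raise ValueError(f"{path}:{lineno}: CDS feature without ID attribute")
            if seqid not in by_id:
                raise ValueError(f"{path}:{lineno}: unknown contig {seqid!r}")
            start, end = int(start_s), int(end_s)
            partial5, partial3 = _parse_partial_digits(
                attrs.get("partial", "00"), strand
            )
            nt = by_id[seqid].sequence[start - 1 : end]
            if strand == "-":
                nt = str(Seq(nt).reverse_complement())
            nt = nt[: len(nt) // 3 * 3]
            prot = str(Seq(nt).translate(table=11))
            if prot.endswith("*"):
                prot = prot[:-1]
            records.append(
                CdsRecord(
                    id=attrs["ID"],
                    contig_id=seqid,
                    assembly_label=assembly_label,
                    start=start,
                    end=end,
                    strand=strand,
                    partial5=partial5,
                    partial3=partial3,
                    protein_seq=prot,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Per-base depth tables (bedtools genomecov -d layout)
# ---------------------------------------------------------------------------


def read_depth_table(path: str | Path) -> list[DepthTrack]:
    """Read a ``genomecov -d`` TSV: contig, 1-based position, depth.

    Positions must be contiguous from 1 per contig; gaps or negative
    depths are errors.  An empty file yields an empty list with a warning.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["contig", "pos", "depth"],
            dtype={"contig": str},
        )
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty depth table", path)
        return []
    tracks: list[DepthTrack] = []
    for contig, grp in df.groupby("contig", sort=False):
        pos = grp["pos"].to_numpy()
        expected = np.arange(1, len(pos) + 1)
        if not np.array_equal(pos, expected):
            bad = int(pos[np.argmax(pos != expected)])
            raise ValueError(
                f"{path}: non-contiguous positions for contig {contig!r} near position {bad}"
            )
        depth = grp["depth"].to_numpy()
        if (depth < 0).any():
            raise ValueError(f"{path}: negative depth for contig {contig!r}")
        tracks.append(DepthTrack(contig_id=str(contig), depth=depth.astype(np.int64)))
    return tracks


def write_depth_table(tracks: Iterable[DepthTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tracks:
            for i, d in enumerate(t.depth, start=1):
                fh.write(f"{t.contig_id}\t{i}\t{int(d)}\n")


def depth_dict(tracks: Iterable[DepthTrack]) -> dict[str, DepthTrack]:
    return {t.contig_id: t for t in tracks}


# ---------------------------------------------------------------------------
# Alignment hit tables (outfmt-6 dialect)
# ---------------------------------------------------------------------------

_OUTFMT6_COLS = [
    "query_id", "subject_id", "pct_identity", "aln_len", "mismatches",
    "gap_opens", "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits_table(
    path: str | Path, lengths: Mapping[str, int] | None = None
) -> list[AlignmentHit]:
    """Read a 12- or 14-column BLAST outfmt-6 table.

    The 14-column dialect appends ``qlen`` and ``slen``.  For 12-column
    input, ``lengths`` must resolve both query and subject lengths (e.g.
    from loaded CDS records plus a reference length table); otherwise the
    read fails.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty hits table", path)
        return []
    ncol = df.shape[1]
    if ncol == 12:
        df.columns = _OUTFMT6_COLS
    elif ncol == 14:
        df.columns = _OUTFMT6_COLS + ["qlen", "slen"]
    else:
        raise ValueError(f"{path}: expected 12 or 14 columns, found {ncol}")
    numeric = [c for c in df.columns if c not in ("query_id", "subject_id")]
    for col in numeric:
        # python float(): correctly rounded, unlike pandas' fast parser
        try:
            df[col] = [float(x) for x in df[col]]
        except (TypeError, ValueError):
            for i, x in enumerate(df[col]):
                try:
                    float(x)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}:{i + 1}: non-numeric value in column {col!r}"
                    ) from None
    if ncol == 12:
        if lengths is None:
            raise ValueError(
                f"{path}: 12-column table needs query/subject lengths "
                "(pass a length mapping or load a 14-column table)"
            )
        missing = sorted(
            set(df["query_id"]).union(df["subject_id"]) - set(lengths)
        )
        if missing:
            raise ValueError(f"{path}: no length known for ids: {missing[:10]}")
        df["qlen"] = df["query_id"].map(lengths)
        df["slen"] = df["subject_id"].map(lengths)
    hits = [
        AlignmentHit(
            query_id=r.query_id, subject_id=r.subject_id,
            pct_identity=float(r.pct_identity), aln_len=int(r.aln_len),
            mismatches=int(r.mismatches), gap_opens=int(r.gap_opens),
            qstart=int(r.qstart), qend=int(r.qend),
            sstart=int(r.sstart), send=int(r.send),
            evalue=float(r.evalue), bitscore=float(r.bitscore),
            qlen=int(r.qlen), slen=int(r.slen),
        )
        for r in df.itertuples(index=False)
    ]
    return hits


def write_hits_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 14-column dialect."""
    with open(path, "w") as fh:
        for h in hits:
            # repr-precision floats so a written table reads back identically
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity!r}\t{h.aln_len}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.qstart}\t{h.qend}\t"
                f"{h.sstart}\t{h.send}\t{h.evalue!r}\t{h.bitscore!r}\t"
                f"{h.qlen}\t{h.slen}\n"
            )


# ---------------------------------------------------------------------------
# idxstats and peptide evidence
# ---------------------------------------------------------------------------


def read_idxstats(path: str | Path) -> tuple[list[ContigMapStats], int]:
    """Read a ``samtools idxstats`` table.

    Returns ``(per-contig stats, unmapped-read count)``; the ``*`` row
    carries the unmapped count and produces no ContigMapStats entry.
    """
    stats: list[ContigMapStats] = []
    unmapped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 idxstats columns")
            contig, length_s, mapped_s, unmapped_s = cols
            try:
                length, mapped, unm = int(length_s), int(mapped_s), int(unmapped_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
            if contig == "*":
                unmapped = unm
                continue
            stats.append(ContigMapStats(contig_id=contig, length=length, mapped_reads=mapped))
    return stats, unmapped


def write_idxstats(
    stats: Iterable[ContigMapStats], unmapped: int, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for s in stats:
            fh.write(f"{s.contig_id}\t{s.length}\t{s.mapped_reads}\t0\n")
        fh.write(f"*\t0\t0\t{unmapped}\n")


def read_peptide_evidence(path: str | Path) -> list[PeptideEvidence]:
    """Read a two-column TSV of protein id and distinct peptide count."""
    out: list[PeptideEvidence] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            try:
                n = int(cols[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric peptide count") from exc
            out.append(PeptideEvidence(protein_id=cols[0], n_peptides=n))
    return out


def write_peptide_evidence(evidence: Iterable[PeptideEvidence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in evidence:
            fh.write(f"{e.protein_id}\t{e.n_peptides}\n")
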