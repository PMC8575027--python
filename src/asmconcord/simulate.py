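"""Ground-truthed synthetic multi-assembly meta-omic data.

The generator emulates the situation the pipeline analyses: one
underlying gene catalogue assembled several times by tools with different
error characteristics.  A gene's fate in a given assembly is one of

* ``intact`` — one complete CDS, optionally with residue substitutions
  (polishing/consensus errors),
* ``dropped`` — the gene is missing from the assembly,
* ``fragmented`` — the contig breaks inside the gene, yielding two
  partial CDSs on two contigs (short-read-style fragmentation),
* ``frameshifted`` — a 1-nt deletion inside the gene shifts the frame and
  introduces a premature stop, yielding two complete CDSs on one contig
  that tile the true protein (long-read-style indel error).

Two archetype error profiles mirror those characteristics: SR-like
assemblies are fragmentation-prone, LR-like assemblies indel- and
substitution-prone.

The generator emits gene-caller-style output directly (protein FASTA
with Prodigal-dialect headers, homology hits against the truth proteins,
per-base metaT depth, idxstats, peptide evidence), so gene prediction and
read mapping stay outside the pipeline while truth bookkeeping stays
exact.  All randomness flows from one seed through named substreams, so
each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .core_io import (
    AlignmentHit,
    CdsRecord,
    Contig,
    ContigMapStats,
    DepthTrack,
    PeptideEvidence,
    write_contigs,
    write_depth_table,
    write_hits_table,
    write_idxstats,
    write_peptide_evidence,
    write_prodigal_faa,
)

logger = logging.getLogger("asmconcord")

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(_TABLE11.forward_table.items()):
    CODONS_BY_AA.setdefault(_aa, []).append(_codon)
STOP_CODONS = tuple(sorted(_TABLE11.stop_codons))
START_CODONS = ("ATG", "GTG", "TTG")

# substream indices for deriving independent RNG streams from one seed
_STREAMS = {"truth": 0, "assembly": 1, "depth": 2, "peptides": 3, "spacers": 4}


def stream_rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    """Named, independent RNG substream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[stream], index]))


# ---------------------------------------------------------------------------
# Truth catalogue
# ---------------------------------------------------------------------------


@dataclass
class GeneTruth:
    gene_id: str
    protein_seq: str
    cds_nt: str  # coding sequence including the stop codon
    expressed: bool
    depth_mean: float
    fates: dict[str, str] = field(default_factory=dict)
    indel_pos: dict[str, int] = field(default_factory=dict)  # per assembly, 1-based nt
    fragments: dict[str, list[str]] = field(default_factory=dict)

    @property
    def length_aa(self) -> int:
        return len(self.protein_seq)


@dataclass
class ErrorProfile:
    """Per-gene fate probabilities for one assembly archetype.

    ``p_sub`` is applied independently per residue to intact copies; the
    remaining mass 1 - p_drop - p_frag - p_indel is the intact rate.
    """

    label: str
    p_drop: float = 0.0
    p_frag: float = 0.0
    p_indel: float = 0.0
    p_sub: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_drop", "p_frag", "p_indel", "p_sub"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"ErrorProfile {self.label!r}: {name}={v} not in [0,1]")
        if self.p_drop + self.p_frag + self.p_indel > 1.0 + 1e-12:
            raise ValueError(
                f"ErrorProfile {self.label!r}: fate probabilities exceed 1"
            )

    @property
    def p_intact(self) -> float:
        return 1.0 - self.p_drop - self.p_frag - self.p_indel


def sr_like(label: str = "SR", p_frag: float = 0.1) -> ErrorProfile:
    """Fragmentation-prone (short-read-style) archetype."""
    return ErrorProfile(label=label, p_frag=p_frag)


def lr_like(
    label: str = "LR", p_indel: float = 0.1, p_sub: float = 0.01
) -> ErrorProfile:
    """Indel- and substitution-prone (long-read-style) archetype."""
    return ErrorProfile(label=label, p_indel=p_indel, p_sub=p_sub)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """DNA for a protein with uniformly random synonymous codons plus a stop."""
    codons = [
        CODONS_BY_AA[aa][rng.integers(len(CODONS_BY_AA[aa]))] for aa in protein
    ]
    codons.append(STOP_CODONS[rng.integers(len(STOP_CODONS))])
    return "".join(codons)


def generate_truth(
    n_genes: int,
    median_len_aa: float = 250.0,
    len_sigma: float = 0.5,
    expressed_frac: float = 0.5,
    median_depth: float = 20.0,
    depth_sigma: float = 0.6,
    seed: int = 0,
    min_len_aa: int = 80,
) -> list[GeneTruth]:
    """Draw a ground-truth gene catalogue.

    Protein lengths are log-normal (median ``median_len_aa``, floor
    ``min_len_aa`` so fragment fates stay realisable); proteins start
    with M and are uniform over the 20-letter alphabet otherwise; coding
    sequences use uniformly random synonymous codons (translation table
    11).  A fraction ``expressed_frac`` of genes is expressed with
    log-normal mean depth (median ``median_depth``).
    """
    if n_genes < 1:
        raise ValueError("generate_truth: n_genes must be >= 1")
    if not (0 <= expressed_frac <= 1):
        raise ValueError("generate_truth: expressed_frac must be in [0,1]")
    if median_len_aa <= 0 or len_sigma <= 0 or median_depth <= 0 or depth_sigma <= 0:
        raise ValueError("generate_truth: distribution parameters must be positive")
    rng = stream_rng(seed, "truth")
    genes: list[GeneTruth] = []
    width = len(str(n_genes))
    for gi in range(n_genes):
        length = max(min_len_aa, int(round(rng.lognormal(np.log(median_len_aa), len_sigma))))
        body = rng.integers(0, len(AA20), size=length - 1)
        protein = "M" + "".join(AA20[i] for i in body)
        expressed = bool(rng.random() < expressed_frac)
        depth_mean = float(rng.lognormal(np.log(median_depth), depth_sigma)) if expressed else 0.0
        genes.append(
            GeneTruth(
                gene_id=f"g{gi:0{width}d}",
                protein_seq=protein,
                cds_nt=reverse_translate(protein, rng),
                expressed=expressed,
                depth_mean=depth_mean,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Assembly emission
# ---------------------------------------------------------------------------


@dataclass
class GenePlacement:
    gene_id: str
    contig_id: str
    start: int
    end: int
    expressed: bool
    depth_mean: float
    junction: int | None = None  # contig coordinate of the indel, 1-based


@dataclass
class SyntheticAssembly:
    label: str
    contigs: list[Contig]
    cds: list[CdsRecord]
    hits: list[AlignmentHit]
    placements: list[GenePlacement]


def _synthetic_evalue(aln_len: int) -> float:
    """Monotone decreasing in alignment length; longer hit, smaller e-value.

    Uses round decimal powers so that serialised tables parse back to the
    identical float.
    """
    return float(f"1e-{min(aln_len, 150) // 2}")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _substitute(
    protein: str, cds_nt: str, p_sub: float, rng: np.random.Generator
) -> tuple[str, str, int]:
    """Apply per-residue substitutions to a gene copy.

    Only the substituted codons are re-encoded; untouched codons keep the
    truth nucleotide sequence, so error-free gene copies are identical at
    the nucleotide level across assemblies.
    """
    if p_sub <= 0:
        return protein, cds_nt, 0
    chars = list(protein)
    codons = [cds_nt[3 * i : 3 * i + 3] for i in range(len(cds_nt) // 3)]
    n_sub = 0
    # the initiator M is kept so re-emitted genes stay caller-plausible
    for i in range(1, len(chars)):
        if rng.random() < p_sub:
            choices = AA20.replace(chars[i], "")
            chars[i] = choices[rng.integers(len(choices))]
            aa_codons = CODONS_BY_AA[chars[i]]
            codons[i] = aa_codons[rng.integers(len(aa_codons))]
            n_sub += 1
    return "".join(chars), "".join(codons), n_sub


def _translate_frame(nt: str) -> str:
    return str(Seq(nt[: len(nt) // 3 * 3]).translate(table=11))


def _frameshift_fragments(
    nt: str, rng: np.random.Generator, min_frag_aa: int = 30, max_attempts: int = 20
):
    """Realise a 1-nt deletion that splits the gene into two valid fragments.

    Returns ``(mutated_nt, d, a_end_nt, b_start_nt)`` where ``d`` is the
    0-based deletion site in the original sequence, fragment A spans
    mutated positions [0, a_end_nt) ending in a premature stop, and
    fragment B spans [b_start_nt, len(mutated)) starting at a start codon
    at or before the indel in the frame of the gene's original stop.
    ``None`` if no valid realisation was found within ``max_attempts``.
    """
    L = len(nt)
    lo, hi = int(0.2 * L), int(0.8 * L)
    if hi <= lo:
        return None
    for _ in range(max_attempts):
        d = int(rng.integers(lo, hi))
        mut = nt[:d] + nt[d + 1 :]
        # fragment A: first in-frame stop of the mutated sequence
        a_stop = None
        for t in range(0, len(mut) - 2, 3):
            if mut[t : t + 3] in STOP_CODONS:
                a_stop = t
                break
        if a_stop is None or a_stop // 3 < min_frag_aa:
            continue
        a_end_nt = a_stop + 3
        # fragment B: latest start codon at or before d in the frame of
        # the original (final) stop codon, with a stop-free translation
        final_frame = (len(mut) - 3) % 3
        b_start_nt = None
        p = d - (d - final_frame) % 3
        while p >= 0:
            if mut[p : p + 3] in START_CODONS:
                body = _translate_frame(mut[p : len(mut) - 3])
                if "*" not in body:
                    b_start_nt = p
                    break
            p -= 3
        if b_start_nt is None:
            continue
        b_len_aa = (len(mut) - 3 - b_start_nt) // 3
        if b_len_aa < min_frag_aa:
            continue
        return mut, d, a_end_nt, b_start_nt
    return None


class _ContigBuilder:
    """Accumulates gene and spacer segments into contigs for one assembly.

    Spacer sequences come from their own substream shared by all
    assemblies, so identical layouts (e.g. under all-zero error
    profiles) produce identical contig sequences across labels.
    """

    def __init__(self, label: str, spacer_rng: np.random.Generator, spacer_len: int):
        self.label = label
        self.rng = spacer_rng
        self.spacer_len = spacer_len
        self.contigs: list[Contig] = []
        self._segments: list[str] = []
        self._pos = 0
        self._cds_serial = 0

    @property
    def current_id(self) -> str:
        return f"{self.label}_c{len(self.contigs):04d}"

    def append(self, seq: str) -> tuple[int, int]:
        """Append a segment; returns its 1-based inclusive span."""
        start = self._pos + 1
        self._segments.append(seq)
        self._pos += len(seq)
        return start, self._pos

    def spacer(self) -> None:
        self.append(_random_dna(self.rng, self.spacer_len))

    def next_cds_id(self) -> str:
        self._cds_serial += 1
        return f"{self.current_id}_{self._cds_serial}"

    def flush(self) -> None:
        if self._pos:
            self.contigs.append(
                Contig(
                    id=self.current_id,
                    assembly_label=self.label,
                    sequence="".join(self._segments),
                )
            )
        self._segments = []
        self._pos = 0
        self._cds_serial = 0


def emit_assembly(
    truth: Sequence[GeneTruth],
    profile: ErrorProfile,
    seed: int,
    assembly_index: int = 0,
    genes_per_contig: int = 5,
    spacer_len: int = 200,
    min_frag_aa: int = 30,
) -> SyntheticAssembly:
    """Emit one assembly of the truth catalogue under an error profile.

    Genes are laid on contigs of ``genes_per_contig`` genes (fragmentation
    forces extra breaks) separated by ``spacer_len`` bp of random
    intergenic sequence, all on the plus strand.  Each emitted CDS also
    yields a homology hit against its truth protein whose subject
    interval is the truth region the fragment covers.
    """
    rng = stream_rng(seed, "assembly", assembly_index)
    builder = _ContigBuilder(profile.label, stream_rng(seed, "spacers"), spacer_len)
    cds: list[CdsRecord] = []
    hits: list[AlignmentHit] = []
    placements: list[GenePlacement] = []
    genes_on_contig = 0
    fate_names = np.array(["intact", "dropped", "fragmented", "frameshifted"])
    fate_probs = np.clip(
        [profile.p_intact, profile.p_drop, profile.p_frag, profile.p_indel], 0.0, 1.0
    )
    fate_probs = fate_probs / fate_probs.sum()

    def add_hit(qid, sid, prot_len, qstart, qend, sstart, send, slen,
                pident=100.0, mism=0):
        aln = qend - qstart + 1
        hits.append(
            AlignmentHit(
                query_id=qid, subject_id=sid, pct_identity=pident, aln_len=aln,
                mismatches=mism, gap_opens=0, qstart=qstart, qend=qend,
                sstart=sstart, send=send, evalue=_synthetic_evalue(aln),
                bitscore=2.0 * aln, qlen=prot_len, slen=slen,
            )
        )

    for gene in truth:
        fate = str(rng.choice(fate_names, p=fate_probs))
        L = gene.length_aa
        if fate == "frameshifted":
            realised = _frameshift_fragments(gene.cds_nt, rng, min_frag_aa)
            if realised is None:
                logger.info(
                    "%s/%s: no valid frameshift realisation, downgraded to intact",
                    profile.label, gene.gene_id,
                )
                fate = "intact"
        gene.fates[profile.label] = fate
        if fate == "dropped":
            gene.fragments[profile.label] = []
            continue
        if genes_on_contig >= genes_per_contig:
            builder.flush()
            genes_on_contig = 0
        builder.spacer()
        if fate == "intact":
            prot, nt, n_sub = _substitute(
                gene.protein_seq, gene.cds_nt, profile.p_sub, rng
            )
            start, end = builder.append(nt)
            cid = builder.next_cds_id()
            cds.append(
                CdsRecord(
                    id=cid, contig_id=builder.current_id,
                    assembly_label=profile.label, start=start, end=end,
                    strand="+", partial5=False, partial3=False, protein_seq=prot,
                )
            )
            add_hit(
                cid, gene.gene_id, L, 1, L, 1, L,
                slen=L, pident=100.0 * (1 - n_sub / L), mism=n_sub,
            )
            placements.append(
                GenePlacement(gene.gene_id, builder.current_id, start, end,
                              gene.expressed, gene.depth_mean)
            )
            gene.fragments[profile.label] = [cid]
            genes_on_contig += 1
        elif fate == "fragmented":
            split = int(rng.integers(min_frag_aa, L - min_frag_aa + 1))
            codons = [gene.cds_nt[3 * i : 3 * i + 3] for i in range(L + 1)]
            nt_a = "".join(codons[:split])
            nt_b = "".join(codons[split:])  # includes the stop codon
            start_a, end_a = builder.append(nt_a)
            cid_a = builder.next_cds_id()
            contig_a = builder.current_id
            cds.append(
                CdsRecord(
                    id=cid_a, contig_id=contig_a, assembly_label=profile.label,
                    start=start_a, end=end_a, strand="+",
                    partial5=False, partial3=True,
                    protein_seq=gene.protein_seq[:split],
                )
            )
            add_hit(cid_a, gene.gene_id, split, 1, split, 1, split, slen=L)
            placements.append(
                GenePlacement(gene.gene_id, contig_a, start_a, end_a,
                              gene.expressed, gene.depth_mean)
            )
            builder.flush()  # contig break inside the gene
            start_b, end_b = builder.append(nt_b)
            cid_b = builder.next_cds_id()
            contig_b = builder.current_id
            cds.append(
                CdsRecord(
                    id=cid_b, contig_id=contig_b, assembly_label=profile.label,
                    start=start_b, end=end_b, strand="+",
                    partial5=True, partial3=False,
                    protein_seq=gene.protein_seq[split:],
                )
            )
            add_hit(cid_b, gene.gene_id, L - split, 1, L - split, split + 1, L, slen=L)
            placements.append(
                GenePlacement(gene.gene_id, contig_b, start_b, end_b,
                              gene.expressed, gene.depth_mean)
            )
            gene.fragments[profile.label] = [cid_a, cid_b]
            genes_on_contig = 1
        else:  # frameshifted
            mut, d, a_end_nt, b_start_nt = realised
            start, end = builder.append(mut)
            contig_id = builder.current_id
            gene.indel_pos[profile.label] = d + 1
            # fragment A: gene start to premature stop
            prot_a = _translate_frame(mut[: a_end_nt - 3])
            cid_a = builder.next_cds_id()
            cds.append(
                CdsRecord(
                    id=cid_a, contig_id=contig_id, assembly_label=profile.label,
                    start=start, end=start + a_end_nt - 1, strand="+",
                    partial5=False, partial3=False, protein_seq=prot_a,
                )
            )
            ha = d // 3  # full truth codons upstream of the indel
            add_hit(cid_a, gene.gene_id, len(prot_a), 1, ha, 1, ha, slen=L)
            # fragment B: shifted-frame start codon to gene end
            prot_b = _translate_frame(mut[b_start_nt : len(mut) - 3])
            cid_b = builder.next_cds_id()
            cds.append(
                CdsRecord(
                    id=cid_b, contig_id=contig_id, assembly_label=profile.label,
                    start=start + b_start_nt, end=end, strand="+",
                    partial5=False, partial3=False, protein_seq=prot_b,
                )
            )
            # subject start of fragment B; capped so the aligned region
            # never exceeds the fragment (start codon may sit on the indel)
            hb = max(ha + 1, L - len(prot_b) + 1)
            homol = L - hb + 1
            add_hit(cid_b, gene.gene_id, len(prot_b),
                    len(prot_b) - homol + 1, len(prot_b), hb, L, slen=L)
            placements.append(
                GenePlacement(gene.gene_id, contig_id, start, end,
                              gene.expressed, gene.depth_mean,
                              junction=start + d)
            )
            gene.fragments[profile.label] = [cid_a, cid_b]
            genes_on_contig += 1
    builder.flush()
    return SyntheticAssembly(
        label=profile.label, contigs=builder.contigs, cds=cds,
        hits=hits, placements=placements,
    )


# ---------------------------------------------------------------------------
# Depth simulation
# ---------------------------------------------------------------------------


def simulate_depth(
    assemblies: Sequence[SyntheticAssembly],
    dip_depth_frac: float = 0.3,
    dip_width: int = 5,
    background_depth: float = 0.5,
    seed: int = 0,
) -> dict[str, dict[str, DepthTrack]]:
    """Poisson per-base metaT depth for every contig of every assembly.

    Expressed gene intervals get the gene's mean depth; intergenic
    sequence and unexpressed genes get a low background
    (``background_depth``); frameshifted expressed genes get a dip
    window of ``dip_width`` bp centred on the indel at
    ``dip_depth_frac`` times the gene mean — the localized single drop
    in coverage such indels leave in real data.
    """
    out: dict[str, dict[str, DepthTrack]] = {}
    for ai, asm in enumerate(assemblies):
        rng = stream_rng(seed, "depth", ai)
        means: dict[str, np.ndarray] = {
            c.id: np.full(c.length, background_depth) for c in asm.contigs
        }
        for pl in asm.placements:
            if not pl.expressed:
                continue
            mean = means[pl.contig_id]
            mean[pl.start - 1 : pl.end] = pl.depth_mean
        for pl in asm.placements:
            if pl.junction is None or not pl.expressed:
                continue
            mean = means[pl.contig_id]
            lo = max(0, pl.junction - 1 - dip_width // 2)
            mean[lo : lo + dip_width] = dip_depth_frac * pl.depth_mean
        out[asm.label] = {
            cid: DepthTrack(cid, rng.poisson(mean))
            for cid, mean in means.items()
        }
    return out


def make_idxstats(
    assembly: SyntheticAssembly,
    tracks: dict[str, DepthTrack],
    read_len: int = 100,
    unmapped_frac: float = 0.1,
) -> tuple[list[ContigMapStats], int]:
    """Per-contig mapped-read counts consistent with the depth tracks.

    Mapped reads per contig are total depth divided by the nominal read
    length, so contigs carrying expressed genes dominate the mapping
    rate, as they would for metaT reads.
    """
    stats = [
        ContigMapStats(
            contig_id=c.id,
            length=c.length,
            mapped_reads=int(tracks[c.id].depth.sum() // read_len),
        )
        for c in assembly.contigs
    ]
    total = sum(s.mapped_reads for s in stats)
    return stats, int(round(unmapped_frac * total))


def make_peptide_evidence(
    truth: Sequence[GeneTruth],
    assemblies: Sequence[SyntheticAssembly],
    detected_frac: float = 0.5,
    mean_peptides: float = 3.0,
    seed: int = 0,
) -> list[PeptideEvidence]:
    """Peptide evidence for a random subset of expressed genes.

    A fraction ``detected_frac`` of expressed genes is proteomically
    detected; every emitted CDS of a detected gene gets a positive
    peptide count (shifted Poisson).
    """
    rng = stream_rng(seed, "peptides")
    detected = {
        g.gene_id for g in truth if g.expressed and rng.random() < detected_frac
    }
    out: list[PeptideEvidence] = []
    for asm in assemblies:
        for gene in truth:
            if gene.gene_id not in detected:
                continue
            for cid in gene.fragments.get(asm.label, []):
                out.append(
                    PeptideEvidence(cid, 1 + int(rng.poisson(mean_peptides - 1)))
                )
    return out


# ---------------------------------------------------------------------------
# Bundle assembly and serialisation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticBundle:
    seed: int
    params: dict
    truth: list[GeneTruth]
    assemblies: dict[str, SyntheticAssembly]
    depth: dict[str, dict[str, DepthTrack]]
    idxstats: dict[str, tuple[list[ContigMapStats], int]]
    peptides: list[PeptideEvidence]


def default_profiles() -> list[ErrorProfile]:
    """The default study conditions: one LR-like, two SR-like assemblies."""
    return [lr_like("LR1"), sr_like("SR1"), sr_like("SR2")]


def simulate_bundle(
    n_genes: int = 300,
    profiles: Sequence[ErrorProfile] | None = None,
    expressed_frac: float = 0.5,
    seed: int = 0,
    with_peptides: bool = True,
    **truth_kwargs,
) -> SyntheticBundle:
    """Generate a complete multi-assembly meta-omic bundle."""
    if profiles is None:
        profiles = default_profiles()
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("simulate_bundle: duplicate assembly labels")
    truth = generate_truth(
        n_genes, expressed_frac=expressed_frac, seed=seed, **truth_kwargs
    )
    assemblies = [
        emit_assembly(truth, prof, seed, assembly_index=i)
        for i, prof in enumerate(profiles)
    ]
    depth = simulate_depth(assemblies, seed=seed)
    idxstats = {
        asm.label: make_idxstats(asm, depth[asm.label]) for asm in assemblies
    }
    peptides = (
        make_peptide_evidence(truth, assemblies, seed=seed) if with_peptides else []
    )
    params = {
        "n_genes": n_genes,
        "expressed_frac": expressed_frac,
        "profiles": [dataclasses.asdict(p) for p in profiles],
        **truth_kwargs,
    }
    return SyntheticBundle(
        seed=seed,
        params=params,
        truth=truth,
        assemblies={a.label: a for a in assemblies},
        depth=depth,
        idxstats=idxstats,
        peptides=peptides,
    )


def write_truth_table(truth: Sequence[GeneTruth], labels: Sequence[str], path: Path) -> None:
    cols = ["gene_id", "length_aa", "expressed", "depth_mean"]
    for lab in labels:
        cols += [f"fate_{lab}", f"fragments_{lab}", f"indel_pos_{lab}"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for g in truth:
            row = [g.gene_id, str(g.length_aa), str(int(g.expressed)), f"{g.depth_mean:.4f}"]
            for lab in labels:
                row.append(g.fates.get(lab, ""))
                row.append(",".join(g.fragments.get(lab, [])))
                row.append(str(g.indel_pos.get(lab, "")))
            fh.write("\t".join(row) + "\n")


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict:
    """Write every bundle component in its contract format; returns the manifest.

    Regeneration from the same seed and parameters is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = sorted(bundle.assemblies)
    files: dict[str, dict[str, str]] = {}
    for lab in labels:
        asm = bundle.assemblies[lab]
        paths = {
            "contigs": f"{lab}.contigs.fna",
            "proteins": f"{lab}.proteins.faa",
            "depth": f"{lab}.depth.tsv",
            "hits": f"{lab}.hits.tsv",
            "idxstats": f"{lab}.idxstats.tsv",
        }
        write_contigs(asm.contigs, outdir / paths["contigs"])
        write_prodigal_faa(asm.cds, outdir / paths["proteins"])
        tracks = [bundle.depth[lab][c.id] for c in asm.contigs]
        write_depth_table(tracks, outdir / paths["depth"])
        write_hits_table(asm.hits, outdir / paths["hits"])
        stats, unmapped = bundle.idxstats[lab]
        write_idxstats(stats, unmapped, outdir / paths["idxstats"])
        files[lab] = paths
    if bundle.peptides:
        write_peptide_evidence(bundle.peptides, outdir / "peptides.tsv")
    write_truth_table(bundle.truth, labels, outdir / "truth.tsv")
    manifest = {
        "seed": bundle.seed,
        "params": bundle.params,
        "assemblies": files,
        "peptides": "peptides.tsv" if bundle.peptides else None,
        "truth": "truth.tsv",
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
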