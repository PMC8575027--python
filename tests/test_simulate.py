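import json
from pathlib import Path

import numpy as np
import pytest
from Bio.Seq import Seq

from asmconcord import core_io, coverage, frameshift, simulate as sim
from asmconcord.concordance import best_hits


def _truth_small(seed=3, n=40, **kw):
    return sim.generate_truth(n, seed=seed, **kw)


# ---------------------------------------------------------------------------
# truth catalogue
# ---------------------------------------------------------------------------


def test_truth_is_deterministic_per_seed():
    a, b = _truth_small(), _truth_small()
    assert [(g.gene_id, g.protein_seq, g.cds_nt, g.expressed, g.depth_mean)
            for g in a] == [
        (g.gene_id, g.protein_seq, g.cds_nt, g.expressed, g.depth_mean) for g in b
    ]
    c = _truth_small(seed=4)
    assert [g.protein_seq for g in a] != [g.protein_seq for g in c]


def test_reverse_translation_round_trip():
    for g in _truth_small():
        assert str(Seq(g.cds_nt).translate(table=11)) == g.protein_seq + "*"
        assert g.depth_mean > 0 if g.expressed else g.depth_mean == 0.0


def test_expressed_fraction_binomial_bound():
    n, f = 1000, 0.5
    truth = sim.generate_truth(n, expressed_frac=f, seed=1)
    observed = sum(g.expressed for g in truth)
    sd = (n * f * (1 - f)) ** 0.5
    assert abs(observed - n * f) <= 3 * sd


def test_invalid_parameters_error():
    with pytest.raises(ValueError):
        sim.generate_truth(0)
    with pytest.raises(ValueError):
        sim.generate_truth(10, median_len_aa=-5)
    with pytest.raises(ValueError):
        sim.ErrorProfile("X", p_drop=0.6, p_frag=0.5)


# ---------------------------------------------------------------------------
# assembly emission
# ---------------------------------------------------------------------------


def test_zero_error_assemblies_identical_across_labels():
    profs = [sim.ErrorProfile(lab) for lab in "ABC"]
    truth = _truth_small()
    asms = [sim.emit_assembly(truth, p, seed=3, assembly_index=i)
            for i, p in enumerate(profs)]
    seqs = [[c.sequence for c in a.contigs] for a in asms]
    assert seqs[0] == seqs[1] == seqs[2]
    for a in asms:
        assert len(a.cds) == len(truth)
        assert all(not r.is_partial for r in a.cds)


def test_fragmented_gene_yields_complementary_partials():
    truth = _truth_small()
    asm = sim.emit_assembly(truth, sim.ErrorProfile("F", p_frag=1.0), seed=3)
    for g in truth:
        frags = g.fragments["F"]
        assert len(frags) == 2
        a, b = (next(r for r in asm.cds if r.id == f) for f in frags)
        assert (a.partial5, a.partial3) == (False, True)
        assert (b.partial5, b.partial3) == (True, False)
        assert a.contig_id != b.contig_id
        assert a.protein_seq + b.protein_seq == g.protein_seq


def test_frameshifted_gene_is_detectable_at_defaults():
    """Emitted fragment pairs satisfy the split-gene predicate thresholds."""
    truth = _truth_small(n=60)
    asm = sim.emit_assembly(truth, sim.ErrorProfile("I", p_indel=1.0), seed=3)
    best = best_hits(asm.hits)
    n_shifted = sum(1 for g in truth if g.fates["I"] == "frameshifted")
    assert n_shifted >= 50  # downgrades to intact are rare
    for g in truth:
        if g.fates["I"] != "frameshifted":
            continue
        fa, fb = g.fragments["I"]
        ha, hb = best[fa], best[fb]
        ia, ib = ha.subject_interval, hb.subject_interval
        ov = max(0, min(ia[1], ib[1]) - max(ia[0], ib[0]) + 1)
        la, lb = ia[1] - ia[0] + 1, ib[1] - ib[0] + 1
        assert ov / min(la, lb) <= 0.2
        assert (la + lb - ov) / g.length_aa >= 0.8
        ra = next(r for r in asm.cds if r.id == fa)
        rb = next(r for r in asm.cds if r.id == fb)
        assert ra.contig_id == rb.contig_id
        assert rb.start - ra.end - 1 <= 100
        assert len(ra.protein_seq) >= 30 and len(rb.protein_seq) >= 30


def test_dropped_genes_emit_nothing():
    truth = _truth_small()
    asm = sim.emit_assembly(truth, sim.ErrorProfile("D", p_drop=1.0), seed=3)
    assert asm.cds == [] and asm.contigs == []
    assert all(g.fragments["D"] == [] for g in truth)


# ---------------------------------------------------------------------------
# depth simulation
# ---------------------------------------------------------------------------


def _forced_truth(expressed, depth_mean=20.0, n=40):
    truth = _truth_small(n=n)
    for g in truth:
        g.expressed = expressed
        g.depth_mean = depth_mean if expressed else 0.0
    return truth


def test_unexpressed_genes_stay_below_threshold():
    truth = _forced_truth(expressed=False)
    asm = sim.emit_assembly(truth, sim.ErrorProfile("A"), seed=3)
    tracks = sim.simulate_depth([asm], seed=3)["A"]
    for rec in asm.cds:
        assert coverage.mean_cds_depth(tracks[rec.contig_id], rec) < 10


def test_expressed_genes_near_their_mean():
    truth = _forced_truth(expressed=True, depth_mean=20.0)
    asm = sim.emit_assembly(truth, sim.ErrorProfile("A"), seed=3)
    tracks = sim.simulate_depth([asm], seed=3)["A"]
    for rec in asm.cds:
        m = coverage.mean_cds_depth(tracks[rec.contig_id], rec)
        se = (20.0 / rec.nt_length) ** 0.5
        assert abs(m - 20.0) <= 3 * se + 1e-9


def test_dip_window_only_at_expressed_frameshift_junctions():
    truth = _forced_truth(expressed=True, depth_mean=30.0)
    asm = sim.emit_assembly(truth, sim.ErrorProfile("I", p_indel=1.0), seed=3)
    tracks = sim.simulate_depth([asm], dip_depth_frac=0.2, dip_width=5, seed=3)["I"]
    for pl in asm.placements:
        if pl.junction is None:
            continue
        window = tracks[pl.contig_id].depth[pl.junction - 3 : pl.junction + 2]
        assert window.mean() < 15  # dip visibly below the gene mean
    intact = sim.emit_assembly(truth, sim.ErrorProfile("A"), seed=3)
    assert all(pl.junction is None for pl in intact.placements)


def test_idxstats_tracks_expressed_content(bundle):
    for lab, (stats, unmapped) in bundle.idxstats.items():
        tracks = bundle.depth[lab]
        for s in stats:
            assert s.mapped_reads == int(tracks[s.contig_id].depth.sum() // 100)
        assert unmapped >= 0


# ---------------------------------------------------------------------------
# bundle round-trip and reproducibility
# ---------------------------------------------------------------------------


def test_bundle_round_trip_through_readers(bundle, bundle_dir):
    for lab, asm in bundle.assemblies.items():
        contigs = core_io.read_contigs(bundle_dir / f"{lab}.contigs.fna", lab)
        assert contigs == asm.contigs
        cds = core_io.read_prodigal_faa(bundle_dir / f"{lab}.proteins.faa", lab)
        assert cds == asm.cds
        hits = core_io.read_hits_table(bundle_dir / f"{lab}.hits.tsv")
        assert hits == asm.hits
        tracks = core_io.depth_dict(
            core_io.read_depth_table(bundle_dir / f"{lab}.depth.tsv")
        )
        assert tracks == bundle.depth[lab]
        stats, unmapped = core_io.read_idxstats(bundle_dir / f"{lab}.idxstats.tsv")
        assert (stats, unmapped) == bundle.idxstats[lab]
    peptides = core_io.read_peptide_evidence(bundle_dir / "peptides.tsv")
    assert peptides == bundle.peptides


def test_bundle_regeneration_is_byte_identical(tmp_path):
    for d in ("r1", "r2"):
        b = sim.simulate_bundle(n_genes=25, seed=9)
        sim.write_bundle(b, tmp_path / d)
    files = sorted(p.name for p in (tmp_path / "r1").iterdir())
    assert files == sorted(p.name for p in (tmp_path / "r2").iterdir())
    for name in files:
        assert (tmp_path / "r1" / name).read_bytes() == (
            tmp_path / "r2" / name
        ).read_bytes(), name


def test_manifest_records_seed_and_fates(bundle_dir):
    manifest = json.loads((bundle_dir / "manifest.json").read_text())
    assert manifest["seed"] == 11
    assert set(manifest["assemblies"]) == {"LR1", "SR1", "SR2"}
    truth_lines = (bundle_dir / "truth.tsv").read_text().splitlines()
    assert truth_lines[0].startswith("gene_id\t")
    assert len(truth_lines) == 61
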