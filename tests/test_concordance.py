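import random

import numpy as np
import pytest

from asmconcord import concordance
from asmconcord.clustering import ProteinCluster
from asmconcord.core_io import AlignmentHit, PeptideEvidence
from asmconcord.coverage import ExpressionCall
from conftest import make_cds


def _hit(q, s, evalue=1e-10, bitscore=100.0, qlen=100, slen=100,
         sstart=1, send=None):
    send = send if send is not None else slen
    return AlignmentHit(
        query_id=q, subject_id=s, pct_identity=99.0, aln_len=min(qlen, slen),
        mismatches=0, gap_opens=0, qstart=1, qend=qlen, sstart=sstart, send=send,
        evalue=evalue, bitscore=bitscore, qlen=qlen, slen=slen,
    )


def _cluster(cid, members):
    return ProteinCluster(cid, members[0][0], members)


# ---------------------------------------------------------------------------
# partial stats
# ---------------------------------------------------------------------------


def test_partial_stats_counts():
    recs = (
        [make_cds(f"p{i}", "MKV", label="A") for i in range(3)]
        + [make_cds(f"q{i}", "MKV", label="A", partial5=True) for i in range(2)]
    )
    stats = concordance.partial_stats(recs)["A"]
    assert (stats.n_total, stats.n_partial, stats.n_complete) == (5, 2, 3)
    assert concordance.partial_stats([]) == {}


def test_partial_stats_random_recount():
    rng = random.Random(2)
    recs = []
    for i in range(200):
        lab = rng.choice("AB")
        p5, p3 = rng.random() < 0.3, rng.random() < 0.3
        recs.append(make_cds(f"p{i}", "MKV", label=lab, partial5=p5, partial3=p3))
    stats = concordance.partial_stats(recs)
    for lab in "AB":
        mine = [r for r in recs if r.assembly_label == lab]
        assert stats[lab].n_total == len(mine)
        assert stats[lab].n_partial == sum(1 for r in mine if r.partial5 or r.partial3)
        assert stats[lab].n_total == stats[lab].n_partial + stats[lab].n_complete


# ---------------------------------------------------------------------------
# best hits
# ---------------------------------------------------------------------------


def test_best_hits_evalue_ascending_rule():
    hits = [_hit("q1", "s1", evalue=1e-5), _hit("q1", "s2", evalue=1e-10)]
    assert concordance.best_hits(hits)["q1"].subject_id == "s2"


def test_best_hits_tie_breaks():
    hits = [
        _hit("q1", "s1", evalue=1e-10, bitscore=50),
        _hit("q1", "s2", evalue=1e-10, bitscore=60),
    ]
    assert concordance.best_hits(hits)["q1"].subject_id == "s2"
    hits = [
        _hit("q1", "sB", evalue=1e-10, bitscore=60),
        _hit("q1", "sA", evalue=1e-10, bitscore=60),
    ]
    assert concordance.best_hits(hits)["q1"].subject_id == "sA"


def test_best_hits_single_hit_is_itself():
    h = _hit("q1", "s1")
    assert concordance.best_hits([h])["q1"] is h


# ---------------------------------------------------------------------------
# length ratios
# ---------------------------------------------------------------------------


def test_length_ratio_values_and_histogram():
    best = {
        "q1": _hit("q1", "s1", qlen=100, slen=100),
        "q2": _hit("q2", "s2", qlen=100, slen=200),
        "q3": _hit("q3", "s3", qlen=100, slen=105),
    }
    summary = concordance.length_ratios(best)
    assert summary.ratios["q1"] == 1.0
    assert summary.ratios["q2"] == 0.5
    assert summary.counts.sum() == 3
    assert summary.n_below_half == 0  # 0.5 itself is not below 0.5
    assert summary.n_near_one == 2


def test_length_ratio_overflow_bin():
    best = {"q1": _hit("q1", "s1", qlen=100, slen=10, send=10)}
    summary = concordance.length_ratios(best)
    assert summary.counts[-1] == 1


# ---------------------------------------------------------------------------
# high-confidence procedure
# ---------------------------------------------------------------------------


def _toy_instance():
    clusters = [
        _cluster("c1", [("p1", "A"), ("p2", "B")]),
        _cluster("c2", [("p3", "A")]),
        _cluster("c3", [("p4", "B")]),
    ]
    calls = [
        ExpressionCall("p1", 0.0, False),
        ExpressionCall("p2", 0.0, False),
        ExpressionCall("p3", 12.0, True),
        ExpressionCall("p4", 2.0, False),
    ]
    return clusters, calls


def test_high_confidence_worked_toy_instance():
    """2 assemblies, 3 clusters, one coverage rescue at tau=10."""
    clusters, calls = _toy_instance()
    rep = concordance.high_confidence(clusters, calls, tau=10, mode="metaT")
    assert (rep.pct_core_clusters, rep.pct_core_proteins) == (33.33, 50.00)
    assert (rep.pct_hc_clusters, rep.pct_hc_proteins) == (66.67, 75.00)
    assert rep.n_hc_proteins == 3 and rep.n_hc_clusters == 2


def test_high_confidence_cluster_scope_includes_comembers():
    clusters, calls = _toy_instance()
    rep = concordance.high_confidence(
        clusters, calls, tau=10, mode="metaT", protein_scope="cluster"
    )
    # same clusters, but hc proteins now include every member of hc clusters
    assert rep.hc_protein_ids == {"p1", "p2", "p3"}


def test_high_confidence_full_provenance_without_evidence():
    clusters = [
        _cluster("c1", [("p1", "A"), ("p2", "B")]),
        _cluster("c2", [("p3", "A"), ("p4", "B")]),
    ]
    rep = concordance.high_confidence(clusters, mode="none")
    assert rep.pct_core_proteins == rep.pct_hc_proteins == 100.0
    assert rep.pct_core_clusters == rep.pct_hc_clusters == 100.0


def test_high_confidence_huge_tau_disables_rescue():
    clusters, calls = _toy_instance()
    rep = concordance.high_confidence(clusters, calls, tau=1e12, mode="metaT")
    assert rep.hc_protein_ids == rep.core_protein_ids
    assert rep.hc_cluster_ids == rep.core_cluster_ids


def test_high_confidence_unknown_protein_evidence_error():
    clusters, _ = _toy_instance()
    with pytest.raises(ValueError, match="unknown"):
        concordance.high_confidence(
            clusters, [ExpressionCall("ghost", 50.0, True)], mode="metaT"
        )
    with pytest.raises(ValueError, match="unknown"):
        concordance.high_confidence(
            clusters, peptide_evidence=[PeptideEvidence("ghost", 2)], mode="metaP"
        )


def _random_instance(rng):
    labels = ["A", "B", "C"]
    clusters = []
    calls = []
    peptides = []
    pid = 0
    for ci in range(rng.randint(2, 12)):
        members = [
            (f"p{pid + i}", rng.choice(labels))
            for i in range(rng.randint(1, 4))
        ]
        pid += len(members)
        clusters.append(_cluster(f"c{ci}", members))
        for m, _ in members:
            calls.append(ExpressionCall(m, rng.random() * 30, False))
            if rng.random() < 0.2:
                peptides.append(PeptideEvidence(m, rng.randint(1, 5)))
    return clusters, calls, peptides


def test_high_confidence_monotonicity_random_instances():
    """Lowering tau or adding evidence can only grow the hc sets."""
    rng = random.Random(13)
    for _ in range(100):
        clusters, calls, peptides = _random_instance(rng)
        prev_p, prev_c = None, None
        for tau in (25, 15, 10, 5, 1):
            rep = concordance.high_confidence(clusters, calls, tau=tau, mode="metaT")
            assert rep.core_protein_ids <= rep.hc_protein_ids
            assert rep.core_cluster_ids <= rep.hc_cluster_ids
            if prev_p is not None:
                assert prev_p <= rep.hc_protein_ids
                assert prev_c <= rep.hc_cluster_ids
            prev_p, prev_c = rep.hc_protein_ids, rep.hc_cluster_ids
        t_only = concordance.high_confidence(clusters, calls, tau=10, mode="metaT")
        both = concordance.high_confidence(
            clusters, calls, peptides, tau=10, mode="either"
        )
        assert t_only.hc_protein_ids <= both.hc_protein_ids
        assert t_only.hc_cluster_ids <= both.hc_cluster_ids
        # core does not depend on evidence
        assert t_only.core_protein_ids == both.core_protein_ids


def test_core_matches_combination_table(bundle):
    """Core protein count equals the full-provenance combination total."""
    from asmconcord import clustering as cl

    recs = [r for a in bundle.assemblies.values() for r in a.cds]
    clusters = cl.greedy_cluster(recs)
    labels = sorted(bundle.assemblies)
    table = cl.combination_counts(clusters, all_labels=labels)
    rep = concordance.high_confidence(clusters, mode="none", all_labels=labels)
    assert rep.n_core_proteins == table.n_core_proteins
    assert rep.n_core_clusters == table.n_core_clusters
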