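import pytest

from asmconcord import simulate as sim


def make_cds(id, seq, label="A", contig="c1", start=1, strand="+",
             partial5=False, partial3=False, end=None):
    """CdsRecord with consistent coordinates for a given protein length."""
    from asmconcord.core_io import CdsRecord

    if end is None:
        end = start + 3 * len(seq) + 2  # CDS includes the stop codon
    return CdsRecord(
        id=id, contig_id=contig, assembly_label=label, start=start, end=end,
        strand=strand, partial5=partial5, partial3=partial3, protein_seq=seq,
    )


@pytest.fixture(scope="session")
def bundle():
    """Default study conditions at a modest catalogue size."""
    return sim.simulate_bundle(n_genes=60, seed=11)


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    sim.write_bundle(bundle, outdir)
    return outdir
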