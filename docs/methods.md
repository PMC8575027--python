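# Methods

This note records the models and procedures `asmconcord` implements, the
defaults it ships, the numerical choices that were genuinely open, and what
the synthetic data generator does and does not emulate.

## Rationale

Multiple assemblies of one metagenome act as mutually independent witnesses
for each protein-coding gene. The package formalises two ideas: (i)
*concordance* — a gene reconstructed by every assembly is unlikely to be an
assembler artifact; and (ii) *orthogonal rescue* — a gene seen by only some
assemblies but with clear metatranscriptomic coverage (or peptide evidence)
is validated by a different data layer and should not be discarded. Both are
reference-independent: no external genome or database quality is assumed;
homology hit tables, where used (split-gene diagnosis, length ratios), are
consumed generically.

## Protein clustering

Proteins from all assemblies are pooled and clustered greedily in the CD-HIT
style: sort by (length descending, id ascending); each protein joins the
first established representative whose global alignment reaches identity
≥ `min_id` (default 0.9) with coverage ≥ `min_cov` (default 0.8) of *both*
sequences, else founds a new cluster. Determinism is part of the contract:
ties in length are broken by id, representatives are tried in creation
order, and the partition is invariant to input order.

Alignment is global with affine gaps (match +1, mismatch −1, gap open −5,
gap extend −1; a gap of length L costs open + (L−1)·extend), computed with a
Gotoh dynamic program whose traceback tie-breaks are fixed (substitution,
then gap-in-second, then gap-in-first sequence). Identity is matched columns
over all alignment columns, gap columns included; coverage of a sequence is
the fraction of its residues between the first and last substitution column,
so terminal overhangs count against coverage. An exact amino-acid 5-mer
prefilter skips pairs sharing no word; it can only skip alignments, never
change an accepted pair's values (asserted in tests against prefilter-free
runs). This clusterer is an explicit, reproducible approximation of the
linclust-style engines used in large-scale practice, not a re-implementation
of any of them.

Each cluster's *provenance* is the set of assembly labels among its members.
The combination table counts clusters and member proteins per distinct
provenance set; member CDS records are the primary protein count, with a
secondary count collapsing identical sequences within one assembly.

## High-confidence procedure

Core clusters have provenance equal to the full label set; core proteins are
their members. Rescue adds individually evidenced proteins — mean metaT
depth ≥ τ (default 10×, boundary inclusive), ≥ 1 peptide, or either — and
their clusters. Two protein scopes are implemented because the natural-
language rule is ambiguous about co-members of a rescued cluster: `strict`
(default; hc proteins = core ∪ evidenced proteins) and `cluster` (hc
proteins = all members of hc clusters). Percentages are reported over the
explicit totals of the analysed input set, to two decimals, half-up.
Peptide evidence is thresholded at presence (≥ 1) on the assumption that
false-discovery control happened in the upstream search.

## Coverage, expression, retention

Expression of a CDS is called from the arithmetic mean of the per-base depth
over its genomic interval, strand-agnostic (the depth dialect is
unstranded). No normalisation (TPM/RPKM) is applied: the threshold is in
raw fold-coverage, matching how such cutoffs are used on per-gene averages.
Contigs missing from a depth table receive an all-zero track with a warning,
since `genomecov -d` emits every position and absence indicates truncation.

Retention curves are read-weighted: retention(L) is the fraction of all
mapped reads on contigs of length ≥ L, at cutoffs {0, 1000, 2000, 5000} bp
by default; a contig-count column is emitted alongside. Multi-mapped reads
are consumed as counted upstream.

## Split-gene (frameshift) diagnosis

A 1–2 nt indel shifts the reading frame, usually introducing a premature
stop, so one real gene is predicted as two fragments. The detector scans
same-contig CDS pairs (same strand by default; a flag relaxes this for
assembly-breakpoint cases) whose best hits name the same subject and tile
it: subject-interval overlap ≤ 0.2 of the shorter segment, joint subject
coverage ≥ 0.8, genomic gap ≤ 100 bp (negative gaps — overlapping CDSs — are
typical, since the downstream fragment's start codon precedes the indel),
and order consistency (the genomically upstream fragment maps to the
N-terminal segment on '+', reversed on '−'; interval midpoints are
compared). Subject intervals use min/max of (sstart, send) so orientation
cannot flip them. The gap/overlap/coverage defaults are package choices —
exposed on the CLI — tuned to the geometry of in-place single-indel splits;
chains of ≥ 3 fragments are out of scope.

Coverage verification grades each candidate from the depth around the
junction window (the span between the two fragment boundaries ± 50 bp
flanks): `supported` when depth never falls below `min_continuity` (0.5) of
the smaller flank mean; `dip_only` when exactly one interior run of
≤ `max_dip_width` (10) bp falls below half that reference and recovers on
both sides — the signature of a single localized drop at the indel;
`unsupported` otherwise, including flanks without signal; `no_data` without
a track. Verdicts are computed on a 5-bp moving average of the depth while
the reported junction profile stays raw: per-base counts at, say, 20× drop
below half-reference at isolated positions about once per 200 bp by Poisson
sampling alone, which would fragment the below-threshold region and destroy
the single-run criterion on almost every genuinely split gene; a 5-bp mean
suppresses those one-base excursions without hiding multi-base dips.

## Assembly sketches

Each assembly is reduced to the `sketch_size` (default 100 000) smallest
64-bit hashes over its canonical k-mers (default k = 31; lexicographic
minimum of k-mer and reverse complement via 2-bit encoding; k-mers
containing N skipped; murmur-style finalizer seeded by `hash_seed`). The
Jaccard index j between two assemblies is estimated from the bottom
s′ = min(sketch_size, |hash union|) of the merged hash sets — the standard
Mash estimator — and converted to d = −(1/k)·ln(2j/(1+j)), capped at 1,
with d = 1 when j = 0. When the true k-mer union fits inside the sketch, j
is the exact Jaccard index; the tests verify this against exhaustive k-mer
sets. Dendrograms and significance models for the matrix are out of scope.

## Synthetic data generator

The generator emulates the statistical structure the pipeline is built to
detect, with exact bookkeeping: one truth catalogue of `n_genes` proteins
(lengths log-normal, median 250 aa, σ = 0.5, floor 80 aa so split fates stay
realisable; uniform residues after an initiator M; coding sequences via
uniformly random synonymous codons under translation table 11), half the
genes expressed by default with log-normal mean depth (median 20×, σ = 0.6).
Each assembly draws a per-gene fate from its error profile — intact
(optionally with per-residue substitution probability `p_sub`), dropped,
fragmented (contig break inside the gene: two partial CDSs on two contigs),
or frameshifted (a 1-nt deletion in the middle 60 % of the gene; fragment A
runs to the first shifted-frame stop, fragment B from the latest in-frame
start codon at or before the indel; realisations are retried up to 20 times
until both fragments reach 30 aa, else the fate downgrades to intact with a
log note). The shipped archetypes mirror the two assembler families:
SR-like (`p_frag` = 0.1) and LR-like (`p_indel` = 0.1, `p_sub` = 0.01).

Genes are laid five per contig with 200-bp random spacers, all on the plus
strand. Spacer sequences and unmutated gene copies are shared across
assemblies (spacers come from their own substream; intact copies reuse the
truth nucleotides), so error-free assemblies are identical up to contig
naming and k-mer sharing between assemblies reflects only the injected
errors. Homology hits against the truth proteins are emitted directly with
each fragment's true subject sub-interval, a bitscore of 2·(alignment
length) and a decimal-power e-value monotone in alignment length — this
stands in for the database search so that gene calling and alignment tools
stay outside the test loop. MetaT depth is Poisson per base (gene mean over
expressed gene bodies, 0.5× background elsewhere) with a 5-bp dip at
dip_depth_frac = 0.3 of the gene mean at injected indels; idxstats counts
derive from track sums at a nominal 100-bp read length; peptide evidence
covers a random half of the expressed genes. All randomness flows from one
seed through named substreams, and bundle regeneration is byte-identical.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: read-level error models and mapping ambiguity,
strand mixture, operonic/overlapping gene structure, codon usage bias,
chimeric contigs, uneven taxon abundance, and homology search noise
(spurious or missing hits). Detector recall measured against this truth is
an upper bound for real assemblies, where hit tables are noisy and indels
co-occur with other errors.

## Problem sizes and defaults in the checks

The test suite and `scripts/acceptance.py` run the study at 300 genes ×
3 assemblies (the end-to-end determinism check at 60 genes), sizes at which
every stage's behaviour — clustering partitions, recall/false-positive
rates, calibration of expression calls — is already stable across seeds
while the whole suite stays interactive.

## Known limitations

* The clusterer is quadratic in the number of non-redundant proteins per
  k-mer-sharing group; it is built for per-sample assembly comparison
  (10³–10⁴ proteins), not catalogue-scale clustering.
* Split-gene detection considers fragment pairs only; a gene shattered into
  three or more fragments yields at most pairwise candidates.
* Depth handling is strand-agnostic and unnormalised by design; stranded
  metaT protocols lose that information at the contract boundary.
* The GFF3 CDS reader derives proteins by direct translation of the
  in-frame interval; unusual partial-frame annotations should be supplied
  through the Prodigal-dialect FASTA instead.
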