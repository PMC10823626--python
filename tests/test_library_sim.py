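"""Library simulation: expression, cDNA, capture, size selection,
concatenation and the HiFi error model."""

import edlib
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from masiso.library_sim import (CDNAMolecule, DEFAULT_POLYA, PRIMER_3,
                                PRIMER_5, apply_hifi_errors, capture_filter,
                                capture_retention, concatenate,
                                make_array_designs, sample_expression,
                                size_select, synthesize_cdna)
from masiso.reference import make_sirv_like_module, transcript_sequence


@pytest.fixture(scope="module")
def ref():
    return make_sirv_like_module(3, 12, 200, 1000, seed=7)


def test_equimolar_spikein_sampling(sirv_reference):
    _genome, ann = sirv_reference
    records = sample_expression(ann, 69000, 1.0, seed=1)
    copies = {r.transcript_id: r.copies for r in records}
    assert sum(copies.values()) == 69000
    # multinomial, p = 1/69: 4 sigma around 1000
    sigma = np.sqrt(69000 * (1 / 69) * (1 - 1 / 69))
    assert all(abs(c - 1000) < 4 * sigma for c in copies.values())
    total_tpm = sum(r.tpm for r in records)
    assert abs(total_tpm - 1e6) < 1e6 * 1e-3


def test_spikein_fraction_two_percent(sirv_reference):
    from masiso.reference import combine, make_background_module
    _g, bg = make_background_module(10, 30, seed=3)
    genome, ann = combine(sirv_reference, (_g, bg))
    records = sample_expression(ann, 100000, 0.02, seed=3)
    spike = sum(r.copies for r in records
                if r.transcript_id in ann.spikein_ids)
    sigma = np.sqrt(100000 * 0.02 * 0.98)
    assert abs(spike - 2000) <= 3 * sigma


def test_zero_molecules_all_zero(ref):
    _genome, ann = ref
    assert all(r.copies == 0 for r in sample_expression(ann, 0, 1.0, seed=0))


def test_cdna_no_artifacts_at_rate_zero(ref):
    genome, ann = ref
    records = sample_expression(ann, 500, 1.0, seed=2)
    mols = synthesize_cdna(records, ann, genome, 0.0, seed=2)
    assert sum(r.copies for r in records) == len(mols)
    assert all(m.artifact == "none" for m in mols)


def test_cdna_artifact_rate_binomial(ref):
    genome, ann = ref
    records = sample_expression(ann, 1000, 1.0, seed=4)
    mols = synthesize_cdna(records, ann, genome, 0.1, seed=4)
    n_art = sum(1 for m in mols if m.artifact == "tso_artifact")
    sigma = np.sqrt(1000 * 0.1 * 0.9)
    assert abs(n_art - 100) <= 3 * sigma
    # artifacts lack the oligo(dT) structure
    assert all("A" * 20 + PRIMER_3 not in m.sequence
               for m in mols if m.artifact == "tso_artifact")


def test_cdna_insert_identity(ref):
    genome, ann = ref
    contigs = {g.contig_id: g for g in genome}
    records = sample_expression(ann, 200, 1.0, seed=5)
    mols = synthesize_cdna(records, ann, contigs, 0.0, seed=5)
    for m in mols[:50]:
        t = ann.transcripts[m.source_transcript_id]
        expected = (PRIMER_5 + transcript_sequence(t, contigs[t.contig_id])
                    + "A" * DEFAULT_POLYA + PRIMER_3)
        assert m.sequence == expected


def test_capture_keeps_everything_below_knee():
    mols = [CDNAMolecule("A" * n, "t") for n in (100, 500, 1999, 2000)]
    assert capture_filter(mols, seed=0) == mols


def test_capture_removes_artifacts_outright():
    mols = [CDNAMolecule("A" * 300, "t", artifact="tso_artifact")] * 10
    assert capture_filter(mols, seed=0) == []


def test_capture_no_12kb_survivors_and_binomial_retention():
    cohort = [CDNAMolecule("A" * 12000, "t")] * 10000
    assert capture_filter(cohort, seed=1) == []
    # at 8 kb the retention is high but < 1: binomial check
    r = capture_retention(8000)
    assert 0.5 < r < 1.0
    cohort = [CDNAMolecule("A" * 8000, "t")] * 10000
    kept = len(capture_filter(cohort, seed=1))
    sigma = np.sqrt(10000 * r * (1 - r))
    assert abs(kept - 10000 * r) <= 3 * sigma


def test_capture_retention_monotone_declining():
    lengths = [2000, 3000, 5000, 8000, 10000, 12000, 20000]
    rets = [capture_retention(n) for n in lengths]
    assert rets[0] == 1.0
    assert all(a >= b for a, b in zip(rets, rets[1:]))


def test_size_select_boundaries():
    mols = {n: CDNAMolecule("A" * n, "t") for n in (400, 500, 2000, 2001)}
    long_f, short_f, discarded = size_select(list(mols.values()))
    assert [m.length for m in discarded] == [400]
    assert sorted(m.length for m in short_f) == [500, 2000]
    assert [m.length for m in long_f] == [2001]


def test_size_select_empty():
    assert size_select([]) == ([], [], [])


@given(st.lists(st.integers(min_value=1, max_value=5000), max_size=200))
def test_size_select_partition_matches_bruteforce(lengths):
    mols = [CDNAMolecule("A" * n, "t") for n in lengths]
    long_f, short_f, disc = size_select(mols)
    assert len(long_f) + len(short_f) + len(disc) == len(mols)
    assert all(m.length > 2000 for m in long_f)
    assert all(500 <= m.length <= 2000 for m in short_f)
    assert all(m.length < 500 for m in disc)


def test_barcode_designs_distinct(designs):
    barcodes = [b for d in designs for b in d.junction_barcodes]
    assert len(barcodes) == 3 + 5
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1:]:
            assert edlib.align(a, b, task="distance")["editDistance"] >= 5


def test_concatenate_exact_packing(designs):
    dimer, tetramer = designs
    mols = [CDNAMolecule("ACGT" * 50, f"t{i}") for i in range(8)]
    reads = concatenate(mols, tetramer, 1.0, seed=0)
    assert len(reads) == 2
    for read in reads:
        assert read.n_segments_true == 4
        # reconstruction oracle: barcodes + truth spans rebuild the read
        rebuilt = ""
        for i, seg in enumerate(read.truth_segments):
            rebuilt += tetramer.junction_barcodes[i]
            assert read.sequence[seg.start:seg.end] == "ACGT" * 50
            rebuilt += read.sequence[seg.start:seg.end]
        rebuilt += tetramer.junction_barcodes[len(read.truth_segments)]
        assert rebuilt == read.sequence


def test_concatenate_full_array_rate(designs):
    dimer, _ = designs
    mols = [CDNAMolecule("ACGT" * 100, f"t{i}") for i in range(18000)]
    reads = concatenate(mols, dimer, 0.777, seed=9)
    full = sum(1 for r in reads if r.n_segments_true == 2)
    n = len(reads)
    sigma = np.sqrt(n * 0.777 * 0.223)
    assert abs(full - n * 0.777) <= 3 * sigma
    # molecule conservation: every molecule in exactly one array
    assert sum(r.n_segments_true for r in reads) == len(mols)


def test_concatenate_empty(designs):
    assert concatenate([], designs[0], 0.777, seed=0) == []


def test_hifi_errors_zero_rate_identity(designs):
    mols = [CDNAMolecule("ACGTACGTAC" * 30, f"t{i}") for i in range(10)]
    reads = concatenate(mols, designs[0], 1.0, seed=1)
    out = apply_hifi_errors(reads, 0.0, seed=2)
    assert [r.sequence for r in out] == [r.sequence for r in reads]
    assert [[(s.start, s.end) for s in r.truth_segments] for r in out] == \
        [[(s.start, s.end) for s in r.truth_segments] for r in reads]


def test_hifi_error_rate_totals(designs, rng):
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    mols = [CDNAMolecule(seq, "t")] * 250  # 500 kb or so of array sequence
    reads = concatenate(mols, designs[1], 1.0, seed=3)
    total_bases = sum(len(r.sequence) for r in reads)
    out = apply_hifi_errors(reads, 0.001, seed=4)
    total_edits = sum(s.n_edits for r in out for s in r.truth_segments)
    # edits land in barcodes too; compare against segment-only expectation
    seg_bases = sum(s.end - s.start for r in reads for s in r.truth_segments)
    expected = seg_bases * 0.001
    assert abs(total_edits - expected) <= 3 * np.sqrt(expected) + 1
    assert total_bases > seg_bases


def test_hifi_error_offsets_and_edit_counts(designs, rng):
    """Extracting post-error truth spans and aligning them to the original
    segments recovers exactly the injected edit counts."""
    seqs = ["".join(rng.choice(list("ACGT"), size=800)) for _ in range(40)]
    mols = [CDNAMolecule(s, f"t{i}") for i, s in enumerate(seqs)]
    reads = concatenate(mols, designs[1], 1.0, seed=5)
    originals = {}
    for read in reads:
        for i, seg in enumerate(read.truth_segments):
            originals[(read.read_id, i)] = read.sequence[seg.start:seg.end]
    out = apply_hifi_errors(reads, 0.01, seed=6)
    checked = 0
    for read in out:
        for i, seg in enumerate(read.truth_segments):
            observed = read.sequence[seg.start:seg.end]
            dist = edlib.align(observed, originals[(read.read_id, i)],
                               task="distance")["editDistance"]
            assert dist <= seg.n_edits
            checked += 1
    assert checked == 40  # 10 tetramer reads x 4 segments


def test_hifi_errors_rejects_bad_rate(designs):
    with pytest.raises(ValueError):
        apply_hifi_errors([], 0.5, seed=0)
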