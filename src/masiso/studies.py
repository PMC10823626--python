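"""Scaled-down simulation studies.

Each function runs one self-contained in-silico experiment — the package's
reusable equivalents of benchmark figures: s-read gain of a mixed
dimer/tetramer run, length-dependent capture loss, spike-in recall,
two-condition differential filtering, and the concatenation-artifact fusion
sentinel. Problem sizes default to desk scale (seconds to a few minutes on
one CPU); see docs/methods.md for the rationale behind each default.
"""

from __future__ import annotations

import numpy as np

from .classify import classify_isoforms
from .collapse import AlignedRead, cluster_chains, collapse_flnc, filter_by_support
from .deconcat import array_efficiency, split_reads
from .diff_fusion import IsoformExpressionRecord, de_filter
from .library_sim import (CDNAMolecule, apply_hifi_errors, capture_filter,
                          capture_retention, concatenate, make_array_designs,
                          sample_expression, synthesize_cdna)
from .metrics import merge_samples
from .pipeline import PipelineConfig, run_pipeline
from .reference import make_background_module, make_sirv_like_module
from .utils import substream


def concatemer_sread_study(seed: int, n_dimer: int = 4000,
                           n_tetramer: int = 16000,
                           dimer_eff: float = 0.777,
                           tetramer_eff: float = 0.727,
                           per_base_error: float = 0.001,
                           max_edit: int = 3) -> dict:
    """Mixed dimer/tetramer run vs a monomer run of equal HiFi read count.

    Builds cDNA pools from a spike-in style reference (long molecules for
    dimers, short for tetramers), concatenates at the configured full-array
    efficiencies, injects HiFi errors, splits, and measures recovered
    full-array fractions and the s-read gain (monomer: 1 s-read per read).
    The default mix is 20% dimer / 80% tetramer arrays.
    """
    rng = substream(seed, "sread_study")
    genome, annotation = make_sirv_like_module(7, 69, 160, 2940,
                                               int(rng.integers(2**31)))
    contigs = {g.contig_id: g for g in genome}
    records = sample_expression(annotation, 200, 1.0, int(rng.integers(2**31)))
    protos = synthesize_cdna(records, annotation, contigs, 0.0,
                             int(rng.integers(2**31)))
    long_protos = [m for m in protos if m.length > 2000]
    short_protos = [m for m in protos if 500 <= m.length <= 2000]
    if not long_protos or not short_protos:
        raise RuntimeError("reference produced no usable cDNA pool")

    # expected segments per array at these efficiencies
    exp_dimer = dimer_eff * 2 + (1 - dimer_eff) * 1
    exp_tetra = tetramer_eff * 4 + (1 - tetramer_eff) * 2
    n_long = int(np.ceil(n_dimer * exp_dimer))
    n_short = int(np.ceil(n_tetramer * exp_tetra))
    long_pool = [long_protos[i] for i in rng.integers(0, len(long_protos), n_long)]
    short_pool = [short_protos[i] for i in rng.integers(0, len(short_protos), n_short)]

    designs = make_array_designs([2, 4], int(rng.integers(2**31)))
    dimer, tetramer = designs
    reads = (concatenate(long_pool, dimer, dimer_eff,
                         int(rng.integers(2**31)), "dim")
             + concatenate(short_pool, tetramer, tetramer_eff,
                           int(rng.integers(2**31)), "tet"))
    reads = apply_hifi_errors(reads, per_base_error, int(rng.integers(2**31)))
    splits = split_reads(reads, designs, max_edit)
    stats = array_efficiency(splits)
    n_truth_segments = sum(r.n_segments_true for r in reads)
    return {
        "n_reads": stats.n_reads,
        "n_sreads": stats.n_sreads,
        "n_truth_segments": n_truth_segments,
        "per_arity": stats.per_arity,
        "dimer_full_fraction": stats.per_arity[2]["full_array_fraction"],
        "tetramer_full_fraction": stats.per_arity[4]["full_array_fraction"],
        "configured": {"dimer_eff": dimer_eff, "tetramer_eff": tetramer_eff},
        # a monomer run of the same HiFi read count yields one s-read each
        "sread_gain_vs_monomer": stats.n_sreads / stats.n_reads,
    }


def capture_length_study(seed: int, n_molecules: int = 10000,
                         lengths: tuple[int, ...] = (4000, 6000, 8000,
                                                     10000, 12000)) -> dict:
    """Survivors of the capture step for cohorts of fixed-length molecules.

    Mirrors a long spike-in dilution: each cohort holds `n_molecules`
    molecules of one length; returns surviving counts and the analytic
    retention for reference.
    """
    out = {"n_molecules": n_molecules, "survivors": {}, "retention": {}}
    for i, length in enumerate(lengths):
        cohort = [CDNAMolecule("A" * length, f"L{length}") ] * n_molecules
        kept = capture_filter(cohort, int(substream(seed, f"cap{i}").integers(2**31)))
        out["survivors"][length] = len(kept)
        out["retention"][length] = capture_retention(length)
    return out


def recall_study(seed: int, copies_per_isoform: int = 40,
                 per_base_error: float = 0.001) -> dict:
    """Spike-in recall of the full concatemer pipeline on a spike-only pool.

    Every isoform receives ~`copies_per_isoform` molecules; recall counts an
    isoform as detected when an FSM cluster with >= min_ccs reads matches it.
    """
    config = PipelineConfig(
        seed=int(substream(seed, "recall").integers(2**31)),
        with_long_module=False, with_background=False,
        n_molecules=69 * copies_per_isoform, spikein_fraction=1.0,
        tso_artifact_rate=0.02, per_base_error=per_base_error)
    result = run_pipeline(config)
    return {
        "n_isoforms": 69,
        "detected": result.report["sirv_detected"],
        "recall_pct": result.report["sirv_recall_pct"],
        "report": result.report,
    }


def _jittered_chains(model, copies: int, jitter5: int, jitter3: int, jrng,
                     name: str) -> tuple[list[AlignedRead], list[int]]:
    """Unique jittered exon chains for `copies` reads of one transcript,
    with multiplicities (terminal exons shrink by the sampled jitter)."""
    j5 = jrng.integers(0, jitter5 + 1, size=copies)
    j3 = jrng.integers(0, jitter3 + 1, size=copies)
    combos, counts = np.unique(np.stack([j5, j3], axis=1), axis=0,
                               return_counts=True)
    reads, weights = [], []
    for (a, b), count in zip(combos.tolist(), counts.tolist()):
        exons = [list(e) for e in model.exons]
        if model.strand == "+":
            exons[0][0] += min(a, exons[0][1] - exons[0][0] - 1)
            exons[-1][1] -= min(b, exons[-1][1] - exons[-1][0] - 1)
        else:
            exons[-1][1] -= min(a, exons[-1][1] - exons[-1][0] - 1)
            exons[0][0] += min(b, exons[0][1] - exons[0][0] - 1)
        reads.append(AlignedRead(f"{name}_{model.transcript_id}_{a}_{b}",
                                 model.contig_id, model.strand,
                                 tuple(tuple(e) for e in exons)))
        weights.append(int(count))
    return reads, weights


def _truth_groups(models) -> list[list]:
    """Group reference transcripts the workflow cannot tell apart: identical
    intron chains (multi-exon) or near-coincident spans (mono-exon)."""
    multi: dict[tuple, list] = {}
    mono = []
    for m in models:
        if len(m.exons) > 1:
            multi.setdefault((m.contig_id, m.strand, m.introns), []).append(m)
        else:
            mono.append(m)
    groups = list(multi.values())
    if mono:
        for idxs in cluster_chains(mono, d5=60, d3=60, gap=0):
            groups.append([mono[i] for i in idxs])
    return groups


def two_condition_study(seed: int, n_genes: int = 40, n_isoforms: int = 120,
                        molecules_per_condition: int = 20000,
                        n_spiked_genes: int = 4, spike_fold: float = 10.0,
                        background_sigma: float = 0.8,
                        jitter5: int = 20, jitter3: int = 8) -> dict:
    """Two-condition differential study with a known up-regulated gene set.

    One annotation, one abundance profile; the "tumor" condition multiplies
    the TPM of the `n_spiked_genes` lowest-abundance genes by `spike_fold`
    (renormalised). Reads follow the expression -> truth-alignment ->
    collapse -> classify path, the two samples merge into one matrix, and
    the differential filter runs at default thresholds. Sensitivity is
    measured over distinguishable spiked isoform groups; false positives are
    passing isoforms of non-spiked genes.
    """
    rng = substream(seed, "two_cond")
    _genome, annotation = make_background_module(
        n_genes, n_isoforms, seed=int(rng.integers(2**31)))
    # one shared weight profile: the same expression seed drives both
    # conditions, so baseline abundances agree and only the spike differs
    expr_seed = int(rng.integers(2**31))
    base = sample_expression(annotation, 0, 0.0, expr_seed,
                             background_sigma=background_sigma)
    tpm_base = {r.transcript_id: r.tpm for r in base}
    gene_tpm: dict[str, float] = {}
    for tid, tpm in tpm_base.items():
        gid = annotation.transcripts[tid].gene_id
        gene_tpm[gid] = gene_tpm.get(gid, 0.0) + tpm
    spiked = set(sorted(gene_tpm, key=lambda g: gene_tpm[g])[:n_spiked_genes])
    overexpress = {g: spike_fold for g in spiked}

    def sample_condition(name: str, over: dict | None):
        recs = sample_expression(annotation, molecules_per_condition, 0.0,
                                 expr_seed, background_sigma=background_sigma,
                                 overexpress=over)
        jrng = substream(seed, f"jitter_{name}")
        aligned: list[AlignedRead] = []
        weights: list[int] = []
        for r in recs:
            if r.copies <= 0:
                continue
            reads, w = _jittered_chains(annotation.transcripts[r.transcript_id],
                                        r.copies, jitter5, jitter3, jrng, name)
            aligned.extend(reads)
            weights.extend(w)
        clusters = filter_by_support(
            collapse_flnc(aligned, weights=weights), 2)
        classified = classify_isoforms(clusters, annotation)
        tpm = {r.transcript_id: r.tpm for r in recs}
        return classified, tpm

    comp_cls, comp_tpm = sample_condition("comp", None)
    tumor_cls, tumor_tpm = sample_condition("tumor", overexpress)
    matrix = merge_samples([comp_cls, tumor_cls], ["comp", "tumor"],
                           drop_unknown=False)
    records = []
    for row in matrix.rows:
        if row.category != "FSM" or row.matched_transcript_id is None:
            continue
        tid = row.matched_transcript_id
        records.append(IsoformExpressionRecord(
            isoform_id=tid,
            gene_id=annotation.transcripts[tid].gene_id,
            category="FSM",
            long_read_support_comp=row.supports[0],
            long_read_support_tumor=row.supports[1],
            tpm_comp=comp_tpm[tid],
            tpm_tumor=tumor_tpm[tid]))
    passing = de_filter(records)
    passing_ids = {r.isoform_id for r in passing}

    # distinguishable spiked isoforms: dedup reference models the workflow
    # cannot separate (shared intron chain / coincident mono-exon spans)
    spiked_models = [annotation.transcripts[tid] for tid in sorted(tpm_base)
                     if annotation.transcripts[tid].gene_id in spiked]
    truth_groups = _truth_groups(spiked_models)
    n_truth = len(truth_groups)
    n_recovered = sum(
        1 for group in truth_groups
        if any(m.transcript_id in passing_ids for m in group))
    false_positives = [r for r in passing if r.gene_id not in spiked]
    return {
        "n_spiked_genes": n_spiked_genes,
        "n_truth_isoforms": n_truth,
        "n_recovered": n_recovered,
        "sensitivity": n_recovered / n_truth if n_truth else 0.0,
        "n_false_positives": len(false_positives),
        "n_passing": len(passing),
        "spiked_genes": sorted(spiked),
    }


def fusion_artifact_study(seed: int, n_molecules: int = 4000) -> dict:
    """Full concatemer pipeline; counts passing fusions with spike-in
    partners (the incomplete-deconcatenation artifact sentinel)."""
    config = PipelineConfig(seed=int(substream(seed, "fusion").integers(2**31)),
                            n_molecules=n_molecules, spikein_fraction=0.1,
                            with_long_module=False,
                            background_genes=20, background_isoforms=60)
    result = run_pipeline(config)
    return {
        "n_reads": result.report["n_reads"],
        "n_fusion_candidates": result.report["n_fusion_candidates"],
        "n_passing_fusions": result.report["n_passing_fusions"],
        "n_passing_with_spikein_partner":
            result.report["n_passing_fusions_with_spikein_partner"],
    }


def threshold_monotonicity_curve(matrix, thresholds=(2, 4, 10)) -> list[int]:
    """Unique surviving isoforms per support threshold (non-increasing)."""
    from .metrics import overlap_stats
    return [overlap_stats(matrix, t).n_unique for t in thresholds]
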