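"""End-to-end orchestration: reference -> library -> split -> refine ->
collapse -> classify, with a machine-readable run report.

All randomness descends from a single seed through named substreams, so a
re-run with the same config reproduces byte-identical outputs and any stage
can be re-run independently. Alignment is simulated by construction: each
FLNC read inherits its source transcript's exon chain with a small inward
end jitter emulating alignment end uncertainty.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as mio
from .classify import classify_isoforms, length_bins, sirv_recall
from .collapse import AlignedRead, collapse_flnc, filter_by_support
from .deconcat import SplitResult, array_efficiency, split_reads
from .diff_fusion import FusionCandidate, fusion_filter
from .library_sim import (ArrayDesign, ConcatemerRead, apply_hifi_errors,
                          capture_filter, concatenate, make_array_designs,
                          sample_expression, size_select, synthesize_cdna)
from .reference import (Annotation, combine, make_background_module,
                        make_long_module, make_sirv_like_module)
from .refine import DEFAULT_PRIMERS, STATUS_FLNC, FLNCRead, refine_sreads
from .utils import substream


@dataclass
class PipelineConfig:
    """All stage parameters plus the single seed they descend from."""

    seed: int = 1
    # reference (replicate runs share ref_seed and vary only `seed`)
    ref_seed: int = -1  # -1: derive from `seed`
    sirv_genes: int = 7
    sirv_isoforms: int = 69
    sirv_length_min: int = 160
    sirv_length_max: int = 2940
    long_sizes: tuple[int, ...] = (4000, 6000, 8000, 10000, 12000)
    long_copies: int = 3
    with_long_module: bool = True
    background_genes: int = 50
    background_isoforms: int = 150
    with_background: bool = True
    # library
    n_molecules: int = 5000
    spikein_fraction: float = 0.02
    tso_artifact_rate: float = 0.02
    capture_knee_bp: int = 2000
    capture_floor: float = 0.0
    dimer_eff: float = 0.777
    tetramer_eff: float = 0.727
    per_base_error: float = 0.001
    mode: str = "concatemer"  # or "monomer" (Iso-Seq comparator arm)
    # split/refine
    max_edit: int = 3
    # collapse/classify
    d5: int = 100
    d3: int = 30
    gap: int = 10
    min_ccs: int = 2
    end_tolerance: int = 50
    align_jitter5: int = 20
    align_jitter3: int = 8

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected key = value")
            key, value = (x.strip() for x in line.split("=", 1))
            if key not in known:
                raise ValueError(f"line {lineno}: unknown config key {key!r}")
            ftype = known[key].type
            if ftype in ("int", int):
                kwargs[key] = int(value)
            elif ftype in ("float", float):
                kwargs[key] = float(value)
            elif ftype in ("bool", bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif "tuple" in str(ftype):
                kwargs[key] = tuple(int(x) for x in value.split(",") if x)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class PipelineResult:
    config: PipelineConfig
    annotation: Annotation
    reads: list[ConcatemerRead]
    splits: list[SplitResult]
    flnc: list[FLNCRead]
    clusters: list
    classified: list
    fusion_candidates: list[FusionCandidate]
    report: dict = field(default_factory=dict)


def _stage_seed(seed: int, name: str) -> int:
    return int(substream(seed, name).integers(0, 2**31 - 1))


def build_reference(config: PipelineConfig):
    ref_seed = config.ref_seed if config.ref_seed >= 0 else config.seed
    modules = [make_sirv_like_module(config.sirv_genes, config.sirv_isoforms,
                                     config.sirv_length_min,
                                     config.sirv_length_max,
                                     _stage_seed(ref_seed, "ref_sirv"))]
    if config.with_long_module:
        modules.append(make_long_module(list(config.long_sizes),
                                        config.long_copies,
                                        _stage_seed(ref_seed, "ref_long")))
    if config.with_background:
        modules.append(make_background_module(
            config.background_genes, config.background_isoforms,
            seed=_stage_seed(ref_seed, "ref_bg")))
    return combine(*modules)


def map_sreads_to_truth(splits: list[SplitResult],
                        reads_by_id: dict[str, ConcatemerRead],
                        min_overlap_frac: float = 0.5,
                        ) -> dict[str, list[tuple[str | None, str, float]]]:
    """Assign each s-read the truth segments it overlaps.

    Returns sread_id -> list of (transcript_id, artifact, overlap fraction
    of the s-read), sorted by decreasing overlap. Oriented coordinates are
    handled for reverse-complemented splits.
    """
    origin: dict[str, list[tuple[str | None, str, float]]] = {}
    for sp in splits:
        read = reads_by_id[sp.parent_read_id]
        n = len(read.sequence)
        truth = read.truth_segments
        for seg in sp.segments:
            s, e = seg.start, seg.end
            if sp.orientation == "-":
                s, e = n - seg.end, n - seg.start
            hits = []
            for t in truth:
                ov = min(e, t.end) - max(s, t.start)
                if ov > 0:
                    frac = ov / (e - s)
                    if frac >= min_overlap_frac / 10:  # keep minor partners too
                        hits.append((t.transcript_id, t.artifact, frac))
            hits.sort(key=lambda h: -h[2])
            origin[seg.sread_id] = hits
    return origin


def align_flnc_truth(flnc: list[FLNCRead], origin, annotation: Annotation,
                     jitter5: int, jitter3: int, seed: int,
                     ) -> list[AlignedRead]:
    """Place FLNC reads on the genome using their hidden source transcript,
    shrinking terminal exons by a small random jitter (alignment end
    uncertainty). Reads without a clean single-transcript origin are skipped.
    """
    rng = substream(seed, "truth_align")
    aligned = []
    for fr in flnc:
        if fr.status != STATUS_FLNC:
            continue
        hits = origin.get(fr.source_sread_id, [])
        primary = [h for h in hits if h[0] is not None and h[1] == "none"]
        if not primary or primary[0][2] < 0.5:
            continue
        t = annotation.transcripts[primary[0][0]]
        exons = [list(e) for e in t.exons]
        j5 = int(rng.integers(0, jitter5 + 1)) if jitter5 else 0
        j3 = int(rng.integers(0, jitter3 + 1)) if jitter3 else 0
        if t.strand == "+":
            exons[0][0] += min(j5, exons[0][1] - exons[0][0] - 1)
            exons[-1][1] -= min(j3, exons[-1][1] - exons[-1][0] - 1)
        else:
            exons[-1][1] -= min(j5, exons[-1][1] - exons[-1][0] - 1)
            exons[0][0] += min(j3, exons[0][1] - exons[0][0] - 1)
        aligned.append(AlignedRead(fr.flnc_id, t.contig_id, t.strand,
                                   tuple(tuple(e) for e in exons)))
    return aligned


def extract_fusion_candidates(flnc: list[FLNCRead], origin,
                              annotation: Annotation,
                              min_partner_frac: float = 0.05,
                              ) -> list[FusionCandidate]:
    """Build fusion candidates from FLNC reads whose insert overlaps truth
    segments of two or more genes; support counts FLNC reads per gene pair.
    """
    by_pair: dict[tuple[str, ...], list[dict[str, float]]] = {}
    for fr in flnc:
        if fr.status != STATUS_FLNC:
            continue
        hits = [h for h in origin.get(fr.source_sread_id, [])
                if h[0] is not None]
        genes: dict[str, float] = {}
        for tid, _art, frac in hits:
            gid = annotation.transcripts[tid].gene_id
            genes[gid] = genes.get(gid, 0.0) + frac
        partners = {g: f for g, f in genes.items() if f >= min_partner_frac}
        if len(partners) >= 2:
            key = tuple(sorted(partners))
            by_pair.setdefault(key, []).append(partners)
    candidates = []
    for i, (pair, events) in enumerate(sorted(by_pair.items()), 1):
        mean_frac = {g: sum(ev[g] for ev in events) / len(events) for g in pair}
        total = sum(mean_frac.values())
        candidates.append(FusionCandidate(
            candidate_id=f"fusion_{i:04d}",
            loci=tuple((g, min(1.0, mean_frac[g])) for g in pair),
            combined_coverage=min(1.0, total),
            flnc_support=len(events)))
    return candidates


def run_pipeline(config: PipelineConfig, out_dir: str | None = None,
                 ) -> PipelineResult:
    """Execute the full simulated workflow and assemble the run report."""
    seed = config.seed
    genome, annotation = build_reference(config)
    contigs = {g.contig_id: g for g in genome}

    records = sample_expression(annotation, config.n_molecules,
                                config.spikein_fraction,
                                _stage_seed(seed, "expression"))
    molecules = synthesize_cdna(records, annotation, contigs,
                                config.tso_artifact_rate,
                                _stage_seed(seed, "cdna"))
    captured = capture_filter(molecules, _stage_seed(seed, "capture"),
                              knee_bp=config.capture_knee_bp,
                              floor_retention=config.capture_floor)
    n_artifacts = sum(1 for m in molecules if m.artifact != "none")

    if config.mode == "monomer":
        designs = make_array_designs([1], _stage_seed(seed, "designs"))
        reads = concatenate(captured, designs[0], 1.0,
                            _stage_seed(seed, "concat_mono"), "mono")
        long_f, short_f, too_short = captured, [], []
    else:
        long_f, short_f, too_short = size_select(captured)
        designs = make_array_designs([2, 4], _stage_seed(seed, "designs"))
        dimer, tetramer = designs
        reads = (concatenate(long_f, dimer, config.dimer_eff,
                             _stage_seed(seed, "concat_dimer"), "dim")
                 + concatenate(short_f, tetramer, config.tetramer_eff,
                               _stage_seed(seed, "concat_tetra"), "tet"))
    reads = apply_hifi_errors(reads, config.per_base_error,
                              _stage_seed(seed, "errors"))

    splits = split_reads(reads, designs, config.max_edit)
    stats = array_efficiency(splits)
    reads_by_id = {r.read_id: r for r in reads}
    origin = map_sreads_to_truth(splits, reads_by_id)

    barcodes = [b for d in designs for b in d.junction_barcodes]
    sreads = [seg for sp in splits for seg in sp.segments]
    flnc = refine_sreads(sreads, primer_pairs=DEFAULT_PRIMERS,
                         barcodes=barcodes, max_edit=config.max_edit)
    aligned = align_flnc_truth(flnc, origin, annotation,
                               config.align_jitter5, config.align_jitter3,
                               _stage_seed(seed, "align"))

    clusters = collapse_flnc(aligned, config.d5, config.d3, config.gap)
    hq = filter_by_support(clusters, config.min_ccs)
    classified = classify_isoforms(hq, annotation, config.end_tolerance)
    fusion_candidates = extract_fusion_candidates(flnc, origin, annotation)
    passing_fusions, spike_flags = fusion_filter(
        fusion_candidates, spikein_ids={
            annotation.genes[g].gene_id for g in annotation.genes
            if any(t.spike_class != "background"
                   for t in annotation.transcripts_of_gene(g))})

    sirv_ids = {t.transcript_id for t in annotation
                if t.spike_class == "sirv_isoform"}
    recall = sirv_recall(classified, sirv_ids) if sirv_ids else (0, 0.0)

    status_counts = pd.Series([f.status for f in flnc]).value_counts().to_dict()
    category_counts = pd.Series([c.category for c in classified]) \
        .value_counts().to_dict() if classified else {}
    report = {
        "config_hash": config.config_hash(),
        "mode": config.mode,
        "n_transcripts_reference": len(annotation),
        "n_molecules_sampled": int(sum(r.copies for r in records)),
        "n_tso_artifacts": int(n_artifacts),
        "n_molecules_captured": len(captured),
        "dropped": {
            "capture_or_artifact": len(molecules) - len(captured),
            "size_selection": len(too_short),
        },
        "n_reads": len(reads),
        "n_sreads": stats.n_sreads,
        "full_array_fraction": stats.full_array_fraction,
        "per_arity": {str(k): v for k, v in stats.per_arity.items()},
        "flnc_status_counts": {k: int(v) for k, v in status_counts.items()},
        "n_flnc": int(status_counts.get(STATUS_FLNC, 0)),
        "n_aligned": len(aligned),
        "n_clusters": len(clusters),
        "n_hq_isoforms": len(hq),
        "category_counts": {k: int(v) for k, v in category_counts.items()},
        "sirv_detected": recall[0],
        "sirv_recall_pct": recall[1],
        "support_histogram": length_bins(classified) if classified else {},
        "n_fusion_candidates": len(fusion_candidates),
        "n_passing_fusions": len(passing_fusions),
        "n_passing_fusions_with_spikein_partner": int(sum(spike_flags)),
    }

    result = PipelineResult(config, annotation, reads, splits, flnc,
                            clusters, classified, fusion_candidates, report)
    if out_dir is not None:
        _write_outputs(result, genome, records, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, genome, records, out: Path) -> None:
    mio.ensure_dir(out)
    mio.write_fasta(out / "reference.fasta", genome)
    mio.write_gtf(out / "annotation.gtf", result.annotation)
    mio.write_fastq(out / "reads.fastq",
                    [(r.read_id, r.sequence) for r in result.reads])
    truth_rows = [
        {"read_id": r.read_id, "segment_index": i,
         "transcript_id": s.transcript_id or "", "artifact": s.artifact,
         "start": s.start, "end": s.end}
        for r in result.reads for i, s in enumerate(r.truth_segments)]
    mio.write_tsv(out / "truth_segments.tsv", pd.DataFrame(truth_rows))
    mio.write_fasta(out / "sreads.fasta",
                    [(seg.sread_id, seg.sequence)
                     for sp in result.splits for seg in sp.segments
                     if seg.sequence])
    flnc_rows = [{"flnc_id": f.flnc_id, "status": f.status,
                  "polya_len": f.polya_len, "length": len(f.sequence)}
                 for f in result.flnc]
    mio.write_tsv(out / "flnc_status.tsv", pd.DataFrame(flnc_rows))
    if result.classified:
        cls_rows = [{"cluster_id": c.cluster_id, "category": c.category,
                     "matched_transcript": c.matched_transcript_id or "",
                     "genes": ";".join(c.gene_ids),
                     "length": c.spliced_length, "support": c.support}
                    for c in result.classified]
        mio.write_tsv(out / "classification.tsv", pd.DataFrame(cls_rows))
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True, default=str)
    with open(out / "config.txt", "w") as fh:
        fh.write(result.config.to_text())
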