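"""Splitting concatemer reads into segmented reads (s-reads).

Junction barcodes are located by bounded-edit-distance matching (edlib),
overlap conflicts are resolved by lowest edit distance then leftmost
position, the whole read's orientation is decided once by total barcode
match score, and the inter-barcode intervals are emitted with barcodes
trimmed. Array-completeness statistics mirror what a deconcatenation tool
reports: per-arity s-read counts and full-array fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .library_sim import ArrayDesign, ConcatemerRead
from .utils import revcomp, round_half_up

SHORT_SEGMENT = 50  # segments shorter than this are flagged, not dropped


@dataclass
class SegmentedRead:
    """One segment recovered from a concatemer read."""

    sread_id: str
    sequence: str
    flanking_barcodes: tuple[int | None, int | None]
    parent_read_id: str
    start: int  # within the (oriented) parent read
    end: int
    short: bool = False


@dataclass
class BarcodeHit:
    barcode_index: int
    start: int
    end: int
    edit_distance: int


@dataclass
class SplitResult:
    parent_read_id: str
    segments: list[SegmentedRead]
    design: ArrayDesign | None
    orientation: str  # '+' as given, '-' reverse-complemented
    barcode_hits: list[BarcodeHit]
    is_full_array: bool


@dataclass
class ArrayStats:
    n_reads: int
    n_sreads: int
    n_full_arrays: int
    full_array_fraction: float
    per_arity: dict[int, dict[str, float]] = field(default_factory=dict)


def find_occurrences(pattern: str, text: str, max_edit: int,
                     ) -> list[tuple[int, int, int]]:
    """All non-overlapping approximate occurrences of `pattern` in `text`
    (edit distance <= max_edit), best-first with leftmost tie-break.

    Found occurrences are masked and the search repeats, so lower-distance
    hits always win overlapping conflicts.
    """
    hits: list[tuple[int, int, int]] = []
    work = text
    while True:
        res = edlib.align(pattern, work, mode="HW", task="locations", k=max_edit)
        if res["editDistance"] < 0:
            break
        start, end_inc = res["locations"][0]
        start = start or 0
        end = end_inc + 1
        hits.append((start, end, res["editDistance"]))
        work = work[:start] + "#" * (end - start) + work[end:]
    return sorted(hits)


def _scan_design(sequence: str, design: ArrayDesign, max_edit: int,
                 ) -> tuple[list[BarcodeHit], int]:
    """Locate design barcodes and keep the best ladder-consistent subset.

    Overlapping hits are resolved by lowest edit distance then leftmost
    position; the surviving hits are then filtered to the best subsequence
    whose barcode indices strictly increase in design order (each junction
    used once), maximising hit count and then total match quality. This is
    what suppresses chance 16-mer matches inside segments.
    """
    raw: list[tuple[int, int, int, int]] = []  # (dist, start, end, barcode_idx)
    for bi, barcode in enumerate(design.junction_barcodes):
        for start, end, dist in find_occurrences(barcode, sequence, max_edit):
            raw.append((dist, start, end, bi))
    raw.sort()
    accepted: list[BarcodeHit] = []
    occupied: list[tuple[int, int]] = []
    for dist, start, end, bi in raw:
        if any(start < e and s < end for s, e in occupied):
            continue
        occupied.append((start, end))
        accepted.append(BarcodeHit(bi, start, end, dist))
    accepted.sort(key=lambda h: h.start)
    # best strictly-increasing ladder subsequence (count, then quality)
    n = len(accepted)
    best_val: list[tuple[int, int]] = [(0, 0)] * n  # (count, -total_dist)
    prev = [-1] * n
    for i in range(n):
        best_val[i] = (1, -accepted[i].edit_distance)
        for j in range(i):
            if accepted[j].barcode_index < accepted[i].barcode_index:
                cand = (best_val[j][0] + 1,
                        best_val[j][1] - accepted[i].edit_distance)
                if cand > best_val[i]:
                    best_val[i] = cand
                    prev[i] = j
    if n:
        end_i = max(range(n), key=lambda i: (best_val[i], -i))
        chosen = []
        while end_i != -1:
            chosen.append(accepted[end_i])
            end_i = prev[end_i]
        chosen.reverse()
    else:
        chosen = []
    score = sum(max_edit + 1 - h.edit_distance for h in chosen)
    return chosen, score


def split_read(sequence: str, designs: list[ArrayDesign], max_edit: int = 3,
               read_id: str = "read") -> SplitResult:
    """Split one read at junction barcodes.

    The best-matching design and whole-read orientation (forward vs
    reverse-complement) are chosen once by total barcode score; segments are
    the non-empty intervals between accepted barcode hits. A read with no
    barcode match yields a single s-read equal to the input.
    """
    if max_edit < 0:
        raise ValueError("max_edit must be >= 0")
    if not designs:
        raise ValueError("designs must be non-empty")
    best = None  # (score, orient_rank, design_rank, hits, oriented_seq, design, orient)
    for orient_rank, (orient, seq) in enumerate(
            (("+", sequence), ("-", revcomp(sequence)))):
        for design_rank, design in enumerate(designs):
            hits, score = _scan_design(seq, design, max_edit)
            key = (-score, orient_rank, design_rank)
            if best is None or key < best[0]:
                best = (key, hits, seq, design, orient)
    _, hits, seq, design, orient = best
    segments: list[SegmentedRead] = []
    bounds: list[tuple[int, int, int | None, int | None]] = []
    if not hits:
        bounds.append((0, len(seq), None, None))
    else:
        # terminal slop <= max_edit around an end barcode is matching jitter
        if hits[0].start > max_edit:
            bounds.append((0, hits[0].start, None, hits[0].barcode_index))
        for left, right in zip(hits, hits[1:]):
            if right.start > left.end:
                bounds.append((left.end, right.start,
                               left.barcode_index, right.barcode_index))
        if len(seq) - hits[-1].end > max_edit:
            bounds.append((hits[-1].end, len(seq), hits[-1].barcode_index, None))
        if not bounds:  # barcodes only; treat the whole read as one segment
            bounds.append((0, len(seq), None, None))
    for ordinal, (s, e, lb, rb) in enumerate(bounds, 1):
        segments.append(SegmentedRead(
            sread_id=f"{read_id}/s{ordinal}",
            sequence=seq[s:e],
            flanking_barcodes=(lb, rb),
            parent_read_id=read_id,
            start=s, end=e,
            short=(e - s) < SHORT_SEGMENT,
        ))
    ladder = [h.barcode_index for h in hits]
    is_full = (len(segments) == design.arity
               and ladder == list(range(design.arity + 1)))
    return SplitResult(read_id, segments, design if hits else None,
                       orient, hits, is_full)


def split_reads(reads: list[ConcatemerRead], designs: list[ArrayDesign],
                max_edit: int = 3) -> list[SplitResult]:
    return [split_read(r.sequence, designs, max_edit, read_id=r.read_id)
            for r in reads]


def array_efficiency(splits: list[SplitResult],
                     designs: list[ArrayDesign] | None = None) -> ArrayStats:
    """Aggregate split results into array statistics.

    A read counts as a full array iff its observed segment count equals its
    design's arity with the complete barcode ladder in order; fractions are
    reported per design arity and overall. s-read totals are conserved:
    the per-arity counts sum to n_sreads exactly.
    """
    n_reads = len(splits)
    n_sreads = 0
    n_full = 0
    per: dict[int, dict[str, float]] = {}
    for sp in splits:
        arity = sp.design.arity if sp.design is not None else 1
        bucket = per.setdefault(arity, {"n_reads": 0, "n_sreads": 0, "n_full": 0})
        bucket["n_reads"] += 1
        bucket["n_sreads"] += len(sp.segments)
        n_sreads += len(sp.segments)
        if sp.is_full_array:
            n_full += 1
            bucket["n_full"] += 1
    for bucket in per.values():
        bucket["full_array_fraction"] = (
            bucket["n_full"] / bucket["n_reads"] if bucket["n_reads"] else 0.0)
    return ArrayStats(
        n_reads=n_reads,
        n_sreads=n_sreads,
        n_full_arrays=n_full,
        full_array_fraction=(n_full / n_reads if n_reads else 0.0),
        per_arity=per,
    )


def sread_gain(concat_stats: ArrayStats, monomer_read_count: int) -> float:
    """Fold increase in s-reads over a monomer run, to one decimal."""
    if monomer_read_count <= 0:
        raise ValueError("monomer_read_count must be > 0")
    return round_half_up(concat_stats.n_sreads / monomer_read_count, 1)
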