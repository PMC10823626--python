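"""Cross-sample isoform comparison and summary arithmetic.

Builds a non-redundant isoform x sample support matrix (the same merge rule
as read collapse, applied across samples), replicate-concordance statistics
at CCS support thresholds, and the percent/fold arithmetic used to report
recall means, s-read gains, and low-expression panel detection. All printed
percentages and folds use half-up rounding to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import ClassifiedIsoform
from .collapse import D3_DEFAULT, D5_DEFAULT, GAP_DEFAULT, cluster_chains
from .utils import round_half_up


@dataclass
class MatrixRow:
    """One non-redundant isoform with per-sample CCS support."""

    contig_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    category: str
    matched_transcript_id: str | None
    supports: tuple[int, ...]            # one cell per sample, 0 = absent
    members: tuple[tuple[str, ...], ...]  # member cluster_ids per sample


@dataclass
class ComparisonMatrix:
    sample_ids: tuple[str, ...]
    rows: list[MatrixRow]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, r in enumerate(self.rows):
            rec = {"row": i, "contig": r.contig_id, "strand": r.strand,
                   "category": r.category, "matched": r.matched_transcript_id}
            rec.update({s: v for s, v in zip(self.sample_ids, r.supports)})
            recs.append(rec)
        return pd.DataFrame(recs)


@dataclass
class OverlapStats:
    min_support: int
    n_unique: int
    n_in_all: int
    n_in_at_least_2: int
    pct_in_all: float
    pct_in_at_least_2: float


@dataclass
class PanelDetection:
    n_panel: int
    n_in_all: int
    n_in_at_least_one: int
    pct_in_all: float
    pct_in_at_least_one: float


def merge_samples(samples: list[list[ClassifiedIsoform]],
                  sample_ids: list[str] | None = None,
                  drop_unknown: bool = True,
                  d5: int = D5_DEFAULT, d3: int = D3_DEFAULT,
                  gap: int = GAP_DEFAULT) -> ComparisonMatrix:
    """Merge per-sample classified isoforms into a non-redundant matrix.

    Isoforms are merged across samples with the same end/junction wobble
    rule used for read collapse; per-sample support sums over merged
    members. Rows classified intergenic (the "unknown" analog) are dropped
    when `drop_unknown`.
    """
    if not samples:
        raise ValueError("need at least one sample")
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(len(samples))]
    if len(sample_ids) != len(samples):
        raise ValueError("sample_ids/samples length mismatch")
    entries: list[tuple[int, ClassifiedIsoform]] = [
        (si, iso) for si, sample in enumerate(samples) for iso in sample]
    items = [iso for _, iso in entries]
    rows: list[MatrixRow] = []
    for idxs in cluster_chains(items, d5, d3, gap):
        group = [entries[i] for i in idxs]
        rep = min((iso for _, iso in group),
                  key=lambda c: (-(c.exons[-1][1] - c.exons[0][0]), c.cluster_id))
        supports = [0] * len(samples)
        members: list[list[str]] = [[] for _ in samples]
        for si, iso in group:
            supports[si] += iso.support
            members[si].append(iso.cluster_id)
        rows.append(MatrixRow(
            contig_id=rep.contig_id, strand=rep.strand, exons=rep.exons,
            category=rep.category,
            matched_transcript_id=rep.matched_transcript_id,
            supports=tuple(supports),
            members=tuple(tuple(sorted(m)) for m in members)))
    if drop_unknown:
        rows = [r for r in rows if r.category != "intergenic"]
    return ComparisonMatrix(tuple(sample_ids), rows)


def overlap_stats(matrix: ComparisonMatrix, min_support: int) -> OverlapStats:
    """Replicate concordance at a support threshold.

    A row "passes" in a sample iff its cell >= min_support; n_unique counts
    rows passing anywhere, and the percents (one decimal) are relative to
    n_unique.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    n_samples = len(matrix.sample_ids)
    n_unique = n_in_all = n_in_2 = 0
    for row in matrix.rows:
        passing = sum(1 for s in row.supports if s >= min_support)
        if passing >= 1:
            n_unique += 1
        if passing >= 2:
            n_in_2 += 1
        if passing == n_samples:
            n_in_all += 1
    pct = lambda n: round_half_up(n / n_unique * 100.0, 1) if n_unique else 0.0
    return OverlapStats(min_support, n_unique, n_in_all, n_in_2,
                        pct(n_in_all), pct(n_in_2))


def fold_change(numerator: float, denominator: float, pseudocount: float = 1,
                decimals: int = 1) -> float:
    """Ratio with zero operands replaced by a pseudocount, half-up rounded.

    Whole-number ratios of 1000-fold or more are reported without decimals
    (e.g. an 11,676-fold change), matching how large folds are printed.
    """
    if numerator < 0 or denominator < 0:
        raise ValueError("counts must be non-negative")
    num = numerator if numerator > 0 else pseudocount
    den = denominator if denominator > 0 else pseudocount
    ratio = num / den
    if ratio >= 1000 and float(numerator).is_integer() and \
            float(denominator).is_integer():
        return round_half_up(ratio, 0)
    return round_half_up(ratio, decimals)


def mean_recall(detected_counts: list[int], total: int) -> float:
    """Mean detection percent over replicates, one decimal."""
    if not detected_counts:
        raise ValueError("detected_counts must be non-empty")
    if total < 1:
        raise ValueError("total must be >= 1")
    if any(c > total or c < 0 for c in detected_counts):
        raise ValueError("counts must lie in [0, total]")
    mean = sum(detected_counts) / len(detected_counts)
    return round_half_up(mean / total * 100.0, 1)


def low_expression_panel(tpm_tables: list[pd.DataFrame],
                         tpm_equal: float = 0.5,
                         tolerance: float = 1e-9) -> set[str]:
    """Transcripts whose TPM equals `tpm_equal` in every replicate table.

    Tables carry columns transcript_id and tpm; intersection semantics over
    replicates, equality within `tolerance`.
    """
    if not tpm_tables:
        raise ValueError("need at least one TPM table")
    panel: set[str] | None = None
    for table in tpm_tables:
        hits = set(table.loc[(table["tpm"] - tpm_equal).abs() <= tolerance,
                             "transcript_id"])
        panel = hits if panel is None else panel & hits
    return panel


def panel_detection(panel: set[str], matrix: ComparisonMatrix,
                    min_support: int = 1) -> PanelDetection:
    """How many panel transcripts an FSM row detects per replicate.

    A panel transcript is detected in a replicate iff an FSM row matched to
    it has support >= min_support there; percents are over the panel size.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    n_samples = len(matrix.sample_ids)
    by_tid: dict[str, list[MatrixRow]] = {}
    for row in matrix.rows:
        if row.category == "FSM" and row.matched_transcript_id in panel:
            by_tid.setdefault(row.matched_transcript_id, []).append(row)
    n_all = n_any = 0
    for tid in panel:
        rows = by_tid.get(tid, [])
        per_sample = [any(r.supports[i] >= min_support for r in rows)
                      for i in range(n_samples)]
        if any(per_sample):
            n_any += 1
        if all(per_sample):
            n_all += 1
    pct = lambda n: round_half_up(n / len(panel) * 100.0, 1)
    return PanelDetection(len(panel), n_all, n_any, pct(n_all), pct(n_any))
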