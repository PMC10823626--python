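"""Structural classification of HQ isoforms against a reference annotation.

Nine categories, assigned with a fixed, documented precedence:

1. FSM  - intron chain identical to a reference transcript (multi-exon), or
          a mono-exon chain contained in a mono-exon reference's span within
          an end tolerance;
2. ISM  - intron chain equals a contiguous sub-chain of a reference's;
3. fusion - exonic overlap with two or more distinct same-strand gene loci;
4. NIC  - every donor and acceptor individually annotated but the
          combination is novel (covers exon skipping and intron retention
          bounded by annotated junctions);
   NNC  - at least one unannotated splice site;
5. genic_genomic   - mono-exon chain overlapping same-strand exonic sequence
                     (partial exon/intron overlap);
   genic_intronic  - inside a gene span with no exon overlap (entirely
                     within an annotated intron);
   antisense       - exonic overlap only with the opposite strand;
   intergenic      - no overlap with any annotated gene on either strand.

Splice-match classes are tested before overlap classes and fusion before
NIC/NNC; an empty annotation classifies everything intergenic.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .collapse import IsoformCluster
from .reference import Annotation
from .utils import round_half_up

CATEGORIES = ("FSM", "ISM", "NIC", "NNC", "genic_genomic", "antisense",
              "fusion", "intergenic", "genic_intronic")

END_TOLERANCE = 50  # bp window for mono-exon FSM containment


@dataclass
class ClassifiedIsoform:
    cluster_id: str
    category: str
    matched_transcript_id: str | None
    gene_ids: tuple[str, ...]
    spliced_length: int
    support: int
    contig_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category}")


def _chain_introns(exons) -> tuple[tuple[int, int], ...]:
    return tuple((exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1))


def _splice_sites(introns, strand) -> tuple[set[int], set[int]]:
    donors, acceptors = set(), set()
    for s, e in introns:
        if strand == "+":
            donors.add(s), acceptors.add(e)
        else:
            donors.add(e), acceptors.add(s)
    return donors, acceptors


def classify_isoform(cluster: IsoformCluster, annotation: Annotation,
                     end_tolerance: int = END_TOLERANCE) -> ClassifiedIsoform:
    """Assign exactly one structural category to one HQ isoform."""
    contig, strand, exons = cluster.contig_id, cluster.strand, cluster.exons
    span_s, span_e = exons[0][0], exons[-1][1]
    opp = "-" if strand == "+" else "+"
    introns = _chain_introns(exons)

    def result(category, matched=None, genes=()):
        return ClassifiedIsoform(
            cluster_id=cluster.cluster_id, category=category,
            matched_transcript_id=matched, gene_ids=tuple(genes),
            spliced_length=cluster.spliced_length, support=cluster.support,
            contig_id=contig, strand=strand, exons=exons)

    genes_same = annotation.genes_overlapping(contig, span_s, span_e, strand)

    # 1. FSM (same intron chain; among alternative-TSS/TES references the
    # one with the closest ends wins)
    if introns:
        tids = annotation.transcripts_with_intron_chain(contig, strand, introns)
        if tids:
            def end_shift(tid):
                t = annotation.transcripts[tid]
                return abs(t.start - span_s) + abs(t.end - span_e), tid
            _, tid = min(end_shift(t) for t in tids)
            return result("FSM", tid, (annotation.transcripts[tid].gene_id,))
    else:
        # best-matching containing mono-exon reference (smallest end shift)
        candidates = []
        for g in genes_same:
            for t in annotation.transcripts_of_gene(g.gene_id):
                if (len(t.exons) == 1
                        and span_s >= t.start - end_tolerance
                        and span_e <= t.end + end_tolerance):
                    shift = abs(t.start - span_s) + abs(t.end - span_e)
                    candidates.append((shift, t.transcript_id, g.gene_id))
        if candidates:
            _, tid, gid = min(candidates)
            return result("FSM", tid, (gid,))

    # 2. ISM: contiguous sub-chain of a reference intron chain
    if introns:
        for g in genes_same:
            for t in sorted(annotation.transcripts_of_gene(g.gene_id),
                            key=lambda t: t.transcript_id):
                ref = t.introns
                if len(ref) <= len(introns):
                    continue
                for off in range(len(ref) - len(introns) + 1):
                    if ref[off:off + len(introns)] == introns:
                        return result("ISM", t.transcript_id, (g.gene_id,))

    # exonic overlap per strand, computed exon-by-exon
    hit_genes: set[str] = set()
    hit_genes_opp: set[str] = set()
    for s, e in exons:
        hit_genes |= annotation.exons_overlapping(contig, s, e, strand)
        hit_genes_opp |= annotation.exons_overlapping(contig, s, e, opp)

    # 3. fusion
    if len(hit_genes) >= 2:
        return result("fusion", genes=sorted(hit_genes))

    # 4. splice-site novelty within a same-strand gene
    if genes_same:
        if hit_genes:
            gene = sorted(hit_genes)[0]
            if introns:
                donors, acceptors = _splice_sites(introns, strand)
                known = (donors <= annotation.donors(contig, strand)
                         and acceptors <= annotation.acceptors(contig, strand))
                return result("NIC" if known else "NNC", genes=(gene,))
            return result("genic_genomic", genes=(gene,))
        return result("genic_intronic", genes=(genes_same[0].gene_id,))

    # 5. no same-strand gene overlap
    if hit_genes_opp:
        return result("antisense", genes=sorted(hit_genes_opp))
    genes_opp = annotation.genes_overlapping(contig, span_s, span_e, opp)
    if genes_opp:
        return result("genic_intronic", genes=(genes_opp[0].gene_id,))
    return result("intergenic")


def classify_isoforms(clusters: list[IsoformCluster], annotation: Annotation,
                      end_tolerance: int = END_TOLERANCE,
                      ) -> list[ClassifiedIsoform]:
    out = [classify_isoform(c, annotation, end_tolerance) for c in clusters]
    assign_novel_gene_ids(out)
    return out


def assign_novel_gene_ids(classified: list[ClassifiedIsoform],
                          prefix: str = "novelGene") -> None:
    """Give intergenic isoforms novel gene ids, one per overlap cluster.

    Overlapping intergenic isoforms on the same contig (either strand) share
    one curated novel gene, so unique-gene counting is well defined.
    """
    by_contig: dict[str, list[ClassifiedIsoform]] = defaultdict(list)
    for c in classified:
        if c.category == "intergenic":
            by_contig[c.contig_id].append(c)
    counter = 0
    for contig in sorted(by_contig):
        isos = sorted(by_contig[contig], key=lambda c: (c.exons[0][0], c.cluster_id))
        cur_end = None
        gid = None
        for c in isos:  # sweep: overlapping spans share one novel gene
            s, e = c.exons[0][0], c.exons[-1][1]
            if cur_end is None or s >= cur_end:
                counter += 1
                gid = f"{prefix}_{counter}"
                cur_end = e
            else:
                cur_end = max(cur_end, e)
            c.gene_ids = (gid,)


def sirv_recall(classified: list[ClassifiedIsoform], truth_ids: set[str],
                min_support: int = 1) -> tuple[int, float]:
    """Spike-in recall: a truth transcript is detected iff some FSM isoform
    matches it with at least `min_support` reads. Returns (n_detected,
    percent recall to one decimal)."""
    if not truth_ids:
        raise ValueError("truth set must be non-empty")
    detected = {c.matched_transcript_id for c in classified
                if c.category == "FSM" and c.support >= min_support
                and c.matched_transcript_id in truth_ids}
    n = len(detected)
    return n, round_half_up(n / len(truth_ids) * 100.0, 1)


def length_bins(classified: list[ClassifiedIsoform], bin_width: int = 1000,
                ) -> dict[int, int]:
    """Histogram of total read support per transcript-length bin.

    Bin b spans [b*width, (b+1)*width); weights are read support, so the
    histogram total equals the summed support (conservation).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    hist: dict[int, int] = defaultdict(int)
    for c in classified:
        hist[c.spliced_length // bin_width] += c.support
    return dict(hist)


def intergenic_length_summary(classified: list[ClassifiedIsoform]) -> float | None:
    """Arithmetic mean spliced length of intergenic isoforms (None if none)."""
    lengths = [c.spliced_length for c in classified if c.category == "intergenic"]
    if not lengths:
        return None
    return sum(lengths) / len(lengths)
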