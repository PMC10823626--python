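"""Collapse of aligned FLNC reads into high-quality (HQ) isoform clusters.

Two exon chains merge when their strand-aware 5' ends differ by < 100 bp,
their 3' ends by < 30 bp, and every internal splice junction agrees within a
10 bp per-boundary wobble (10 passes, 11 fails). Clusters are the connected
components of this relation, computed in a deterministic order
(single-linkage), so transitive chaining of near-identical reads is the
documented behaviour. Alignment itself is out of scope: simulation mode
supplies truth-derived chains, real-data mode consumes BED12/GFF chains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

D5_DEFAULT = 100
D3_DEFAULT = 30
GAP_DEFAULT = 10


class ExonChain(Protocol):
    contig_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class AlignedRead:
    """An FLNC read placed on the genome as a strand-aware exon chain."""

    flnc_id: str
    contig_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    source: str = "simulation"

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class IsoformCluster:
    """A collapsed HQ isoform: representative chain plus CCS read support."""

    cluster_id: str
    contig_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    support: int
    members: tuple[str, ...]
    representative: str

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def _introns(exons: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


def mergeable(a: ExonChain, b: ExonChain, d5: int = D5_DEFAULT,
              d3: int = D3_DEFAULT, gap: int = GAP_DEFAULT) -> bool:
    """True iff two chains describe the same isoform up to end wobble.

    5'/3' ends are strand-aware; junction agreement allows a per-boundary
    wobble of at most `gap` bp with no unmatched internal junction.
    """
    if a.contig_id != b.contig_id or a.strand != b.strand:
        return False
    a_start, a_end = a.exons[0][0], a.exons[-1][1]
    b_start, b_end = b.exons[0][0], b.exons[-1][1]
    if a.strand == "+":
        diff5, diff3 = abs(a_start - b_start), abs(a_end - b_end)
    else:
        diff5, diff3 = abs(a_end - b_end), abs(a_start - b_start)
    if diff5 >= d5 or diff3 >= d3:
        return False
    ia, ib = _introns(a.exons), _introns(b.exons)
    if len(ia) != len(ib):
        return False
    return all(abs(sa - sb) <= gap and abs(ea - eb) <= gap
               for (sa, ea), (sb, eb) in zip(ia, ib))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_chains(items: Sequence, d5: int = D5_DEFAULT, d3: int = D3_DEFAULT,
                   gap: int = GAP_DEFAULT) -> list[list[int]]:
    """Connected components of the mergeable relation over arbitrary
    exon-chain carriers; returns lists of indices into `items`.

    Any mergeable pair has genomic start positions within max(d5, d3) bp, so
    after sorting only a bounded window needs comparing; the result equals
    the all-pairs union-find.
    """
    window = max(d5, d3)
    order = sorted(range(len(items)),
                   key=lambda i: (items[i].contig_id, items[i].strand,
                                  items[i].exons[0][0], items[i].exons[-1][1]))
    uf = _UnionFind(len(items))
    for oi in range(len(order)):
        i = order[oi]
        ci = items[i]
        for oj in range(oi + 1, len(order)):
            j = order[oj]
            cj = items[j]
            if (cj.contig_id, cj.strand) != (ci.contig_id, ci.strand):
                break
            if cj.exons[0][0] - ci.exons[0][0] >= window:
                break
            if mergeable(ci, cj, d5, d3, gap):
                uf.union(i, j)
    components: dict[int, list[int]] = {}
    for i in range(len(items)):
        components.setdefault(uf.find(i), []).append(i)
    return sorted(components.values(),
                  key=lambda idxs: (items[idxs[0]].contig_id,
                                    items[idxs[0]].strand,
                                    min(items[k].exons[0][0] for k in idxs),
                                    min(items[k].flnc_id if hasattr(items[k], "flnc_id")
                                        else "" for k in idxs)))


def collapse_flnc(reads: Sequence[AlignedRead], d5: int = D5_DEFAULT,
                  d3: int = D3_DEFAULT, gap: int = GAP_DEFAULT,
                  weights: Sequence[int] | None = None,
                  ) -> list[IsoformCluster]:
    """Group aligned FLNC reads into HQ isoform clusters.

    Every read lands in exactly one cluster and supports sum to len(reads);
    the representative is the member with the longest genomic span (tie:
    lexicographically smallest id). `weights` lets callers pass
    pre-deduplicated chains, each standing for that many identical reads.
    """
    if weights is not None and len(weights) != len(reads):
        raise ValueError("weights/reads length mismatch")
    clusters: list[IsoformCluster] = []
    for n, idxs in enumerate(cluster_chains(reads, d5, d3, gap), 1):
        members = [reads[i] for i in idxs]
        support = (len(members) if weights is None
                   else sum(weights[i] for i in idxs))
        rep = min(members, key=lambda r: (-(r.end - r.start), r.flnc_id))
        clusters.append(IsoformCluster(
            cluster_id=f"HQ_{n:06d}",
            contig_id=rep.contig_id,
            strand=rep.strand,
            exons=rep.exons,
            support=support,
            members=tuple(sorted(r.flnc_id for r in members)),
            representative=rep.flnc_id,
        ))
    return clusters


def filter_by_support(clusters: Iterable[IsoformCluster], min_ccs: int,
                      ) -> list[IsoformCluster]:
    """Keep clusters with support >= min_ccs (order preserved)."""
    if min_ccs < 1:
        raise ValueError("min_ccs must be >= 1")
    return [c for c in clusters if c.support >= min_ccs]
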