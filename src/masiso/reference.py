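"""Synthetic reference transcriptomes for spike-in style benchmarking.

This module builds small, fully known genomes and annotations that emulate a
commercial spike-in reference: an "isoform module" of a few genes carrying
many alternatively spliced isoforms (mono- and multi-exonic, alternative
start/stop sites, at least one antisense transcript), and a "long module" of
mono-exonic transcripts at nominal sizes of several kilobases. An optional
background module (same generator, more genes) stands in for the complexity
of a real transcriptome.

Coordinates are 0-based half-open internally; GTF I/O converts to 1-based
inclusive. Splice sites are written as GT..AG on the transcript strand so
that donor/acceptor-aware classification is exercised realistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .utils import random_dna, revcomp

# spike classes a transcript may belong to
SIRV_ISOFORM = "sirv_isoform"
LONG_SIRV = "long_sirv"
BACKGROUND = "background"


@dataclass(frozen=True)
class GenomeSequence:
    """One contig of the synthetic genome (uppercase A/C/G/T)."""

    contig_id: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValueError("empty contig sequence")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("contig alphabet restricted to A/C/G/T")


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware exon chain on a genome; the universal annotation unit.

    exons are (start, end) genomic intervals, 0-based half-open, strictly
    increasing and non-overlapping with >= 1 bp introns between them.
    """

    transcript_id: str
    gene_id: str
    contig_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    spike_class: str = BACKGROUND

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("exon count must be >= 1")
        prev_end = None
        for start, end in self.exons:
            if not (0 <= start < end):
                raise ValueError(f"bad exon ({start},{end})")
            if prev_end is not None and start <= prev_end:
                raise ValueError("exons must be separated by >= 1 bp introns")
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intron intervals between successive exons."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class Gene:
    gene_id: str
    contig_id: str
    strand: str
    start: int
    end: int


class Annotation:
    """A set of transcript models with gene spans and interval indexes."""

    def __init__(self, transcripts: list[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript_id {t.transcript_id}")
            self.transcripts[t.transcript_id] = t
        self.genes: dict[str, Gene] = {}
        by_gene: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        for gid, ts in by_gene.items():
            contigs = {t.contig_id for t in ts}
            strands = {t.strand for t in ts}
            if len(contigs) != 1 or len(strands) != 1:
                raise ValueError(f"gene {gid} spans multiple contigs/strands")
            self.genes[gid] = Gene(
                gid, ts[0].contig_id, ts[0].strand,
                min(t.start for t in ts), max(t.end for t in ts),
            )
        self._gene_tree: dict[str, IntervalTree] = {}
        self._exon_tree: dict[tuple[str, str], IntervalTree] = {}
        for g in self.genes.values():
            self._gene_tree.setdefault(g.contig_id, IntervalTree()).addi(
                g.start, g.end, g.gene_id
            )
        for t in transcripts:
            tree = self._exon_tree.setdefault((t.contig_id, t.strand), IntervalTree())
            for s, e in t.exons:
                tree.addi(s, e, t.gene_id)
        # splice-site and intron-chain indexes, per contig+strand
        self._donors: dict[tuple[str, str], set[int]] = {}
        self._acceptors: dict[tuple[str, str], set[int]] = {}
        self._chains: dict[tuple[str, str], dict[tuple, str]] = {}
        for t in transcripts:
            key = (t.contig_id, t.strand)
            d = self._donors.setdefault(key, set())
            a = self._acceptors.setdefault(key, set())
            for istart, iend in t.introns:
                # donor = transcription-order start of the intron
                if t.strand == "+":
                    d.add(istart), a.add(iend)
                else:
                    d.add(iend), a.add(istart)
            if t.introns:
                self._chains.setdefault(key, {}).setdefault(t.introns, []) \
                    .append(t.transcript_id)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def transcripts_of_gene(self, gene_id: str) -> list[TranscriptModel]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]

    def genes_overlapping(self, contig_id: str, start: int, end: int,
                          strand: str | None = None) -> list[Gene]:
        tree = self._gene_tree.get(contig_id)
        if tree is None:
            return []
        hits = [self.genes[iv.data] for iv in tree.overlap(start, end)]
        if strand is not None:
            hits = [g for g in hits if g.strand == strand]
        return sorted(hits, key=lambda g: (g.start, g.gene_id))

    def exons_overlapping(self, contig_id: str, start: int, end: int,
                          strand: str) -> set[str]:
        """Gene ids with an exon on `strand` overlapping [start, end)."""
        tree = self._exon_tree.get((contig_id, strand))
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def donors(self, contig_id: str, strand: str) -> set[int]:
        return self._donors.get((contig_id, strand), set())

    def acceptors(self, contig_id: str, strand: str) -> set[int]:
        return self._acceptors.get((contig_id, strand), set())

    def transcripts_with_intron_chain(self, contig_id: str, strand: str,
                                      chain: tuple) -> list[str]:
        """All transcript ids sharing this exact intron chain (alternative
        TSS/TES isoforms can share one)."""
        return list(self._chains.get((contig_id, strand), {}).get(chain, []))

    @property
    def spikein_ids(self) -> set[str]:
        return {t.transcript_id for t in self
                if t.spike_class in (SIRV_ISOFORM, LONG_SIRV)}


def transcript_sequence(model: TranscriptModel, genome: GenomeSequence) -> str:
    """RNA-sense sequence (as DNA text) of a transcript model.

    Concatenates exon substrings in genomic order and reverse-complements
    the result for minus-strand models.
    """
    if model.contig_id != genome.contig_id:
        raise ValueError("transcript/contig mismatch")
    n = len(genome.sequence)
    for s, e in model.exons:
        if e > n:
            raise ValueError(f"exon ({s},{e}) outside contig of length {n}")
    seq = "".join(genome.sequence[s:e] for s, e in model.exons)
    return revcomp(seq) if model.strand == "-" else seq


# ---------------------------------------------------------------------------
# generator internals

_MIN_TERMINAL = 30   # minimum contribution of a terminal exon to spliced length
_MIN_INTRON = 60


@dataclass
class _Locus:
    """Scaffolding for one gene during generation."""

    gene_id: str
    contig_id: str
    strand: str
    master: list[tuple[int, int]]       # master exon skeleton
    right_limit: int                    # rightmost coordinate isoforms may reach


def _make_master(rng: np.random.Generator, origin: int, n_exons: int,
                 exon_rng=(80, 350), intron_rng=(_MIN_INTRON, 300)) -> list[tuple[int, int]]:
    exons = []
    pos = origin
    for i in range(n_exons):
        length = int(rng.integers(*exon_rng))
        if i in (0, n_exons - 1):
            length = int(rng.integers(300, 700))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(*intron_rng))
    return exons


def _isoform_chain(rng: np.random.Generator, locus: _Locus,
                   length_min: int, length_max: int,
                   force_k: int | None = None) -> tuple[tuple[int, int], ...]:
    """Sample one isoform exon chain from a locus master skeleton.

    Internal exons of the chosen subset keep master coordinates (shared
    splice sites across isoforms); terminal exons get alternative start/stop
    positions so that the spliced length lands inside [length_min, length_max].
    """
    master = locus.master
    m = len(master)
    for attempt in range(40):
        if force_k is not None and attempt < 20:
            k = min(force_k, m) if force_k > 1 else 1
        else:
            k = int(rng.integers(1, m + 1))
        if force_k == 1 and attempt >= 10:
            # the last master exon can always extend rightwards far enough
            idx = [m - 1]
        else:
            idx = sorted(rng.choice(m, size=k, replace=False).tolist())
        sel = [master[i] for i in idx]
        # room to extend the 3'-most selected exon rightwards
        last_i = idx[-1]
        if last_i == m - 1:
            ext_limit = locus.right_limit
        else:
            ext_limit = master[last_i + 1][0] - _MIN_INTRON
        if k == 1:
            s, e = sel[0]
            lo, hi = _MIN_TERMINAL, ext_limit - s
        else:
            internal = sum(e - s for s, e in sel[1:-1])
            first_len = sel[0][1] - sel[0][0]
            last_cap = ext_limit - sel[-1][0]
            lo = internal + 2 * _MIN_TERMINAL
            hi = internal + first_len + last_cap
        t_lo, t_hi = max(length_min, lo), min(length_max, hi)
        if t_lo > t_hi:
            continue
        target = int(rng.integers(t_lo, t_hi + 1))
        if k == 1:
            s = sel[0][0]
            return ((s, s + target),)
        terminal = target - internal
        a5_lo = max(_MIN_TERMINAL, terminal - last_cap)
        a5_hi = min(first_len, terminal - _MIN_TERMINAL)
        a5 = int(rng.integers(a5_lo, a5_hi + 1))
        a3 = terminal - a5
        chain = [(sel[0][1] - a5, sel[0][1])]
        chain.extend(sel[1:-1])
        chain.append((sel[-1][0], sel[-1][0] + a3))
        return tuple(chain)
    raise RuntimeError(
        f"could not sample an isoform in [{length_min},{length_max}] "
        f"for locus {locus.gene_id}"
    )


def _write_splice_sites(seq: list[str], model: TranscriptModel) -> None:
    """Stamp canonical GT..AG dinucleotides on the transcript strand."""
    for istart, iend in model.introns:
        if model.strand == "+":
            seq[istart:istart + 2] = "GT"
            seq[iend - 2:iend] = "AG"
        else:
            seq[istart:istart + 2] = "CT"   # revcomp(AG)
            seq[iend - 2:iend] = "AC"       # revcomp(GT)


def _build_module(n_genes: int, n_isoforms: int, length_min: int, length_max: int,
                  rng: np.random.Generator, prefix: str,
                  spike_class: str) -> tuple[list[GenomeSequence], Annotation]:
    # gene layout: one contig per gene, except (n_genes >= 2) the last gene is
    # placed antisense, fully within the span of the first gene's contig
    flank = length_max + 1000
    loci: list[_Locus] = []
    contig_lengths: dict[str, int] = {}
    antisense_gene = n_genes - 1 if n_genes >= 2 else None
    for gi in range(n_genes):
        gid = f"{prefix}G{gi + 1}"
        if gi == antisense_gene:
            host = loci[0]
            strand = "-" if host.strand == "+" else "+"
            span = host.master[-1][1] - host.master[0][0]
            origin = host.master[0][0] + 50
            n_exons = 3
            master = _make_master(rng, origin, n_exons,
                                  exon_rng=(60, 150), intron_rng=(_MIN_INTRON, 120))
            # antisense isoforms may extend to the host gene's end
            loci.append(_Locus(gid, host.contig_id, strand, master,
                               right_limit=origin + span - 50))
        else:
            contig = f"{prefix}C{gi + 1}"
            strand = "+" if rng.random() < 0.7 else "-"
            n_exons = int(rng.integers(5, 10))
            master = _make_master(rng, 1000, n_exons)
            loci.append(_Locus(gid, contig, strand, master,
                               right_limit=master[-1][1] + flank))
            contig_lengths[contig] = master[-1][1] + flank + 1000

    def _near_duplicate(chain, existing) -> bool:
        # two isoforms with the same intron chain and both ends closer than
        # the collapse tolerances (plus alignment end-jitter headroom) are
        # indistinguishable downstream; resample such candidates
        def introns_of(c):
            return tuple((c[i][1], c[i + 1][0]) for i in range(len(c) - 1))
        for other in existing:
            if introns_of(chain) == introns_of(other) \
                    and abs(chain[0][0] - other[0][0]) < 130 \
                    and abs(chain[-1][1] - other[-1][1]) < 130:
                return True
        return False

    transcripts: list[TranscriptModel] = []
    chains_per_locus: dict[str, list] = {l.gene_id: [] for l in loci}
    for i in range(n_isoforms):
        locus = loci[i % n_genes]
        force_k = None
        if i == 0:
            force_k = 1           # guarantee a mono-exonic transcript
        elif i == 1 and n_isoforms >= 2:
            force_k = 4           # guarantee a multi-exonic transcript
        chain = _isoform_chain(rng, locus, length_min, length_max, force_k=force_k)
        for _retry in range(25):
            if not _near_duplicate(chain, chains_per_locus[locus.gene_id]):
                break
            chain = _isoform_chain(rng, locus, length_min, length_max,
                                   force_k=force_k)
        chains_per_locus[locus.gene_id].append(chain)
        transcripts.append(TranscriptModel(
            transcript_id=f"{prefix}T{i + 1:04d}",
            gene_id=locus.gene_id,
            contig_id=locus.contig_id,
            strand=locus.strand,
            exons=chain,
            spike_class=spike_class,
        ))

    annotation = Annotation(transcripts)
    genome = []
    for contig, length in sorted(contig_lengths.items()):
        seq = list(random_dna(rng, length))
        for t in transcripts:
            if t.contig_id == contig:
                _write_splice_sites(seq, t)
        genome.append(GenomeSequence(contig, "".join(seq)))
    return genome, annotation


# ---------------------------------------------------------------------------
# public generators

def make_sirv_like_module(n_genes: int, n_isoforms: int, length_min: int,
                          length_max: int, seed: int,
                          prefix: str = "SIRV",
                          spike_class: str = SIRV_ISOFORM,
                          ) -> tuple[list[GenomeSequence], Annotation]:
    """Generate an isoform spike-in module.

    Produces exactly `n_isoforms` transcripts over `n_genes` loci with every
    spliced length inside [length_min, length_max], including at least one
    mono-exonic, one multi-exonic (n_isoforms >= 2) and one antisense
    (n_genes >= 2) transcript. Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_isoforms < n_genes:
        raise ValueError("n_isoforms must be >= n_genes")
    if length_min < 50:
        raise ValueError("length_min must be >= 50 (must host primers/exons)")
    if length_min > length_max:
        raise ValueError("length_min must be <= length_max")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    return _build_module(n_genes, n_isoforms, length_min, length_max, rng,
                         prefix, spike_class)


def make_long_module(sizes: list[int], copies_per_size: int, seed: int,
                     prefix: str = "LSIRV",
                     ) -> tuple[list[GenomeSequence], Annotation]:
    """Generate the long spike-in module: mono-exonic transcripts at the
    nominal sizes (each within +/-2%), `copies_per_size` distinct transcripts
    per size, one contig per transcript, flagged `long_sirv`.
    """
    if not sizes:
        raise ValueError("sizes must be non-empty")
    if any(s < 1000 for s in sizes):
        raise ValueError("long-module sizes must be >= 1000 bp")
    if copies_per_size < 1:
        raise ValueError("copies_per_size must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    genome: list[GenomeSequence] = []
    transcripts: list[TranscriptModel] = []
    for size in sizes:
        for c in range(1, copies_per_size + 1):
            length = int(round(size * (1 + rng.uniform(-0.015, 0.015))))
            contig = f"{prefix}{size}_{c}"
            pad = 200
            seq = random_dna(rng, length + 2 * pad)
            genome.append(GenomeSequence(contig, seq))
            transcripts.append(TranscriptModel(
                transcript_id=f"{prefix}{size}_{c}",
                gene_id=f"{prefix}{size}_{c}_G",
                contig_id=contig,
                strand="+",
                exons=((pad, pad + length),),
                spike_class=LONG_SIRV,
            ))
    return genome, Annotation(transcripts)


def make_background_module(n_genes: int = 50, n_isoforms: int = 150,
                           length_min: int = 300, length_max: int = 5000,
                           seed: int = 0,
                           ) -> tuple[list[GenomeSequence], Annotation]:
    """Optional multi-gene background standing in for a complex transcriptome."""
    return make_sirv_like_module(n_genes, n_isoforms, length_min, length_max,
                                 seed, prefix="BG", spike_class=BACKGROUND)


def combine(*modules: tuple[list[GenomeSequence], Annotation]
            ) -> tuple[list[GenomeSequence], Annotation]:
    """Merge several (genome, annotation) modules into one reference."""
    genome: list[GenomeSequence] = []
    transcripts: list[TranscriptModel] = []
    seen = set()
    for contigs, ann in modules:
        for c in contigs:
            if c.contig_id in seen:
                raise ValueError(f"duplicate contig {c.contig_id}")
            seen.add(c.contig_id)
            genome.append(c)
        transcripts.extend(ann)
    return genome, Annotation(transcripts)
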