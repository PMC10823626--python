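"""In-silico concatemer library construction.

Emulates the wet-lab path from an RNA pool to concatemer HiFi reads:
expression sampling (equimolar spike-ins on a log-normal background), cDNA
synthesis with template-switching (TSO) artifacts, length-dependent bead
capture loss, two-fraction size selection, barcode-directed dimer/tetramer
ligation, and a substitution/indel HiFi error model (~0.1%/base by default).
Every read carries hidden truth segments so downstream splitting, refinement
and clustering can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib
import numpy as np

from .reference import Annotation, GenomeSequence, transcript_sequence
from .utils import random_dna

# fixed synthetic 5'/3' cDNA primers (not any vendor's sequences; only their
# detectability matters)
PRIMER_5 = "AAGCAGTGGTATCAACGCAGAG"
PRIMER_3 = "GTACTCTGCGTTGATACCACTG"
DEFAULT_POLYA = 30

ARTIFACT_NONE = "none"
ARTIFACT_TSO = "tso_artifact"
ARTIFACT_TRUNCATED = "truncated"

# capture-loss defaults: retention 1 up to the knee, then a steep logistic
# decline in log-length placed so ~10 kb molecules survive at ~2e-3 while
# ~12 kb molecules are effectively never captured
CAPTURE_KNEE = 2000
CAPTURE_MIDPOINT = 8600.0
CAPTURE_STEEPNESS = 42.0

# size-selection boundaries; 2,000 bp itself goes to the short fraction
SIZE_LONG_MIN = 2001
SIZE_SHORT_MIN = 500


@dataclass
class ExpressionRecord:
    """Simulated abundance for one transcript (TPM plus sampled copies)."""

    transcript_id: str
    tpm: float
    copies: int = 0


@dataclass
class CDNAMolecule:
    """One cDNA: 5' adapter + insert (+ poly(A)) + 3' primer."""

    sequence: str
    source_transcript_id: str | None
    artifact: str = ARTIFACT_NONE

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ArrayDesign:
    """Barcode layout of a concatemer array.

    An arity-k array is B0 seg1 B1 seg2 ... segk Bk with all segments
    sense-oriented; the arity+1 junction barcodes are pairwise distinct with
    minimum edit distance >= 5.
    """

    name: str
    arity: int
    junction_barcodes: tuple[str, ...]

    def __post_init__(self):
        if self.arity < 1:
            raise ValueError("arity must be >= 1")
        if len(self.junction_barcodes) != self.arity + 1:
            raise ValueError("need arity+1 junction barcodes")


@dataclass
class TruthSegment:
    """Hidden provenance of one segment inside a concatemer read."""

    transcript_id: str | None
    artifact: str
    start: int
    end: int
    n_edits: int = 0


@dataclass
class ConcatemerRead:
    read_id: str
    sequence: str
    truth_segments: list[TruthSegment]
    design: ArrayDesign | None
    n_segments_true: int = field(default=0)

    def __post_init__(self):
        if not self.n_segments_true:
            self.n_segments_true = len(self.truth_segments)


def make_array_designs(arities: list[int], seed: int, barcode_len: int = 16,
                       min_edit: int = 5) -> list[ArrayDesign]:
    """Generate one design per arity with globally distinct barcodes.

    Barcodes across all designs satisfy the pairwise minimum edit distance so
    that a pooled dimer/tetramer run remains unambiguous.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10,)))
    n_needed = sum(a + 1 for a in arities)
    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < n_needed:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("cannot satisfy barcode distance constraint")
        cand = random_dna(rng, barcode_len)
        if all(edlib.align(cand, b, task="distance")["editDistance"] >= min_edit
               for b in barcodes):
            barcodes.append(cand)
    designs = []
    pos = 0
    for a in arities:
        designs.append(ArrayDesign(f"arity{a}", a,
                                   tuple(barcodes[pos:pos + a + 1])))
        pos += a + 1
    return designs


def sample_expression(annotation: Annotation, total_molecules: int,
                      spikein_fraction: float, seed: int,
                      background_sigma: float = 1.5,
                      overexpress: dict[str, float] | None = None,
                      ) -> list[ExpressionRecord]:
    """Sample molecule counts: equimolar spike-ins at `spikein_fraction` of
    the pool, log-normal abundances across background transcripts.

    `overexpress` maps gene_ids to fold multipliers applied to the TPM of
    every transcript of that gene before renormalisation (used to build
    two-condition differential studies). Sum of TPM is exactly 1e6.
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    if total_molecules < 0:
        raise ValueError("total_molecules must be >= 0")
    if not (0.0 <= spikein_fraction <= 1.0):
        raise ValueError("spikein_fraction must be in [0,1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
    spikes = sorted(annotation.spikein_ids)
    background = sorted(t.transcript_id for t in annotation
                        if t.transcript_id not in annotation.spikein_ids)
    ids = spikes + background
    weights = np.zeros(len(ids))
    if spikes:
        frac = spikein_fraction if background else 1.0
        weights[:len(spikes)] = frac / len(spikes)
    if background:
        w = rng.lognormal(mean=0.0, sigma=background_sigma, size=len(background))
        w = w / w.sum() * (1.0 - (spikein_fraction if spikes else 0.0))
        weights[len(spikes):] = w
    if overexpress:
        gene_of = {tid: annotation.transcripts[tid].gene_id for tid in ids}
        for i, tid in enumerate(ids):
            fold = overexpress.get(gene_of[tid])
            if fold is not None:
                weights[i] *= fold
    weights = weights / weights.sum()
    copies = rng.multinomial(total_molecules, weights) if total_molecules else \
        np.zeros(len(ids), dtype=int)
    tpm = weights * 1e6
    return [ExpressionRecord(tid, float(t), int(c))
            for tid, t, c in zip(ids, tpm, copies)]


def synthesize_cdna(records: list[ExpressionRecord], annotation: Annotation,
                    genome: list[GenomeSequence] | dict[str, GenomeSequence],
                    tso_artifact_rate: float, seed: int,
                    polya_len: int = DEFAULT_POLYA) -> list[CDNAMolecule]:
    """One error-free cDNA per sampled copy, plus TSO artifact molecules.

    Real molecules are 5' primer + full transcript + poly(A) + 3' primer;
    artifacts carry an internal transcript fragment and no oligo(dT)
    structure (no poly(A) tail).
    """
    if not (0.0 <= tso_artifact_rate < 1.0):
        raise ValueError("tso_artifact_rate must be in [0,1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(12,)))
    contigs = ({g.contig_id: g for g in genome}
               if not isinstance(genome, dict) else genome)
    seq_cache: dict[str, str] = {}

    def tseq(tid: str) -> str:
        if tid not in seq_cache:
            t = annotation.transcripts[tid]
            seq_cache[tid] = transcript_sequence(t, contigs[t.contig_id])
        return seq_cache[tid]

    molecules: list[CDNAMolecule] = []
    for rec in records:
        if rec.copies <= 0:
            continue
        insert = tseq(rec.transcript_id)
        seq = PRIMER_5 + insert + "A" * polya_len + PRIMER_3
        for _ in range(rec.copies):
            molecules.append(CDNAMolecule(seq, rec.transcript_id))
    n_real = len(molecules)
    n_artifacts = int(rng.binomial(n_real, tso_artifact_rate)) if n_real else 0
    tids = [r.transcript_id for r in records if r.copies > 0]
    for _ in range(n_artifacts):
        tid = tids[int(rng.integers(0, len(tids)))]
        src = tseq(tid)
        frag_len = int(rng.integers(100, max(101, min(len(src), 1500) + 1)))
        start = int(rng.integers(0, max(1, len(src) - frag_len + 1)))
        frag = src[start:start + frag_len]
        molecules.append(CDNAMolecule(PRIMER_5 + frag + PRIMER_3, tid,
                                      artifact=ARTIFACT_TSO))
    return molecules


def capture_retention(length: int, knee_bp: int = CAPTURE_KNEE,
                      floor_retention: float = 0.0,
                      midpoint_bp: float = CAPTURE_MIDPOINT,
                      steepness: float = CAPTURE_STEEPNESS) -> float:
    """Bead-capture retention probability as a function of molecule length:
    1 below the knee, then a logistic decline in log-length to the floor."""
    if length <= knee_bp:
        return 1.0
    logit = -steepness * np.log(length / midpoint_bp)
    r = floor_retention + (1.0 - floor_retention) / (1.0 + np.exp(-logit))
    return float(min(1.0, r))


def capture_filter(molecules: list[CDNAMolecule], seed: int,
                   knee_bp: int = CAPTURE_KNEE, floor_retention: float = 0.0,
                   midpoint_bp: float = CAPTURE_MIDPOINT,
                   steepness: float = CAPTURE_STEEPNESS) -> list[CDNAMolecule]:
    """Length-dependent capture: TSO artifacts are removed outright (that is
    the capture step's purpose); real molecules survive with probability
    `capture_retention(length)`."""
    if knee_bp <= 0:
        raise ValueError("knee_bp must be > 0")
    if not (0.0 <= floor_retention <= 1.0):
        raise ValueError("floor_retention must be in [0,1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(13,)))
    kept = []
    for mol in molecules:
        if mol.artifact == ARTIFACT_TSO:
            continue
        r = capture_retention(mol.length, knee_bp, floor_retention,
                              midpoint_bp, steepness)
        if r >= 1.0 or rng.random() < r:
            kept.append(mol)
    return kept


def size_select(molecules: list[CDNAMolecule]
                ) -> tuple[list[CDNAMolecule], list[CDNAMolecule], list[CDNAMolecule]]:
    """Exact two-fraction size selection on total molecule length.

    Returns (long_fraction > 2,000 bp, short_fraction 500-2,000 bp,
    discarded < 500 bp); 2,000 bp itself belongs to the short fraction.
    """
    long_f, short_f, discarded = [], [], []
    for mol in molecules:
        if mol.length >= SIZE_LONG_MIN:
            long_f.append(mol)
        elif mol.length >= SIZE_SHORT_MIN:
            short_f.append(mol)
        else:
            discarded.append(mol)
    return long_f, short_f, discarded


def concatenate(fraction: list[CDNAMolecule], design: ArrayDesign,
                full_array_rate: float, seed: int,
                read_prefix: str = "read") -> list[ConcatemerRead]:
    """Pack molecules into barcode-directed arrays without replacement.

    With probability `full_array_rate` an array receives the full `arity`
    segments; otherwise ligation stalls and the array holds a uniform
    1..arity-1 segments. Every molecule ends up in exactly one array (the
    final array may be partial when fewer than the drawn number remain).
    """
    if not (0.0 < full_array_rate <= 1.0):
        raise ValueError("full_array_rate must be in (0,1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(14,)))
    order = rng.permutation(len(fraction))
    pool = [fraction[j] for j in order]
    reads: list[ConcatemerRead] = []
    pos = 0
    i = 0
    while pos < len(pool):
        if design.arity == 1:
            m = 1
        elif rng.random() < full_array_rate:
            m = design.arity
        else:
            m = int(rng.integers(1, design.arity))
        m = min(m, len(pool) - pos)
        segs = pool[pos:pos + m]
        pos += m
        parts = []
        truth = []
        offset = 0
        for j, mol in enumerate(segs):
            bc = design.junction_barcodes[j]
            parts.append(bc)
            offset += len(bc)
            parts.append(mol.sequence)
            truth.append(TruthSegment(mol.source_transcript_id, mol.artifact,
                                      offset, offset + mol.length))
            offset += mol.length
        parts.append(design.junction_barcodes[m])
        i += 1
        reads.append(ConcatemerRead(f"{read_prefix}_{design.name}_{i:07d}",
                                    "".join(parts), truth, design))
    return reads


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def apply_hifi_errors(reads: list[ConcatemerRead], per_base_error: float,
                      seed: int, weights: tuple[float, float, float] = (2, 1, 1),
                      ) -> list[ConcatemerRead]:
    """Inject substitution/insertion/deletion errors at the given per-base
    rate (default mix 2:1:1) and carry truth-segment offsets through indels.

    An insertion at position p lands before the original base p and is
    attributed to the region starting at p; per-segment injected edit counts
    are recorded on the truth segments for oracle testing.
    """
    if not (0.0 <= per_base_error < 0.1):
        raise ValueError("per_base_error must be in [0, 0.1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(15,)))
    if per_base_error == 0.0:
        return [replace(r, truth_segments=[replace(s) for s in r.truth_segments])
                for r in reads]
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    out = []
    for read in reads:
        n = len(read.sequence)
        n_err = int(rng.binomial(n, per_base_error))
        n_err = min(n_err, n)
        if n_err == 0:
            out.append(replace(read,
                               truth_segments=[replace(s) for s in read.truth_segments]))
            continue
        positions = np.sort(rng.choice(n, size=n_err, replace=False))
        kinds = rng.choice(3, size=n_err, p=w)  # 0 sub, 1 ins, 2 del
        arr = np.frombuffer(read.sequence.encode(), dtype=np.uint8).copy()
        pieces = []
        prev = 0
        for p, k in zip(positions.tolist(), kinds.tolist()):
            pieces.append(arr[prev:p])
            if k == 0:
                alts = _BASES[_BASES != arr[p]]
                pieces.append(alts[rng.integers(0, 3)][None])
                prev = p + 1
            elif k == 1:
                pieces.append(_BASES[rng.integers(0, 4)][None])
                prev = p
            else:
                prev = p + 1
        pieces.append(arr[prev:])
        new_seq = np.concatenate(pieces).tobytes().decode()
        ins_pos = positions[kinds == 1]
        del_pos = positions[kinds == 2]
        new_truth = []
        for seg in read.truth_segments:
            shift_s = int(np.searchsorted(ins_pos, seg.start, "left")
                          - np.searchsorted(del_pos, seg.start, "left"))
            shift_e = int(np.searchsorted(ins_pos, seg.end, "left")
                          - np.searchsorted(del_pos, seg.end, "left"))
            inside = int(np.sum((positions >= seg.start) & (positions < seg.end)))
            new_truth.append(TruthSegment(seg.transcript_id, seg.artifact,
                                          seg.start + shift_s, seg.end + shift_e,
                                          n_edits=inside))
        out.append(ConcatemerRead(read.read_id, new_seq, new_truth,
                                  read.design, read.n_segments_true))
    return out
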