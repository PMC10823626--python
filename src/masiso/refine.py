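"""Refinement of s-reads into full-length non-concatemer (FLNC) reads.

Mirrors the primer-removal + refine stage of a long-read isoform pipeline:
find the best 5'/3' primer pair across both orientations, trim it, orient
the insert to sense, trim the trailing poly(A) run, and reject inserts that
still contain internal primers or junction barcodes (residual concatemers).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .deconcat import SegmentedRead, find_occurrences
from .library_sim import PRIMER_3, PRIMER_5
from .utils import revcomp

STATUS_FLNC = "flnc"
STATUS_NO_PRIMER = "no_primer"
STATUS_NO_POLYA = "no_polya"
STATUS_RESIDUAL = "residual_concatemer"
STATUS_SHORT = "short"

MIN_INSERT = 80          # inserts below this after trimming are statused short
_TERMINAL_SLOP = 8       # how far from a read end a terminal primer may start


@dataclass(frozen=True)
class PrimerPair:
    name: str
    five_prime: str
    three_prime: str


DEFAULT_PRIMERS = [PrimerPair("default", PRIMER_5, PRIMER_3)]


@dataclass
class FLNCRead:
    flnc_id: str
    sequence: str            # sense-oriented insert, poly(A) removed
    polya_len: int
    source_sread_id: str
    status: str
    primer_pair: str | None = None


def _match_terminal(primer: str, text: str, max_edit: int,
                    end: bool) -> tuple[int, int] | None:
    """Find `primer` at a read terminus; returns (cut_position, distance).

    For the 5' end the cut is where the insert begins; for the 3' end where
    it stops. The hit must sit within a small slop of the terminus.
    """
    window = len(primer) + max_edit + _TERMINAL_SLOP
    if end:
        sub = text[-window:] if len(text) > window else text
        offset = len(text) - len(sub)
    else:
        sub = text[:window]
        offset = 0
    res = edlib.align(primer, sub, mode="HW", task="locations", k=max_edit)
    if res["editDistance"] < 0:
        return None
    if end:
        # rightmost optimal hit, must end near the read end
        start, stop_inc = res["locations"][-1]
        if len(sub) - (stop_inc + 1) > _TERMINAL_SLOP:
            return None
        return offset + (start or 0), res["editDistance"]
    start, stop_inc = res["locations"][0]
    if (start or 0) > _TERMINAL_SLOP:
        return None
    return offset + stop_inc + 1, res["editDistance"]


def detect_and_trim_primers(sread_seq: str, primer_pairs: list[PrimerPair],
                            max_edit: int = 3,
                            ) -> tuple[str, str, str] | None:
    """Best 5'/3' primer pair over both orientations.

    Returns (sense-oriented insert, pair name, orientation) or None when no
    orientation presents both primers at its termini.
    """
    if not primer_pairs:
        raise ValueError("primer pairs must be non-empty")
    best = None
    for orient, seq in (("+", sread_seq), ("-", revcomp(sread_seq))):
        for pair in primer_pairs:
            m5 = _match_terminal(pair.five_prime, seq, max_edit, end=False)
            m3 = _match_terminal(pair.three_prime, seq, max_edit, end=True)
            if m5 is None or m3 is None:
                continue
            cut5, d5 = m5
            cut3, d3 = m3
            if cut3 <= cut5:
                continue
            cand = (d5 + d3, 0 if orient == "+" else 1,
                    seq[cut5:cut3], pair.name, orient)
            if best is None or cand[:2] < best[:2]:
                best = cand
    if best is None:
        return None
    return best[2], best[3], best[4]


def trim_polya(insert: str, min_a_run: int = 20, max_mismatch: int = 1,
               ) -> tuple[str, int] | None:
    """Trim the trailing A-rich run (>= min_a_run A's, at most max_mismatch
    interior non-A bases); returns (trimmed insert, tail length) or None."""
    if min_a_run < 1:
        raise ValueError("min_a_run must be >= 1")
    pos = len(insert) - 1
    mismatches = 0
    while pos >= 0:
        if insert[pos] == "A":
            pos -= 1
            continue
        if mismatches < max_mismatch and pos > 0 and insert[pos - 1] == "A":
            mismatches += 1
            pos -= 1
            continue
        break
    cut = pos + 1
    # the run must start on an A, not on a tolerated mismatch
    while cut < len(insert) and insert[cut] != "A":
        cut += 1
    tail = insert[cut:]
    if tail.count("A") >= min_a_run:
        return insert[:cut], len(tail)
    return None


def drop_residual_concatemers(insert: str, primers: list[PrimerPair],
                              barcodes: list[str], max_edit: int = 1,
                              barcode_max_edit: int = 0,
                              margin: int = 5) -> bool:
    """True (pass) iff no internal approximate primer/barcode occurrence.

    Terminal leftovers within `margin` bp of either end are ignored; an
    interior hit marks the insert as a residual concatemer. A missed
    junction always leaves intact internal primers, so primers are scanned
    with a small edit allowance while barcodes (whose corruption is what
    caused the miss) are only matched exactly — keeping the false-positive
    rate from chance 16-mer matches negligible.
    """
    jobs = [(p, max_edit) for pair in primers
            for p in (pair.five_prime, pair.three_prime,
                      revcomp(pair.five_prime), revcomp(pair.three_prime))]
    jobs += [(b, barcode_max_edit) for b in barcodes]
    for pat, k in jobs:
        for start, end, _ in find_occurrences(pat, insert, k):
            if start > margin and end < len(insert) - margin:
                return False
    return True


def refine_sread(sread: SegmentedRead, primer_pairs: list[PrimerPair] | None = None,
                 barcodes: list[str] | None = None, max_edit: int = 3,
                 min_a_run: int = 20, max_mismatch: int = 1,
                 require_polya: bool = True, min_insert: int = MIN_INSERT,
                 ) -> FLNCRead:
    """Run the full refinement ladder on one s-read.

    Status order: no_primer -> residual_concatemer -> no_polya -> short ->
    flnc. TSO artifacts that leak past capture lack the oligo(dT) structure
    and fall out at the no_polya step.
    """
    primer_pairs = primer_pairs or DEFAULT_PRIMERS
    barcodes = barcodes or []
    hit = detect_and_trim_primers(sread.sequence, primer_pairs, max_edit)
    if hit is None:
        return FLNCRead(sread.sread_id, "", 0, sread.sread_id, STATUS_NO_PRIMER)
    insert, pair_name, _orient = hit
    if not drop_residual_concatemers(insert, primer_pairs, barcodes):
        return FLNCRead(sread.sread_id, insert, 0, sread.sread_id,
                        STATUS_RESIDUAL, pair_name)
    polya_len = 0
    if require_polya:
        trimmed = trim_polya(insert, min_a_run, max_mismatch)
        if trimmed is None:
            return FLNCRead(sread.sread_id, insert, 0, sread.sread_id,
                            STATUS_NO_POLYA, pair_name)
        insert, polya_len = trimmed
    if len(insert) < min_insert:
        return FLNCRead(sread.sread_id, insert, polya_len, sread.sread_id,
                        STATUS_SHORT, pair_name)
    return FLNCRead(sread.sread_id, insert, polya_len, sread.sread_id,
                    STATUS_FLNC, pair_name)


def refine_sreads(sreads: list[SegmentedRead], **kwargs) -> list[FLNCRead]:
    return [refine_sread(s, **kwargs) for s in sreads]
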