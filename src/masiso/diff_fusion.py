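"""Tumor-vs-comparator differential isoform filters and fusion calling.

These are deterministic threshold filters, not statistical models: the
differential filter keeps known (FSM) isoforms with >= 10 long reads and
TPM >= 10 in the tumor and at least five-fold more reads AND TPM than the
comparator (zero operands replaced by a pseudocount of one); the novel
filter keeps NIC/NNC isoforms with >= 10 tumor reads and zero comparator
reads (no TPM involved, as novel isoforms have none); fusion candidates
must hit >= 2 loci with >= 5% of the read on each, >= 99% combined
coverage, and >= 5 supporting FLNC reads. Passing fusions with a spike-in
partner are flagged as concatenation-artifact sentinels.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class IsoformExpressionRecord:
    isoform_id: str
    gene_id: str
    category: str
    long_read_support_tumor: int
    long_read_support_comp: int
    tpm_tumor: float
    tpm_comp: float

    def __post_init__(self):
        if min(self.long_read_support_tumor, self.long_read_support_comp) < 0:
            raise ValueError("read counts must be >= 0")
        if min(self.tpm_tumor, self.tpm_comp) < 0:
            raise ValueError("TPM values must be >= 0")


@dataclass
class FusionCandidate:
    candidate_id: str
    loci: tuple[tuple[str, float], ...]  # (gene_id, aligned fraction of read)
    combined_coverage: float
    flnc_support: int

    def __post_init__(self):
        if sum(f for _, f in self.loci) > 1.0 + 1e-9:
            raise ValueError("aligned fractions must sum to <= 1")


def _ratio(numerator: float, denominator: float, pseudocount: float) -> float:
    """Unrounded fold ratio with zero operands replaced by the pseudocount.

    Thresholding happens on the exact ratio; rounding is only for display.
    """
    num = numerator if numerator > 0 else pseudocount
    den = denominator if denominator > 0 else pseudocount
    return num / den


def de_filter(records: list[IsoformExpressionRecord], min_reads: int = 10,
              min_tpm: float = 10.0, min_fold: float = 5.0,
              pseudocount: float = 1.0) -> list[IsoformExpressionRecord]:
    """Differentially expressed known isoforms, single conjunctive pass:
    FSM category, tumor support >= min_reads, tumor TPM >= min_tpm, and both
    the read fold and the TPM fold >= min_fold (inclusive)."""
    if min(min_reads, min_tpm, min_fold) <= 0:
        raise ValueError("thresholds must be > 0")
    passing = []
    for r in records:
        if r.category != "FSM":
            continue
        if r.long_read_support_tumor < min_reads or r.tpm_tumor < min_tpm:
            continue
        read_fold = _ratio(r.long_read_support_tumor,
                           r.long_read_support_comp, pseudocount)
        tpm_fold = _ratio(r.tpm_tumor, r.tpm_comp, pseudocount)
        if read_fold >= min_fold and tpm_fold >= min_fold:
            passing.append(r)
    return passing


def unique_gene_rollup(records: list[IsoformExpressionRecord]) -> set[str]:
    """Distinct gene ids over passing isoforms (for pathway hand-off)."""
    return {r.gene_id for r in records}


def novel_filter(records: list[IsoformExpressionRecord], min_reads: int = 10,
                 ) -> list[IsoformExpressionRecord]:
    """Tumor-unique novel isoforms: NIC/NNC with >= min_reads tumor reads
    and zero comparator reads; TPM fields are ignored."""
    return [r for r in records
            if r.category in ("NIC", "NNC")
            and r.long_read_support_tumor >= min_reads
            and r.long_read_support_comp == 0]


def fusion_filter(candidates: list[FusionCandidate], min_frac: float = 0.05,
                  min_cov: float = 0.99, min_flnc: int = 5,
                  spikein_ids: set[str] | None = None,
                  ) -> tuple[list[FusionCandidate], list[bool]]:
    """Apply the fusion-calling criteria; returns (passing candidates,
    per-candidate flags marking a spike-in gene partner).

    A spike-in partner in a passing fusion is the sentinel for incomplete
    deconcatenation artifacts.
    """
    if not (0.0 < min_frac <= 1.0 and 0.0 < min_cov <= 1.0):
        raise ValueError("fractions must be in (0,1]")
    if min_flnc < 1:
        raise ValueError("min_flnc must be >= 1")
    spikein_ids = spikein_ids or set()
    passing, flags = [], []
    for c in candidates:
        if len(c.loci) < 2:
            continue
        if any(frac < min_frac for _, frac in c.loci):
            continue
        if c.combined_coverage < min_cov:
            continue
        if c.flnc_support < min_flnc:
            continue
        passing.append(c)
        flags.append(any(gene in spikein_ids for gene, _ in c.loci))
    return passing, flags
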