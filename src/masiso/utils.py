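"""Small shared primitives: sequence ops, seeded RNG substreams, rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA of the given length."""
    return "".join(np.array(list(DNA_ALPHABET))[rng.integers(0, 4, size=length)])


def substream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream derived from a single integer seed.

    Every stage of the pipeline draws from its own named substream so that
    re-running one stage with the same seed reproduces it independently of
    the others.
    """
    ss = np.random.SeedSequence(seed, spawn_key=tuple(name.encode()))
    return np.random.default_rng(ss)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at a fixed number of decimals.

    Printed percentages and fold changes in the outputs use conventional
    half-up rounding rather than banker's rounding.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
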