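"""Nucleotide-string helpers shared across the pipeline.

All sequences are handled internally in the DNA alphabet (ACGT, upper case);
RNA input (U) is normalised to T on entry. Duplex pairing helpers interpret
T as U.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")

VALID_CHARS = frozenset("ACGTN")


def normalize(seq: str) -> str:
    """Upper-case and map U->T; raise on characters outside ACGUTN."""
    s = seq.upper().replace("U", "T")
    if not set(s) <= VALID_CHARS:
        bad = sorted(set(s) - VALID_CHARS)
        raise ValueError(f"sequence contains non-ACGU/T/N symbols: {bad}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMP)


def is_watson_crick(a: str, b: str) -> bool:
    """True if bases a and b (both DNA-alphabet) form an A:U or G:C pair."""
    return (a, b) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def is_wobble(a: str, b: str) -> bool:
    """True for a G:U wobble pair (T standing in for U)."""
    return (a, b) in {("G", "T"), ("T", "G")}


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
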