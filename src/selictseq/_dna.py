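"""Small DNA sequence utilities shared across modules."""

from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGTNRYKMSWacgtn", "TGCANYRMKSWtgcan")

# IUPAC nucleotide codes -> set of concrete bases they admit
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

BASES = "ACGT"

# byte-level base -> small integer code (A=0 C=1 G=2 T=3, everything else 4)
BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    BASE_CODE[ord(_b)] = _i
    BASE_CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware for common codes)."""
    return seq.translate(COMPLEMENT)[::-1]


def iupac_match(pattern_char: str, base: str) -> bool:
    """True if ``base`` is admitted by the (possibly degenerate) pattern char."""
    allowed = IUPAC.get(pattern_char.upper())
    if allowed is None:
        raise ValueError(f"unknown IUPAC code {pattern_char!r}")
    return base.upper() in allowed


def matches_pattern(pattern: str, seq: str) -> bool:
    """True if ``seq`` matches an equal-length IUPAC ``pattern``."""
    return len(pattern) == len(seq) and all(
        iupac_match(p, b) for p, b in zip(pattern, seq)
    )


def seq_to_codes(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes (A=0 C=1 G=2 T=3, N/other=4)."""
    return BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
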