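"""Shared helpers: rounding, sequence validation, genetic code tables."""

from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_table = CodonTable.unambiguous_dna_by_id[1]  # standard code

#: codon -> amino acid, with '*' for the three stop codons
CODON_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_AA[_stop] = "*"

STOP_CODONS = frozenset(_table.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in CODON_AA if CODON_AA[c] != "*"))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention used in printed tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 2) -> float:
    """count/total as a percentage rounded half-up; total must be positive."""
    if total <= 0:
        raise ValueError("percent undefined for non-positive total")
    return round_half_up(100.0 * count / total, ndigits)


def validate_cds(cds: str, name: str = "sequence") -> str:
    """Check a coding sequence: ACGT only, length a multiple of 3, no internal stop.

    Returns the upper-cased sequence.
    """
    s = cds.upper()
    if not s:
        raise ValueError(f"{name}: empty coding sequence")
    if len(s) % 3 != 0:
        raise ValueError(f"{name}: CDS length {len(s)} is not a multiple of 3")
    bad = set(s) - set(NUCLEOTIDES)
    if bad:
        raise ValueError(f"{name}: non-ACGT characters {sorted(bad)}")
    codons = [s[i : i + 3] for i in range(0, len(s) - 3, 3)]  # internal only
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"{name}: internal stop codon {c} at codon {i + 1}")
    return s


def translate_cds(cds: str, name: str = "sequence") -> str:
    """Translate a validated frame-0 CDS; a terminal stop is dropped."""
    s = validate_cds(cds, name)
    aa = "".join(CODON_AA[s[i : i + 3]] for i in range(0, len(s), 3))
    return aa[:-1] if aa.endswith("*") else aa


def seq_to_ints(seq: str) -> np.ndarray:
    """Encode ACGT as 0..3 (uint8) for vectorised distance computations."""
    lut = np.full(128, 255, dtype=np.uint8)
    for i, b in enumerate(NUCLEOTIDES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    return arr


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Named sub-stream of a root seed.

    Each generator draws from its own stream so adding one simulator does not
    perturb the output of another under the same root seed.
    """
    tag = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), tag]))
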