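"""Small nucleotide-string utilities shared across the package.

Coordinates are 0-based half-open everywhere inside the package; report
writers convert to 1-based inclusive.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-transparent)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(rng: np.random.Generator, n: int) -> str:
    """i.i.d. uniform A/C/G/T string of length ``n``."""
    return "".join(rng.choice(list(BASES), size=n)) if n else ""


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply uniform substitutions at the given per-base rate.

    Each selected base is replaced by one of the three other bases with
    equal probability.  Indels are never introduced here.
    """
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    idx = np.flatnonzero(hit)
    for i in idx:
        base = arr[i].decode()
        choices = [b for b in BASES if b != base]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode()


def rotate(seq: str, offset: int) -> str:
    """Rotate a circular sequence string by ``offset`` positions."""
    if not seq:
        return seq
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


def rotation_canonical(seq: str) -> str:
    """Lexicographically least rotation (Booth's algorithm).

    Used as a content-based canonical form when comparing circle strings
    for rotation equivalence; the acceptor-rooted string remains the
    presentation form for isoforms.
    """
    if not seq:
        return seq
    s = seq + seq
    n = len(seq)
    i, j, k = 0, 1, 0
    while i < n and j < n and k < n:
        a, b = s[i + k], s[j + k]
        if a == b:
            k += 1
            continue
        if a > b:
            i = max(i + k + 1, j)
        else:
            j = max(j + k + 1, i)
        if i == j:
            j += 1
        k = 0
    start = min(i, j)
    return s[start : start + n]


def check_alphabet(seq: str, allowed: str = "ACGTN") -> None:
    bad = set(seq.upper()) - set(allowed)
    if bad:
        raise ValueError(f"non-{allowed} characters in sequence: {sorted(bad)}")
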