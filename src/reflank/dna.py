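"""Small DNA sequence helpers shared across the package."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string of the given length."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def random_seq_avoiding(rng: np.random.Generator, length: int,
                        forbidden: list[str], max_tries: int = 200) -> str:
    """Random DNA string containing none of the forbidden motifs.

    Resamples the offending window locally until clean; motifs must be short
    relative to `length` for this to terminate quickly.
    """
    seq = list(random_seq(rng, length))
    for _ in range(max_tries):
        s = "".join(seq)
        hit = None
        for motif in forbidden:
            i = s.find(motif)
            if i >= 0:
                hit = (i, len(motif))
                break
        if hit is None:
            return s
        i, m = hit
        for j in range(i, i + m):
            seq[j] = BASES[rng.integers(0, 4)]
    raise RuntimeError("could not purge forbidden motifs")


def mutate(rng: np.random.Generator, seq: str, rate: float,
           protect: set[int] | None = None) -> str:
    """Apply random substitutions at the given per-base rate.

    Positions in `protect` are never touched. Substitutions always change
    the base.
    """
    if rate <= 0:
        return seq
    out = list(seq)
    n_mut = rng.binomial(len(seq), rate)
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
    for p in positions:
        if protect and int(p) in protect:
            continue
        old = out[p]
        choices = [b for b in BASES if b != old]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
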