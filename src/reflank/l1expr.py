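"""Quantify transcription of retrotransposition-competent L1 copies.

Counting rule: a read pair contributes iff both mates align with 100%
identity (no mismatches or indels) to the same active-set element as a
proper pair — convergent mates within an insert-size bound — and identical
pairs are counted once. Exact matching confines the signal to transcripts
of intact elements; diverged (inactive) L1 transcripts fail somewhere in
every read-length window. Group differences are tested with the two-sided
Mann–Whitney U and Benjamini–Hochberg adjustment across the comparisons of
one invocation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import substream
from .dna import revcomp
from .simulate import L1Reference, ReadPair


# ---------------------------------------------------------------------------
# QC filtering (PRINSEQ-style) and batching
# ---------------------------------------------------------------------------

def _mean_qual(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual) if qual else 0.0


def qc_filter(pairs: list[ReadPair], min_mean_q: float = 20.0,
              max_n_pct: float = 3.0, dedup: bool = True,
              truncate_to: int | None = 75) -> list[ReadPair]:
    """Remove low-quality, N-rich and duplicate pairs; truncate to 75+75.

    A pair is removed when either mate's mean quality is strictly below
    ``min_mean_q`` or its N percentage exceeds ``max_n_pct``; duplicate
    removal is by exact concatenated mate sequence (quality-blind), first
    occurrence kept. Truncation happens before filtering, matching a
    trim-then-clean workflow.
    """
    out = []
    seen: set[str] = set()
    for p in pairs:
        if truncate_to is not None:
            p = ReadPair(p.read_id, p.seq1[:truncate_to], p.qual1[:truncate_to],
                         p.seq2[:truncate_to], p.qual2[:truncate_to],
                         p.source_molecule_id)
        if len(p.seq1) != len(p.qual1) or len(p.seq2) != len(p.qual2):
            raise ValueError(f"malformed record {p.read_id}: "
                             "sequence/quality length mismatch")
        if _mean_qual(p.qual1) < min_mean_q or _mean_qual(p.qual2) < min_mean_q:
            continue
        if any(100.0 * s.count("N") / max(1, len(s)) > max_n_pct
               for s in (p.seq1, p.seq2)):
            continue
        if dedup:
            key = p.seq1 + "\x00" + p.seq2
            if key in seen:
                continue
            seen.add(key)
        out.append(p)
    return out


@dataclass
class BatchResult:
    batches: list[list[ReadPair]]
    truncated: bool     # fewer pairs than one batch: single short batch


def batch_downsample(pairs: list[ReadPair], batch_size: int = 4_500_000,
                     seed: int = 0, count_reads: bool = True) -> BatchResult:
    """Deterministically shuffle and split into fixed-size batches.

    ``batch_size`` counts single reads when ``count_reads`` (a pair
    contributes two), matching read-based depth normalization; the
    incomplete trailing batch is discarded. When the input is smaller than
    one batch, the whole (shuffled) input is returned flagged truncated.
    """
    if not pairs:
        raise ValueError("no read pairs to batch")
    pairs_per_batch = batch_size // 2 if count_reads else batch_size
    rng = substream(seed, "batches")
    order = rng.permutation(len(pairs))
    shuffled = [pairs[i] for i in order]
    if len(shuffled) < pairs_per_batch:
        return BatchResult([shuffled], truncated=True)
    n = len(shuffled) // pairs_per_batch
    return BatchResult([shuffled[i * pairs_per_batch:(i + 1) * pairs_per_batch]
                        for i in range(n)], truncated=False)


# ---------------------------------------------------------------------------
# exact-match proper-pair counting
# ---------------------------------------------------------------------------

class _ExactIndex:
    """Seed-and-verify exact placement of reads on the active-element set."""

    def __init__(self, reference: L1Reference, k: int = 31):
        self.k = k
        self.elements = {eid: (seq, fam)
                         for eid, (seq, fam) in reference.active.items()}
        if not self.elements:
            raise ValueError("empty active-element reference")
        self.seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for eid, (seq, _fam) in self.elements.items():
            for i in range(len(seq) - k + 1):
                self.seeds[seq[i:i + k]].append((eid, i))

    def placements(self, read: str) -> list[tuple[str, int, str]]:
        """All (element, position, strand) with a full-length exact match."""
        out = []
        for strand, q in (("+", read), ("-", revcomp(read))):
            if len(q) < self.k:
                # short queries: brute force over elements
                for eid, (seq, _f) in self.elements.items():
                    j = seq.find(q)
                    while j >= 0:
                        out.append((eid, j, strand))
                        j = seq.find(q, j + 1)
                continue
            for eid, pos in self.seeds.get(q[:self.k], ()):  # noqa: B020
                seq = self.elements[eid][0]
                if seq[pos:pos + len(q)] == q:
                    out.append((eid, pos, strand))
        return out


def count_active_l1(pairs: list[ReadPair], reference: L1Reference,
                    insert_range: tuple[int, int] = (50, 600),
                    index: "_ExactIndex | None" = None) -> dict[str, int]:
    """Unique proper pairs aligned with 100% identity, per subfamily.

    Both mates must place exactly (zero mismatches/indels) on the same
    element with convergent orientation and an insert within
    ``insert_range``; identical pairs count once, and a pair counts at
    most once per subfamily however many elements it matches.
    """
    idx = index if index is not None else _ExactIndex(reference)
    counts = {fam: 0 for fam in
              sorted({f for _s, f in reference.active.values()})}
    seen: set[str] = set()
    for p in pairs:
        key = p.seq1 + "\x00" + p.seq2
        if key in seen:
            continue
        seen.add(key)
        p1 = idx.placements(p.seq1)
        if not p1:
            continue
        p2 = idx.placements(p.seq2)
        if not p2:
            continue
        hits2 = defaultdict(list)
        for eid, pos, strand in p2:
            hits2[eid].append((pos, strand))
        fams_hit = set()
        for eid, pos1, strand1 in p1:
            seq_len = {"m1": len(p.seq1), "m2": len(p.seq2)}
            for pos2, strand2 in hits2.get(eid, ()):
                if strand1 == strand2:
                    continue
                if strand1 == "+":
                    left, right = pos1, pos2 + seq_len["m2"]
                else:
                    left, right = pos2, pos1 + seq_len["m1"]
                insert = right - left
                if insert_range[0] <= insert <= insert_range[1] and left <= right:
                    fams_hit.add(idx.elements[eid][1])
        for fam in fams_hit:
            counts[fam] += 1
    return counts


def count_batches(batches: list[list[ReadPair]], reference: L1Reference,
                  sample_id: str = "", **kw) -> pd.DataFrame:
    """Per-batch, per-subfamily unique proper-pair counts."""
    idx = _ExactIndex(reference)
    rows = []
    for b, batch in enumerate(batches):
        for fam, n in count_active_l1(batch, reference, index=idx, **kw).items():
            rows.append({"sample_id": sample_id, "batch_id": b,
                         "subfamily": fam, "count": n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def mann_whitney_p(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U with exact nulls when tie-free.

    Degenerate pooled samples (zero rank variance) return p = 1 — no
    evidence of a shift when every observation ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        u = len(x) * len(y) / 2.0
        return u, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "asymptotic" if has_ties else "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float),
                         method="fdr_bh")[1]


def compare_groups(counts: dict[str, list[float]],
                   comparisons: list[tuple[str, str]] | None = None
                   ) -> pd.DataFrame:
    """Pairwise Mann–Whitney tests with BH adjustment across one invocation.

    ``counts`` maps group label to per-sample counts; all pairwise
    comparisons are run unless an explicit list is given. Every group needs
    at least two samples.
    """
    labels = list(counts)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab in labels:
        if len(counts[lab]) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(labels)
                       for b in labels[i + 1:]]
    rows = []
    for a, b in comparisons:
        u, p = mann_whitney_p(counts[a], counts[b])
        rows.append({"group_a": a, "group_b": b, "u_statistic": u,
                     "p_raw": p,
                     "median_a": float(np.median(counts[a])),
                     "median_b": float(np.median(counts[b]))})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bh_adjust(df["p_raw"].to_numpy())
    return df
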