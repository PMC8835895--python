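"""Q1 thresholding, discriminating-insertion selection, edit-tolerant
flank search and the scaled mixture experiment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reflank.config import MixtureDesign
from reflank.dna import random_seq, revcomp
from reflank.experiments import l1_mixture_config
from reflank.sensitivity import (build_donor_pair, q1_threshold,
                                 run_mixture_experiment, search_flanks,
                                 select_discriminating)


# ---------------------------------------------------------------------------
# Q1
# ---------------------------------------------------------------------------

def sort_interpolation_q1(values):
    """Oracle: type-7 quantile from first principles."""
    xs = sorted(values)
    h = (len(xs) - 1) * 0.25
    lo = int(np.floor(h))
    return xs[lo] + (h - lo) * (xs[min(lo + 1, len(xs) - 1)] - xs[lo])


def test_q1_worked_example():
    assert q1_threshold([1, 2, 3, 4]) == pytest.approx(1.75)


def test_q1_constant_list_and_order_invariance():
    assert q1_threshold([7, 7, 7, 7, 7]) == 7
    vals = [9, 1, 4, 100, 3]
    assert q1_threshold(vals) == q1_threshold(sorted(vals, reverse=True))


def test_q1_requires_four_counts():
    with pytest.raises(ValueError):
        q1_threshold([1, 2, 3])


@given(st.lists(st.integers(0, 10_000), min_size=4, max_size=60))
@settings(max_examples=1000, deadline=None)
def test_q1_matches_sort_interpolation_oracle(values):
    assert q1_threshold(values) == pytest.approx(
        sort_interpolation_q1(values))


# ---------------------------------------------------------------------------
# discriminating selection
# ---------------------------------------------------------------------------

def test_selection_boundaries():
    d1 = {"a": 10, "b": 9, "c": 100, "d": 10}
    d2 = {"a": 0, "b": 0, "c": 1, "d": 0}
    got = select_discriminating(d1, d2, q1=10)
    assert got == ["a", "d"]          # >= Q1 is inclusive; Q1-1 excluded
    # a locus missing from donor 2's table counts as zero reads
    assert select_discriminating({"x": 50}, {}, 10) == ["x"]


# ---------------------------------------------------------------------------
# flank search
# ---------------------------------------------------------------------------

def brute_force_edit_hit(flank, read, k):
    """Oracle: banded DP over every read substring boundary (full DP)."""
    m, n = len(flank), len(read)
    prev = [0] * (n + 1)         # free start position in read
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = flank[i - 1] != read[j - 1]
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return min(prev) <= k


def test_one_substitution_counts_two_edits_do_not(rng):
    flank = random_seq(rng, 30)
    one = flank[:10] + ("A" if flank[10] != "A" else "C") + flank[11:]
    read = random_seq(rng, 40) + one + random_seq(rng, 40)
    assert search_flanks([read], [flank], max_edits=1)[0] == 1
    two = list(one)
    two[20] = "A" if two[20] != "A" else "C"
    read2 = random_seq(rng, 40) + "".join(two) + random_seq(rng, 40)
    assert search_flanks([read2], [flank], max_edits=1)[0] == 0


def test_exact_search_equals_naive_substring_count(rng):
    flank = random_seq(rng, 25)
    reads = [random_seq(rng, 120) for _ in range(50)]
    reads[3] = reads[3][:40] + flank + reads[3][65:]
    reads[7] = flank + reads[7][25:]
    naive = sum(1 for r in reads if flank in r or revcomp(flank) in r)
    assert search_flanks(reads, [flank], max_edits=0)[0] == naive


def test_search_matches_brute_force_dp_oracle(rng):
    """1,000 random (flank, read) instances, mixed planted edit counts."""
    hits_seen = 0
    for i in range(1000):
        flank = random_seq(rng, int(rng.integers(15, 35)))
        read = random_seq(rng, 90)
        if i % 3 == 0:
            q = list(flank)
            for _ in range(int(rng.integers(0, 3))):
                op = rng.integers(0, 3)
                p = int(rng.integers(0, len(q)))
                if op == 0:
                    q[p] = "ACGT"[rng.integers(0, 4)]
                elif op == 1 and len(q) > 2:
                    del q[p]
                else:
                    q.insert(p, "ACGT"[rng.integers(0, 4)])
            pos = int(rng.integers(0, 50))
            read = read[:pos] + "".join(q) + read[pos + len(q):]
        expected = brute_force_edit_hit(flank, read, 1) or \
            brute_force_edit_hit(revcomp(flank), read, 1)
        got = bool(search_flanks([read], [flank], max_edits=1)[0])
        assert got == expected
        hits_seen += got
    assert 0 < hits_seen < 1000


def test_each_read_counted_at_most_once_per_flank(rng):
    flank = random_seq(rng, 25)
    read = flank + "AAAA" + flank     # two occurrences, one read
    assert search_flanks([read], [flank])[0] == 1


# ---------------------------------------------------------------------------
# mixture experiment limit cases (scaled sizes)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_pair():
    cfg = l1_mixture_config(seed=19)
    cfg.sim.n_cells = 30
    return cfg, build_donor_pair(cfg, n_private_donor1=4, n_private_donor2=2,
                                 n_shared=2)


def test_pure_minor_sample_detects_everything(tiny_pair):
    cfg, pair = tiny_pair
    design = MixtureDesign(n_cells_minor=60, n_cells_major=0, depth=4000,
                           n_replicates=1)
    rep = run_mixture_experiment(pair, design, cfg, seed=1,
                                 insertion_ids=pair.donor1_private)
    assert all(f == 1.0 for f in rep.detection_fraction.values())


def test_zero_minor_cells_detect_nothing(tiny_pair):
    cfg, pair = tiny_pair
    design = MixtureDesign(n_cells_minor=0, n_cells_major=400, depth=4000,
                           n_replicates=1)
    rep = run_mixture_experiment(pair, design, cfg, seed=1,
                                 insertion_ids=pair.donor1_private)
    assert all(f == 0.0 for f in rep.detection_fraction.values())


def test_detection_monotone_in_depth_with_common_reads(tiny_pair):
    cfg, pair = tiny_pair
    design = MixtureDesign(n_cells_minor=6, n_cells_major=400, depth=3000,
                           n_replicates=2)
    rep = run_mixture_experiment(pair, design, cfg, seed=3,
                                 insertion_ids=pair.donor1_private,
                                 depths=[300, 1000, 3000])
    for r in range(design.n_replicates):
        fr = [rep.detection_fraction[(r, d)] for d in (300, 1000, 3000)]
        assert fr == sorted(fr)
    for d in (300, 1000, 3000):
        per_rep = [rep.detection_fraction[(r, d)] for r in range(2)]
        assert rep.intersection_fraction[d] <= min(per_rep)


def test_empty_discriminating_set_rejected(tiny_pair):
    cfg, pair = tiny_pair
    with pytest.raises(ValueError):
        run_mixture_experiment(pair, MixtureDesign(), cfg, 0,
                               insertion_ids=[])
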