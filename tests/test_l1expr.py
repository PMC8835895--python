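"""Active-L1 expression: QC, batching, exact-match counting, statistics."""

import itertools

import numpy as np
import pytest

from reflank.l1expr import (batch_downsample, bh_adjust, compare_groups,
                            count_active_l1, mann_whitney_p, qc_filter)
from reflank.simulate import ReadPair, simulate_rnaseq


def pair(seq1, seq2, q1=None, q2=None, rid="r"):
    q1 = q1 or chr(33 + 30) * len(seq1)
    q2 = q2 or chr(33 + 30) * len(seq2)
    return ReadPair(rid, seq1, q1, seq2, q2)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_mean_quality_threshold_is_strict():
    just_below = chr(33 + 19) * 36 + chr(33 + 20) * 39  # mean 19.52
    at = chr(33 + 20) * 75
    bad = pair("A" * 75, "C" * 75, q2=just_below)
    good = pair("A" * 75, "C" * 75, q2=at)
    kept = qc_filter([bad, good], truncate_to=75)
    assert kept == [good]


def test_duplicate_pairs_collapse_to_first():
    a = pair("ACGT" * 19, "TTTT" * 19, rid="a")
    b = pair("ACGT" * 19, "TTTT" * 19, rid="b")
    kept = qc_filter([a, b], truncate_to=None)
    assert [p.read_id for p in kept] == ["a"]


def test_reads_truncated_to_75():
    p = pair("A" * 80, "C" * 80)
    kept = qc_filter([p])
    assert len(kept[0].seq1) == 75 and len(kept[0].qual2) == 75


def test_n_fraction_filter():
    ok = pair("A" * 73 + "NN", "C" * 75)      # 2.7% N
    bad = pair("A" * 72 + "NNN", "C" * 75)    # 4% N
    assert qc_filter([ok, bad]) == [ok]


def test_malformed_record_raises():
    with pytest.raises(ValueError, match="malformed"):
        qc_filter([ReadPair("x", "ACGT", "II", "ACGT", "IIII")],
                  truncate_to=None)


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

def test_batches_are_exact_and_trailing_discarded():
    pairs = list(range(10_000))   # pair objects are opaque to the splitter
    res = batch_downsample(pairs, batch_size=4_000, seed=5)
    assert len(res.batches) == 5 and not res.truncated
    assert all(len(b) == 2_000 for b in res.batches)
    flat = list(itertools.chain.from_iterable(res.batches))
    assert len(set(flat)) == len(flat)


def test_fewer_than_one_batch_flags_truncation():
    res = batch_downsample(list(range(999)), batch_size=4_000, seed=0)
    assert res.truncated and len(res.batches) == 1
    assert len(res.batches[0]) == 999


def test_batch_membership_deterministic_in_seed():
    pairs = list(range(5_000))
    a = batch_downsample(pairs, batch_size=2_000, seed=3)
    b = batch_downsample(pairs, batch_size=2_000, seed=3)
    c = batch_downsample(pairs, batch_size=2_000, seed=4)
    assert a.batches == b.batches
    assert a.batches != c.batches


# ---------------------------------------------------------------------------
# exact-match proper-pair counting
# ---------------------------------------------------------------------------

def test_verbatim_pair_counts_once(l1_reference):
    eid, (seq, fam) = next(iter(l1_reference.active.items()))
    from reflank.dna import revcomp
    m1 = seq[100:175]
    m2 = revcomp(seq[300:375])
    counts = count_active_l1([pair(m1, m2)], l1_reference)
    assert counts[fam] == 1
    assert sum(counts.values()) == 1


def test_single_mismatch_excludes_pair(l1_reference):
    eid, (seq, fam) = next(iter(l1_reference.active.items()))
    from reflank.dna import revcomp
    m1 = list(seq[100:175])
    m1[40] = "A" if m1[40] != "A" else "C"
    m2 = revcomp(seq[300:375])
    counts = count_active_l1([pair("".join(m1), m2)], l1_reference)
    assert sum(counts.values()) == 0


def test_pair_matching_many_elements_counts_once():
    from reflank.dna import revcomp
    from reflank.simulate import L1Reference
    from reflank.dna import random_seq
    rng = np.random.default_rng(8)
    core = random_seq(rng, 600)
    # three elements sharing the core: multi-matching pair
    ref = L1Reference({f"L1PA2_{i}": (random_seq(rng, 50) + core, "L1PA2")
                       for i in range(3)}, {})
    m1 = core[10:85]
    m2 = revcomp(core[200:275])
    assert count_active_l1([pair(m1, m2)], ref)["L1PA2"] == 1


def test_improper_orientation_or_insert_rejected(l1_reference):
    eid, (seq, fam) = next(iter(l1_reference.active.items()))
    from reflank.dna import revcomp
    same_strand = [pair(seq[100:175], seq[300:375])]
    assert sum(count_active_l1(same_strand, l1_reference).values()) == 0
    too_far = [pair(seq[0:75], revcomp(seq[800:875]))]
    assert sum(count_active_l1(too_far, l1_reference).values()) == 0


def test_counting_matches_brute_force_oracle(l1_reference, rng):
    """Simulated batch against an oracle that scans every element with
    exhaustive substring placement."""
    from reflank.dna import revcomp
    ab = {k: 1.0 for k in list(l1_reference.active)[:4]}
    ab |= {k: 2.0 for k in list(l1_reference.decoys)[:4]}
    reads, truth = simulate_rnaseq(l1_reference, ab, 400, seed=11,
                                   duplicate_fraction=0.3)
    got = count_active_l1(reads, l1_reference)

    def placements(read, seq):
        out = []
        for strand, q in (("+", read), ("-", revcomp(read))):
            start = seq.find(q)
            while start >= 0:
                out.append((start, strand))
                start = seq.find(q, start + 1)
        return out

    expected = {fam: 0 for fam in got}
    seen = set()
    for p in reads:
        key = (p.seq1, p.seq2)
        if key in seen:
            continue
        seen.add(key)
        fams = set()
        for eid, (seq, fam) in l1_reference.active.items():
            for pos1, s1 in placements(p.seq1, seq):
                for pos2, s2 in placements(p.seq2, seq):
                    if s1 == s2:
                        continue
                    left = pos1 if s1 == "+" else pos2
                    right = (pos2 + len(p.seq2)) if s1 == "+" \
                        else (pos1 + len(p.seq1))
                    if 50 <= right - left <= 600:
                        fams.add(fam)
        for fam in fams:
            expected[fam] += 1
    assert got == expected
    assert sum(got.values()) > 0


def test_monotonicity_of_counts(l1_reference):
    from reflank.dna import revcomp
    eid, (seq, fam) = next(iter(l1_reference.active.items()))
    batch = [pair(seq[i:i + 75], revcomp(seq[i + 150:i + 225]), rid=f"r{i}")
             for i in range(5)]
    base = count_active_l1(batch, l1_reference)[fam]
    more = batch + [pair(seq[400:475], revcomp(seq[500:575]), rid="new")]
    assert count_active_l1(more, l1_reference)[fam] == base + 1
    noise = batch + [pair("A" * 75, "C" * 75, rid="junk")]
    assert count_active_l1(noise, l1_reference)[fam] == base


def test_empty_reference_rejected():
    from reflank.simulate import L1Reference
    with pytest.raises(ValueError):
        count_active_l1([pair("A" * 75, "C" * 75)], L1Reference({}, {}))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def test_identical_groups_give_p_one():
    assert mann_whitney_p([5, 5, 5], [5, 5, 5])[1] == 1.0


def test_exact_p_small_groups():
    # all 20 orderings enumerable: perfect separation of 3 vs 3
    assert mann_whitney_p([1, 2, 3], [10, 11, 12])[1] == pytest.approx(0.1)


def test_mann_whitney_matches_exhaustive_permutation(rng):
    """Exact two-sided p against full enumeration for groups up to (4,4)."""
    import itertools as it
    for _ in range(60):
        nx, ny = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        pooled = rng.choice(10_000, size=nx + ny, replace=False).astype(float)
        x, y = pooled[:nx], pooled[nx:]
        u_obs, p_obs = mann_whitney_p(x, y)

        def u_stat(xs, ys):
            return sum(1 for a in xs for b in ys if a > b) + \
                0.5 * sum(1 for a in xs for b in ys if a == b)

        null = []
        for combo in it.combinations(range(nx + ny), nx):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(nx + ny) if i not in combo]
            null.append(u_stat(xs, ys))
        mu = nx * ny / 2
        obs_dev = abs(u_stat(x, y) - mu)
        p_exact = np.mean([abs(u - mu) >= obs_dev - 1e-12 for u in null])
        assert p_obs == pytest.approx(p_exact, abs=1e-12)


def test_bh_step_up_hand_example():
    assert bh_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])
    # general property: adjusted >= raw, within [0, 1], monotone in rank
    raw = [0.001, 0.02, 0.04, 0.9]
    adj = bh_adjust(raw)
    assert np.all(adj >= np.asarray(raw)) and np.all(adj <= 1)


def test_compare_groups_requires_two_samples_each():
    with pytest.raises(ValueError):
        compare_groups({"A": [1], "B": [2, 3]})


def test_compare_groups_bh_family_is_one_invocation():
    df = compare_groups({"A": [1, 2, 3], "B": [10, 11, 12],
                         "C": [1.5, 2.5, 3.5]},
                        comparisons=[("A", "B"), ("A", "C")])
    assert list(df["p_adjusted"]) == list(bh_adjust(df["p_raw"]))
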