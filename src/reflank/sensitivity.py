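"""Mixture-based sensitivity evaluation of the flank-seq assay.

The protocol: identify polymorphic L1 insertions private to donor 1 with
read count at least the first quartile (Q1) of the fixed-insertion counts
and zero reads in donor 2; mix donor-1 cells into donor-2 cells at ~1:100;
sequence; and search each discriminating flank in the raw reads allowing
one mismatch or indel. An insertion is detected with >= 2 matching reads
(the raw-read criterion); the >= 2-distinct-UMI criterion is reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .config import MixtureDesign, PipelineConfig, STEM_REMNANT, substream
from .dna import revcomp
from .mapping import GenomeIndex
from .pipeline import process_sample
from .simulate import (MiniGenome, amplify_and_sequence, build_mini_genome,
                       generate_molecule_pool)


def q1_threshold(counts) -> float:
    """First quartile of fixed-insertion read counts.

    Linear-interpolation (type-7) quantile; order-invariant; requires at
    least four observations.
    """
    arr = np.asarray(list(counts), dtype=float)
    if arr.size < 4:
        raise ValueError("Q1 requires at least 4 read counts")
    return float(np.percentile(arr, 25, method="linear"))


def select_discriminating(donor1_counts: dict[str, float],
                          donor2_counts: dict[str, float],
                          q1: float) -> list[str]:
    """Loci with read count >= Q1 in donor 1 and exactly 0 in donor 2.

    Loci absent from a metatable count as zero reads in that donor.
    """
    out = [locus for locus, c1 in donor1_counts.items()
           if c1 >= q1 and donor2_counts.get(locus, 0) == 0]
    return sorted(out)


def _matches(flank: str, read_seq: str, max_edits: int) -> bool:
    r = edlib.align(flank, read_seq, mode="HW", task="distance", k=max_edits)
    return r["editDistance"] != -1


def search_flanks(read_seqs: list[str], flanks: list[str],
                  max_edits: int = 1, search_rc: bool = True) -> np.ndarray:
    """Per-flank counts of reads containing the flank within an edit budget.

    Substring (infix) alignment with <= ``max_edits`` mismatches or indels;
    the reverse complement is searched too; each read counts at most once
    per flank.
    """
    queries = [(f, revcomp(f)) for f in flanks]
    counts = np.zeros(len(flanks), dtype=int)
    for seq in read_seqs:
        for i, (f, rc) in enumerate(queries):
            if _matches(f, seq, max_edits) or \
                    (search_rc and _matches(rc, seq, max_edits)):
                counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# donor pair construction and metatables
# ---------------------------------------------------------------------------

@dataclass
class DonorPair:
    """Two individuals sharing a reference but with private polymorphic
    insertions; donor 1 carries the discriminating candidates."""

    donor1: MiniGenome
    donor2: MiniGenome

    @property
    def donor1_private(self) -> list[str]:
        d2 = {u.event.event_id for u in self.donor2.units}
        return sorted(u.event.event_id for u in self.donor1.units
                      if u.event.category == "polymorphic_germline"
                      and u.event.event_id not in d2)


def build_donor_pair(cfg: PipelineConfig, n_private_donor1: int = 12,
                     n_private_donor2: int = 6, n_shared: int = 4) -> DonorPair:
    """Build two donor genomes over one reference backbone.

    Donor 1 receives ``n_private_donor1`` private polymorphic insertions of
    the amplified families (the pool from which discriminating insertions
    are drawn), donor 2 its own private set, and both share ``n_shared``.
    """
    # both donors come from one genome built with enough polymorphic events;
    # partitioning its insertions guarantees a shared backbone and identical
    # reference-copy coordinates
    sim = cfg.sim
    n_total = n_private_donor1 + n_private_donor2 + n_shared
    per_family = -(-n_total // len(sim.families))  # ceil
    from dataclasses import replace as dc_replace
    sim_all = dc_replace(sim, n_polymorphic_per_family=per_family)
    full = build_mini_genome(sim_all)
    poly = [u for u in full.units if u.event.category == "polymorphic_germline"]
    rng = substream(sim.seed, "donor-split")
    order = rng.permutation(len(poly))
    poly = [poly[i] for i in order]
    p1 = poly[:n_private_donor1]
    p2 = poly[n_private_donor1:n_private_donor1 + n_private_donor2]
    sh = poly[n_private_donor1 + n_private_donor2:
              n_private_donor1 + n_private_donor2 + n_shared]
    refs = full.units_by_category("reference")

    def make(units):
        g = MiniGenome(full.contig, full.reference, full.annotations,
                       [u.event for u in units], list(units), full.panels,
                       full.config)
        return g

    return DonorPair(make(refs + p1 + sh), make(refs + p2 + sh))


def donor_metatable(genome: MiniGenome, cfg: PipelineConfig, tag: str,
                    depth: int) -> dict[str, int]:
    """Per-insertion read counts from an individual donor library.

    The donor library is sequenced, parsed, mapped and clustered; each
    truth insertion is assigned the read count of the nearest call of its
    family within the cluster window (zero when absent).
    """
    sim = cfg.sim
    pool = generate_molecule_pool(genome, sim, "normal",
                                  rng=substream(sim.seed, f"mt-pool:{tag}"))
    lib = amplify_and_sequence(pool, sim, rng=substream(sim.seed, f"mt-seq:{tag}"),
                               depth=depth, annotations=genome.annotations,
                               reference=genome.reference)
    index = GenomeIndex(genome)
    sample = process_sample(lib, index, cfg, tag)
    table = {}
    for u in genome.units:
        ev = u.event
        best = 0
        for c in sample.calls:
            if c.family == ev.family and abs(c.junction - ev.junction) <= cfg.cluster_window:
                best = max(best, c.read_count)
        table[ev.event_id] = best
    return table


# ---------------------------------------------------------------------------
# the mixture experiment
# ---------------------------------------------------------------------------

@dataclass
class SensitivityReport:
    """Detection outcomes of discriminating insertions in mixture replicates."""

    design: MixtureDesign
    insertion_ids: list[str]
    per_replicate: pd.DataFrame       # insertion_id, replicate, depth, reads, umis, detected
    detection_fraction: dict[tuple[int, int], float] = field(default_factory=dict)
    intersection_fraction: dict[int, float] = field(default_factory=dict)


def run_mixture_experiment(pair: DonorPair, design: MixtureDesign,
                           cfg: PipelineConfig, seed: int,
                           insertion_ids: list[str] | None = None,
                           depths: list[int] | None = None) -> SensitivityReport:
    """Simulate donor-1-into-donor-2 cell mixtures and score detection.

    Reads are drawn once per replicate at the largest requested depth;
    shallower depths are read prefixes, so detection is non-decreasing in
    depth by construction (common random numbers). Detection per insertion:
    >= ``design.min_detect_reads`` raw reads matching its flank within
    ``design.max_edits`` edits; the UMI criterion counts distinct UMIs among
    matching reads.
    """
    ids = insertion_ids if insertion_ids is not None else pair.donor1_private
    if not ids:
        raise ValueError("no discriminating insertions to score")
    depths = sorted(depths or [design.depth])
    sim = cfg.sim
    flanks = []
    for eid in ids:
        unit = next(u for u in pair.donor1.units if u.event.event_id == eid)
        flanks.append(unit.flank_mol[:design.flank_search_length])

    rows = []
    umi_off = len(STEM_REMNANT)
    for rep in range(design.n_replicates):
        rng = substream(seed, f"mixture:rep{rep}")
        pool1 = generate_molecule_pool(pair.donor1, sim, "normal", rng=rng,
                                       n_cells=design.n_cells_minor)
        pool2 = generate_molecule_pool(pair.donor2, sim, "normal", rng=rng,
                                       n_cells=design.n_cells_major)
        pool = pool1 + pool2
        lib = amplify_and_sequence(pool, sim, rng=rng, depth=max(depths),
                                   annotations=pair.donor1.annotations,
                                   reference=pair.donor1.reference)
        # per-read matches once at full depth; prefix-evaluate per depth
        match_read_idx: list[list[int]] = [[] for _ in ids]
        for ri, read in enumerate(lib.reads):
            for fi, flank in enumerate(flanks):
                rc = revcomp(flank)
                if _matches(flank, read.seq1, design.max_edits) \
                        or _matches(rc, read.seq1, design.max_edits) \
                        or _matches(flank, read.seq2, design.max_edits) \
                        or _matches(rc, read.seq2, design.max_edits):
                    match_read_idx[fi].append(ri)
        for depth in depths:
            for fi, eid in enumerate(ids):
                hits = [ri for ri in match_read_idx[fi] if ri < depth]
                umis = {lib.reads[ri].seq2[umi_off:umi_off + sim.umi_length]
                        for ri in hits}
                rows.append({"insertion_id": eid, "replicate": rep,
                             "depth": depth, "reads": len(hits),
                             "umis": len(umis),
                             "detected": len(hits) >= design.min_detect_reads,
                             "detected_umi": len(umis) >= design.min_detect_umis})
    table = pd.DataFrame(rows)
    report = SensitivityReport(design, list(ids), table)
    for (rep, depth), sub in table.groupby(["replicate", "depth"]):
        report.detection_fraction[(int(rep), int(depth))] = \
            float(sub["detected"].mean())
    for depth, sub in table.groupby("depth"):
        both = sub.groupby("insertion_id")["detected"].all()
        report.intersection_fraction[int(depth)] = float(both.mean())
    return report
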