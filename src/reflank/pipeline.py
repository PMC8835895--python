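"""End-to-end drivers: simulate, parse, map, filter, classify, call.

These functions are the programmatic pipeline behind the CLI; every stage
consumes and returns plain objects so tests and analyses can enter at any
point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig, substream
from .mapping import (GenomeIndex, InsertionCall, cluster_calls,
                      filter_chimeras, map_records)
from .readproc import SpecificityReport, compute_specificity, parse_library
from .simulate import (MiniGenome, SequencedLibrary, amplify_and_sequence,
                       build_mini_genome, generate_molecule_pool)
from .somatic import KnownInsertionDB, call_candidates, classify_calls


@dataclass
class SampleResult:
    """Everything derived from one sequenced sample."""

    sample_id: str
    library: SequencedLibrary
    specificity: SpecificityReport
    calls: list[InsertionCall]


@dataclass
class PairResult:
    """Matched tumor/normal run: per-sample results plus candidates."""

    genome: MiniGenome
    tumor: SampleResult
    normal: SampleResult
    candidates: list[InsertionCall]
    truth_somatic: dict[str, int] = field(default_factory=dict)


def process_sample(library: SequencedLibrary, index: GenomeIndex,
                   cfg: PipelineConfig, sample_id: str) -> SampleResult:
    """Parse reads, compute specificity, map, cluster and filter chimeras."""
    records = parse_library(library.reads, index.genome.panels, cfg)
    spec = compute_specificity(records)
    mapped = map_records(records, index, cfg)
    calls = cluster_calls(mapped, sample_id, cfg.cluster_window)
    calls = filter_chimeras(calls, index, cfg)
    return SampleResult(sample_id, library, spec, calls)


def sequence_sample(genome: MiniGenome, cfg: PipelineConfig, role: str,
                    seed_tag: str, depth: int | None = None,
                    n_cells: int | None = None,
                    somatic_carrier_u: dict[str, np.ndarray] | None = None
                    ) -> SequencedLibrary:
    sim = cfg.sim
    pool = generate_molecule_pool(
        genome, sim, role, rng=substream(sim.seed, f"pool:{seed_tag}"),
        somatic_carrier_u=somatic_carrier_u, n_cells=n_cells)
    return amplify_and_sequence(
        pool, sim, rng=substream(sim.seed, f"seq:{seed_tag}"), depth=depth,
        annotations=genome.annotations, reference=genome.reference)


def run_pair(cfg: PipelineConfig, genome: MiniGenome | None = None,
             pair_id: str = "P0",
             extra_cohort: KnownInsertionDB | None = None) -> PairResult:
    """Simulate and call one matched tumor/normal pair.

    The tumor library carries the configured somatic events; the matched
    normal shares the germline genome. Candidates are tumor-only,
    database-absent, cohort-absent calls with >= min_umi distinct UMIs.
    """
    if genome is None:
        genome = build_mini_genome(cfg.sim)
    index = GenomeIndex(genome)
    tumor_lib = sequence_sample(genome, cfg, "tumor", f"{pair_id}:tumor")
    normal_lib = sequence_sample(genome, cfg, "normal", f"{pair_id}:normal")
    tumor = process_sample(tumor_lib, index, cfg, f"{pair_id}_tumor")
    normal = process_sample(normal_lib, index, cfg, f"{pair_id}_normal")
    db = KnownInsertionDB.from_genome(genome)
    if extra_cohort is not None:
        db.cohort |= extra_cohort.cohort
    classify_calls(tumor.calls, db, cfg.cluster_window)
    classify_calls(normal.calls, db, cfg.cluster_window)
    candidates = call_candidates(tumor.calls, normal.calls, db,
                                 cfg.min_umi, cfg.cluster_window)
    truth = {u.event.event_id: u.event.junction
             for u in genome.units if u.event.category == "somatic"}
    return PairResult(genome, tumor, normal, candidates, truth)


def candidates_table(result: PairResult) -> pd.DataFrame:
    rows = [{"sample_id": c.sample_id, "family": c.family, "contig": c.contig,
             "junction": c.junction, "strand": c.strand,
             "umi_count": c.umi_count, "read_count": c.read_count,
             "classification": "candidate"} for c in result.candidates]
    return pd.DataFrame(rows, columns=["sample_id", "family", "contig",
                                       "junction", "strand", "umi_count",
                                       "read_count", "classification"])


def match_candidates_to_truth(result: PairResult,
                              window: int = 10) -> dict[str, bool]:
    """Which planted somatic events are recovered within the window."""
    out = {}
    for eid, junction in result.truth_somatic.items():
        fam = result.genome.event(eid).family
        out[eid] = any(c.family == fam and abs(c.junction - junction) <= window
                       for c in result.candidates)
    return out
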