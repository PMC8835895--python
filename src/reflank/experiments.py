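"""Study-level experiments composing the pipeline stages.

Each function runs one of the package's headline analyses at a stated
problem size and returns plain results; the numbered scripts under
``analysis/`` are thin drivers over these.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (FamilySpec, MixtureDesign, PipelineConfig, SimConfig,
                     SomaticEventSpec, substream)
from .l1expr import compare_groups, count_active_l1
from .pipeline import run_pair
from .sensitivity import (SensitivityReport, build_donor_pair,
                          donor_metatable, q1_threshold,
                          run_mixture_experiment, select_discriminating)
from .simulate import make_l1_reference, simulate_rnaseq


# ---------------------------------------------------------------------------
# cohort negative control (the central finding: no somatic insertions)
# ---------------------------------------------------------------------------

def negative_control_cohort(n_pairs: int = 20, base_seed: int = 0,
                            n_cells: int = 80, depth: int = 12_000
                            ) -> pd.DataFrame:
    """Matched tumor/normal pairs with germline polymorphism, realistic
    chimera rates and zero somatic events; reports candidates per pair.

    Germline leakage is the fraction of pairs with any candidate — the
    somatic caller's false-positive control.
    """
    rows = []
    for i in range(n_pairs):
        cfg = PipelineConfig(sim=SimConfig(seed=base_seed + 1000 + i,
                                           n_cells=n_cells, depth=depth))
        res = run_pair(cfg, pair_id=f"NC{i}")
        spec = res.tumor.specificity.per_family
        rows.append({
            "pair": i, "n_candidates": len(res.candidates),
            "n_tumor_calls": len(res.tumor.calls),
            "n_normal_calls": len(res.normal.calls),
            **{f"specificity_{f}": round(d["specificity"], 4)
               for f, d in spec.items() if f != "unassigned"}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# positive control: somatic recovery across cell fractions and depths
# ---------------------------------------------------------------------------

def positive_control_titration(cell_fractions=(1.0, 0.1, 0.01),
                               depths=(6_000, 12_000, 25_000),
                               n_seeds: int = 10, base_seed: int = 0,
                               n_cells: int = 200) -> pd.DataFrame:
    """Plant one somatic L1HS insertion per run and score its recovery.

    Carrier-cell draws share one uniform vector per seed, and reads at
    shallower depths are prefixes of the deepest run, so detection is
    monotone non-decreasing in both cell fraction and depth run-by-run.
    """
    rows = []
    for s in range(n_seeds):
        seed = base_seed + 2000 + s
        u = substream(seed, "carriers").random(n_cells)
        for cf in sorted(cell_fractions):
            cfg = PipelineConfig(sim=SimConfig(
                seed=seed, n_cells=n_cells, depth=max(depths),
                tumor_blast_fraction=1.0,
                somatic_events=[SomaticEventSpec("L1HS", cf)]))
            res = run_pair_with_depths(cfg, {"som_0": u}, sorted(depths))
            for depth, recovered in res.items():
                rows.append({"seed": s, "cell_fraction": cf, "depth": depth,
                             "recovered": recovered})
    return pd.DataFrame(rows)


def run_pair_with_depths(cfg: PipelineConfig,
                         somatic_carrier_u: dict[str, np.ndarray],
                         depths: list[int]) -> dict[int, bool]:
    """Call one pair at several depths using prefix reads (common numbers)."""
    from .mapping import GenomeIndex
    from .pipeline import process_sample
    from .simulate import (SequencedLibrary, amplify_and_sequence,
                           build_mini_genome, generate_molecule_pool)
    from .somatic import KnownInsertionDB, call_candidates, classify_calls

    sim = cfg.sim
    genome = build_mini_genome(sim)
    index = GenomeIndex(genome)
    pool_t = generate_molecule_pool(genome, sim, "tumor",
                                    rng=substream(sim.seed, "pool:tumor"),
                                    somatic_carrier_u=somatic_carrier_u)
    pool_n = generate_molecule_pool(genome, sim, "normal",
                                    rng=substream(sim.seed, "pool:normal"))
    lib_t = amplify_and_sequence(pool_t, sim, rng=substream(sim.seed, "seq:t"),
                                 depth=max(depths),
                                 annotations=genome.annotations,
                                 reference=genome.reference)
    lib_n = amplify_and_sequence(pool_n, sim, rng=substream(sim.seed, "seq:n"),
                                 depth=max(depths),
                                 annotations=genome.annotations,
                                 reference=genome.reference)
    db = KnownInsertionDB.from_genome(genome)
    truth = {u.event.event_id: u.event.junction
             for u in genome.units if u.event.category == "somatic"}
    out = {}
    for depth in depths:
        t = process_sample(SequencedLibrary(lib_t.reads[:depth],
                                            lib_t.truth.iloc[:depth]),
                           index, cfg, "t")
        n = process_sample(SequencedLibrary(lib_n.reads[:depth],
                                            lib_n.truth.iloc[:depth]),
                           index, cfg, "n")
        classify_calls(t.calls, db, cfg.cluster_window)
        classify_calls(n.calls, db, cfg.cluster_window)
        cands = call_candidates(t.calls, n.calls, db, cfg.min_umi,
                                cfg.cluster_window)
        out[depth] = all(
            any(c.family == genome.event(eid).family
                and abs(c.junction - j) <= cfg.cluster_window for c in cands)
            for eid, j in truth.items())
    return out


# ---------------------------------------------------------------------------
# mixture sensitivity (Q1 selection + 1:100 mixture)
# ---------------------------------------------------------------------------

@dataclass
class MixtureStudy:
    q1: float
    n_discriminating: int
    discriminating: list[str]
    report: SensitivityReport


def l1_mixture_config(seed: int) -> PipelineConfig:
    """L1-only protocol configuration, as in the wet sensitivity experiment."""
    sim = SimConfig(seed=seed,
                    families=[FamilySpec("L1HS", 1000, "3p",
                                         ("TaqI", "FspBI"))],
                    n_reference_res_per_family=6)
    return PipelineConfig(sim=sim)


def mixture_sensitivity_study(seed: int = 0,
                              design: MixtureDesign | None = None,
                              metatable_depth: int = 20_000,
                              depths: list[int] | None = None) -> MixtureStudy:
    """The full sensitivity protocol on two synthetic donors.

    Individual donor libraries give per-insertion read counts; Q1 of the
    fixed (reference) insertion counts selects discriminating polymorphic
    insertions (>= Q1 in donor 1, zero in donor 2); the cell mixture is
    sequenced and each discriminating flank searched with one allowed edit.
    """
    cfg = l1_mixture_config(seed)
    pair = build_donor_pair(cfg, n_private_donor1=12, n_private_donor2=6,
                            n_shared=4)
    mt1 = donor_metatable(pair.donor1, cfg, "donor1", metatable_depth)
    mt2 = donor_metatable(pair.donor2, cfg, "donor2", metatable_depth)
    fixed = [c for eid, c in mt1.items() if eid.startswith("ref_")]
    q1 = q1_threshold(fixed)
    private1 = set(pair.donor1_private)
    disc = select_discriminating(
        {k: v for k, v in mt1.items() if k in private1},
        {k: mt2.get(k, 0) for k in private1}, q1)
    design = design or MixtureDesign(n_cells_minor=40, n_cells_major=4000,
                                     depth=3000)
    report = run_mixture_experiment(pair, design, cfg, seed=seed,
                                    insertion_ids=disc,
                                    depths=depths or [design.depth])
    return MixtureStudy(q1, len(disc), disc, report)


# ---------------------------------------------------------------------------
# expression contrast (active-L1 transcription, group comparison)
# ---------------------------------------------------------------------------

@dataclass
class ExpressionContrast:
    counts: pd.DataFrame          # sample, group, subfamily, count
    comparison: pd.DataFrame      # per-subfamily U, raw and adjusted p


def expression_contrast(seed: int = 0, n_per_group: int = 7,
                        n_pairs: int = 3000, fold_b: float = 2.0,
                        biological_sigma: float = 0.3,
                        active_share: float = 0.2,
                        duplicate_fraction: float = 0.1,
                        per_base_error: float = 0.002,
                        reference=None) -> ExpressionContrast:
    """Two groups of polyA RNA-seq libraries differing in active-L1 output.

    Group B's active-element abundances are ``fold_b`` times group A's;
    decoy (inactive, diverged) transcripts form the background. Per-sample
    active output varies log-normally with ``biological_sigma``. Both
    subfamily contrasts are BH-adjusted in one family.
    """
    ref = reference if reference is not None else make_l1_reference(seed=97)
    rng = substream(seed, "expr-groups")
    rows = []
    for group, fold in (("A", 1.0), ("B", fold_b)):
        for s in range(n_per_group):
            scale = fold * float(np.exp(rng.normal(0.0, biological_sigma)))
            ab = {}
            n_active = len(ref.active)
            for eid in ref.active:
                ab[eid] = scale * active_share / n_active
            for did in ref.decoys:
                ab[did] = (1 - active_share) / len(ref.decoys)
            reads, _ = simulate_rnaseq(
                ref, ab, n_pairs, seed=int(rng.integers(2**31)),
                per_base_error=per_base_error,
                duplicate_fraction=duplicate_fraction)
            counts = count_active_l1(reads, ref)
            for fam, n in counts.items():
                rows.append({"sample": f"{group}{s}", "group": group,
                             "subfamily": fam, "count": n})
    counts = pd.DataFrame(rows)
    groups: dict[str, list[float]] = {}
    comparisons = []
    for fam in sorted(counts["subfamily"].unique()):
        for g in ("A", "B"):
            key = f"{g}_{fam}"
            groups[key] = counts.query(
                "group == @g and subfamily == @fam")["count"].tolist()
        comparisons.append((f"A_{fam}", f"B_{fam}"))
    comp = compare_groups(groups, comparisons)
    comp["subfamily"] = [c[0].split("_", 1)[1] for c in comparisons]
    return ExpressionContrast(counts, comp)
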