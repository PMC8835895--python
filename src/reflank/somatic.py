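"""Tumor-specific candidate calling and in-silico validation-PCR prediction.

A clustered call becomes a candidate only when it is absent from the
reference annotation and known-polymorphic databases, absent (zero support)
from the matched normal sample, absent from every other genome of the
cohort, and supported by at least two distinct UMIs — the criteria that
make single-molecule artifacts ineligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .mapping import InsertionCall
from .simulate import MiniGenome


@dataclass
class KnownInsertionDB:
    """Loci known before somatic calling: reference copies, polymorphic DB,
    and every call seen in the cohort (this run's other samples plus any
    prior-run table)."""

    reference: set[tuple[str, int]] = field(default_factory=set)    # (family, junction)
    polymorphic: set[tuple[str, int]] = field(default_factory=set)
    cohort: set[tuple[str, int]] = field(default_factory=set)

    @classmethod
    def from_genome(cls, genome: MiniGenome) -> "KnownInsertionDB":
        db = cls()
        for unit in genome.units:
            ev = unit.event
            if ev.category == "reference":
                db.reference.add((ev.family, ev.junction))
            elif ev.category == "polymorphic_germline" and ev.in_database:
                db.polymorphic.add((ev.family, ev.junction))
        # annotated copies whose flank failed size selection are still known
        for ev in genome.truth_insertions:
            if ev.category == "reference":
                db.reference.add((ev.family, ev.junction))
        return db

    def add_cohort_calls(self, calls: list[InsertionCall]) -> None:
        for c in calls:
            self.cohort.add((c.family, c.junction))

    def add_cohort_table(self, table: pd.DataFrame) -> None:
        for _, row in table.iterrows():
            self.cohort.add((row["family"], int(row["junction"])))


def _near(junction: int, entries: set[tuple[str, int]], window: int) -> bool:
    # matching is by locus alone: a call of the wrong subfamily at a known
    # junction is a template-switch signature, not a novel insertion
    return any(abs(j - junction) <= window for _f, j in entries)


def classify_call(call: InsertionCall, db: KnownInsertionDB,
                  window: int = 10) -> str:
    """reference | known_polymorphic | unclassified (candidate-eligible)."""
    if _near(call.junction, db.reference, window):
        return "reference"
    if _near(call.junction, db.polymorphic, window):
        return "known_polymorphic"
    return "unclassified"


def classify_calls(calls: list[InsertionCall], db: KnownInsertionDB,
                   window: int = 10) -> None:
    for c in calls:
        c.classification = classify_call(c, db, window)


def call_candidates(tumor_calls: list[InsertionCall],
                    normal_calls: list[InsertionCall] | None,
                    db: KnownInsertionDB, min_umi: int = 2,
                    window: int = 10) -> list[InsertionCall]:
    """Tumor-specific candidates under the conservative absence rules.

    The normal-absence test is zero-UMI absence: any support at the locus
    in the matched normal vetoes the call. Requires a matched normal —
    unmatched calling is unsupported.
    """
    if normal_calls is None:
        raise ValueError("matched normal sample is required for somatic calling")
    normal_loci = {(c.family, c.junction) for c in normal_calls}
    out = []
    for call in sorted(tumor_calls, key=lambda c: (c.family, c.junction)):
        if call.classification != "unclassified":
            continue
        if call.umi_count < min_umi:
            continue
        if _near(call.junction, normal_loci, window):
            continue
        if _near(call.junction, db.cohort, window):
            continue
        out.append(call)
    out.sort(key=lambda c: (-c.umi_count, c.family, c.junction))
    return out


# ---------------------------------------------------------------------------
# validation-PCR prediction
# ---------------------------------------------------------------------------

@dataclass
class ValidationScheme:
    """Primer layout of a locus-specific validation assay.

    GSP-F anneals upstream of the junction, GSP-R downstream; the RE
    primer(s) anneal inside the inserted element. L1 uses one junction
    reaction (3'-L1 + GSP-R), Alu uses two (GSP-F + 5'-Alu and GSP-R +
    3'-Alu); GSP-F + GSP-R is the empty-allele control in both designs.
    """

    family: str                  # L1HS | AluYa5 | AluYb8
    gsp_f: int                   # reference coordinate of forward primer 5' end
    gsp_r: int                   # reference coordinate of reverse primer site
    junction: int
    element_length: int = 300
    max_amplicon: int = 3000

    def __post_init__(self) -> None:
        if not self.gsp_f < self.junction < self.gsp_r:
            raise ValueError("GSP-F must lie upstream and GSP-R downstream "
                             "of the junction")

    @property
    def is_l1(self) -> bool:
        return self.family.startswith("L1")

    def junction_reactions(self) -> list[str]:
        if self.is_l1:
            return ["3L1+GSP-R"]
        return ["GSP-F+5Alu", "GSP-R+3Alu"]


GENOTYPES = ("no_insertion", "heterozygous", "homozygous", "absent_artifact")


def predict_validation_pcr(genotype: str, scheme: ValidationScheme) -> dict:
    """Expected band pattern of each reaction for one sample genotype.

    Junction reactions yield product iff an insertion-bearing allele is
    present; the GSP-F + GSP-R control yields the empty-allele product iff
    an insertion-free allele is present, or a size-shifted product when the
    insertion is homozygous but still within amplifiable size.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    has_insertion_allele = genotype in ("heterozygous", "homozygous")
    has_empty_allele = genotype in ("no_insertion", "heterozygous",
                                    "absent_artifact")
    empty_size = scheme.gsp_r - scheme.gsp_f
    shifted_size = empty_size + scheme.element_length
    bands = {}
    for rxn in scheme.junction_reactions():
        bands[rxn] = {"band": has_insertion_allele,
                      "size": None if not has_insertion_allele else
                      abs(scheme.gsp_r - scheme.junction) if "GSP-R" in rxn
                      else abs(scheme.junction - scheme.gsp_f)}
    if has_empty_allele:
        bands["GSP-F+GSP-R"] = {"band": True, "size": empty_size}
    elif shifted_size <= scheme.max_amplicon:
        bands["GSP-F+GSP-R"] = {"band": True, "size": shifted_size}
    else:
        bands["GSP-F+GSP-R"] = {"band": False, "size": None}
    return bands


def validation_outcome(tumor_genotype: str, normal_genotype: str,
                       scheme: ValidationScheme) -> str:
    """Interpret a tumor/normal validation pair the way a reviewer would.

    somatic  — junction band in tumor only;
    germline — junction band in both samples (false-positive candidate);
    artifact — junction band in neither sample.
    """
    t = predict_validation_pcr(tumor_genotype, scheme)
    n = predict_validation_pcr(normal_genotype, scheme)
    rxns = scheme.junction_reactions()
    t_band = all(t[r]["band"] for r in rxns)
    n_band = all(n[r]["band"] for r in rxns)
    if t_band and not n_band:
        return "somatic"
    if t_band and n_band:
        return "germline"
    return "artifact"
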