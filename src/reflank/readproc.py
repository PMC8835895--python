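"""Parse raw read pairs into (UMI, flank, family) records and score specificity.

Mate 1 is expected to start with a subfamily primer followed by a
diagnostic RE tail and the genomic flank; mate 2 starts with the stem-loop
remnant, the UMI, and the flank read from the restriction cut inward.
Records that violate the structure are kept with a reject reason — parsing
never raises on malformed reads.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import (DIAG_TAIL_LEN, PRIMER_LEN, STEM_REMNANT, PipelineConfig)
from .dna import revcomp
from .simulate import FamilyPanel, ReadPair


@dataclass
class ParsedFlank:
    """One read pair reduced to its molecule-identifying parts."""

    read_id: str
    family: str | None
    umi: str | None
    flank_sequence: str          # junction-proximal flank, molecule orientation
    full_flank_len: int | None   # known when the adapter anchor is visible
    distal_sequence: str         # cut-site-proximal flank from mate 2
    is_target: bool
    reject_reason: str           # none | no_primer | no_adapter | short_flank | offtarget_re


def _mismatches_within(a: str, b: str, limit: int) -> int | None:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return None
    return d


def parse_read_pair(pair: ReadPair, panels: dict[str, FamilyPanel],
                    cfg: PipelineConfig) -> ParsedFlank:
    """Locate primer, diagnostic positions, adapter and UMI in one pair.

    Family is assigned by the best primer match within the configured
    mismatch budget (no indels); the diagnostic-position check is exact.
    UMIs containing N are rejected, since molecule counting requires exact
    UMI identity.
    """
    s1, s2 = pair.seq1, pair.seq2

    best_family, best_d = None, None
    for name, panel in panels.items():
        d = _mismatches_within(s1[:PRIMER_LEN], panel.primer,
                               cfg.primer_max_mismatch)
        if d is not None and (best_d is None or d < best_d):
            best_family, best_d = name, d
    if best_family is None:
        return ParsedFlank(pair.read_id, None, None, "", None, "", False,
                           "no_primer")
    panel = panels[best_family]

    stem = s2[:len(STEM_REMNANT)]
    if _mismatches_within(stem, STEM_REMNANT, 1) is None:
        return ParsedFlank(pair.read_id, best_family, None, "", None, "",
                           False, "no_adapter")
    umi = s2[len(STEM_REMNANT):len(STEM_REMNANT) + cfg.sim.umi_length]
    if len(umi) < cfg.sim.umi_length or "N" in umi:
        return ParsedFlank(pair.read_id, best_family, None, "", None, "",
                           False, "no_adapter")

    tail = s1[PRIMER_LEN:PRIMER_LEN + DIAG_TAIL_LEN]
    for off, base in panel.diagnostic_bases():
        if off >= len(tail) or tail[off] != base:
            return ParsedFlank(pair.read_id, best_family, umi, "", None, "",
                               False, "offtarget_re")

    # flank on mate 1, trimmed at the adapter anchor when visible
    rest = s1[PRIMER_LEN + DIAG_TAIL_LEN:]
    anchor18 = revcomp(umi) + revcomp(STEM_REMNANT)
    t = rest.find(anchor18)
    full_len: int | None = None
    if t >= 0:
        flank, full_len = rest[:t], t
    else:
        t8 = rest.find(revcomp(STEM_REMNANT))
        if t8 >= cfg.sim.umi_length:
            full_len = t8 - cfg.sim.umi_length
            flank = rest[:full_len]
        else:
            flank = rest
    if full_len is None:
        # medium flanks run off mate 1 but mate 2 still reads through them
        # into the reverse complement of the RE part, which anchors the
        # flank's true length
        re_anchor = revcomp(panel.mate1_re_part())[:20]
        q = s2.find(re_anchor, len(STEM_REMNANT) + cfg.sim.umi_length)
        if q >= 0:
            full_len = q - len(STEM_REMNANT) - cfg.sim.umi_length
            flank = rest[:full_len]
    if full_len is not None and full_len < cfg.min_mappable_flank:
        return ParsedFlank(pair.read_id, best_family, umi, flank, full_len,
                           "", False, "short_flank")

    distal_start = len(STEM_REMNANT) + cfg.sim.umi_length
    if full_len is not None:
        distal = s2[distal_start:distal_start + full_len]
    else:
        distal = s2[distal_start:]
    return ParsedFlank(pair.read_id, best_family, umi, flank, full_len,
                       distal, True, "none")


def parse_library(reads: list[ReadPair], panels: dict[str, FamilyPanel],
                  cfg: PipelineConfig) -> list[ParsedFlank]:
    return [parse_read_pair(r, panels, cfg) for r in reads]


@dataclass
class SpecificityReport:
    """Per-family fraction of structurally valid target flanks."""

    per_family: dict[str, dict[str, float]]

    def specificity(self, family: str) -> float:
        return self.per_family[family]["specificity"]


def compute_specificity(records: list[ParsedFlank]) -> SpecificityReport:
    """Fraction of target RE flanks among all reads assigned to each family.

    Reads whose primer is unrecognizable cannot be assigned and are pooled
    under the pseudo-family ``unassigned`` (counted in ``all`` only).
    """
    if not records:
        raise ValueError("no parsed records")
    fams: dict[str, dict[str, float]] = {}
    for rec in records:
        key = rec.family or "unassigned"
        d = fams.setdefault(key, {"n_total": 0, "n_target": 0})
        d["n_total"] += 1
        d["n_target"] += int(rec.is_target)
    n_tot = sum(d["n_total"] for d in fams.values())
    n_tgt = sum(d["n_target"] for d in fams.values())
    fams["all"] = {"n_total": n_tot, "n_target": n_tgt}
    for d in fams.values():
        d["specificity"] = d["n_target"] / d["n_total"] if d["n_total"] else 0.0
    return SpecificityReport(fams)
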