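"""Synthetic-data generator emulating targeted UMI-tagged RE-flank sequencing.

The generator builds a diploid mini-genome carrying reference, polymorphic
germline and somatic retroelement copies, then walks the wet protocol:
restriction digestion, stem-loop adapter ligation with a 10-nt UMI per
molecule, subfamily-specific nested amplification, artifact (chimera)
formation, and paired-end 150+150 sequencing with uniform substitution
error. Every read is linked to its source molecule and truth event so
downstream assertions never rely on re-deriving the truth.

Read layout (declared here, honored by the parser): mate 1 begins with the
20-nt subfamily primer, then a 30-nt diagnostic RE tail, then the genomic
flank read away from the element; mate 2 begins with the 8-nt stem-loop
remnant, the 10-nt UMI, and the flank read inward from the restriction cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (DIAG_TAIL_LEN, PRIMER_LEN, STEM_REMNANT, EnzymeSpec,
                     FamilySpec, SimConfig, substream)
from .dna import mutate, random_seq, random_seq_avoiding, revcomp

# fixed panel entropy: the primer panel is a property of the assay, not of
# any particular simulated sample, so it does not depend on the run seed
_PANEL_SEED = 715_2022


# ---------------------------------------------------------------------------
# restriction digestion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    """One restriction fragment with its coordinates and bounding enzymes."""

    sequence: str
    start: int
    end: int
    left_enzyme: str | None
    right_enzyme: str | None


def cut_positions(sequence: str, enzymes: list[EnzymeSpec]) -> list[tuple[int, str]]:
    """All top-strand cut coordinates (site_start + cut_offset), sorted."""
    cuts: list[tuple[int, str]] = []
    for enz in enzymes:
        site = enz.recognition_site
        i = sequence.find(site)
        while i >= 0:
            cuts.append((i + enz.cut_offset, enz.name))
            i = sequence.find(site, i + 1)
    cuts.sort()
    # coincident cuts from different enzymes collapse to one
    dedup: list[tuple[int, str]] = []
    for pos, name in cuts:
        if dedup and dedup[-1][0] == pos:
            continue
        dedup.append((pos, name))
    return dedup


def digest(sequence: str, enzymes: list[EnzymeSpec]) -> list[Fragment]:
    """Cut a sequence at every recognition site of every enzyme.

    Fragments concatenate back to the input; a sequence without sites
    yields itself as a single fragment.
    """
    cuts = cut_positions(sequence, enzymes)
    bounds = [(0, None)] + [(p, n) for p, n in cuts if 0 < p < len(sequence)] \
        + [(len(sequence), None)]
    frags = []
    for (s, left), (e, right) in zip(bounds[:-1], bounds[1:]):
        frags.append(Fragment(sequence[s:e], s, e, left, right))
    return frags


def is_cut_site_boundary(sequence: str, coord: int,
                         enzymes: list[EnzymeSpec]) -> bool:
    """Whether genome coordinate ``coord`` is a cut position of any enzyme."""
    for enz in enzymes:
        s = coord - enz.cut_offset
        if s >= 0 and sequence[s:s + len(enz.recognition_site)] == enz.recognition_site:
            return True
    return False


# ---------------------------------------------------------------------------
# subfamily panel (primers, diagnostic positions, consensus)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyPanel:
    """Assay-level constants for one subfamily derived from its consensus."""

    spec: FamilySpec
    consensus: str
    primer: str          # first 20 nt of mate 1
    diag_tail: str       # next 30 nt of mate 1 (expected sequence)

    @property
    def name(self) -> str:
        return self.spec.name

    def mate1_re_part(self, element_seq: str | None = None) -> str:
        """Primer + diagnostic tail as read on mate 1 for a given copy."""
        seq = element_seq if element_seq is not None else self.consensus
        k = PRIMER_LEN + DIAG_TAIL_LEN
        if self.spec.side == "5p":
            return revcomp(seq[:k])
        return seq[-k:]

    def diagnostic_bases(self) -> list[tuple[int, str]]:
        return [(o, self.diag_tail[o]) for o in self.spec.diagnostic_offsets]


def build_family_panels(families: list[FamilySpec],
                        enzymes: dict[str, EnzymeSpec]) -> dict[str, FamilyPanel]:
    """Deterministic consensus + primer panel per subfamily.

    Consensi avoid every recognition site so restriction never severs the
    primer from the junction; panels are independent of the run seed.
    """
    sites = [e.recognition_site for e in enzymes.values()]
    panels = {}
    for i, fam in enumerate(families):
        rng = substream(_PANEL_SEED + i, f"panel:{fam.name}")
        consensus = random_seq_avoiding(rng, fam.consensus_length, sites)
        re_part = FamilyPanel(fam, consensus, "", "").mate1_re_part(consensus)
        panels[fam.name] = FamilyPanel(
            fam, consensus, re_part[:PRIMER_LEN],
            re_part[PRIMER_LEN:PRIMER_LEN + DIAG_TAIL_LEN])
    return panels


# ---------------------------------------------------------------------------
# mini-genome
# ---------------------------------------------------------------------------

@dataclass
class InsertionEvent:
    """A planted RE copy: reference, polymorphic germline, or somatic."""

    event_id: str
    family: str
    junction: int                  # 0-based flank-proximal junction on reference
    strand: str                    # element strand
    category: str                  # reference | polymorphic_germline | somatic
    cell_fraction: float
    tsd_length: int = 0
    in_database: bool = True       # germline: listed in the polymorphic DB

    def __post_init__(self) -> None:
        if self.category in ("reference", "polymorphic_germline") \
                and self.cell_fraction not in (0.5, 1.0):
            raise ValueError("constitutional events must have fraction 0.5 or 1.0")


@dataclass
class AmplUnit:
    """One amplifiable junction: truth event plus its precomputed molecule parts."""

    event: InsertionEvent
    flank_mol: str                 # flank in molecule orientation (away from RE)
    flank_ref_start: int           # reference interval covered by the flank
    flank_ref_end: int
    re_part: str                   # primer + diagnostic tail as on mate 1
    n_haplotypes: int              # 2 for homozygous/reference, 1 for het/somatic

    @property
    def flank_len(self) -> int:
        return len(self.flank_mol)


@dataclass
class MiniGenome:
    """Synthetic reference with annotated RE copies and a truth event set."""

    contig: str
    reference: str
    annotations: list[dict]            # family/start/end/strand of reference copies
    truth_insertions: list[InsertionEvent]
    units: list[AmplUnit]
    panels: dict[str, FamilyPanel]
    config: SimConfig
    dropped_units: list[str] = field(default_factory=list)

    def units_by_category(self, *categories: str) -> list[AmplUnit]:
        return [u for u in self.units if u.event.category in categories]

    def event(self, event_id: str) -> InsertionEvent:
        for ev in self.truth_insertions:
            if ev.event_id == event_id:
                return ev
        raise KeyError(event_id)


def _oriented_element(panel: FamilyPanel, strand: str, seq: str | None = None) -> str:
    s = seq if seq is not None else panel.consensus
    return s if strand == "+" else revcomp(s)


def _flank_for_unit(reference: str, element_genomic: str, elem_strand: str,
                    junction_left: int, junction_right: int,
                    panel: FamilyPanel, enzymes: list[EnzymeSpec],
                    window: int = 900) -> tuple[str, int, int] | None:
    """Flank of the amplified junction, read away from the element.

    ``junction_left``/``junction_right`` are the reference coordinates where
    the element (re)joins the reference on its left and right genomic side.
    Returns (flank in molecule orientation, ref start, ref end) or None when
    no cut site exists within the search window.
    """
    side, strand = panel.spec.side, elem_strand
    flank_leftward = (side == "5p") == (strand == "+")
    if flank_leftward:
        lo = max(0, junction_left - window)
        local = reference[lo:junction_left] + element_genomic[:40]
        cuts = [p for p, _ in cut_positions(local, enzymes)
                if p <= junction_left - lo]
        if not cuts:
            return None
        c = lo + max(cuts)
        return revcomp(reference[c:junction_left]), c, junction_left
    hi = min(len(reference), junction_right + window)
    local = element_genomic[-40:] + reference[junction_right:hi]
    off = len(element_genomic[-40:])
    cuts = [p - off for p, _ in cut_positions(local, enzymes) if p >= off]
    if not cuts:
        return None
    c = junction_right + min(cuts)
    return reference[junction_right:c], junction_right, c


def _re_part_for(panel: FamilyPanel, element_oriented: str) -> str:
    return panel.mate1_re_part(element_oriented)


def build_mini_genome(config: SimConfig) -> MiniGenome:
    """Construct the diploid mini-genome and its truth table.

    Reference copies are planted into a random backbone with per-copy
    divergence (edges protected so primers anneal); polymorphic germline
    and somatic insertion events are placed on the finished reference at
    positions whose flank passes the size-selection window, so every
    non-reference event is recoverable by design. Deterministic given the
    config seed.
    """
    rng = substream(config.seed, "genome")
    panels = build_family_panels(config.families, config.enzyme_set)
    spacing = config.min_event_spacing

    backbone = random_seq(rng, config.genome_length)

    # -- place reference copies in backbone coordinates
    placements = []  # (backbone position, family, strand)
    taken: list[int] = []
    for fam in config.families:
        for _ in range(config.n_reference_res_per_family):
            for _try in range(500):
                pos = int(rng.integers(spacing, config.genome_length - spacing))
                if all(abs(pos - t) >= spacing for t in taken):
                    taken.append(pos)
                    strand = "+" if rng.random() < 0.5 else "-"
                    placements.append((pos, fam.name, strand))
                    break
            else:
                raise ValueError(
                    "genome too short to place requested reference copies")
    placements.sort()

    # -- build the reference sequence right-to-left, with per-copy divergence;
    # inserting from the rightmost placement first keeps the remaining
    # backbone coordinates valid
    reference = backbone
    copy_seqs: dict[str, str] = {}
    events: list[InsertionEvent] = []
    for i, (pos, fam_name, strand) in enumerate(reversed(placements)):
        panel = panels[fam_name]
        L = len(panel.consensus)
        protect = set(range(60)) if panel.spec.side == "5p" \
            else set(range(L - 60, L))
        diverged = mutate(rng, panel.consensus, config.reference_divergence,
                          protect=protect)
        genomic = _oriented_element(panel, strand, diverged)
        reference = reference[:pos] + genomic + reference[pos:]
        copy_seqs[f"ref_{fam_name}_{i}"] = diverged
    annotations = _locate_annotations(placements, panels)

    units: list[AmplUnit] = []
    dropped: list[str] = []
    lo, hi = config.flank_length_range

    for ann in annotations:
        panel = panels[ann["family"]]
        diverged = copy_seqs[ann["copy_id"]]
        genomic = _oriented_element(panel, ann["strand"], diverged)
        res = _flank_for_unit(reference, genomic, ann["strand"],
                              ann["start"], ann["end"], panel,
                              [config.enzyme_set[n] for n in panel.spec.enzymes])
        side, strand = panel.spec.side, ann["strand"]
        junction = ann["start"] if (side == "5p") == (strand == "+") else ann["end"]
        ev = InsertionEvent(ann["copy_id"], ann["family"], junction,
                            ann["strand"], "reference", 1.0)
        events.append(ev)
        if res is None or not lo <= len(res[0]) <= hi:
            dropped.append(ev.event_id)
            continue
        units.append(AmplUnit(ev, res[0], res[1], res[2],
                              _re_part_for(panel, diverged), 2))

    # -- polymorphic germline + somatic events on the finished reference
    blocked = [(a["start"] - spacing, a["end"] + spacing) for a in annotations]

    def place_event(fam_name: str, category: str, cell_fraction: float,
                    tsd: int, event_id: str, in_db: bool) -> AmplUnit | None:
        panel = panels[fam_name]
        enz = [config.enzyme_set[n] for n in panel.spec.enzymes]
        for _try in range(800):
            j = int(rng.integers(spacing, len(reference) - spacing))
            if any(s <= j <= e for s, e in blocked):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            genomic = _oriented_element(panel, strand)
            if tsd:
                genomic = genomic + reference[j - tsd:j]
            res = _flank_for_unit(reference, genomic, strand, j, j, panel, enz)
            if res is None or not lo <= len(res[0]) <= hi:
                continue
            blocked.append((j - spacing, j + spacing))
            ev = InsertionEvent(event_id, fam_name, j, strand, category,
                                cell_fraction, tsd, in_db)
            events.append(ev)
            n_hap = 1 if category == "somatic" else (2 if cell_fraction == 1.0 else 1)
            return AmplUnit(ev, res[0], res[1], res[2],
                            _re_part_for(panel, panel.consensus), n_hap)
        return None

    k = 0
    for fam in config.families:
        for _ in range(config.n_polymorphic_per_family):
            cf = 0.5 if rng.random() < 0.6 else 1.0
            in_db = rng.random() >= config.private_germline_fraction
            unit = place_event(fam.name, "polymorphic_germline", cf, 0,
                               f"poly_{k}", in_db)
            if unit is not None:
                units.append(unit)
            k += 1
    for i, spec in enumerate(config.somatic_events):
        eid = spec.event_id or f"som_{i}"
        unit = place_event(spec.family, "somatic", spec.cell_fraction,
                           spec.tsd_length, eid, False)
        if unit is None:
            raise ValueError(f"could not place somatic event {eid}")
        units.append(unit)

    return MiniGenome("miniG", reference, annotations, events, units,
                      panels, config, dropped)


def _locate_annotations(placements: list[tuple[int, str, str]],
                        panels: dict[str, FamilyPanel]) -> list[dict]:
    """Final coordinates of planted copies.

    A copy planted at backbone position p ends up shifted right by the
    summed lengths of all copies planted strictly left of it.
    """
    out = []
    shift = 0
    for i, (pos, fam, strand) in enumerate(placements):
        L = panels[fam].spec.consensus_length
        out.append({"family": fam, "start": pos + shift,
                    "end": pos + shift + L, "strand": strand,
                    "copy_id": f"ref_{fam}_{len(placements) - 1 - i}"})
        shift += L
    return out


# ---------------------------------------------------------------------------
# molecule pool
# ---------------------------------------------------------------------------

@dataclass
class TaggedMolecule:
    """A pre-amplification adapter-ligated molecule with its UMI."""

    molecule_id: str
    umi: str
    re_part: str
    flank: str
    family: str
    source_event_id: str | None
    source_cell_index: int
    chimera_class: str = "none"     # none | ligation | template_switch
    amp_efficiency: float = 0.9     # locus-level per-cycle PCR efficiency

    @property
    def is_chimera(self) -> bool:
        return self.chimera_class != "none"


def _bulk_umis(rng: np.random.Generator, n: int, length: int) -> list[str]:
    arr = rng.integers(0, 4, size=(n, length))
    lut = np.array(list("ACGT"))
    return ["".join(row) for row in lut[arr]]


def _random_genomic_window(rng: np.random.Generator, reference: str,
                           lo: int, hi: int) -> tuple[str, int, int]:
    n = int(rng.integers(lo, min(hi, 400) + 1))
    start = int(rng.integers(0, len(reference) - n))
    seq = reference[start:start + n]
    if rng.random() < 0.5:
        seq = revcomp(seq)
    return seq, start, start + n


def generate_molecule_pool(genome: MiniGenome, config: SimConfig,
                           sample_role: str,
                           rng: np.random.Generator | None = None,
                           somatic_carrier_u: dict[str, np.ndarray] | None = None,
                           n_cells: int | None = None) -> list[TaggedMolecule]:
    """One tagged molecule per cell per haplotype carrying each RE junction.

    Somatic events contribute only in the ``tumor`` role, per-cell by
    Bernoulli(cell_fraction); ``somatic_carrier_u`` optionally supplies the
    per-cell uniform draws so carrier sets can be coupled across runs.
    Off-target and ligation-chimera molecules are injected at the configured
    rates with truth labels.
    """
    if sample_role not in ("tumor", "normal"):
        raise ValueError("sample_role must be 'tumor' or 'normal'")
    rng = rng if rng is not None else substream(config.seed, f"pool:{sample_role}")
    ncells = n_cells if n_cells is not None else config.n_cells
    pool: list[TaggedMolecule] = []
    mol_idx = 0

    lo_e = max(0.05, config.pcr_efficiency - config.pcr_efficiency_spread)
    hi_e = min(1.0, config.pcr_efficiency + config.pcr_efficiency_spread)

    def draw_eff() -> float:
        return float(rng.uniform(lo_e, hi_e))

    def locus_eff(event_id: str) -> float:
        # locus-intrinsic: flank length, GC and primer context make a locus
        # amplify consistently well or poorly across samples and replicates
        r = substream(config.seed, f"locus-eff:{event_id}")
        return float(r.uniform(lo_e, hi_e))

    def emit(umi, re_part, flank, family, event_id, cell, chim="none",
             eff=None):
        nonlocal mol_idx
        pool.append(TaggedMolecule(f"M{mol_idx}", umi, re_part, flank,
                                   family, event_id, cell, chim,
                                   eff if eff is not None else draw_eff()))
        mol_idx += 1

    lo, hi = config.flank_length_range
    for unit in genome.units:
        ev = unit.event
        unit_eff = locus_eff(ev.event_id)
        if ev.category == "somatic":
            if sample_role != "tumor":
                continue
            u = somatic_carrier_u.get(ev.event_id) if somatic_carrier_u else None
            if u is None:
                u = rng.random(ncells)
            carriers = np.nonzero(u[:ncells] < ev.cell_fraction)[0]
            copies = [(int(c), 1) for c in carriers]
        else:
            copies = [(c, unit.n_haplotypes) for c in range(ncells)]
        if not lo <= unit.flank_len <= hi:
            genome.dropped_units.append(ev.event_id)
            continue
        umis = _bulk_umis(rng, sum(h for _, h in copies), config.umi_length)
        i = 0
        for cell, n_hap in copies:
            for _ in range(n_hap):
                emit(umis[i], unit.re_part, unit.flank_mol, ev.family,
                     ev.event_id, cell, eff=unit_eff)
                i += 1

    n_target = mol_idx
    panels = list(genome.panels.values())

    # off-target molecules: correct primer, diverged diagnostic positions
    n_off = rng.binomial(max(n_target, 1),
                         min(1.0, config.offtarget_rate / max(1e-9, 1 - config.offtarget_rate)))
    for umi in _bulk_umis(rng, n_off, config.umi_length):
        panel = panels[int(rng.integers(len(panels)))]
        re_part = list(panel.mate1_re_part())
        offs = rng.choice(panel.spec.diagnostic_offsets,
                          size=min(2, len(panel.spec.diagnostic_offsets)),
                          replace=False)
        for o in offs:
            pos = PRIMER_LEN + int(o)
            re_part[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[re_part[pos]]
        emit(umi, "".join(re_part),
             _random_genomic_window(rng, genome.reference, lo, hi)[0],
             panel.name, "offtarget", -1)

    # ligation chimeras: intact RE part joined to a random genomic window
    # whose ends do not fall on restriction cut sites
    n_lig = rng.binomial(max(n_target, 1), config.chimera_rates.get("ligation", 0.0))
    for umi in _bulk_umis(rng, n_lig, config.umi_length):
        panel = panels[int(rng.integers(len(panels)))]
        enz = [config.enzyme_set[n] for n in panel.spec.enzymes]
        flank = ""
        for _try in range(50):
            flank, w_start, w_end = _random_genomic_window(
                rng, genome.reference, lo, hi)
            if not is_cut_site_boundary(genome.reference, w_start, enz) \
                    and not is_cut_site_boundary(genome.reference, w_end, enz):
                break
        emit(umi, panel.mate1_re_part(), flank, panel.name, None, -1, "ligation")

    return pool


# ---------------------------------------------------------------------------
# amplification and sequencing
# ---------------------------------------------------------------------------

@dataclass
class ReadPair:
    """A sequenced paired-end record."""

    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    source_molecule_id: str | None = None


@dataclass
class SequencedLibrary:
    """Reads plus the per-read truth table of one simulated library."""

    reads: list[ReadPair]
    truth: pd.DataFrame


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    out = list(seq)
    for p in rng.choice(len(seq), size=min(k, len(seq)), replace=False):
        old = out[p]
        out[p] = "ACGT".replace(old, "")[rng.integers(0, 3)]
    return "".join(out)


def pcr_copy_numbers(rng: np.random.Generator, efficiency: np.ndarray,
                     cycles: int) -> np.ndarray:
    """Per-molecule copy numbers under per-cycle Bernoulli doubling.

    ``efficiency`` is the per-molecule per-cycle duplication probability;
    locus-to-locus differences compound into orders-of-magnitude yield
    differences over a full protocol.
    """
    x = np.ones(len(efficiency), dtype=np.int64)
    for _ in range(cycles):
        x = x + rng.binomial(x, efficiency)
    return x


def amplify_and_sequence(pool: list[TaggedMolecule], config: SimConfig,
                         rng: np.random.Generator | None = None,
                         depth: int | None = None,
                         annotations: list[dict] | None = None,
                         reference: str | None = None) -> SequencedLibrary:
    """PCR-duplicate the pool and emit paired-end reads with truth labels.

    Template-switch chimeras arise per amplification event at the configured
    rate: the emitted read keeps the original molecule's RE part and UMI but
    carries a foreign flank (another molecule's flank, or an interior window
    of an annotated same-family copy when annotations are supplied).
    Sampling is i.i.d. proportional to PCR copy number, so a prefix of the
    read list is itself a valid shallower sequencing run.
    """
    if not pool:
        raise ValueError("empty molecule pool")
    rng = rng if rng is not None else substream(config.seed, "sequence")
    n_reads = depth if depth is not None else config.depth
    cycles = config.pcr_cycles.get("pcr1", 14) + config.pcr_cycles.get("pcr2", 12)
    eff = np.array([m.amp_efficiency for m in pool])
    weights = pcr_copy_numbers(rng, eff, cycles)
    if n_reads > int(weights.sum()):
        logging.getLogger(__name__).warning(
            "requested depth %d exceeds %d amplified copies; sampling with "
            "replacement", n_reads, int(weights.sum()))
    probs = weights / weights.sum()
    picks = rng.choice(len(pool), size=n_reads, replace=True, p=probs)

    ts_rate = config.chimera_rates.get("template_switch", 0.0)
    ts_mask = rng.random(n_reads) < ts_rate

    L = config.read_length
    qual = chr(33 + 37) * L
    stem_rc = revcomp(STEM_REMNANT)
    amplicon_cache: dict[int, str] = {}
    fam_copies: dict[str, list[dict]] = {}
    if annotations:
        for ann in annotations:
            fam_copies.setdefault(ann["family"], []).append(ann)

    def amplicon_of(idx: int) -> str:
        amp = amplicon_cache.get(idx)
        if amp is None:
            m = pool[idx]
            amp = m.re_part + m.flank + revcomp(m.umi) + stem_rc
            amplicon_cache[idx] = amp
        return amp

    # template switching happens within one PCR tube: families amplified
    # with the same enzyme cocktail share a library and can donate templates
    # to each other, L1 and Alu libraries cannot
    lib_of = {f.name: f.enzymes for f in config.families}
    donors_by_lib: dict[tuple, list[int]] = {}
    for j, mol in enumerate(pool):
        donors_by_lib.setdefault(lib_of.get(mol.family, ()), []).append(j)

    def ts_flank(mol: TaggedMolecule) -> str:
        copies = fam_copies.get(mol.family)
        if copies and reference and rng.random() < 0.5:
            ann = copies[int(rng.integers(len(copies)))]
            span = ann["end"] - ann["start"]
            n = int(rng.integers(40, min(160, span - 80)))
            s = ann["start"] + int(rng.integers(60, span - 60 - n))
            w = reference[s:s + n]
            return w if rng.random() < 0.5 else revcomp(w)
        donors = donors_by_lib.get(lib_of.get(mol.family, ()), [])
        donor = pool[donors[int(rng.integers(len(donors)))]] if donors \
            else pool[int(rng.integers(len(pool)))]
        return donor.flank

    reads: list[ReadPair] = []
    rows = []
    for i, idx in enumerate(picks):
        m = pool[idx]
        chim = m.chimera_class
        if ts_mask[i]:
            amp = m.re_part + ts_flank(m) + revcomp(m.umi) + stem_rc
            chim = "template_switch"
        else:
            amp = amplicon_of(int(idx))
        s1 = (amp[:L] + "A" * L)[:L]
        s2 = (revcomp(amp)[:L] + "A" * L)[:L]
        s1 = _apply_errors(rng, s1, config.per_base_error)
        s2 = _apply_errors(rng, s2, config.per_base_error)
        rid = f"sim.{i}"
        reads.append(ReadPair(rid, s1, qual, s2, qual, m.molecule_id))
        rows.append((rid, m.molecule_id, m.source_event_id or "", chim,
                     m.umi, m.family))
    truth = pd.DataFrame(rows, columns=["read_id", "molecule_id", "event_id",
                                        "chimera_class", "umi", "family"])
    return SequencedLibrary(reads, truth)


# ---------------------------------------------------------------------------
# RNA-seq simulation over active/decoy L1 references
# ---------------------------------------------------------------------------

@dataclass
class L1Reference:
    """Active-element reference plus decoy (diverged) elements for simulation."""

    active: dict[str, tuple[str, str]]    # id -> (sequence, subfamily)
    decoys: dict[str, tuple[str, str]]

    def all_elements(self) -> dict[str, tuple[str, str, bool]]:
        out = {k: (s, f, True) for k, (s, f) in self.active.items()}
        out.update({k: (s, f, False) for k, (s, f) in self.decoys.items()})
        return out


def make_l1_reference(seed: int = 0, n_l1hs: int = 12, n_l1pa2: int = 8,
                      length: int = 1200, n_decoys: int = 20,
                      divergence: float = 0.05,
                      max_clean_window: int = 70) -> L1Reference:
    """Synthetic stand-in for a curated active-L1 set plus inactive decoys.

    Decoys derive from active elements with substitutions spaced so that no
    read-length window is mutation-free: an error-free decoy read can never
    align to the active set with 100% identity.
    """
    rng = substream(seed, "l1ref")
    active = {}
    for i in range(n_l1hs):
        active[f"L1HS_{i}"] = (random_seq(rng, length), "L1HS")
    for i in range(n_l1pa2):
        active[f"L1PA2_{i}"] = (random_seq(rng, length), "L1PA2")
    decoys = {}
    ids = list(active)
    for i in range(n_decoys):
        src_id = ids[int(rng.integers(len(ids)))]
        src, fam = active[src_id]
        seq = list(src)
        pos = 0
        muts = []
        while pos < length:
            step = int(rng.integers(10, max_clean_window + 1))
            pos = min(pos + step, length - 1)
            muts.append(pos)
            if pos >= length - 1:
                break
        extra = rng.binomial(length, divergence)
        muts.extend(int(p) for p in rng.integers(0, length, size=extra))
        for p in set(muts):
            seq[p] = "ACGT".replace(seq[p], "")[rng.integers(0, 3)]
        decoys[f"decoy_{i}"] = ("".join(seq), fam)
    return L1Reference(active, decoys)


def simulate_rnaseq(reference: L1Reference, abundances: dict[str, float],
                    n_pairs: int, seed: int = 0, read_length: int = 75,
                    per_base_error: float = 0.0, duplicate_fraction: float = 0.0,
                    insert_range: tuple[int, int] = (150, 400)
                    ) -> tuple[list[ReadPair], pd.DataFrame]:
    """PolyA RNA-seq read pairs drawn from elements proportionally to abundance.

    Pairs are proper by construction (convergent mates, insert within
    ``insert_range``); a ``duplicate_fraction`` of pairs re-reads an existing
    template. Returns reads and a truth table with template and element ids.
    """
    elements = reference.all_elements()
    ids = [k for k in abundances if abundances[k] > 0]
    if not ids:
        raise ValueError("no element with positive abundance")
    missing = [k for k in ids if k not in elements]
    if missing:
        raise KeyError(f"unknown elements: {missing}")
    rng = substream(seed, "rnaseq")
    w = np.array([abundances[k] for k in ids], dtype=float)
    w = w / w.sum()
    n_templates = max(1, int(round(n_pairs * (1 - duplicate_fraction))))
    tmpl_elems = rng.choice(len(ids), size=n_templates, p=w)
    templates = []
    for t, ei in enumerate(tmpl_elems):
        eid = ids[int(ei)]
        seq, fam, is_active = elements[eid]
        ins = int(rng.integers(insert_range[0],
                               min(insert_range[1], len(seq) - 1) + 1))
        start = int(rng.integers(0, len(seq) - ins + 1))
        frag = seq[start:start + ins]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        templates.append((f"T{t}", eid, fam, is_active,
                          frag[:read_length], revcomp(frag)[:read_length]))
    picks = list(range(n_templates))
    picks += [int(i) for i in rng.integers(0, n_templates,
                                           size=n_pairs - n_templates)]
    qual = chr(33 + 37) * read_length
    reads, rows = [], []
    for i, t in enumerate(picks):
        tid, eid, fam, is_active, m1, m2 = templates[t]
        s1 = _apply_errors(rng, m1, per_base_error)
        s2 = _apply_errors(rng, m2, per_base_error)
        rid = f"rna.{i}"
        reads.append(ReadPair(rid, s1, qual[:len(s1)], s2, qual[:len(s2)], tid))
        rows.append((rid, tid, eid, fam, is_active))
    truth = pd.DataFrame(rows, columns=["read_id", "template_id", "element_id",
                                        "subfamily", "from_active"])
    return reads, truth
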