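"""Configuration objects for the flank-seq simulator and pipeline.

All tunable constants of the protocol live here: restriction enzymes,
subfamily panels, UMI length, flank size-selection window, PCR model,
chimera rates and the calling thresholds. Everything round-trips through
YAML so a run is fully described by one config file plus one seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

#: stem-loop adapter remnant retained 5' of the UMI on the flank-side mate
STEM_REMNANT = "GCTGAGGA"

#: length of the subfamily-specific primer at the start of the RE-side mate
PRIMER_LEN = 20

#: length of the diagnostic RE tail between primer and junction
DIAG_TAIL_LEN = 30

#: offsets (within the diagnostic tail) checked exactly to confirm subfamily
DEFAULT_DIAGNOSTIC_OFFSETS = (2, 6, 11, 17, 23, 28)


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction endonuclease: recognition site and top-strand cut offset."""

    name: str
    recognition_site: str
    cut_offset: int
    overhang_label: str = ""

    def __post_init__(self) -> None:
        site = self.recognition_site
        if not site or any(b not in "ACGT" for b in site):
            raise ValueError(f"recognition site must be uppercase ACGT: {site!r}")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError("cut_offset outside recognition site")


# The vendors' definitions for the three enzymes used by the wet protocol.
DEFAULT_ENZYMES = {
    "FspBI": EnzymeSpec("FspBI", "CTAG", 1, "TA"),
    "Csp6I": EnzymeSpec("Csp6I", "GTAC", 1, "TA"),
    "TaqI": EnzymeSpec("TaqI", "TCGA", 1, "CG"),
}


@dataclass(frozen=True)
class FamilySpec:
    """A targeted retroelement subfamily.

    ``side`` is the amplified flank: ``5p`` for Alu subfamilies (5' genomic
    flank), ``3p`` for L1HS (3' genomic flank). ``enzymes`` names the
    restriction cocktail of that library.
    """

    name: str
    consensus_length: int
    side: str  # "5p" | "3p"
    enzymes: tuple[str, ...]
    diagnostic_offsets: tuple[int, ...] = DEFAULT_DIAGNOSTIC_OFFSETS

    def __post_init__(self) -> None:
        if self.side not in ("5p", "3p"):
            raise ValueError("side must be '5p' or '3p'")
        if self.consensus_length < PRIMER_LEN + DIAG_TAIL_LEN + 20:
            raise ValueError("consensus too short for primer + diagnostic tail")
        if any(not 0 <= o < DIAG_TAIL_LEN for o in self.diagnostic_offsets):
            raise ValueError("diagnostic offsets outside the diagnostic tail")


def default_families() -> list[FamilySpec]:
    """L1HS (3' flank, TaqI+FspBI) and AluYa5/AluYb8 (5' flank, FspBI+Csp6I).

    Consensus lengths are mini-genome scale: full-length L1 (~6 kb) and Alu
    (~300 bp) are represented by 1000 and 300 bp synthetic consensi.
    """
    return [
        FamilySpec("L1HS", 1000, "3p", ("TaqI", "FspBI")),
        FamilySpec("AluYa5", 300, "5p", ("FspBI", "Csp6I")),
        FamilySpec("AluYb8", 300, "5p", ("FspBI", "Csp6I")),
    ]


@dataclass
class SomaticEventSpec:
    """A somatic insertion to plant: subfamily and fraction of tumor cells."""

    family: str
    cell_fraction: float
    tsd_length: int = 0
    event_id: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.cell_fraction <= 1:
            raise ValueError("cell_fraction must be in (0, 1]")
        if self.tsd_length < 0:
            raise ValueError("tsd_length must be >= 0")


@dataclass
class SimConfig:
    """Everything the generator needs to emulate one sequencing run."""

    seed: int = 0
    genome_length: int = 60_000
    n_reference_res_per_family: int = 5
    families: list[FamilySpec] = field(default_factory=default_families)
    enzyme_set: dict[str, EnzymeSpec] = field(
        default_factory=lambda: dict(DEFAULT_ENZYMES))
    umi_length: int = 10
    flank_length_range: tuple[int, int] = (25, 800)
    # cycle counts are wet-protocol metadata; the stochastic duplication model
    # runs pcr1 + pcr2 cycles at `pcr_efficiency` per-cycle success
    pcr_cycles: dict[str, int] = field(
        default_factory=lambda: {"pcr1": 14, "pcr2": 12, "index": 12})
    pcr_efficiency: float = 0.9
    # per-locus amplification efficiency is drawn uniformly from
    # pcr_efficiency +/- spread (clipped to (0,1]): flank length, GC and
    # primer context make locus yields vary over orders of magnitude
    pcr_efficiency_spread: float = 0.1
    chimera_rates: dict[str, float] = field(
        default_factory=lambda: {"ligation": 0.01, "template_switch": 0.005})
    per_base_error: float = 0.001
    read_length: int = 150
    depth: int = 20_000
    n_cells: int = 100
    n_polymorphic_per_family: int = 2
    private_germline_fraction: float = 0.25
    offtarget_rate: float = 0.08
    reference_divergence: float = 0.03
    min_event_spacing: int = 1200
    tumor_blast_fraction: float = 0.9
    somatic_events: list[SomaticEventSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.umi_length <= 0:
            raise ValueError("umi_length must be positive")
        lo, hi = self.flank_length_range
        if not lo < hi:
            raise ValueError("flank_length_range low must be < high")
        for key, rate in self.chimera_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"chimera rate {key} outside [0, 1]")
        for p in (self.per_base_error, self.pcr_efficiency,
                  self.offtarget_rate, self.private_germline_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 < self.tumor_blast_fraction <= 1:
            raise ValueError("tumor_blast_fraction must be in (0, 1]")
        for ev in self.somatic_events:
            if ev.cell_fraction > self.tumor_blast_fraction:
                raise ValueError(
                    "somatic cell_fraction cannot exceed tumor_blast_fraction")
        for fam in self.families:
            for enz in fam.enzymes:
                if enz not in self.enzyme_set:
                    raise ValueError(f"family {fam.name} names unknown enzyme {enz}")

    def family(self, name: str) -> FamilySpec:
        for fam in self.families:
            if fam.name == name:
                return fam
        raise KeyError(name)

    def enzymes_for(self, family_name: str) -> list[EnzymeSpec]:
        fam = self.family(family_name)
        return [self.enzyme_set[n] for n in fam.enzymes]


@dataclass
class MixtureDesign:
    """The 1:100 cell-mixture sensitivity experiment.

    Defaults mirror the wet experiment: 500 minor-donor cells sorted into
    50,000 major-donor cells, sequenced to ~500,000 read pairs, two
    replicates.
    """

    n_cells_minor: int = 500
    n_cells_major: int = 50_000
    depth: int = 500_000
    n_replicates: int = 2
    max_edits: int = 1
    min_detect_reads: int = 2
    min_detect_umis: int = 2
    flank_search_length: int = 30

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if min(self.n_cells_minor, self.n_cells_major) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def minor_fraction(self) -> float:
        total = self.n_cells_minor + self.n_cells_major
        return self.n_cells_minor / total if total else 0.0


@dataclass
class PipelineConfig:
    """Calling thresholds shared by the downstream stages."""

    sim: SimConfig = field(default_factory=SimConfig)
    cluster_window: int = 10
    min_umi: int = 2
    primer_max_mismatch: int = 2
    map_max_mismatch_frac: float = 0.02
    min_mappable_flank: int = 25
    max_edits: int = 1
    min_detect_reads: int = 2
    batch_size: int = 4_500_000
    merge_similar_umis: bool = False


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def _as_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _as_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _as_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_dict(v) for v in obj]
    return obj


def config_to_yaml(cfg: PipelineConfig) -> str:
    return yaml.safe_dump(_as_dict(cfg), sort_keys=False)


def config_from_yaml(text: str) -> PipelineConfig:
    raw = yaml.safe_load(text)
    sim_raw = raw.pop("sim", {})
    fams = [FamilySpec(name=f["name"], consensus_length=f["consensus_length"],
                       side=f["side"], enzymes=tuple(f["enzymes"]),
                       diagnostic_offsets=tuple(f["diagnostic_offsets"]))
            for f in sim_raw.pop("families", [])] or default_families()
    enz = {k: EnzymeSpec(**v) for k, v in sim_raw.pop("enzyme_set", {}).items()} \
        or dict(DEFAULT_ENZYMES)
    events = [SomaticEventSpec(**e) for e in sim_raw.pop("somatic_events", [])]
    if "flank_length_range" in sim_raw:
        sim_raw["flank_length_range"] = tuple(sim_raw["flank_length_range"])
    sim = SimConfig(families=fams, enzyme_set=enz, somatic_events=events,
                    **sim_raw)
    return PipelineConfig(sim=sim, **raw)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from one root seed."""
    import zlib
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) % (2**31),
                               spawn_key=(zlib.crc32(name.encode()),)))
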