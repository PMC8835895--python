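"""Map parsed flanks to the mini-genome and cluster junctions into calls.

A k-mer seed index with pigeonhole seeding and Hamming verification serves
the synthetic mini-genomes; it is not a genome-scale aligner. Multi-mapping
flanks are reported unmapped (ambiguous) rather than assigned at random —
the conservative choice for somatic calling.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .config import PipelineConfig
from .dna import revcomp
from .readproc import ParsedFlank
from .simulate import MiniGenome, is_cut_site_boundary


@dataclass(frozen=True)
class MapHit:
    contig: str
    position: int      # 0-based start of the flank's genomic interval
    strand: str        # '+': flank reads left-to-right away from the element
    mismatches: int
    length: int


class GenomeIndex:
    """Exact k-mer seed table over the mini-genome reference."""

    def __init__(self, genome: MiniGenome, k: int = 13):
        self.genome = genome
        self.contig = genome.contig
        self.seq = genome.reference
        self.k = k
        table: dict[str, list[int]] = defaultdict(list)
        for i in range(len(self.seq) - k + 1):
            table[self.seq[i:i + k]].append(i)
        self.table = dict(table)

    def seed_positions(self, kmer: str) -> list[int]:
        return self.table.get(kmer, [])


def _count_mismatches(a: str, b: str, limit: int) -> int:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return limit + 1
    return d


def map_flank(flank: str, index: GenomeIndex,
              max_mismatch_frac: float = 0.02,
              min_length: int = 25) -> MapHit | None:
    """Best unique Hamming placement of a flank on either strand.

    Pigeonhole seeding: with e allowed mismatches, e+1 disjoint seeds are
    looked up, so at least one seed of the true placement is exact. Ties on
    the best mismatch count across distinct loci return None (ambiguous).
    """
    n = len(flank)
    if n < min_length:
        return None
    seq, N, k = index.seq, len(index.seq), index.k
    e = int(max_mismatch_frac * n)
    n_seeds = min(e + 1, max(1, n // k))
    best: tuple[int, int, str] | None = None
    ambiguous = False
    seen: set[tuple[int, str]] = set()
    for strand in "+-":
        query = flank if strand == "+" else revcomp(flank)
        offsets = [round(i * (n - k) / max(1, n_seeds - 1)) for i in range(n_seeds)] \
            if n_seeds > 1 else [0]
        for off in offsets:
            for pos in index.seed_positions(query[off:off + k]):
                start = pos - off
                if start < 0 or start + n > N or (start, strand) in seen:
                    continue
                seen.add((start, strand))
                d = _count_mismatches(query, seq[start:start + n], e)
                if d > e:
                    continue
                if best is None or d < best[0]:
                    best, ambiguous = (d, start, strand), False
                elif d == best[0]:
                    ambiguous = True
    if best is None or ambiguous:
        return None
    d, start, strand = best
    return MapHit(index.contig, start, strand, d, n)


@dataclass
class MappedFlank:
    """A parsed record placed on the genome with its inferred junction."""

    record: ParsedFlank
    hit: MapHit
    junction: int
    element_strand: str


def junction_of(hit: MapHit, family_side: str) -> tuple[int, str]:
    """Junction coordinate and element strand implied by a flank placement.

    A '+' placement means the flank extends rightward from the junction
    (element on the left); '-' means leftward (element on the right).
    """
    if hit.strand == "+":
        j, elem_right = hit.position, False
    else:
        j, elem_right = hit.position + hit.length, True
    if family_side == "5p":
        elem_strand = "+" if elem_right else "-"
    else:
        elem_strand = "-" if elem_right else "+"
    return j, elem_strand


def map_records(records: list[ParsedFlank], index: GenomeIndex,
                cfg: PipelineConfig) -> list[MappedFlank]:
    """Map all target records, memoizing identical flank strings."""
    panels = index.genome.panels
    cache: dict[str, MapHit | None] = {}
    out = []
    for rec in records:
        if not rec.is_target:
            continue
        hit = cache.get(rec.flank_sequence, Ellipsis)
        if hit is Ellipsis:
            hit = map_flank(rec.flank_sequence, index,
                            cfg.map_max_mismatch_frac, cfg.min_mappable_flank)
            cache[rec.flank_sequence] = hit
        if hit is None:
            continue
        side = panels[rec.family].spec.side
        j, strand = junction_of(hit, side)
        out.append(MappedFlank(rec, hit, j, strand))
    return out


@dataclass
class InsertionCall:
    """A clustered junction with UMI and read support."""

    sample_id: str
    family: str
    contig: str
    junction: int
    strand: str
    umi_count: int
    read_count: int
    supporting: list[MappedFlank] = field(repr=False, default_factory=list)
    classification: str = "unclassified"

    def recount(self) -> None:
        self.read_count = len(self.supporting)
        self.umi_count = len({m.record.umi for m in self.supporting})
        if self.supporting:
            self.junction = Counter(
                m.junction for m in self.supporting).most_common(1)[0][0]


def cluster_calls(mapped: list[MappedFlank], sample_id: str,
                  window: int = 10) -> list[InsertionCall]:
    """Single-linkage clustering of junctions within ``window`` bp.

    Records sharing family and element strand whose junction positions are
    chained by gaps <= window merge into one call; the reported junction is
    the modal position (smallest wins ties).
    """
    groups: dict[tuple[str, str], list[MappedFlank]] = defaultdict(list)
    for m in mapped:
        groups[(m.record.family, m.element_strand)].append(m)
    calls = []
    for (family, strand), ms in sorted(groups.items()):
        ms.sort(key=lambda m: m.junction)
        cluster: list[MappedFlank] = []
        for m in ms:
            if cluster and m.junction - cluster[-1].junction > window:
                calls.append(_make_call(cluster, sample_id, family, strand))
                cluster = []
            cluster.append(m)
        if cluster:
            calls.append(_make_call(cluster, sample_id, family, strand))
    calls.sort(key=lambda c: (c.contig, c.junction, c.family))
    return calls


def _make_call(cluster: list[MappedFlank], sample_id: str, family: str,
               strand: str) -> InsertionCall:
    counts = Counter(m.junction for m in cluster)
    top = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    call = InsertionCall(sample_id, family, cluster[0].hit.contig, top, strand,
                         len({m.record.umi for m in cluster}), len(cluster),
                         cluster)
    return call


# ---------------------------------------------------------------------------
# chimera filtering
# ---------------------------------------------------------------------------

def _distal_end_coord(m: MappedFlank, index: GenomeIndex,
                      cfg: PipelineConfig) -> int | None:
    """Reference coordinate of the flank's adapter-proximal (distal) end."""
    full = m.record.full_flank_len
    if full is not None:
        return m.junction + full if m.hit.strand == "+" else m.junction - full
    distal = m.record.distal_sequence
    if len(distal) < cfg.min_mappable_flank:
        return None
    hit = map_flank(distal, index, cfg.map_max_mismatch_frac,
                    cfg.min_mappable_flank)
    if hit is None and len(distal) >= cfg.min_mappable_flank + 20:
        # flanks a little shorter than the mate run the segment into RE
        # sequence at its junction-proximal end; trimming that tail leaves
        # the adapter-side terminus (the end we check) untouched
        hit = map_flank(distal[:-20], index, cfg.map_max_mismatch_frac,
                        cfg.min_mappable_flank)
    if hit is None:
        return None
    # mate-2 distal segment is the reverse complement of the flank's far
    # end: a '+' placement puts the adapter-side terminus at its start
    return hit.position if hit.strand == "+" else hit.position + hit.length


def filter_chimeras(calls: list[InsertionCall], index: GenomeIndex,
                    cfg: PipelineConfig) -> list[InsertionCall]:
    """Remove support bearing ligation or template-switch signatures.

    (a) ligation signature — the flank's distal end does not abut a
    restriction cut site of the family's enzyme cocktail;
    (b) template-switch signature — the flank's junction lies strictly
    inside an annotated RE copy (any family: a cross-subfamily switch
    within one library leaves the same footprint).
    Reads whose distal end cannot be placed are retained (no false
    filtering at the cost of recall). Calls are recounted; empty calls drop.
    """
    genome = index.genome
    intervals = [(ann["start"], ann["end"]) for ann in genome.annotations]
    kept_calls = []
    for call in calls:
        enzymes = genome.config.enzymes_for(call.family)
        kept = []
        for m in call.supporting:
            inside = any(s < m.junction < e for s, e in intervals)
            if inside:
                continue
            t = _distal_end_coord(m, index, cfg)
            if t is not None and not is_cut_site_boundary(genome.reference, t,
                                                          enzymes):
                continue
            kept.append(m)
        if kept:
            call.supporting = kept
            call.recount()
            kept_calls.append(call)
    return kept_calls
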