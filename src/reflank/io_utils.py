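"""Readers and writers for the pipeline's file formats.

FASTA via Biopython; FASTQ as gzip with Illumina-style ``/1``/``/2`` mate
naming (mtime pinned to zero so identical runs are byte-identical); calls
as BED6+ and TSV with a schema-version comment line.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mapping import InsertionCall
from .simulate import MiniGenome, ReadPair

SCHEMA_VERSION = "reflank/1"


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="")
            for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def write_fastq_pair(prefix: str | Path, reads: list[ReadPair]) -> tuple[Path, Path]:
    """Write mates to ``<prefix>_R1.fastq.gz`` / ``<prefix>_R2.fastq.gz``."""
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_R1.fastq.gz")
    p2 = prefix.with_name(prefix.name + "_R2.fastq.gz")
    for path, mate in ((p1, 1), (p2, 2)):
        with gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"),
                           mtime=0) as fh:
            for r in reads:
                seq = r.seq1 if mate == 1 else r.seq2
                qual = r.qual1 if mate == 1 else r.qual2
                fh.write(f"@{r.read_id}/{mate}\n{seq}\n+\n{qual}\n".encode())
    return p1, p2


def read_fastq_pair(p1: str | Path, p2: str | Path) -> list[ReadPair]:
    def records(path):
        op = gzip.open if str(path).endswith(".gz") else open
        with op(path, "rt") as fh:
            while True:
                header = fh.readline().strip()
                if not header:
                    return
                seq = fh.readline().strip()
                fh.readline()
                qual = fh.readline().strip()
                yield header[1:].split("/")[0].split()[0], seq, qual

    out = []
    for (id1, s1, q1), (id2, s2, q2) in zip(records(p1), records(p2)):
        if id1 != id2:
            raise ValueError(f"mate id mismatch: {id1} vs {id2}")
        out.append(ReadPair(id1, s1, q1, s2, q2))
    return out


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(f"# schema={SCHEMA_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_annotations_bed(path: str | Path, genome: MiniGenome) -> None:
    with open(path, "w") as fh:
        for ann in genome.annotations:
            fh.write(f"{genome.contig}\t{ann['start']}\t{ann['end']}\t"
                     f"{ann['copy_id']}\t0\t{ann['strand']}\n")


def write_calls_bed(path: str | Path, calls: list[InsertionCall]) -> None:
    """BED6+ with family, umi_count, read_count, classification columns."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.contig}\t{c.junction}\t{c.junction + 1}\t"
                     f"{c.family}\t{c.umi_count}\t{c.strand}\t"
                     f"{c.read_count}\t{c.classification}\n")


def calls_to_frame(calls: list[InsertionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": c.sample_id, "family": c.family, "contig": c.contig,
          "junction": c.junction, "strand": c.strand,
          "umi_count": c.umi_count, "read_count": c.read_count,
          "classification": c.classification} for c in calls],
        columns=["sample_id", "family", "contig", "junction", "strand",
                 "umi_count", "read_count", "classification"])


def write_truth_tsv(path: str | Path, genome: MiniGenome) -> None:
    rows = [{"event_id": ev.event_id, "family": ev.family,
             "junction": ev.junction, "strand": ev.strand,
             "category": ev.category, "cell_fraction": ev.cell_fraction,
             "tsd_length": ev.tsd_length, "in_database": ev.in_database}
            for ev in genome.truth_insertions]
    write_tsv(path, pd.DataFrame(rows))


def write_manifest(path: str | Path, config_text: str, seed: int,
                   inputs: dict[str, str] | None = None) -> None:
    """Run manifest: config hash, seed and input paths for reproducibility."""
    manifest = {
        "schema": SCHEMA_VERSION,
        "seed": seed,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "inputs": inputs or {},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
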