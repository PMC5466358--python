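"""Readers and writers for every external format the toolkit touches.

All interval coordinates, in memory and on disk, are BED-style 0-based
half-open ``[start, end)``.  GTF input (1-based closed) is converted on
read.  Junction identity is the tuple ``(chrom, start, end)``; strand is
carried but only enters identity when a caller asks for strict-strand
matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("circbench")

VALID_STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """Malformed input file (message names the offending line where known)."""


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome or mRNA sequence: uppercase nucleotides over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("sequence record with empty name")
        if not self.sequence:
            raise FormatError(f"sequence record {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript: ordered, non-overlapping exon intervals on one chromosome."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(
                f"transcript {self.transcript_id}: unknown strand {self.strand!r}"
            )
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise FormatError(
                    f"transcript {self.transcript_id}: exon ({start},{end}) has end <= start"
                )
            if start < prev_end:
                raise FormatError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class CircRNARecord:
    """A back-splice junction interval: acceptor at ``start``, donor side at ``end``."""

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"circRNA {self.circ_id}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise FormatError(f"circRNA {self.circ_id}: unknown strand {self.strand!r}")

    @property
    def genomic_span(self) -> int:
        return self.end - self.start

    @property
    def junction(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class PredictionRecord:
    """One tool-reported circRNA candidate with its junction read count."""

    tool: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    support: int = 0
    circ_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"prediction {self.circ_id or ''}: invalid interval [{self.start},{self.end})"
            )
        if self.support < 0:
            raise FormatError(
                f"prediction {self.chrom}:{self.start}-{self.end}: negative support"
            )

    @property
    def junction(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class TruthEntry:
    """Realized junction support for one simulated circRNA.

    ``support_pairs`` counts read pairs with at least one junction-spanning
    mate, once per pair regardless of how many mates (or wraps) cross.
    """

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    spliced_length: int
    genomic_span: int
    support_pairs: int
    total_pairs: int

    def __post_init__(self) -> None:
        if self.support_pairs < 0 or self.support_pairs > self.total_pairs:
            raise ValueError(
                f"truth {self.circ_id}: support_pairs {self.support_pairs} "
                f"outside [0, total_pairs={self.total_pairs}]"
            )
        if self.spliced_length > self.genomic_span:
            raise ValueError(
                f"truth {self.circ_id}: spliced length exceeds genomic span"
            )

    @property
    def junction(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file; sequences are uppercased, N is allowed."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(GenomeSequence(name=rec.id, sequence=seq))
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        raise FormatError(f"{path}: duplicate sequence names")
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.name, description="") for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def genome_dict(records: Sequence[GenomeSequence]) -> dict[str, str]:
    """Unique name -> sequence lookup."""
    return {r.name: r.sequence for r in records}


# ---------------------------------------------------------------------------
# GTF

def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            continue
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf_exons(path: str | Path) -> list[TranscriptModel]:
    """Parse exon features from a GTF file into transcript models.

    GTF's 1-based closed coordinates become 0-based half-open on read.
    """
    path = Path(path)
    grouped: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: exon end < start")
            if strand not in {"+", "-"}:
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            attrs = _parse_gtf_attributes(attr)
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id", tid or "")
            if not tid:
                raise FormatError(f"{path}:{lineno}: exon lacks transcript_id")
            entry = grouped.setdefault(
                tid, {"gene_id": gid, "chrom": chrom, "strand": strand, "exons": []}
            )
            if entry["chrom"] != chrom:
                raise FormatError(
                    f"{path}:{lineno}: transcript {tid} spans multiple chromosomes"
                )
            entry["exons"].append((start1 - 1, end1))
    models = []
    for tid in sorted(grouped):
        entry = grouped[tid]
        exons = tuple(sorted(entry["exons"]))
        models.append(
            TranscriptModel(
                gene_id=entry["gene_id"],
                transcript_id=tid,
                chrom=entry["chrom"],
                strand=entry["strand"],
                exons=exons,
            )
        )
    return models


def write_gtf_exons(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            for start, end in m.exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{m.chrom}\tcircbench\texon\t{start + 1}\t{end}\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED / predictions

def read_circ_bed(path: str | Path) -> list[CircRNARecord]:
    """Read a BED6 (or BED4+) file of circRNA junction intervals."""
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 and fields[3] else f"circ_{lineno}"
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in VALID_STRANDS:
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            records.append(
                CircRNARecord(circ_id=name, chrom=chrom, start=start, end=end, strand=strand)
            )
    return records


def write_circ_bed(records: Iterable[CircRNARecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.circ_id}\t0\t{r.strand}\n")


def read_predictions(path: str | Path, tool: str) -> list[PredictionRecord]:
    """Read a BED-like TSV of predicted junctions with a support column.

    Expected columns: chrom, start, end, name, support, strand (a header
    line starting with ``#`` or the word ``chrom`` is skipped).  Duplicate
    ``(chrom, start, end, strand)`` rows are merged by summing support,
    with a logged warning.
    """
    path = Path(path)
    merged: dict[tuple, dict] = {}
    n_dupes = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in {"chrom", "chr", "chromosome"}:
                continue
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: fewer than 5 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                support = int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            if support < 0:
                raise FormatError(f"{path}:{lineno}: negative support")
            name = fields[3] or None
            strand = fields[5] if len(fields) > 5 else "."
            key = (chrom, start, end, strand)
            if key in merged:
                merged[key]["support"] += support
                n_dupes += 1
            else:
                merged[key] = {"name": name, "support": support}
    if n_dupes:
        logger.warning(
            "%s: merged %d duplicate prediction row(s) by summing support", path, n_dupes
        )
    return [
        PredictionRecord(
            tool=tool,
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            support=entry["support"],
            circ_id=entry["name"],
        )
        for (chrom, start, end, strand), entry in merged.items()
    ]


def write_predictions(records: Iterable[PredictionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tname\tsupport\tstrand\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.circ_id or '.'}\t{r.support}\t{r.strand}\n"
            )


# ---------------------------------------------------------------------------
# FASTQ

def write_fastq_pair(pairs, path1: str | Path, path2: str | Path) -> None:
    """Write paired reads to two FASTQ files; mate ids get /1 and /2 suffixes.

    ``pairs`` is an iterable of objects exposing pair_id, mate1_seq,
    mate1_qual, mate2_seq, mate2_qual (see ReadPairRecord).
    """
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            if len(p.mate1_seq) != len(p.mate1_qual) or len(p.mate2_seq) != len(p.mate2_qual):
                raise ValueError(f"pair {p.pair_id}: sequence/quality length mismatch")
            f1.write(f"@{p.pair_id}/1\n{p.mate1_seq}\n+\n{p.mate1_qual}\n")
            f2.write(f"@{p.pair_id}/2\n{p.mate2_seq}\n+\n{p.mate2_qual}\n")


def read_fastq_pair(path1: str | Path, path2: str | Path) -> list[tuple[str, str, str, str, str]]:
    """Read two paired FASTQ files; returns (pair_id, seq1, qual1, seq2, qual2) tuples."""
    mates1 = list(SeqIO.parse(str(path1), "fastq"))
    mates2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(mates1) != len(mates2):
        raise FormatError(f"{path1} and {path2} have different read counts")
    out = []
    for m1, m2 in zip(mates1, mates2):
        pid1 = m1.id.removesuffix("/1")
        pid2 = m2.id.removesuffix("/2")
        if pid1 != pid2:
            raise FormatError(f"mate id mismatch: {m1.id} vs {m2.id}")
        q1 = "".join(chr(q + 33) for q in m1.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in m2.letter_annotations["phred_quality"])
        out.append((pid1, str(m1.seq), q1, str(m2.seq), q2))
    return out


# ---------------------------------------------------------------------------
# Truth and metric tables

_TRUTH_COLUMNS = [
    "circ_id", "chrom", "start", "end", "strand",
    "spliced_length", "genomic_span", "support_pairs", "total_pairs",
]


def write_truth(entries: Iterable[TruthEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for e in entries:
            fh.write(
                f"{e.circ_id}\t{e.chrom}\t{e.start}\t{e.end}\t{e.strand}\t"
                f"{e.spliced_length}\t{e.genomic_span}\t{e.support_pairs}\t{e.total_pairs}\n"
            )


def read_truth(path: str | Path) -> list[TruthEntry]:
    path = Path(path)
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TRUTH_COLUMNS:
            raise FormatError(f"{path}: unexpected truth header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(_TRUTH_COLUMNS):
                raise FormatError(f"{path}:{lineno}: wrong column count")
            entries.append(
                TruthEntry(
                    circ_id=f[0], chrom=f[1], start=int(f[2]), end=int(f[3]),
                    strand=f[4], spliced_length=int(f[5]), genomic_span=int(f[6]),
                    support_pairs=int(f[7]), total_pairs=int(f[8]),
                )
            )
    return entries


def write_metrics(report: dict, path: str | Path) -> None:
    """Write a flat metrics mapping as a two-column TSV (or JSON by extension)."""
    path = Path(path)
    if path.suffix == ".json":
        import json

        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for key in report:
                fh.write(f"{key}\t{report[key]}\n")
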