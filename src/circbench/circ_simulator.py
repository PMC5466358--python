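"""Paired-end read simulation from circularized spliced transcripts.

A circRNA is modelled as its spliced exonic sequence joined head-to-tail:
the back-splice junction lies between template positions ``L-1`` and ``0``.
Fragments are sampled from the circle with a uniform start offset and read
off the circular template, wrapping modulo ``L`` (rolling circle) whenever
the fragment is longer than the spliced length.  A mate supports the
junction iff its interval on the circle crosses the wrap point; a read
pair supports the circle iff at least one mate does, and each such pair is
counted once in the truth regardless of how many mates or wraps cross.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io_formats import (
    CircRNARecord,
    GenomeSequence,
    TranscriptModel,
    TruthEntry,
    read_fastq_pair,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: default seed for every stochastic operation in the toolkit
DEFAULT_SEED = 20160830


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class CircularTemplate:
    """The circularized spliced sequence for one circRNA.

    ``sequence`` is read 5'→3' on the transcript strand; position 0 is the
    junction acceptor side, so the back-splice junction sits between
    positions ``spliced_length - 1`` and ``0``.
    """

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"template {self.circ_id}: zero-length spliced sequence")
        if len(self.sequence) > self.genomic_span:
            raise ValueError(
                f"template {self.circ_id}: spliced length exceeds genomic span"
            )

    @property
    def spliced_length(self) -> int:
        return len(self.sequence)

    @property
    def genomic_span(self) -> int:
        return self.end - self.start

    def junction_window(self, read_len: int) -> str:
        """The junction-straddling substring: the last ``read_len - 1`` bases
        joined to the first ``read_len - 1`` bases.  Every junction-spanning
        mate of a circle with ``L >= read_len`` is a substring of it."""
        k = read_len - 1
        if self.spliced_length >= read_len:
            return self.sequence[-k:] + self.sequence[:k]
        reps = math.ceil(2 * k / self.spliced_length) + 1
        return (self.sequence * reps)[: 2 * k]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the positive (circle-derived) read simulation.

    Exactly one of ``coverage`` (fold coverage per circle) or
    ``target_support`` (junction-supporting pairs per circle) must be set.
    """

    read_len: int = 101
    insert_mean: int = 350
    insert_sd: float = 0.0
    error_rate: float = 0.01
    coverage: float | None = None
    target_support: int | None = None
    seed: int = DEFAULT_SEED
    min_support: int = 2
    max_support: int = 24

    def __post_init__(self) -> None:
        if self.read_len < 1:
            raise ConfigError("read_len must be >= 1")
        if self.insert_mean < self.read_len:
            raise ConfigError("insert_mean must be >= read_len")
        if not (0 <= self.error_rate < 1):
            raise ConfigError("error_rate must be in [0, 1)")
        if (self.coverage is None) == (self.target_support is None):
            raise ConfigError("exactly one of coverage / target_support must be set")
        if self.min_support < 0 or self.max_support < self.min_support:
            raise ConfigError("invalid [min_support, max_support] range")


@dataclass(frozen=True)
class ReadPairRecord:
    """One simulated read pair with its provenance on the source molecule."""

    pair_id: str
    mate1_seq: str
    mate2_seq: str
    mate1_qual: str
    mate2_qual: str
    origin: str
    mate1_spans: bool = False
    mate2_spans: bool = False
    frag_start: int = 0
    frag_len: int = 0

    def __post_init__(self) -> None:
        if len(self.mate1_seq) != len(self.mate1_qual) or len(self.mate2_seq) != len(
            self.mate2_qual
        ):
            raise ValueError(f"pair {self.pair_id}: sequence/quality length mismatch")

    @property
    def spans_junction(self) -> bool:
        return self.mate1_spans or self.mate2_spans


# ---------------------------------------------------------------------------
# Template construction

def build_circular_template(
    circ: CircRNARecord,
    transcripts: Sequence[TranscriptModel],
    genome: dict[str, str],
) -> CircularTemplate:
    """Build the circularized spliced template for one circRNA.

    The exon structure is taken from the annotated transcript (same
    chromosome) whose exons maximally overlap ``[start, end)``, each exon
    intersected with the circle interval.  With no overlapping transcript
    the whole genomic interval is treated as a single exon.  For minus-
    strand circles the concatenated sequence is reverse-complemented as a
    whole, so position 0 is always the junction acceptor on the transcript
    strand.
    """
    if circ.chrom not in genome:
        raise ValueError(f"circRNA {circ.circ_id}: chromosome {circ.chrom} not in genome")
    chrom_seq = genome[circ.chrom]
    if circ.end > len(chrom_seq):
        raise ValueError(
            f"circRNA {circ.circ_id}: interval [{circ.start},{circ.end}) exceeds "
            f"chromosome length {len(chrom_seq)}"
        )

    best: TranscriptModel | None = None
    best_overlap = 0
    for tm in transcripts:
        if tm.chrom != circ.chrom:
            continue
        overlap = sum(
            max(0, min(e, circ.end) - max(s, circ.start)) for s, e in tm.exons
        )
        if overlap > best_overlap:
            best, best_overlap = tm, overlap

    if best is None:
        pieces = [(circ.start, circ.end)]
    else:
        pieces = [
            (max(s, circ.start), min(e, circ.end))
            for s, e in best.exons
            if min(e, circ.end) > max(s, circ.start)
        ]

    seq = "".join(chrom_seq[s:e] for s, e in pieces).upper()
    if not seq:
        raise ValueError(f"circRNA {circ.circ_id}: zero-length spliced sequence")
    if circ.strand == "-":
        seq = reverse_complement(seq)
    return CircularTemplate(
        circ_id=circ.circ_id,
        chrom=circ.chrom,
        start=circ.start,
        end=circ.end,
        strand=circ.strand,
        sequence=seq,
    )


# ---------------------------------------------------------------------------
# Fragment geometry

def sample_fragment_start(L: int, fragment_len: int, rng: np.random.Generator) -> int:
    """Uniform fragment start offset on the circle: an integer in [0, L)."""
    if L < 1:
        raise ValueError("spliced length must be >= 1")
    return int(rng.integers(0, L))


def circular_fragment(template_seq: str, start: int, fragment_len: int) -> str:
    """Read ``fragment_len`` bases from the circular template beginning at
    ``start``, wrapping modulo the spliced length (rolling circle)."""
    L = len(template_seq)
    reps = math.ceil((start + fragment_len) / L)
    return (template_seq * reps)[start : start + fragment_len]


def mate_crosses_junction(offset: int, read_len: int, L: int) -> bool:
    """True iff a mate covering unrolled positions [offset, offset+read_len)
    contains the junction, i.e. covers both position kL-1 and kL for some k."""
    return (offset + read_len - 1) // L > offset // L


def pair_span_flags(start: int, fragment_len: int, read_len: int, L: int) -> tuple[bool, bool]:
    """(mate1 spans, mate2 spans) for a fragment at ``start`` on a circle of
    spliced length ``L``.  Mate2 reads the last ``read_len`` bases of the
    fragment (reverse strand), i.e. unrolled offset start+fragment_len-read_len."""
    m1 = mate_crosses_junction(start, read_len, L)
    m2 = mate_crosses_junction(start + fragment_len - read_len, read_len, L)
    return m1, m2


def junction_span_probability(L: int, fragment_len: int, read_len: int) -> float:
    """Exact probability that a pair with this geometry supports the junction,
    by exhaustive enumeration of all integer start offsets on the circle."""
    hits = sum(
        1 for s in range(L) if any(pair_span_flags(s, fragment_len, read_len, L))
    )
    return hits / L


# ---------------------------------------------------------------------------
# Error model

def phred_char(error_rate: float) -> str:
    """Constant Phred+33 quality character for a per-base error rate
    (Phred 40 when the rate is zero)."""
    q = 40 if error_rate == 0 else round(-10 * math.log10(error_rate))
    return chr(int(q) + 33)


def inject_errors(seq: str, error_rate: float, rng: np.random.Generator) -> tuple[str, str]:
    """Substitute each base independently with probability ``error_rate``,
    uniformly among the three alternatives; N bases are never mutated.
    Returns the mutated sequence and its constant-Phred quality string."""
    if not (0 <= error_rate < 1):
        raise ConfigError("error_rate must be in [0, 1)")
    qual = phred_char(error_rate) * len(seq)
    if error_rate == 0 or not seq:
        return seq, qual
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < error_rate
    hit &= arr != ord("N")
    idx = np.nonzero(hit)[0]
    if idx.size:
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        # pick uniformly among the 3 alternatives to the current base
        choice = rng.integers(0, 3, size=idx.size)
        for j, i in enumerate(idx):
            alts = bases[bases != arr[i]]
            arr[i] = alts[choice[j]]
    return arr.tobytes().decode("ascii"), qual


# ---------------------------------------------------------------------------
# Read simulation

def _draw_fragment_len(config: SimulationConfig, rng: np.random.Generator) -> int:
    if config.insert_sd == 0:
        return config.insert_mean
    f = int(round(rng.normal(config.insert_mean, config.insert_sd)))
    return max(f, config.read_len)


def _make_pair(
    template: CircularTemplate,
    start: int,
    frag_len: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    pair_id: str,
) -> ReadPairRecord:
    frag = circular_fragment(template.sequence, start, frag_len)
    m1_raw = frag[: config.read_len]
    m2_raw = reverse_complement(frag[-config.read_len :])
    m1, q1 = inject_errors(m1_raw, config.error_rate, rng)
    m2, q2 = inject_errors(m2_raw, config.error_rate, rng)
    s1, s2 = pair_span_flags(start, frag_len, config.read_len, template.spliced_length)
    return ReadPairRecord(
        pair_id=pair_id,
        mate1_seq=m1,
        mate2_seq=m2,
        mate1_qual=q1,
        mate2_qual=q2,
        origin=template.circ_id,
        mate1_spans=s1,
        mate2_spans=s2,
        frag_start=start,
        frag_len=frag_len,
    )


def _simulate_target_support(
    template: CircularTemplate,
    target: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    id_prefix: str,
) -> list[ReadPairRecord]:
    """Draw fragment starts conditioned on junction crossing until exactly
    ``target`` supporting pairs exist (rejection sampling)."""
    pairs: list[ReadPairRecord] = []
    L = template.spliced_length
    while len(pairs) < target:
        frag_len = _draw_fragment_len(config, rng)
        start = sample_fragment_start(L, frag_len, rng)
        if not any(pair_span_flags(start, frag_len, config.read_len, L)):
            continue
        pairs.append(
            _make_pair(template, start, frag_len, config, rng,
                       f"{id_prefix}:{len(pairs)}")
        )
    return pairs


def simulate_circ_reads(
    templates: Sequence[CircularTemplate],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadPairRecord], list[TruthEntry]]:
    """Emit paired-end reads from circular templates with truth accounting.

    In coverage mode each circle gets ``round(coverage * L / (2 * read_len))``
    pairs with uniform fragment starts; circles whose realized junction
    support falls outside ``[min_support, max_support]`` are re-drawn in
    target-support mode with a target sampled uniformly from that range.
    In target-support mode every emitted pair supports the junction and
    ``support_pairs == total_pairs == target_support``.
    """
    if not templates:
        raise ValueError("no templates to simulate from")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    reads: list[ReadPairRecord] = []
    truth: list[TruthEntry] = []
    for template in templates:
        L = template.spliced_length
        prefix = template.circ_id
        if config.target_support is not None:
            pairs = _simulate_target_support(
                template, config.target_support, config, rng, prefix
            )
        else:
            n_pairs = int(round(config.coverage * L / (2 * config.read_len)))
            pairs = []
            for i in range(n_pairs):
                frag_len = _draw_fragment_len(config, rng)
                start = sample_fragment_start(L, frag_len, rng)
                pairs.append(_make_pair(template, start, frag_len, config, rng,
                                        f"{prefix}:{i}"))
            support = sum(p.spans_junction for p in pairs)
            if not (config.min_support <= support <= config.max_support):
                target = int(rng.integers(config.min_support, config.max_support + 1))
                pairs = _simulate_target_support(template, target, config, rng, prefix)
        support = sum(p.spans_junction for p in pairs)
        reads.extend(pairs)
        truth.append(
            TruthEntry(
                circ_id=template.circ_id,
                chrom=template.chrom,
                start=template.start,
                end=template.end,
                strand=template.strand,
                spliced_length=L,
                genomic_span=template.genomic_span,
                support_pairs=support,
                total_pairs=len(pairs),
            )
        )
    return reads, truth


# ---------------------------------------------------------------------------
# Dataset mixing

def mix_datasets(
    positive_pair: tuple[str, str],
    background_pair: tuple[str, str],
    out_pair: tuple[str, str],
) -> int:
    """Concatenate a positive and a background paired FASTQ dataset.

    Read ids must be disjoint between the two inputs; the truth of the
    mixture is the positive truth unchanged.  Returns the number of pairs
    written.
    """
    pos = read_fastq_pair(*positive_pair)
    bg = read_fastq_pair(*background_pair)
    pos_ids = {p[0] for p in pos}
    collision = pos_ids.intersection(p[0] for p in bg)
    if collision:
        raise ValueError(f"read id collision between datasets: {sorted(collision)[:3]}")
    with open(out_pair[0], "w") as f1, open(out_pair[1], "w") as f2:
        for pid, s1, q1, s2, q2 in pos + bg:
            f1.write(f"@{pid}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{pid}/2\n{s2}\n+\n{q2}\n")
    return len(pos) + len(bg)
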