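"""Background dataset: paired-end reads from linear mRNA sequences.

Emulates a standard Illumina paired-end library on linear transcripts —
fragments drawn uniformly along each mRNA (no wrapping), FR orientation,
uniform substitution errors with a constant Phred string.  The elevated
default error rate models libraries whose base qualities have been shifted
down to mimic poor sequencing quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .circ_simulator import (
    ConfigError,
    DEFAULT_SEED,
    ReadPairRecord,
    inject_errors,
    reverse_complement,
)
from .io_formats import GenomeSequence

logger = logging.getLogger("circbench")

#: baseline Phred quality assumed before any quality shift
_BASE_PHRED = 30


def error_rate_from_shift(quality_shift: int, base_phred: int = _BASE_PHRED) -> float:
    """Per-base substitution rate implied by shifting a baseline Phred-30
    profile down by ``quality_shift`` (shift 13 → Phred 17 ≈ 0.02)."""
    return 10 ** (-(base_phred - quality_shift) / 10)


@dataclass(frozen=True)
class BackgroundConfig:
    """Knobs for the linear-mRNA background simulation."""

    fold_coverage: float = 200.0
    read_len: int = 101
    insert_mean: int = 350
    insert_sd: float = 10.0
    error_rate: float | None = None
    indel_rate: float = 0.0
    quality_shift: int = 13
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.fold_coverage <= 0:
            raise ConfigError("fold_coverage must be > 0")
        if self.read_len < 1:
            raise ConfigError("read_len must be >= 1")
        if self.insert_mean < self.read_len:
            raise ConfigError("insert_mean must be >= read_len")
        if self.error_rate is not None and not (0 <= self.error_rate < 1):
            raise ConfigError("error_rate must be in [0, 1)")
        if not (0 <= self.indel_rate < 1):
            raise ConfigError("indel_rate must be in [0, 1)")

    @property
    def effective_error_rate(self) -> float:
        if self.error_rate is not None:
            return self.error_rate
        return error_rate_from_shift(self.quality_shift)


def pairs_per_transcript(length: int, config: BackgroundConfig) -> int:
    """Pair count giving the configured fold coverage:
    ``round(fold_coverage * length / (2 * read_len))``."""
    return int(round(config.fold_coverage * length / (2 * config.read_len)))


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Optional geometric-length (1–3 bp) insertions/deletions at ``rate``
    events per base; output is re-trimmed/padded by the caller."""
    if rate == 0:
        return seq
    out = []
    i = 0
    bases = "ACGT"
    while i < len(seq):
        if rng.random() < rate:
            length = min(int(rng.geometric(0.5)), 3)
            if rng.random() < 0.5:  # deletion
                i += length
                continue
            out.append("".join(bases[rng.integers(0, 4)] for _ in range(length)))
        out.append(seq[i])
        i += 1
    return "".join(out)


def simulate_background(
    mrna: list[GenomeSequence],
    config: BackgroundConfig,
    rng: np.random.Generator | None = None,
) -> list[ReadPairRecord]:
    """Generate background read pairs from linear mRNA sequences.

    Transcripts no longer than the mean insert size are skipped with a
    warning; fragment lengths are Normal(insert_mean, insert_sd) rounded and
    clipped to [read_len, transcript length]; fragment starts are uniform on
    the valid placements, so no fragment wraps.  Origins are recorded as
    ``linear:<transcript_id>``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    eps = config.effective_error_rate

    eligible = [m for m in mrna if len(m) > config.insert_mean]
    skipped = len(mrna) - len(eligible)
    if skipped:
        logger.warning(
            "skipped %d transcript(s) shorter than the mean insert size (%d bp)",
            skipped,
            config.insert_mean,
        )
    if not eligible:
        raise ValueError("all transcripts are too short for the configured insert size")

    reads: list[ReadPairRecord] = []
    for m in eligible:
        n_pairs = pairs_per_transcript(len(m), config)
        for i in range(n_pairs):
            if config.insert_sd == 0:
                frag_len = config.insert_mean
            else:
                frag_len = int(round(rng.normal(config.insert_mean, config.insert_sd)))
                frag_len = min(max(frag_len, config.read_len), len(m))
            start = int(rng.integers(0, len(m) - frag_len + 1))
            frag = m.sequence[start : start + frag_len]
            if config.indel_rate:
                frag = _apply_indels(frag, config.indel_rate, rng)
                if len(frag) < config.read_len:
                    frag = frag + m.sequence[: config.read_len - len(frag)]
            m1_raw = frag[: config.read_len]
            m2_raw = reverse_complement(frag[-config.read_len :])
            m1, q1 = inject_errors(m1_raw, eps, rng)
            m2, q2 = inject_errors(m2_raw, eps, rng)
            reads.append(
                ReadPairRecord(
                    pair_id=f"linear:{m.name}:{i}",
                    mate1_seq=m1,
                    mate2_seq=m2,
                    mate1_qual=q1,
                    mate2_qual=q2,
                    origin=f"linear:{m.name}",
                    mate1_spans=False,
                    mate2_spans=False,
                    frag_start=start,
                    frag_len=frag_len,
                )
            )
    return reads
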