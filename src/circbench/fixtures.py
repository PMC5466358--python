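"""Deterministic desk-scale fixture generation and the demo pipeline.

``make_fixture`` fabricates a random genome, multi-exon gene models,
exon-bounded circRNA intervals and spliced linear mRNAs, standing in for
public catalogue downloads so every pipeline stage can run self-contained.
``end_to_end_demo`` chains fixture → simulation → mixing → evaluation →
cross-method analyses into one JSON report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats as io
from .circ_simulator import (
    DEFAULT_SEED,
    SimulationConfig,
    build_circular_template,
    mix_datasets,
    reverse_complement,
    simulate_circ_reads,
)
from .comparative import (
    classify_enrichment,
    cluster_methods,
    enrichment_summary,
    overlap_matrix,
    read_level_matrix,
)
from .evaluation import confusion, pr_curve
from .io_formats import CircRNARecord, GenomeSequence, PredictionRecord, TranscriptModel
from .linear_simulator import BackgroundConfig, simulate_background

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class FixtureError(ValueError):
    """Infeasible fixture specification (message names the constraint)."""


@dataclass(frozen=True)
class FixtureSpec:
    """Scale knobs for the synthetic genome/annotation/circRNA bundle.

    Circle spans default to 51 bp – 50 kb, junction support to 2–24 pairs,
    mirroring realistic exonic circRNA catalogues at desk scale.
    """

    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (2, 6)
    n_circles: int = 50
    circle_span: tuple[int, int] = (51, 50_000)
    support_range: tuple[int, int] = (2, 24)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1000:
            raise FixtureError("need >= 1 chromosome of >= 1 kb")
        if self.exons_per_gene[0] < 1 or self.exons_per_gene[1] < self.exons_per_gene[0]:
            raise FixtureError("exons_per_gene range is empty")
        if self.circle_span[0] < 1 or self.circle_span[1] < self.circle_span[0]:
            raise FixtureError("circle_span range is empty")
        if self.support_range[0] < 0 or self.support_range[1] < self.support_range[0]:
            raise FixtureError("support range is empty")
        if self.n_circles < 0:
            raise FixtureError("n_circles must be >= 0")


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _make_gene(
    gene_idx: int,
    chrom: str,
    chrom_length: int,
    spec: FixtureSpec,
    rng: np.random.Generator,
) -> TranscriptModel | None:
    n_exons = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
    exon_lens = rng.integers(80, 301, size=n_exons)
    # log-uniform intron lengths so both small and multi-kb circles arise
    intron_lens = np.exp(
        rng.uniform(np.log(100), np.log(max(200, spec.circle_span[1] // 3)), size=max(0, n_exons - 1))
    ).astype(int)
    gene_len = int(exon_lens.sum() + intron_lens.sum())
    if gene_len >= chrom_length - 2:
        return None
    start = int(rng.integers(0, chrom_length - gene_len))
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append((pos, pos + int(exon_lens[i])))
        pos += int(exon_lens[i])
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    strand = "+" if rng.random() < 0.5 else "-"
    return TranscriptModel(
        gene_id=f"gene{gene_idx}",
        transcript_id=f"tx{gene_idx}",
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
    )


def make_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write genome.fa, annotation.gtf, circles.bed and mrna.fa.

    Circles are exon-bounded sub-intervals of the generated transcripts
    (junctions at annotated exon boundaries), with genomic spans inside
    ``spec.circle_span``.  Fully deterministic under ``spec.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    chroms = [
        GenomeSequence(name=f"chr{i + 1}", sequence=_random_seq(spec.chrom_length, rng))
        for i in range(spec.n_chromosomes)
    ]

    transcripts: list[TranscriptModel] = []
    attempts = 0
    while len(transcripts) < spec.n_genes and attempts < 20 * spec.n_genes:
        attempts += 1
        chrom = chroms[len(transcripts) % len(chroms)]
        tm = _make_gene(len(transcripts), chrom.name, spec.chrom_length, spec, rng)
        if tm is not None:
            transcripts.append(tm)
    if len(transcripts) < spec.n_genes:
        raise FixtureError(
            f"could not place {spec.n_genes} genes on {spec.n_chromosomes} x "
            f"{spec.chrom_length} bp chromosomes"
        )

    lo, hi = spec.circle_span
    circles: list[CircRNARecord] = []
    seen: set[tuple] = set()
    attempts = 0
    max_attempts = max(1000, 400 * spec.n_circles)
    while len(circles) < spec.n_circles and attempts < max_attempts:
        attempts += 1
        tm = transcripts[int(rng.integers(0, len(transcripts)))]
        n = len(tm.exons)
        i = int(rng.integers(0, n))
        j = int(rng.integers(i, n))
        start, end = tm.exons[i][0], tm.exons[j][1]
        span = end - start
        if not (lo <= span <= hi):
            continue
        key = (tm.chrom, start, end)
        if key in seen:
            continue
        seen.add(key)
        circles.append(
            CircRNARecord(
                circ_id=f"circ{len(circles)}",
                chrom=tm.chrom,
                start=start,
                end=end,
                strand=tm.strand,
            )
        )
    if len(circles) < spec.n_circles:
        raise FixtureError(
            f"only {len(circles)}/{spec.n_circles} exon-bounded circles with span in "
            f"[{lo}, {hi}] are feasible under this gene model"
        )

    genome = io.genome_dict(chroms)
    mrnas = []
    for tm in transcripts:
        seq = "".join(genome[tm.chrom][s:e] for s, e in tm.exons)
        if tm.strand == "-":
            seq = reverse_complement(seq)
        mrnas.append(GenomeSequence(name=tm.transcript_id, sequence=seq))

    paths = {
        "genome": out_dir / "genome.fa",
        "gtf": out_dir / "annotation.gtf",
        "circles": out_dir / "circles.bed",
        "mrna": out_dir / "mrna.fa",
    }
    io.write_fasta(chroms, paths["genome"])
    io.write_gtf_exons(transcripts, paths["gtf"])
    io.write_circ_bed(circles, paths["circles"])
    io.write_fasta(mrnas, paths["mrna"])
    return paths


# ---------------------------------------------------------------------------
# Demo pipeline

def truth_as_predictions(truth_entries, tool: str = "truth") -> list[PredictionRecord]:
    """Score the simulator's own truth as a perfect predictor."""
    return [
        PredictionRecord(
            tool=tool,
            chrom=t.chrom,
            start=t.start,
            end=t.end,
            strand=t.strand,
            support=t.support_pairs,
            circ_id=t.circ_id,
        )
        for t in truth_entries
    ]


def perturb_predictions(
    preds: list[PredictionRecord], fraction: float, rng: np.random.Generator
) -> tuple[list[PredictionRecord], int]:
    """Shift the start of a given fraction of junctions by 1 bp (making
    them mismatches at tolerance 0).  Returns (perturbed, n_shifted)."""
    n_shift = int(round(fraction * len(preds)))
    idx = set(rng.choice(len(preds), size=n_shift, replace=False).tolist())
    out = []
    for i, p in enumerate(preds):
        if i in idx:
            out.append(
                PredictionRecord(
                    tool=p.tool, chrom=p.chrom, start=p.start + 1, end=p.end,
                    strand=p.strand, support=p.support, circ_id=p.circ_id,
                )
            )
        else:
            out.append(p)
    return out, n_shift


def end_to_end_demo(
    spec: FixtureSpec,
    out_dir: str | Path,
    coverage: float = 4.0,
    background_coverage: float = 3.0,
    error_rate: float = 0.01,
) -> dict:
    """Run every pipeline stage on a fixture and write demo_report.json."""
    out_dir = Path(out_dir)
    paths = make_fixture(spec, out_dir)
    genome = io.genome_dict(io.read_fasta(paths["genome"]))
    transcripts = io.read_gtf_exons(paths["gtf"])
    circles = io.read_circ_bed(paths["circles"])
    mrnas = io.read_fasta(paths["mrna"])

    templates = [build_circular_template(c, transcripts, genome) for c in circles]
    sim_cfg = SimulationConfig(
        coverage=coverage,
        error_rate=error_rate,
        seed=spec.seed,
        min_support=spec.support_range[0],
        max_support=spec.support_range[1],
    )
    reads, truth = simulate_circ_reads(templates, sim_cfg)
    pos1, pos2 = out_dir / "positive_1.fastq", out_dir / "positive_2.fastq"
    io.write_fastq_pair(reads, pos1, pos2)
    io.write_truth(truth, out_dir / "positive.truth.tsv")

    bg_cfg = BackgroundConfig(fold_coverage=background_coverage, seed=spec.seed)
    bg_reads = simulate_background(mrnas, bg_cfg)
    bg1, bg2 = out_dir / "background_1.fastq", out_dir / "background_2.fastq"
    io.write_fastq_pair(bg_reads, bg1, bg2)

    mix1, mix2 = out_dir / "mixed_1.fastq", out_dir / "mixed_2.fastq"
    n_mixed = mix_datasets((pos1, pos2), (bg1, bg2), (mix1, mix2))

    rng = np.random.default_rng(spec.seed + 1)
    perfect = truth_as_predictions(truth)
    perturbed, n_shifted = perturb_predictions(perfect, 0.10, rng)

    cc_perfect = confusion(perfect, truth, min_support=spec.support_range[0])
    cc_perturbed = confusion(perturbed, truth, min_support=spec.support_range[0])
    curve = pr_curve(perfect, truth)

    # two seeded pseudo-samples: jittered supports emulate an untreated /
    # RNase R-treated pair from the same candidate catalogue
    def jitter(preds, scale, seed):
        r = np.random.default_rng(seed)
        out = []
        for p in preds:
            s = max(0, int(round(p.support * scale * r.uniform(0.5, 1.5))))
            out.append(
                PredictionRecord(
                    tool="pseudo", chrom=p.chrom, start=p.start, end=p.end,
                    strand=p.strand, support=s, circ_id=p.circ_id,
                )
            )
        return out

    untreated = jitter(perfect, 1.0, spec.seed + 2)
    treated = jitter(perfect, 2.0, spec.seed + 3)
    enrich = classify_enrichment(
        untreated, treated,
        depth_untreated=max(1, len(reads) + len(bg_reads)),
        depth_treated=max(1, len(reads)),
    )
    esum = enrichment_summary(enrich)

    ov = overlap_matrix(
        {"truth": perfect, "perturbed": perturbed, "untreated": [p for p in untreated if p.support >= 2]}
    )
    spliced = {t.junction: t.spliced_length for t in truth}
    rlm = read_level_matrix(
        {"truth": perfect, "untreated": untreated, "treated": treated},
        spliced_lengths=spliced,
        insert_size=sim_cfg.insert_mean,
    )
    newick = None
    if rlm.values.shape[1] >= 1:
        _, newick = cluster_methods(rlm)

    report = {
        "fixture": {
            "n_circles": len(circles),
            "n_transcripts": len(transcripts),
            "seed": spec.seed,
        },
        "simulation": {
            "n_positive_pairs": len(reads),
            "n_background_pairs": len(bg_reads),
            "n_mixed_pairs": n_mixed,
        },
        "evaluation": {
            "truth_as_predictions": cc_perfect.report(),
            "perturbed_predictions": cc_perturbed.report(),
            "n_junctions_shifted": n_shifted,
            "pr_auc": round(curve.auc, 4),
            "max_recall": round(curve.max_recall, 4),
        },
        "comparative": {
            "overlap_N": ov.N.to_dict(),
            "enrichment": esum,
            "read_level_columns": int(rlm.values.shape[1]),
            "dendrogram": newick,
        },
    }
    with open(out_dir / "demo_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    return report
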