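"""Cross-method analyses on real (or realistically simulated) samples.

Covers four analyses run on tool outputs rather than simulated truth:
pairwise candidate-overlap proportions, depth-normalized RNase-R
depletion/enrichment classification with top-N summaries, read-level
sensitivity matrices with UPGMA clustering, and recovery of externally
validated circRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree

from .evaluation import match_predictions

logger = logging.getLogger("circbench")

ENRICHED_FOLD = 5.0  # ratio >= 5: significantly enriched after RNase R
NOT_DEPLETED_MIN = 1.0  # ratio >= 1: normalized counts not reduced


def _as_junction(obj) -> tuple[str, int, int]:
    if isinstance(obj, tuple):
        return obj[:3]
    return obj.junction


@dataclass(frozen=True)
class OverlapMatrix:
    """Pairwise common-candidate counts and row-normalized proportions.

    ``P.loc[i, j] = C.loc[i, j] / N[i]`` is the proportion of method i's
    candidates also found by method j; rows with N_i = 0 are NaN.
    """

    methods: tuple[str, ...]
    N: pd.Series
    C: pd.DataFrame
    P: pd.DataFrame


@dataclass(frozen=True)
class EnrichmentRecord:
    """One candidate's depth-normalized counts before/after RNase R."""

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    raw_untreated: int
    raw_treated: int
    depth_untreated: int
    depth_treated: int
    norm_untreated: float
    norm_treated: float
    ratio: float
    enrichment_class: str  # depleted | not_depleted | enriched

    @property
    def junction(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class ReadLevelMatrix:
    """log2(support + 1) per method (rows) over shared candidates (columns)."""

    values: pd.DataFrame
    n_common: int
    n_excluded_short: int


# ---------------------------------------------------------------------------

def overlap_matrix(
    candidate_sets: Mapping[str, Iterable], tolerance: int = 0
) -> OverlapMatrix:
    """Common-candidate counts C(i,j) and proportions P(i,j) = C(i,j)/N_i.

    ``candidate_sets`` maps method name to its (already support-filtered)
    candidates — junction tuples or records with a ``junction`` attribute.
    """
    methods = tuple(candidate_sets)
    junctions = {
        m: {_as_junction(c) for c in cands} for m, cands in candidate_sets.items()
    }
    N = pd.Series({m: len(junctions[m]) for m in methods}, dtype=int)
    C = pd.DataFrame(0, index=methods, columns=methods, dtype=int)
    for i in methods:
        for j in methods:
            if tolerance == 0:
                C.loc[i, j] = len(junctions[i] & junctions[j])
            else:
                recs_i = sorted(junctions[i])
                recs_j = sorted(junctions[j])
                preds = [_JunctionView(*t) for t in recs_i]
                truth = [_JunctionView(*t) for t in recs_j]
                C.loc[i, j] = len(match_predictions(preds, truth, tolerance))
    P = C.astype(float).div(N.replace(0, np.nan), axis=0)
    return OverlapMatrix(methods=methods, N=N, C=C, P=P)


@dataclass(frozen=True)
class _JunctionView:
    chrom: str
    start: int
    end: int
    strand: str = "."


def classify_enrichment(
    untreated_preds: Sequence,
    treated_preds: Sequence,
    depth_untreated: int,
    depth_treated: int,
    min_support: int = 2,
) -> list[EnrichmentRecord]:
    """Classify untreated-sample candidates by their response to RNase R.

    The classification domain is candidates with ``support >= min_support``
    in the untreated sample; candidates absent from the treated sample get
    a raw treated count of 0.  Counts are normalized per million sequenced
    read pairs and the treated/untreated ratio is classified as depleted
    (< 1), not_depleted (>= 1) or enriched (>= 5).
    """
    if depth_untreated <= 0 or depth_treated <= 0:
        raise ValueError("sequencing depths must be positive")
    treated_by_junction: dict[tuple, int] = {}
    for p in treated_preds:
        j = _as_junction(p)
        treated_by_junction[j] = treated_by_junction.get(j, 0) + p.support

    records = []
    for p in untreated_preds:
        if p.support < min_support:
            continue
        raw_t = treated_by_junction.get(_as_junction(p), 0)
        norm_u = p.support * 1e6 / depth_untreated
        norm_t = raw_t * 1e6 / depth_treated
        ratio = norm_t / norm_u
        if ratio >= ENRICHED_FOLD:
            cls = "enriched"
        elif ratio >= NOT_DEPLETED_MIN:
            cls = "not_depleted"
        else:
            cls = "depleted"
        records.append(
            EnrichmentRecord(
                circ_id=getattr(p, "circ_id", None) or f"{p.chrom}:{p.start}-{p.end}",
                chrom=p.chrom,
                start=p.start,
                end=p.end,
                strand=p.strand,
                raw_untreated=p.support,
                raw_treated=raw_t,
                depth_untreated=depth_untreated,
                depth_treated=depth_treated,
                norm_untreated=norm_u,
                norm_treated=norm_t,
                ratio=ratio,
                enrichment_class=cls,
            )
        )
    return records


def enrichment_summary(records: Sequence[EnrichmentRecord]) -> dict:
    """Count and percentage of candidates not depleted (ratio >= 1,
    including the enriched) among the classification domain."""
    n = len(records)
    n_not_depleted = sum(r.ratio >= NOT_DEPLETED_MIN for r in records)
    n_enriched = sum(r.enrichment_class == "enriched" for r in records)
    return {
        "n_candidates": n,
        "n_not_depleted": n_not_depleted,
        "n_enriched": n_enriched,
        "pct_not_depleted": round(100 * n_not_depleted / n, 2) if n else None,
    }


def top_n_summary(
    records: Sequence[EnrichmentRecord], n: int, rank_key: str = "norm_untreated"
) -> tuple[int, int]:
    """(enriched count, not-depleted count) among the top-n most highly
    expressed candidates, ranked by ``rank_key`` descending with ties
    broken by (chrom, start, end)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(records):
        logger.warning("top_n_summary: only %d records for n=%d", len(records), n)
    ranked = sorted(
        records, key=lambda r: (-getattr(r, rank_key), r.chrom, r.start, r.end)
    )[:n]
    n_enriched = sum(r.enrichment_class == "enriched" for r in ranked)
    n_not_depleted = sum(r.ratio >= NOT_DEPLETED_MIN for r in ranked)
    return n_enriched, n_not_depleted


def read_level_matrix(
    per_method_preds: Mapping[str, Sequence],
    spliced_lengths: Mapping[tuple[str, int, int], int],
    insert_size: int,
    common_only: bool = True,
) -> ReadLevelMatrix:
    """Per-method log2(support + 1) over shared candidates.

    Columns are candidates detected by every method (when ``common_only``);
    candidates whose spliced length is smaller than the insert size are
    excluded, since for those the once-vs-twice pair-counting conventions
    of different tools diverge.
    """
    methods = list(per_method_preds)
    support: dict[str, dict[tuple, int]] = {}
    for m, preds in per_method_preds.items():
        support[m] = {}
        for p in preds:
            j = _as_junction(p)
            support[m][j] = support[m].get(j, 0) + p.support
    if common_only:
        shared = set.intersection(*(set(support[m]) for m in methods)) if methods else set()
    else:
        shared = set().union(*(set(support[m]) for m in methods))
    n_common = len(shared)
    kept = {
        j for j in shared if spliced_lengths.get(j, insert_size) >= insert_size
    }
    n_excluded = n_common - len(kept)
    if not kept:
        logger.warning("read_level_matrix: no candidates left after filtering")
    columns = sorted(kept)
    data = {
        f"{c}:{s}-{e}": [np.log2(support[m].get((c, s, e), 0) + 1) for m in methods]
        for (c, s, e) in columns
    }
    values = pd.DataFrame(data, index=methods)
    return ReadLevelMatrix(values=values, n_common=n_common, n_excluded_short=n_excluded)


def convert_pair_counting(
    support_once: int, both_mates_span: bool | Sequence[bool]
) -> int:
    """Convert a once-per-pair junction count to the twice-counting
    convention: each pair whose two mates both span the junction adds 1.

    ``both_mates_span`` is one flag per supporting pair, or a single flag
    applied to all pairs (e.g. True for circles smaller than the read
    length, where geometry forces both mates to span).
    """
    if support_once < 0:
        raise ValueError("support must be >= 0")
    if isinstance(both_mates_span, bool):
        return support_once * 2 if both_mates_span else support_once
    flags = list(both_mates_span)
    if len(flags) != support_once:
        raise ValueError("need one both-mates flag per supporting pair")
    return support_once + sum(bool(f) for f in flags)


def cluster_methods(matrix: ReadLevelMatrix | pd.DataFrame):
    """Average-linkage (UPGMA) hierarchical clustering of methods by
    Euclidean distance between their log2 read-count profiles.

    Returns ``(linkage_matrix, newick)`` where the linkage matrix follows
    the scipy convention and the newick string carries merge heights.
    """
    values = matrix.values if isinstance(matrix, ReadLevelMatrix) else matrix
    if values.shape[0] < 2:
        raise ValueError("clustering needs at least 2 method rows")
    Z = linkage(values.to_numpy(dtype=float), method="average", metric="euclidean")
    labels = list(values.index)
    tree = to_tree(Z)

    def _newick(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left = _newick(node.left)
        right = _newick(node.right)
        return f"({left},{right}):{node.dist:.6g}"

    return Z, _newick(tree) + ";"


def validated_recovery(
    preds: Sequence, validated: Sequence, tolerance: int = 0
) -> tuple[int, int]:
    """(GE1, GE2): validated junctions recovered at support >= 1 and >= 2."""
    counts = []
    for min_support in (1, 2):
        kept = [p for p in preds if p.support >= min_support]
        matched = match_predictions(list(validated), kept, tolerance)
        counts.append(len(matched))
    return counts[0], counts[1]
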