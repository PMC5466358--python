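"""Circular-template construction, rolling-circle geometry and error model.

The junction accounting is checked against independent oracles: exhaustive
enumeration of integer fragment offsets for the spanning probability, and a
string search over the rotated template for read placement.
"""

import math

import numpy as np
import pytest
from scipy import stats

from circbench import io_formats as io
from circbench.circ_simulator import (
    ConfigError,
    SimulationConfig,
    build_circular_template,
    circular_fragment,
    inject_errors,
    junction_span_probability,
    mix_datasets,
    pair_span_flags,
    phred_char,
    reverse_complement,
    sample_fragment_start,
    simulate_circ_reads,
)
from conftest import make_template


def _unbounded(**kw) -> SimulationConfig:
    """Coverage-mode config with support-range enforcement disabled."""
    kw.setdefault("coverage", 20.0)
    kw.setdefault("error_rate", 0.0)
    return SimulationConfig(min_support=0, max_support=10**9, **kw)


# ---------------------------------------------------------------------------
# Template construction

def test_template_from_two_exons(toy_genome, toy_transcript):
    circ = io.CircRNARecord("c", "chr1", 0, 30, "+")
    t = build_circular_template(circ, [toy_transcript], toy_genome)
    assert t.spliced_length == 20
    assert t.genomic_span == 30
    assert t.sequence == toy_genome["chr1"][0:10] + toy_genome["chr1"][20:30]


def test_template_minus_strand_is_reverse_complement(toy_genome, toy_transcript):
    plus = build_circular_template(
        io.CircRNARecord("c", "chr1", 0, 30, "+"), [toy_transcript], toy_genome
    )
    minus = build_circular_template(
        io.CircRNARecord("c", "chr1", 0, 30, "-"), [toy_transcript], toy_genome
    )
    assert minus.sequence == reverse_complement(plus.sequence)


def test_template_fallback_single_exon(toy_genome):
    circ = io.CircRNARecord("c", "chr1", 100, 200, "+")
    t = build_circular_template(circ, [], toy_genome)
    assert t.spliced_length == t.genomic_span == 100
    assert t.sequence == toy_genome["chr1"][100:200]


def test_template_partial_exon_intersection(toy_genome, toy_transcript):
    # circle starts inside exon 1: exon pieces (5,10) and (20,30)
    circ = io.CircRNARecord("c", "chr1", 5, 30, "+")
    t = build_circular_template(circ, [toy_transcript], toy_genome)
    assert t.spliced_length == 15


def test_template_out_of_bounds_raises(toy_genome):
    circ = io.CircRNARecord("c", "chr1", 100, 10_000, "+")
    with pytest.raises(ValueError):
        build_circular_template(circ, [], toy_genome)


def test_template_unknown_chromosome_raises(toy_genome):
    with pytest.raises(ValueError):
        build_circular_template(io.CircRNARecord("c", "chrX", 0, 10, "+"), [], toy_genome)


# ---------------------------------------------------------------------------
# Fragment geometry

def test_small_circle_both_mates_always_span():
    # L=100 < fragment 350: the fragment wraps >= 3 times
    for start in range(100):
        m1, m2 = pair_span_flags(start, 350, 101, 100)
        assert m1 and m2


def test_mate1_crosses_near_template_end():
    m1, m2 = pair_span_flags(9990, 350, 101, 10_000)
    assert m1  # covers 9990..10090, wrapping the junction at 10000
    assert not m2  # covers 10239..10339


def test_fragment_wraps_modulo_spliced_length():
    t = make_template("c", 100, seed=1)
    frag = circular_fragment(t.sequence, 90, 25)
    assert frag == t.sequence[90:] + t.sequence[:15]


def test_sample_fragment_start_seeded_deterministic():
    a = [sample_fragment_start(1000, 350, np.random.default_rng(5)) for _ in range(3)]
    b = [sample_fragment_start(1000, 350, np.random.default_rng(5)) for _ in range(3)]
    assert a == b


@pytest.mark.parametrize("L", [100, 1_000, 50_000])
def test_spanning_fraction_matches_exhaustive_offset_oracle(L):
    """Empirical junction-support fraction vs enumeration of all starts."""
    p_exact = junction_span_probability(L, 350, 101)
    cfg = _unbounded(coverage=100.0)
    reads, truth = simulate_circ_reads([make_template("c", L, seed=L)], cfg)
    n = truth[0].total_pairs
    k = truth[0].support_pairs
    sigma = math.sqrt(n * p_exact * (1 - p_exact))
    assert abs(k - n * p_exact) <= max(3 * sigma, 1e-9)


def test_coverage_mode_pair_count_formula():
    cfg = _unbounded(coverage=10.0)
    _, truth = simulate_circ_reads([make_template("c", 2_000, seed=3)], cfg)
    assert truth[0].total_pairs == round(10.0 * 2_000 / (2 * 101))


# ---------------------------------------------------------------------------
# Read simulation and truth accounting

def test_target_support_mode_contract():
    cfg = SimulationConfig(target_support=5, error_rate=0.0)
    reads, truth = simulate_circ_reads([make_template("c", 100, seed=2)], cfg)
    assert truth[0].support_pairs == 5
    assert truth[0].total_pairs == 5
    assert all(r.spans_junction for r in reads)


def test_tiny_circle_every_pair_spans():
    # L=80 < read_len=101: every mate wraps, so support == total
    cfg = _unbounded(coverage=50.0)
    _, truth = simulate_circ_reads([make_template("c", 80, seed=4)], cfg)
    assert truth[0].total_pairs > 0
    assert truth[0].support_pairs == truth[0].total_pairs


def test_coverage_mode_support_range_enforced():
    cfg = SimulationConfig(coverage=400.0, error_rate=0.0)  # would realize >> 24
    _, truth = simulate_circ_reads([make_template("c", 500, seed=6)], cfg)
    assert 2 <= truth[0].support_pairs <= 24


def test_truth_support_recomputable_from_fragment_coordinates():
    cfg = _unbounded(coverage=30.0)
    reads, truth = simulate_circ_reads([make_template("c", 1_500, seed=7)], cfg)
    recount = sum(
        any(pair_span_flags(r.frag_start, r.frag_len, cfg.read_len, 1_500))
        for r in reads
    )
    assert recount == truth[0].support_pairs


def test_spanning_mates_found_in_junction_window():
    """String-search oracle: every junction-spanning mate (error-free) is a
    substring of the junction-straddling window of the rotated template."""
    for L in (150, 1_000):
        t = make_template("c", L, seed=L)
        cfg = _unbounded(coverage=40.0)
        reads, _ = simulate_circ_reads([t], cfg)
        window = t.junction_window(cfg.read_len)
        unrolled = t.sequence * math.ceil((L + 350 + 101) / L + 1)
        for r in reads:
            if r.mate1_spans:
                assert r.mate1_seq in window
            else:
                assert r.mate1_seq in unrolled
            mate2_fwd = reverse_complement(r.mate2_seq)
            if r.mate2_spans:
                assert mate2_fwd in window
            else:
                assert mate2_fwd in unrolled


def test_mates_are_fragment_ends():
    t = make_template("c", 5_000, seed=8)
    cfg = _unbounded(coverage=5.0)
    reads, _ = simulate_circ_reads([t], cfg)
    for r in reads[:20]:
        frag = circular_fragment(t.sequence, r.frag_start, r.frag_len)
        assert r.mate1_seq == frag[:101]
        assert r.mate2_seq == reverse_complement(frag[-101:])


def test_insert_mean_below_read_len_rejected():
    with pytest.raises(ConfigError):
        SimulationConfig(insert_mean=50, read_len=101, coverage=1.0)


def test_exactly_one_sampling_mode_required():
    with pytest.raises(ConfigError):
        SimulationConfig(coverage=1.0, target_support=5)
    with pytest.raises(ConfigError):
        SimulationConfig()


def test_support_scales_with_coverage():
    """Realized support grows ~linearly with coverage at fixed spliced length."""
    t = make_template("c", 20_000, seed=9)
    coverages = [2, 4, 8, 16, 32, 64, 128]
    supports = []
    for cov in coverages:
        cfg = _unbounded(coverage=float(cov))
        _, truth = simulate_circ_reads([t], cfg, rng=np.random.default_rng(11))
        supports.append(truth[0].support_pairs)
    rho = stats.spearmanr(coverages, supports).statistic
    assert rho > 0.95


def test_no_pair_attributed_to_two_circles():
    templates = [make_template(f"c{i}", 400 + 100 * i, seed=i) for i in range(4)]
    cfg = _unbounded(coverage=10.0)
    reads, truth = simulate_circ_reads(templates, cfg)
    assert len(reads) == sum(t.total_pairs for t in truth)
    assert len({r.pair_id for r in reads}) == len(reads)
    per_circle = {t.circ_id: t.total_pairs for t in truth}
    for r in reads:
        per_circle[r.origin] -= 1
    assert all(v == 0 for v in per_circle.values())


# ---------------------------------------------------------------------------
# Error model

def test_inject_errors_zero_rate_identity(rng):
    seq = "ACGTN" * 20
    out, qual = inject_errors(seq, 0.0, rng)
    assert out == seq
    assert qual == phred_char(0.0) * len(seq)
    assert phred_char(0.0) == chr(40 + 33)


def test_inject_errors_rate_one_rejected(rng):
    with pytest.raises(ConfigError):
        inject_errors("ACGT", 1.0, rng)


def test_inject_errors_never_mutates_n(rng):
    out, _ = inject_errors("N" * 1000, 0.5, rng)
    assert out == "N" * 1000


def test_inject_errors_binomial_oracle(rng):
    """Mismatch count over 1e6 bases within 3 binomial sigma of eps=0.01."""
    n, eps = 1_000_000, 0.01
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
    out, qual = inject_errors(seq, eps, rng)
    mismatches = sum(a != b for a, b in zip(seq, out))
    sigma = math.sqrt(n * eps * (1 - eps))
    assert abs(mismatches - n * eps) <= 3 * sigma
    assert qual == chr(20 + 33) * n  # Phred 20 at 1% error


def test_inject_errors_substitutes_to_different_base(rng):
    seq = "A" * 5000
    out, _ = inject_errors(seq, 0.5, rng)
    changed = {b for a, b in zip(seq, out) if b != a}
    assert changed <= {"C", "G", "T"} and changed  # never silently resamples A


# ---------------------------------------------------------------------------
# Determinism and mixing

def test_simulation_deterministic_byte_identical(tmp_path):
    cfg = SimulationConfig(coverage=5.0, seed=20160830)
    templates = [make_template("c0", 600, seed=0), make_template("c1", 90, seed=1)]
    outs = []
    for run in ("a", "b"):
        reads, truth = simulate_circ_reads(templates, cfg)
        p1, p2 = tmp_path / f"{run}_1.fastq", tmp_path / f"{run}_2.fastq"
        pt = tmp_path / f"{run}.truth.tsv"
        io.write_fastq_pair(reads, p1, p2)
        io.write_truth(truth, pt)
        outs.append((p1.read_bytes(), p2.read_bytes(), pt.read_bytes()))
    assert outs[0] == outs[1]


def _write_pairs(tmp_path, prefix, pairs):
    p1 = tmp_path / f"{prefix}_1.fastq"
    p2 = tmp_path / f"{prefix}_2.fastq"
    io.write_fastq_pair(pairs, p1, p2)
    return p1, p2


def test_mix_concatenates_and_preserves_counts(tmp_path):
    cfg = SimulationConfig(target_support=5, error_rate=0.0)
    reads, _ = simulate_circ_reads([make_template("c", 300, seed=3)], cfg)
    pos = _write_pairs(tmp_path, "pos", reads[:2])
    bg = _write_pairs(tmp_path, "bg", [])
    out = (tmp_path / "mix_1.fastq", tmp_path / "mix_2.fastq")
    n = mix_datasets(pos, bg, out)
    assert n == 2
    # mixing with an empty background leaves the positive set unchanged
    assert out[0].read_bytes() == pos[0].read_bytes()


def test_mix_rejects_id_collision(tmp_path):
    cfg = SimulationConfig(target_support=3, error_rate=0.0)
    reads, _ = simulate_circ_reads([make_template("c", 300, seed=3)], cfg)
    pos = _write_pairs(tmp_path, "pos", reads)
    bg = _write_pairs(tmp_path, "bg", reads)  # identical ids
    out = (tmp_path / "mix_1.fastq", tmp_path / "mix_2.fastq")
    with pytest.raises(ValueError):
        mix_datasets(pos, bg, out)
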