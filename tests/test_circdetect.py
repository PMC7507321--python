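"""Back-splice detector: anchor index, breakpoint placement against a
rotation oracle, strand behaviour, QC filters and normalization."""

import numpy as np
import pandas as pd
import pytest

from circnigra import (
    BackspliceJunction, CircCountMatrix, DetectParams, build_index,
    call_junctions, detect_backsplice, filter_by_tissue, normalize_per_million,
    qc_filter_samples, default_cohort_design, simulate_cohort,
)
from circnigra._seq import revcomp
from circnigra.synthgen import junction_key


# ---------------------------------------------------------------------------
# k-mer index
# ---------------------------------------------------------------------------

def test_kmer_index_lookup_classes():
    genome = {"c1": "ACGTACGTACGTACGT" * 2}
    idx = build_index(genome, k=12)
    hits = idx.lookup(genome["c1"][:12])
    assert any(h == ("c1", 0, "+") for h in hits)
    assert idx.classify(genome["c1"][:12]) == "multi"  # periodic sequence
    assert idx.classify("A" * 12) == "none"
    rng = np.random.default_rng(5)
    from circnigra._seq import decode
    uniq = decode(rng.integers(0, 4, 400).astype(np.uint8))
    idx2 = build_index({"c1": uniq + uniq[:50]}, k=20)  # duplicated prefix
    assert idx2.classify(uniq[:20]) == "multi"
    assert idx2.classify(uniq[100:120]) == "unique"


def test_kmer_index_rejects_bad_k():
    genome = {"c1": "ACGT" * 20}
    with pytest.raises(ValueError):
        build_index(genome, k=8)
    with pytest.raises(ValueError):
        build_index(genome, k=100)


# ---------------------------------------------------------------------------
# breakpoint placement
# ---------------------------------------------------------------------------

def _rotation_oracle(circle, chrom_seq, s, e, read, max_mm):
    """Independent check: some rotation of the circle reproduces the read."""
    L = len(circle)
    best = None
    for x in range(L):
        rot = (circle + circle)[x:x + len(read)]
        mm = sum(1 for a, b in zip(rot, read) if a != b)
        if best is None or mm < best:
            best = mm
    return best is not None and best <= max_mm


@pytest.fixture
def toy(toy_circle_genome):
    genome = toy_circle_genome
    idx = build_index(genome, k=20)
    seq = genome.chromosomes["c1"]
    circle = seq[300:400]
    return genome, idx, seq, circle


def test_constructed_canonical_circle(toy):
    genome, idx, seq, circle = toy
    read = seq[380:400] + seq[300:320]
    params = DetectParams(anchor_len=20)
    jun = detect_backsplice(read, idx, genome, params)
    assert (jun.chrom, jun.start, jun.end, jun.strand) == ("c1", 300, 400, "+")
    # linear order: no head-to-tail
    assert detect_backsplice(seq[300:320] + seq[380:400], idx, genome,
                             params) is None


def test_interior_substitution_recovers_same_junction(toy):
    genome, idx, seq, circle = toy
    read = seq[370:400] + seq[300:330]
    mutated = read[:30] + ("A" if read[30] != "A" else "C") + read[31:]
    params = DetectParams(anchor_len=20, max_mismatch_extend=2)
    jun = detect_backsplice(mutated, idx, genome, params)
    assert (jun.start, jun.end) == (300, 400)
    assert _rotation_oracle(circle, seq, 300, 400, mutated, max_mm=2)


def test_rotation_invariance_of_detected_junction(toy):
    genome, idx, seq, circle = toy
    R, L = 60, len(circle)
    params = DetectParams(anchor_len=20)
    doubled = circle + circle
    seen = set()
    for x in range(L - R + 1, L):  # every junction-crossing start
        read = doubled[x:x + R]
        b = L - x  # breakpoint offset inside the read
        jun = detect_backsplice(read, idx, genome, params)
        if 20 <= b <= R - 20:
            assert (jun.start, jun.end) == (300, 400)
            seen.add(x)
    assert len(seen) == R - 39


def test_reverse_complement_flips_strand(toy):
    genome, idx, seq, circle = toy
    read = circle[-40:] + circle[:40]
    params = DetectParams(anchor_len=20)
    j1 = detect_backsplice(read, idx, genome, params)
    j2 = detect_backsplice(revcomp(read), idx, genome, params)
    assert (j1.start, j1.end, j1.strand) == (300, 400, "+")
    assert (j2.start, j2.end, j2.strand) == (300, 400, "-")


def test_non_canonical_junction_requires_gt_ag_off(toy):
    genome, idx, seq, circle = toy
    # a "circle" whose bounds carry no GT/AG: shift inside the exon
    read = seq[370:390] + seq[310:330]
    strict = DetectParams(anchor_len=20, require_gt_ag=True,
                          breakpoint_ambiguity_max=2)
    assert detect_backsplice(read, idx, genome, strict) is None
    lax = DetectParams(anchor_len=20, require_gt_ag=False)
    jun = detect_backsplice(read, idx, genome, lax)
    assert (jun.start, jun.end) == (310, 390)


def test_read_with_ambiguous_base_is_skipped(toy):
    genome, idx, seq, circle = toy
    read = seq[380:400] + seq[300:319] + "N"
    assert detect_backsplice(read, idx, genome) is None


# ---------------------------------------------------------------------------
# cohort-level calling and filters
# ---------------------------------------------------------------------------

def _toy_matrix(counts: dict, mapped: dict, junctions=None) -> CircCountMatrix:
    keys = sorted(counts)
    if junctions is None:
        junctions = []
        for k in keys:
            chrom, rest = k.split(":")
            coords, strand = rest[:-3], rest[-2]
            s, e = coords.split("-")
            junctions.append(BackspliceJunction(chrom, int(s), int(e), strand))
    df = pd.DataFrame({sid: [counts[k][sid] for k in keys]
                       for sid in mapped}, index=keys)
    return CircCountMatrix(junctions=junctions, counts=df,
                           mapped_totals=pd.Series(mapped))


def test_call_junctions_counts_and_min_support(toy):
    genome, idx, seq, circle = toy
    junc_read = seq[380:400] + seq[300:320]
    linear_read = seq[100:140]
    reads = {"s1": [junc_read] * 10 + [linear_read] * 5}
    mat = call_junctions(reads, genome, min_support=2)
    assert list(mat.counts.index) == ["c1:300-400(+)"]
    assert mat.counts.iloc[0, 0] == 10
    assert mat.mapped_totals["s1"] == 15
    single = call_junctions({"s1": [junc_read, linear_read]}, genome,
                            min_support=2)
    assert len(single.junctions) == 0
    empty = call_junctions({"s1": [junc_read] * 3, "s2": []}, genome,
                           min_support=2)
    assert list(empty.counts.columns) == ["s1", "s2"]
    assert empty.counts["s2"].sum() == 0


def test_recovery_on_simulated_sample(demo_genome, demo_cohort):
    """Error-free simulation: detected set == truth junctions with >= 2
    expected reads; every detected coordinate matches truth exactly."""
    cohort = demo_cohort
    mat = call_junctions(
        {sid: s.reads for sid, s in cohort.samples.items()},
        demo_genome, min_support=2)
    truth = {junction_key(*c) for c in cohort.truth.junction_coords}
    detected = set(mat.counts.index)
    assert detected <= truth  # precision 1.0
    exp = cohort.truth.expected_counts.sum(axis=1)
    strong = set(exp[exp >= 2].index)
    assert len(detected & strong) / len(strong) >= 0.95


def test_slide_variant_consensus_merge():
    """Breakpoint-slide variants (same span, starts within the ambiguity
    window) collapse onto the majority placement; unrelated junctions and
    same-span junctions further apart are untouched."""
    from circnigra.circdetect import _merge_slide_variants

    juns = {
        "a": BackspliceJunction("c1", 300, 400, "+"),
        "b": BackspliceJunction("c1", 298, 398, "+"),   # slide of `a`
        "c": BackspliceJunction("c1", 800, 900, "+"),   # same span, far away
        "d": BackspliceJunction("c1", 300, 400, "-"),   # other strand
    }
    objs = {j.key: j for j in juns.values()}
    per_sample = {
        "s1": {juns["a"].key: 5, juns["b"].key: 2, juns["c"].key: 3},
        "s2": {juns["a"].key: 4, juns["d"].key: 1},
    }
    counts, kept = _merge_slide_variants(per_sample, objs, window=2)
    assert juns["b"].key not in kept
    assert counts["s1"][juns["a"].key] == 7
    assert counts["s2"][juns["a"].key] == 4
    assert counts["s1"][juns["c"].key] == 3
    assert counts["s2"][juns["d"].key] == 1


def test_qc_filter_samples_strict_threshold():
    counts = {"c1:10-20(+)": {"a": 4999, "b": 5000, "c": 0}}
    mat = _toy_matrix(counts, {"a": 10000, "b": 10000, "c": 10000})
    out = qc_filter_samples(mat, min_detected=5000, unit="reads")
    assert list(out.counts.columns) == ["b"]
    assert list(qc_filter_samples(mat, 0).counts.columns) == ["a", "b", "c"]
    with pytest.raises(ValueError, match="all samples"):
        qc_filter_samples(mat, min_detected=10_000, unit="reads")


def test_filter_by_tissue_strict_and_unique():
    counts = {
        "c1:10-20(+)": {"sn1": 3, "sn2": 3, "mtg1": 0},   # 6 reads in SN
        "c1:30-40(+)": {"sn1": 5, "sn2": 0, "mtg1": 0},   # exactly 5: out
        "c1:50-60(+)": {"sn1": 0, "sn2": 0, "mtg1": 9},
    }
    mat = _toy_matrix(counts, {"sn1": 100, "sn2": 100, "mtg1": 100})
    meta = pd.DataFrame({"region": ["SN", "SN", "MTG"]},
                        index=["sn1", "sn2", "mtg1"])
    out = filter_by_tissue(mat, meta, min_reads=5)
    assert set(out.counts.index) == {"c1:10-20(+)", "c1:50-60(+)"}
    exp = out.tissue_expressed
    assert bool(exp.loc["c1:10-20(+)", "SN"]) and not bool(
        exp.loc["c1:10-20(+)", "MTG"])
    assert bool(exp.loc["c1:50-60(+)", "MTG"])
    with pytest.raises(ValueError):
        filter_by_tissue(mat, pd.DataFrame(index=meta.index), min_reads=5)


def test_filter_monotonicity(demo_genome, demo_cohort):
    cohort = demo_cohort
    reads = {sid: s.reads for sid, s in cohort.samples.items()}
    m1 = call_junctions(reads, demo_genome, min_support=1)
    m2 = call_junctions(reads, demo_genome, min_support=3)
    assert set(m2.counts.index) <= set(m1.counts.index)
    meta = pd.DataFrame(
        {"region": [s.meta.region for s in cohort.samples.values()]},
        index=list(cohort.samples))
    f5 = filter_by_tissue(m1, meta, min_reads=5)
    f10 = filter_by_tissue(m1, meta, min_reads=10)
    assert set(f10.counts.index) <= set(f5.counts.index)


def test_normalize_per_million():
    counts = {"c1:10-20(+)": {"a": 50, "b": 0}}
    mat = _toy_matrix(counts, {"a": 1_000_000, "b": 2_000_000})
    norm = normalize_per_million(mat)
    assert norm.loc["c1:10-20(+)", "a"] == pytest.approx(50.0)
    assert norm.loc["c1:10-20(+)", "b"] == 0.0
    doubled = _toy_matrix({"c1:10-20(+)": {"a": 100, "b": 0}},
                          {"a": 2_000_000, "b": 4_000_000})
    assert np.allclose(normalize_per_million(doubled), norm)
    bad = _toy_matrix({"c1:10-20(+)": {"a": 0}}, {"a": 0})
    with pytest.raises(ValueError, match="a"):
        normalize_per_million(bad)
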