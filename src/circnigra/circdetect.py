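"""Back-splice (head-to-tail) junction detection and circRNA count matrices.

A read supports a back-splice junction when its two terminal anchors map
uniquely to the same chromosome in reversed genomic order (the 5' anchor
downstream of the 3' anchor).  Anchors are matched exactly through a k-mer
index; the breakpoint is located by extending both anchors toward the read
interior under a mismatch budget and is disambiguated by the canonical GT/AG
splice signal.  Reads supporting a junction are the absolute abundance
measure; sample- and tissue-level QC filters and per-million normalization
turn the raw calls into an analysis-ready count matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from ._seq import revcomp
from .synthgen import GenomeModel, junction_key

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")


# ---------------------------------------------------------------------------
# k-mer anchor index
# ---------------------------------------------------------------------------

class KmerIndex:
    """Exact-match k-mer index over both strands of a genome.

    Positions refer to the plus strand; a '-' hit at (chrom, pos) means the
    reverse complement of the query k-mer occurs at [pos, pos+k).
    """

    def __init__(self, genome: Union[GenomeModel, dict], k: int):
        chroms = genome.chromosomes if isinstance(genome, GenomeModel) else genome
        if not 12 <= k <= 32:
            raise ValueError("anchor length k must be in [12, 32]")
        if k > min(len(s) for s in chroms.values()):
            raise ValueError("k longer than the shortest chromosome")
        self.k = k
        self.chromosomes = dict(chroms)
        positions: dict[str, list[tuple[str, int, str]]] = {}
        for chrom, seq in chroms.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos:pos + k]
                positions.setdefault(kmer, []).append((chrom, pos, "+"))
        self.positions = positions

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All exact hits of the k-mer on either strand."""
        hits = list(self.positions.get(kmer, ()))
        rc = revcomp(kmer)
        hits += [(c, p, "-") for (c, p, _s) in self.positions.get(rc, ())]
        return hits

    def classify(self, kmer: str) -> str:
        n = len(self.lookup(kmer))
        return "none" if n == 0 else ("unique" if n == 1 else "multi")


def build_index(genome: Union[GenomeModel, dict], k: int = 20) -> KmerIndex:
    return KmerIndex(genome, k)


# ---------------------------------------------------------------------------
# junction type and detection parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackspliceJunction:
    """A genomic circle: [start, end) with the acceptor at start (first base
    of the circle) and the donor at end (one past its last base)."""

    chrom: str
    start: int
    end: int
    strand: str
    splice_signal: tuple[str, str] = ("", "")  # (donor-side, acceptor-side)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("junction start must be < end")

    @property
    def key(self) -> str:
        return junction_key(self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DetectParams:
    anchor_len: int = 20
    max_span: int = 100_000
    breakpoint_ambiguity_max: int = 2
    require_gt_ag: bool = True
    max_mismatch_extend: int = 2


def _splice_signal_ok(genome_seq: str, s: int, e: int) -> bool:
    """Canonical GT/AG at the circle bounds, in either transcribed orientation.

    A plus-strand circle shows GT just past ``end`` and AG just before
    ``start``; a minus-strand circle shows their reverse complements AC/CT.
    """
    if s < 2 or e + 2 > len(genome_seq):
        return False
    up = genome_seq[s - 2:s]     # acceptor side on plus strand
    dn = genome_seq[e:e + 2]     # donor side on plus strand
    return (dn == "GT" and up == "AG") or (up == "AC" and dn == "CT")


def detect_backsplice(
    read: str,
    index: KmerIndex,
    genome: Union[GenomeModel, dict],
    params: DetectParams = DetectParams(),
) -> Optional[BackspliceJunction]:
    """Detect a head-to-tail junction candidate in one read, or return None.

    The first and last ``anchor_len`` bases must each map uniquely (exact
    match) to the same chromosome with the 3' anchor genomically upstream of
    the 5' anchor.  Both anchors are extended toward the read interior under
    the mismatch budget to place the breakpoint; ambiguous placements slide
    within ``breakpoint_ambiguity_max`` to the position giving the canonical
    GT/AG signal, from which the circle strand is assigned.
    """
    a = params.anchor_len
    if len(read) < 2 * a:
        raise ValueError("read shorter than two anchors")
    if not _VALID.issuperset(read):
        logger.warning("skipping read with non-ACGT base")
        return None
    chroms = genome.chromosomes if isinstance(genome, GenomeModel) else genome

    for oriented, strand in ((read, "+"), (revcomp(read), "-")):
        hit1 = index.positions.get(oriented[:a], ())
        hit2 = index.positions.get(oriented[-a:], ())
        if len(hit1) != 1 or len(hit2) != 1:
            continue
        (c1, p1, _), (c2, p2, _) = hit1[0], hit2[0]
        if c1 != c2:
            continue
        jun = _place_breakpoint(oriented, chroms[c1], c1, p1, p2, params,
                                strand)
        if jun is not None:
            return jun
    return None


def _place_breakpoint(
    read: str, seq: str, chrom: str, p1: int, p2: int, params: DetectParams,
    strand: str = "+",
) -> Optional[BackspliceJunction]:
    a, R = params.anchor_len, len(read)
    # read[j] aligns to seq[p1 + j] before the breakpoint and to
    # seq[p2 + j - (R - a)] after it; breakpoint b in [a, R - a].
    off2 = p2 - (R - a)
    # circle bounds are (off2 + b, p1 + b): span is constant, so the
    # head-to-tail geometry can be rejected before any extension work
    if off2 >= p1 or p1 - off2 > params.max_span:
        return None
    # mismatch prefix sums
    pre = np.zeros(R + 1, dtype=np.int32)
    suf = np.zeros(R + 1, dtype=np.int32)
    for j in range(R):
        g = p1 + j
        pre[j + 1] = pre[j] + (1 if (g >= len(seq) or read[j] != seq[g]) else 0)
    for j in range(R - 1, -1, -1):
        g = off2 + j
        suf[j] = suf[j + 1] + (1 if (g < 0 or g >= len(seq) or read[j] != seq[g]) else 0)
    bs = np.arange(a, R - a + 1)
    mism = pre[bs] + suf[bs]
    best = int(mism.min())
    if best > params.max_mismatch_extend:
        return None
    best_bs = bs[mism == best]

    def bounds(b: int) -> tuple[int, int]:
        return off2 + b, p1 + b  # (circle start s, circle end e)

    # candidate breakpoints: within the ambiguity window of a minimal one
    feasible = []
    for b in bs[mism <= params.max_mismatch_extend]:
        if np.min(np.abs(best_bs - b)) <= params.breakpoint_ambiguity_max:
            feasible.append(int(b))
    canonical = []
    for b in feasible:
        s, e = bounds(b)
        if not (s < e and e - s <= params.max_span):
            continue
        if _splice_signal_ok(seq, s, e):
            canonical.append((int(pre[b] + suf[b]), b, s, e))
    if canonical:
        _, b, s, e = min(canonical)
        return BackspliceJunction(chrom, s, e, strand, ("GT", "AG"))
    if params.require_gt_ag:
        return None
    b = int(best_bs[0])
    s, e = bounds(b)
    if not (s < e and e - s <= params.max_span):
        return None
    signal = (seq[e:e + 2] if e + 2 <= len(seq) else "",
              seq[s - 2:s] if s >= 2 else "")
    return BackspliceJunction(chrom, s, e, strand, signal)


# ---------------------------------------------------------------------------
# cohort-level junction calling
# ---------------------------------------------------------------------------

@dataclass
class CircCountMatrix:
    """Junction x sample supporting-read counts plus per-sample mapped totals."""

    junctions: list[BackspliceJunction]
    counts: pd.DataFrame          # index: junction keys; columns: sample ids
    mapped_totals: pd.Series      # per-sample reads with >= 1 anchor hit
    meta: Optional[pd.DataFrame] = None
    tissue_expressed: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        keys = [j.key for j in self.junctions]
        if list(self.counts.index) != keys:
            raise ValueError("counts index inconsistent with junction list")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        short = self.mapped_totals.reindex(self.counts.columns)
        if (short < self.counts.sum(axis=0)).any():
            raise ValueError("mapped_totals below column sums")

    def subset(self, keys: Iterable[str] = None, samples: Iterable[str] = None
               ) -> "CircCountMatrix":
        keys = list(self.counts.index if keys is None else keys)
        samples = list(self.counts.columns if samples is None else samples)
        jmap = {j.key: j for j in self.junctions}
        return CircCountMatrix(
            junctions=[jmap[k] for k in keys],
            counts=self.counts.loc[keys, samples].copy(),
            mapped_totals=self.mapped_totals.loc[samples].copy(),
            meta=None if self.meta is None else self.meta.loc[
                self.meta.index.intersection(samples)].copy(),
            tissue_expressed=None if self.tissue_expressed is None
            else self.tissue_expressed.loc[keys].copy(),
        )


def _iter_read_seqs(source) -> Iterable[str]:
    if isinstance(source, (str,)) or hasattr(source, "__fspath__"):
        from .io import read_fastq

        for _name, seq, _q in read_fastq(source):
            yield seq
    else:
        for item in source:
            yield item if isinstance(item, str) else item[1]


def call_junctions(
    reads_by_sample: Mapping[str, object],
    genome: Union[GenomeModel, dict],
    params: DetectParams = DetectParams(),
    min_support: int = 2,
    meta: Optional[pd.DataFrame] = None,
    index: Optional[KmerIndex] = None,
) -> CircCountMatrix:
    """Count junction-supporting reads per sample and assemble the matrix.

    ``reads_by_sample`` maps sample id to a FASTQ path or an iterable of read
    sequences.  Junctions with total cohort support below ``min_support`` are
    dropped.  ``mapped_totals`` counts reads with at least one unique-or-multi
    anchor hit (the stand-in for aligner mapped-read totals).
    """
    if not reads_by_sample:
        raise ValueError("at least one sample required")
    chroms = genome.chromosomes if isinstance(genome, GenomeModel) else genome
    if index is None:
        index = build_index(chroms, params.anchor_len)
    a = params.anchor_len

    per_sample: dict[str, dict[str, int]] = {}
    junction_objs: dict[str, BackspliceJunction] = {}
    mapped: dict[str, int] = {}
    for sid, source in reads_by_sample.items():
        counts: dict[str, int] = {}
        n_mapped = 0
        n_total = 0
        pos = index.positions
        for seq in _iter_read_seqs(source):
            n_total += 1
            if not _VALID.issuperset(seq):
                logger.warning("sample %s: skipping read with non-ACGT base", sid)
                continue
            R = len(seq)
            h1 = pos.get(seq[:a])
            if h1 is not None and len(h1) == 1:
                c, p, _s = h1[0]
                if chroms[c][p:p + R] == seq:
                    n_mapped += 1   # fast path: perfect contiguous match
                    continue
            jun = None
            any_hit = False
            for oriented, strand in ((seq, "+"), (revcomp(seq), "-")):
                hh1 = pos.get(oriented[:a], ())
                hh2 = pos.get(oriented[-a:], ())
                if hh1 or hh2:
                    any_hit = True
                if len(hh1) == 1 and len(hh2) == 1 and hh1[0][0] == hh2[0][0]:
                    c1, p1, _ = hh1[0]
                    _c2, p2, _ = hh2[0]
                    jun = _place_breakpoint(oriented, chroms[c1], c1, p1, p2,
                                            params, strand)
                    if jun is not None:
                        break
            if jun is not None:
                counts[jun.key] = counts.get(jun.key, 0) + 1
                junction_objs.setdefault(jun.key, jun)
                n_mapped += 1
            elif any_hit:
                n_mapped += 1
        if n_total == 0:
            logger.warning("sample %s: empty input, zero column retained", sid)
        per_sample[sid] = counts
        mapped[sid] = n_mapped

    # consensus merge of breakpoint-slide variants: reads with sequencing
    # errors can legally place the breakpoint at an alternative canonical
    # position within the ambiguity window; variants with identical span on
    # the same strand whose coordinates differ by <= the window collapse to
    # the majority-supported placement
    merged = _merge_slide_variants(per_sample, junction_objs,
                                   params.breakpoint_ambiguity_max)
    per_sample, junction_objs = merged

    keys = sorted(junction_objs)
    counts_df = pd.DataFrame(
        {sid: [per_sample[sid].get(k, 0) for k in keys] for sid in per_sample},
        index=keys, dtype=np.int64,
    )
    support = counts_df.sum(axis=1)
    keep = support[support >= min_support].index.tolist()
    dropped = len(keys) - len(keep)
    if dropped:
        logger.info("call_junctions: dropped %d junctions below min_support=%d",
                    dropped, min_support)
    counts_df = counts_df.loc[keep]
    return CircCountMatrix(
        junctions=[junction_objs[k] for k in keep],
        counts=counts_df,
        mapped_totals=pd.Series(mapped, dtype=np.int64),
        meta=meta,
    )


def _merge_slide_variants(per_sample, junction_objs, window):
    """Collapse junctions that are pure breakpoint slides of one another
    (same chrom, strand and circle span; starts within ``window``) onto the
    variant with the highest cohort-wide support (ties: smallest start)."""
    totals: dict[str, int] = {}
    for counts in per_sample.values():
        for k, n in counts.items():
            totals[k] = totals.get(k, 0) + n
    groups: dict[tuple, list[str]] = {}
    for k, j in junction_objs.items():
        groups.setdefault((j.chrom, j.strand, j.end - j.start), []).append(k)
    remap: dict[str, str] = {}
    for members in groups.values():
        members.sort(key=lambda k: junction_objs[k].start)
        cluster: list[str] = []
        for k in members + [None]:
            if (k is not None and cluster
                    and junction_objs[k].start
                    - junction_objs[cluster[-1]].start <= window):
                cluster.append(k)
                continue
            if len(cluster) > 1:
                rep = max(cluster,
                          key=lambda c: (totals[c], -junction_objs[c].start))
                for c in cluster:
                    remap[c] = rep
                logger.info("merged %d breakpoint-slide variants into %s",
                            len(cluster), rep)
            cluster = [k] if k is not None else []
    if remap:
        for sid, counts in per_sample.items():
            out: dict[str, int] = {}
            for k, n in counts.items():
                out[remap.get(k, k)] = out.get(remap.get(k, k), 0) + n
            per_sample[sid] = out
        junction_objs = {k: j for k, j in junction_objs.items()
                         if remap.get(k, k) == k}
    return per_sample, junction_objs


# ---------------------------------------------------------------------------
# QC filters and normalization
# ---------------------------------------------------------------------------

def qc_filter_samples(
    matrix: CircCountMatrix,
    min_detected: int = 5000,
    unit: str = "junctions",
) -> CircCountMatrix:
    """Remove samples with < min_detected circRNAs (strict inequality).

    ``unit`` selects whether 'detected' counts distinct junctions with at
    least one read ('junctions') or total junction-supporting reads ('reads').
    """
    if min_detected < 0:
        raise ValueError("threshold must be >= 0")
    if unit not in ("junctions", "reads"):
        raise ValueError("unit must be 'junctions' or 'reads'")
    if unit == "junctions":
        detected = (matrix.counts > 0).sum(axis=0)
    else:
        detected = matrix.counts.sum(axis=0)
    keep = detected[detected >= min_detected].index.tolist()
    removed = [s for s in matrix.counts.columns if s not in keep]
    if removed:
        logger.info("qc_filter_samples: excluded samples %s (< %d %s)",
                    ", ".join(removed), min_detected, unit)
    if not keep:
        raise ValueError("all samples removed by the detected-circRNA filter")
    return matrix.subset(samples=keep)


def filter_by_tissue(
    matrix: CircCountMatrix,
    meta: pd.DataFrame,
    min_reads: int = 5,
    tissue_col: str = "region",
) -> CircCountMatrix:
    """Keep junctions expressed (> min_reads summed reads, strict) in >= 1 tissue.

    The returned matrix carries a boolean junction x tissue table
    ``tissue_expressed`` recording where each junction passed.
    """
    if tissue_col not in meta.columns:
        raise ValueError(f"metadata lacks a {tissue_col!r} column")
    samples = [s for s in matrix.counts.columns if s in meta.index]
    missing = set(matrix.counts.columns) - set(samples)
    if missing:
        raise ValueError(f"samples absent from metadata: {sorted(missing)}")
    tissues = sorted(meta.loc[samples, tissue_col].unique())
    expressed = pd.DataFrame(False, index=matrix.counts.index, columns=tissues)
    for t in tissues:
        cols = [s for s in samples if meta.at[s, tissue_col] == t]
        expressed[t] = matrix.counts[cols].sum(axis=1) > min_reads
    keep = expressed.index[expressed.any(axis=1)].tolist()
    logger.info("filter_by_tissue: %d/%d junctions expressed in >= 1 tissue "
                "(> %d reads)", len(keep), len(expressed), min_reads)
    out = matrix.subset(keys=keep)
    out.tissue_expressed = expressed.loc[keep]
    return out


def normalize_per_million(matrix: CircCountMatrix) -> pd.DataFrame:
    """Counts per million mapped reads: count / mapped_total * 1e6."""
    totals = matrix.mapped_totals.reindex(matrix.counts.columns)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"zero mapped totals for samples: {', '.join(zero.index)}")
    return matrix.counts / totals * 1e6
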