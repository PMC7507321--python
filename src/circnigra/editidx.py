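"""Alu editing index: global, per mismatch type, and circRNA-proximal.

The index pools read bases over all covered Alu positions whose
transcribed-strand reference base equals the mismatch's reference base:
index = 100 * sum(alt reads) / (sum(ref reads) + sum(alt reads)).  Pooling
read counts (rather than averaging per-site rates) is what makes the index
expression-weighted.  Strand context comes from the containing gene (falling
back to the Alu's own strand when intergenic); for minus-strand context the
plus-strand pileup is complement-mapped, so A-to-G editing is measured as
T-to-C on the plus strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from ._seq import BASES
from .synthgen import AluElement, GeneModel, GenomeModel, alu_strand_context

logger = logging.getLogger(__name__)

_CODE = {b: i for i, b in enumerate(BASES)}
MISMATCH_TYPES = [(r, a) for r in BASES for a in BASES if r != a]


# ---------------------------------------------------------------------------
# region sets
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[str, int, int]]
                    ) -> list[tuple[str, int, int]]:
    """Union of half-open intervals, merged per chromosome."""
    out: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        if s < e:
            by_chrom.setdefault(c, []).append((s, e))
    for c in sorted(by_chrom):
        cur_s = cur_e = None
        for s, e in sorted(by_chrom[c]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((c, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((c, cur_s, cur_e))
    return out


@dataclass
class RegionSet:
    """A labelled set of merged half-open genomic intervals."""

    label: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)

    def total_length(self) -> int:
        return sum(e - s for _c, s, e in self.intervals)

    def mask(self, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
        masks = {c: np.zeros(L, dtype=bool) for c, L in chrom_lengths.items()}
        for c, s, e in self.intervals:
            if c in masks:
                masks[c][s:e] = True
        return masks


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

class Pileup:
    """Per-position A/C/G/T read-base counts on the plus strand."""

    def __init__(self, counts: dict[str, np.ndarray]):
        for c, arr in counts.items():
            if arr.shape[0] != 4:
                raise ValueError("pileup arrays must be 4 x chrom length")
        self.counts = counts

    def coverage(self, chrom: str) -> np.ndarray:
        return self.counts[chrom].sum(axis=0)

    def at(self, chrom: str, pos: int) -> dict[str, int]:
        col = self.counts[chrom][:, pos]
        return {b: int(col[i]) for i, b in enumerate(BASES)}

    def restrict(self, regions: RegionSet) -> "Pileup":
        lengths = {c: arr.shape[1] for c, arr in self.counts.items()}
        masks = regions.mask(lengths)
        return Pileup({
            c: self.counts[c] * masks[c][None, :] for c in self.counts
        })

    def __add__(self, other: "Pileup") -> "Pileup":
        if set(self.counts) != set(other.counts):
            raise ValueError("pileups cover different chromosomes")
        return Pileup({c: self.counts[c] + other.counts[c]
                       for c in self.counts})


def empty_pileup(genome: Union[GenomeModel, dict]) -> Pileup:
    chroms = genome.chromosomes if isinstance(genome, GenomeModel) else genome
    return Pileup({c: np.zeros((4, len(s)), dtype=np.int64)
                   for c, s in chroms.items()})


def pileup_from_sam(
    sam_path,
    genome: Union[GenomeModel, dict],
    regions: Optional[RegionSet] = None,
) -> Pileup:
    """Per-position base counts from a SAM/BAM file.

    Unmapped and secondary records are skipped; primary and supplementary
    mapped segments both contribute (the wrapped part of a back-splice read
    is carried by a supplementary-style record).  Deletions and clipped bases
    contribute nothing.
    """
    chroms = genome.chromosomes if isinstance(genome, GenomeModel) else genome
    pile = empty_pileup(chroms)
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        sq = dict(zip(fh.references, fh.lengths))
        for name, L in sq.items():
            if name not in chroms or len(chroms[name]) != L:
                raise ValueError(
                    f"SAM @SQ {name}:{L} does not match the genome")
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            arr = pile.counts[rec.reference_name]
            seq = rec.query_sequence
            qpos, rpos = 0, rec.reference_start
            for op, ln in rec.cigartuples:
                if op in (0, 7, 8):  # M, =, X
                    codes = np.frombuffer(seq[qpos:qpos + ln].encode(),
                                          dtype=np.uint8)
                    codes = _ENC_TABLE[codes]
                    ok = codes < 4
                    np.add.at(arr, (codes[ok], np.arange(rpos, rpos + ln)[ok]), 1)
                    qpos += ln
                    rpos += ln
                elif op in (1, 4):   # I, S consume query
                    qpos += ln
                elif op in (2, 3):   # D, N consume reference
                    rpos += ln
    if regions is not None:
        pile = pile.restrict(regions)
    return pile


_ENC_TABLE = np.full(256, 255, dtype=np.uint8)
for _b, _i in _CODE.items():
    _ENC_TABLE[ord(_b)] = _i


# ---------------------------------------------------------------------------
# editing index
# ---------------------------------------------------------------------------

@dataclass
class EditingIndexResult:
    mismatch_type: str            # e.g. "A>G", in transcribed orientation
    numerator: int                # summed alt-base reads at eligible positions
    denominator: int              # numerator + summed ref-base reads
    index_percent: float          # 100 * numerator / denominator (nan if undefined)
    n_positions: int
    region_label: str = "global"
    defined: bool = True

    def __post_init__(self) -> None:
        if self.denominator < self.numerator:
            raise ValueError("denominator < numerator")


def _eligible_positions(
    genome: Union[GenomeModel, dict],
    alus: Sequence[AluElement],
    genes: Sequence[GeneModel],
    regions: Optional[RegionSet],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: (positions, strand flags) of strand-resolved Alu bases.

    strand flag True means plus-strand transcribed context.
    """
    chroms = genome.chromosomes if isinstance(genome, GenomeModel) else genome
    ctx = alu_strand_context(alus, genes)
    masks = None
    if regions is not None:
        masks = regions.mask({c: len(s) for c, s in chroms.items()})
    per_chrom: dict[str, tuple[list[int], list[bool]]] = {}
    for (chrom, pos), strand in ctx.items():
        if masks is not None and not masks[chrom][pos]:
            continue
        lst = per_chrom.setdefault(chrom, ([], []))
        lst[0].append(pos)
        lst[1].append(strand == "+")
    return {
        c: (np.asarray(p, dtype=np.int64), np.asarray(f, dtype=bool))
        for c, (p, f) in per_chrom.items()
    }


def alu_editing_index(
    pileup: Pileup,
    genome: Union[GenomeModel, dict],
    alus: Sequence[AluElement],
    genes: Sequence[GeneModel],
    mismatch: tuple[str, str] = ("A", "G"),
    min_coverage: int = 1,
    regions: Optional[RegionSet] = None,
    region_label: Optional[str] = None,
) -> EditingIndexResult:
    """Expression-weighted editing index for one ordered mismatch type.

    Eligible positions lie inside an Alu element, have transcribed-strand
    reference base equal to ``mismatch[0]`` and coverage >= ``min_coverage``.
    A zero denominator yields an undefined result (flagged, not 0).
    """
    if mismatch not in MISMATCH_TYPES:
        raise ValueError(f"mismatch must be one of the 12 ordered pairs")
    chroms = genome.chromosomes if isinstance(genome, GenomeModel) else genome
    label = region_label or (regions.label if regions is not None else "global")
    ref_c, alt_c = _CODE[mismatch[0]], _CODE[mismatch[1]]
    num = den_ref = 0
    n_pos = 0
    elig = _eligible_positions(chroms, alus, genes, regions)
    for chrom, (pos, plus) in elig.items():
        arr = pileup.counts[chrom]
        refcodes = _ENC_TABLE[np.frombuffer(chroms[chrom].encode(),
                                            dtype=np.uint8)][pos]
        cov = arr[:, pos].sum(axis=0)
        # transcribed ref base equals mismatch ref:
        #   plus context  -> genomic base == ref
        #   minus context -> genomic base == complement(ref)
        want = np.where(plus, ref_c, 3 - ref_c)
        sel = (refcodes == want) & (cov >= min_coverage)
        if not sel.any():
            continue
        p_sel, plus_sel = pos[sel], plus[sel]
        ref_row = np.where(plus_sel, ref_c, 3 - ref_c)
        alt_row = np.where(plus_sel, alt_c, 3 - alt_c)
        num += int(arr[alt_row, p_sel].sum())
        den_ref += int(arr[ref_row, p_sel].sum())
        n_pos += int(sel.sum())
    den = num + den_ref
    if den == 0:
        return EditingIndexResult(
            f"{mismatch[0]}>{mismatch[1]}", 0, 0, float("nan"),
            n_pos, label, defined=False)
    return EditingIndexResult(
        f"{mismatch[0]}>{mismatch[1]}", num, den, 100.0 * num / den,
        n_pos, label)


def mismatch_spectrum(
    pileup: Pileup,
    genome: Union[GenomeModel, dict],
    alus: Sequence[AluElement],
    genes: Sequence[GeneModel],
    min_coverage: int = 1,
    regions: Optional[RegionSet] = None,
    region_label: Optional[str] = None,
) -> list[EditingIndexResult]:
    """Editing index for all 12 ordered mismatch types (A>G dominance check)."""
    return [
        alu_editing_index(pileup, genome, alus, genes, mm, min_coverage,
                          regions, region_label)
        for mm in MISMATCH_TYPES
    ]


# ---------------------------------------------------------------------------
# circRNA-proximal regions
# ---------------------------------------------------------------------------

def circ_flank_regions(
    junctions: Sequence,
    genes: Sequence[GeneModel],
    window: int = 1000,
    chrom_lengths: Optional[dict[str, int]] = None,
    subtract_exons: bool = True,
) -> tuple[RegionSet, RegionSet]:
    """Circle exons and their flanking intron windows.

    Each junction is assigned to a host gene by coordinate containment
    (unassignable junctions are excluded with a warning).  Flanks
    [start-w, start) and [end, end+w) are clipped to the host gene span and
    to chromosome bounds; when ``subtract_exons`` the host gene's exonic
    sequence is removed so flanks are intronic.
    """
    circ_iv: list[tuple[str, int, int]] = []
    flank_iv: list[tuple[str, int, int]] = []
    for j in junctions:
        hosts = [g for g in genes
                 if g.chrom == j.chrom and g.span[0] <= j.start
                 and j.end <= g.span[1]]
        same = [g for g in hosts if g.strand == j.strand]
        host = (same or hosts or [None])[0]
        if host is None:
            logger.warning("junction %s has no host gene; excluded", j.key)
            continue
        circ_iv.append((j.chrom, j.start, j.end))
        lo, hi = host.span
        if chrom_lengths:
            lo, hi = max(lo, 0), min(hi, chrom_lengths[j.chrom])
        left = (j.chrom, max(lo, j.start - window), j.start)
        right = (j.chrom, j.end, min(hi, j.end + window))
        for c, s, e in (left, right):
            if s >= e:
                continue
            if subtract_exons:
                pieces = [(s, e)]
                for (xs, xe) in host.exons:
                    nxt = []
                    for (ps, pe) in pieces:
                        if xe <= ps or xs >= pe:
                            nxt.append((ps, pe))
                        else:
                            if ps < xs:
                                nxt.append((ps, xs))
                            if xe < pe:
                                nxt.append((xe, pe))
                    pieces = nxt
                flank_iv.extend((c, ps, pe) for ps, pe in pieces)
            else:
                flank_iv.append((c, s, e))
    return (RegionSet("circ_exons", circ_iv),
            RegionSet(f"flank_{window}", flank_iv))


def regional_editing_report(
    pileup: Pileup,
    genome: Union[GenomeModel, dict],
    alus: Sequence[AluElement],
    genes: Sequence[GeneModel],
    junctions: Sequence,
    windows: Sequence[int] = (1000, 5000, 10000),
    min_coverage: int = 1,
    subtract_exons: bool = True,
) -> pd.DataFrame:
    """Editing index across {global, circ_exons, flank_w...} x 12 mismatches."""
    chroms = genome.chromosomes if isinstance(genome, GenomeModel) else genome
    lengths = {c: len(s) for c, s in chroms.items()}
    region_sets: list[Optional[RegionSet]] = [None]
    labels = ["global"]
    circ_done = False
    for w in windows:
        circ, flank = circ_flank_regions(junctions, genes, w, lengths,
                                         subtract_exons)
        if not circ_done:
            region_sets.append(circ)
            labels.append("circ_exons")
            circ_done = True
        region_sets.append(flank)
        labels.append(flank.label)
    rows = []
    for regions, label in zip(region_sets, labels):
        for res in mismatch_spectrum(pileup, chroms, alus, genes,
                                     min_coverage, regions, label):
            rows.append({
                "region_label": res.region_label,
                "mismatch": res.mismatch_type,
                "numerator": res.numerator,
                "denominator": res.denominator,
                "index_percent": res.index_percent,
                "n_positions": res.n_positions,
                "defined": res.defined,
            })
    return pd.DataFrame(rows)


def sample_aei(
    pileup: Pileup,
    genome: Union[GenomeModel, dict],
    alus: Sequence[AluElement],
    genes: Sequence[GeneModel],
    min_coverage: int = 1,
) -> float:
    """Convenience: the global A>G Alu editing index of one sample (percent)."""
    return alu_editing_index(pileup, genome, alus, genes,
                             min_coverage=min_coverage).index_percent
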