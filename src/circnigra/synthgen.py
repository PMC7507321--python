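"""Synthetic genomes, cohorts and reads with full ground truth.

This module generates the desk-scale stand-in for a postmortem brain RNA-seq
cohort: multi-gene genomes whose exons carry canonical GT/AG splice signals,
sense/antisense Alu annotations in exons and flanking introns, per-site A-to-I
editing rates over Alu adenosines of the transcribed strand, and per-sample
read mixtures of spliced linear transcripts, unspliced pre-mRNA and
back-spliced (circular) exons.  Every read's error-free alignment is recorded,
so downstream junction detection and editing-index computation can be scored
against truth.

Coordinates are 0-based half-open throughout; 1-based only at SAM output.
Editing is applied on the transcribed strand (for minus-strand genes the
genomic plus strand shows T-to-C).  Sequencing error is a uniform substitution
to one of the three other bases; reads are single-end with fixed quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from ._seq import BASES, decode, encode, revcomp

logger = logging.getLogger(__name__)

READ_QUAL_CHAR = "I"  # fixed Phred+33 quality written to FASTQ/SAM


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene: sorted disjoint exons on one strand, optionally circularizable.

    ``circ_fraction`` is the fraction of this gene's transcripts that are
    back-spliced into the single circularizable exon ``circ_exon_index``.
    ``base_expression`` is a relative transcript abundance (any nonnegative
    scale; normalized across genes at simulation time).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    circ_exon_index: Optional[int] = None
    base_expression: float = 1.0
    circ_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not 0.0 <= self.circ_fraction <= 1.0:
            raise ValueError("circ_fraction must be in [0, 1]")
        if self.base_expression < 0:
            raise ValueError("base_expression must be nonnegative")
        if self.circ_exon_index is not None and not (
            0 <= self.circ_exon_index < len(self.exons)
        ):
            raise ValueError("circ_exon_index addresses no exon")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if not (s0 < e0 <= s1 < e1):
                raise ValueError("exons must be sorted and disjoint")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def circ_exon(self) -> Optional[tuple[int, int]]:
        if self.circ_exon_index is None:
            return None
        return self.exons[self.circ_exon_index]


@dataclass
class AluElement:
    alu_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("Alu start must be < end")
        if self.end - self.start < 50:
            raise ValueError("Alu elements are >= 50 nt")


@dataclass
class GenomeModel:
    chromosomes: dict[str, str]
    genes: list[GeneModel]
    alus: list[AluElement]

    def validate(self) -> None:
        for g in self.genes:
            L = len(self.chromosomes[g.chrom])
            if not (0 <= g.span[0] and g.span[1] <= L):
                raise ValueError(f"{g.gene_id} exceeds chromosome bounds")
        for a in self.alus:
            if not (0 <= a.start and a.end <= len(self.chromosomes[a.chrom])):
                raise ValueError(f"{a.alu_id} exceeds chromosome bounds")


@dataclass
class EditingModel:
    """Per-site A-to-I editing rates at Alu adenosines of the transcribed strand."""

    per_site_rate: dict[tuple[str, int], float]
    alpha: float
    beta: float

    @property
    def global_mean(self) -> float:
        if not self.per_site_rate:
            return 0.0
        return float(np.mean(list(self.per_site_rate.values())))


@dataclass
class SampleMeta:
    sample_id: str
    region: str
    condition: str
    age: float
    sex: str


@dataclass
class GroupEffect:
    """Multipliers applied to circ_fraction and to editing rates for one group."""

    circ: float = 1.0
    editing: float = 1.0

    def __post_init__(self) -> None:
        if self.circ <= 0 or self.editing <= 0:
            raise ValueError("effect multipliers must be positive")


@dataclass
class CohortDesign:
    """Cohort covariates and the effects that couple them to the biology.

    ``effects`` maps (metadata column, level) pairs, e.g. ("condition", "PD"),
    to multipliers; a sample accumulates the product of all matching entries.
    ``age_slope`` linearly couples age (years, centred at ``age_ref``) to the
    expected circRNA output within ``age_region`` (all regions when None).
    ``sample_sigma`` adds per-sample lognormal variation to the circularization
    factor, and ``editing_circ_coupling`` g makes the editing multiplier vary
    as that factor to the power -g (inverse coupling, g > 0).
    """

    samples: list[SampleMeta]
    effects: dict[tuple[str, str], GroupEffect] = field(default_factory=dict)
    age_slope: float = 0.0
    age_region: Optional[str] = None
    age_ref: float = 70.0
    sample_sigma: float = 0.0
    editing_circ_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")

    def _index(self, sample_id: str) -> int:
        for i, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return i
        raise KeyError(f"unknown sample_id {sample_id!r}")

    def sample_factor(self, sample_id: str) -> float:
        """Deterministic per-sample lognormal circularization factor."""
        i = self._index(sample_id)
        if self.sample_sigma == 0.0:
            return 1.0
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.seed), 0x5F, i])
        )
        return float(np.exp(self.sample_sigma * rng.standard_normal()))

    def multipliers(self, meta: SampleMeta) -> tuple[float, float]:
        """(circ multiplier, editing multiplier) for one sample."""
        self._index(meta.sample_id)  # reject unknown samples
        circ = 1.0
        edit = 1.0
        levels = {
            "region": meta.region,
            "condition": meta.condition,
            "sex": meta.sex,
        }
        for (col, level), eff in self.effects.items():
            if levels.get(col) == level:
                circ *= eff.circ
                edit *= eff.editing
        if self.age_region is None or meta.region == self.age_region:
            circ *= max(0.0, 1.0 + self.age_slope * (meta.age - self.age_ref))
        m = self.sample_factor(meta.sample_id)
        circ *= m
        if self.editing_circ_coupling != 0.0:
            edit *= m ** (-self.editing_circ_coupling)
        return circ, edit


@dataclass
class SyntheticTruth:
    """Simulator ground truth against which every stage is scored."""

    junction_coords: list[tuple[str, int, int, str]]
    expected_counts: "object"  # pandas.DataFrame, junction key x sample
    editing_model: EditingModel
    cohort: CohortDesign
    sample_editing_mean: dict[str, float]
    sample_circ_multiplier: dict[str, float]

    @property
    def true_junctions(self):
        """Truth junctions as detector-compatible records."""
        from .circdetect import BackspliceJunction  # local import: layering

        return [
            BackspliceJunction(chrom=c, start=s, end=e, strand=st)
            for (c, s, e, st) in self.junction_coords
        ]


def junction_key(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}-{end}({strand})"


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

@dataclass
class GenomeConfig:
    """Sizing and composition parameters for :func:`build_genome`."""

    chrom_lengths: tuple[int, ...] = (50_000,)
    n_genes: int = 15
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_len: tuple[int, int] = (150, 400)
    intron_len: tuple[int, int] = (200, 600)
    intergenic_len: tuple[int, int] = (200, 800)
    circ_gene_fraction: float = 0.5
    circ_fraction_range: tuple[float, float] = (0.1, 0.4)
    base_expression_sigma: float = 1.0
    alu_exon_prob: float = 0.8
    alus_per_circ_flank: int = 1
    alu_len: tuple[int, int] = (80, 250)
    alu_intergenic_per_kb: float = 0.05
    alu_antisense_prob: float = 0.5


def build_genome(config: GenomeConfig, seed: int) -> GenomeModel:
    """Deterministically generate a genome with splice-signalled exons and Alus.

    Every exon boundary carries a canonical signal in transcribed orientation:
    GT immediately downstream of the donor and AG immediately upstream of the
    acceptor (their reverse complements AC/CT on the plus strand for minus
    strand genes), so both linear and back-splice junctions are canonically
    flanked.  Raises ``ValueError`` when the requested genes cannot fit.
    """
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    seqs = {
        name: rng.integers(0, 4, size=L).astype(np.uint8)
        for name, L in zip(chrom_names, config.chrom_lengths)
    }

    # assign genes to chromosomes round-robin
    per_chrom: dict[str, int] = {name: 0 for name in chrom_names}
    for i in range(config.n_genes):
        per_chrom[chrom_names[i % len(chrom_names)]] += 1

    genes: list[GeneModel] = []
    alus: list[AluElement] = []
    gi = 0
    n_circ_target = int(round(config.n_genes * config.circ_gene_fraction))
    circ_flags = np.zeros(config.n_genes, dtype=bool)
    circ_flags[:n_circ_target] = True
    rng.shuffle(circ_flags)

    for chrom in chrom_names:
        L = len(seqs[chrom])
        cursor = 20
        for _ in range(per_chrom[chrom]):
            n_ex = int(rng.integers(config.exons_per_gene[0],
                                    config.exons_per_gene[1] + 1))
            ex_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1,
                                   size=n_ex)
            in_lens = rng.integers(config.intron_len[0], config.intron_len[1] + 1,
                                   size=max(0, n_ex - 1))
            gap = int(rng.integers(config.intergenic_len[0],
                                   config.intergenic_len[1] + 1))
            start = cursor + gap
            span = int(ex_lens.sum() + in_lens.sum())
            if start + span + 20 > L:
                raise ValueError(
                    f"chromosome {chrom} of length {L} cannot fit the requested "
                    f"genes; increase chrom_lengths or reduce gene sizing"
                )
            exons = []
            pos = start
            for k in range(n_ex):
                exons.append((pos, pos + int(ex_lens[k])))
                pos += int(ex_lens[k])
                if k < n_ex - 1:
                    pos += int(in_lens[k])
            strand = "+" if rng.random() < 0.5 else "-"

            circ_idx: Optional[int] = None
            cf = 0.0
            if circ_flags[gi]:
                if n_ex >= 3:
                    circ_idx = int(rng.integers(1, n_ex - 1))
                else:
                    circ_idx = int(rng.integers(0, n_ex))
                cf = float(rng.uniform(*config.circ_fraction_range))
            expr = float(np.exp(config.base_expression_sigma
                                * rng.standard_normal()))
            gene = GeneModel(
                gene_id=f"g{gi + 1:03d}", chrom=chrom, strand=strand,
                exons=exons, circ_exon_index=circ_idx,
                base_expression=expr, circ_fraction=cf,
            )
            genes.append(gene)

            # install splice signals in transcribed orientation:
            # plus strand GT after exon end / AG before exon start; on the
            # minus strand the transcribed GT/AG read as AC / CT on plus
            if strand == "+":
                for (s, e) in exons:
                    seqs[chrom][e:e + 2] = encode("GT")
                    seqs[chrom][s - 2:s] = encode("AG")
            else:
                for (s, e) in exons:
                    seqs[chrom][s - 2:s] = encode("AC")
                    seqs[chrom][e:e + 2] = encode("CT")

            # Alus inside the circularizable exon and its flanking introns
            if circ_idx is not None:
                cs, ce = exons[circ_idx]
                if (rng.random() < config.alu_exon_prob
                        and ce - cs >= config.alu_len[0] + 20):
                    alen = int(min(rng.integers(*config.alu_len), ce - cs - 20))
                    alen = max(alen, 50)
                    astart = int(rng.integers(cs + 5, ce - alen - 5 + 1))
                    alus.append(_mk_alu(alus, chrom, astart, astart + alen,
                                        strand, rng, config))
                for side in (-1, +1):
                    nbr = circ_idx + side
                    if not (0 <= nbr < n_ex):
                        continue
                    if side < 0:
                        i0, i1 = exons[nbr][1] + 2, cs - 2
                    else:
                        i0, i1 = ce + 2, exons[nbr][0] - 2
                    for _k in range(config.alus_per_circ_flank):
                        if i1 - i0 < config.alu_len[0] + 10:
                            break
                        alen = int(min(rng.integers(*config.alu_len),
                                       i1 - i0 - 10))
                        alen = max(alen, 50)
                        astart = int(rng.integers(i0 + 2, i1 - alen - 2 + 1))
                        alus.append(_mk_alu(alus, chrom, astart, astart + alen,
                                            strand, rng, config))
            cursor = exons[-1][1] + 4
            gi += 1

        # background intergenic Alus
        n_bg = rng.poisson(config.alu_intergenic_per_kb * L / 1000.0)
        for _ in range(int(n_bg)):
            alen = int(rng.integers(*config.alu_len))
            astart = int(rng.integers(0, max(1, L - alen)))
            alus.append(AluElement(f"alu{len(alus) + 1:04d}", chrom,
                                   astart, astart + alen,
                                   "+" if rng.random() < 0.5 else "-"))

    genome = GenomeModel(
        chromosomes={c: decode(arr) for c, arr in seqs.items()},
        genes=genes, alus=alus,
    )
    genome.validate()
    return genome


def _mk_alu(alus, chrom, start, end, gene_strand, rng, config) -> AluElement:
    strand = gene_strand
    if rng.random() < config.alu_antisense_prob:
        strand = "-" if strand == "+" else "+"
    return AluElement(f"alu{len(alus) + 1:04d}", chrom, start, end, strand)


# ---------------------------------------------------------------------------
# editing model
# ---------------------------------------------------------------------------

_CTX_CACHE: dict = {}


def alu_strand_context(
    alus: Iterable[AluElement], genes: Iterable[GeneModel]
) -> dict[tuple[str, int], str]:
    """Transcribed-strand context for every Alu position.

    Containing gene strand wins; the Alu's own strand is used when intergenic;
    positions under two genes on opposite strands are excluded (no entry).
    Results are memoized on the interval structure (cheap for repeated
    per-sample index calls over one genome).
    """
    alus = list(alus)
    genes = list(genes)
    cache_key = (
        tuple((a.chrom, a.start, a.end, a.strand) for a in alus),
        tuple((g.chrom, g.span, g.strand) for g in genes),
    )
    cached = _CTX_CACHE.get(cache_key)
    if cached is not None:
        return cached
    ctx: dict[tuple[str, int], str] = {}
    for alu in alus:
        # per-position resolution handles Alus partially overlapping genes
        for pos in range(alu.start, alu.end):
            strands = {
                g.strand for g in genes
                if g.chrom == alu.chrom and g.span[0] <= pos < g.span[1]
            }
            if len(strands) == 1:
                ctx[(alu.chrom, pos)] = next(iter(strands))
            elif len(strands) == 0:
                ctx[(alu.chrom, pos)] = alu.strand
            # ambiguous: excluded
    if len(_CTX_CACHE) > 32:
        _CTX_CACHE.clear()
    _CTX_CACHE[cache_key] = ctx
    return ctx


def build_editing_model(
    genome: GenomeModel,
    seed: int,
    alpha: float = 2.0,
    beta: float = 48.0,
    uniform_rate: Optional[float] = None,
    region_filter=None,
) -> EditingModel:
    """Draw per-site editing rates at Alu adenosines of the transcribed strand.

    Rates are Beta(alpha, beta) draws (default mean 4%), or ``uniform_rate``
    everywhere when given.  ``region_filter(chrom, pos) -> bool`` optionally
    restricts editable sites (used to confine editing to e.g. flanking introns).
    """
    rng = np.random.default_rng(seed)
    ctx = alu_strand_context(genome.alus, genome.genes)
    rates: dict[tuple[str, int], float] = {}
    for (chrom, pos), strand in sorted(ctx.items()):
        base = genome.chromosomes[chrom][pos]
        transcribed = base if strand == "+" else base.translate(
            str.maketrans("ACGT", "TGCA"))
        if transcribed != "A":
            continue
        if region_filter is not None and not region_filter(chrom, pos):
            continue
        r = uniform_rate if uniform_rate is not None else float(
            rng.beta(alpha, beta))
        rates[(chrom, pos)] = float(np.clip(r, 0.0, 1.0))
    return EditingModel(per_site_rate=rates, alpha=alpha, beta=beta)


# ---------------------------------------------------------------------------
# transcription units (internal)
# ---------------------------------------------------------------------------

@dataclass
class _Unit:
    gene: GeneModel
    kind: str  # 'spliced' | 'pre' | 'circ'
    chrom: str
    strand: str
    codes: np.ndarray   # transcript-orientation base codes
    rates: np.ndarray   # per-position base editing rate (before multipliers)
    gpos: np.ndarray    # genome position of each transcript position

    @property
    def length(self) -> int:
        return len(self.codes)


def _build_units(genome: GenomeModel, editing: EditingModel) -> list[_Unit]:
    units: list[_Unit] = []
    chrom_codes = {c: encode(s) for c, s in genome.chromosomes.items()}
    rate_map = editing.per_site_rate
    for gene in genome.genes:
        arr = chrom_codes[gene.chrom]

        def make(blocks: list[tuple[int, int]], kind: str) -> _Unit:
            gpos = np.concatenate([np.arange(s, e) for s, e in blocks])
            codes = arr[gpos]
            if gene.strand == "-":
                gpos = gpos[::-1].copy()
                codes = (3 - codes[::-1]).astype(np.uint8)
            rates = np.zeros(len(codes))
            if rate_map:
                for t in range(len(codes)):
                    if codes[t] == 0:  # transcript A
                        r = rate_map.get((gene.chrom, int(gpos[t])))
                        if r:
                            rates[t] = r
            return _Unit(gene, kind, gene.chrom, gene.strand,
                         codes.copy(), rates, gpos)

        units.append(make(gene.exons, "spliced"))
        units.append(make([gene.span], "pre"))
        if gene.circ_exon is not None:
            units.append(make([gene.circ_exon], "circ"))
    return units


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class SampleSim:
    """One simulated sample: reads plus truth alignments and truth counts."""

    sample_id: str
    meta: SampleMeta
    read_len: int
    genome: GenomeModel
    groups: list[tuple[_Unit, np.ndarray, np.ndarray]]  # (unit, starts, bases)
    circ_multiplier: float
    editing_multiplier: float
    expected_junctions: dict[str, float]
    realized_junctions: dict[str, int]

    @property
    def n_reads(self) -> int:
        return sum(len(starts) for _, starts, _ in self.groups)

    def iter_reads(self):
        """Yield (name, sequence) in deterministic order."""
        i = 0
        from ._seq import _DEC  # local: avoid polluting module namespace
        R = self.read_len
        for unit, starts, mat in self.groups:
            raw = _DEC[mat].tobytes()
            for k in range(len(starts)):
                yield f"{self.sample_id}.r{i:07d}", raw[k * R:(k + 1) * R].decode()
                i += 1

    @property
    def reads(self) -> list[str]:
        return [seq for _, seq in self.iter_reads()]

    # -- output writers ----------------------------------------------------

    def write_fastq(self, path) -> None:
        qual = READ_QUAL_CHAR * self.read_len
        with open(path, "w") as fh:
            for name, seq in self.iter_reads():
                fh.write(f"@{name}\n{seq}\n+\n{qual}\n")

    def write_sam(self, path) -> None:
        """Error-free truth alignments: N-skip CIGAR across linear splices,
        two supplementary-style records for back-splice junction reads."""
        R = self.read_len
        lines = ["@HD\tVN:1.6\tSO:unsorted"]
        for c, s in self.genome.chromosomes.items():
            lines.append(f"@SQ\tSN:{c}\tLN:{len(s)}")
        i = 0
        for unit, starts, mat in self.groups:
            from ._seq import _DEC
            raw = _DEC[mat].tobytes()
            L = unit.length
            for k in range(len(starts)):
                name = f"{self.sample_id}.r{i:07d}"
                seq = raw[k * R:(k + 1) * R].decode()
                x = int(starts[k])
                if unit.kind == "circ" and x + R > L:
                    parts = [(x, L, 0), (0, x + R - L, L - x)]
                else:
                    parts = [(x, min(x + R, L), 0)]
                for pi, (t0, t1, q0) in enumerate(parts):
                    flag = 0 if unit.strand == "+" else 16
                    if pi > 0:
                        flag |= 2048
                    lines.append(_sam_record(
                        name, flag, unit, t0, t1, seq[q0:q0 + (t1 - t0)]))
                i += 1
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    # -- pileup ------------------------------------------------------------

    def base_count_arrays(self) -> dict[str, np.ndarray]:
        """Plus-strand base counts (4 x chrom length) from truth alignments."""
        out = {
            c: np.zeros((4, len(s)), dtype=np.int64)
            for c, s in self.genome.chromosomes.items()
        }
        R = self.read_len
        for unit, starts, mat in self.groups:
            L = unit.length
            idx = starts[:, None] + np.arange(R)[None, :]
            if unit.kind == "circ":
                idx = idx % L
            gp = unit.gpos[idx]
            bases = mat if unit.strand == "+" else (3 - mat)
            np.add.at(out[unit.chrom], (bases.ravel(), gp.ravel()), 1)
        return out

    def pileup(self):
        from .editidx import Pileup  # local import: layering

        return Pileup(self.base_count_arrays())


def _sam_record(name: str, flag: int, unit: _Unit, t0: int, t1: int,
                part_seq: str) -> str:
    """One SAM line for the transcript interval [t0, t1) of a unit."""
    gp = unit.gpos[t0:t1]
    if unit.strand == "-":
        gp = gp[::-1]
        part_seq = revcomp(part_seq)
    # contiguous ascending runs -> M blocks separated by N
    breaks = np.where(np.diff(gp) != 1)[0]
    block_bounds = np.concatenate([[0], breaks + 1, [len(gp)]])
    cig = []
    for b0, b1 in zip(block_bounds[:-1], block_bounds[1:]):
        if b0 > 0:
            gap = int(gp[b0] - gp[b0 - 1] - 1)
            cig.append(f"{gap}N")
        cig.append(f"{b1 - b0}M")
    pos1 = int(gp[0]) + 1
    qual = READ_QUAL_CHAR * len(part_seq)
    return (f"{name}\t{flag}\t{unit.chrom}\t{pos1}\t60\t{''.join(cig)}"
            f"\t*\t0\t0\t{part_seq}\t{qual}")


def simulate_sample(
    genome: GenomeModel,
    meta: SampleMeta,
    design: CohortDesign,
    n_reads: int,
    read_len: int = 100,
    error_rate: float = 0.002,
    seed: int = 0,
    *,
    editing: Optional[EditingModel] = None,
    unspliced_fraction: float = 0.15,
    _units: Optional[list[_Unit]] = None,
) -> SampleSim:
    """Simulate one sample's single-end reads with ground truth.

    Reads are drawn from spliced transcripts, unspliced pre-mRNA (fraction
    ``unspliced_fraction`` of the linear output, emulating the intronic signal
    of rRNA-depleted libraries) and circular exons with wrap-around; a circular
    read starting within read_len-1 of the circle end crosses the back-splice
    junction.  Editing (A->G on the transcribed strand, before sequencing
    error) and uniform substitution errors are applied per base.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0.0 <= error_rate < 0.05:
        raise ValueError("error_rate must be in [0, 0.05)")
    circ_mult, edit_mult = design.multipliers(meta)

    if editing is None:
        editing = EditingModel({}, 0.0, 0.0)
    units = _units if _units is not None else _build_units(genome, editing)

    probs = []
    for u in units:
        p_g = u.gene.base_expression
        cf = float(np.clip(u.gene.circ_fraction * circ_mult, 0.0, 1.0)) \
            if u.gene.circ_exon is not None else 0.0
        if u.kind == "circ":
            if read_len >= u.length:
                raise ValueError(
                    f"read_len {read_len} >= circle length {u.length} "
                    f"({u.gene.gene_id})")
            probs.append(p_g * cf)
        elif u.kind == "pre":
            probs.append(p_g * (1.0 - cf) * unspliced_fraction)
        else:
            if u.length < read_len:
                raise ValueError(
                    f"spliced transcript of {u.gene.gene_id} shorter than "
                    f"read_len")
            probs.append(p_g * (1.0 - cf) * (1.0 - unspliced_fraction))
    probs = np.asarray(probs)
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, probs)

    groups: list[tuple[_Unit, np.ndarray, np.ndarray]] = []
    expected: dict[str, float] = {}
    realized: dict[str, int] = {}
    R = read_len
    for u, n, p in zip(units, counts, probs):
        if u.kind == "circ":
            cs, ce = u.gene.circ_exon
            key = junction_key(u.chrom, cs, ce, u.strand)
            expected[key] = float(n_reads * p * (R - 1) / u.length)
            realized[key] = 0
        if n == 0:
            if u.kind == "circ":
                realized[key] = 0
            continue
        L = u.length
        if u.kind == "circ":
            starts = rng.integers(0, L, size=n)
            realized[key] = int((starts > L - R).sum())
            idx = (starts[:, None] + np.arange(R)[None, :]) % L
        else:
            starts = rng.integers(0, L - R + 1, size=n)
            idx = starts[:, None] + np.arange(R)[None, :]
        mat = u.codes[idx].copy()
        rates = u.rates[idx] * edit_mult
        if rates.any():
            edit_mask = rng.random(mat.shape) < np.clip(rates, 0.0, 1.0)
            mat[edit_mask] = 2  # G (rates are nonzero only at transcript A)
        if error_rate > 0:
            err = rng.random(mat.shape) < error_rate
            n_err = int(err.sum())
            if n_err:
                mat[err] = (mat[err] + rng.integers(1, 4, size=n_err)) % 4
        groups.append((u, starts.astype(np.int64), mat))

    return SampleSim(
        sample_id=meta.sample_id, meta=meta, read_len=read_len,
        genome=genome, groups=groups,
        circ_multiplier=circ_mult, editing_multiplier=edit_mult,
        expected_junctions=expected, realized_junctions=realized,
    )


@dataclass
class CohortSim:
    samples: dict[str, SampleSim]
    truth: SyntheticTruth

    def write(self, outdir) -> dict[str, dict[str, str]]:
        """Write per-sample FASTQ and truth SAM files; return the paths."""
        import os

        paths: dict[str, dict[str, str]] = {}
        for sid, sim in self.samples.items():
            fq = os.path.join(outdir, f"{sid}.fastq")
            sam = os.path.join(outdir, f"{sid}.truth.sam")
            sim.write_fastq(fq)
            sim.write_sam(sam)
            paths[sid] = {"fastq": fq, "sam": sam}
        return paths


def simulate_cohort(
    genome: GenomeModel,
    design: CohortDesign,
    *,
    editing: Optional[EditingModel] = None,
    n_reads: int = 4000,
    read_len: int = 100,
    error_rate: float = 0.002,
    unspliced_fraction: float = 0.15,
) -> CohortSim:
    """Simulate every sample of a cohort design, reproducibly from design.seed."""
    import pandas as pd

    if not design.samples:
        raise ValueError("cohort design has no samples")
    if editing is None:
        editing = build_editing_model(genome, seed=int(design.seed) + 1)
    units = _build_units(genome, editing)
    ss = np.random.SeedSequence(design.seed)
    child = ss.generate_state(len(design.samples)) & 0x7FFFFFFF

    sims: dict[str, SampleSim] = {}
    for i, meta in enumerate(design.samples):
        sims[meta.sample_id] = simulate_sample(
            genome, meta, design, n_reads, read_len, error_rate,
            seed=int(child[i]), editing=editing,
            unspliced_fraction=unspliced_fraction, _units=units,
        )

    keys = sorted({k for s in sims.values() for k in s.expected_junctions})
    expected = pd.DataFrame(
        {sid: [sims[sid].expected_junctions.get(k, 0.0) for k in keys]
         for sid in sims},
        index=keys,
    )
    coords = []
    for g in genome.genes:
        if g.circ_exon is not None:
            cs, ce = g.circ_exon
            coords.append((g.chrom, cs, ce, g.strand))
    truth = SyntheticTruth(
        junction_coords=coords,
        expected_counts=expected,
        editing_model=editing,
        cohort=design,
        sample_editing_mean={
            sid: editing.global_mean * s.editing_multiplier
            for sid, s in sims.items()
        },
        sample_circ_multiplier={
            sid: s.circ_multiplier for sid, s in sims.items()
        },
    )
    return CohortSim(samples=sims, truth=truth)


# ---------------------------------------------------------------------------
# convenience designs
# ---------------------------------------------------------------------------

def default_cohort_design(
    n_per_group: int = 3,
    regions: tuple[str, ...] = ("SN", "MTG", "AMG"),
    conditions: tuple[str, ...] = ("CT", "PD"),
    age_range: tuple[float, float] = (55.0, 90.0),
    seed: int = 0,
    **kwargs,
) -> CohortDesign:
    """A small balanced region x condition cohort with random ages and sexes."""
    rng = np.random.default_rng(seed)
    samples = []
    for region in regions:
        for cond in conditions:
            for i in range(n_per_group):
                samples.append(SampleMeta(
                    sample_id=f"{region}_{cond}_{i + 1}",
                    region=region, condition=cond,
                    age=float(np.round(rng.uniform(*age_range), 1)),
                    sex="F" if rng.random() < 0.5 else "M",
                ))
    return CohortDesign(samples=samples, seed=seed, **kwargs)
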