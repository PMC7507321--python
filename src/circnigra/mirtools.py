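"""miRNA seed sites on circular sequences, target enrichment, qPCR curves.

Canonical TargetScan seed-site classes against a circular target: the 6mer is
the reverse complement of miRNA positions 2-7, the 7mer-m8 of positions 2-8;
7mer-A1 is the 6mer followed by an A on the target and the 8mer the 7mer-m8
followed by an A.  Sites are anchored at their 6mer core and classified by
their strongest class; scanning is performed on the circular topology, so a
site spanning the back-splice junction (invisible to a linear scan) is
reported with its start modulo the circle length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from ._seq import revcomp
from .cohortstats import bh_adjust

logger = logging.getLogger(__name__)

MIR_128_SEQUENCE = "UCACAGUGAACCGGUCUCUUU"

_CLASS_RANK = {"8mer": 3, "7mer-m8": 2, "7mer-A1": 1, "6mer": 0}


def _dna(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    if set(s) - set("ACGT"):
        raise ValueError("non-nucleotide characters in sequence")
    return s


@dataclass
class MirnaRecord:
    """A miRNA with its derived seed (positions 2-8 of the 5'->3' sequence)."""

    mirna_id: str
    sequence: str

    def __post_init__(self) -> None:
        s = self.sequence.upper()
        if set(s) - set("ACGU"):
            raise ValueError(f"{self.mirna_id}: sequence must be RNA (A/C/G/U)")
        if len(s) < 19:
            raise ValueError(f"{self.mirna_id}: sequence shorter than 19 nt")
        self.sequence = s

    @property
    def seed(self) -> str:
        return self.sequence[1:8]  # positions 2-8, 1-based

    @property
    def core6(self) -> str:
        """Reverse complement of positions 2-7, in DNA target space."""
        return revcomp(_dna(self.sequence[1:7]))

    @property
    def m8_base(self) -> str:
        """Target base pairing miRNA position 8 (precedes the 6mer core)."""
        return revcomp(_dna(self.sequence[7]))


MIR_128 = MirnaRecord("hsa-miR-128-3p", MIR_128_SEQUENCE)


@dataclass(frozen=True)
class SeedSite:
    position: int          # 0-based start of the full matched motif
    site_class: str        # 6mer | 7mer-A1 | 7mer-m8 | 8mer
    spans_junction: bool = False


def scan_seed_sites(
    circle_seq: str,
    mirna: MirnaRecord,
    circular: bool = True,
) -> list[SeedSite]:
    """All canonical seed sites of one miRNA on a (circular) target sequence.

    Sites are anchored at 6mer-core matches and upgraded to the strongest
    class supported by the m8 base (one position upstream) and the A1 base
    (immediately downstream); each core yields exactly one site.  With
    ``circular=False`` the junction is not crossed (linear scan).
    """
    target = _dna(circle_seq)
    L = len(target)
    core = mirna.core6
    if L < len(core):
        raise ValueError("target shorter than the seed core")
    if circular and L < 8:
        raise ValueError("circle length must be >= 8")

    def at(i: int) -> Optional[str]:
        if circular:
            return target[i % L]
        return target[i] if 0 <= i < L else None

    sites: list[SeedSite] = []
    for j in range(L):  # candidate 6mer-core starts
        if not circular and j + 6 > L:
            break
        if any(at(j + k) != core[k] for k in range(6)):
            continue
        has_m8 = at(j - 1) == mirna.m8_base
        has_a1 = at(j + 6) == "A"
        if has_m8 and has_a1:
            cls, start, ln = "8mer", j - 1, 8
        elif has_m8:
            cls, start, ln = "7mer-m8", j - 1, 7
        elif has_a1:
            cls, start, ln = "7mer-A1", j, 7
        else:
            cls, start, ln = "6mer", j, 6
        pos = start % L if circular else start
        spans = circular and (pos + ln > L)
        sites.append(SeedSite(position=pos, site_class=cls,
                              spans_junction=spans))
    sites.sort(key=lambda s: (s.position, -_CLASS_RANK[s.site_class]))
    return sites


def count_sites_per_mirna(
    circle_seq: str,
    mirna_list: Sequence[MirnaRecord],
    min_sites: int = 3,
    circular: bool = True,
) -> tuple[dict[str, int], dict[str, int]]:
    """Seed-site counts per miRNA: (full table, table filtered to >= min_sites)."""
    ids = [m.mirna_id for m in mirna_list]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate mirna_id in list")
    full = {
        m.mirna_id: len(scan_seed_sites(circle_seq, m, circular=circular))
        for m in mirna_list
    }
    report = {k: v for k, v in full.items() if v >= min_sites}
    return full, report


# ---------------------------------------------------------------------------
# target-set enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    mirna_id: str
    contingency: tuple[int, int, int, int]  # (DE&T, DE-T, bg&T, bg-T)
    odds_ratio: float
    p_value: float
    q_value: float = float("nan")
    continuity_corrected: bool = False


def fisher_enrichment(
    de_genes: set,
    target_map: Mapping[str, set],
    universe: set,
) -> list[EnrichmentResult]:
    """One-sided (enrichment) Fisher exact test per miRNA target set.

    The p-value is the hypergeometric upper tail of the DE/target overlap
    within the universe; q-values are BH across miRNAs.  The odds ratio uses
    a 0.5 continuity correction only when a zero cell occurs (flagged).
    """
    if not universe:
        raise ValueError("empty universe")
    de = set(de_genes) & set(universe)
    if de != set(de_genes):
        raise ValueError("de_genes must be a subset of the universe")
    N = len(universe)
    n = len(de)
    results = []
    for mid in sorted(target_map):
        T = set(target_map[mid]) & set(universe)
        K = len(T)
        a = len(de & T)
        b = n - a
        c = K - a
        d = N - n - c
        p = float(stats.hypergeom.sf(a - 1, N, K, n))
        corrected = False
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            corrected = True
        else:
            orr = (a * d) / (b * c)
        results.append(EnrichmentResult(
            mirna_id=mid, contingency=(a, b, c, d),
            odds_ratio=float(orr), p_value=min(p, 1.0),
            continuity_corrected=corrected))
    qs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


# ---------------------------------------------------------------------------
# qPCR standard curve and stoichiometry
# ---------------------------------------------------------------------------

@dataclass
class StandardCurve:
    """Linear qPCR calibration: Cq = slope * log10(copies) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    flagged: bool = False

    def quantify(self, cq: float) -> float:
        """Copy number corresponding to one Cq on the calibration line."""
        return float(10.0 ** ((cq - self.intercept) / self.slope))


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares calibration from (copies, Cq) dilution points.

    Requires >= 3 points spanning >= 2 log10 units of template copies.
    Amplification efficiency is 10^(-1/slope) - 1 and is flagged when
    outside [0.8, 1.1].
    """
    if len(points) < 3:
        raise ValueError("need >= 3 dilution points")
    copies = np.array([p[0] for p in points], dtype=float)
    cq = np.array([p[1] for p in points], dtype=float)
    if (copies <= 0).any():
        raise ValueError("copy numbers must be positive")
    logc = np.log10(copies)
    if logc.max() - logc.min() < 2.0:
        raise ValueError("dilution series must span >= 2 log10 units")
    res = stats.linregress(logc, cq)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope >= 0:
        raise ValueError("slope must be negative for a valid dilution series")
    eff = float(10.0 ** (-1.0 / slope) - 1.0)
    flagged = not (0.8 <= eff <= 1.1)
    if not 0.0 < eff <= 1.5:
        flagged = True
    return StandardCurve(slope=slope, intercept=intercept,
                         r_squared=float(res.rvalue ** 2),
                         efficiency=eff, flagged=flagged)


def stoichiometry(n_sites: int, circ_molar: float, mir_molar: float) -> float:
    """Binding sites offered per miRNA molecule: n_sites * [circ] / [miR]."""
    if circ_molar <= 0:
        raise ValueError("circRNA concentration must be positive")
    if mir_molar <= 0:
        raise ValueError("miRNA concentration must be positive")
    if n_sites < 0:
        raise ValueError("n_sites must be nonnegative")
    return n_sites * circ_molar / mir_molar


# ---------------------------------------------------------------------------
# synthetic worked-example circle
# ---------------------------------------------------------------------------

def synthetic_circslc8a1(seed: int = 128, length: int = 1832) -> str:
    """SYNTHETIC surrogate for the circularized SLC8A1 exon (not the real
    human sequence, which is not bundled): a deterministic random circle of
    the given length carrying exactly 7 embedded canonical miR-128 seed
    sites — the site count reported for the real circRNA — with one site
    spanning the back-splice junction.  The random background is
    rejection-sampled by plain substring search (independent of the scanner)
    so that no accidental seed cores occur.
    """
    rng = np.random.default_rng(seed)
    core = revcomp(_dna(MIR_128_SEQUENCE[1:7]))          # ACTGTG
    motifs = {
        "8mer": revcomp(_dna(MIR_128_SEQUENCE[1:8])) + "A",   # CACTGTGA
        "7mer-m8": revcomp(_dna(MIR_128_SEQUENCE[1:8])),      # CACTGTG
        "7mer-A1": core + "A",                                # ACTGTGA
        "6mer": core,                                         # ACTGTG
    }
    plan = ["8mer", "8mer", "7mer-m8", "7mer-m8", "7mer-A1", "7mer-A1", "6mer"]
    for _attempt in range(1000):
        seq = list("ACGT"[i] for i in rng.integers(0, 4, size=length))
        # place 6 interior sites at well-separated positions, plus one 8mer
        # spanning the junction (starting 3 nt before the circle end)
        starts = np.linspace(60, length - 120, num=6).astype(int)
        starts = starts + rng.integers(-20, 21, size=6)
        for st, cls in zip(starts, plan[1:]):
            m = motifs[cls]
            seq[st:st + len(m)] = list(m)
        jm = motifs["8mer"]
        jstart = length - 3
        for k, ch in enumerate(jm):
            seq[(jstart + k) % length] = ch
        s = "".join(seq)
        doubled = s + s[:8]
        n_cores = sum(
            1 for i in range(length) if doubled[i:i + 6] == core)
        if n_cores == 7:
            # guard against motif-adjacent upgrades changing class counts
            return s
    raise RuntimeError("failed to construct the synthetic circle")
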