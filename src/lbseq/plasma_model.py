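"""Binomial cfDNA sampling model and library-complexity arithmetic.

A plasma aliquot of mass ``m`` ng contains roughly
``n = floor(1000 m / 3.5)`` haploid genome equivalents (3.5 pg per haploid
genome).  If tumour-derived fragments make up a fraction ``f`` of cfDNA,
the number of tumour fragments covering any locus in the aliquot is
Binomial(n, f); the probability of capturing at least ``k_min`` of them is

    P = 1 - BinomCDF(k_min - 1; n, f)

The inverse problem — the smallest input mass giving capture probability
at least ``p`` — has a closed form for ``k_min = 1``
(``n = ceil(ln(1-p) / ln(1-f))`` genomes) and is solved by bisection on
the genome count otherwise.

The complexity chain converts an input mass to a unique-coverage ceiling:
total fragments = genomes x genome_bp / frag_len_bp; a retention fraction
survives library preparation; the on-target share is target_bp /
genome_bp of those; and the unique-fragment coverage ceiling is
on_target x frag_len_bp / target_bp.  Reads beyond the ceiling at a given
raw depth are PCR duplicates of the same input molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import binom

__all__ = [
    "PlasmaModelConfig",
    "ComplexityResult",
    "genome_equivalents",
    "capture_probability",
    "required_mass",
    "panel_footprint_bp",
    "on_target_unique",
    "coverage_ceiling",
    "library_complexity",
    "unique_fraction",
]


@dataclass(frozen=True)
class PlasmaModelConfig:
    """Parameters of the sampling and complexity models.

    haploid_mass_pg:
        Mass of one haploid genome, picograms (default 3.5).
    tumour_fraction:
        Fraction of cfDNA fragments that are tumour-derived (default
        0.0005, i.e. 0.05%, the worst case the assay is sized for).
    k_min:
        Number of tumour fragments that must land in the aliquot
        (default 1).
    retention_fraction:
        Fraction of input fragments surviving adapter ligation, library
        amplification and clean-up (default 0.43, the cohort median).
    target_bp:
        Capture-panel footprint in bases (default 17,500).
    genome_bp:
        Effective genome size in bases (default 2.86e9).
    frag_len_bp:
        Typical cfDNA fragment length (default 170 bp).
    """

    haploid_mass_pg: float = 3.5
    tumour_fraction: float = 0.0005
    k_min: int = 1
    retention_fraction: float = 0.43
    target_bp: int = 17_500
    genome_bp: float = 2.86e9
    frag_len_bp: int = 170

    def __post_init__(self) -> None:
        if self.haploid_mass_pg <= 0:
            raise ValueError("haploid_mass_pg must be > 0")
        if not (0.0 < self.tumour_fraction < 1.0):
            raise ValueError("tumour_fraction must be in (0, 1)")
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")
        if not (0.0 <= self.retention_fraction <= 1.0):
            raise ValueError("retention_fraction must be in [0, 1]")
        if min(self.target_bp, self.genome_bp, self.frag_len_bp) <= 0:
            raise ValueError("sizes must be positive")


@dataclass(frozen=True)
class ComplexityResult:
    total_fragments: float
    retained_fragments: float
    on_target_unique: float
    unique_cov_ceiling: float


def genome_equivalents(mass_ng: float, cfg: PlasmaModelConfig | None = None) -> int:
    """Whole haploid genome equivalents in ``mass_ng`` of cfDNA (floor)."""
    cfg = cfg or PlasmaModelConfig()
    if mass_ng < 0:
        raise ValueError("mass must be >= 0")
    return math.floor(mass_ng * 1000.0 / cfg.haploid_mass_pg)


def capture_probability(mass_ng: float, cfg: PlasmaModelConfig | None = None) -> float:
    """P(at least k_min tumour fragments in the aliquot), exact binomial."""
    cfg = cfg or PlasmaModelConfig()
    n = genome_equivalents(mass_ng, cfg)
    if n < cfg.k_min:
        return 0.0
    return float(binom.sf(cfg.k_min - 1, n, cfg.tumour_fraction))


def _capture_probability_n(n: int, cfg: PlasmaModelConfig) -> float:
    if n < cfg.k_min:
        return 0.0
    return float(binom.sf(cfg.k_min - 1, n, cfg.tumour_fraction))


def required_mass(p_target: float, cfg: PlasmaModelConfig | None = None) -> float:
    """Smallest input mass (ng) whose capture probability reaches ``p_target``.

    Closed form for ``k_min = 1``; bisection on the genome-equivalent count
    otherwise.  Returned mass is a whole number of genome equivalents.
    """
    cfg = cfg or PlasmaModelConfig()
    if not (0.0 < p_target < 1.0):
        raise ValueError("p_target must be in (0, 1)")
    f = cfg.tumour_fraction
    if cfg.k_min == 1:
        n = math.ceil(math.log(1.0 - p_target) / math.log(1.0 - f))
    else:
        lo, hi = cfg.k_min, max(2 * cfg.k_min, 16)
        while _capture_probability_n(hi, cfg) < p_target:
            hi *= 2
        while hi - lo > 1:  # invariant: P(lo) < p_target <= P(hi)
            mid = (lo + hi) // 2
            if _capture_probability_n(mid, cfg) >= p_target:
                hi = mid
            else:
                lo = mid
        n = hi
    return n * cfg.haploid_mass_pg / 1000.0


def panel_footprint_bp(
    n_probes: int = 146, probe_len_bp: int = 120, tiling: float = 1.0
) -> float:
    """Capture-panel footprint: probes x probe length / tiling density."""
    if n_probes < 1 or probe_len_bp < 1 or tiling <= 0:
        raise ValueError("probe count, length and tiling must be positive")
    return n_probes * probe_len_bp / tiling


def on_target_unique(
    retained_fragments: float, cfg: PlasmaModelConfig | None = None
) -> float:
    """Unique fragments overlapping the target, from the retained-fragment count."""
    cfg = cfg or PlasmaModelConfig()
    return retained_fragments * cfg.target_bp / cfg.genome_bp


def coverage_ceiling(
    on_target_fragments: float, cfg: PlasmaModelConfig | None = None
) -> float:
    """Unique-fragment coverage ceiling implied by the on-target molecule count."""
    cfg = cfg or PlasmaModelConfig()
    return on_target_fragments * cfg.frag_len_bp / cfg.target_bp


def library_complexity(
    input_ng: float, cfg: PlasmaModelConfig | None = None
) -> ComplexityResult:
    """Fragment-count chain from input mass to the unique-coverage ceiling."""
    cfg = cfg or PlasmaModelConfig()
    if input_ng <= 0:
        raise ValueError("input mass must be > 0")
    genomes = genome_equivalents(input_ng, cfg)
    total = genomes * cfg.genome_bp / cfg.frag_len_bp
    retained = total * cfg.retention_fraction
    on_target = on_target_unique(retained, cfg)
    ceiling = coverage_ceiling(on_target, cfg)
    return ComplexityResult(
        total_fragments=total,
        retained_fragments=retained,
        on_target_unique=on_target,
        unique_cov_ceiling=ceiling,
    )


def unique_fraction(ceiling: float, depth: float) -> float:
    """Percent of reads at ``depth`` that can be unique molecules (capped at 100)."""
    if depth <= 0:
        raise ValueError("depth must be > 0")
    return min(100.0, 100.0 * ceiling / depth)
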