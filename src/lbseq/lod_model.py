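"""Tumour LOD scoring from read counts under a substitution error model.

The tumour LOD score is the log10 likelihood ratio of the data at a locus
under "a variant is present at its maximum-likelihood allele fraction"
versus "every non-reference read is a sequencing error".  Each read is
modelled as a two-component mixture: with probability ``f`` it derives from
a variant-carrying fragment (read as the alternate base unless miscalled),
and with probability ``1 - f`` from a reference fragment.  A base is
miscalled with probability ``e``; a *specific* wrong base occurs with
probability ``e/3``.

Per-read likelihoods:

    P(alt read | f) = f (1 - e) + (1 - f) e/3
    P(ref read | f) = (1 - f)(1 - e) + f e/3

    LOD = sum over reads of log10 [ P(read | f = f_hat) / P(read | f = 0) ]

with ``f_hat = alt_count / depth``, the unconstrained maximum-likelihood
allele fraction.  The sum groups into a closed form
``alt*log10(r_alt) + ref*log10(r_ref)``.

A single uniform error rate stands in for per-base quality scores: the
downstream filtering statistic operates on within-sample LOD *distributions*
(median / MAD normalisation), not on absolute calibration, so only the
structural shape of the score matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ErrorModel",
    "ReadCounts",
    "allele_fraction_mle",
    "tumour_lod",
    "tumour_lod_array",
    "detection_floor",
    "NOT_ATTAINABLE",
]

#: Sentinel returned by :func:`detection_floor` when no alt count up to the
#: full depth reaches the requested LOD.
NOT_ATTAINABLE: int = -1


@dataclass(frozen=True)
class ErrorModel:
    """Uniform per-base substitution error probability.

    Parameters
    ----------
    e:
        Probability that a sequenced base is misread.  A specific wrong
        base is observed with probability ``e / 3``.  Default 1e-3, a
        typical Illumina raw substitution rate.
    """

    e: float = 1e-3

    def __post_init__(self) -> None:
        if not (0.0 < self.e < 0.5):
            raise ValueError(f"error rate must be in (0, 0.5), got {self.e}")


@dataclass(frozen=True)
class ReadCounts:
    """Read counts at one locus: total depth and alternate-allele count."""

    depth: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError(
                f"alt_count must be in [0, depth], got {self.alt_count} / {self.depth}"
            )

    @property
    def ref_count(self) -> int:
        return self.depth - self.alt_count


def allele_fraction_mle(counts: ReadCounts) -> float:
    """Maximum-likelihood allele fraction, ``alt_count / depth``."""
    return counts.alt_count / counts.depth


def _per_read_ratios(f: float, e: float) -> tuple[float, float]:
    """log10 per-read likelihood ratios (alt, ref) of f versus f = 0."""
    p_alt_f = f * (1.0 - e) + (1.0 - f) * e / 3.0
    p_ref_f = (1.0 - f) * (1.0 - e) + f * e / 3.0
    p_alt_0 = e / 3.0
    p_ref_0 = 1.0 - e
    return math.log10(p_alt_f / p_alt_0), math.log10(p_ref_f / p_ref_0)


def tumour_lod(counts: ReadCounts, err: ErrorModel) -> float:
    """Tumour LOD score for one locus.

    Zero exactly when ``alt_count == 0`` (the MLE fraction is 0, so
    numerator and denominator coincide).  Monotone increasing in
    ``alt_count`` once the observed fraction clears the error rate;
    below that floor the plug-in MLE can score slightly negative, since
    an observed fraction under ``e`` is better explained by pure error.
    """
    if counts.alt_count == 0:
        return 0.0
    f_hat = allele_fraction_mle(counts)
    r_alt, r_ref = _per_read_ratios(f_hat, err.e)
    return counts.alt_count * r_alt + counts.ref_count * r_ref


def tumour_lod_array(
    alt_counts: np.ndarray, depths: np.ndarray, e: float
) -> np.ndarray:
    """Vectorised :func:`tumour_lod` over parallel alt/depth arrays."""
    alt = np.asarray(alt_counts, dtype=float)
    depth = np.asarray(depths, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = alt / depth
        p_alt_f = f * (1.0 - e) + (1.0 - f) * e / 3.0
        p_ref_f = (1.0 - f) * (1.0 - e) + f * e / 3.0
        lod = alt * np.log10(p_alt_f / (e / 3.0)) + (depth - alt) * np.log10(
            p_ref_f / (1.0 - e)
        )
    return np.where(alt == 0, 0.0, lod)


def detection_floor(depth: int, err: ErrorModel, lod_min: float) -> int:
    """Smallest alt count whose tumour LOD reaches ``lod_min``.

    Returns :data:`NOT_ATTAINABLE` if even ``alt_count == depth`` falls
    short.  Uses bisection, valid because the LOD is monotone
    non-decreasing in the alt count.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if lod_min < 0:
        raise ValueError("lod_min must be >= 0")
    if lod_min == 0:
        return 0
    if tumour_lod(ReadCounts(depth, depth), err) < lod_min:
        return NOT_ATTAINABLE
    lo, hi = 0, depth  # invariant: lod(lo) < lod_min <= lod(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if tumour_lod(ReadCounts(depth, mid), err) >= lod_min:
            hi = mid
        else:
            lo = mid
    return hi
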