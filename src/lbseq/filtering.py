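"""Per-sample robust LOD filtering with modified Z-scores.

Absolute tumour LOD scores vary strongly between samples and sequencing
batches, so a single cohort-wide LOD cutoff is unusable.  Instead each
sample's LOD distribution is normalised by its own robust location and
scale: the modified Z-score of a call is its distance from the sample
median divided by the sample MAD (median absolute deviation, used *raw*
— no 1.4826 consistency constant and no 0.6745 modified-Z constant, so
that the calibrated threshold of 20 keeps its meaning).  The pool for the
median/MAD is the calls the upstream caller kept (judgement KEEP), prior
to any downstream filtering.

Filtering proceeds stepwise, each call removed by the FIRST step that
rejects it:

1. judgement — calls the upstream caller rejected;
2. modified Z — calls with z below the threshold (pass is z >= threshold);
3. germline — calls annotated at > 0.1% population allele frequency.

Survivors are putative somatic mutations.  Modified Z-scores are invariant
under adding a constant to (or positively rescaling) all of a sample's
LODs, which is exactly the batch-effect resistance the normalisation is
for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from statistics import median
from typing import Iterable, Optional, Sequence

from .callset_io import Judgement, SampleCallSet, VariantCall

__all__ = [
    "FilterConfig",
    "Disposition",
    "SampleStats",
    "FilterReport",
    "EmptySampleError",
    "lod_location_scale",
    "modified_z_scores",
    "germline_popaf_filter",
    "run_lbseq_filter",
]


class EmptySampleError(ValueError):
    """Raised when a sample has no KEEP calls to estimate location/scale from."""


@dataclass(frozen=True)
class FilterConfig:
    """Tunable filter parameters.

    z_threshold:
        Modified Z-score above which (inclusive) a call survives the
        outlier step.  Default 20, the ROC-calibrated value.
    pop_af_cutoff:
        Population allele frequency above which (strict) a call is
        considered a germline polymorphism.  Default 0.001 (0.1%).
    mad_floor:
        Substitute scale when the sample MAD is exactly zero (all KEEP
        LODs identical); keeps cohort runs from dividing by zero.
    """

    z_threshold: float = 20.0
    pop_af_cutoff: float = 0.001
    mad_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        if not (0.0 <= self.pop_af_cutoff < 1.0):
            raise ValueError("pop_af_cutoff must be in [0, 1)")
        if self.mad_floor <= 0:
            raise ValueError("mad_floor must be > 0")


class Disposition(str, Enum):
    SOMATIC_KEPT = "SOMATIC_KEPT"
    REMOVED_JUDGEMENT = "REMOVED_JUDGEMENT"
    REMOVED_Z = "REMOVED_Z"
    REMOVED_GERMLINE = "REMOVED_GERMLINE"


@dataclass(frozen=True)
class SampleStats:
    """Robust location/scale of a sample's KEEP-call LOD distribution."""

    median: float
    mad: float
    degenerate: bool = False  # True if the raw MAD was 0 and the floor was used


@dataclass
class FilterReport:
    """Per-call dispositions plus the sample statistics that produced them."""

    sample_id: str
    lod_median: float
    lod_mad: float
    lod_threshold: float
    dispositions: list[Disposition]
    z_scores: list[float]
    mad_degenerate: bool = False
    empty_pool: bool = False
    calls: list[VariantCall] = field(default_factory=list)

    @property
    def counts(self) -> dict[Disposition, int]:
        out = {d: 0 for d in Disposition}
        for d in self.dispositions:
            out[d] += 1
        return out

    @property
    def n_kept(self) -> int:
        return sum(1 for d in self.dispositions if d is Disposition.SOMATIC_KEPT)

    def kept_calls(self) -> list[VariantCall]:
        return [
            c
            for c, d in zip(self.calls, self.dispositions)
            if d is Disposition.SOMATIC_KEPT
        ]


def lod_location_scale(
    callset: SampleCallSet, mad_floor: float = 1e-6
) -> SampleStats:
    """Median and raw MAD of tumour LODs over the sample's KEEP calls.

    Raises :class:`EmptySampleError` with zero KEEP calls.  A zero MAD
    (all pooled LODs identical) is replaced by ``mad_floor`` and flagged.
    """
    pool = [c.t_lod for c in callset.keep_calls()]
    if not pool:
        raise EmptySampleError(
            f"sample {callset.sample_id}: no KEEP calls to estimate statistics"
        )
    med = median(pool)
    mad = median(abs(x - med) for x in pool)
    if mad == 0.0:
        return SampleStats(median=med, mad=mad_floor, degenerate=True)
    return SampleStats(median=med, mad=mad, degenerate=False)


def modified_z_scores(
    callset: SampleCallSet, stats: SampleStats
) -> list[float]:
    """Modified Z-score (lod - median) / mad for every call, REJECTs included."""
    return [(c.t_lod - stats.median) / stats.mad for c in callset.calls]


def germline_popaf_filter(
    calls: Iterable[VariantCall], cutoff: float = 0.001
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition calls into (kept, removed-as-germline).

    A call is removed iff its population allele frequency is annotated AND
    strictly exceeds the cutoff; unannotated calls are kept.
    """
    kept: list[VariantCall] = []
    removed: list[VariantCall] = []
    for c in calls:
        if c.pop_af is not None and c.pop_af > cutoff:
            removed.append(c)
        else:
            kept.append(c)
    return kept, removed


def _is_germline(call: VariantCall, cutoff: float) -> bool:
    return call.pop_af is not None and call.pop_af > cutoff


def run_lbseq_filter(
    callset: SampleCallSet, config: Optional[FilterConfig] = None
) -> FilterReport:
    """Run the full stepwise filter on one sample.

    Each call receives exactly one disposition, assigned by the first
    step that removes it (judgement, then modified Z, then germline); the
    reported ``lod_threshold`` is ``median + z_threshold * mad``.  A sample
    with no KEEP calls yields a report with NaN statistics and every call
    REMOVED_JUDGEMENT.
    """
    if config is None:
        config = FilterConfig()

    try:
        stats = lod_location_scale(callset, mad_floor=config.mad_floor)
    except EmptySampleError:
        nan = float("nan")
        return FilterReport(
            sample_id=callset.sample_id,
            lod_median=nan,
            lod_mad=nan,
            lod_threshold=nan,
            dispositions=[Disposition.REMOVED_JUDGEMENT] * len(callset.calls),
            z_scores=[nan] * len(callset.calls),
            empty_pool=True,
            calls=list(callset.calls),
        )

    zs = modified_z_scores(callset, stats)
    dispositions: list[Disposition] = []
    for call, z in zip(callset.calls, zs):
        if call.judgement is not Judgement.KEEP:
            dispositions.append(Disposition.REMOVED_JUDGEMENT)
        elif z < config.z_threshold:
            dispositions.append(Disposition.REMOVED_Z)
        elif _is_germline(call, config.pop_af_cutoff):
            dispositions.append(Disposition.REMOVED_GERMLINE)
        else:
            dispositions.append(Disposition.SOMATIC_KEPT)

    return FilterReport(
        sample_id=callset.sample_id,
        lod_median=stats.median,
        lod_mad=stats.mad,
        lod_threshold=stats.median + config.z_threshold * stats.mad,
        dispositions=dispositions,
        z_scores=zs,
        mad_degenerate=stats.degenerate,
        calls=list(callset.calls),
    )
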