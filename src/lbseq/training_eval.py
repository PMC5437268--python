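"""Threshold training and cohort evaluation against bone-marrow truth.

The modified Z-score threshold is trained with an ROC sweep: for each
candidate threshold the full stepwise filter is run over a training cohort
and pooled sensitivity (detected truth mutations / truth mutations) and
specificity (removed non-truth KEEP candidates / non-truth KEEP
candidates) are recorded; the selected threshold maximises Youden's
J = sensitivity + specificity - 1, ties broken toward the smaller
threshold (favouring sensitivity).

Evaluation utilities cover cohort concordance (a truth mutation counts as
detected if it is kept in any cfDNA sample of that patient), per-patient
ordinary least-squares regression of cfDNA on bone-marrow allele
fractions (patients with >= 3 shared mutations), subclonal rank
concordance, and fragment-overlap phasing of adjacent variants (two
variants carried by disjoint sets of sequenced fragments reside on
different molecules, hence in distinct subclones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .callset_io import GenomicLocus, SampleCallSet, TruthSet
from .filtering import Disposition, FilterConfig, FilterReport, run_lbseq_filter

__all__ = [
    "RocPoint",
    "ConcordanceResult",
    "RegressionResult",
    "PhaseVerdict",
    "PhaseResult",
    "sweep_roc",
    "select_threshold",
    "concordance",
    "af_regression",
    "rank_concordance",
    "phase_overlap",
    "DEFAULT_THRESHOLD_GRID",
]

#: Default ROC grid: integer thresholds 1..100.
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = tuple(float(t) for t in range(1, 101))


@dataclass(frozen=True)
class RocPoint:
    z_threshold: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class ConcordanceResult:
    n_truth: int
    n_detected: int
    fp_calls: tuple[tuple[str, GenomicLocus], ...]
    n_nontruth_candidates: int

    @property
    def concordance_pct(self) -> int:
        if self.n_truth == 0:
            return 0
        return round(100.0 * self.n_detected / self.n_truth)

    @property
    def sensitivity(self) -> float:
        return self.n_detected / self.n_truth if self.n_truth else float("nan")

    @property
    def specificity(self) -> float:
        if self.n_nontruth_candidates == 0:
            return float("nan")
        return 1.0 - len(self.fp_calls) / self.n_nontruth_candidates

    @property
    def specificity_pct(self) -> float:
        return 100.0 * self.specificity


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


class PhaseVerdict(str, Enum):
    co_occurring = "co-occurring"
    mutually_exclusive = "mutually exclusive"
    mixed = "mixed"


@dataclass(frozen=True)
class PhaseResult:
    shared_count: int
    a_only: int
    b_only: int
    verdict: PhaseVerdict


def _filter_cohort(
    cohort: Sequence[SampleCallSet], config: FilterConfig
) -> list[FilterReport]:
    return [run_lbseq_filter(cs, config) for cs in cohort]


def _tally(
    cohort: Sequence[SampleCallSet],
    reports: Sequence[FilterReport],
    truth: TruthSet,
) -> tuple[set[tuple[str, GenomicLocus]], list[tuple[str, GenomicLocus]], int]:
    """Pooled (detected truth keys, false-positive keys, n non-truth candidates)."""
    detected: set[tuple[str, GenomicLocus]] = set()
    fps: list[tuple[str, GenomicLocus]] = []
    n_nontruth = 0
    for cs, rep in zip(cohort, reports):
        pid = cs.patient_id or cs.sample_id
        for call, disp in zip(rep.calls, rep.dispositions):
            if call.judgement.value != "KEEP":
                continue
            key = (pid, call.locus)
            if key in truth:
                if disp is Disposition.SOMATIC_KEPT:
                    detected.add(key)
            else:
                n_nontruth += 1
                if disp is Disposition.SOMATIC_KEPT:
                    fps.append(key)
    return detected, fps, n_nontruth


def sweep_roc(
    cohort: Sequence[SampleCallSet],
    truth: TruthSet,
    thresholds: Iterable[float] = DEFAULT_THRESHOLD_GRID,
    config: Optional[FilterConfig] = None,
) -> list[RocPoint]:
    """Run the full filter at each threshold and pool sensitivity/specificity.

    Sensitivity is over pooled truth loci (a truth mutation is detected if
    kept in any sample of its patient); specificity over pooled non-truth
    KEEP candidates.
    """
    if not cohort:
        raise ValueError("empty cohort")
    thresholds = sorted(set(float(t) for t in thresholds))
    if not thresholds:
        raise ValueError("empty threshold grid")
    base = config or FilterConfig()

    points: list[RocPoint] = []
    for t in thresholds:
        reports = _filter_cohort(cohort, replace(base, z_threshold=t))
        detected, fps, n_nontruth = _tally(cohort, reports, truth)
        n_truth = len(truth)
        sens = len(detected) / n_truth if n_truth else 1.0
        spec = 1.0 - len(fps) / n_nontruth if n_nontruth else 1.0
        points.append(RocPoint(z_threshold=t, sensitivity=sens, specificity=spec))
    return points


def select_threshold(roc: Sequence[RocPoint]) -> float:
    """Threshold maximising Youden's J; ties go to the smaller threshold."""
    if not roc:
        raise ValueError("empty ROC")
    best = roc[0]
    for p in roc[1:]:
        if p.youden_j > best.youden_j or (
            p.youden_j == best.youden_j and p.z_threshold < best.z_threshold
        ):
            best = p
    return best.z_threshold


def concordance(
    cohort: Sequence[SampleCallSet],
    truth: TruthSet,
    config: Optional[FilterConfig] = None,
) -> ConcordanceResult:
    """Cohort-level detection of bone-marrow truth mutations.

    A truth mutation is detected iff its locus is SOMATIC_KEPT in any
    cfDNA sample of that patient.  Kept loci absent from the patient's
    truth are false positives; specificity is 1 - FP / (non-truth KEEP
    candidates).  Patients present in the cohort but absent from the truth
    set contribute to the false-positive accounting only (with a warning).
    """
    reports = _filter_cohort(cohort, config or FilterConfig())
    truth_patients = truth.patients()
    for cs in cohort:
        pid = cs.patient_id or cs.sample_id
        if pid not in truth_patients:
            warnings.warn(
                f"patient {pid} has no truth records; "
                "excluded from sensitivity, included in FP accounting",
                stacklevel=2,
            )
    detected, fps, n_nontruth = _tally(cohort, reports, truth)
    return ConcordanceResult(
        n_truth=len(truth),
        n_detected=len(detected),
        fp_calls=tuple(fps),
        n_nontruth_candidates=n_nontruth,
    )


def af_regression(
    pairs: Sequence[tuple[float, float]]
) -> RegressionResult:
    """OLS of bone-marrow AF on cfDNA AF for one patient (>= 3 mutations).

    Pairs are (cfDNA AF, BM AF).  Fewer than three pairs, or zero variance
    in the cfDNA AFs, is an error.
    """
    if len(pairs) < 3:
        raise ValueError(
            f"allele-fraction regression needs >= 3 mutation pairs, got {len(pairs)}"
        )
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in cfDNA allele fractions")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n=len(pairs),
    )


def rank_concordance(
    cf_afs: Sequence[float], bm_afs: Sequence[float]
) -> tuple[bool, float]:
    """Do cfDNA and bone-marrow allele fractions order the clones identically?

    Returns (concordant, Kendall's tau).  Concordant means the two AF
    rankings are identical (tau == 1 with no ties broken differently).
    """
    if len(cf_afs) != len(bm_afs):
        raise ValueError("cfDNA and BM allele-fraction lists differ in length")
    if len(cf_afs) < 2:
        raise ValueError("need at least 2 mutations to compare orderings")
    cf_order = np.argsort(np.asarray(cf_afs, dtype=float), kind="stable")
    bm_order = np.argsort(np.asarray(bm_afs, dtype=float), kind="stable")
    concordant = bool(np.array_equal(cf_order, bm_order))
    tau = sps.kendalltau(cf_afs, bm_afs).statistic
    return concordant, float(tau)


def phase_overlap(
    obs: Sequence[tuple[bool, bool]]
) -> PhaseResult:
    """Phase two nearby variants from per-fragment co-occurrence.

    ``obs`` holds, for each sequenced fragment spanning both positions,
    whether it carries variant A and variant B.  Mutually exclusive iff no
    fragment carries both and each variant has at least one supporting
    fragment; co-occurring iff every supporting fragment carries both.
    """
    shared = sum(1 for a, b in obs if a and b)
    a_only = sum(1 for a, b in obs if a and not b)
    b_only = sum(1 for a, b in obs if b and not a)
    n_a = shared + a_only
    n_b = shared + b_only
    if shared == 0 and n_a >= 1 and n_b >= 1:
        verdict = PhaseVerdict.mutually_exclusive
    elif shared >= 1 and a_only == 0 and b_only == 0:
        verdict = PhaseVerdict.co_occurring
    else:
        verdict = PhaseVerdict.mixed
    return PhaseResult(
        shared_count=shared, a_only=a_only, b_only=b_only, verdict=verdict
    )
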