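"""Synthetic per-sample call tables with matched bone-marrow truth.

The generator emulates the statistical structure the filtering algorithm
assumes in deep (~20,000x) targeted cfDNA sequencing of a small gene
panel:

* a background of sequencing-artefact sites whose alt counts are binomial
  draws at the per-base error rate, with a heavy-tailed minority of sites
  error-inflated (polymerase / damage hotspots) — these form the bulk of
  each sample's LOD distribution;
* germline SNPs at allele fraction ~0.5 or ~1.0, carrying population
  allele-frequency annotations above the 0.1% germline cutoff;
* spiked somatic variants at allele fractions spanning 0.25–46%, the
  range observed in the modelled cohort, with matched bone-marrow allele
  fractions related to the cfDNA fractions by a per-patient scaling plus
  multiplicative noise;
* additive per-batch LOD shifts (default 0 vs +15, emulating reported
  batch medians of ~8.5 vs ~23.2) — the batch effect the modified
  Z-score normalisation exists to absorb.

Every emitted call carries exactly one ground-truth label (artefact,
germline or somatic); the TruthSet contains exactly the somatic labels.
All randomness flows from a single seed; per-sample substreams are derived
from (seed, sample_index) so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Optional, Sequence

import numpy as np

from .callset_io import (
    GenomicLocus,
    Judgement,
    SampleCallSet,
    TruthRecord,
    TruthSet,
    VariantCall,
)
from .lod_model import tumour_lod_array

__all__ = [
    "CohortConfig",
    "CallLabel",
    "simulate_sample",
    "simulate_cohort",
    "simulate_training_set",
    "SeparationError",
]

_PANEL_GENES = ("KRAS", "NRAS", "BRAF", "EGFR", "PIK3CA")
_BASES = np.array(list("ACGT"))


class SeparationError(RuntimeError):
    """Raised when a requested artefact/somatic z separation is infeasible."""


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the modelled assay: 48 evaluable samples carrying 51
    somatic truth variants in total, ~20,000x mean depth, per-base error
    5e-4, 200 artefact sites and 30 germline SNPs per sample, somatic
    allele fractions 0.25-46%, two batches with LOD medians offset by 15,
    and 5% relative noise between cfDNA and bone-marrow fractions.
    """

    n_samples: int = 48
    seed: int = 0
    depth_mean: int = 20_000
    depth_dispersion: float = 50.0
    error_rate: float = 5e-4
    n_artefact_sites: int = 200
    artefact_inflated_fraction: float = 0.1
    artefact_multiplier_tail: float = 3.0
    n_germline: int = 30
    rare_germline_fraction: float = 0.0
    somatic_af_range: tuple[float, float] = (0.0025, 0.46)
    n_somatic_total: int = 51
    batch_lod_shifts: tuple[float, ...] = (0.0, 15.0)
    bm_noise_cv: float = 0.05
    n_reject: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        lo, hi = self.somatic_af_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("somatic_af_range must satisfy 0 < lo <= hi < 1")
        for name in (
            "n_artefact_sites",
            "n_germline",
            "n_somatic_total",
            "n_reject",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.error_rate < 0.5):
            raise ValueError("error_rate must be in (0, 0.5)")


@dataclass(frozen=True)
class CallLabel:
    """Ground-truth label of one emitted call."""

    sample_id: str
    locus: GenomicLocus
    label: str  # artefact | germline | somatic
    true_af: float  # the sampling fraction the alt count was drawn at


def _sample_rng(seed: int, sample_index: int) -> np.random.Generator:
    # fixed-offset substream: reproducible per sample, independent of order
    return np.random.default_rng([seed, sample_index])


def _draw_depths(rng: np.random.Generator, n: int, cfg: CohortConfig) -> np.ndarray:
    r = cfg.depth_dispersion
    p = r / (r + cfg.depth_mean)
    return np.maximum(1, rng.negative_binomial(r, p, size=n))


def _draw_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


def simulate_sample(
    cfg: CohortConfig,
    sample_index: int,
    somatic_afs: Optional[Sequence[float]] = None,
    patient_id: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[SampleCallSet, list[CallLabel]]:
    """Simulate one plasma sample's candidate-call table.

    Read counts: depth ~ negative binomial (mean ``depth_mean``); artefact
    alt ~ Binomial(depth, site error rate); somatic alt ~ Binomial(depth,
    AF); germline alt ~ Binomial(depth, ~0.5 or ~1.0).  LODs are computed
    with the package's own scorer at the nominal error rate (the analyst
    does not know which sites are error-inflated), then shifted by the
    sample's batch offset.  ``somatic_afs`` overrides the number and the
    allele fractions of spiked somatic variants; by default none are
    spiked at the single-sample level (the cohort generator allocates
    them).
    """
    if rng is None:
        rng = _sample_rng(cfg.seed, sample_index)
    sample_id = f"SYN-{sample_index:03d}"
    # one sample per synthetic patient; sharing the id keeps serialized
    # cohorts joinable to their truth table without a sample manifest
    pid = patient_id if patient_id is not None else sample_id
    batch_idx = sample_index % max(1, len(cfg.batch_lod_shifts))
    batch_shift = cfg.batch_lod_shifts[batch_idx] if cfg.batch_lod_shifts else 0.0
    afs = list(somatic_afs) if somatic_afs is not None else []

    n_art = cfg.n_artefact_sites
    n_germ = cfg.n_germline
    n_som = len(afs)
    n_rej = cfg.n_reject
    n_total = n_art + n_germ + n_som + n_rej

    depths = _draw_depths(rng, n_total, cfg)
    refs, alts = _draw_alleles(rng, n_total)
    positions = 1 + rng.choice(5_000_000, size=n_total, replace=False)

    # per-site sampling fractions
    true_af = np.empty(n_total)
    labels = []
    # artefacts: error rate, inflated at a heavy-tailed minority of sites
    e_site = np.full(n_art, cfg.error_rate)
    n_inflated = int(round(cfg.artefact_inflated_fraction * n_art))
    if n_inflated:
        mult = 1.0 + rng.pareto(cfg.artefact_multiplier_tail, size=n_inflated)
        e_site[:n_inflated] *= mult
    # an error generates one of 3 wrong bases; the emitted call tracks one
    true_af[:n_art] = np.minimum(e_site / 3.0, 0.5)
    labels += ["artefact"] * n_art
    # germline SNPs: het or hom
    hom = rng.random(n_germ) < 0.25
    true_af[n_art : n_art + n_germ] = np.where(hom, 0.999, 0.5)
    labels += ["germline"] * n_germ
    # somatic spikes
    true_af[n_art + n_germ : n_art + n_germ + n_som] = afs
    labels += ["somatic"] * n_som
    # optional upstream-rejected artefact-like calls
    true_af[n_art + n_germ + n_som :] = cfg.error_rate / 3.0
    labels += ["artefact"] * n_rej

    alt_counts = rng.binomial(depths, true_af)
    # an emitted candidate needs at least one supporting read
    alt_counts = np.maximum(alt_counts, 1)
    lods = tumour_lod_array(alt_counts, depths, cfg.error_rate) + batch_shift

    # germline population-frequency annotations
    pop_af = np.full(n_total, np.nan)
    g0, g1 = n_art, n_art + n_germ
    common = 10 ** rng.uniform(np.log10(0.0011), np.log10(0.5), size=n_germ)
    rare = 10 ** rng.uniform(np.log10(1e-5), np.log10(0.0009), size=n_germ)
    is_rare = rng.random(n_germ) < cfg.rare_germline_fraction
    pop_af[g0:g1] = np.where(is_rare, rare, common)

    calls: list[VariantCall] = []
    out_labels: list[CallLabel] = []
    for i in range(n_total):
        locus = GenomicLocus(
            "chr1", int(positions[i]), str(refs[i]), str(alts[i])
        )
        judgement = (
            Judgement.REJECT if i >= n_art + n_germ + n_som else Judgement.KEEP
        )
        calls.append(
            VariantCall(
                locus=locus,
                t_ref_count=int(depths[i] - alt_counts[i]),
                t_alt_count=int(alt_counts[i]),
                tumour_f=float(alt_counts[i] / depths[i]),
                t_lod=float(lods[i]),
                judgement=judgement,
                pop_af=None if np.isnan(pop_af[i]) else float(pop_af[i]),
                gene=_PANEL_GENES[i % len(_PANEL_GENES)],
            )
        )
        out_labels.append(
            CallLabel(
                sample_id=sample_id,
                locus=locus,
                label=labels[i],
                true_af=float(true_af[i]),
            )
        )

    callset = SampleCallSet(
        sample_id=sample_id,
        patient_id=pid,
        batch_id=f"batch{batch_idx}",
        calls=calls,
    )
    return callset, out_labels


def simulate_cohort(
    cfg: CohortConfig,
) -> tuple[list[SampleCallSet], TruthSet, list[CallLabel]]:
    """Simulate a cohort of samples with matched bone-marrow truth.

    The ``n_somatic_total`` somatic variants are spread over samples
    uniformly at random; each patient carries one sample.  Bone-marrow
    truth AFs are the cfDNA sampling AFs scaled by a per-patient tumour
    content factor (log-normal around 2: marrow plasma cells are enriched
    relative to plasma cfDNA) with ``bm_noise_cv`` relative noise, clipped
    to [0, 1].
    """
    alloc_rng = np.random.default_rng([cfg.seed, 2**20])
    counts = np.bincount(
        alloc_rng.integers(0, cfg.n_samples, size=cfg.n_somatic_total),
        minlength=cfg.n_samples,
    ) if cfg.n_samples else np.zeros(0, dtype=int)

    lo, hi = cfg.somatic_af_range
    cohort: list[SampleCallSet] = []
    all_labels: list[CallLabel] = []
    truth = TruthSet()
    for i in range(cfg.n_samples):
        rng = _sample_rng(cfg.seed, i)
        if lo == hi:
            afs = np.full(counts[i], lo)
        else:
            afs = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=counts[i])
        callset, labels = simulate_sample(cfg, i, somatic_afs=afs, rng=rng)
        cohort.append(callset)
        all_labels.extend(labels)

        scale = rng.lognormal(mean=np.log(2.0), sigma=0.3)
        for lab in labels:
            if lab.label != "somatic":
                continue
            bm = lab.true_af * scale * (1.0 + rng.normal(0.0, cfg.bm_noise_cv))
            truth.add(
                TruthRecord(
                    patient_id=callset.patient_id,
                    locus=lab.locus,
                    bm_allele_fraction=float(np.clip(bm, 0.0, 1.0)),
                )
            )
    return cohort, truth, all_labels


def _adjust_sample_separation(
    callset: SampleCallSet,
    labels: list[CallLabel],
    ceiling: float,
    floor: float,
    rng: np.random.Generator,
    max_iter: int = 50,
) -> None:
    """Pin LODs so artefact z < ceiling and somatic/germline z > floor.

    Iterates to a fixed point: sample statistics are recomputed after each
    adjustment because the adjusted LODs themselves enter the median/MAD
    pool.  The top artefact sites are spread just below the ceiling so
    that every lower threshold loses specificity (the ROC is informative
    across the whole grid up to the boundary).
    """
    idx_by_label = {"artefact": [], "germline": [], "somatic": []}
    for i, lab in enumerate(labels):
        idx_by_label[lab.label].append(i)
    art = idx_by_label["artefact"]
    signal = idx_by_label["somatic"] + idx_by_label["germline"]
    if len(callset.calls) < 3 or not art:
        raise SeparationError(
            f"sample {callset.sample_id}: too few calls to impose separation"
        )

    n_pin = min(len(art), 30)
    pin_z = ceiling - 0.1 - 0.5 * np.arange(n_pin)  # fill (0, ceiling)
    pin_z = pin_z[pin_z > 0.5]
    target_z = rng.uniform(floor + 0.5, floor + 25.0, size=len(signal))

    keep_idx = [
        i for i, c in enumerate(callset.calls) if c.judgement is Judgement.KEEP
    ]
    for _ in range(max_iter):
        pool = [callset.calls[i].t_lod for i in keep_idx]
        med = median(pool)
        mad = median(abs(x - med) for x in pool)
        if mad == 0:
            raise SeparationError("degenerate MAD; cannot impose separation")
        changed = False
        ranked = sorted(art, key=lambda i: callset.calls[i].t_lod, reverse=True)
        for j, i in enumerate(ranked[: len(pin_z)]):
            want = med + pin_z[j] * mad
            if abs(callset.calls[i].t_lod - want) > 1e-9:
                callset.calls[i].t_lod = want
                changed = True
        for j, i in enumerate(signal):
            want = med + target_z[j] * mad
            if abs(callset.calls[i].t_lod - want) > 1e-9:
                callset.calls[i].t_lod = want
                changed = True
        if not changed:
            break
    # verify the guarantee on the final statistics
    pool = [callset.calls[i].t_lod for i in keep_idx]
    med = median(pool)
    mad = median(abs(x - med) for x in pool)
    for i in art:
        if (callset.calls[i].t_lod - med) / mad >= ceiling:
            raise SeparationError(
                f"sample {callset.sample_id}: artefact z-score reached the ceiling"
            )
    for i in signal:
        if (callset.calls[i].t_lod - med) / mad <= floor:
            raise SeparationError(
                f"sample {callset.sample_id}: somatic z-score fell below the floor"
            )


def simulate_training_set(
    cfg: CohortConfig,
    separation: tuple[float, float] = (19.5, 20.5),
) -> tuple[list[SampleCallSet], TruthSet, list[CallLabel]]:
    """Cohort whose artefact and somatic z-scores are forced apart.

    ``separation`` is (artefact z ceiling, somatic z floor).  Emitted LODs
    are adjusted post hoc so that, per sample, every artefact z-score lies
    below the ceiling and every somatic (and germline) z-score above the
    floor; the guarantee is verified after adjustment.  Built for
    threshold-recovery experiments: an ROC sweep over a grid must select
    the integer boundary between ceiling and floor.
    """
    ceiling, floor = separation
    if ceiling >= floor:
        raise ValueError("separation ceiling must be below the floor")
    cohort, truth, all_labels = simulate_cohort(cfg)
    by_sample: dict[str, list[CallLabel]] = {}
    for lab in all_labels:
        by_sample.setdefault(lab.sample_id, []).append(lab)
    for i, callset in enumerate(cohort):
        rng = np.random.default_rng([cfg.seed, 2**21 + i])
        _adjust_sample_separation(
            callset, by_sample[callset.sample_id], ceiling, floor, rng
        )
    return cohort, truth, all_labels
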