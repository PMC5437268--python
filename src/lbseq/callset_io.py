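"""Data model and readers/writers for candidate-variant call tables.

The on-disk dialect is a tab-separated table modelled on the caller's
"call-stats" output, one row per candidate substitution, with header::

    sample_id  contig  position  ref_allele  alt_allele  t_ref_count
    t_alt_count  tumour_f  t_lod_fstar  judgement  pop_af  gene
    protein_change

Coordinates are 1-based inclusive (VCF / call-stats convention).  Lines
starting with ``#`` are comments.  ``pop_af`` is the maximum population
allele frequency over all annotation sources present on the row; an empty
field means no population annotation.  Substitutions only: rows whose
alleles are not single A/C/G/T bases are loaded into the ``flagged`` list
(with a reason) and excluded from analysis, as are rows whose reported
allele fraction disagrees with the read counts by more than half a read.
Nothing is silently dropped: rows_in = calls + flagged (+ raised parse
errors).

The truth-set table (bone-marrow comparator) is a TSV with columns
``patient_id contig position ref_allele alt_allele bm_af source``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "Judgement",
    "TruthSource",
    "GenomicLocus",
    "VariantCall",
    "FlaggedRow",
    "SampleCallSet",
    "TruthRecord",
    "TruthSet",
    "CallstatsFormatError",
    "CallstatsParseError",
    "TruthSetError",
    "read_callstats",
    "write_callstats",
    "read_truth",
    "write_truth",
    "CALLSTATS_COLUMNS",
    "TRUTH_COLUMNS",
]

_BASES = frozenset("ACGT")

CALLSTATS_COLUMNS = (
    "sample_id",
    "contig",
    "position",
    "ref_allele",
    "alt_allele",
    "t_ref_count",
    "t_alt_count",
    "tumour_f",
    "t_lod_fstar",
    "judgement",
    "pop_af",
    "gene",
    "protein_change",
)
_REQUIRED_COLUMNS = (
    "contig",
    "position",
    "ref_allele",
    "alt_allele",
    "t_ref_count",
    "t_alt_count",
    "tumour_f",
    "t_lod_fstar",
    "judgement",
)

TRUTH_COLUMNS = (
    "patient_id",
    "contig",
    "position",
    "ref_allele",
    "alt_allele",
    "bm_af",
    "source",
)


class CallstatsFormatError(ValueError):
    """Table-level format problem (e.g. a required column is missing)."""


class CallstatsParseError(ValueError):
    """Row-level parse problem; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str) -> None:
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class TruthSetError(ValueError):
    """Invalid truth-set table (duplicate key or out-of-range fraction)."""


class Judgement(str, Enum):
    KEEP = "KEEP"
    REJECT = "REJECT"


class TruthSource(str, Enum):
    clinical_panel = "clinical_panel"
    five_gene_panel = "five_gene_panel"
    commpass = "commpass"


@dataclass(frozen=True, order=True)
class GenomicLocus:
    """A single-base substitution site, 1-based inclusive coordinates."""

    contig: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for name in ("ref_allele", "alt_allele"):
            base = getattr(self, name)
            if base not in _BASES:
                raise ValueError(f"{name} must be one of A/C/G/T, got {base!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    def __str__(self) -> str:
        return f"{self.contig}:{self.position}{self.ref_allele}>{self.alt_allele}"


@dataclass
class VariantCall:
    """One candidate substitution with counts, fraction, LOD and annotations."""

    locus: GenomicLocus
    t_ref_count: int
    t_alt_count: int
    tumour_f: float
    t_lod: float
    judgement: Judgement
    pop_af: Optional[float] = None
    gene: Optional[str] = None
    protein_change: Optional[str] = None

    @property
    def depth(self) -> int:
        return self.t_ref_count + self.t_alt_count

    def counts_consistent(self, tol: float = 0.5) -> bool:
        """True if the stated fraction matches the counts within half a read."""
        return abs(self.tumour_f * self.depth - self.t_alt_count) <= tol


@dataclass(frozen=True)
class FlaggedRow:
    """A data row loaded but excluded from analysis, with the reason why."""

    line_number: int
    reason: str
    fields: dict


@dataclass
class SampleCallSet:
    """All candidate calls for one plasma sample plus sample metadata."""

    sample_id: str
    patient_id: str = ""
    batch_id: str = ""
    calls: list[VariantCall] = field(default_factory=list)
    input_mass_ng: Optional[float] = None
    flagged: list[FlaggedRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls)

    def keep_calls(self) -> list[VariantCall]:
        return [c for c in self.calls if c.judgement is Judgement.KEEP]


@dataclass(frozen=True)
class TruthRecord:
    patient_id: str
    locus: GenomicLocus
    bm_allele_fraction: float
    source: TruthSource = TruthSource.clinical_panel

    def __post_init__(self) -> None:
        if not (0.0 <= self.bm_allele_fraction <= 1.0):
            raise ValueError(
                f"bm_allele_fraction must be in [0, 1], got {self.bm_allele_fraction}"
            )


class TruthSet:
    """Per-patient bone-marrow mutation list keyed by (patient, locus)."""

    def __init__(self, records: Iterable[TruthRecord] = ()) -> None:
        self._records: dict[tuple[str, GenomicLocus], TruthRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: TruthRecord) -> None:
        key = (rec.patient_id, rec.locus)
        if key in self._records:
            raise TruthSetError(
                f"duplicate truth record for patient {rec.patient_id}, locus {rec.locus}"
            )
        self._records[key] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[TruthRecord]:
        return iter(self._records.values())

    def __contains__(self, key: tuple[str, GenomicLocus]) -> bool:
        return key in self._records

    @property
    def records(self) -> list[TruthRecord]:
        return list(self._records.values())

    def patients(self) -> set[str]:
        return {pid for pid, _ in self._records}

    def for_patient(self, patient_id: str) -> list[TruthRecord]:
        return [r for r in self._records.values() if r.patient_id == patient_id]


# ---------------------------------------------------------------------------
# call-stats I/O


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)  # shortest repr round-trips exactly
    if isinstance(value, Enum):
        return value.value
    return str(value)


def _parse_float(text: str, column: str, line_number: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise CallstatsParseError(
            line_number, f"non-numeric value {text!r} in column {column}"
        ) from None


def _parse_int(text: str, column: str, line_number: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise CallstatsParseError(
            line_number, f"non-numeric value {text!r} in column {column}"
        ) from None


def read_callstats(
    path: str | Path,
    sample_id: Optional[str] = None,
    patient_id: str = "",
    batch_id: str = "",
    input_mass_ng: Optional[float] = None,
) -> SampleCallSet:
    """Read one call-stats table into a :class:`SampleCallSet`.

    Rows failing the substitution-only or count/fraction-consistency
    invariants are loaded into ``flagged`` rather than dropped.  A missing
    required column raises :class:`CallstatsFormatError`; an unparseable
    numeric field raises :class:`CallstatsParseError` with the line number.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.readlines()

    header: Optional[list[str]] = None
    header_line = 0
    rows: list[tuple[int, list[str]]] = []
    for i, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if header is None:
            header = line.split("\t")
            header_line = i
        else:
            rows.append((i, line.split("\t")))

    if header is None:
        raise CallstatsFormatError(f"{path}: no header row found")
    missing = [c for c in _REQUIRED_COLUMNS if c not in header]
    if missing:
        raise CallstatsFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    col = {name: idx for idx, name in enumerate(header)}

    def get(fields: list[str], name: str) -> str:
        idx = col.get(name)
        if idx is None or idx >= len(fields):
            return ""
        return fields[idx]

    inferred_sample = sample_id
    calls: list[VariantCall] = []
    flagged: list[FlaggedRow] = []
    for line_number, fields in rows:
        raw = dict(zip(header, fields))
        if inferred_sample is None and get(fields, "sample_id"):
            inferred_sample = get(fields, "sample_id")

        ref = get(fields, "ref_allele").upper()
        alt = get(fields, "alt_allele").upper()
        t_ref = _parse_int(get(fields, "t_ref_count"), "t_ref_count", line_number)
        t_alt = _parse_int(get(fields, "t_alt_count"), "t_alt_count", line_number)
        tumour_f = _parse_float(get(fields, "tumour_f"), "tumour_f", line_number)
        t_lod = _parse_float(get(fields, "t_lod_fstar"), "t_lod_fstar", line_number)
        position = _parse_int(get(fields, "position"), "position", line_number)

        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            flagged.append(
                FlaggedRow(line_number, "non-substitution alleles", raw)
            )
            continue
        if ref == alt:
            flagged.append(FlaggedRow(line_number, "ref equals alt", raw))
            continue

        judgement_text = get(fields, "judgement")
        if judgement_text in Judgement.__members__:
            judgement = Judgement[judgement_text]
        else:
            warnings.warn(
                f"{path} line {line_number}: unknown judgement "
                f"{judgement_text!r}, treating as REJECT",
                stacklevel=2,
            )
            judgement = Judgement.REJECT

        pop_text = get(fields, "pop_af")
        pop_af = (
            _parse_float(pop_text, "pop_af", line_number) if pop_text else None
        )

        call = VariantCall(
            locus=GenomicLocus(get(fields, "contig"), position, ref, alt),
            t_ref_count=t_ref,
            t_alt_count=t_alt,
            tumour_f=tumour_f,
            t_lod=t_lod,
            judgement=judgement,
            pop_af=pop_af,
            gene=get(fields, "gene") or None,
            protein_change=get(fields, "protein_change") or None,
        )
        if not call.counts_consistent():
            flagged.append(
                FlaggedRow(line_number, "allele fraction inconsistent with counts", raw)
            )
            continue
        calls.append(call)

    if inferred_sample is None:
        inferred_sample = path.stem
    return SampleCallSet(
        sample_id=inferred_sample,
        patient_id=patient_id,
        batch_id=batch_id,
        calls=calls,
        input_mass_ng=input_mass_ng,
        flagged=flagged,
    )


def write_callstats(callset: SampleCallSet, path: str | Path) -> None:
    """Write a callset as a call-stats TSV re-readable by :func:`read_callstats`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(CALLSTATS_COLUMNS) + "\n")
        for c in callset.calls:
            row = (
                callset.sample_id,
                c.locus.contig,
                c.locus.position,
                c.locus.ref_allele,
                c.locus.alt_allele,
                c.t_ref_count,
                c.t_alt_count,
                c.tumour_f,
                c.t_lod,
                c.judgement,
                c.pop_af,
                c.gene,
                c.protein_change,
            )
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# truth-set I/O


def read_truth(path: str | Path) -> TruthSet:
    """Read a bone-marrow truth TSV; duplicate (patient, locus) rows are errors."""
    path = Path(path)
    with path.open() as fh:
        lines = [
            ln.rstrip("\n")
            for ln in fh
            if ln.strip() and not ln.startswith("#")
        ]
    if not lines:
        raise TruthSetError(f"{path}: empty truth table")
    header = lines[0].split("\t")
    missing = [c for c in TRUTH_COLUMNS[:-1] if c not in header]
    if missing:
        raise TruthSetError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    col = {name: idx for idx, name in enumerate(header)}

    truth = TruthSet()
    for line_number, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")

        def get(name: str, default: str = "") -> str:
            idx = col.get(name)
            if idx is None or idx >= len(fields):
                return default
            return fields[idx]

        bm_af = float(get("bm_af"))
        if not (0.0 <= bm_af <= 1.0):
            raise TruthSetError(
                f"{path} line {line_number}: bm_af {bm_af} outside [0, 1]"
            )
        source_text = get("source") or TruthSource.clinical_panel.value
        try:
            source = TruthSource(source_text)
        except ValueError:
            raise TruthSetError(
                f"{path} line {line_number}: unknown source {source_text!r}"
            ) from None
        rec = TruthRecord(
            patient_id=get("patient_id"),
            locus=GenomicLocus(
                get("contig"),
                int(get("position")),
                get("ref_allele").upper(),
                get("alt_allele").upper(),
            ),
            bm_allele_fraction=bm_af,
            source=source,
        )
        truth.add(rec)  # raises TruthSetError on duplicates
    return truth


def write_truth(truth: TruthSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in truth:
            row = (
                r.patient_id,
                r.locus.contig,
                r.locus.position,
                r.locus.ref_allele,
                r.locus.alt_allele,
                r.bm_allele_fraction,
                r.source,
            )
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
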