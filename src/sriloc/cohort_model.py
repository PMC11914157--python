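"""Domain types, validation and CSV I/O for per-lesion cohort tables.

All dates are integer day offsets from each lesion's baseline planning-MRI
day (day 0).  Calendar parsing, if any, happens outside this package; keeping
the math on integer offsets removes timezone and format ambiguity from every
downstream stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence


class CohortValidationError(ValueError):
    """Raised when a record or table violates the cohort schema."""


class Modality(str, Enum):
    SRS = "SRS"
    FSRT = "FSRT"
    WBRT = "WBRT"


class CorrectionGroup(str, Enum):
    CORRECTED_2D = "CORRECTED_2D"
    UNCORRECTED_ND = "UNCORRECTED_ND"
    CORRECTED_3D = "CORRECTED_3D"
    UNKNOWN = "UNKNOWN"


class ResectionHistology(str, Enum):
    TUMOR = "TUMOR"
    NECROSIS = "NECROSIS"


#: Histology vocabulary (nine classes, "other" as catch-all).
HISTOLOGIES = (
    "melanoma",
    "lung",
    "breast",
    "renal",
    "gastrointestinal",
    "bladder",
    "sarcoma",
    "gynecologic",
    "other",
)

#: Primaries conventionally considered radioresistant.
RADIORESISTANT_HISTOLOGIES = frozenset({"melanoma", "renal", "sarcoma"})

#: Default DICOM ImageType tokens marking the distortion-correction state.
#: Vendors write the correction mode into ImageType (tag 0008,0008);
#: "ND" = not distortion corrected, "DIS2D"/"DIS3D" = 2-D/3-D corrected.
DIS2D_TOKENS = frozenset({"DIS2D"})
DIS3D_TOKENS = frozenset({"DIS3D"})
ND_TOKENS = frozenset({"ND"})


@dataclass(frozen=True)
class TreatmentPlan:
    """One radiotherapy course: ``n_fractions`` fractions of ``dose_per_fraction`` Gy."""

    modality: Modality
    n_fractions: int
    dose_per_fraction: float
    start_day: int

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise CohortValidationError(f"n_fractions must be >= 1, got {self.n_fractions}")
        if not (0.0 < self.dose_per_fraction <= 30.0):
            raise CohortValidationError(
                f"dose_per_fraction must be in (0, 30] Gy, got {self.dose_per_fraction}"
            )
        if self.modality is Modality.SRS and self.n_fractions != 1:
            raise CohortValidationError("SRS is single-session: n_fractions must be 1")

    @property
    def total_dose(self) -> float:
        return self.n_fractions * self.dose_per_fraction


@dataclass(frozen=True)
class LesionRecord:
    """One treated brain metastasis with covariates, plans and key dates."""

    lesion_id: str
    patient_id: str
    correction_group: CorrectionGroup
    histology: str
    baseline_volume_cm3: float
    mri_to_treatment_days: int
    planning_mri_year: int
    plans: tuple[TreatmentPlan, ...]
    last_followup_day: int
    death_day: int | None = None
    resected_with_histology: ResectionHistology | None = None

    def __post_init__(self) -> None:
        if self.histology not in HISTOLOGIES:
            raise CohortValidationError(
                f"{self.lesion_id}: unknown histology {self.histology!r}"
            )
        if self.baseline_volume_cm3 <= 0:
            raise CohortValidationError(f"{self.lesion_id}: baseline volume must be > 0")
        if self.mri_to_treatment_days < 0:
            raise CohortValidationError(f"{self.lesion_id}: mri_to_treatment_days < 0")
        if self.last_followup_day < 0:
            raise CohortValidationError(f"{self.lesion_id}: last_followup_day < 0")
        srt = [p for p in self.plans if p.modality in (Modality.SRS, Modality.FSRT)]
        if len(srt) != 1:
            raise CohortValidationError(
                f"{self.lesion_id}: exactly one SRS/FSRT plan required, found {len(srt)}"
            )

    @property
    def srt_plan(self) -> TreatmentPlan:
        return next(p for p in self.plans if p.modality in (Modality.SRS, Modality.FSRT))

    @property
    def wbrt_plan(self) -> TreatmentPlan | None:
        return next((p for p in self.plans if p.modality is Modality.WBRT), None)


@dataclass(frozen=True)
class VolumeTimeSeries:
    """Ordered (day, volume) measurements for one lesion; day 0 is the baseline MRI."""

    lesion_id: str
    days: tuple[int, ...]
    volumes_cm3: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.volumes_cm3):
            raise CohortValidationError(f"{self.lesion_id}: days/volumes length mismatch")
        if len(self.days) < 1:
            raise CohortValidationError(f"{self.lesion_id}: empty volume series")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise CohortValidationError(
                f"{self.lesion_id}: measurement days must be strictly increasing"
            )
        if any(v <= 0 for v in self.volumes_cm3):
            raise CohortValidationError(f"{self.lesion_id}: all volumes must be > 0")


class EventCode(int, Enum):
    CENSORED = 0
    LOCAL_PROGRESSION = 1
    DEATH = 2


@dataclass(frozen=True)
class EventRecord:
    """Classifier output for one lesion: time-to-event from radiotherapy start."""

    lesion_id: str
    time_days: int
    event: EventCode
    progression_day: int | None = None
    pseudo_progression_days: tuple[int, ...] = ()
    reference_volume_at_call: float | None = None
    confirmed_on_last_scan: bool = False

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise CohortValidationError(
                f"{self.lesion_id}: non-positive time-to-event ({self.time_days})"
            )
        if self.event is EventCode.LOCAL_PROGRESSION and self.progression_day is None:
            raise CohortValidationError(
                f"{self.lesion_id}: progression event without progression_day"
            )


# ---------------------------------------------------------------------------
# operations


def radiotherapy_start_day(record: LesionRecord) -> int:
    """Day radiotherapy started for this lesion.

    When upfront whole-brain radiotherapy was delivered (WBRT starting on or
    before the stereotactic course), WBRT is an integral part of the treatment
    and its start date defines the start of radiotherapy.  Salvage WBRT given
    after the stereotactic course does not move the clock.
    """
    srt = record.srt_plan
    wbrt = record.wbrt_plan
    if wbrt is not None and wbrt.start_day <= srt.start_day:
        return wbrt.start_day
    return srt.start_day


def is_radioresistant(histology: str) -> bool:
    """True for melanoma, renal cell carcinoma and sarcoma primaries."""
    if histology not in HISTOLOGIES:
        raise CohortValidationError(f"unknown histology {histology!r}")
    return histology in RADIORESISTANT_HISTOLOGIES


def classify_distortion_correction(
    image_type_tokens: Sequence[str],
    *,
    dis2d_tokens: frozenset[str] = DIS2D_TOKENS,
    dis3d_tokens: frozenset[str] = DIS3D_TOKENS,
    nd_tokens: frozenset[str] = ND_TOKENS,
) -> CorrectionGroup:
    """Classify a series' distortion-correction state from its ImageType tokens.

    The multi-valued DICOM ImageType attribute carries the vendor's
    post-processing labels.  Any ``DIS2D`` token wins over ``ND``; an ``ND``
    token with no correction token means uncorrected; anything else (including
    an empty list) is unknown.
    """
    tokens = set(image_type_tokens)
    if tokens & dis2d_tokens:
        return CorrectionGroup.CORRECTED_2D
    if tokens & dis3d_tokens:
        return CorrectionGroup.CORRECTED_3D
    if tokens & nd_tokens:
        return CorrectionGroup.UNCORRECTED_ND
    return CorrectionGroup.UNKNOWN


# ---------------------------------------------------------------------------
# CSV I/O

LESION_COLUMNS = [
    "lesion_id",
    "patient_id",
    "correction_group",
    "histology",
    "baseline_volume_cm3",
    "mri_to_treatment_days",
    "planning_mri_year",
    "srt_modality",
    "srt_fractions",
    "srt_dose_per_fraction_gy",
    "srt_start_day",
    "wbrt_fractions",
    "wbrt_dose_per_fraction_gy",
    "wbrt_start_day",
    "death_day",
    "last_followup_day",
    "resected_with_histology",
]

VOLUME_COLUMNS = ["lesion_id", "day", "volume_cm3"]

EVENT_COLUMNS = [
    "lesion_id",
    "time_days",
    "event",
    "progression_day",
    "pseudo_progression_days",
]


def _fmt(x: float) -> str:
    # shortest representation that round-trips float64 exactly
    return repr(float(x))


def write_cohort(
    records: Iterable[LesionRecord],
    series: Iterable[VolumeTimeSeries],
    lesions_csv: str | Path,
    volumes_csv: str | Path,
) -> None:
    with open(lesions_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(LESION_COLUMNS)
        for r in records:
            srt, wbrt = r.srt_plan, r.wbrt_plan
            w.writerow(
                [
                    r.lesion_id,
                    r.patient_id,
                    r.correction_group.value,
                    r.histology,
                    _fmt(r.baseline_volume_cm3),
                    r.mri_to_treatment_days,
                    r.planning_mri_year,
                    srt.modality.value,
                    srt.n_fractions,
                    _fmt(srt.dose_per_fraction),
                    srt.start_day,
                    wbrt.n_fractions if wbrt else "",
                    _fmt(wbrt.dose_per_fraction) if wbrt else "",
                    wbrt.start_day if wbrt else "",
                    r.death_day if r.death_day is not None else "",
                    r.last_followup_day,
                    r.resected_with_histology.value if r.resected_with_histology else "",
                ]
            )
    with open(volumes_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(VOLUME_COLUMNS)
        for s in series:
            for d, v in zip(s.days, s.volumes_cm3):
                w.writerow([s.lesion_id, d, _fmt(v)])


def _parse_lesion_row(row: dict[str, str], line_no: int) -> LesionRecord:
    lesion_id = row.get("lesion_id", f"<row {line_no}>")
    try:
        plans = [
            TreatmentPlan(
                modality=Modality(row["srt_modality"]),
                n_fractions=int(row["srt_fractions"]),
                dose_per_fraction=float(row["srt_dose_per_fraction_gy"]),
                start_day=int(row["srt_start_day"]),
            )
        ]
        if row.get("wbrt_fractions", "").strip():
            plans.append(
                TreatmentPlan(
                    modality=Modality.WBRT,
                    n_fractions=int(row["wbrt_fractions"]),
                    dose_per_fraction=float(row["wbrt_dose_per_fraction_gy"]),
                    start_day=int(row["wbrt_start_day"]),
                )
            )
        resected = row.get("resected_with_histology", "").strip()
        return LesionRecord(
            lesion_id=row["lesion_id"],
            patient_id=row["patient_id"],
            correction_group=CorrectionGroup(row["correction_group"]),
            histology=row["histology"],
            baseline_volume_cm3=float(row["baseline_volume_cm3"]),
            mri_to_treatment_days=int(row["mri_to_treatment_days"]),
            planning_mri_year=int(row["planning_mri_year"]),
            plans=tuple(plans),
            death_day=int(row["death_day"]) if row.get("death_day", "").strip() else None,
            last_followup_day=int(row["last_followup_day"]),
            resected_with_histology=ResectionHistology(resected) if resected else None,
        )
    except (KeyError, ValueError) as exc:
        if isinstance(exc, CohortValidationError):
            raise
        raise CohortValidationError(
            f"lesions.csv row {line_no} (lesion {lesion_id}): {exc}"
        ) from exc


def read_cohort(
    lesions_csv: str | Path,
    volumes_csv: str | Path,
    *,
    allow_single_scan: bool = False,
) -> tuple[list[LesionRecord], list[VolumeTimeSeries]]:
    """Read and validate a lesion table plus long-format volume measurements.

    ``allow_single_scan`` admits lesions whose only measurement is the
    baseline MRI (lost to imaging follow-up immediately); by default such
    series are rejected because no response assessment is possible.
    """
    records: list[LesionRecord] = []
    with open(lesions_csv, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            records.append(_parse_lesion_row(row, i))
    ids = [r.lesion_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({x for x in ids if ids.count(x) > 1})
        raise CohortValidationError(f"duplicate lesion_id(s) in lesions.csv: {dup}")

    per_lesion: dict[str, list[tuple[int, float]]] = {}
    with open(volumes_csv, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                lid = row["lesion_id"]
                day = int(row["day"])
                vol = float(row["volume_cm3"])
            except (KeyError, ValueError) as exc:
                raise CohortValidationError(f"volumes.csv row {i}: {exc}") from exc
            if vol <= 0:
                raise CohortValidationError(
                    f"volumes.csv row {i} (lesion {lid}): volume must be > 0, got {vol}"
                )
            per_lesion.setdefault(lid, []).append((day, vol))

    series: list[VolumeTimeSeries] = []
    for r in records:
        meas = per_lesion.get(r.lesion_id)
        if meas is None:
            raise CohortValidationError(f"lesion {r.lesion_id} has no volume measurements")
        meas.sort(key=lambda t: t[0])
        days = [d for d, _ in meas]
        if len(set(days)) != len(days):
            dup_day = next(d for i, d in enumerate(days) if d in days[:i])
            raise CohortValidationError(
                f"lesion {r.lesion_id}: duplicate measurement day {dup_day}"
            )
        if len(days) < 2 and not allow_single_scan:
            raise CohortValidationError(
                f"lesion {r.lesion_id}: only the baseline scan is present; "
                "pass allow_single_scan=True to censor such lesions at baseline"
            )
        series.append(
            VolumeTimeSeries(r.lesion_id, tuple(days), tuple(v for _, v in meas))
        )
    return records, series


def write_events(events: Iterable[EventRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_COLUMNS)
        for e in events:
            w.writerow(
                [
                    e.lesion_id,
                    e.time_days,
                    int(e.event),
                    e.progression_day if e.progression_day is not None else "",
                    ";".join(str(d) for d in e.pseudo_progression_days),
                ]
            )


def read_events(path: str | Path) -> list[EventRecord]:
    out: list[EventRecord] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                pp = row.get("pseudo_progression_days", "").strip()
                out.append(
                    EventRecord(
                        lesion_id=row["lesion_id"],
                        time_days=int(row["time_days"]),
                        event=EventCode(int(row["event"])),
                        progression_day=int(row["progression_day"])
                        if row.get("progression_day", "").strip()
                        else None,
                        pseudo_progression_days=tuple(
                            int(x) for x in pp.split(";") if x
                        ),
                    )
                )
            except (KeyError, ValueError) as exc:
                if isinstance(exc, CohortValidationError):
                    raise
                raise CohortValidationError(f"events.csv row {i}: {exc}") from exc
    return out
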