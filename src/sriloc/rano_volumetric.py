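"""Volumetric response assessment of treated brain metastases.

Implements a volumetric extension of the RANO-BM criteria.  Local progression
requires BOTH a relative volume increase of at least 72.8% over the running
nadir (baseline included) — the cube of the unidimensional 20% diameter
criterion for a sphere — AND an absolute increase of at least 0.2 cm^3, the
volume gained by a 5 mm sphere growing 3 mm in diameter.  A progression
candidate that later regresses spontaneously (back to the reference volume at
the call, or by a volumetric partial response of >= 65% from the candidate
peak) without intervening salvage therapy is labelled pseudo-progression and
produces no event.  Lesions resected for enlargement are classified by the
surgical histology: viable tumor confirms progression, pure necrosis refutes
it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .cohort_model import (
    CohortValidationError,
    EventCode,
    EventRecord,
    LesionRecord,
    ResectionHistology,
    VolumeTimeSeries,
    radiotherapy_start_day,
)


@dataclass(frozen=True)
class RanoThresholds:
    """Decision thresholds of the volumetric progression rule.

    relative_increase
        Minimum fractional volume increase over the reference (default 0.728,
        the volume equivalent of a 20% diameter increase of a sphere).
    absolute_increase_cm3
        Minimum absolute increase in cm^3 (default 0.2), applied to every
        call so that measurement noise on tiny lesions cannot trigger one.
    partial_response_fraction
        Fractional volume reduction from the candidate peak that counts as a
        volumetric partial response (default 0.65, the volume equivalent of
        RANO-BM's 30% diameter decrease).
    """

    relative_increase: float = 0.728
    absolute_increase_cm3: float = 0.2
    partial_response_fraction: float = 0.65

    def __post_init__(self) -> None:
        if min(self.relative_increase, self.absolute_increase_cm3) <= 0:
            raise ValueError("progression thresholds must be strictly positive")
        if not (0 < self.partial_response_fraction < 1):
            raise ValueError("partial_response_fraction must be in (0, 1)")


def relative_threshold_from_diameter(diameter_increase_fraction: float) -> float:
    """Volume-change fraction equivalent to a diameter-change fraction of a sphere.

    ``(1 + f)**3 - 1``: a 20% diameter increase maps to a 72.8% volume
    increase; a 30% diameter decrease maps to a 65.7% volume decrease.
    """
    if diameter_increase_fraction <= -1:
        raise ValueError("diameter change fraction must exceed -1")
    return (1.0 + diameter_increase_fraction) ** 3 - 1.0


def absolute_threshold_from_spheres(d0_mm: float, growth_mm: float) -> float:
    """Volume gained (cm^3) by a sphere of diameter ``d0_mm`` growing ``growth_mm``.

    A 5 mm sphere growing 3 mm gains 0.2026 cm^3, the origin of the 0.2 cm^3
    absolute floor.
    """
    from math import pi

    if d0_mm <= 0 or growth_mm < 0:
        raise ValueError("require d0_mm > 0 and growth_mm >= 0")
    d1 = d0_mm + growth_mm
    return (pi / 6.0) * (d1**3 - d0_mm**3) / 1000.0


@dataclass(frozen=True)
class VisitAudit:
    """Per-visit trace of the classifier walk (for the audit CSV)."""

    lesion_id: str
    day: int
    volume_cm3: float
    reference_cm3: float
    ratio: float
    decision: str  # "no-call" | "candidate" | "pseudo" | "progression"


def classify_lesion(
    series: VolumeTimeSeries,
    record: LesionRecord,
    thresholds: RanoThresholds = RanoThresholds(),
    *,
    salvage_day: int | None = None,
    audit: list[VisitAudit] | None = None,
) -> EventRecord:
    """Classify one lesion's volume trajectory into an event record.

    Walks the scans in order keeping the running nadir (baseline included) as
    reference.  A scan meeting both thresholds is a progression candidate; it
    is adjudicated against all later scans — spontaneous regression (return to
    the reference at call, or >= 65% reduction from the candidate peak, with
    no salvage therapy on or before the regressing scan's day) demotes it to
    pseudo-progression, otherwise it is confirmed at the candidate scan's day.
    A candidate on the final scan is confirmed (regression cannot be
    demonstrated) and flagged ``confirmed_on_last_scan``.  Without a confirmed
    progression the lesion ends in death (if a death day is recorded) or is
    censored at the last follow-up day.  Times count from the radiotherapy
    start day.
    """
    rt0 = radiotherapy_start_day(record)
    days, vols = series.days, series.volumes_cm3
    if days[-1] < rt0:
        raise CohortValidationError(
            f"{series.lesion_id}: all scans precede radiotherapy start (day {rt0})"
        )

    resected = record.resected_with_histology
    pseudo_days: list[int] = []
    progression_day: int | None = None
    ref_at_call: float | None = None
    on_last_scan = False

    reference = vols[0]
    for i in range(1, len(days)):
        v, day = vols[i], days[i]
        ratio = v / reference
        is_candidate = (
            v >= reference * (1.0 + thresholds.relative_increase)
            and v - reference >= thresholds.absolute_increase_cm3
        )
        decision = "no-call"
        if is_candidate:
            if resected is ResectionHistology.NECROSIS:
                # surgical specimen showed pure necrosis: never a true event
                decision = "pseudo"
                pseudo_days.append(day)
            elif resected is ResectionHistology.TUMOR:
                decision = "progression"
                progression_day, ref_at_call = day, reference
            else:
                regressed = False
                for j in range(i + 1, len(days)):
                    if salvage_day is not None and days[j] > salvage_day:
                        break  # later shrinkage may be treatment effect, not spontaneous
                    if (
                        vols[j] <= reference
                        or vols[j] <= (1.0 - thresholds.partial_response_fraction) * v
                    ):
                        regressed = True
                        break
                if regressed:
                    decision = "pseudo"
                    pseudo_days.append(day)
                else:
                    decision = "progression"
                    progression_day, ref_at_call = day, reference
                    on_last_scan = i == len(days) - 1
        if audit is not None:
            audit.append(VisitAudit(series.lesion_id, day, v, reference, ratio, decision))
        if progression_day is not None:
            break
        reference = min(reference, v)

    if resected is ResectionHistology.TUMOR and progression_day is None:
        # enlarging lesion went to surgery without meeting the volumetric
        # thresholds on file; classify at the last available scan
        progression_day, ref_at_call = days[-1], reference

    if progression_day is not None:
        time = progression_day - rt0
        if time <= 0:
            raise CohortValidationError(
                f"{series.lesion_id}: progression at day {progression_day} is not "
                f"after radiotherapy start (day {rt0})"
            )
        return EventRecord(
            lesion_id=series.lesion_id,
            time_days=time,
            event=EventCode.LOCAL_PROGRESSION,
            progression_day=progression_day,
            pseudo_progression_days=tuple(pseudo_days),
            reference_volume_at_call=ref_at_call,
            confirmed_on_last_scan=on_last_scan,
        )

    if record.death_day is not None:
        end_day, code = record.death_day, EventCode.DEATH
    else:
        end_day, code = record.last_followup_day, EventCode.CENSORED
    time = end_day - rt0
    if time <= 0:
        raise CohortValidationError(
            f"{series.lesion_id}: follow-up ends on/before radiotherapy start"
        )
    return EventRecord(
        lesion_id=series.lesion_id,
        time_days=time,
        event=code,
        pseudo_progression_days=tuple(pseudo_days),
    )


def classify_cohort(
    records: Sequence[LesionRecord],
    series: Iterable[VolumeTimeSeries],
    thresholds: RanoThresholds = RanoThresholds(),
    *,
    salvage_days: dict[str, int] | None = None,
    audit: list[VisitAudit] | None = None,
) -> list[EventRecord]:
    """Classify every lesion, matching series to records by lesion_id."""
    by_id = {r.lesion_id: r for r in records}
    out: list[EventRecord] = []
    for s in series:
        rec = by_id.get(s.lesion_id)
        if rec is None:
            raise CohortValidationError(f"series {s.lesion_id} has no lesion record")
        out.append(
            classify_lesion(
                s,
                rec,
                thresholds,
                salvage_day=(salvage_days or {}).get(s.lesion_id),
                audit=audit,
            )
        )
    return out
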