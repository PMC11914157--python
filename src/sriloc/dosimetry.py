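"""Biologically effective dose (BED) under the LQC and LQ fractionation models.

The working model is the linear-quadratic-cubic (LQC) BED with alpha/beta =
12 Gy and alpha/gamma = 648 Gy^2, appropriate for the large fraction doses of
radiosurgery:

    BED = n * d * (1 + d/(alpha/beta) - d^2/(alpha/gamma))

A plain linear-quadratic sensitivity model is also provided (alpha/beta =
20 Gy for the stereotactic course, 10 Gy for whole-brain radiotherapy).  When
upfront WBRT was part of the treatment, BEDs are computed separately per
course and summed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort_model import LesionRecord, Modality, TreatmentPlan


class BedModelError(ValueError):
    """Raised when a plan falls outside a model's validity range."""


@dataclass(frozen=True)
class BedModel:
    """A fractionation-correction model.

    ``alpha_gamma`` (Gy^2) enables the cubic term; ``None`` selects the plain
    LQ model.  ``alpha_beta_*`` are per-modality alpha/beta ratios in Gy.
    """

    name: str
    alpha_beta_srt: float
    alpha_beta_wbrt: float
    alpha_gamma: float | None = None

    @staticmethod
    def lqc12() -> "BedModel":
        """LQC with alpha/beta 12 Gy and alpha/gamma 648 Gy^2 (both courses)."""
        return BedModel("LQC_12", alpha_beta_srt=12.0, alpha_beta_wbrt=12.0, alpha_gamma=648.0)

    @staticmethod
    def lq_sensitivity() -> "BedModel":
        """LQ sensitivity model: alpha/beta 20 Gy for SRT, 10 Gy for WBRT."""
        return BedModel("LQ_SENSITIVITY", alpha_beta_srt=20.0, alpha_beta_wbrt=10.0)

    def alpha_beta(self, modality: Modality) -> float:
        return self.alpha_beta_wbrt if modality is Modality.WBRT else self.alpha_beta_srt


def bed(plan: TreatmentPlan, model: BedModel) -> float:
    """BED in Gy of one course under ``model``.

    Raises :class:`BedModelError` when the cubic bracket becomes non-positive,
    i.e. the dose per fraction lies outside the LQC model's validity range.
    """
    n, d = plan.n_fractions, plan.dose_per_fraction
    ab = model.alpha_beta(plan.modality)
    bracket = 1.0 + d / ab
    if model.alpha_gamma is not None:
        bracket -= d * d / model.alpha_gamma
        if bracket <= 0.0:
            raise BedModelError(
                f"dose per fraction {d} Gy outside LQC validity "
                f"(bracket {bracket:.4g} <= 0)"
            )
    return n * d * bracket


def total_bed(record: LesionRecord, model: BedModel) -> float:
    """Total BED: stereotactic course plus upfront WBRT, if any.

    WBRT counts only when delivered upfront (start on or before the SRT
    start); salvage WBRT is not part of the evaluated treatment.
    """
    srt = record.srt_plan
    total = bed(srt, model)
    wbrt = record.wbrt_plan
    if wbrt is not None and wbrt.start_day <= srt.start_day:
        total += bed(wbrt, model)
    return total
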