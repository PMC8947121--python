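"""Streamline-to-axon calibration on the corpus callosum.

The corpus callosum is the one tract where an absolute axon count is
unambiguous: essentially all interhemispheric corticocortical axons pass
through it, its cross-section is well defined, and histology provides its
axon packing density. For each subject

    callosal axons      N_cc = A_cc * rho          (area x density)
    conversion ratio    c    = N_cc / sum(S_inter)

where ``sum(S_inter)`` is the subject's total interhemispheric streamline
count (each unordered left-right parcel pair counted once). The cohort ratio
is the arithmetic mean of the per-subject quotients. Because c rescales with
1/S, downstream axon counts ``c * S`` are invariant to the arbitrary overall
scale of the tractography metric — only proportionality between streamlines
and axons is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    HistologyParams,
    ParcelTable,
    SubjectRecord,
    pair_class_masks,
    pair_indices,
    validate_connectivity_matrix,
)


@dataclass
class CalibrationResult:
    """Per-subject and cohort-level streamline-to-axon conversion factors."""

    per_subject_ratio: list[tuple[str, float]]
    cohort_ratio: float  # mean of per-subject quotients (primary estimate)
    ratio_of_means: float  # mean callosal axons / mean streamline sum (diagnostic)
    per_subject_callosal_axons: list[tuple[str, float]]
    cohort_mean_callosal_axons: float
    cohort_mean_interhemispheric_streamlines: float

    def to_dict(self) -> dict:
        return {
            "cohort_ratio": self.cohort_ratio,
            "ratio_of_means": self.ratio_of_means,
            "cohort_mean_callosal_axons": self.cohort_mean_callosal_axons,
            "cohort_mean_interhemispheric_streamlines":
                self.cohort_mean_interhemispheric_streamlines,
            "per_subject": [
                {"subject_id": sid, "ratio": r, "callosal_axons": ax}
                for (sid, r), (_, ax) in zip(
                    self.per_subject_ratio, self.per_subject_callosal_axons
                )
            ],
        }


def callosal_axon_count(callosal_area: float, params: HistologyParams) -> float:
    """Number of axons traversing a callosum of the given cross-section.

    ``area (mm^2) x callosal packing density (axons/mm^2)``.
    """
    if not callosal_area > 0:
        raise ValueError(f"callosal_area must be > 0, got {callosal_area}")
    return callosal_area * params.callosal_density


def interhemispheric_streamline_sum(m: np.ndarray, parcels: ParcelTable) -> float:
    """Total streamlines over unordered left-right parcel pairs.

    For 180 parcels per hemisphere this sums the 180^2 cross-hemisphere pairs,
    each counted once (matrices are undirected).
    """
    m = validate_connectivity_matrix(m, n_parcels=parcels.n_parcels)
    iu = pair_indices(parcels.n_parcels)
    inter = pair_class_masks(parcels)["inter"]
    return float(m[iu][inter].sum())


def calibrate(
    cohort: list[SubjectRecord],
    parcels: ParcelTable,
    params: HistologyParams | None = None,
) -> CalibrationResult:
    """Calibrate the axons-per-streamline ratio on a cohort.

    The primary cohort estimate is the mean of per-subject quotients
    ``(A_cc * rho) / sum(S_inter)``; the ratio of cohort means is reported
    alongside as a diagnostic (the two differ when areas and streamline sums
    covary across subjects).
    """
    params = params or HistologyParams()
    if not cohort:
        raise ValueError("cohort must be nonempty")
    ratios: list[tuple[str, float]] = []
    axons: list[tuple[str, float]] = []
    inter_sums: list[float] = []
    degenerate: list[str] = []
    for sub in cohort:
        s_inter = interhemispheric_streamline_sum(sub.streamlines, parcels)
        if s_inter <= 0:
            degenerate.append(sub.subject_id)
            continue
        n_cc = callosal_axon_count(sub.callosal_area, params)
        ratios.append((sub.subject_id, n_cc / s_inter))
        axons.append((sub.subject_id, n_cc))
        inter_sums.append(s_inter)
    if degenerate:
        raise ValueError(
            "subject(s) with zero interhemispheric streamlines: "
            + ", ".join(degenerate)
        )
    mean_axons = float(np.mean([a for _, a in axons]))
    mean_inter = float(np.mean(inter_sums))
    return CalibrationResult(
        per_subject_ratio=ratios,
        cohort_ratio=float(np.mean([r for _, r in ratios])),
        ratio_of_means=mean_axons / mean_inter,
        per_subject_callosal_axons=axons,
        cohort_mean_callosal_axons=mean_axons,
        cohort_mean_interhemispheric_streamlines=mean_inter,
    )
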