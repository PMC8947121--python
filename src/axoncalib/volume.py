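"""White-matter volume and white-gray interface accounting.

The effective cross-sectional area of one axon is the reciprocal of the
callosal packing density (it therefore includes myelin, supporting cells and
extracellular space). Interareal axons then occupy

    V = sum_pairs N_ij * L_ij * a        (axons x length x area/axon)

of hemispheric white matter, and claim ``total_axons * a`` of the white-gray
interface. Both are compared against user-supplied anatomical references —
reference volumes/areas are inputs, never computed from images here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    DEFAULT_TOTAL_NEURONS,
    DEFAULT_WHITE_GRAY_AREA,
    HistologyParams,
    ParcelTable,
    pair_indices,
)


@dataclass
class VolumeBudget:
    per_axon_area: float  # mm^2/axon
    occupied_volume: float  # mm^3
    occupied_fraction: float | None  # vs total_wm_volume_reference
    total_wm_volume_reference: float | None
    interface_area: float  # mm^2
    interface_fraction: float
    white_gray_area_reference: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "per_axon_area", "occupied_volume", "occupied_fraction",
            "total_wm_volume_reference", "interface_area",
            "interface_fraction", "white_gray_area_reference",
        )}


def effective_axon_area(params: HistologyParams) -> float:
    """Effective per-axon cross-sectional area, mm^2/axon (1/callosal density)."""
    return 1.0 / params.callosal_density


def occupied_wm_volume(
    n: np.ndarray,
    lengths: np.ndarray,
    per_axon_area: float,
    reference_volume: float | None = None,
) -> tuple[float, float | None]:
    """White-matter volume occupied by interareal axons, mm^3.

    Sum over unordered pairs of ``N_ij * L_ij * per_axon_area``. Pairs with
    axons but no length are an input error and are listed.
    """
    n = np.asarray(n, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if n.shape != lengths.shape:
        raise ValueError(
            f"axon matrix {n.shape} and length matrix {lengths.shape} differ"
        )
    iu = pair_indices(n.shape[0])
    nv, lv = n[iu], lengths[iu]
    missing = (nv > 0) & ~(lv > 0)
    if missing.any():
        bad = [(int(iu[0][k]), int(iu[1][k])) for k in np.flatnonzero(missing)[:10]]
        raise ValueError(
            f"pairs with axons but no fiber length: {bad}"
            + (" ..." if missing.sum() > 10 else "")
        )
    volume = float((nv * lv).sum() * per_axon_area)
    fraction = volume / reference_volume if reference_volume else None
    return volume, fraction


def interface_area(
    total_axons: float,
    per_axon_area: float,
    white_gray_area_reference: float = DEFAULT_WHITE_GRAY_AREA,
) -> tuple[float, float]:
    """Cortical interface area claimed by interareal axons, mm^2, and its
    fraction of the white-gray interface reference."""
    if total_axons < 0 or per_axon_area <= 0 or white_gray_area_reference <= 0:
        raise ValueError("inputs must be nonnegative (areas strictly positive)")
    area = total_axons * per_axon_area
    return area, area / white_gray_area_reference


def subcortical_budget(
    projecting_neurons: float,
    mean_path_length: float,
    per_axon_area: float,
    wm_volume_reference: float,
) -> float:
    """Fraction of reference WM volume that a subcortical projection system
    would occupy (one axon per projecting neuron, common mean path length)."""
    if projecting_neurons < 0:
        raise ValueError("projecting_neurons must be >= 0")
    if mean_path_length < 0 or per_axon_area <= 0 or wm_volume_reference <= 0:
        raise ValueError("lengths/areas/volumes must be positive")
    return projecting_neurons * mean_path_length * per_axon_area / wm_volume_reference


def neural_density(
    total_neurons: float = DEFAULT_TOTAL_NEURONS,
    white_gray_area: float = DEFAULT_WHITE_GRAY_AREA,
) -> float:
    """Mean cortical neurons per mm^2 of white-gray interface."""
    if total_neurons <= 0 or white_gray_area <= 0:
        raise ValueError("inputs must be strictly positive")
    return total_neurons / white_gray_area


def wm_volume_budget(
    n: np.ndarray,
    lengths: np.ndarray,
    params: HistologyParams | None = None,
    total_wm_volume_reference: float | None = None,
    white_gray_area_reference: float = DEFAULT_WHITE_GRAY_AREA,
) -> VolumeBudget:
    """Full volume/interface budget for an axon-count matrix."""
    params = params or HistologyParams()
    a = effective_axon_area(params)
    volume, fraction = occupied_wm_volume(n, lengths, a, total_wm_volume_reference)
    iu = pair_indices(np.asarray(n).shape[0])
    total_axons = float(np.asarray(n)[iu].sum())
    area, afrac = interface_area(total_axons, a, white_gray_area_reference)
    return VolumeBudget(
        per_axon_area=a,
        occupied_volume=volume,
        occupied_fraction=fraction,
        total_wm_volume_reference=total_wm_volume_reference,
        interface_area=area,
        interface_fraction=afrac,
        white_gray_area_reference=white_gray_area_reference,
    )
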