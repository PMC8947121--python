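"""What-if simulations of misestimated density and length-dependent sensitivity.

Calibration rests on callosal fibers, which are long; if tractography were
systematically less sensitive to short fibers, short-range axon counts would
be underestimated. These simulations apply length-dependent corrections to
the axon matrix and ask how much the summary statistics actually move:

* ``uniform_short`` — multiply every pair shorter than a threshold (default
  40 mm) by a constant factor (default 2);
* ``inverse_length`` — multiply each pair by ``m(L) = 1 + slope*(1/L -
  1/L_ref)``: the correction grows with inverse fiber length and vanishes at
  the reference length (longest fibers, where the calibration is trusted).

Because packing density and axons-per-streamline are co-constrained by the
fixed hemispheric white-matter volume, ``hold_volume_constant`` reciprocally
rescales the effective per-axon area so the occupied volume is exactly
invariant — more axons must then be thinner axons.

The slope is expressed in mm (the multiplier is dimensionless in 1/L times
mm); :func:`slope_for_multiplier` converts a target multiplier at the
shortest length into this unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ConfigError, ParcelTable, pair_class_masks, pair_indices
from .volume import occupied_wm_volume

_RANK_TOL = 1e-12


@dataclass(frozen=True)
class SensitivitySpec:
    """Parameters of one sensitivity adjustment.

    ``slope`` (mm) applies to ``inverse_length`` mode; ``short_length_threshold``
    (mm) and ``short_factor`` to ``uniform_short``. ``reference_length``
    defaults to the longest observed fiber, where the multiplier is anchored
    to 1.
    """

    mode: str = "inverse_length"
    short_length_threshold: float = 40.0
    short_factor: float = 2.0
    slope: float = 0.0
    reference_length: float | None = None
    hold_volume_constant: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("uniform_short", "inverse_length"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.short_factor < 1:
            raise ConfigError("short_factor must be >= 1")
        if self.slope < 0:
            raise ConfigError("slope must be >= 0 (multiplier may not drop below 1)")
        if self.short_length_threshold <= 0:
            raise ConfigError("short_length_threshold must be > 0")
        if self.reference_length is not None and self.reference_length <= 0:
            raise ConfigError("reference_length must be > 0")


@dataclass
class AdjustmentReport:
    delta_total_pct: float
    delta_median_intra_pct: float
    delta_median_inter_pct: float
    rank_order_preserved: bool
    density_factor: float  # adjusted density / baseline (1 unless volume held)
    multiplier_min: float
    multiplier_max: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "delta_total_pct", "delta_median_intra_pct", "delta_median_inter_pct",
            "rank_order_preserved", "density_factor",
            "multiplier_min", "multiplier_max",
        )}


def slope_for_multiplier(
    target_multiplier: float, min_length: float, reference_length: float
) -> float:
    """Slope (mm) giving ``m(min_length) = target_multiplier`` with the
    multiplier anchored to 1 at ``reference_length``."""
    if target_multiplier < 1:
        raise ValueError("target_multiplier must be >= 1")
    if not 0 < min_length < reference_length:
        raise ValueError("need 0 < min_length < reference_length")
    return (target_multiplier - 1.0) / (1.0 / min_length - 1.0 / reference_length)


def _pct(new: float, old: float) -> float:
    if old == 0:
        return 0.0 if new == 0 else float("inf")
    return 100.0 * (new - old) / old


def _rank_preserved(base: np.ndarray, adj: np.ndarray) -> bool:
    """Weak-order preservation: sorted by baseline, adjusted values must be
    nondecreasing (up to float tolerance)."""
    order = np.argsort(base, kind="stable")
    d = np.diff(adj[order])
    return bool((d >= -_RANK_TOL * max(adj.max(initial=0.0), 1.0)).all())


def _report(
    base: np.ndarray,
    adj: np.ndarray,
    lengths: np.ndarray,
    parcels: ParcelTable,
    multipliers: np.ndarray,
    hold_volume: bool,
    per_axon_area: float,
) -> AdjustmentReport:
    iu = pair_indices(parcels.n_parcels)
    masks = pair_class_masks(parcels)
    bv, av = base[iu], adj[iu]
    density_factor = 1.0
    if hold_volume:
        v0, _ = occupied_wm_volume(base, lengths, per_axon_area)
        v1, _ = occupied_wm_volume(adj, lengths, per_axon_area)
        # per-axon area shrinks by v0/v1, i.e. density grows by v1/v0
        density_factor = v1 / v0 if v0 > 0 else 1.0
    return AdjustmentReport(
        delta_total_pct=_pct(av.sum(), bv.sum()),
        delta_median_intra_pct=_pct(
            float(np.median(av[masks["intra"]])), float(np.median(bv[masks["intra"]]))
        ),
        delta_median_inter_pct=_pct(
            float(np.median(av[masks["inter"]])), float(np.median(bv[masks["inter"]]))
        ),
        rank_order_preserved=_rank_preserved(bv, av),
        density_factor=float(density_factor),
        multiplier_min=float(multipliers.min(initial=1.0)),
        multiplier_max=float(multipliers.max(initial=1.0)),
    )


def adjust_uniform_short(
    n: np.ndarray,
    lengths: np.ndarray,
    parcels: ParcelTable,
    spec: SensitivitySpec,
    per_axon_area: float | None = None,
) -> tuple[np.ndarray, AdjustmentReport]:
    """Multiply all pairs shorter than the threshold by ``short_factor``."""
    n = np.asarray(n, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    short = (lengths < spec.short_length_threshold) & (lengths > 0)
    mult = np.where(short, spec.short_factor, 1.0)
    adj = n * mult
    iu = pair_indices(parcels.n_parcels)
    return adj, _report(
        n, adj, lengths, parcels, mult[iu],
        spec.hold_volume_constant, per_axon_area or 1.0,
    )


def adjust_inverse_length(
    n: np.ndarray,
    lengths: np.ndarray,
    parcels: ParcelTable,
    spec: SensitivitySpec,
    per_axon_area: float | None = None,
) -> tuple[np.ndarray, AdjustmentReport]:
    """Apply the inverse-length multiplier ``m(L) = 1 + slope*(1/L - 1/L_ref)``.

    Raises if any pair with axons sits beyond the reference length (where the
    multiplier would dip below 1) or has no length. With
    ``hold_volume_constant`` the report's ``density_factor`` gives the implied
    packing-density increase (per-axon area shrinks by its reciprocal) that
    keeps the occupied white-matter volume exactly fixed.
    """
    n = np.asarray(n, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    iu = pair_indices(parcels.n_parcels)
    lv = lengths[iu]
    nv = n[iu]
    if ((nv > 0) & ~(lv > 0)).any():
        raise ValueError("pairs with axons but no fiber length")
    connected = lv > 0
    l_ref = spec.reference_length or float(lv[connected].max())
    mult = np.ones_like(lv)
    mult[connected] = 1.0 + spec.slope * (1.0 / lv[connected] - 1.0 / l_ref)
    if (mult < 1.0 - 1e-12).any():
        worst = float(mult.min())
        raise ConfigError(
            f"adjustment multiplier drops below 1 (min {worst:.6g}); fibers "
            f"longer than reference_length={l_ref:.6g} mm are present"
        )
    full = np.ones_like(n)
    full[iu] = mult
    full.T[iu] = mult
    adj = n * full
    return adj, _report(
        n, adj, lengths, parcels, mult,
        spec.hold_volume_constant, per_axon_area or 1.0,
    )


def adjust(
    n: np.ndarray,
    lengths: np.ndarray,
    parcels: ParcelTable,
    spec: SensitivitySpec,
    per_axon_area: float | None = None,
) -> tuple[np.ndarray, AdjustmentReport]:
    """Dispatch on ``spec.mode``."""
    fn = adjust_uniform_short if spec.mode == "uniform_short" else adjust_inverse_length
    return fn(n, lengths, parcels, spec, per_axon_area)


def slope_sweep(
    n: np.ndarray,
    lengths: np.ndarray,
    parcels: ParcelTable,
    slopes: np.ndarray,
    per_axon_area: float | None = None,
    reference_length: float | None = None,
    hold_volume_constant: bool = True,
) -> pd.DataFrame:
    """Evaluate the inverse-length adjustment over a range of slopes.

    Returns a tidy table: slope, multiplier at the shortest length, percent
    changes of the medians and total, and the implied density factor.
    """
    rows = []
    for s in np.asarray(slopes, dtype=float):
        spec = SensitivitySpec(
            mode="inverse_length", slope=float(s),
            reference_length=reference_length,
            hold_volume_constant=hold_volume_constant,
        )
        _, rep = adjust_inverse_length(n, lengths, parcels, spec, per_axon_area)
        rows.append({
            "slope": float(s),
            "multiplier_at_min_length": rep.multiplier_max,
            "delta_median_intra_pct": rep.delta_median_intra_pct,
            "delta_median_inter_pct": rep.delta_median_inter_pct,
            "delta_total_pct": rep.delta_total_pct,
            "density_factor": rep.density_factor,
        })
    return pd.DataFrame(rows)
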