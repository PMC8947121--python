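"""Absolute axon-count matrices and their connectivity summaries.

Applying the calibrated axons-per-streamline ratio to the cohort-mean
streamline matrix gives the absolute number of axons linking every parcel
pair. This module computes the summaries read off that matrix: total
interareal axons, pairwise medians (intra- vs interhemispheric), the fraction
of axons terminating in physically adjacent parcels, bounds on the fraction
of pyramidal cells projecting outside their parcel, per-parcel totals and
area-normalized densities, log-binned pair-count histograms, and group
comparisons of per-subject interhemispheric axon totals (sex, age).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .types import (
    DEFAULT_PYRAMIDAL_COUNT,
    ParcelTable,
    SubjectRecord,
    pair_class_masks,
    pair_indices,
    validate_connectivity_matrix,
)


def apply_conversion(mean_streamlines: np.ndarray, ratio: float) -> np.ndarray:
    """Convert a streamline matrix to absolute axon counts (elementwise)."""
    if not ratio > 0:
        raise ValueError(f"ratio must be > 0, got {ratio}")
    m = validate_connectivity_matrix(mean_streamlines)
    return ratio * m


def mean_streamline_matrix(cohort: list[SubjectRecord]) -> np.ndarray:
    """Cohort-mean streamline matrix (arithmetic mean over subjects)."""
    if not cohort:
        raise ValueError("cohort must be nonempty")
    return np.mean([s.streamlines for s in cohort], axis=0)


@dataclass
class LogHistogram:
    """Base-10 log-binned pair counts, split by pair class.

    Pairs with zero axons cannot be log-binned; they are tallied separately
    per class in ``zero_pairs`` (they are real observations, not artifacts).
    """

    bin_edges: np.ndarray  # log10(axons), width 0.25 dex
    counts: dict[str, np.ndarray]  # keys: inter, intra_adjacent, intra_nonadjacent
    zero_pairs: dict[str, int]


@dataclass
class ConnectivitySummary:
    total_axons: float
    median_intra: float
    median_inter: float
    adjacent_fraction: float
    frac_projecting: float
    frac_projecting_beyond_adjacent: float
    per_parcel_totals: pd.Series
    per_parcel_density: pd.Series
    histograms: LogHistogram

    def to_dict(self) -> dict:
        return {
            "total_axons": self.total_axons,
            "median_intra": self.median_intra,
            "median_inter": self.median_inter,
            "adjacent_fraction": self.adjacent_fraction,
            "frac_projecting": self.frac_projecting,
            "frac_projecting_beyond_adjacent": self.frac_projecting_beyond_adjacent,
        }


def log_histograms(
    n: np.ndarray, parcels: ParcelTable, bin_width: float = 0.25
) -> LogHistogram:
    """Histogram log10 pairwise counts for inter / intra-adjacent /
    intra-nonadjacent pairs on a shared grid (auto-fit range)."""
    iu = pair_indices(parcels.n_parcels)
    masks = pair_class_masks(parcels)
    vals = np.asarray(n)[iu]
    classes = ("inter", "intra_adjacent", "intra_nonadjacent")
    positive = vals > 0
    if positive.any():
        lo = np.floor(np.log10(vals[positive].min()) / bin_width) * bin_width
        hi = np.ceil(np.log10(vals[positive].max()) / bin_width) * bin_width
        hi = max(hi, lo + bin_width)
        edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    else:
        edges = np.array([0.0, bin_width])
    counts = {}
    zeros = {}
    for cls in classes:
        v = vals[masks[cls]]
        pos = v[v > 0]
        counts[cls], _ = np.histogram(np.log10(pos), bins=edges)
        zeros[cls] = int((v == 0).sum())
    return LogHistogram(bin_edges=edges, counts=counts, zero_pairs=zeros)


def summarize(
    n: np.ndarray,
    parcels: ParcelTable,
    pyramidal_count: float = DEFAULT_PYRAMIDAL_COUNT,
    include_zero_pairs: bool = True,
) -> ConnectivitySummary:
    """All scalar and per-parcel summaries of an axon-count matrix.

    Medians pool unordered pairs: intrahemispheric over both hemispheres,
    interhemispheric over left-right pairs. Zero-count pairs are included by
    default (they are observed pairs); ``include_zero_pairs=False`` restricts
    medians to connected pairs. Projection fractions attribute each interareal
    axon to exactly one projecting pyramidal neuron, giving an upper bound on
    the fraction of pyramidal cells projecting outside their own parcel.
    """
    n = validate_connectivity_matrix(n, n_parcels=parcels.n_parcels, kind="axon")
    iu = pair_indices(parcels.n_parcels)
    masks = pair_class_masks(parcels)
    vals = n[iu]

    def _median(mask: np.ndarray) -> float:
        v = vals[mask]
        if not include_zero_pairs:
            v = v[v > 0]
        return float(np.median(v)) if len(v) else float("nan")

    total = float(vals.sum())
    adjacent_sum = float(vals[masks["adjacent"]].sum())
    adjacent_fraction = adjacent_sum / total if total > 0 else 0.0
    nonadjacent_sum = total - adjacent_sum

    totals = pd.Series(n.sum(axis=1), index=parcels.table.index, name="total_axons")
    density = pd.Series(
        totals.to_numpy() / parcels.areas,
        index=parcels.table.index,
        name="axons_per_mm2",
    )
    return ConnectivitySummary(
        total_axons=total,
        median_intra=_median(masks["intra"]),
        median_inter=_median(masks["inter"]),
        adjacent_fraction=adjacent_fraction,
        frac_projecting=total / pyramidal_count,
        frac_projecting_beyond_adjacent=nonadjacent_sum / pyramidal_count,
        per_parcel_totals=totals,
        per_parcel_density=density,
        histograms=log_histograms(n, parcels),
    )


def hemisphere_average_matrix(
    n: np.ndarray, parcels: ParcelTable
) -> tuple[np.ndarray, pd.Index]:
    """Mean of the left- and right-intrahemispheric blocks, homologs matched
    by base name. Returns the averaged matrix and its base-name index."""
    n = np.asarray(n)
    pairs = parcels.homolog_pairs()
    li = pairs["left"].to_numpy()
    ri = pairs["right"].to_numpy()
    avg = 0.5 * (n[np.ix_(li, li)] + n[np.ix_(ri, ri)])
    return avg, pairs.index


def target_normalized_profile(
    n: np.ndarray,
    parcels: ParcelTable,
    source_parcel: str | int,
    hemisphere_average: bool = False,
) -> pd.Series:
    """Axons from one source parcel to every target, per mm^2 of *target* area.

    With ``hemisphere_average=True`` the source is a base name and the profile
    is computed on the homolog-averaged intrahemispheric matrix with
    homolog-averaged target areas.
    """
    n = np.asarray(n)
    if hemisphere_average:
        avg, base_index = hemisphere_average_matrix(n, parcels)
        pairs = parcels.homolog_pairs()
        if source_parcel not in base_index:
            raise KeyError(f"unknown parcel base name {source_parcel!r}")
        areas = 0.5 * (
            parcels.areas[pairs["left"].to_numpy()]
            + parcels.areas[pairs["right"].to_numpy()]
        )
        row = avg[base_index.get_loc(source_parcel)]
        return pd.Series(row / areas, index=base_index, name="axons_per_mm2")
    if isinstance(source_parcel, str):
        src = parcels.index_of(source_parcel)
    else:
        src = int(source_parcel)
        if not (0 <= src < parcels.n_parcels):
            raise KeyError(f"parcel id {src} out of range")
    return pd.Series(
        n[src] / parcels.areas,
        index=parcels.table.index,
        name="axons_per_mm2",
    )


@dataclass
class GroupCompareResult:
    """One-way F tests for sex and age, their interaction, and bootstrap CIs."""

    f_sex: float
    p_sex: float
    f_age: float
    p_age: float
    f_interaction: float
    p_interaction: float
    group_means: dict[str, dict[str, tuple[float, float, float]]]
    # factor -> level -> (mean, ci_low, ci_high)

    def to_dict(self) -> dict:
        return {
            "sex": {"F": self.f_sex, "p": self.p_sex},
            "age_group": {"F": self.f_age, "p": self.p_age},
            "interaction": {"F": self.f_interaction, "p": self.p_interaction},
            "group_means": {
                fac: {lvl: list(ci) for lvl, ci in levels.items()}
                for fac, levels in self.group_means.items()
            },
        }


def group_compare(
    values: np.ndarray,
    sex: np.ndarray,
    age_group: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> GroupCompareResult:
    """Compare per-subject interhemispheric axon totals across sex and age.

    One-way ANOVA F tests per factor, an interaction F from the two-way
    linear model, and seeded percentile-bootstrap 95% CIs of group means.
    Requires at least two levels per factor and two subjects per level.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex)
    age_group = np.asarray(age_group)
    if not (len(values) == len(sex) == len(age_group)):
        raise ValueError("values, sex and age_group must be equal length")
    df = pd.DataFrame({"value": values, "sex": sex, "age_group": age_group})
    for factor in ("sex", "age_group"):
        counts = df[factor].value_counts()
        if len(counts) < 2 or (counts < 2).any():
            raise ValueError(
                f"degenerate groups for {factor}: need >=2 levels with >=2 "
                f"subjects each, got {counts.to_dict()}"
            )

    def _oneway(factor: str) -> tuple[float, float]:
        groups = [g["value"].to_numpy() for _, g in df.groupby(factor)]
        f, p = scipy.stats.f_oneway(*groups)
        return float(f), float(p)

    f_sex, p_sex = _oneway("sex")
    f_age, p_age = _oneway("age_group")

    # sparse sex-by-age cells make the interaction contrast rank deficient;
    # statsmodels then returns NaN, which is the honest answer here
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.ols("value ~ C(sex) * C(age_group)", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
    inter_row = anova.loc["C(sex):C(age_group)"]
    f_int, p_int = float(inter_row["F"]), float(inter_row["PR(>F)"])

    rng = np.random.default_rng(seed)
    group_means: dict[str, dict[str, tuple[float, float, float]]] = {}
    for factor in ("sex", "age_group"):
        group_means[factor] = {}
        for level, g in df.groupby(factor):
            v = g["value"].to_numpy()
            boots = rng.choice(v, size=(n_boot, len(v)), replace=True).mean(axis=1)
            lo, hi = np.percentile(boots, [2.5, 97.5])
            group_means[factor][str(level)] = (float(v.mean()), float(lo), float(hi))

    return GroupCompareResult(
        f_sex=f_sex, p_sex=p_sex, f_age=f_age, p_age=p_age,
        f_interaction=f_int, p_interaction=p_int, group_means=group_means,
    )


def per_subject_interhemispheric_axons(
    cohort: list[SubjectRecord], parcels: ParcelTable, ratio: float
) -> np.ndarray:
    """Each subject's total interhemispheric axons under a common ratio."""
    from .calibration import interhemispheric_streamline_sum

    return np.array([
        ratio * interhemispheric_streamline_sum(s.streamlines, parcels)
        for s in cohort
    ])
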