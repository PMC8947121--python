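"""Distance profiles and intra- vs interhemispheric tractography parity.

Calibrating on the callosum and applying the ratio hemisphere-wide assumes the
tractography is about equally sensitive to intra- and interhemispheric fibers.
These checks probe that assumption: length-binned mean connectivity with
bootstrap confidence bands for each pair set, ordinary least squares of
log-connectivity on fiber length restricted to the common ("distance-matched")
length domain, bootstrap confidence intervals on the slope and intercept
differences, and a permutation comparison of the two length-connectivity
correlations (with a Fisher-z comparison as a parametric secondary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .types import ParcelTable, pair_class_masks, pair_indices

PAIR_SETS = ("intra", "inter")


def _pair_vectors(
    matrix: np.ndarray,
    lengths: np.ndarray,
    parcels: ParcelTable,
    pair_set: str,
) -> tuple[np.ndarray, np.ndarray]:
    """(length, connectivity) vectors over unordered pairs of one set."""
    if pair_set not in PAIR_SETS:
        raise ValueError(f"pair_set must be one of {PAIR_SETS}, got {pair_set!r}")
    iu = pair_indices(parcels.n_parcels)
    mask = pair_class_masks(parcels)[pair_set]
    return np.asarray(lengths)[iu][mask], np.asarray(matrix)[iu][mask]


@dataclass
class DistanceBinning:
    """Per-bin mean connectivity with percentile-bootstrap 95% CIs.

    Empty bins are reported (count 0, NaN mean/CI), never dropped.
    """

    pair_set: str
    bin_edges: np.ndarray
    counts: np.ndarray
    means: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def bin_by_length(
    matrix: np.ndarray,
    lengths: np.ndarray,
    parcels: ParcelTable,
    pair_set: str,
    n_bins: int = 15,
    n_boot: int = 1000,
    seed: int = 0,
) -> DistanceBinning:
    """Average pairwise connectivity within equal-width fiber-length bins.

    Bins span the pair set's own length range. CIs are percentile bootstrap
    over parcel pairs within each bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lens, vals = _pair_vectors(matrix, lengths, parcels, pair_set)
    edges = np.linspace(lens.min(), lens.max(), n_bins + 1)
    # rightmost bin closed so the max-length pair is counted
    idx = np.clip(np.digitize(lens, edges[1:-1]), 0, n_bins - 1)
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_bins, dtype=int)
    means = np.full(n_bins, np.nan)
    lo = np.full(n_bins, np.nan)
    hi = np.full(n_bins, np.nan)
    for b in range(n_bins):
        v = vals[idx == b]
        counts[b] = len(v)
        if len(v) == 0:
            continue
        means[b] = v.mean()
        boots = rng.choice(v, size=(n_boot, len(v)), replace=True).mean(axis=1)
        lo[b], hi[b] = np.percentile(boots, [2.5, 97.5])
    return DistanceBinning(
        pair_set=pair_set, bin_edges=edges, counts=counts,
        means=means, ci_low=lo, ci_high=hi,
    )


@dataclass
class ParityResult:
    slope_intra: float
    slope_inter: float
    intercept_intra: float
    intercept_inter: float
    slope_diff: float
    slope_diff_ci: tuple[float, float]
    intercept_diff: float
    intercept_diff_ci: tuple[float, float]
    r_intra: float
    r_inter: float
    perm_p: float  # permutation two-sided p for the correlation difference
    fisher_z: float
    fisher_p: float
    common_domain: tuple[float, float]
    n_intra: int
    n_inter: int
    n_zero_excluded: int  # pairs with zero connectivity dropped from the log fit

    def to_dict(self) -> dict:
        return {
            "slope_intra": self.slope_intra,
            "slope_inter": self.slope_inter,
            "intercept_intra": self.intercept_intra,
            "intercept_inter": self.intercept_inter,
            "slope_diff": self.slope_diff,
            "slope_diff_ci": list(self.slope_diff_ci),
            "intercept_diff": self.intercept_diff,
            "intercept_diff_ci": list(self.intercept_diff_ci),
            "r_intra": self.r_intra,
            "r_inter": self.r_inter,
            "perm_p": self.perm_p,
            "fisher_z": self.fisher_z,
            "fisher_p": self.fisher_p,
            "common_domain": list(self.common_domain),
            "n_intra": self.n_intra,
            "n_inter": self.n_inter,
            "n_zero_excluded": self.n_zero_excluded,
        }


def _fit(lens: np.ndarray, logv: np.ndarray):
    res = scipy.stats.linregress(lens, logv)
    return res.slope, res.intercept, res.rvalue


def _boot_fit(rng: np.random.Generator, lens: np.ndarray, logv: np.ndarray):
    """One bootstrap replicate of the OLS fit; redraws the (rare) degenerate
    resamples in which every drawn pair shares one length."""
    for _ in range(100):
        idx = rng.integers(0, len(lens), len(lens))
        if np.ptp(lens[idx]) > 0:
            return _fit(lens[idx], logv[idx])
    raise ValueError("bootstrap resampling degenerate: lengths have no spread")


def edr_slope(
    matrix: np.ndarray,
    lengths: np.ndarray,
    parcels: ParcelTable,
    exclude_adjacent: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Exponential-distance-rule decay rate from pooled pairs.

    OLS slope of natural-log connectivity on fiber length over all connected
    pairs, with a percentile-bootstrap 95% CI. Physically adjacent pairs are
    excluded by default: their counts are disproportionally strong and sit at
    the shortest lengths, which biases the pooled decay estimate.
    """
    iu = pair_indices(parcels.n_parcels)
    masks = pair_class_masks(parcels)
    keep = ~masks["adjacent"] if exclude_adjacent else np.ones(len(iu[0]), bool)
    lens = np.asarray(lengths)[iu][keep]
    vals = np.asarray(matrix)[iu][keep]
    pos = vals > 0
    lens, logv = lens[pos], np.log(vals[pos])
    if len(lens) < 3:
        raise ValueError("fewer than 3 positive pairs for the decay fit")
    slope, _, _ = _fit(lens, logv)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for k in range(n_boot):
        boots[k], _, _ = _boot_fit(rng, lens, logv)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(slope), (float(lo), float(hi))


def parity_test(
    matrix: np.ndarray,
    lengths: np.ndarray,
    parcels: ParcelTable,
    n_boot: int = 1000,
    n_perm: int = 1000,
    n_strata: int = 15,
    seed: int = 0,
) -> ParityResult:
    """Compare intra- vs interhemispheric log-connectivity regressions.

    Both pair sets are restricted to the intersection of their length ranges
    (the common distance domain); zero-connectivity pairs are excluded from
    the log fit and counted in ``n_zero_excluded``. The correlation comparison
    is a seeded *distance-matched* permutation test: group labels are shuffled
    within ``n_strata`` equal-width length strata, preserving each group's
    length distribution, with statistic ``r_intra - r_inter``, two-sided. (An
    unstratified shuffle would confound the label with fiber length, since the
    two pair sets occupy different parts of the common domain.) A Fisher-z
    comparison is reported as a parametric secondary. Bootstrap CIs resample
    pairs within each group independently.
    """
    rng = np.random.default_rng(seed)
    sets = {}
    n_zero = 0
    for ps in PAIR_SETS:
        lens, vals = _pair_vectors(matrix, lengths, parcels, ps)
        pos = vals > 0
        n_zero += int((~pos).sum())
        sets[ps] = (lens[pos], np.log(vals[pos]))
    lo = max(sets[ps][0].min() for ps in PAIR_SETS)
    hi = min(sets[ps][0].max() for ps in PAIR_SETS)
    if not lo < hi:
        raise ValueError(
            f"empty common length domain: intra and inter ranges do not overlap "
            f"(lo={lo:.3g}, hi={hi:.3g})"
        )
    data = {}
    for ps in PAIR_SETS:
        lens, logv = sets[ps]
        keep = (lens >= lo) & (lens <= hi)
        if keep.sum() < 3:
            raise ValueError(f"fewer than 3 {ps} pairs in the common domain")
        data[ps] = (lens[keep], logv[keep])

    slope_a, int_a, r_a = _fit(*data["intra"])
    slope_b, int_b, r_b = _fit(*data["inter"])

    # bootstrap difference CIs (resample pairs within each group)
    sdiffs = np.empty(n_boot)
    idiffs = np.empty(n_boot)
    la, va = data["intra"]
    lb, vb = data["inter"]
    for k in range(n_boot):
        sa, ca, _ = _boot_fit(rng, la, va)
        sb, cb, _ = _boot_fit(rng, lb, vb)
        sdiffs[k] = sa - sb
        idiffs[k] = ca - cb
    slope_ci = tuple(np.percentile(sdiffs, [2.5, 97.5]))
    int_ci = tuple(np.percentile(idiffs, [2.5, 97.5]))

    # distance-matched permutation: shuffle labels within length strata
    pool_l = np.concatenate([data["intra"][0], data["inter"][0]])
    pool_v = np.concatenate([data["intra"][1], data["inter"][1]])
    labels = np.concatenate([
        np.zeros(len(data["intra"][0]), dtype=bool),
        np.ones(len(data["inter"][0]), dtype=bool),
    ])
    edges = np.linspace(lo, hi, n_strata + 1)
    strata = np.clip(np.digitize(pool_l, edges[1:-1]), 0, n_strata - 1)
    stratum_members = [np.flatnonzero(strata == s) for s in range(n_strata)]

    def _rdiff(lab: np.ndarray) -> float:
        ra = np.corrcoef(pool_l[~lab], pool_v[~lab])[0, 1]
        rb = np.corrcoef(pool_l[lab], pool_v[lab])[0, 1]
        return ra - rb

    # ties within float tolerance count as exceedances (valid, conservative)
    obs = abs(_rdiff(labels)) - 1e-12
    exceed = 0
    for _ in range(n_perm):
        lab = labels.copy()
        for members in stratum_members:
            if len(members) > 1:
                lab[members] = lab[members[rng.permutation(len(members))]]
        if abs(_rdiff(lab)) >= obs:
            exceed += 1
    perm_p = (1 + exceed) / (1 + n_perm)

    # Fisher z (independent-samples comparison of correlations); r is clipped
    # away from +/-1 so noise-free perfectly collinear inputs stay finite
    na, nb = len(data["intra"][0]), len(data["inter"][0])
    clip = 1.0 - 1e-15
    z = (np.arctanh(np.clip(r_a, -clip, clip))
         - np.arctanh(np.clip(r_b, -clip, clip))) / np.sqrt(
        1.0 / (na - 3) + 1.0 / (nb - 3)
    )
    fisher_p = 2.0 * scipy.stats.norm.sf(abs(z))

    return ParityResult(
        slope_intra=float(slope_a), slope_inter=float(slope_b),
        intercept_intra=float(int_a), intercept_inter=float(int_b),
        slope_diff=float(slope_a - slope_b),
        slope_diff_ci=(float(slope_ci[0]), float(slope_ci[1])),
        intercept_diff=float(int_a - int_b),
        intercept_diff_ci=(float(int_ci[0]), float(int_ci[1])),
        r_intra=float(r_a), r_inter=float(r_b),
        perm_p=float(perm_p), fisher_z=float(z), fisher_p=float(fisher_p),
        common_domain=(float(lo), float(hi)),
        n_intra=na, n_inter=nb, n_zero_excluded=n_zero,
    )
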