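"""Seeded synthetic connectome cohorts.

The generator produces parcellations, fiber-length matrices and subject-level
streamline matrices whose statistical structure matches what the calibration
pipeline assumes about real parcellated tractography:

* pairwise connectivity is approximately log-normal across nonadjacent parcel
  pairs, with physically adjacent pairs disproportionally strong;
* expected log-connectivity declines linearly with fiber length (exponential
  distance rule) at the *same* rate for intra- and interhemispheric pairs —
  the tractography-parity assumption is built in;
* interhemispheric fibers are on average longer than intrahemispheric ones,
  extending up to the configured maximum (~300 mm);
* per-subject callosal cross-sectional areas scatter about the configured
  cohort mean (689.45 mm^2 by default).

Every cohort carries a manifest recording the ground-truth axons-per-streamline
ratio so downstream calibration can be closure-tested: the generator draws each
subject's callosal area as ``true_ratio * interhemispheric_sum / density``
plus zero-mean jitter of SD ``callosal_area_sd``, and solves the base
streamline scale so the expected callosal area equals ``callosal_area_mean``.
With ``callosal_area_sd = 0`` calibration recovers the true ratio exactly.

Geometry is abstract: parcels live in a random 2-D embedding per hemisphere
(mirrored to the other side), adjacency is the Delaunay triangulation of that
embedding (planar, connected, mirror-symmetric), and lengths are affinely
scaled embedding distances, so adjacent parcels get short fibers and
cross-hemisphere pairs get a callosal detour. No cortical meshes or diffusion
signal are simulated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay

from .types import (
    AGE_GROUPS,
    ConfigError,
    HistologyParams,
    ParcelTable,
    SubjectRecord,
    pair_class_masks,
    pair_indices,
)

import pandas as pd

# rng stream tags so each operation is independently reproducible from the seed
_STREAM_GEOMETRY = 101
_STREAM_COHORT = 202

#: Occupancy fraction the manifest's white-matter volume reference is anchored
#: to: the expected occupied volume of the cohort is ~96% of the reference,
#: mirroring the near-saturation of hemispheric white matter by interareal
#: axons.
_WM_OCCUPANCY_ANCHOR = 0.96

_AGE_PROBS = (0.21, 0.41, 0.35, 0.03)  # roughly the reference cohort's mix


@dataclass(frozen=True)
class GeneratorConfig:
    """Free parameters of the synthetic cohort generator.

    Parameters
    ----------
    n_parcels_per_hemisphere
        Parcels per hemisphere (180 for the full 360-area atlas).
    n_subjects
        Cohort size.
    total_cortical_area
        Total white-gray interface area, mm^2, split equally and mirror-
        symmetrically across hemispheres (default 1.77e5).
    edr_lambda
        Exponential distance rule decay rate, 1/mm: expected natural-log
        streamlines fall by ``edr_lambda`` per mm of fiber length, with the
        same slope intra- and interhemispherically.
    lognormal_sigma
        SD of the multiplicative pair noise in natural-log units.
    adjacency_boost
        Multiplier (>= 1) applied to physically adjacent pairs.
    callosal_area_mean, callosal_area_sd
        Mean and SD of per-subject callosal cross-sectional area, mm^2.
    true_axons_per_streamline
        Ground-truth conversion ratio recorded in the manifest.
    length_range
        (min, max) fiber length in mm; all pairwise lengths fall inside.
    seed
        Master seed; identical config (including seed) gives byte-identical
        cohorts.
    """

    n_parcels_per_hemisphere: int = 180
    n_subjects: int = 50
    total_cortical_area: float = 1.77e5
    edr_lambda: float = 0.05
    lognormal_sigma: float = 1.0
    adjacency_boost: float = 4.0
    callosal_area_mean: float = 689.45
    callosal_area_sd: float = 80.0
    true_axons_per_streamline: float = 2.0
    length_range: tuple[float, float] = (10.0, 300.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_parcels_per_hemisphere, (int, np.integer))
                and self.n_parcels_per_hemisphere >= 1):
            raise ConfigError("n_parcels_per_hemisphere must be a positive integer")
        if not (isinstance(self.n_subjects, (int, np.integer)) and self.n_subjects >= 1):
            raise ConfigError("n_subjects must be a positive integer")
        for fld in ("total_cortical_area", "edr_lambda", "adjacency_boost",
                    "callosal_area_mean", "true_axons_per_streamline"):
            if not getattr(self, fld) > 0:
                raise ConfigError(f"{fld} must be strictly positive")
        if self.adjacency_boost < 1:
            raise ConfigError("adjacency_boost must be >= 1")
        if self.lognormal_sigma < 0:
            raise ConfigError("lognormal_sigma must be >= 0")
        if self.callosal_area_sd < 0:
            raise ConfigError("callosal_area_sd must be >= 0")
        lo, hi = self.length_range
        if not (0 < lo < hi):
            raise ConfigError("length_range must satisfy 0 < min < max")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["length_range"] = list(self.length_range)
        return d


@dataclass
class CohortManifest:
    """Ground truth and provenance for a generated cohort."""

    config: GeneratorConfig
    histology: HistologyParams
    true_axons_per_streamline: float
    base_scale: float  # streamline count at zero length, before noise/boost
    wm_volume_reference: float  # mm^3; expected occupied volume is ~96% of it
    subject_ids: list[str]

    def true_axon_matrix(self, subject: SubjectRecord) -> np.ndarray:
        """The subject's ground-truth axon-count matrix (ratio x streamlines)."""
        return self.true_axons_per_streamline * subject.streamlines

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "histology": dataclasses.asdict(self.histology),
            "true_axons_per_streamline": self.true_axons_per_streamline,
            "base_scale": self.base_scale,
            "wm_volume_reference": self.wm_volume_reference,
            "subject_ids": list(self.subject_ids),
        }


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

# Left-hemisphere parcels are embedded in a wide rectangle; the right
# hemisphere mirrors them about x = _MIRROR_X, leaving a small gap that
# stands in for the interhemispheric (callosal) detour. The rectangle is
# elongated so intra- and interhemispheric length domains overlap broadly,
# as they do in real tract-length distributions, while interhemispheric
# fibers remain longer on average.
_HEMI_WIDTH = 1.5
_MIRROR_X = _HEMI_WIDTH + 0.15


def _left_embedding(config: GeneratorConfig) -> np.ndarray:
    rng = np.random.default_rng([config.seed, _STREAM_GEOMETRY])
    pts = rng.uniform(0.0, 1.0, size=(config.n_parcels_per_hemisphere, 2))
    pts[:, 0] *= _HEMI_WIDTH
    return pts


def _full_embedding(config: GeneratorConfig) -> np.ndarray:
    left = _left_embedding(config)
    right = left.copy()
    right[:, 0] = 2.0 * _MIRROR_X - right[:, 0]
    return np.vstack([left, right])


def _hemisphere_edges(points: np.ndarray) -> set[tuple[int, int]]:
    """Adjacency edges of one hemisphere: Delaunay triangulation (planar-like,
    connected); degenerate small cases fall back to a path graph."""
    n = len(points)
    if n < 3:
        return {(i, i + 1) for i in range(n - 1)}
    tri = Delaunay(points)
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    return edges


def _network_labels(points: np.ndarray) -> np.ndarray:
    """Assign up to 10 spatially contiguous network labels (1-based) by
    angular position about the hemisphere centroid."""
    n = len(points)
    k = min(10, n)
    centered = points - points.mean(axis=0)
    angle = np.arctan2(centered[:, 1], centered[:, 0])
    rank = np.argsort(np.argsort(angle, kind="stable"), kind="stable")
    return (rank * k) // n + 1


def generate_parcel_table(config: GeneratorConfig) -> ParcelTable:
    """Generate a mirror-symmetric two-hemisphere parcellation.

    Areas are Dirichlet-distributed within the left hemisphere (strictly
    positive, summing to half the total) and mirrored to the right, so the
    full table sums to ``total_cortical_area``. Adjacency is the Delaunay
    triangulation of the parcel embedding, hence symmetric, irreflexive and
    connected within each hemisphere.
    """
    n = config.n_parcels_per_hemisphere
    rng = np.random.default_rng([config.seed, _STREAM_GEOMETRY, 1])
    left_pts = _left_embedding(config)

    left_areas = rng.dirichlet(np.full(n, 8.0)) * (config.total_cortical_area / 2.0)
    edges = _hemisphere_edges(left_pts)
    networks = _network_labels(left_pts)

    neighbors: list[set[int]] = [set() for _ in range(2 * n)]
    for i, j in edges:
        for off in (0, n):
            neighbors[i + off].add(j + off)
            neighbors[j + off].add(i + off)

    names = [f"L_P{i + 1:03d}" for i in range(n)] + [f"R_P{i + 1:03d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "name": names,
            "hemisphere": ["left"] * n + ["right"] * n,
            "surface_area_mm2": np.concatenate([left_areas, left_areas]),
            "network": np.concatenate([networks, networks]).astype(int),
        },
        index=pd.RangeIndex(2 * n, name="parcel_id"),
    )
    return ParcelTable(table, neighbors)


def generate_length_matrix(parcels: ParcelTable, config: GeneratorConfig) -> np.ndarray:
    """Pairwise mean fiber lengths (mm) from the parcel embedding.

    Euclidean distances in the mirrored embedding are mapped monotonically
    (by rank) onto the quantiles of a normal distribution truncated to
    ``length_range``. The monotone map preserves the geometry's ordering —
    adjacent parcels (embedding neighbors) get the shortest fibers,
    interhemispheric pairs separated by the mirror gap are on average longer,
    up to the configured maximum — while giving the pair-length distribution
    the bell shape real tract-length distributions show, so that the
    exponential distance rule produces approximately log-normal weights.
    """
    from scipy.stats import rankdata, truncnorm

    n2 = 2 * config.n_parcels_per_hemisphere
    if parcels.n_parcels != n2:
        raise ConfigError(
            f"parcel table has {parcels.n_parcels} parcels but config implies {n2}"
        )
    pts = _full_embedding(config)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    iu = pair_indices(n2)
    lo, hi = config.length_range
    mu, sd = 0.5 * (lo + hi), (hi - lo) / 8.0  # range spans +/- 4 SD
    # average ranks keep mirror-symmetric pairs at identical lengths
    q = rankdata(dist[iu], method="average") / (len(iu[0]) + 1)
    vals = truncnorm.ppf(q, (lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)
    lengths = np.zeros_like(dist)
    lengths[iu] = vals
    lengths = lengths + lengths.T
    return lengths


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def expected_streamline_matrix(
    parcels: ParcelTable, lengths: np.ndarray, config: GeneratorConfig,
    histology: HistologyParams | None = None,
) -> np.ndarray:
    """Expected (noise-averaged) streamline matrix of the generative model."""
    base, s0, _ = _model_components(parcels, lengths, config, histology or HistologyParams())
    return s0 * base * np.exp(0.5 * config.lognormal_sigma**2)


def _model_components(
    parcels: ParcelTable, lengths: np.ndarray, config: GeneratorConfig,
    histology: HistologyParams,
) -> tuple[np.ndarray, float, float]:
    """Return (base shape matrix, base scale s0, expected interhemispheric sum).

    base_ij = exp(-lambda * L_ij) * boost^{adjacent}; s0 solves
    E[callosal area] = callosal_area_mean given the ground-truth ratio.
    """
    n = parcels.n_parcels
    base = np.exp(-config.edr_lambda * lengths)
    adj = parcels.adjacency_matrix()
    base = np.where(adj, base * config.adjacency_boost, base)
    np.fill_diagonal(base, 0.0)

    iu = pair_indices(n)
    inter = pair_class_masks(parcels)["inter"]
    noise_mean = np.exp(0.5 * config.lognormal_sigma**2)
    k = base[iu][inter].sum() * noise_mean
    if k <= 0:
        raise ConfigError("degenerate geometry: no interhemispheric pairs")
    target_inter_sum = (
        config.callosal_area_mean * histology.callosal_density
        / config.true_axons_per_streamline
    )
    s0 = target_inter_sum / k
    return base, s0, s0 * k


def generate_cohort(
    parcels: ParcelTable,
    lengths: np.ndarray,
    config: GeneratorConfig,
    histology: HistologyParams | None = None,
) -> tuple[list[SubjectRecord], CohortManifest]:
    """Draw a cohort of subjects from the generative model.

    Each subject's streamline matrix is the shared exponential-distance-rule
    mean modulated by symmetric per-pair log-normal noise. The callosal area
    is tied to the subject's interhemispheric streamline sum through the
    ground-truth ratio (plus truncated-normal jitter), so calibration closure
    holds by construction.
    """
    histology = histology or HistologyParams()
    n = parcels.n_parcels
    base, s0, expected_inter = _model_components(parcels, lengths, config, histology)
    iu = pair_indices(n)
    inter = pair_class_masks(parcels)["inter"]
    rho = histology.callosal_density
    r = config.true_axons_per_streamline

    subjects: list[SubjectRecord] = []
    for s in range(config.n_subjects):
        rng = np.random.default_rng([config.seed, _STREAM_COHORT, s])
        mat = np.zeros((n, n))
        z = rng.standard_normal(len(iu[0])) if config.lognormal_sigma > 0 else 0.0
        vals = s0 * base[iu] * np.exp(config.lognormal_sigma * z)
        mat[iu] = vals
        mat = mat + mat.T

        inter_sum = vals[inter].sum()
        area = r * inter_sum / rho
        if config.callosal_area_sd > 0:
            jitter = rng.normal(0.0, config.callosal_area_sd)
            # truncate at zero: redraw until positive (mean >> sd in practice)
            while area + jitter <= 0:
                jitter = rng.normal(0.0, config.callosal_area_sd)
            area = area + jitter

        subjects.append(
            SubjectRecord(
                subject_id=f"sub-{s + 1:04d}",
                streamlines=mat,
                callosal_area=float(area),
                sex=str(rng.choice(["F", "M"])),
                age_group=str(rng.choice(AGE_GROUPS, p=_AGE_PROBS)),
            )
        )

    # volume reference anchored so the expected cohort occupies ~96% of it
    expected_counts = r * s0 * base * np.exp(0.5 * config.lognormal_sigma**2)
    per_axon_area = 1.0 / rho
    occupied = (expected_counts[iu] * lengths[iu]).sum() * per_axon_area
    manifest = CohortManifest(
        config=config,
        histology=histology,
        true_axons_per_streamline=r,
        base_scale=s0,
        wm_volume_reference=occupied / _WM_OCCUPANCY_ANCHOR,
        subject_ids=[s.subject_id for s in subjects],
    )
    return subjects, manifest


def generate_default_cohort(
    config: GeneratorConfig | None = None,
    histology: HistologyParams | None = None,
):
    """Convenience: parcels, lengths, subjects and manifest in one call."""
    config = config or GeneratorConfig()
    parcels = generate_parcel_table(config)
    lengths = generate_length_matrix(parcels, config)
    subjects, manifest = generate_cohort(parcels, lengths, config, histology)
    return parcels, lengths, subjects, manifest


def write_cohort(
    directory: str | Path,
    parcels: ParcelTable,
    lengths: np.ndarray,
    subjects: list[SubjectRecord],
    manifest: CohortManifest,
) -> Path:
    """Write a cohort to disk in the plain-text interchange layout.

    ``parcels.tsv``, ``lengths.csv``, ``subjects.tsv``, one dense CSV per
    subject under ``matrices/``, and ``manifest.json``.
    """
    from . import io as cio  # local import to avoid a cycle

    directory = Path(directory)
    (directory / "matrices").mkdir(parents=True, exist_ok=True)
    cio.write_parcel_table(parcels, directory / "parcels.tsv")
    cio.write_matrix(lengths, directory / "lengths.csv")
    rows = []
    for sub in subjects:
        rel = Path("matrices") / f"{sub.subject_id}.csv"
        cio.write_matrix(sub.streamlines, directory / rel)
        rows.append(
            {
                "subject_id": sub.subject_id,
                "callosal_area_mm2": sub.callosal_area,
                "sex": sub.sex,
                "age_group": sub.age_group,
                "matrix_path": str(rel),
            }
        )
    pd.DataFrame(rows).to_csv(directory / "subjects.tsv", sep="\t", index=False)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return directory
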