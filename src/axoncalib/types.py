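"""Core domain types for parcellated connectome analysis.

The package works on a fixed cortical parcellation (two mirror-image
hemispheres, e.g. 180 parcels each for the 360-area multimodal atlas) and on
dense, symmetric, zero-diagonal parcel-by-parcel matrices: streamline counts
(arbitrary tractography units), mean fiber-tract lengths (mm), and calibrated
absolute axon counts. This module holds the containers and the validation
shared by every pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right")
AGE_GROUPS = ("22-25", "26-30", "31-35", "36+")

#: Callosal axon packing density, axons/mm^2, shrinkage-corrected
#: (electron-microscopic counts of the human corpus callosum).
DEFAULT_CALLOSAL_DENSITY = 3.7e5
#: Mean packing density of ipsilateral (prefrontal) white-matter tracts,
#: myelinated axons/mm^2, shrinkage-corrected.
DEFAULT_IPSILATERAL_DENSITY = 3.5e5
#: Cortical pyramidal-cell count used for projection-fraction bounds.
DEFAULT_PYRAMIDAL_COUNT = 11.5e9
#: Total cortical neurons (including interneurons).
DEFAULT_TOTAL_NEURONS = 16.34e9
#: Mean white-gray interface area of the reference cohort, mm^2.
DEFAULT_WHITE_GRAY_AREA = 1.77e5

#: Relative asymmetry below which a read matrix is symmetrized by averaging;
#: above it, the matrix is rejected as corrupt.
ASYMMETRY_RTOL = 1e-8


class SchemaError(ValueError):
    """An on-disk table violates the schema (missing/duplicate/invalid rows)."""


class ConfigError(ValueError):
    """A configuration object has an invalid field; the message names it."""


class MatrixValidationError(ValueError):
    """A connectivity or length matrix violates its invariants."""


@dataclass(frozen=True)
class HistologyParams:
    """Histological axon packing densities used for calibration.

    Parameters
    ----------
    callosal_density
        Axons per mm^2 of callosal cross-section; its reciprocal is the
        effective per-axon cross-sectional area (axon proper plus myelin,
        supporting cells and extracellular space).
    ipsilateral_density
        Mean axons per mm^2 of ipsilateral tract cross-section, used for
        fasciculus capacity estimates.
    shrinkage_corrected
        Metadata flag: densities are taken as already corrected for tissue
        shrinkage; no shrinkage arithmetic is performed internally.
    """

    callosal_density: float = DEFAULT_CALLOSAL_DENSITY
    ipsilateral_density: float = DEFAULT_IPSILATERAL_DENSITY
    shrinkage_corrected: bool = True

    def __post_init__(self) -> None:
        if not self.callosal_density > 0:
            raise ConfigError("callosal_density must be > 0")
        if not self.ipsilateral_density > 0:
            raise ConfigError("ipsilateral_density must be > 0")


class ParcelTable:
    """Cortical parcellation: identities, hemispheres, areas, networks, adjacency.

    Parcel ids are dense 0-based integers. ``table`` is a DataFrame indexed by
    parcel_id with columns ``name``, ``hemisphere`` (``left``/``right``),
    ``surface_area_mm2`` and ``network`` (integer label). ``neighbors`` holds
    one frozenset of parcel ids per parcel; the relation must be symmetric and
    irreflexive (physical adjacency on the cortical sheet).
    """

    REQUIRED_COLUMNS = ("name", "hemisphere", "surface_area_mm2", "network")

    def __init__(self, table: pd.DataFrame, neighbors: Sequence[Iterable[int]]):
        self.table = table
        self.neighbors = tuple(frozenset(int(j) for j in s) for s in neighbors)
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        t = self.table
        for col in self.REQUIRED_COLUMNS:
            if col not in t.columns:
                raise SchemaError(f"parcel table missing column {col!r}")
        n = len(t)
        ids = np.asarray(t.index)
        if not np.array_equal(ids, np.arange(n)):
            raise SchemaError("parcel_id must be dense 0-based integers 0..n-1")
        bad_hemi = t.loc[~t["hemisphere"].isin(HEMISPHERES)]
        if len(bad_hemi):
            raise SchemaError(
                f"invalid hemisphere label(s) at parcel_id {list(bad_hemi.index)}"
            )
        bad_area = t.loc[~(t["surface_area_mm2"] > 0)]
        if len(bad_area):
            raise SchemaError(
                f"surface_area_mm2 must be > 0; offending parcel_id {list(bad_area.index)}"
            )
        if t["name"].duplicated().any():
            dupes = t.loc[t["name"].duplicated(), "name"].tolist()
            raise SchemaError(f"duplicate parcel names: {dupes}")
        if len(self.neighbors) != n:
            raise SchemaError("neighbors must have one entry per parcel")
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise SchemaError(f"parcel {i} lists itself as neighbor")
            for j in nb:
                if not (0 <= j < n):
                    raise SchemaError(f"parcel {i} has out-of-range neighbor {j}")
                if i not in self.neighbors[j]:
                    raise SchemaError(
                        f"asymmetric adjacency: {i} lists {j} but not conversely"
                    )

    # -- basic accessors ----------------------------------------------------

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def names(self) -> np.ndarray:
        return self.table["name"].to_numpy()

    @property
    def hemispheres(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    @property
    def areas(self) -> np.ndarray:
        return self.table["surface_area_mm2"].to_numpy(dtype=float)

    @property
    def networks(self) -> np.ndarray:
        return self.table["network"].to_numpy()

    @property
    def is_left(self) -> np.ndarray:
        return self.hemispheres == "left"

    def hemisphere_ids(self, hemisphere: str) -> np.ndarray:
        if hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {hemisphere!r}")
        return np.flatnonzero(self.hemispheres == hemisphere)

    def index_of(self, name: str) -> int:
        hits = np.flatnonzero(self.names == name)
        if len(hits) != 1:
            raise KeyError(f"unknown or ambiguous parcel name {name!r}")
        return int(hits[0])

    def adjacency_matrix(self) -> np.ndarray:
        n = self.n_parcels
        adj = np.zeros((n, n), dtype=bool)
        for i, nb in enumerate(self.neighbors):
            for j in nb:
                adj[i, j] = True
        return adj

    # -- homologs -----------------------------------------------------------

    def base_names(self) -> np.ndarray:
        """Parcel names with a leading ``L_``/``R_`` hemisphere prefix removed."""
        out = []
        for nm in self.names:
            if nm.startswith(("L_", "R_")):
                out.append(nm[2:])
            else:
                out.append(nm)
        return np.asarray(out)

    def homolog_pairs(self) -> pd.DataFrame:
        """Match homologous parcels across hemispheres by base name.

        Returns a DataFrame indexed by base name with columns ``left`` and
        ``right`` (parcel ids). Raises if any base name does not occur exactly
        once per hemisphere.
        """
        base = self.base_names()
        left = {}
        right = {}
        for pid, (b, h) in enumerate(zip(base, self.hemispheres)):
            d = left if h == "left" else right
            if b in d:
                raise SchemaError(f"base name {b!r} duplicated within {h} hemisphere")
            d[b] = pid
        if set(left) != set(right):
            missing = sorted(set(left) ^ set(right))
            raise SchemaError(f"unpaired homolog base names: {missing}")
        keys = sorted(left)
        return pd.DataFrame(
            {"left": [left[k] for k in keys], "right": [right[k] for k in keys]},
            index=pd.Index(keys, name="base_name"),
        )


@dataclass
class SubjectRecord:
    """One subject: streamline matrix, callosal cross-sectional area, demographics."""

    subject_id: str
    streamlines: np.ndarray
    callosal_area: float  # mm^2
    sex: str  # "F" or "M"
    age_group: str

    def __post_init__(self) -> None:
        if not self.callosal_area > 0:
            raise ConfigError(
                f"subject {self.subject_id}: callosal_area must be > 0"
            )
        if self.sex not in ("F", "M"):
            raise ConfigError(f"subject {self.subject_id}: sex must be F or M")


# ---------------------------------------------------------------------------
# matrix validation
# ---------------------------------------------------------------------------


def validate_connectivity_matrix(
    m: np.ndarray,
    n_parcels: int | None = None,
    kind: str = "streamline",
    asymmetry_rtol: float = ASYMMETRY_RTOL,
) -> np.ndarray:
    """Validate a square symmetric nonnegative zero-diagonal matrix.

    Asymmetry up to ``asymmetry_rtol`` (relative to the largest magnitude
    entry) is repaired by averaging with the transpose — this tolerates float
    round-trip through text files. Larger asymmetry raises, naming the worst
    cell, since it indicates genuinely corrupt data.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise MatrixValidationError(f"matrix must be square, got shape {m.shape}")
    if n_parcels is not None and m.shape[0] != n_parcels:
        raise MatrixValidationError(
            f"matrix is {m.shape[0]}x{m.shape[1]} but parcel table has "
            f"{n_parcels} parcels"
        )
    if not np.isfinite(m).all():
        bad = np.argwhere(~np.isfinite(m))[0]
        raise MatrixValidationError(
            f"{kind} matrix has non-finite entry at cell ({bad[0]}, {bad[1]})"
        )
    if (m < 0).any():
        bad = np.argwhere(m < 0)[0]
        raise MatrixValidationError(
            f"{kind} matrix has negative entry at cell ({bad[0]}, {bad[1]})"
        )
    scale = np.abs(m).max()
    if scale > 0:
        asym = np.abs(m - m.T)
        worst = np.unravel_index(np.argmax(asym), asym.shape)
        if asym[worst] > asymmetry_rtol * scale:
            raise MatrixValidationError(
                f"{kind} matrix asymmetric beyond tolerance: worst cell "
                f"({worst[0]}, {worst[1]}) differs from its transpose by "
                f"{asym[worst]:.3g} (relative {asym[worst] / scale:.3g})"
            )
        m = 0.5 * (m + m.T)
    if np.abs(np.diag(m)).max(initial=0.0) > 0:
        bad = int(np.argmax(np.abs(np.diag(m))))
        raise MatrixValidationError(
            f"{kind} matrix must have zero diagonal; cell ({bad}, {bad}) is "
            f"{m[bad, bad]:.3g}"
        )
    return m


# ---------------------------------------------------------------------------
# unordered-pair bookkeeping
# ---------------------------------------------------------------------------


def pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of all unordered parcel pairs (upper triangle, i<j)."""
    return np.triu_indices(n, k=1)


def pair_class_masks(parcels: ParcelTable) -> dict[str, np.ndarray]:
    """Boolean masks over unordered pairs, keyed by pair class.

    Classes: ``intra`` (same hemisphere, pooled across both), ``inter``
    (left-right), ``adjacent`` (physically adjacent parcels; adjacency is
    intrahemispheric by construction), ``intra_adjacent``,
    ``intra_nonadjacent``. All masks align with ``pair_indices(n)``.
    """
    iu = pair_indices(parcels.n_parcels)
    left = parcels.is_left
    same = left[iu[0]] == left[iu[1]]
    adj = parcels.adjacency_matrix()[iu]
    return {
        "intra": same,
        "inter": ~same,
        "adjacent": adj,
        "intra_adjacent": same & adj,
        "intra_nonadjacent": same & ~adj,
    }


def pair_values(matrix: np.ndarray, parcels: ParcelTable, pair_class: str) -> np.ndarray:
    """Matrix entries over the unordered pairs of one class (each pair once)."""
    masks = pair_class_masks(parcels)
    if pair_class not in masks:
        raise ValueError(
            f"unknown pair class {pair_class!r}; choose from {sorted(masks)}"
        )
    iu = pair_indices(parcels.n_parcels)
    return np.asarray(matrix)[iu][masks[pair_class]]
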