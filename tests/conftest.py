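"""Shared fixtures: seeded synthetic cohorts and hand-built toy parcellations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import axoncalib as axc
from axoncalib.types import ParcelTable


def make_parcels(
    hemispheres: list[str],
    areas: list[float] | None = None,
    neighbors: list[set[int]] | None = None,
    names: list[str] | None = None,
    networks: list[int] | None = None,
) -> ParcelTable:
    """Build a small explicit parcel table for toy tests."""
    n = len(hemispheres)
    counters = {"left": 0, "right": 0}
    if names is None:
        names = []
        for h in hemispheres:
            counters[h] += 1
            names.append(f"{'L' if h == 'left' else 'R'}_P{counters[h]:03d}")
    table = pd.DataFrame(
        {
            "name": names,
            "hemisphere": hemispheres,
            "surface_area_mm2": areas if areas is not None else [1.0] * n,
            "network": networks if networks is not None else [1] * n,
        },
        index=pd.RangeIndex(n, name="parcel_id"),
    )
    return ParcelTable(table, neighbors if neighbors is not None else [set() for _ in range(n)])


def symmetric(vals: np.ndarray) -> np.ndarray:
    """Symmetrize an upper-triangle-specified square matrix, zero diagonal."""
    vals = np.asarray(vals, dtype=float)
    out = np.triu(vals, k=1)
    return out + out.T


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized seeded cohort with the default generator settings."""
    config = axc.GeneratorConfig(n_parcels_per_hemisphere=24, n_subjects=12, seed=11)
    parcels, lengths, subjects, manifest = axc.generate_default_cohort(config)
    return config, parcels, lengths, subjects, manifest


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Deterministic limit: no pair noise, no adjacency boost, no area jitter."""
    config = axc.GeneratorConfig(
        n_parcels_per_hemisphere=10,
        n_subjects=4,
        lognormal_sigma=0.0,
        adjacency_boost=1.0,
        callosal_area_sd=0.0,
        seed=7,
    )
    parcels, lengths, subjects, manifest = axc.generate_default_cohort(config)
    return config, parcels, lengths, subjects, manifest
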