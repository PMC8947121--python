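"""Trans-terminal tract fractions ("tunnel vs highway").

A fasciculus' mid-tract axon capacity is its cross-sectional area times the
mean ipsilateral packing density. The number of *trans-terminal* axons —
those running the tract's full length between its two cortical termination
fields — is read off the axon-count matrix as the sum over (anterior x
posterior) field parcel pairs within one hemisphere. The quotient is an upper
bound on the trans-terminal fraction: it assumes every field-to-field axon
actually travels through the tract.

Termination fields are data, not code: YAML specs ship for the arcuate +
superior longitudinal fasciculus (AF/SLF) system with conservative fields
centered on Broca's area (44, 45, 6r, IFSa, IFSp, FOP4) and Wernicke's area
(PSL, RI, STV, PFcm), and liberal fields adding 47l, p47r anteriorly and PF,
PFm, PGi posteriorly. Any other tract can be specified the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .types import DEFAULT_IPSILATERAL_DENSITY, ConfigError, ParcelTable

HEMI_KEYS = ("left", "right")


@dataclass(frozen=True)
class TractSpec:
    """A fasciculus: per-hemisphere cross-sections, density, termination fields.

    ``anterior_field``/``posterior_field`` hold hemisphere-neutral parcel base
    names (e.g. ``"44"``, ``"PSL"``); they resolve against each hemisphere's
    parcels at evaluation time. ``hemisphere`` optionally restricts
    evaluation to one side; by default both are computed.
    """

    name: str
    cross_section_left: float  # mm^2
    cross_section_right: float  # mm^2
    anterior_field: frozenset[str]
    posterior_field: frozenset[str]
    density: float = DEFAULT_IPSILATERAL_DENSITY  # axons/mm^2
    hemisphere: str | None = None

    def __post_init__(self) -> None:
        if not self.cross_section_left > 0 or not self.cross_section_right > 0:
            raise ConfigError(f"tract {self.name!r}: cross-sections must be > 0")
        if not self.density > 0:
            raise ConfigError(f"tract {self.name!r}: density must be > 0")
        if not self.anterior_field or not self.posterior_field:
            raise ConfigError(f"tract {self.name!r}: termination fields must be nonempty")
        overlap = set(self.anterior_field) & set(self.posterior_field)
        if overlap:
            raise ConfigError(
                f"tract {self.name!r}: termination fields overlap: {sorted(overlap)}"
            )
        if self.hemisphere is not None and self.hemisphere not in HEMI_KEYS:
            raise ConfigError(f"tract {self.name!r}: invalid hemisphere")

    def cross_section(self, hemisphere: str) -> float:
        if hemisphere == "left":
            return self.cross_section_left
        if hemisphere == "right":
            return self.cross_section_right
        raise ValueError(f"unknown hemisphere {hemisphere!r}")

    def hemispheres(self) -> tuple[str, ...]:
        return (self.hemisphere,) if self.hemisphere else HEMI_KEYS


def tract_axon_capacity(spec: TractSpec, hemisphere: str | None = None):
    """Mid-tract axon capacity: cross-section x ipsilateral density.

    Returns a float for one hemisphere, else a dict for both.
    """
    if hemisphere is not None:
        return spec.cross_section(hemisphere) * spec.density
    return {h: spec.cross_section(h) * spec.density for h in spec.hemispheres()}


def _resolve_field(
    names: frozenset[str], parcels: ParcelTable, hemisphere: str
) -> np.ndarray:
    base = parcels.base_names()
    hemi_mask = parcels.hemispheres == hemisphere
    ids = []
    for nm in sorted(names):
        hits = np.flatnonzero((base == nm) & hemi_mask)
        if len(hits) != 1:
            raise KeyError(
                f"parcel {nm!r} not found (or ambiguous) in {hemisphere} hemisphere"
            )
        ids.append(int(hits[0]))
    return np.asarray(ids)


def trans_terminal_fraction(
    n: np.ndarray, spec: TractSpec, parcels: ParcelTable,
    hemisphere: str | None = None,
):
    """Fraction of mid-tract axons running between the two termination fields.

    Numerator: sum of axon counts over all unordered (anterior, posterior)
    parcel pairs within the hemisphere (fields are disjoint, so each pair
    appears exactly once in the anterior x posterior double sum). Denominator:
    the tract's mid-section axon capacity. Upper-bound semantics: assumes all
    field-to-field axons pass through the tract.
    """
    n = np.asarray(n, dtype=float)
    hemis = (hemisphere,) if hemisphere else spec.hemispheres()
    out = {}
    for h in hemis:
        ant = _resolve_field(spec.anterior_field, parcels, h)
        post = _resolve_field(spec.posterior_field, parcels, h)
        numerator = float(n[np.ix_(ant, post)].sum())
        out[h] = numerator / tract_axon_capacity(spec, h)
    if hemisphere:
        return out[hemisphere]
    return out


# ---------------------------------------------------------------------------
# YAML specs
# ---------------------------------------------------------------------------


def _spec_from_mapping(raw: dict, origin: str) -> TractSpec:
    if "components" in raw:
        comps = raw["components"]
        left = sum(float(c["left"]) for c in comps.values())
        right = sum(float(c["right"]) for c in comps.values())
    else:
        left = float(raw["cross_section_left"])
        right = float(raw["cross_section_right"])
    kwargs = dict(
        name=str(raw.get("name", origin)),
        cross_section_left=left,
        cross_section_right=right,
        anterior_field=frozenset(str(p) for p in raw["anterior_field"]),
        posterior_field=frozenset(str(p) for p in raw["posterior_field"]),
    )
    if "density" in raw:
        kwargs["density"] = float(raw["density"])
    if raw.get("hemisphere"):
        kwargs["hemisphere"] = str(raw["hemisphere"])
    return TractSpec(**kwargs)


def load_tract_spec(path: str | Path) -> TractSpec:
    """Load a tract spec from a YAML file (see the shipped AF/SLF specs)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: tract spec must be a mapping")
    return _spec_from_mapping(raw, str(path))


def builtin_tract_spec(name: str) -> TractSpec:
    """Load a packaged tract spec: ``afslf_conservative`` or ``afslf_liberal``."""
    ref = resources.files("axoncalib").joinpath(f"data/{name}.yaml")
    if not ref.is_file():
        available = sorted(
            p.name[:-5] for p in resources.files("axoncalib").joinpath("data").iterdir()
            if p.name.endswith(".yaml")
        )
        raise KeyError(f"no builtin tract spec {name!r}; available: {available}")
    raw = yaml.safe_load(ref.read_text())
    return _spec_from_mapping(raw, name)
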