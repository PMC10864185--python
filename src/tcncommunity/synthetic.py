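"""Synthetic spatial tissue maps with known ground-truth neighbourhoods.

Three archetypes of real tissue architecture are emulated on the unit
square with a uniform point process:

* ``compartmentalized`` -- two half-plane regions with disjoint default
  cell-type compositions, mimicking tumours whose immune cells are
  spatially segregated from neoplastic cells;
* ``mixed`` -- a single homogeneous region (high intermixing), one
  ground-truth neighbourhood;
* ``nuclei`` -- four small mirrored discs (two bilateral pairs, each
  pair sharing a composition and a ground-truth label) on a background,
  mimicking small symmetric brain nuclei.

Region borders are softened logistically: within ``boundary_softness``
of a border a cell's composition interpolates between the two regions.
A labeled two-class cohort generator pairs compartmentalized and mixed
maps and can inject a condition-specific marker-enriched disc into one
class only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datatypes import CellMap, SpatialMapSet, TCNPartition

__all__ = ["SynthConfig", "simulate_map", "simulate_labeled_cohort"]

_GEOMETRIES = ("compartmentalized", "mixed", "nuclei")

# disc centres of the nuclei geometry: two pairs mirrored across x = 0.5
_NUCLEI_CENTRES = np.array([[0.3, 0.3], [0.7, 0.3], [0.3, 0.7], [0.7, 0.7]])
_NUCLEI_PAIR = np.array([1, 1, 2, 2])  # ground-truth label per disc
_NUCLEI_RADIUS = 0.12


def _default_composition(geometry: str, m: int) -> np.ndarray:
    if geometry == "compartmentalized":
        comp = np.zeros((2, m))
        half = m // 2
        comp[0, :half] = np.linspace(0.7, 0.3, half)
        comp[1, half:] = np.linspace(0.7, 0.3, m - half)
        return comp / comp.sum(axis=1, keepdims=True)
    if geometry == "mixed":
        return np.full((1, m), 1.0 / m)
    # nuclei: background heavy on type 0, each pair heavy on its own type
    comp = np.full((3, m), 0.1 / max(m - 1, 1))
    comp[0, 0] = 0.9
    comp[1, 1 % m] = 0.9
    comp[2, 2 % m] = 0.9
    return comp / comp.sum(axis=1, keepdims=True)


@dataclass
class SynthConfig:
    """Parameters of one synthetic map.

    ``composition`` has one row per region (2 for compartmentalized,
    1 for mixed, 3 for nuclei: background + two disc pairs); rows sum to
    one.  ``boundary_softness`` is the logistic mixing width, in unit-
    square coordinates, applied at region borders.
    """

    n_cells: int = 2000
    geometry: str = "compartmentalized"
    m: int = 4
    composition: Optional[np.ndarray] = None
    boundary_softness: float = 0.02
    seed: int = 0
    type_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if self.geometry not in _GEOMETRIES:
            raise ValueError(f"geometry must be one of {_GEOMETRIES}")
        if self.n_cells < 50:
            raise ValueError("n_cells must be >= 50 for geometry fidelity")
        if self.composition is None:
            self.composition = _default_composition(self.geometry, self.m)
        self.composition = np.asarray(self.composition, dtype=float)
        n_regions = {"compartmentalized": 2, "mixed": 1, "nuclei": 3}[self.geometry]
        if self.composition.shape != (n_regions, self.m):
            raise ValueError(
                f"composition must have shape ({n_regions}, {self.m}), "
                f"got {self.composition.shape}"
            )
        if not np.allclose(self.composition.sum(axis=1), 1.0):
            raise ValueError("composition rows must sum to 1")
        if self.type_names is None:
            self.type_names = [f"type{j:02d}" for j in range(self.m)]
        elif len(self.type_names) != self.m:
            raise ValueError("type_names length must equal m")


def _region_mix(config: SynthConfig, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth region labels and per-cell composition weights.

    Returns (labels, W) with W of shape (n, n_regions); a cell's type is
    drawn from W @ composition.  With zero boundary softness W is the
    one-hot region indicator.
    """
    n = coords.shape[0]
    w = config.boundary_softness
    if config.geometry == "mixed":
        return np.zeros(n, dtype=int), np.ones((n, 1))
    if config.geometry == "compartmentalized":
        signed = coords[:, 0] - 0.5  # >0: region 1
        labels = (signed > 0).astype(int)
        if w > 0:
            p1 = 1.0 / (1.0 + np.exp(-signed / w))
        else:
            p1 = labels.astype(float)
        W = np.column_stack([1.0 - p1, p1])
        return labels, W
    # nuclei: signed distance to nearest disc boundary (negative inside)
    d = np.linalg.norm(coords[:, None, :] - _NUCLEI_CENTRES[None, :, :], axis=2)
    nearest = np.argmin(d, axis=1)
    signed = d[np.arange(n), nearest] - _NUCLEI_RADIUS
    labels = np.where(signed <= 0, _NUCLEI_PAIR[nearest], 0)
    if w > 0:
        p_in = 1.0 / (1.0 + np.exp(signed / w))
    else:
        p_in = (signed <= 0).astype(float)
    W = np.zeros((n, 3))
    W[:, 0] = 1.0 - p_in
    W[np.arange(n), _NUCLEI_PAIR[nearest]] += p_in
    return labels, W


def simulate_map(config: SynthConfig) -> tuple[CellMap, TCNPartition]:
    """Sample one map and its ground-truth TCN partition (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    coords = rng.uniform(0.0, 1.0, size=(config.n_cells, 2))
    labels, W = _region_mix(config, coords)
    probs = W @ config.composition
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.uniform(size=config.n_cells)
    cum = np.cumsum(probs, axis=1)
    type_idx = (u[:, None] > cum).sum(axis=1)
    cell_types = [config.type_names[j] for j in type_idx]
    cell_map = CellMap(
        cell_ids=[f"c{i:05d}" for i in range(config.n_cells)],
        coords=coords,
        cell_types=cell_types,
        sample_id=f"synth-{config.geometry}-{config.seed}",
        vocabulary=list(config.type_names),
    )
    return cell_map, TCNPartition(labels)


@dataclass
class CohortSpec:
    """Per-class generator settings for a labeled synthetic cohort."""

    geometry: str
    boundary_softness: float = 0.02


def simulate_labeled_cohort(
    n_per_class: int = 20,
    class_configs: Optional[Sequence[CohortSpec]] = None,
    seed: int = 0,
    n_cells: int = 800,
    condition_disc: bool = True,
    marker_fraction: float = 0.6,
    marker_baseline: float = 0.02,
    disc_radius: float = 0.15,
) -> tuple[SpatialMapSet, list[TCNPartition], str]:
    """Two-class cohort: compartmentalized (class 0) vs mixed (class 1) maps.

    All maps share a vocabulary of four base types plus a rare ``marker``
    type mixed in at ``marker_baseline`` frequency everywhere.  With
    ``condition_disc`` a central disc whose composition is
    ``marker_fraction`` marker is injected into class-1 maps only,
    emulating a condition-specific neighbourhood.  Returns the map set,
    ground-truth partitions, and the marker type name.
    """
    if class_configs is None:
        class_configs = [CohortSpec("compartmentalized"), CohortSpec("mixed")]
    if len(class_configs) != 2:
        raise ValueError("exactly two class configurations are required")
    m_base = 4
    marker = "typeMK"
    names = [f"type{j:02d}" for j in range(m_base)] + [marker]
    ss = np.random.SeedSequence(seed)
    map_seeds = ss.generate_state(2 * n_per_class) % (2**31)
    maps: list[CellMap] = []
    gts: list[TCNPartition] = []
    cohort_labels: list[int] = []
    idx = 0
    for cls, spec in enumerate(class_configs):
        base = _default_composition(spec.geometry, m_base)
        comp = np.column_stack([base * (1.0 - marker_baseline),
                                np.full(base.shape[0], marker_baseline)])
        for _ in range(n_per_class):
            cfg = SynthConfig(
                n_cells=n_cells,
                geometry=spec.geometry,
                m=m_base + 1,
                composition=comp,
                boundary_softness=spec.boundary_softness,
                seed=int(map_seeds[idx]),
                type_names=names,
            )
            cell_map, gt = simulate_map(cfg)
            if condition_disc and cls == 1:
                cell_map, gt = _inject_marker_disc(
                    cell_map, gt, marker, marker_fraction, disc_radius,
                    np.random.default_rng(int(map_seeds[idx]) + 1),
                )
            cell_map.condition = cls
            maps.append(cell_map)
            gts.append(gt)
            cohort_labels.append(cls)
            idx += 1
    return SpatialMapSet(maps=maps, labels=cohort_labels), gts, marker


def _inject_marker_disc(
    cell_map: CellMap,
    gt: TCNPartition,
    marker: str,
    marker_fraction: float,
    radius: float,
    rng: np.random.Generator,
) -> tuple[CellMap, TCNPartition]:
    """Resample types inside a central disc to be marker-dominated."""
    centre = np.array([0.5, 0.5])
    inside = np.linalg.norm(cell_map.coords - centre, axis=1) <= radius
    types = list(cell_map.cell_types)
    flip = rng.uniform(size=cell_map.n_cells) < marker_fraction
    for i in np.flatnonzero(inside & flip):
        types[i] = marker
    labels = gt.labels.copy()
    labels[inside] = labels.max() + 1
    new_map = CellMap(
        cell_ids=list(cell_map.cell_ids),
        coords=cell_map.coords.copy(),
        cell_types=types,
        sample_id=cell_map.sample_id,
        condition=cell_map.condition,
        vocabulary=list(cell_map.vocabulary),
    )
    return new_map, TCNPartition(labels)
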