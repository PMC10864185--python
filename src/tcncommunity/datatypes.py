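"""Core in-memory containers shared by all pipeline stages.

A *cell map* is one tissue sample: cell identifiers, 2D spatial
coordinates, and a categorical phenotype per cell.  A *spatial map set*
is a cohort of maps sharing one phenotype vocabulary, optionally with a
binary condition label per map (required for supervised training).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CellMap",
    "SpatialMapSet",
    "RunConfig",
    "TCNPartition",
    "SoftAssignment",
]


def _vocabulary(types: Sequence[str]) -> list[str]:
    """Deterministic (lexicographic) phenotype vocabulary."""
    return sorted(set(types))


@dataclass
class CellMap:
    """One sample's cells: ids, 2D coordinates and phenotype labels.

    Coordinates are dimensionless Euclidean; all distances used by the
    graph construction are scale-invariant.  The phenotype vocabulary is
    the lexicographically sorted union of labels, and may be widened to a
    shared cohort vocabulary via :meth:`with_vocabulary`.
    """

    cell_ids: list[str]
    coords: np.ndarray  # (n, 2) float
    cell_types: list[str]
    sample_id: str = "sample"
    condition: Optional[int] = None
    vocabulary: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.cell_ids)
        if n < 1:
            raise ValueError("a cell map must contain at least one cell")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicated cell_ids in cell map")
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords must have shape ({n}, 2), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in cell map")
        if len(self.cell_types) != n:
            raise ValueError("cell_types length does not match cell_ids")
        if not self.vocabulary:
            self.vocabulary = _vocabulary(self.cell_types)
        else:
            missing = set(self.cell_types) - set(self.vocabulary)
            if missing:
                raise ValueError(f"cell types outside vocabulary: {sorted(missing)}")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_types(self) -> int:
        return len(self.vocabulary)

    def with_vocabulary(self, vocabulary: Sequence[str]) -> "CellMap":
        """Return a copy of this map using a (wider) shared vocabulary."""
        return CellMap(
            cell_ids=list(self.cell_ids),
            coords=self.coords.copy(),
            cell_types=list(self.cell_types),
            sample_id=self.sample_id,
            condition=self.condition,
            vocabulary=list(vocabulary),
        )


@dataclass
class SpatialMapSet:
    """An ordered cohort of cell maps sharing one phenotype vocabulary."""

    maps: list[CellMap]
    labels: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.maps:
            raise ValueError("empty spatial map set")
        vocab = sorted(set().union(*(set(m.cell_types) for m in self.maps)))
        self.maps = [m.with_vocabulary(vocab) for m in self.maps]
        if self.labels is not None:
            if len(self.labels) != len(self.maps):
                raise ValueError("labels length does not match number of maps")
            values = sorted(set(self.labels))
            if len(values) != 2:
                raise ValueError(
                    f"condition labels must take exactly two values, got {values}"
                )
            remap = {v: i for i, v in enumerate(values)}
            self.labels = [remap[v] for v in self.labels]

    @property
    def vocabulary(self) -> list[str]:
        return self.maps[0].vocabulary

    def __len__(self) -> int:
        return len(self.maps)


_UNSUP_DEFAULTS = dict(d=128, n_models=20, learning_rate=1e-3, max_epochs=300)
_SUP_DEFAULTS = dict(d=512, n_models=10, learning_rate=None, max_epochs=100)


@dataclass
class RunConfig:
    """Run configuration with mode-dependent defaults.

    ``k="auto"`` resolves to the square-root-of-mean-cells rule over the
    dataset at graph-construction time.  Unset (``None``) numeric fields
    take the defaults for the selected mode: embedding dimension ``d`` is
    128 (unsupervised) or 512 (supervised), the MinCut/cross-entropy
    weight ``beta`` is 0.9, the maximum TCN count ``c`` is 10, and the
    unsupervised ensemble trains 20 models.  The supervised learning rate
    defaults to the minibatch-scaled convention (1e-4 for minibatches of
    up to 16 graphs, 1e-3 above).
    """

    mode: str = "unsupervised"
    k: int | str = "auto"
    c: int = 10
    d: Optional[int] = None
    beta: float = 0.9
    learning_rate: Optional[float] = None
    minibatch_size: Optional[int] = None
    max_epochs: Optional[int] = None
    n_models: Optional[int] = None
    n_folds: int = 10
    n_repeats: int = 10
    patience: int = 20
    min_improvement: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("unsupervised", "supervised"):
            raise ValueError(f"mode must be unsupervised|supervised, got {self.mode!r}")
        defaults = _SUP_DEFAULTS if self.mode == "supervised" else _UNSUP_DEFAULTS
        if self.d is None:
            self.d = defaults["d"]
        if self.n_models is None:
            self.n_models = defaults["n_models"]
        if self.max_epochs is None:
            self.max_epochs = defaults["max_epochs"]
        if self.learning_rate is None and self.mode == "unsupervised":
            self.learning_rate = _UNSUP_DEFAULTS["learning_rate"]
        if self.c < 2:
            raise ValueError(f"c must be >= 2, got {self.c}")
        if self.d < 1:
            raise ValueError(f"d must be >= 1, got {self.d}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")
        if self.n_models < 1:
            raise ValueError(f"n_models must be >= 1, got {self.n_models}")
        if isinstance(self.k, str):
            if self.k != "auto":
                raise ValueError(f"k must be a positive integer or 'auto', got {self.k!r}")
        elif self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")

    def resolve_learning_rate(self, minibatch_size: int) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 1e-4 if minibatch_size <= 16 else 1e-3


@dataclass
class SoftAssignment:
    """Row-stochastic n x c matrix of TCN membership probabilities."""

    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 2:
            raise ValueError("S must be a 2D matrix")
        if np.any(np.isnan(self.S)):
            raise ValueError("NaN entries in soft assignment")
        if np.any(self.S < -1e-12):
            raise ValueError("negative entries in soft assignment")
        rows = self.S.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError("soft assignment rows must sum to 1")

    @property
    def n_cells(self) -> int:
        return self.S.shape[0]

    @property
    def n_tcns(self) -> int:
        return self.S.shape[1]


@dataclass
class TCNPartition:
    """Hard per-cell TCN labels (0-based contiguous after consolidation)."""

    labels: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1D integer vector")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("negative TCN labels")

    @property
    def n_cells(self) -> int:
        return self.labels.size

    @property
    def n_tcns(self) -> int:
        return int(np.unique(self.labels).size)

    def relabeled_by_size(self) -> "TCNPartition":
        """Renumber labels 0..K-1 by descending TCN size (ties: old label)."""
        uniq, counts = np.unique(self.labels, return_counts=True)
        order = np.lexsort((uniq, -counts))
        mapping = {int(uniq[o]): rank for rank, o in enumerate(order)}
        new = np.array([mapping[int(v)] for v in self.labels], dtype=int)
        return TCNPartition(new, provenance=list(self.provenance))


def warn_unknown_keys(keys: Sequence[str]) -> None:
    if keys:
        warnings.warn(f"ignoring unknown config keys: {sorted(keys)}", stacklevel=3)
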