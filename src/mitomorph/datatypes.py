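"""Shared lightweight containers used across the pipeline stages.

All images are 2-D numpy arrays in (row, col) orientation with 0-based
coordinates. Label images use 0 for background and contiguous positive
integers for objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Feature column order used everywhere a 4-D morphology vector appears.
FEATURE_COLUMNS = ("area_px", "perimeter_px", "formfactor", "solidity")

#: Morphology class names, in canonical order.
CLASS_FRAGMENTED = "fragmented"
CLASS_FUSED = "fused"


@dataclass
class IntensityImage:
    """One 2-D fluorescence channel plus acquisition metadata.

    Parameters
    ----------
    data:
        2-D array of pixel intensities (any real dtype; rendered synthetic
        channels are uint16).
    pixel_size_um:
        Physical pixel size in micrometres per pixel.
    channel:
        Channel tag, e.g. ``"mito"``, ``"nuclei"``, ``"rho123"``, ``"pi"``,
        ``"em408"``, ``"em488"``.
    metadata:
        Free-form provenance (condition, timepoint, replicate, image id...).
    """

    data: np.ndarray
    pixel_size_um: float = 0.1
    channel: str = ""
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"IntensityImage must be 2-D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class SyntheticScene:
    """A rendered multi-channel field with its ground truth.

    ``truth_mask`` is a label image over the mitochondria channel;
    ``truth_labels[i]`` is the morphology class of object ``i + 1`` and
    ``truth_cell_map[i]`` the 1-based id of the owning cell. The nuclei
    ground truth is a separate label image.
    """

    channels: dict[str, IntensityImage]
    truth_mask: np.ndarray
    truth_labels: list[str]
    truth_cell_map: list[int]
    nuclei_mask: np.ndarray | None = None
    params: Any = None

    def __post_init__(self) -> None:
        n = int(self.truth_mask.max())
        if len(self.truth_labels) != n or len(self.truth_cell_map) != n:
            raise ValueError("one truth class and cell id required per labelled object")
        for img in self.channels.values():
            if img.shape != self.truth_mask.shape:
                raise ValueError("channel and truth_mask dimensions differ")

    @property
    def n_objects(self) -> int:
        return len(self.truth_labels)


@dataclass
class TimelapseTruth:
    """Planted per-cell trajectories for an MMP/death time-lapse.

    ``rho123_traj`` has shape (n_cells, n_frames) in arbitrary units.
    ``death_onset`` holds, per cell, the first frame index at which the cell
    is PI-positive, or ``None`` for cells that stay alive. ``pi_fraction``
    is the planted fraction of nuclear pixels rendered PI-positive once a
    cell has died (>= 0.10 by construction so the death rule can fire).
    """

    rho123_traj: np.ndarray
    death_onset: list[int | None]
    pi_fraction: float = 0.15

    def __post_init__(self) -> None:
        self.rho123_traj = np.atleast_2d(np.asarray(self.rho123_traj, dtype=float))
        if len(self.death_onset) != self.rho123_traj.shape[0]:
            raise ValueError("death_onset length must match number of cells")
        dead = any(t is not None for t in self.death_onset)
        if dead and self.pi_fraction < 0.10:
            raise ValueError("planted PI fraction for dead cells must be >= 0.10")

    @property
    def n_cells(self) -> int:
        return self.rho123_traj.shape[0]

    @property
    def n_frames(self) -> int:
        return self.rho123_traj.shape[1]


def as_feature_matrix(table: Any) -> np.ndarray:
    """Return an (n, 4) float array from a DataFrame or array-like.

    DataFrames are read through :data:`FEATURE_COLUMNS`; arrays must already
    have four columns.
    """
    if hasattr(table, "loc") and hasattr(table, "columns"):
        missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"feature table is missing columns {missing}")
        X = table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
    if X.ndim != 2 or X.shape[1] != len(FEATURE_COLUMNS):
        raise ValueError(f"expected an (n, {len(FEATURE_COLUMNS)}) feature matrix, got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    return X
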