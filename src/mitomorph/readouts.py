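"""Functional endpoints: MMP (rho123), PI death rule, FRET ATP ratio,
vehicle normalisation, nuclear-count normalisation and OPA1 cleavage.

The mitochondrial membrane potential readout is the mean rhodamine-123
intensity over each cell's cytoplasm, defined as the pixels within a
maximal Euclidean distance of 10 px around the nucleus, with contested
pixels going to the nearest nucleus. A cell counts as dead once at least
10% of its nuclear pixels are PI-positive. The ATP biosensor readout is
the ratio of mean 488-nm to mean 408-nm emission over the cell area
determined by thresholding the 408-nm image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .datatypes import IntensityImage

DEATH_PI_FRACTION = 0.10  # >= 10% of nuclear pixels PI-positive => dead


@dataclass
class CellRegion:
    """Nucleus and cytoplasm-ring pixel sets of one cell (1-based id)."""

    cell_id: int
    nucleus_pixels: tuple[np.ndarray, np.ndarray]
    cytoplasm_pixels: tuple[np.ndarray, np.ndarray]


@dataclass
class FretMeasurement:
    """One FRET ratio measurement over the thresholded cell area."""

    mean_em408: float
    mean_em488: float
    ratio: float
    n_pixels: int
    orientation: str = "488/408"
    timepoint: int | None = None


def _image_data(image) -> np.ndarray:
    return image.data if isinstance(image, IntensityImage) else np.asarray(image)


def build_cell_regions(nuclei_labels: np.ndarray, max_distance: float = 10.0) -> list[CellRegion]:
    """Cytoplasm ring per nucleus: pixels within ``max_distance`` (Euclidean).

    Nuclear pixels are excluded from every ring; a pixel within reach of
    several nuclei goes to the nearest one, ties to the lower label. Zero
    nuclei yields an empty list.
    """
    labels = np.asarray(nuclei_labels)
    n = int(labels.max())
    if n == 0:
        return []
    # per-label distance maps; argmin with ties to the first (lowest) label
    dists = np.stack([ndi.distance_transform_edt(labels != lab) for lab in range(1, n + 1)])
    nearest = np.argmin(dists, axis=0)  # 0-based component index
    min_dist = np.take_along_axis(dists, nearest[None], axis=0)[0]
    any_nucleus = labels > 0
    regions = []
    for lab in range(1, n + 1):
        ring = (nearest == lab - 1) & (min_dist > 0) & (min_dist <= max_distance) & ~any_nucleus
        regions.append(
            CellRegion(
                cell_id=lab,
                nucleus_pixels=tuple(np.nonzero(labels == lab)),
                cytoplasm_pixels=tuple(np.nonzero(ring)),
            )
        )
    return regions


def pi_positive_fraction(
    pi_image,
    nucleus_pixels: tuple[np.ndarray, np.ndarray],
    threshold: float | None = None,
) -> float:
    """Fraction of a cell's nuclear pixels above the PI threshold.

    With ``threshold=None`` an Otsu threshold over the whole PI image is
    used (the method write-ups give no pixel-level cutoff); pass an
    explicit intensity for full determinism.
    """
    pi = _image_data(pi_image).astype(float)
    if threshold is None:
        threshold = float(threshold_otsu(pi)) if pi.max() > pi.min() else np.inf
    vals = pi[nucleus_pixels]
    if vals.size == 0:
        raise ValueError("empty nucleus pixel set")
    return float((vals > threshold).mean())


def measure_mmp_timecourse(
    frames: Sequence[dict],
    regions: Sequence[CellRegion],
    pi_threshold: float | None = None,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Per-cell per-frame rho123 intensity, PI nuclear fraction and death flag.

    ``frames`` is a sequence of channel dicts with at least ``rho123`` and
    ``pi`` entries (IntensityImage or array). ``statistic`` selects mean
    (default) or integrated cytoplasmic intensity.
    """
    if statistic not in ("mean", "integrated"):
        raise ValueError("statistic must be 'mean' or 'integrated'")
    records = []
    for t, frame in enumerate(frames):
        rho = _image_data(frame["rho123"]).astype(float)
        pi = frame["pi"]
        for reg in regions:
            rr, cc = reg.cytoplasm_pixels
            vals = rho[rr, cc]
            if vals.size == 0:
                raise ValueError(f"cell {reg.cell_id} has an empty cytoplasm ring")
            intensity = vals.sum() if statistic == "integrated" else vals.mean()
            frac = pi_positive_fraction(pi, reg.nucleus_pixels, threshold=pi_threshold)
            records.append(
                {
                    "cell_id": reg.cell_id,
                    "timepoint_h": t,
                    "rho123_mean": float(intensity),
                    "pi_nuclear_fraction": frac,
                    "dead": frac >= DEATH_PI_FRACTION,
                }
            )
    return pd.DataFrame.from_records(records)


def death_fraction(measurements: pd.DataFrame, timepoint: int | None = None) -> float:
    """Fraction of cells flagged dead (at one frame, or the last by default)."""
    t = measurements["timepoint_h"].max() if timepoint is None else timepoint
    sub = measurements[measurements["timepoint_h"] == t]
    if sub.empty:
        raise ValueError(f"no measurements at timepoint {t}")
    return float(sub["dead"].mean())


def measure_fret_ratio(
    img_em408,
    img_em488,
    threshold: float | None = None,
    orientation: str = "488/408",
    timepoint: int | None = None,
) -> FretMeasurement:
    """FRET ratio over the cell area thresholded from the 408-nm image.

    The cell area is ``em408 > threshold`` (Otsu on the 408 image by
    default). Raises rather than returning NaN when the area is empty or
    the denominator channel is zero there.
    """
    a408 = _image_data(img_em408).astype(float)
    a488 = _image_data(img_em488).astype(float)
    if a408.shape != a488.shape:
        raise ValueError("emission image shapes differ")
    if threshold is None:
        if a408.max() == a408.min():
            raise ValueError("flat 408-nm image: no cell area can be determined")
        threshold = float(threshold_otsu(a408))
    area = a408 > threshold
    if not area.any():
        raise ValueError("empty cell area after thresholding the 408-nm image")
    m408 = float(a408[area].mean())
    m488 = float(a488[area].mean())
    if orientation == "488/408":
        if m408 == 0:
            raise ValueError("zero mean 408-nm intensity in cell area")
        ratio = m488 / m408
    elif orientation == "408/488":
        if m488 == 0:
            raise ValueError("zero mean 488-nm intensity in cell area")
        ratio = m408 / m488
    else:
        raise ValueError("orientation must be '488/408' or '408/488'")
    return FretMeasurement(m408, m488, float(ratio), int(area.sum()), orientation, timepoint)


def normalize_to_vehicle(series: pd.Series | np.ndarray, vehicle: pd.Series | np.ndarray):
    """Divide a condition's time series by the vehicle's at matched timepoints."""
    s = np.asarray(series, dtype=float)
    v = np.asarray(vehicle, dtype=float)
    if s.shape != v.shape:
        raise ValueError("series and vehicle must share timepoints")
    if np.any(v == 0):
        raise ValueError("vehicle value of 0 at a matched timepoint")
    out = s / v
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index, name=series.name)
    return out


def replicate_mean_se(replicates: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard error across already-normalised replicate series."""
    stacked = np.vstack([np.asarray(r, dtype=float) for r in replicates])
    mean = stacked.mean(axis=0)
    se = stacked.std(axis=0, ddof=1) / np.sqrt(stacked.shape[0])
    return mean, se


def opa1_cleavage_ratio(intensity_long: float, intensity_short: float) -> float:
    """L-OPA1 over total OPA1: L / (L + S), in [0, 1]."""
    if intensity_long < 0 or intensity_short < 0:
        raise ValueError("band intensities must be non-negative")
    total = intensity_long + intensity_short
    if total == 0:
        raise ValueError("total OPA1 intensity is zero")
    return intensity_long / total


def nuclei_count_normalize(raw_value: float, nuclei_count: int) -> float:
    """Per-image assay value divided by the image's nuclear count."""
    if nuclei_count < 1:
        raise ValueError("nuclei_count must be >= 1")
    return raw_value / nuclei_count
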