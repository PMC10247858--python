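"""Seeded synthetic microscopy scenes with known ground truth.

The generator emulates the confocal morphology-screening acquisition this
pipeline targets: single z-plane fields (nominally 1024×1024 px at
0.1 µm/px with 5–30 HepG2-like cells), a Hoechst nuclei channel and a
MitoTracker-style mitochondria channel in which each cell carries a
population of small roundish ("fragmented") and elongated/branched
("fused") objects at a controllable class fraction. Rendering is
foreground amplitude on a constant background, convolved with a Gaussian
PSF, then Poisson shot noise plus additive Gaussian read noise, written
as 16-bit unsigned intensities.

Every scene is a pure function of its :class:`SceneParams` (including the
seed): identical parameters give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

from .datatypes import (
    CLASS_FRAGMENTED,
    CLASS_FUSED,
    FEATURE_COLUMNS,
    IntensityImage,
    SyntheticScene,
    TimelapseTruth,
)

MAX_UINT16 = 65535


class PackingError(RuntimeError):
    """Requested objects cannot be placed without overlap in the field."""


def _check_range(name: str, rng: Sequence[float]) -> tuple[float, float]:
    lo, hi = float(rng[0]), float(rng[1])
    if lo > hi:
        raise ValueError(f"{name}: min {lo} > max {hi}")
    return lo, hi


@dataclass
class SceneParams:
    """Parameters of one synthetic morphology field.

    Defaults mirror the acquisition geometry the pipeline is designed for
    (1024×1024 px, 0.1 µm/px, 5–30 cells per field) and a peak
    signal-to-noise ratio of about 10 at the default foreground level.
    Shape ranges for the two morphology classes are generator assumptions
    chosen to produce clearly separated classes, not measured values.
    """

    image_size: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.1
    n_cells: int = 15
    fragmented_fraction: float = 0.5
    # small roundish objects: filled ellipses
    fragmented_shape: dict = field(
        default_factory=lambda: {"area_range": (20.0, 120.0), "eccentricity_range": (0.0, 0.6)}
    )
    # elongated/branched objects: dilated self-avoiding random walks
    fused_shape: dict = field(
        default_factory=lambda: {
            "tube_length_range": (30.0, 90.0),
            "tube_width_range": (3, 5),
            "branch_probability": 0.3,
        }
    )
    n_objects_per_cell: tuple[int, int] = (6, 12)
    nucleus_radius_range: tuple[float, float] = (35.0, 55.0)
    cell_radius_factor: float = 2.5
    psf_sigma: float = 1.0
    noise_model: dict = field(default_factory=lambda: {"gaussian_sd": 30.0, "poisson_scale": 0.04})
    background_level: float = 200.0
    foreground_level: float = 3000.0
    min_separation_px: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        self.image_size = (int(self.image_size[0]), int(self.image_size[1]))
        self.n_objects_per_cell = tuple(self.n_objects_per_cell)
        self.nucleus_radius_range = tuple(self.nucleus_radius_range)
        for shape in (self.fragmented_shape, self.fused_shape):
            for key, val in shape.items():
                if isinstance(val, (list, tuple)):
                    shape[key] = tuple(val)
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.fragmented_fraction <= 1.0:
            raise ValueError("fragmented_fraction must lie in [0, 1]")
        _check_range("area_range", self.fragmented_shape["area_range"])
        _check_range("eccentricity_range", self.fragmented_shape["eccentricity_range"])
        _check_range("tube_length_range", self.fused_shape["tube_length_range"])
        _check_range("tube_width_range", self.fused_shape["tube_width_range"])
        _check_range("n_objects_per_cell", self.n_objects_per_cell)
        _check_range("nucleus_radius_range", self.nucleus_radius_range)
        if self.psf_sigma < 0 or self.background_level < 0 or self.foreground_level <= 0:
            raise ValueError("psf_sigma/background must be >= 0 and foreground > 0")

    # -- YAML round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_size"] = list(self.image_size)
        d["n_objects_per_cell"] = list(self.n_objects_per_cell)
        d["nucleus_radius_range"] = list(self.nucleus_radius_range)
        for key in ("fragmented_shape", "fused_shape"):
            d[key] = {k: (list(v) if isinstance(v, (tuple, list)) else v) for k, v in d[key].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneParams":
        d = dict(d)
        for key in ("image_size", "n_objects_per_cell", "nucleus_radius_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SceneParams":
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# object stamps


def _fragmented_stamp(rng: np.random.Generator, shape: dict, shrink: float = 1.0) -> np.ndarray:
    """Small filled ellipse with sampled area and eccentricity."""
    a_lo, a_hi = shape["area_range"]
    e_lo, e_hi = shape["eccentricity_range"]
    area = max(rng.uniform(a_lo, a_hi) * shrink**2, 4.0)
    ecc = rng.uniform(e_lo, e_hi)
    q = np.sqrt(max(1.0 - ecc**2, 1e-6))  # minor/major axis ratio
    r_eq = np.sqrt(area / np.pi)
    a, b = r_eq / np.sqrt(q), r_eq * np.sqrt(q)
    theta = rng.uniform(0, np.pi)
    size = int(np.ceil(2 * a)) + 3
    canvas = np.zeros((size, size), dtype=bool)
    rr, cc = draw_ellipse(size // 2, size // 2, a, b, shape=canvas.shape, rotation=theta)
    canvas[rr, cc] = True
    return _crop_to_content(canvas)


def _fused_stamp(rng: np.random.Generator, shape: dict, shrink: float = 1.0) -> np.ndarray:
    """Dilated self-avoiding random walk, optionally with one side branch."""
    l_lo, l_hi = shape["tube_length_range"]
    w_lo, w_hi = shape["tube_width_range"]
    length = max(int(rng.uniform(l_lo, l_hi) * shrink), 6)
    width = int(rng.integers(int(w_lo), int(w_hi) + 1))
    size = 2 * length + 2 * width + 5
    canvas = np.zeros((size, size), dtype=bool)
    path = _random_walk(rng, canvas.shape, (size // 2, size // 2), length)
    if rng.uniform() < shape.get("branch_probability", 0.0) and len(path) > 4:
        start = path[rng.integers(1, len(path) - 1)]
        path += _random_walk(rng, canvas.shape, start, max(length // 2, 4))
    for r, c in path:
        canvas[r, c] = True
    canvas = binary_dilation(canvas, structure=disk(max(width // 2, 1)))
    return _crop_to_content(canvas)


def _random_walk(
    rng: np.random.Generator,
    shape: tuple[int, int],
    start: tuple[int, int],
    n_steps: int,
) -> list[tuple[int, int]]:
    """Approximately self-avoiding pixel walk with smooth heading changes."""
    r, c = float(start[0]), float(start[1])
    heading = rng.uniform(0, 2 * np.pi)
    visited = {(int(r), int(c))}
    path = [(int(r), int(c))]
    recent: list[tuple[int, int]] = path[:]
    for _ in range(n_steps):
        placed = False
        for _attempt in range(8):
            trial = heading + rng.normal(0, 0.35)
            nr, nc = r + np.sin(trial), c + np.cos(trial)
            pix = (int(round(nr)), int(round(nc)))
            inside = 1 <= pix[0] < shape[0] - 1 and 1 <= pix[1] < shape[1] - 1
            revisits = pix in visited and pix not in recent[-3:]
            if inside and not revisits:
                r, c, heading = nr, nc, trial
                placed = True
                break
            heading = rng.uniform(0, 2 * np.pi)
        if not placed:
            break
        if path[-1] != (int(round(r)), int(round(c))):
            path.append((int(round(r)), int(round(c))))
            visited.add(path[-1])
            recent.append(path[-1])
    return path


def _crop_to_content(mask: np.ndarray) -> np.ndarray:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


# ---------------------------------------------------------------------------
# layout and rendering


def _place_nuclei(
    rng: np.random.Generator, params: SceneParams, max_tries: int = 200
) -> tuple[np.ndarray, list[tuple[int, int]], list[float]]:
    """Place non-overlapping elliptical nuclei; returns label image, centres, radii."""
    h, w = params.image_size
    labels = np.zeros((h, w), dtype=np.int32)
    centres: list[tuple[int, int]] = []
    radii: list[float] = []
    r_lo, r_hi = params.nucleus_radius_range
    for i in range(params.n_cells):
        radius = rng.uniform(r_lo, r_hi)
        margin = int(np.ceil(radius)) + 2
        for attempt in range(max_tries):
            cr = int(rng.integers(margin, max(h - margin, margin + 1)))
            cc = int(rng.integers(margin, max(w - margin, margin + 1)))
            if all(
                (cr - pr) ** 2 + (cc - pc) ** 2 > (2.2 * max(radius, prad)) ** 2
                for (pr, pc), prad in zip(centres, radii)
            ):
                break
        else:
            raise PackingError(f"could not place nucleus {i + 1} after {max_tries} tries")
        rr, cc_px = draw_ellipse(cr, cc, radius, radius * rng.uniform(0.8, 1.0), shape=(h, w))
        labels[rr, cc_px] = i + 1
        centres.append((cr, cc))
        radii.append(radius)
    return labels, centres, radii


def _apply_noise(img: np.ndarray, noise: dict, rng: np.random.Generator) -> np.ndarray:
    scale = float(noise.get("poisson_scale", 0.0))
    sd = float(noise.get("gaussian_sd", 0.0))
    out = img.astype(float)
    if scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * scale).astype(float) / scale
    if sd > 0:
        out = out + rng.normal(0.0, sd, size=out.shape)
    return out


def render_channel(
    mask_amplitude: np.ndarray,
    params: SceneParams,
    rng: np.random.Generator,
    psf_sigma: float | None = None,
) -> np.ndarray:
    """Background + amplitude image → PSF blur → noise → clipped uint16."""
    img = params.background_level + mask_amplitude.astype(float)
    sigma = params.psf_sigma if psf_sigma is None else psf_sigma
    if sigma > 0:
        img = ndi.gaussian_filter(img, sigma)
    img = _apply_noise(img, params.noise_model, rng)
    return np.clip(np.round(img), 0, MAX_UINT16).astype(np.uint16)


def generate_mito_scene(params: SceneParams, max_tries: int = 400) -> SyntheticScene:
    """Render one nuclei + mitochondria field with per-object ground truth.

    Mitochondrial objects are placed cell-by-cell inside a disk around each
    nucleus, never crossing the image border, and kept at least
    ``params.min_separation_px`` apart so ground truth stays recoverable
    after PSF blur. Each object's class is an independent Bernoulli draw at
    ``fragmented_fraction``.

    Raises
    ------
    PackingError
        If an object cannot be placed after ``max_tries`` attempts.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    nuclei_labels, centres, radii = _place_nuclei(rng, params)

    truth = np.zeros((h, w), dtype=np.int32)
    occupied = nuclei_labels > 0
    pad = max(params.min_separation_px // 2, 1)
    border = max(int(np.ceil(4 * params.psf_sigma)) + 1, pad + 1)
    truth_labels: list[str] = []
    truth_cells: list[int] = []
    next_label = 1
    n_lo, n_hi = params.n_objects_per_cell
    for cell_id, ((cr, cc), radius) in enumerate(zip(centres, radii), start=1):
        n_obj = int(rng.integers(int(n_lo), int(n_hi) + 1))
        reach = params.cell_radius_factor * radius
        for _ in range(n_obj):
            is_frag = rng.uniform() < params.fragmented_fraction
            placed = False
            for shrink in (1.0, 1.0, 0.75, 0.55):  # resample smaller if it will not fit
                if placed:
                    break
                stamp = (
                    _fragmented_stamp(rng, params.fragmented_shape, shrink)
                    if is_frag
                    else _fused_stamp(rng, params.fused_shape, shrink)
                )
                sh, sw = stamp.shape
                # dilated footprint enforces >= 2*pad px gap between objects
                grown = binary_dilation(np.pad(stamp, pad), structure=disk(pad))
                for _attempt in range(max_tries):
                    if _attempt < max_tries // 2:
                        # preferred: annulus around the owning nucleus
                        ang = rng.uniform(0, 2 * np.pi)
                        dist = radius * 1.1 + rng.uniform(0, max(reach - radius, 1.0))
                        r0 = int(cr + dist * np.sin(ang)) - sh // 2
                        c0 = int(cc + dist * np.cos(ang)) - sw // 2
                    else:
                        # crowded field: fall back to anywhere that fits
                        r0 = int(rng.integers(border, max(h - border - sh, border + 1)))
                        c0 = int(rng.integers(border, max(w - border - sw, border + 1)))
                    if r0 < border or c0 < border or r0 + sh > h - border or c0 + sw > w - border:
                        continue
                    window = occupied[r0 - pad : r0 + sh + pad, c0 - pad : c0 + sw + pad]
                    if np.any(window & grown):
                        continue
                    truth[r0 : r0 + sh, c0 : c0 + sw][stamp] = next_label
                    window |= grown
                    placed = True
                    break
            if not placed:
                raise PackingError(
                    f"could not place object for cell {cell_id} after {max_tries} tries"
                )
            truth_labels.append(CLASS_FRAGMENTED if is_frag else CLASS_FUSED)
            truth_cells.append(cell_id)
            next_label += 1

    mito = render_channel((truth > 0) * params.foreground_level, params, rng)
    nuclei = render_channel((nuclei_labels > 0) * params.foreground_level, params, rng)
    meta = {"seed": params.seed}
    return SyntheticScene(
        channels={
            "mito": IntensityImage(mito, params.pixel_size, "mito", dict(meta)),
            "nuclei": IntensityImage(nuclei, params.pixel_size, "nuclei", dict(meta)),
        },
        truth_mask=truth,
        truth_labels=truth_labels,
        truth_cell_map=truth_cells,
        nuclei_mask=nuclei_labels,
        params=params,
    )


# ---------------------------------------------------------------------------
# MMP / death time-lapse


def generate_mmp_timelapse(params: SceneParams, truth: TimelapseTruth) -> list[SyntheticScene]:
    """Render an hourly Hoechst/rho123/PI stack from planted trajectories.

    The cell layout is drawn once from ``params``; per frame, each cell's
    cytoplasm ring (10 px around its nucleus) is rendered at that cell's
    planted rho123 intensity, and cells past their planted death onset get
    an exact planted fraction of their nuclear pixels set PI-positive.
    No PSF blur is applied (the readouts are regional means, not shapes).
    """
    from .readouts import build_cell_regions  # runtime import avoids a module cycle

    if truth.n_cells != params.n_cells:
        raise ValueError("trajectory cell count must match params.n_cells")
    rng = np.random.default_rng(params.seed)
    nuclei_labels, _, _ = _place_nuclei(rng, params)
    regions = build_cell_regions(nuclei_labels, max_distance=10)

    # fixed PI-positive pixel subset per dead cell, constant across frames
    pi_pixels: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for reg in regions:
        onset = truth.death_onset[reg.cell_id - 1]
        if onset is None:
            continue
        rr, cc = reg.nucleus_pixels
        n_pos = int(round(truth.pi_fraction * rr.size))
        idx = rng.choice(rr.size, size=n_pos, replace=False)
        pi_pixels[reg.cell_id] = (rr[idx], cc[idx])

    frames: list[SyntheticScene] = []
    h, w = params.image_size
    for t in range(truth.n_frames):
        rho = np.zeros((h, w), dtype=float)
        pi = np.zeros((h, w), dtype=float)
        for reg in regions:
            rr, cc = reg.cytoplasm_pixels
            rho[rr, cc] = truth.rho123_traj[reg.cell_id - 1, t]
            onset = truth.death_onset[reg.cell_id - 1]
            if onset is not None and t >= onset:
                pr, pc = pi_pixels[reg.cell_id]
                pi[pr, pc] = params.foreground_level
        frame_rng = np.random.default_rng((params.seed, t))
        chans = {
            "nuclei": IntensityImage(
                render_channel((nuclei_labels > 0) * params.foreground_level, params, frame_rng, 0.0),
                params.pixel_size,
                "nuclei",
                {"frame": t},
            ),
            "rho123": IntensityImage(
                render_channel(rho, params, frame_rng, 0.0), params.pixel_size, "rho123", {"frame": t}
            ),
            "pi": IntensityImage(
                render_channel(pi, params, frame_rng, 0.0), params.pixel_size, "pi", {"frame": t}
            ),
        }
        frames.append(
            SyntheticScene(
                channels=chans,
                truth_mask=np.zeros((h, w), dtype=np.int32),
                truth_labels=[],
                truth_cell_map=[],
                nuclei_mask=nuclei_labels,
                params=params,
            )
        )
    return frames


# ---------------------------------------------------------------------------
# FRET biosensor pair


def generate_fret_pair(
    planted_ratio_map: np.ndarray,
    cell_mask: np.ndarray | None = None,
    base_level: float = 2000.0,
    background_level: float = 50.0,
    noise: dict | None = None,
    seed: int = 0,
) -> tuple[IntensityImage, IntensityImage]:
    """Render a (408 nm, 488 nm) emission image pair with a planted ratio.

    Inside ``cell_mask`` the 408-em image is ``base_level`` and the 488-em
    image is ``base_level × planted_ratio_map``, so the expected per-pixel
    488/408 ratio equals the planted map. Outside the mask both channels sit
    at ``background_level``.
    """
    ratio = np.asarray(planted_ratio_map, dtype=float)
    if cell_mask is None:
        cell_mask = np.ones_like(ratio, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.shape != ratio.shape:
        raise ValueError("cell_mask and ratio map shapes differ")
    if np.any(ratio[cell_mask] <= 0):
        raise ValueError("planted ratio must be strictly positive inside the cell area")
    rng = np.random.default_rng(seed)
    noise = noise or {}
    em408 = np.where(cell_mask, base_level, background_level)
    em488 = np.where(cell_mask, base_level * ratio, background_level)
    em408 = np.clip(np.round(_apply_noise(em408, noise, rng)), 0, MAX_UINT16).astype(np.uint16)
    em488 = np.clip(np.round(_apply_noise(em488, noise, rng)), 0, MAX_UINT16).astype(np.uint16)
    return (
        IntensityImage(em408, channel="em408"),
        IntensityImage(em488, channel="em488"),
    )


# ---------------------------------------------------------------------------
# direct feature-space sampling


def sample_feature_table(model, n_objects: int, seed: int = 0):
    """Draw an i.i.d. feature table from a 2-component Gaussian mixture.

    ``model`` needs ``weights``, ``means`` and ``covariances`` attributes
    (a fitted :class:`~mitomorph.gmm.GmmModel` works). Returns a DataFrame
    with the canonical feature columns plus the true component index per row.
    """
    import pandas as pd

    weights = np.asarray(model.weights, dtype=float)
    means = np.asarray(model.means, dtype=float)
    covs = np.asarray(model.covariances, dtype=float)
    if not np.isclose(weights.sum(), 1.0, atol=1e-9):
        raise ValueError("component weights must sum to 1")
    for k, cov in enumerate(covs):
        if not np.allclose(cov, cov.T):
            raise ValueError(f"covariance {k} is not symmetric")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"covariance {k} is not positive definite") from err
    rng = np.random.default_rng(seed)
    d = means.shape[1]
    if n_objects == 0:
        return (
            pd.DataFrame(columns=list(FEATURE_COLUMNS[:d])),
            np.zeros(0, dtype=int),
        )
    labels = rng.choice(len(weights), size=n_objects, p=weights)
    X = np.empty((n_objects, d))
    for k in range(len(weights)):
        sel = labels == k
        if sel.any():
            X[sel] = rng.multivariate_normal(means[k], covs[k], size=int(sel.sum()))
    return pd.DataFrame(X, columns=list(FEATURE_COLUMNS[:d])), labels
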