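"""Reading and writing the pipeline's on-disk formats.

Images travel as single-channel TIFF (8/16-bit grayscale in, 16-bit out),
label images as 16-bit TIFF, masks as 8-bit TIFF, annotations and feature
tables as CSV, scene parameters as YAML and mixture models as JSON.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .datatypes import IntensityImage, SyntheticScene
from .segmentation import PixelAnnotation


def read_image(path, pixel_size_um: float = 0.1, channel: str = "") -> IntensityImage:
    data = tifffile.imread(str(path))
    return IntensityImage(np.asarray(data), pixel_size_um, channel, {"path": str(path)})


def write_image(path, image) -> None:
    data = image.data if isinstance(image, IntensityImage) else np.asarray(image)
    tifffile.imwrite(str(path), np.asarray(data))


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), (np.asarray(mask, bool)).astype(np.uint8) * 255)


def write_labels(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def write_scene(scene: SyntheticScene, out_dir, stem: str = "scene", multipage: bool = False) -> dict:
    """Write a synthetic scene's channels, truth labels and truth CSV.

    With ``multipage=True`` all channels go into one multi-page TIFF in
    sorted channel order; otherwise one file per channel. Returns the
    written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    names = sorted(scene.channels)
    if multipage:
        stack = np.stack([scene.channels[n].data for n in names])
        paths["channels"] = out / f"{stem}_channels.tif"
        tifffile.imwrite(str(paths["channels"]), stack, metadata={"channels": names})
    else:
        for name in names:
            paths[name] = out / f"{stem}_{name}.tif"
            write_image(paths[name], scene.channels[name])
    paths["truth_mask"] = out / f"{stem}_truth_labels.tif"
    write_labels(paths["truth_mask"], scene.truth_mask)
    truth = pd.DataFrame(
        {
            "object_id": np.arange(1, scene.n_objects + 1),
            "truth_class": scene.truth_labels,
            "cell_id": scene.truth_cell_map,
        }
    )
    paths["truth_csv"] = out / f"{stem}_truth.csv"
    truth.to_csv(paths["truth_csv"], index=False)
    if scene.params is not None:
        paths["params"] = out / f"{stem}_params.yaml"
        paths["params"].write_text(scene.params.to_yaml())
    return paths


def write_annotations_csv(path, annotations: Sequence[PixelAnnotation]) -> None:
    rows = []
    for ann in annotations:
        for r, c, l in zip(ann.rows, ann.cols, ann.labels):
            rows.append({"image_id": ann.image_id, "row": r, "col": c, "label": l})
    pd.DataFrame(rows, columns=["image_id", "row", "col", "label"]).to_csv(path, index=False)


def read_annotations_csv(path) -> list[PixelAnnotation]:
    df = pd.read_csv(path)
    out = []
    for image_id, sub in df.groupby("image_id", sort=True):
        out.append(
            PixelAnnotation(
                str(image_id),
                sub["row"].to_numpy(int),
                sub["col"].to_numpy(int),
                sub["label"].to_numpy(int),
            )
        )
    return out
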