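"""End-to-end orchestration: simulate → segment → measure → classify → stats.

A single YAML (or dict) config drives the whole run. Every stage seed is
derived deterministically from the master seed, so a config run twice
produces byte-identical CSV/JSON outputs. Stage timings are logged to
stderr only; the on-disk run log records seeds and package versions so
reruns stay reproducible and comparable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import gmm as gmm_mod
from . import segmentation, stats, synthetic
from .benchmarks import desk_scene_params
from .features import measure_objects

logger = logging.getLogger("mitomorph")

DEFAULT_CONFIG = {
    "seed": 0,
    "scene": {},  # overrides of the desk-scale SceneParams
    "conditions": [
        {"name": "vehicle", "fragmented_fraction": 0.3},
        {"name": "oligomycin", "fragmented_fraction": 0.6},
    ],
    "n_replicates": 3,
    "n_images_per_replicate": 2,
    "segmentation": {"n_trees": 100, "n_annotation_px": 400, "n_train_scenes": 2},
    "gmm": {"n_restarts": 10, "formfactor_formula": "standard"},
    "stats": {"control": "vehicle", "alpha": 0.05},
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    features: pd.DataFrame
    fractions: pd.DataFrame
    summary: pd.DataFrame
    model: gmm_mod.GmmModel
    stats_results: dict
    out_dir: Path | None = None
    written: dict = field(default_factory=dict)


def load_config(source) -> dict:
    if isinstance(source, (str, Path)):
        cfg = yaml.safe_load(Path(source).read_text())
    else:
        cfg = dict(source)
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _stage(name):
    def wrap(fn):
        def run(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - re-tag with the stage name
                raise StageError(f"stage {name!r} failed: {err}") from err
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out

        return run

    return wrap


@_stage("simulate")
def _simulate(cfg) -> list[dict]:
    seq = np.random.SeedSequence(cfg["seed"])
    n_scenes = len(cfg["conditions"]) * cfg["n_replicates"] * cfg["n_images_per_replicate"]
    seeds = seq.generate_state(n_scenes + cfg["segmentation"]["n_train_scenes"]).tolist()
    records = []
    i = 0
    for cond in cfg["conditions"]:
        for rep in range(cfg["n_replicates"]):
            for img in range(cfg["n_images_per_replicate"]):
                params = desk_scene_params(
                    seed=int(seeds[i]) % 2**31,
                    fragmented_fraction=cond["fragmented_fraction"],
                    **cfg["scene"],
                )
                records.append(
                    {
                        "condition": cond["name"],
                        "replicate": rep,
                        "image_id": f"{cond['name']}_r{rep}_i{img}",
                        "scene": synthetic.generate_mito_scene(params),
                    }
                )
                i += 1
    # spare scenes for classifier training (vehicle-like, first condition)
    train_scenes = []
    for j in range(cfg["segmentation"]["n_train_scenes"]):
        params = desk_scene_params(
            seed=int(seeds[n_scenes + j]) % 2**31,
            fragmented_fraction=cfg["conditions"][0]["fragmented_fraction"],
            **cfg["scene"],
        )
        train_scenes.append(synthetic.generate_mito_scene(params))
    return records, train_scenes


@_stage("segment")
def _segment(cfg, records, train_scenes):
    seg_cfg = cfg["segmentation"]
    images, anns = [], []
    for k, scene in enumerate(train_scenes):
        images.append(scene.channels["mito"].data)
        anns.append(
            segmentation.sample_annotations_from_truth(
                scene, seg_cfg["n_annotation_px"], seed=cfg["seed"] + k
            )
        )
    model = segmentation.train_pixel_classifier(
        images, anns, n_trees=seg_cfg["n_trees"], seed=cfg["seed"]
    )
    for rec in records:
        mask = segmentation.predict_segmentation(model, rec["scene"].channels["mito"].data)
        rec["labels"] = segmentation.label_objects(mask, connectivity=2)
    return model


@_stage("measure")
def _measure(cfg, records) -> pd.DataFrame:
    tables = []
    for rec in records:
        tables.append(
            measure_objects(
                rec["labels"],
                {
                    "image_id": rec["image_id"],
                    "condition": rec["condition"],
                    "replicate": rec["replicate"],
                },
                formfactor_formula=cfg["gmm"].get("formfactor_formula", "standard"),
            )
        )
    features = pd.concat(tables, ignore_index=True)
    if features.empty:
        raise ValueError("no objects segmented in any image")
    return features


@_stage("classify")
def _classify(cfg, features):
    model = gmm_mod.fit_gmm(features, n_restarts=cfg["gmm"]["n_restarts"], seed=cfg["seed"])
    assignment = gmm_mod.assign_classes(model, features)
    fractions = gmm_mod.fraction_fragmented(
        assignment, features, group_by=["condition", "replicate"]
    )
    summary = gmm_mod.replicate_summary(fractions)
    return model, assignment, fractions, summary


@_stage("stats")
def _stats(cfg, fractions) -> dict:
    control = cfg["stats"]["control"]
    alpha = cfg["stats"]["alpha"]
    conditions = fractions["condition"].unique()
    results: dict = {}
    if len(conditions) < 2:
        return results
    enough = fractions.groupby("condition")["fraction_by_count"].count().min() >= 2
    if not enough:
        return results
    for value_col in ("fraction_by_count", "fraction_by_mass"):
        res = stats.compare_to_control(
            fractions, value_col, control=control, alpha=alpha, seed=cfg["seed"]
        )
        results[value_col] = res
    return results


def run_pipeline(config, out_dir=None) -> PipelineResult:
    """Execute the full morphology pipeline from a config dict/YAML path."""
    cfg = load_config(config)
    records, train_scenes = _simulate(cfg)
    seg_model = _segment(cfg, records, train_scenes)
    features = _measure(cfg, records)
    model, assignment, fractions, summary = _classify(cfg, features)
    stats_results = _stats(cfg, fractions)

    result = PipelineResult(features, fractions, summary, model, stats_results)
    if out_dir is not None:
        result.out_dir = Path(out_dir)
        result.written = _write_outputs(cfg, result)
    return result


def _float_fmt(x):  # stable CSV formatting for byte-identical reruns
    return f"{x:.10g}"


def _write_outputs(cfg, result: PipelineResult) -> dict:
    out = result.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in (
        ("features", result.features),
        ("fractions", result.fractions),
        ("summary", result.summary),
    ):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        written[name] = path

    written["gmm_model"] = out / "gmm_model.json"
    written["gmm_model"].write_text(result.model.to_json())

    report = {"config": cfg, "conditions": {}}
    for _, row in result.summary.iterrows():
        report["conditions"][row["condition"]] = {
            "fraction_by_count_mean": row["fraction_by_count_mean"],
            "fraction_by_count_se": None
            if pd.isna(row["fraction_by_count_se"])
            else row["fraction_by_count_se"],
            "fraction_by_mass_mean": row["fraction_by_mass_mean"],
        }
    for value_col, res in result.stats_results.items():
        report.setdefault("stats", {})[value_col] = {
            "anova_F": res.f_statistic,
            "anova_p": res.p_anova,
            "comparisons": res.comparisons.to_dict(orient="records"),
        }
    written["report"] = out / "report.json"
    written["report"].write_text(json.dumps(report, indent=2, sort_keys=True, default=float))

    log = [
        f"mitomorph {__version__}",
        f"numpy {np.__version__}",
        f"pandas {pd.__version__}",
        f"seed {cfg['seed']}",
        f"n_scenes {len(result.features['image_id'].unique())}",
    ]
    written["run_log"] = out / "run_log.txt"
    written["run_log"].write_text("\n".join(log) + "\n")
    return written
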