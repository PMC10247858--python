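"""Seeded benchmark experiments exercising the whole pipeline.

These are the package's own quality checks, shared by the test suite and
the reproduction script: segmentation accuracy against generator ground
truth, mixture parameter recovery from simulated feature tables,
end-to-end morphology classification, planted-value recovery of the
functional readouts, and null-calibration of the statistics.

Problem sizes default to desk scale (256×256 px fields, a handful of
cells) so a full run stays in the minutes range on one CPU.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import gmm as gmm_mod
from . import readouts, segmentation, stats, synthetic
from .datatypes import CLASS_FRAGMENTED, TimelapseTruth
from .features import measure_objects


def desk_scene_params(seed: int = 0, **overrides) -> synthetic.SceneParams:
    """Scaled-down default field: 256×256 px, 5 cells, default SNR."""
    kwargs = dict(
        image_size=(256, 256),
        n_cells=5,
        nucleus_radius_range=(12.0, 18.0),
        n_objects_per_cell=(4, 8),
        fragmented_shape={"area_range": (20.0, 120.0), "eccentricity_range": (0.0, 0.6)},
        fused_shape={
            "tube_length_range": (20.0, 50.0),
            "tube_width_range": (3, 5),
            "branch_probability": 0.3,
        },
        seed=seed,
    )
    kwargs.update(overrides)
    return synthetic.SceneParams(**kwargs)


# ---------------------------------------------------------------------------
# reference mixture for simulation studies


def reference_mixture() -> gmm_mod.GmmModel:
    """A well-separated fragmented/fused mixture in the 4-D feature space.

    Means and spreads echo what the generator's two classes produce (small
    round high-solidity puncta vs large elongated low-solidity networks);
    the two components are >4 apart in pooled Mahalanobis distance.
    """
    means = np.array(
        [
            [60.0, 30.0, 0.75, 0.95],  # fragmented
            [220.0, 110.0, 0.25, 0.60],  # fused
        ]
    )
    cov_frag = np.diag([15.0**2, 6.0**2, 0.08**2, 0.03**2])
    cov_frag[0, 1] = cov_frag[1, 0] = 0.5 * 15.0 * 6.0
    cov_fused = np.diag([50.0**2, 25.0**2, 0.07**2, 0.08**2])
    cov_fused[0, 1] = cov_fused[1, 0] = 0.6 * 50.0 * 25.0
    return gmm_mod.GmmModel(
        weights=np.array([0.45, 0.55]),
        means=means,
        covariances=np.stack([cov_frag, cov_fused]),
        neg_log_likelihood=np.nan,
        n_restarts=0,
        seed=None,
        class_map={0: "fragmented", 1: "fused"},
    )


def mahalanobis_separation(model: gmm_mod.GmmModel) -> float:
    """Between-mean Mahalanobis distance under the pooled covariance."""
    pooled = model.covariances.mean(axis=0)
    diff = model.means[1] - model.means[0]
    return float(np.sqrt(diff @ np.linalg.solve(pooled, diff)))


def _match_components(true_means: np.ndarray, est_means: np.ndarray) -> np.ndarray:
    """Permutation of estimated components best matching the true means."""
    if np.linalg.norm(est_means[0] - true_means[0]) + np.linalg.norm(
        est_means[1] - true_means[1]
    ) <= np.linalg.norm(est_means[0] - true_means[1]) + np.linalg.norm(
        est_means[1] - true_means[0]
    ):
        return np.array([0, 1])
    return np.array([1, 0])


def gmm_recovery_experiment(
    n_objects: int = 10_000, seeds=range(10), n_restarts: int = 5
) -> pd.DataFrame:
    """Fit the EM on samples from the reference mixture; report errors.

    Per seed: maximum relative error over all mean coordinates and the
    absolute weight error, after matching components to the truth.
    """
    truth = reference_mixture()
    rows = []
    for seed in seeds:
        table, _ = synthetic.sample_feature_table(truth, n_objects, seed=seed)
        model = gmm_mod.fit_gmm(table, n_restarts=n_restarts, seed=seed)
        perm = _match_components(truth.means, model.means)
        mean_rel = np.abs(model.means[perm] - truth.means) / np.abs(truth.means)
        rows.append(
            {
                "seed": int(seed),
                "max_mean_rel_error": float(mean_rel.max()),
                "weight_abs_error": float(np.abs(model.weights[perm] - truth.weights).max()),
            }
        )
    return pd.DataFrame(rows)


def subsampling_variance_experiment(
    n_objects: int = 20_000,
    fractions=(0.5, 0.1, 0.002),
    n_reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Spread of refit mean estimates at decreasing object fractions.

    Mirrors the data-size robustness analysis: halving the data should
    barely move the component means, while keeping only 1/500 of the
    objects visibly inflates the estimate spread.
    """
    truth = reference_mixture()
    table, _ = synthetic.sample_feature_table(truth, n_objects, seed=seed)
    table["compound"] = "pooled"
    table["image_id"] = np.arange(len(table)) % 50
    rows = []
    for frac in fractions:
        report = gmm_mod.robustness_analysis(
            table, "object_fraction", n_reps=n_reps, fraction=frac, seed=seed, n_restarts=3
        )
        area_means = report[
            (report["feature"] == "area_px") & (report["component"] == CLASS_FRAGMENTED)
        ]["mean"].to_numpy(float)
        area_means = area_means[np.isfinite(area_means)]
        rows.append(
            {
                "fraction": frac,
                "n_valid_fits": len(area_means),
                "area_mean_sd": float(np.std(area_means, ddof=1)) if len(area_means) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# segmentation benchmark


def train_default_classifier(
    seed: int = 0, n_train_scenes: int = 2, n_px: int = 400, n_trees: int = 100, **scene_overrides
) -> segmentation.PixelClassifierModel:
    """Train the default LoG+DoG forest on truth-annotated synthetic scenes."""
    images, anns = [], []
    for i in range(n_train_scenes):
        scene = synthetic.generate_mito_scene(desk_scene_params(seed=seed + i, **scene_overrides))
        images.append(scene.channels["mito"].data)
        anns.append(segmentation.sample_annotations_from_truth(scene, n_px, seed=seed + i))
    return segmentation.train_pixel_classifier(images, anns, n_trees=n_trees, seed=seed)


def segmentation_iou_benchmark(
    n_scenes: int = 20, seed: int = 0, model=None, **scene_overrides
) -> pd.DataFrame:
    """Mask IoU against generator truth across fresh seeded scenes."""
    model = model or train_default_classifier(seed=seed + 1000, **scene_overrides)
    rows = []
    for i in range(n_scenes):
        scene = synthetic.generate_mito_scene(desk_scene_params(seed=seed + i, **scene_overrides))
        mask = segmentation.predict_segmentation(model, scene.channels["mito"].data)
        rows.append(
            {"scene_seed": seed + i, "iou": segmentation.mask_iou(mask, scene.truth_mask > 0)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end morphology classification


def classification_benchmark(
    fragmented_fraction: float = 0.5,
    n_replicates: int = 3,
    scenes_per_replicate: int = 2,
    seed: int = 0,
    n_restarts: int = 10,
) -> dict:
    """Generate scenes, measure truth objects, fit the mixture, classify.

    Returns per-object agreement with the generator's class labels and the
    count-based fragmented fraction per replicate (to compare with the
    planted fraction). Features are measured on the ground-truth masks so
    the experiment isolates the feature + mixture stages; segmentation
    accuracy is benchmarked separately.
    """
    tables = []
    truth_classes = []
    idx = 0
    for rep in range(n_replicates):
        for _ in range(scenes_per_replicate):
            scene = synthetic.generate_mito_scene(
                desk_scene_params(seed=seed + idx, fragmented_fraction=fragmented_fraction)
            )
            tab = measure_objects(
                scene.truth_mask, {"image_id": f"img{idx}", "replicate": rep}
            )
            tables.append(tab)
            truth_classes.extend(scene.truth_labels)
            idx += 1
    features = pd.concat(tables, ignore_index=True)
    model = gmm_mod.fit_gmm(features, n_restarts=n_restarts, seed=seed)
    assignment = gmm_mod.assign_classes(model, features)
    truth_arr = np.array(truth_classes)
    agreement = float((assignment.class_names == truth_arr).mean())
    fractions = gmm_mod.fraction_fragmented(assignment, features, group_by=["replicate"])
    return {
        "agreement": agreement,
        "n_objects": len(features),
        "fractions_by_replicate": fractions,
        "mean_count_fraction": float(fractions["fraction_by_count"].mean()),
        "planted_fraction": fragmented_fraction,
        "model": model,
    }


# ---------------------------------------------------------------------------
# functional readout recovery


def mmp_recovery_experiment(
    seed: int = 0, n_cells: int = 10, n_frames: int = 6, n_dead: int = 3, rho_level: float = 1000.0
) -> dict:
    """Recover planted rho123 levels and the planted death fraction."""
    params = desk_scene_params(seed=seed, n_cells=n_cells, nucleus_radius_range=(8.0, 12.0))
    rng = np.random.default_rng(seed)
    traj = np.full((n_cells, n_frames), rho_level)
    onsets: list[int | None] = [None] * n_cells
    for cell in rng.choice(n_cells, size=n_dead, replace=False):
        onsets[cell] = int(rng.integers(1, max(n_frames - 1, 2)))
    truth = TimelapseTruth(traj, onsets, pi_fraction=0.15)
    frames = synthetic.generate_mmp_timelapse(params, truth)
    regions = readouts.build_cell_regions(frames[0].nuclei_mask, max_distance=10)
    table = readouts.measure_mmp_timecourse(
        [f.channels for f in frames], regions, pi_threshold=params.foreground_level / 2
    )
    measured = table[table["timepoint_h"] == 0]["rho123_mean"].to_numpy(float)
    noise_sd = float(
        np.sqrt(
            (params.background_level + rho_level) / params.noise_model["poisson_scale"]
            + params.noise_model["gaussian_sd"] ** 2
        )
    )
    return {
        "planted_rho123": rho_level + params.background_level,
        "measured_rho123_mean": float(measured.mean()),
        "per_cell_noise_sd": noise_sd,
        "death_fraction": readouts.death_fraction(table),
        "planted_death_fraction": n_dead / n_cells,
        "table": table,
    }


def fret_recovery_experiment(planted_ratio: float = 0.5, seed: int = 0, size: int = 128) -> dict:
    """Recover a planted uniform FRET ratio inside a synthetic cell area."""
    rr, cc = np.mgrid[0:size, 0:size]
    cell = (rr - size // 2) ** 2 + (cc - size // 2) ** 2 < (size // 3) ** 2
    ratio_map = np.full((size, size), planted_ratio)
    em408, em488 = synthetic.generate_fret_pair(
        ratio_map, cell, noise={"gaussian_sd": 20.0}, seed=seed
    )
    meas = readouts.measure_fret_ratio(em408, em488)
    return {"planted": planted_ratio, "recovered": meas.ratio, "n_pixels": meas.n_pixels}


# ---------------------------------------------------------------------------
# statistics calibration


def anova_type1_simulation(
    n_sims: int = 10_000, k_groups: int = 4, n_per_group: int = 6, alpha: float = 0.05, seed: int = 0
) -> float:
    """Rejection rate of the one-way ANOVA under the global null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        data = rng.normal(size=(k_groups, n_per_group))
        groups = stats.GroupedMeasurements(
            control="g0", groups={f"g{i}": data[i] for i in range(k_groups)}
        )
        _, p = stats.anova_oneway(groups)
        rejections += p < alpha
    return rejections / n_sims


def dunnett_fwer_simulation(
    n_sims: int = 5_000,
    k_treatments: int = 5,
    n_per_group: int = 6,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Familywise error of Dunnett's test under the global null."""
    rng = np.random.default_rng(seed)
    errors = 0
    for sim in range(n_sims):
        data = rng.normal(size=(k_treatments + 1, n_per_group))
        groups = stats.GroupedMeasurements(
            control="control",
            groups={"control": data[0], **{f"t{i}": data[i + 1] for i in range(k_treatments)}},
        )
        res = stats.dunnett_test(groups, alpha=alpha, seed=sim)
        errors += bool(res.comparisons["significant"].any())
    return errors / n_sims
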