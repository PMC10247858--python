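"""Two-component Gaussian mixture over the 4-D morphology feature space.

The mixture is fit by multi-restart expectation–maximization on the raw
(unstandardised) features area, perimeter, formfactor, solidity, with full
covariances. Each restart initialises the means at randomly chosen data
points, the covariances at the pooled data covariance and the weights
uniformly; the restart with the lowest negative log-likelihood wins
(100 restarts by default). Components are named afterwards: the component
with the smaller mean area is called "fragmented", the other "fused" —
small roundish puncta versus large irregular networks.

Objects are assigned to the class with the highest posterior probability,
and condition-level fragmentation is summarised two ways: the fraction of
objects classified fragmented (count-based) and the fraction of total
object area held by fragmented objects (mass-based).

Restart seeds are drawn from a spawned ``numpy`` SeedSequence stream, so
the best of *n* restarts can never be worse than the best of the first
*m < n* restarts on the same data and master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .datatypes import CLASS_FRAGMENTED, CLASS_FUSED, FEATURE_COLUMNS, as_feature_matrix

_COV_REG = 1e-6  # trace-scaled ridge added to every covariance update


@dataclass
class GmmModel:
    """Fitted 2-component full-covariance Gaussian mixture."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    neg_log_likelihood: float
    n_restarts: int
    seed: int | None
    class_map: dict[int, str] = field(default_factory=dict)
    feature_names: tuple[str, ...] = FEATURE_COLUMNS
    log_likelihood_traces: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if self.class_map:
            names = sorted(self.class_map.values())
            if names != sorted([CLASS_FRAGMENTED, CLASS_FUSED]):
                raise ValueError("class_map must be a bijection onto the two class names")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    # -- JSON round-trip -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "means": self.means.tolist(),
                "covariances": self.covariances.tolist(),
                "neg_log_likelihood": self.neg_log_likelihood,
                "n_restarts": self.n_restarts,
                "seed": self.seed,
                "class_map": {str(k): v for k, v in self.class_map.items()},
                "feature_names": list(self.feature_names),
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GmmModel":
        d = json.loads(text)
        return cls(
            weights=np.array(d["weights"]),
            means=np.array(d["means"]),
            covariances=np.array(d["covariances"]),
            neg_log_likelihood=d["neg_log_likelihood"],
            n_restarts=d["n_restarts"],
            seed=d["seed"],
            class_map={int(k): v for k, v in d["class_map"].items()},
            feature_names=tuple(d["feature_names"]),
        )


@dataclass
class ClassAssignment:
    """Per-object posterior probabilities and argmax hard labels."""

    posteriors: np.ndarray  # (n, K)
    hard_component: np.ndarray  # (n,)
    class_names: np.ndarray  # (n,) strings via the model's class_map

    def __post_init__(self) -> None:
        if not np.allclose(self.posteriors.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posteriors must sum to 1 per object")


def _component_log_density(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log N(x; mean, cov) for every row of X, via Cholesky."""
    d = X.shape[1]
    chol = np.linalg.cholesky(cov)
    diff = X - mean
    solved = np.linalg.solve(chol, diff.T)
    maha = np.sum(solved**2, axis=0)
    log_det = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2.0 * np.pi) + log_det + maha)


def _log_weighted_densities(model_or_parts, X: np.ndarray) -> np.ndarray:
    if isinstance(model_or_parts, GmmModel):
        weights, means, covs = model_or_parts.weights, model_or_parts.means, model_or_parts.covariances
    else:
        weights, means, covs = model_or_parts
    cols = []
    for k in range(len(weights)):
        with np.errstate(divide="ignore"):
            logw = np.log(weights[k]) if weights[k] > 0 else -np.inf
        cols.append(logw + _component_log_density(X, means[k], covs[k]))
    return np.column_stack(cols)


def log_likelihood(model: GmmModel, features) -> float:
    """Σᵢ log Σₖ πₖ N(xᵢ; μₖ, Σₖ) of the data under the model."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.means.shape[1]:
        raise ValueError("feature dimension does not match the model")
    return float(logsumexp(_log_weighted_densities(model, X), axis=1).sum())


def _regularise(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    scale = max(np.trace(cov) / d, 1e-12)
    return cov + _COV_REG * scale * np.eye(d)


def _em_single(
    X: np.ndarray,
    K: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray]:
    n, d = X.shape
    idx = rng.choice(n, size=K, replace=False)
    means = X[idx].copy()
    pooled = _regularise(np.atleast_2d(np.cov(X, rowvar=False)))
    covs = np.stack([pooled.copy() for _ in range(K)])
    weights = np.full(K, 1.0 / K)

    trace = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        log_wd = _log_weighted_densities((weights, means, covs), X)
        log_norm = logsumexp(log_wd, axis=1)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_wd - log_norm[:, None])

        nk = resp.sum(axis=0)
        nk = np.clip(nk, 1e-12, None)
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        for k in range(K):
            diff = X - means[k]
            cov = (resp[:, k][:, None] * diff).T @ diff / nk[k]
            covs[k] = _regularise(0.5 * (cov + cov.T))

        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * max(abs(prev_ll), 1.0):
            break
        prev_ll = ll

    final_ll = float(logsumexp(_log_weighted_densities((weights, means, covs), X), axis=1).sum())
    trace.append(final_ll)
    return weights, means, covs, final_ll, np.asarray(trace)


def fit_gmm(
    features,
    n_components: int = 2,
    n_restarts: int = 100,
    seed: int | None = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    keep_traces: bool = False,
    name_classes: bool = True,
    standardize: bool = False,
) -> GmmModel:
    """Multi-restart EM fit; returns the restart with minimal −log-likelihood.

    Each restart draws its own generator from a spawned seed stream of
    ``seed``, so results are reproducible and nested in ``n_restarts``.
    ``keep_traces`` retains the per-restart log-likelihood trajectories
    (non-decreasing by construction of EM) for diagnostics. With
    ``standardize`` the EM runs on z-scored features (a sensitivity
    option; the default fits raw units) and the returned means and
    covariances are mapped back to raw units; the stored
    ``neg_log_likelihood`` then refers to the standardised data.
    """
    X = as_feature_matrix(features) if not isinstance(features, np.ndarray) else np.asarray(features, float)
    if X.ndim == 1:
        X = X[None, :]
    n, d = X.shape
    if n < 2 * n_components:
        raise ValueError(f"need at least {2 * n_components} rows to fit {n_components} components")
    if len(np.unique(X, axis=0)) < n_components:
        raise ValueError("need at least as many distinct rows as components")

    shift = scale = None
    if standardize:
        shift = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        X = (X - shift) / scale

    children = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    traces = []
    for child in children:
        rng = np.random.default_rng(child)
        weights, means, covs, ll, trace = _em_single(X, n_components, rng, tol, max_iter)
        if keep_traces:
            traces.append(trace)
        if best is None or ll > best[3]:
            best = (weights, means, covs, ll)
    weights, means, covs, ll = best
    if standardize:
        means = means * scale + shift
        covs = covs * np.outer(scale, scale)
    model = GmmModel(
        weights=weights,
        means=means,
        covariances=covs,
        neg_log_likelihood=-ll,
        n_restarts=n_restarts,
        seed=seed,
        log_likelihood_traces=traces if keep_traces else None,
    )
    if name_classes and n_components == 2:
        model.class_map = map_component_names(model)
    return model


def map_component_names(model: GmmModel, area_index: int = 0) -> dict[int, str]:
    """Name components by mean area: smaller → fragmented, larger → fused."""
    areas = model.means[:, area_index]
    if areas[0] == areas[1]:
        raise ValueError(
            "components have identical mean area; assign class names manually"
        )
    frag = int(np.argmin(areas))
    return {frag: CLASS_FRAGMENTED, 1 - frag: CLASS_FUSED}


def assign_classes(model: GmmModel, features) -> ClassAssignment:
    """Posterior class probabilities and argmax labels for each object.

    Ties in the posterior break toward the lower component index.
    """
    X = as_feature_matrix(features) if not isinstance(features, np.ndarray) else np.asarray(features, float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.means.shape[1]:
        raise ValueError("feature dimension does not match the model")
    log_wd = _log_weighted_densities(model, X)
    post = np.exp(log_wd - logsumexp(log_wd, axis=1)[:, None])
    hard = np.argmax(post, axis=1)  # argmax returns the lowest index on ties
    class_map = model.class_map or map_component_names(model)
    names = np.array([class_map[int(k)] for k in hard])
    return ClassAssignment(posteriors=post, hard_component=hard, class_names=names)


def fraction_fragmented(
    assignment: ClassAssignment,
    features: pd.DataFrame,
    group_by: Sequence[str] = (),
) -> pd.DataFrame:
    """Fragmented fraction per group, by object count and by object mass.

    ``features`` must carry ``area_px`` plus any grouping columns
    (condition, replicate, ...). Count fraction = fragmented objects over
    all objects; mass fraction = summed fragmented area over total area.
    """
    if len(features) != len(assignment.class_names):
        raise ValueError("assignment and feature table lengths differ")
    if len(features) == 0:
        raise ValueError("cannot summarise an empty group")
    df = features.copy()
    df["_fragmented"] = assignment.class_names == CLASS_FRAGMENTED

    def summarise(sub: pd.DataFrame) -> pd.Series:
        total_area = sub["area_px"].sum()
        return pd.Series(
            {
                "n_objects": len(sub),
                "fraction_by_count": sub["_fragmented"].mean(),
                "fraction_by_mass": sub.loc[sub["_fragmented"], "area_px"].sum() / total_area,
            }
        )

    if not group_by:
        out = summarise(df).to_frame().T
        out["n_objects"] = out["n_objects"].astype(int)
        return out.reset_index(drop=True)
    grouped = df.groupby(list(group_by), sort=True).apply(summarise, include_groups=False)
    grouped["n_objects"] = grouped["n_objects"].astype(int)
    return grouped.reset_index()


def replicate_summary(
    fractions: pd.DataFrame,
    condition_col: str = "condition",
    value_cols: Sequence[str] = ("fraction_by_count", "fraction_by_mass"),
) -> pd.DataFrame:
    """Mean ± SE across replicates of per-replicate fragmentation fractions."""
    rows = []
    for cond, sub in fractions.groupby(condition_col, sort=True):
        rec = {condition_col: cond, "n_replicates": len(sub)}
        for col in value_cols:
            vals = sub[col].to_numpy(float)
            rec[f"{col}_mean"] = vals.mean()
            rec[f"{col}_se"] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def robustness_analysis(
    dataset: pd.DataFrame,
    scheme: Literal["leave_one_compound_out", "image_halves", "object_fraction"],
    n_reps: int = 100,
    fraction: float = 0.5,
    seed: int = 0,
    n_restarts: int = 10,
    min_fit_size: int = 8,
) -> pd.DataFrame:
    """Stability of the mixture parameters under data-size perturbations.

    Schemes: refit after dropping one compound at a time
    (``leave_one_compound_out``); refit on ``n_reps`` random halves of the
    images (``image_halves``); refit on a random ``fraction`` of all
    objects, ``n_reps`` times (``object_fraction``). Each refit's
    per-component per-feature mean and variance are returned long-form with
    the subsample descriptor and seed. Subsamples too small to fit are
    recorded with NaN estimates rather than raising.
    """
    rng = np.random.default_rng(seed)
    feat_cols = [c for c in FEATURE_COLUMNS if c in dataset.columns]
    subsets: list[tuple[str, pd.DataFrame]] = []
    if scheme == "leave_one_compound_out":
        for compound in sorted(dataset["compound"].unique()):
            subsets.append((f"without:{compound}", dataset[dataset["compound"] != compound]))
    elif scheme == "image_halves":
        images = np.array(sorted(dataset["image_id"].unique()))
        for rep in range(n_reps):
            half = rng.choice(images, size=len(images) // 2, replace=False)
            subsets.append((f"half:{rep}", dataset[dataset["image_id"].isin(half)]))
    elif scheme == "object_fraction":
        n_take = max(int(round(len(dataset) * fraction)), 0)
        for rep in range(n_reps):
            idx = rng.choice(len(dataset), size=n_take, replace=False)
            subsets.append((f"frac:{fraction}:{rep}", dataset.iloc[idx]))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    rows = []
    for rep_i, (descriptor, sub) in enumerate(subsets):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        base = {"scheme": scheme, "subsample": descriptor, "seed": sub_seed, "n_objects": len(sub)}
        if len(sub) < min_fit_size or len(np.unique(sub[feat_cols].to_numpy(), axis=0)) < 2:
            for comp in (CLASS_FRAGMENTED, CLASS_FUSED):
                for fcol in feat_cols:
                    rows.append({**base, "component": comp, "feature": fcol, "mean": np.nan, "variance": np.nan})
            continue
        model = fit_gmm(sub[feat_cols], n_restarts=n_restarts, seed=sub_seed)
        for k in range(model.n_components):
            comp = model.class_map[k]
            for j, fcol in enumerate(feat_cols):
                rows.append(
                    {
                        **base,
                        "component": comp,
                        "feature": fcol,
                        "mean": model.means[k, j],
                        "variance": model.covariances[k, j, j],
                    }
                )
    return pd.DataFrame(rows)
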