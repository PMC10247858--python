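"""Optional figures: feature scatter with 95% mixture ellipses, fraction bars.

Requires matplotlib (the ``plot`` extra); nothing else in the package
imports this module.
"""

from __future__ import annotations

import numpy as np

from .datatypes import CLASS_FRAGMENTED, FEATURE_COLUMNS
from .gmm import ClassAssignment, GmmModel

_CLASS_COLORS = {CLASS_FRAGMENTED: "tab:red", "fused": "tab:blue"}
_CHI2_2DF_95 = 5.991464547107979  # chi-square(2 df) 0.95 quantile


def _ellipse_points(mean2: np.ndarray, cov2: np.ndarray, n: int = 200) -> np.ndarray:
    """Points on the 95% Mahalanobis contour of a 2-D Gaussian."""
    vals, vecs = np.linalg.eigh(cov2)
    theta = np.linspace(0, 2 * np.pi, n)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    return mean2 + circle * np.sqrt(_CHI2_2DF_95 * vals) @ vecs.T


def feature_scatter(
    features,
    assignment: ClassAssignment,
    model: GmmModel,
    x: str = "area_px",
    y: str = "perimeter_px",
    ax=None,
    max_points: int = 5000,
):
    """Scatter of two features coloured by class, with 95% ellipses."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    xi, yi = FEATURE_COLUMNS.index(x), FEATURE_COLUMNS.index(y)
    X = features[[x, y]].to_numpy(float)
    if len(X) > max_points:
        step = len(X) // max_points + 1
        X, names = X[::step], assignment.class_names[::step]
    else:
        names = assignment.class_names
    for cls, color in _CLASS_COLORS.items():
        sel = names == cls
        ax.scatter(X[sel, 0], X[sel, 1], s=4, alpha=0.4, color=color, label=cls)
    for k in range(model.n_components):
        mean2 = model.means[k][[xi, yi]]
        cov2 = model.covariances[k][np.ix_([xi, yi], [xi, yi])]
        pts = _ellipse_points(mean2, cov2)
        ax.plot(pts[:, 0], pts[:, 1], color=_CLASS_COLORS[model.class_map[k]], lw=1.5)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.legend()
    return ax


def fraction_bars(summary, value: str = "fraction_by_count", ax=None):
    """Per-condition fragmented-fraction bars with replicate SE."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.bar(
        summary["condition"],
        summary[f"{value}_mean"],
        yerr=summary[f"{value}_se"].fillna(0.0),
        capsize=3,
        color="tab:green",
    )
    ax.set_ylabel(f"fragmented {value.replace('_', ' ')}")
    ax.set_ylim(0, 1)
    return ax
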