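"""EM mixture: likelihood oracle, monotonicity, recovery, fractions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from mitomorph.benchmarks import (
    gmm_recovery_experiment,
    mahalanobis_separation,
    reference_mixture,
)
from mitomorph.datatypes import CLASS_FRAGMENTED, CLASS_FUSED, FEATURE_COLUMNS
from mitomorph.gmm import (
    ClassAssignment,
    GmmModel,
    assign_classes,
    fit_gmm,
    fraction_fragmented,
    log_likelihood,
    map_component_names,
    robustness_analysis,
)
from mitomorph.synthetic import sample_feature_table


def naive_log_likelihood(model: GmmModel, X: np.ndarray) -> float:
    """Brute-force per-point mixture density via scipy, independent of ours."""
    total = 0.0
    for x in X:
        dens = sum(
            w * multivariate_normal.pdf(x, mean=m, cov=c)
            for w, m, c in zip(model.weights, model.means, model.covariances)
        )
        total += np.log(dens)
    return total


@pytest.fixture(scope="module")
def fitted_model_and_data():
    table, _ = sample_feature_table(reference_mixture(), 2000, seed=0)
    model = fit_gmm(table, n_restarts=5, seed=0, keep_traces=True)
    return model, table


def test_log_likelihood_matches_naive_oracle(fitted_model_and_data):
    model, table = fitted_model_and_data
    rng = np.random.default_rng(1)
    X = table.to_numpy(float)[rng.choice(len(table), 100, replace=False)]
    ours = log_likelihood(model, X)
    oracle = naive_log_likelihood(model, X)
    assert ours == pytest.approx(oracle, rel=1e-8)


def test_log_likelihood_additivity_and_closed_form():
    model = GmmModel(
        weights=np.array([1.0, 0.0]),
        means=np.zeros((2, 4)),
        covariances=np.stack([np.eye(4), np.eye(4)]),
        neg_log_likelihood=np.nan,
        n_restarts=0,
        seed=None,
    )
    x = np.zeros((1, 4))
    assert log_likelihood(model, x) == pytest.approx(-0.5 * 4 * np.log(2 * np.pi))
    X = np.random.default_rng(2).normal(size=(50, 4))
    assert log_likelihood(model, np.vstack([X, X])) == pytest.approx(
        2 * log_likelihood(model, X)
    )
    with pytest.raises(ValueError):
        log_likelihood(model, np.zeros((3, 2)))


def test_em_log_likelihood_never_decreases(fitted_model_and_data):
    model, _ = fitted_model_and_data
    assert model.log_likelihood_traces
    for trace in model.log_likelihood_traces:
        # non-decreasing up to floating-point roundoff of the logsumexp sums
        floor = -1e-8 * np.maximum(1.0, np.abs(trace[:-1]))
        assert np.all(np.diff(trace) >= floor)


def test_more_restarts_never_worse_under_nested_seeds():
    table, _ = sample_feature_table(reference_mixture(), 500, seed=3)
    single = fit_gmm(table, n_restarts=1, seed=42)
    many = fit_gmm(table, n_restarts=10, seed=42)
    assert many.neg_log_likelihood <= single.neg_log_likelihood + 1e-9


def test_degenerate_jittered_point_mass_survives():
    rng = np.random.default_rng(0)
    X = np.ones((200, 4)) + 1e-9 * rng.normal(size=(200, 4))
    model = fit_gmm(X, n_restarts=3, seed=0, name_classes=False)
    assert np.isfinite(model.neg_log_likelihood)
    for cov in model.covariances:
        np.linalg.cholesky(cov)  # regularised: still PD


def test_fit_rejects_too_small_or_constant_data():
    with pytest.raises(ValueError):
        fit_gmm(np.ones((3, 4)), n_restarts=1, seed=0)
    with pytest.raises(ValueError):
        fit_gmm(np.ones((50, 4)), n_restarts=1, seed=0)


def test_standardized_fit_recovers_raw_unit_parameters():
    """z-scored EM maps its estimates back to the same raw-unit optimum."""
    table, _ = sample_feature_table(reference_mixture(), 3000, seed=8)
    raw = fit_gmm(table, n_restarts=5, seed=8)
    std = fit_gmm(table, n_restarts=5, seed=8, standardize=True)
    assert np.allclose(
        raw.means[np.argsort(raw.means[:, 0])],
        std.means[np.argsort(std.means[:, 0])],
        rtol=0.02,
    )


def test_parameter_recovery_well_separated():
    assert mahalanobis_separation(reference_mixture()) >= 4
    report = gmm_recovery_experiment(n_objects=10_000, seeds=range(3))
    assert (report["max_mean_rel_error"] < 0.05).all()
    assert (report["weight_abs_error"] < 0.03).all()


def test_agreement_with_sklearn_reference_fit():
    """Independent cross-check: sklearn's EM lands on the same optimum."""
    from sklearn.mixture import GaussianMixture

    table, _ = sample_feature_table(reference_mixture(), 3000, seed=5)
    X = table.to_numpy(float)
    ours = fit_gmm(table, n_restarts=5, seed=5)
    ref = GaussianMixture(2, covariance_type="full", n_init=5, random_state=5).fit(X)
    assert -ours.neg_log_likelihood / len(X) == pytest.approx(ref.score(X), rel=1e-3)
    order = np.argsort(ref.means_[:, 0])
    ours_order = np.argsort(ours.means[:, 0])
    assert np.allclose(ref.means_[order], ours.means[ours_order], rtol=0.02)


# ---------------------------------------------------------------------------
# assignment and naming


def test_posteriors_normalised_and_separation_limit(fitted_model_and_data):
    model, table = fitted_model_and_data
    assignment = assign_classes(model, table)
    assert np.allclose(assignment.posteriors.sum(axis=1), 1.0, atol=1e-12)
    frag_comp = [k for k, v in model.class_map.items() if v == CLASS_FRAGMENTED][0]
    at_mean = assign_classes(model, model.means[frag_comp][None, :])
    assert at_mean.class_names[0] == CLASS_FRAGMENTED
    assert at_mean.posteriors[0, frag_comp] > 0.99


def test_equidistant_point_splits_posterior_evenly():
    model = GmmModel(
        weights=np.array([0.5, 0.5]),
        means=np.array([[-1.0, 0, 0, 0], [1.0, 0, 0, 0]]),
        covariances=np.stack([np.eye(4), np.eye(4)]),
        neg_log_likelihood=np.nan,
        n_restarts=0,
        seed=None,
        class_map={0: CLASS_FRAGMENTED, 1: CLASS_FUSED},
    )
    assignment = assign_classes(model, np.zeros((1, 4)))
    assert assignment.posteriors[0] == pytest.approx([0.5, 0.5])
    # tie breaks toward the lower component index
    assert assignment.hard_component[0] == 0


def test_component_naming_by_mean_area():
    model = reference_mixture()
    assert map_component_names(model) == {0: CLASS_FRAGMENTED, 1: CLASS_FUSED}
    swapped = GmmModel(
        weights=model.weights[::-1].copy(),
        means=model.means[::-1].copy(),
        covariances=model.covariances[::-1].copy(),
        neg_log_likelihood=np.nan,
        n_restarts=0,
        seed=None,
    )
    assert map_component_names(swapped) == {1: CLASS_FRAGMENTED, 0: CLASS_FUSED}
    equal = GmmModel(
        weights=np.array([0.5, 0.5]),
        means=np.array([[5.0, 0, 0, 0], [5.0, 1, 1, 1]]),
        covariances=np.stack([np.eye(4), np.eye(4)]),
        neg_log_likelihood=np.nan,
        n_restarts=0,
        seed=None,
    )
    with pytest.raises(ValueError):
        map_component_names(equal)


def test_model_json_roundtrip(fitted_model_and_data):
    model, table = fitted_model_and_data
    restored = GmmModel.from_json(model.to_json())
    X = table.to_numpy(float)[:50]
    assert log_likelihood(restored, X) == pytest.approx(log_likelihood(model, X))
    assert restored.class_map == model.class_map


# ---------------------------------------------------------------------------
# fractions


def _manual_assignment(names):
    names = np.asarray(names)
    frag = names == CLASS_FRAGMENTED
    post = np.column_stack([frag, ~frag]).astype(float)
    return ClassAssignment(post, (~frag).astype(int), names)


def test_fraction_arithmetic_count_and_mass():
    names = [CLASS_FRAGMENTED] * 3 + [CLASS_FUSED]
    table = pd.DataFrame({"area_px": [10, 10, 10, 70]})
    out = fraction_fragmented(_manual_assignment(names), table)
    assert out.loc[0, "fraction_by_count"] == pytest.approx(0.75)
    assert out.loc[0, "fraction_by_mass"] == pytest.approx(0.30)


def test_equal_areas_collapse_count_and_mass_fractions():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = rng.integers(2, 30)
        names = rng.choice([CLASS_FRAGMENTED, CLASS_FUSED], size=n)
        table = pd.DataFrame({"area_px": np.full(n, 7.0)})
        out = fraction_fragmented(_manual_assignment(names), table)
        assert out.loc[0, "fraction_by_count"] == pytest.approx(out.loc[0, "fraction_by_mass"])
        assert 0.0 <= out.loc[0, "fraction_by_count"] <= 1.0


def test_fraction_grouping_and_empty_rejection():
    names = [CLASS_FRAGMENTED, CLASS_FUSED, CLASS_FRAGMENTED, CLASS_FRAGMENTED]
    table = pd.DataFrame(
        {"area_px": [5.0, 20.0, 5.0, 5.0], "condition": ["a", "a", "b", "b"]}
    )
    out = fraction_fragmented(_manual_assignment(names), table, group_by=["condition"])
    assert out.set_index("condition").loc["a", "fraction_by_count"] == pytest.approx(0.5)
    assert out.set_index("condition").loc["b", "fraction_by_count"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        fraction_fragmented(_manual_assignment([]), pd.DataFrame({"area_px": []}))


# ---------------------------------------------------------------------------
# robustness


def test_robustness_report_deterministic_and_stable():
    table, _ = sample_feature_table(reference_mixture(), 4000, seed=9)
    table["compound"] = np.where(np.arange(len(table)) % 20 == 0, "rare", "common")
    table["image_id"] = np.arange(len(table)) % 10

    r1 = robustness_analysis(table, "object_fraction", n_reps=2, fraction=0.5, seed=4, n_restarts=2)
    r2 = robustness_analysis(table, "object_fraction", n_reps=2, fraction=0.5, seed=4, n_restarts=2)
    pd.testing.assert_frame_equal(r1, r2)

    full = fit_gmm(table, n_restarts=3, seed=0)
    loco = robustness_analysis(table, "leave_one_compound_out", seed=4, n_restarts=3)
    sub = loco[(loco["subsample"] == "without:rare") & (loco["feature"] == "area_px")]
    for comp in (CLASS_FRAGMENTED, CLASS_FUSED):
        full_mean = full.means[[k for k, v in full.class_map.items() if v == comp][0], 0]
        est = sub[sub["component"] == comp]["mean"].iloc[0]
        assert abs(est - full_mean) / full_mean < 0.05
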