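"""Cytoplasm rings, death rule, FRET ratio and normalisations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mitomorph.readouts import (
    build_cell_regions,
    death_fraction,
    measure_fret_ratio,
    measure_mmp_timecourse,
    normalize_to_vehicle,
    nuclei_count_normalize,
    opa1_cleavage_ratio,
    pi_positive_fraction,
    replicate_mean_se,
)


# ---------------------------------------------------------------------------
# cytoplasm-ring construction vs brute force


def brute_force_regions(labels: np.ndarray, max_distance: float):
    """Per-pixel nearest-nucleus oracle with ties to the lower label."""
    h, w = labels.shape
    nuclei = {}
    for lab in range(1, labels.max() + 1):
        nuclei[lab] = np.argwhere(labels == lab)
    assignment = np.zeros((h, w), dtype=int)
    for r in range(h):
        for c in range(w):
            if labels[r, c] > 0:
                continue
            best_lab, best_d = 0, np.inf
            for lab, pts in nuclei.items():
                d = np.sqrt(((pts - [r, c]) ** 2).sum(axis=1).min())
                if d < best_d - 1e-12:
                    best_d, best_lab = d, lab
            if best_d <= max_distance:
                assignment[r, c] = best_lab
    return assignment


def _ring_sets(regions):
    return {reg.cell_id: set(zip(*reg.cytoplasm_pixels)) for reg in regions}


@pytest.mark.parametrize("seed", range(4))
def test_rings_match_nearest_nucleus_brute_force(seed):
    rng = np.random.default_rng(seed)
    labels = np.zeros((40, 40), dtype=int)
    for lab in range(1, 4):
        r, c = rng.integers(5, 35, size=2)
        labels[max(r - 2, 0) : r + 2, max(c - 2, 0) : c + 2] = lab
    regions = build_cell_regions(labels, max_distance=8)
    oracle = brute_force_regions(labels, 8)
    rings = _ring_sets(regions)
    for lab in range(1, labels.max() + 1):
        assert rings[lab] == set(map(tuple, np.argwhere(oracle == lab)))


def test_single_pixel_nucleus_ring_pixel_count():
    labels = np.zeros((31, 31), dtype=int)
    labels[15, 15] = 1
    regions = build_cell_regions(labels, max_distance=10)
    rr, cc = np.mgrid[0:31, 0:31]
    d = np.sqrt((rr - 15.0) ** 2 + (cc - 15.0) ** 2)
    expected = int(((d > 0) & (d <= 10)).sum())
    assert len(regions[0].cytoplasm_pixels[0]) == expected


def test_distant_nuclei_have_disjoint_rings_and_contested_pixels_split():
    labels = np.zeros((40, 70), dtype=int)
    labels[20, 15] = 1
    labels[20, 45] = 2  # 30 px apart: no contest
    rings = _ring_sets(build_cell_regions(labels, max_distance=10))
    assert not rings[1] & rings[2]

    labels2 = np.zeros((40, 40), dtype=int)
    labels2[20, 14] = 1
    labels2[20, 26] = 2  # 12 px apart: contested band
    regions = build_cell_regions(labels2, max_distance=10)
    oracle = brute_force_regions(labels2, 10)
    rings2 = _ring_sets(regions)
    for lab in (1, 2):
        assert rings2[lab] == set(map(tuple, np.argwhere(oracle == lab)))


def test_no_nuclei_yields_empty_region_list():
    assert build_cell_regions(np.zeros((16, 16), dtype=int)) == []


# ---------------------------------------------------------------------------
# MMP and the death rule


def _one_cell_layout():
    labels = np.zeros((40, 40), dtype=int)
    labels[18:23, 18:23] = 1  # 25-px nucleus
    return labels, build_cell_regions(labels, max_distance=6)


def test_planted_cytoplasm_intensity_measured_exactly_without_noise():
    labels, regions = _one_cell_layout()
    rho = np.zeros((40, 40))
    rho[regions[0].cytoplasm_pixels] = 1000.0
    frames = [{"rho123": rho, "pi": np.zeros((40, 40))}]
    table = measure_mmp_timecourse(frames, regions, pi_threshold=10.0)
    assert table.loc[0, "rho123_mean"] == 1000.0
    assert not table.loc[0, "dead"]
    integrated = measure_mmp_timecourse(frames, regions, pi_threshold=10.0, statistic="integrated")
    assert integrated.loc[0, "rho123_mean"] == 1000.0 * len(regions[0].cytoplasm_pixels[0])


def test_death_rule_boundary_exact_at_ten_percent():
    """24/25 fraction rule: 0.08 < 0.10 alive, exactly 0.10 dead, 0.12 dead."""
    labels, regions = _one_cell_layout()
    nucleus = regions[0].nucleus_pixels
    n = nucleus[0].size  # 25 pixels
    for n_pos, dead in [(2, False), (3, True), (4, True)]:  # 0.08, 0.12, 0.16
        pi = np.zeros((40, 40))
        pi[nucleus[0][:n_pos], nucleus[1][:n_pos]] = 100.0
        frac = pi_positive_fraction(pi, nucleus, threshold=50.0)
        assert frac == pytest.approx(n_pos / n)
        table = measure_mmp_timecourse(
            [{"rho123": np.ones((40, 40)), "pi": pi}], regions, pi_threshold=50.0
        )
        assert bool(table.loc[0, "dead"]) is dead
    # exact threshold: 10% of a 10-pixel nucleus
    labels10 = np.zeros((20, 20), dtype=int)
    labels10[5, 5:15] = 1
    regions10 = build_cell_regions(labels10, max_distance=3)
    pi = np.zeros((20, 20))
    pi[5, 5] = 100.0
    frac = pi_positive_fraction(pi, regions10[0].nucleus_pixels, threshold=50.0)
    assert frac == 0.10
    table = measure_mmp_timecourse(
        [{"rho123": np.ones((20, 20)), "pi": pi}], regions10, pi_threshold=50.0
    )
    assert bool(table.loc[0, "dead"]) is True


def test_death_fraction_recovers_planted_fraction():
    from mitomorph.benchmarks import mmp_recovery_experiment

    result = mmp_recovery_experiment(seed=1)
    assert result["death_fraction"] == pytest.approx(result["planted_death_fraction"])
    err = abs(result["measured_rho123_mean"] - result["planted_rho123"])
    n_ring_px = 100  # conservative lower bound on ring size
    assert err < 3 * result["per_cell_noise_sd"] / np.sqrt(n_ring_px)


# ---------------------------------------------------------------------------
# FRET


def test_fret_ratio_planted_values_recovered():
    from mitomorph.benchmarks import fret_recovery_experiment

    exact = fret_recovery_experiment(1.0, seed=0)
    assert exact["recovered"] == pytest.approx(1.0, abs=0.02)
    half = fret_recovery_experiment(0.5, seed=1)
    assert half["recovered"] == pytest.approx(0.5, abs=0.02)


def test_fret_ratio_guards():
    a408 = np.zeros((20, 20))
    a408[5:15, 5:15] = 1000.0
    zero488 = np.zeros((20, 20))
    meas = measure_fret_ratio(a408, zero488)
    assert meas.ratio == 0.0  # zero 488 in area → ratio 0, not an error
    with pytest.raises(ValueError):
        measure_fret_ratio(np.zeros((20, 20)), zero488)  # flat 408: no cell area
    with pytest.raises(ValueError):
        measure_fret_ratio(a408, zero488, orientation="408/488")  # zero denominator
    with pytest.raises(ValueError):
        measure_fret_ratio(a408, np.zeros((10, 10)))


# ---------------------------------------------------------------------------
# normalisations


def test_normalize_to_vehicle_identity_scaling_and_idempotence():
    vehicle = np.array([2.0, 4.0, 8.0])
    assert normalize_to_vehicle(vehicle, vehicle) == pytest.approx([1.0, 1.0, 1.0])
    assert normalize_to_vehicle(2 * vehicle, vehicle) == pytest.approx([2.0, 2.0, 2.0])
    normalised = normalize_to_vehicle(vehicle, vehicle)
    assert normalize_to_vehicle(normalised, normalised) == pytest.approx([1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        normalize_to_vehicle(vehicle, np.array([1.0, 0.0, 1.0]))
    with pytest.raises(ValueError):
        normalize_to_vehicle(vehicle, vehicle[:2])


def test_normalized_replicates_recover_planted_effect():
    rng = np.random.default_rng(0)
    vehicle = np.full(10, 100.0)
    planted, sd, n_rep = 0.6, 0.05, 4
    reps = [
        normalize_to_vehicle(vehicle * planted + rng.normal(0, sd * 100, 10), vehicle)
        for _ in range(n_rep)
    ]
    mean, se = replicate_mean_se(reps)
    assert mean.mean() == pytest.approx(planted, abs=3 * sd / np.sqrt(n_rep * 10))
    assert se.mean() == pytest.approx(sd / np.sqrt(n_rep), rel=0.6)


def test_opa1_cleavage_ratio_limits():
    assert opa1_cleavage_ratio(2.0, 2.0) == pytest.approx(0.5)
    assert opa1_cleavage_ratio(3.0, 0.0) == 1.0
    assert opa1_cleavage_ratio(0.0, 3.0) == 0.0
    with pytest.raises(ValueError):
        opa1_cleavage_ratio(0.0, 0.0)
    with pytest.raises(ValueError):
        opa1_cleavage_ratio(-1.0, 1.0)


def test_nuclei_count_normalize_scale_invariance():
    assert nuclei_count_normalize(1000.0, 100) == 10.0
    assert nuclei_count_normalize(0.0, 50) == 0.0
    assert nuclei_count_normalize(1000.0, 100) == nuclei_count_normalize(2000.0, 200)
    with pytest.raises(ValueError):
        nuclei_count_normalize(10.0, 0)
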