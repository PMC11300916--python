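"""Transformation and scoring layer: exactness and metric structure."""

import itertools

import numpy as np
import pandas as pd
import pytest

from vasculodyn import scoring, syndata, trajectory
from vasculodyn.scoring import (TimeWindow, abs_poly_integral, compute_scores,
                                dissimilarity_score, integrated_discrepancy,
                                make_windows, spread_score, standardize_time,
                                zscore)
from vasculodyn.trajectory import PolynomialFit


def _fit(b0, b1, b2, b3):
    return PolynomialFit(np.array([b0, b1, b2, b3], dtype=float), "ols", (0, 1), 0.0, 8)


# -- time standardisation ----------------------------------------------------

def test_window_endpoints_map_exactly():
    moc1 = TimeWindow("MOC1", 8.0, 12.0)
    b16 = TimeWindow("B16-F10", 17.0, 29.0)
    assert standardize_time(8.0, moc1) == 0.0
    assert standardize_time(12.0, moc1) == 1.0
    assert standardize_time(23.0, b16) == 0.5


def test_standardisation_roundtrip_and_validation(rng):
    win = TimeWindow("L", 5.0, 17.0, 0.0, 1.0)
    t = rng.uniform(5, 17, 100)
    back = scoring.inverse_standardize_time(standardize_time(t, win), win)
    np.testing.assert_allclose(back, t, atol=1e-12)
    with pytest.raises(ValueError):
        TimeWindow("L", 4.0, 4.0)


# -- z-normalisation ---------------------------------------------------------

def _well_table(values, time=1.0, line="L", obj="f"):
    return pd.DataFrame({
        "cell_line": line, "well": [f"W{i}" for i in range(len(values))],
        "object": obj, "time_h": time, "value": values})


def test_zscore_sample_sd_convention():
    out = zscore(_well_table([1.0, 2.0, 3.0]), strata="object")
    np.testing.assert_allclose(sorted(out["value"]), [-1.0, 0.0, 1.0], atol=1e-12)
    assert not out["degenerate"].any()


def test_zscore_constant_stratum_flags_degenerate():
    out = zscore(_well_table([5.0, 5.0, 5.0]))
    assert (out["value"] == 0.0).all()
    assert out["degenerate"].all()


@pytest.mark.parametrize("strata", scoring.ZSCORE_STRATA)
def test_zscore_strata_have_mean0_sd1(noisy_table, strata):
    table, _design = noisy_table
    well = trajectory.average_replicates(table)
    out = zscore(well, strata=strata)
    cols = scoring._strata_cols(strata)
    for _, grp in out.groupby(cols):
        if grp["degenerate"].any():
            continue
        assert abs(grp["value"].mean()) < 1e-12
        assert abs(grp["value"].std(ddof=1) - 1.0) < 1e-12


# -- integrated discrepancy --------------------------------------------------

def test_discrepancy_trivial_cases():
    f = _fit(1.0, -2.0, 0.5, 0.3)
    assert integrated_discrepancy(f, f) == 0.0
    # constant difference c -> |c|
    assert integrated_discrepancy(_fit(2.5, 0, 0, 0), _fit(0, 0, 0, 0)) == pytest.approx(2.5)
    # difference t - 0.5 on [0,1] -> 0.25
    assert integrated_discrepancy(_fit(-0.5, 1, 0, 0), _fit(0, 0, 0, 0)) == pytest.approx(0.25)


def test_closed_form_equals_riemann_oracle(rng):
    mid = np.linspace(0, 1, 100_001)
    mid = 0.5 * (mid[1:] + mid[:-1])
    for _ in range(25):
        b = rng.normal(size=4)
        exact = abs_poly_integral(b, 0.0, 1.0)
        riemann = np.abs(b[0] + b[1] * mid + b[2] * mid**2 + b[3] * mid**3).mean()
        assert exact == pytest.approx(riemann, abs=1e-6)


def test_degenerate_leading_coefficients():
    # quadratic, linear and zero differences all integrate exactly
    # (t - 0.5)^2 over [0, 1] -> 1/12
    assert abs_poly_integral(np.array([0.25, -1.0, 1.0, 0.0]), 0, 1) == pytest.approx(1 / 12)
    assert abs_poly_integral(np.array([0.0, 0.0, 0.0, 0.0]), 0, 1) == 0.0
    assert abs_poly_integral(np.array([-0.5, 1.0, 0.0, 0.0]), 0, 1) == pytest.approx(0.25)


def test_discrepancy_is_a_metric_on_random_cubics(rng):
    for _ in range(20):
        a, b, c = (_fit(*rng.normal(size=4)) for _ in range(3))
        dab = integrated_discrepancy(a, b)
        dba = integrated_discrepancy(b, a)
        dac = integrated_discrepancy(a, c)
        dcb = integrated_discrepancy(c, b)
        assert dab == pytest.approx(dba, rel=1e-12)
        assert dab >= 0
        assert dab <= dac + dcb + 1e-12
    assert integrated_discrepancy(a, a) == 0.0


def test_dissimilarity_sums_all_pairs(rng):
    fits = {f"L{i}": _fit(*rng.normal(size=4)) for i in range(7)}
    score, mat = dissimilarity_score(fits)
    brute = sum(integrated_discrepancy(fits[j], fits[k])
                for j, k in itertools.combinations(sorted(fits), 2))
    assert score == pytest.approx(brute)
    assert len(list(itertools.combinations(fits, 2))) == 21
    assert np.allclose(mat.values, mat.values.T)
    assert np.all(np.diag(mat.values) == 0)
    # two identical lines contribute zero to each other
    same = {"A": _fit(1, 2, 3, 4), "B": _fit(1, 2, 3, 4)}
    s2, _ = dissimilarity_score(same)
    assert s2 == 0.0
    with pytest.raises(ValueError):
        dissimilarity_score({"A": _fit(1, 0, 0, 0)})


# -- spread and stability ----------------------------------------------------

def test_spread_scores():
    assert spread_score(_fit(3.0, 0, 0, 0)) == 0.0
    assert spread_score(_fit(0.0, 1.0, 0, 0)) == pytest.approx(1.0)
    assert spread_score(_fit(0.0, 0.0, 1.0, -1.0)) == pytest.approx(4 / 27)


def test_affine_consistency_of_fitting_and_standardising(rng):
    """Fitting on raw hours then mapping the curve equals fitting on
    standardised time: the two designs are exact affine reparameterisations."""
    win = TimeWindow("L", 6.0, 18.0)
    t = np.linspace(6, 18, 9)
    y = rng.normal(size=t.size)
    raw = trajectory.fit_cubic(t, y, "ols")
    std = trajectory.fit_cubic(standardize_time(t, win), y, "ols")
    grid = np.linspace(6, 18, 40)
    np.testing.assert_allclose(
        trajectory.evaluate(raw, grid),
        trajectory.evaluate(std, standardize_time(grid, win)), atol=1e-8)


def test_ordering_recovery_uniformly_larger_spread():
    lines = ["steady1", "steady2", "volatile"]
    objects = ["obj1", "obj2"]
    windows = {l: (5.0, 15.0) for l in lines}
    true_beta = {
        ("steady1", "obj1"): (10.0, 0.08, 0.0, 0.0),
        ("steady1", "obj2"): (20.0, -0.06, 0.0, 0.0),
        ("steady2", "obj1"): (15.0, -0.10, 0.0, 0.0),
        ("steady2", "obj2"): (5.0, 0.09, 0.0, 0.0),
        ("volatile", "obj1"): (10.0, -1.2, 0.04, 0.0),
        ("volatile", "obj2"): (18.0, 1.0, -0.02, 0.0),
    }
    wins = make_windows(windows)
    for seed in range(10):
        design = syndata.TrajectoryDesign(
            cell_lines=lines, objects=objects, true_beta=true_beta,
            time_window=windows, n_timepoints=8, n_wells=6, n_replicates=4,
            well_effect_sd=0.5, noise_sd=1.0, rng_seed=seed)
        table = syndata.generate_trajectory_dataset(design)
        scores = compute_scores(table, wins)
        assert max(scores.stability, key=scores.stability.get) == "volatile"


def test_compute_scores_requires_windows(noisy_table):
    table, design = noisy_table
    windows = make_windows({l: design.time_window[l]
                            for l in design.cell_lines[:-1]})
    with pytest.raises(ValueError, match=design.cell_lines[-1]):
        compute_scores(table, windows)


def test_mean_discrepancy_variant_orders_like_primary():
    table, design = syndata.generate_trajectory_dataset(syndata.example_design(3)), None
    design = syndata.example_design(3)
    wins = make_windows(design.time_window)
    scores = compute_scores(table, wins)
    alt = scoring.mean_discrepancy_stability(scores.fits)
    assert set(alt) == set(scores.stability)
    assert all(v >= 0 for v in alt.values())
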