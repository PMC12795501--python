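import numpy as np
import pytest
from scipy.spatial import procrustes
from scipy.stats import pearsonr

from geomrep import behavior
from geomrep.behavior import (
    BehavioralRDM,
    TrialRecord,
    empirical_rdm,
    mds_embed,
    project_property,
    rdm_regression,
)
from geomrep.rsa import RDM


def T(p, ref, intr, correct, rt):
    return TrialRecord(p, ref, intr, correct, rt)


# ---------------------------------------------------------------------------
# empirical RDM
# ---------------------------------------------------------------------------


def test_single_pair_raw_value():
    # accuracy 0.9 over 10 trials, constant RT 1500 ms -> 6e-4 per ms
    trials = [T("p0", "a", "b", i < 9, 1500.0) for i in range(10)]
    trials += [T("p0", "b", "a", i < 9, 1500.0) for i in range(10)]
    out = empirical_rdm(trials)
    assert out.raw_values[0] == pytest.approx(0.9 / 1500.0, rel=1e-12)


def test_ordered_estimates_are_averaged():
    # (a->b): acc 1, rt 500 -> 2e-3 ; (b->a): acc 1, rt 250 -> 4e-3 ; mean 3e-3
    trials = [T("p0", "a", "b", True, 500.0), T("p0", "b", "a", True, 250.0)]
    # a third label so that z-scoring has >1 entry
    trials += [T("p0", "a", "c", True, 1000.0), T("p0", "c", "a", True, 1000.0)]
    trials += [T("p0", "b", "c", True, 1000.0), T("p0", "c", "b", True, 1000.0)]
    out = empirical_rdm(trials)
    k = out.labels.index("a"), out.labels.index("b")
    ab = out.raw_values[0] if k == (0, 1) else None
    assert out.labels == ["a", "b", "c"]
    assert out.raw_values[0] == pytest.approx(3e-3, rel=1e-12)


def test_three_shape_toy_set_matches_hand_computation():
    """Hand-listed trials; every cell recomputed spreadsheet-style."""
    trials = [
        # (a,b): 2 trials, 1 correct, RTs 1000, 2000 -> 0.5 / 1500
        T("p0", "a", "b", True, 1000.0),
        T("p1", "a", "b", False, 2000.0),
        # (b,a): 1 trial correct at 500 -> 1/500
        T("p0", "b", "a", True, 500.0),
        # (a,c): 2 trials both correct, RTs 800, 1200 -> 1/1000
        T("p0", "a", "c", True, 800.0),
        T("p1", "a", "c", True, 1200.0),
        # (c,a): 1 trial, error at 700 -> 0/700
        T("p1", "c", "a", False, 700.0),
        # (b,c): 1 trial correct at 1000; (c,b): 1 trial correct at 2000
        T("p0", "b", "c", True, 1000.0),
        T("p1", "c", "b", True, 2000.0),
    ]
    out = empirical_rdm(trials)
    raw_ab = ((0.5 / 1500) + (1 / 500)) / 2
    raw_ac = ((1 / 1000) + 0.0) / 2
    raw_bc = ((1 / 1000) + (1 / 2000)) / 2
    want = np.array([raw_ab, raw_ac, raw_bc])
    assert np.allclose(out.raw_values, want, rtol=1e-12)
    z = (want - want.mean()) / want.std()
    assert np.allclose(out.z_values, z, rtol=1e-12)
    assert list(out.n_trials) == [3, 3, 2]


def test_z_values_standardized(rng):
    trials = []
    labels = list("abcde")
    for p in range(5):
        for r in labels:
            for i in labels:
                if r != i:
                    trials.append(
                        T(f"p{p}", r, i, rng.random() < 0.8, float(rng.uniform(500, 3000)))
                    )
    out = empirical_rdm(trials)
    assert out.z_values.mean() == pytest.approx(0, abs=1e-12)
    assert out.z_values.std() == pytest.approx(1, abs=1e-12)


def test_trial_order_and_participant_relabeling_invariance(rng):
    labels = list("abcd")
    trials = []
    for p in range(4):
        for r in labels:
            for i in labels:
                if r != i:
                    trials.append(
                        T(f"p{p}", r, i, rng.random() < 0.7, float(rng.uniform(400, 2500)))
                    )
    base = empirical_rdm(trials).z_values
    shuffled = [trials[k] for k in rng.permutation(len(trials))]
    assert np.allclose(empirical_rdm(shuffled).z_values, base)
    relabeled = [
        TrialRecord("x" + t.participant_id, t.reference, t.intruder, t.correct, t.rt)
        for t in trials
    ]
    assert np.allclose(empirical_rdm(relabeled).z_values, base)


def test_single_participant_lone_trial_cells():
    """With a lone trial per ordered cell the estimate is 0 or 1/RT."""
    trials = [
        T("p0", "a", "b", True, 800.0),
        T("p0", "b", "a", False, 900.0),
        T("p0", "a", "c", True, 400.0),
        T("p0", "c", "a", True, 500.0),
        T("p0", "b", "c", False, 600.0),
        T("p0", "c", "b", False, 700.0),
    ]
    out = empirical_rdm(trials, pool_participants=False)
    assert out.raw_values[0] == pytest.approx((1 / 800 + 0) / 2)
    assert out.raw_values[1] == pytest.approx((1 / 400 + 1 / 500) / 2)
    assert out.raw_values[2] == pytest.approx(0.0)


def test_error_rt_exclusion_switch():
    trials = [
        T("p0", "a", "b", True, 1000.0),
        T("p0", "a", "b", False, 3000.0),
        T("p0", "b", "a", True, 1000.0),
        T("p0", "a", "c", True, 1000.0),
        T("p0", "c", "a", True, 1000.0),
        T("p0", "b", "c", True, 1000.0),
        T("p0", "c", "b", True, 1000.0),
    ]
    incl = empirical_rdm(trials, include_error_rts=True)
    excl = empirical_rdm(trials, include_error_rts=False)
    assert incl.raw_values[0] == pytest.approx((0.5 / 2000 + 1 / 1000) / 2)
    assert excl.raw_values[0] == pytest.approx((0.5 / 1000 + 1 / 1000) / 2)


def test_empty_cell_raises():
    trials = [T("p0", "a", "b", True, 500.0)]
    trials += [T("p0", "a", "c", True, 500.0)]
    with pytest.raises(ValueError, match="empty cell"):
        empirical_rdm(trials, labels=list("abcd"))


def test_degenerate_identical_entries_warns():
    trials = [
        T("p0", "a", "b", True, 1000.0),
        T("p0", "a", "c", True, 1000.0),
        T("p0", "b", "c", True, 1000.0),
    ]
    with pytest.warns(UserWarning):
        out = empirical_rdm(trials)
    assert np.allclose(out.z_values, 0.0)


# ---------------------------------------------------------------------------
# RDM regression
# ---------------------------------------------------------------------------


def _toy_rdm(vals, labels):
    return RDM(labels=labels, values=np.asarray(vals, dtype=float), metric="toy")


def test_regression_exact_model(rng):
    labels = [f"c{i}" for i in range(6)]
    m1 = _toy_rdm(rng.standard_normal(15), labels)
    m2 = _toy_rdm(rng.standard_normal(15), labels)
    res = rdm_regression(m1, [m1, m2])
    assert res.coefficients[0] == pytest.approx(1.0, abs=1e-10)
    assert res.coefficients[1] == pytest.approx(0.0, abs=1e-10)
    assert res.r_squared == pytest.approx(1.0, abs=1e-12)


def test_regression_orthogonal_exact_combination(rng):
    labels = [f"c{i}" for i in range(8)]
    a = rng.standard_normal(28)
    b = rng.standard_normal(28)
    a -= a.mean()
    b -= b.mean() + (b - b.mean()) @ a / (a @ a) * 0  # center only
    b = b - (b @ a) / (a @ a) * a  # orthogonalize
    emp = _toy_rdm(2 * a + 1 * b, labels)
    res = rdm_regression(emp, [_toy_rdm(a, labels), _toy_rdm(b, labels)])
    assert np.allclose(res.coefficients, [2.0, 1.0], atol=1e-10)


def test_regression_matches_normal_equations_oracle(rng):
    labels = [f"c{i}" for i in range(7)]
    x1, x2 = rng.standard_normal(21), rng.standard_normal(21)
    y = 0.7 * x1 - 0.4 * x2 + 0.3 * rng.standard_normal(21)
    res = rdm_regression(_toy_rdm(y, labels), [_toy_rdm(x1, labels), _toy_rdm(x2, labels)])
    X = np.column_stack([np.ones(21), x1, x2])
    beta = np.linalg.inv(X.T @ X) @ X.T @ y
    assert np.allclose([res.intercept, *res.coefficients], beta, atol=1e-10)


def test_single_model_slope_equals_cov_over_var(rng):
    labels = [f"c{i}" for i in range(6)]
    x = rng.standard_normal(15)
    y = rng.standard_normal(15)
    res = rdm_regression(_toy_rdm(y, labels), [_toy_rdm(x, labels)])
    want = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    assert res.coefficients[0] == pytest.approx(want, rel=1e-10)


def test_regression_rank_deficient_raises(rng):
    labels = [f"c{i}" for i in range(5)]
    x = rng.standard_normal(10)
    with pytest.raises(ValueError):
        rdm_regression(
            _toy_rdm(x, labels), [_toy_rdm(x, labels), _toy_rdm(2 * x, labels)]
        )


def test_regression_per_unit_paired_comparison(rng):
    labels = [f"c{i}" for i in range(6)]
    m1 = _toy_rdm(rng.standard_normal(15), labels)
    m2 = _toy_rdm(rng.standard_normal(15), labels)
    units = [
        _toy_rdm(3 * m1.values + 0.5 * m2.values + 0.1 * rng.standard_normal(15), labels)
        for _ in range(12)
    ]
    pooled = _toy_rdm(np.mean([u.values for u in units], axis=0), labels)
    res = rdm_regression(pooled, [m1, m2], model_names=["big", "small"], per_unit=units)
    assert res.per_unit_coefficients.shape == (12, 2)
    assert res.coef_difference_t > 0 and res.coef_difference_p < 0.01
    assert res.weight_ratio == pytest.approx(6.0, rel=0.2)


def test_label_subsetting_supports_named_shape_exclusion(feature_model_rdm):
    named = {"square", "rectangle", "trapezoid", "isoTrapezoid", "losange", "parallelogram"}
    keep = [l for l in feature_model_rdm.labels if l not in named]
    sub = feature_model_rdm.subset(keep)
    assert sub.n_conditions == 5 and sub.values.size == 10


# ---------------------------------------------------------------------------
# MDS and property projection
# ---------------------------------------------------------------------------


def test_mds_recovers_planar_configuration(rng):
    pts = rng.standard_normal((11, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    rdm = RDM.from_square([f"c{i}" for i in range(11)], d, metric="euclid")
    coords, stress = mds_embed(rdm, seed=0, n_restarts=16)
    assert stress < 1e-3
    _, _, disparity = procrustes(pts, coords)
    assert disparity < 1e-2


def test_mds_equilateral_three_points():
    rdm = RDM(labels=list("abc"), values=np.ones(3), metric="toy")
    coords, _ = mds_embed(rdm, seed=1, n_restarts=8)
    d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    off = d[~np.eye(3, dtype=bool)]
    assert off.std() / off.mean() < 1e-2


def test_mds_deterministic(feature_model_rdm):
    a, sa = mds_embed(feature_model_rdm, seed=3, n_restarts=4)
    b, sb = mds_embed(feature_model_rdm, seed=3, n_restarts=4)
    assert np.array_equal(a, b) and sa == sb


def test_mds_too_few_conditions():
    rdm = RDM(labels=["a", "b"], values=[1.0], metric="toy")
    with pytest.raises(ValueError):
        mds_embed(rdm)


def test_project_property_axis_identity(rng):
    coords = rng.standard_normal((11, 2))
    out = project_property(coords, coords[:, 0])
    assert out["coefficients"][0] == pytest.approx(1.0, abs=1e-10)
    assert out["coefficients"][1] == pytest.approx(0.0, abs=1e-10)


def test_project_property_constant_raises(rng):
    with pytest.raises(ValueError):
        project_property(rng.standard_normal((5, 2)), np.ones(5))


def test_property_projection_bootstrap_recovers_planted_gradient(
    feature_model_rdm, regularity_scores
):
    """Feature-model behavior: the regularity count projects significantly
    onto the MDS plane when 100 simulated participants carry the structure."""
    from geomrep import synth

    trials = synth.simulate_behavior(feature_model_rdm, n_participants=100, rng_seed=11)
    out = behavior.project_property_bootstrap(
        trials, {k: float(v) for k, v in regularity_scores.items()},
        n_resamples=60, seed=0, n_restarts=4,
    )
    # the dominant axis carries the regularity gradient
    assert np.min(out["p_axes"]) < 0.05
    assert np.linalg.norm(out["coefficients"]) > 0
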