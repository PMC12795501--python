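import numpy as np
import pytest

from geomrep import synth
from geomrep.rsa import RDM, pair_indices, crossnobis_time_series
from geomrep.decoding import epoch_condition_patterns
from geomrep.synth import (
    DesignBlock,
    PsychometricParams,
    SimulationSpec,
    display_positions,
    embed_rdm,
    make_intruder_display,
    make_miniblock_design,
    make_run_design,
    random_geometry_rdm,
    random_spd_covariance,
    simulate_behavior,
    simulate_beta_volumes,
    simulate_epochs,
)


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------


def test_miniblock_constraints_hold(rng):
    for seed in range(500):
        b = make_miniblock_design("square", rng_seed=seed)
        pos = b.oddball_positions
        assert len(pos) == 4
        assert min(pos) >= 6  # 0-based: first six items protected
        assert all(q - p > 1 for p, q in zip(pos, pos[1:]))
        assert len(b.items) == 30


def test_miniblock_positions_cover_valid_range():
    seen = set()
    for seed in range(2000):
        seen.update(make_miniblock_design("kite", rng_seed=seed).oddball_positions)
    assert seen == set(range(6, 30))


def test_miniblock_zero_oddballs():
    b = make_miniblock_design("hinge", n_oddballs=0, rng_seed=1)
    assert b.oddball_positions == []


def test_design_block_invariant_enforced():
    items = [dict(scale=1.0, rotation_deg=5.0, is_oddball=(i in (3, 10)), oddball_direction=1)
             for i in range(30)]
    with pytest.raises(ValueError):
        DesignBlock(shape="square", items=items)


def test_run_design_one_block_per_shape():
    shapes = ["a", "b", "c", "d"]
    run = make_run_design(shapes, rng_seed=0, run_index=2)
    assert sorted(b.shape for b in run) == shapes
    assert [b.block_index for b in run] == [8, 9, 10, 11]


# ---------------------------------------------------------------------------
# intruder displays
# ---------------------------------------------------------------------------


def test_display_positions_circle_and_shift_formula():
    import math

    pos = display_positions()
    want = []
    for side in (-1.0, 1.0):
        for th in (0.0, math.pi / 2, math.pi):
            want.append((side * (100.0 + 120.0 * math.sin(th)), 120.0 * math.cos(th)))
    assert np.allclose(pos, want)
    assert (pos[:3, 0] <= -100).all() and (pos[3:, 0] >= 100).all()


def test_intruder_display_contract(rng):
    disp = make_intruder_display("square", "kite", rng_seed=3)
    assert sum(d["is_intruder"] for d in disp) == 1
    assert sum(d["shape"] == "kite" for d in disp) == 1
    assert sum(d["shape"] == "square" for d in disp) == 5
    scales = [d["scale"] for d in disp]
    rots = [d["rotation_deg"] for d in disp]
    assert len(set(scales)) == 6 and len(set(rots)) == 6


def test_intruder_slot_never_repeats_consecutively(rng):
    prev = None
    for seed in range(200):
        disp = make_intruder_display("a", "b", rng_seed=seed, previous_intruder_slot=prev)
        slot = next(d["slot"] for d in disp if d["is_intruder"])
        assert slot != prev
        prev = slot


# ---------------------------------------------------------------------------
# behavior simulation
# ---------------------------------------------------------------------------


def test_simulate_behavior_trial_counts(feature_model_rdm):
    trials = simulate_behavior(feature_model_rdm, n_participants=3, rng_seed=0)
    assert len(trials) == 3 * 110  # one trial per ordered pair, 11 shapes
    per = trials.groupby("participant_id").size()
    assert (per == 110).all()


def test_simulate_behavior_ordering_constraints(feature_model_rdm):
    trials = simulate_behavior(feature_model_rdm, n_participants=2, rng_seed=5)
    for _, g in trials.groupby("participant_id"):
        refs = g["reference"].tolist()
        intr = g["intruder"].tolist()
        for t in range(1, len(refs)):
            assert refs[t] != refs[t - 1]
            assert intr[t] != refs[t - 1]


def test_simulate_behavior_deterministic(feature_model_rdm):
    a = simulate_behavior(feature_model_rdm, n_participants=2, rng_seed=9)
    b = simulate_behavior(feature_model_rdm, n_participants=2, rng_seed=9)
    assert a.equals(b)


def test_simulate_behavior_limit_regime(feature_model_rdm):
    """Steep psychometric slope: the most dissimilar pairs are always
    answered correctly."""
    params = PsychometricParams(accuracy_slope=50.0, accuracy_offset=0.0, rt_sigma=1e-6)
    trials = simulate_behavior(feature_model_rdm, n_participants=5, rng_seed=1, params=params)
    sq = feature_model_rdm.to_square()
    labels = feature_model_rdm.labels
    dmax = sq.max()
    for _, row in trials.iterrows():
        if sq[labels.index(row.reference), labels.index(row.intruder)] == dmax:
            assert row.correct == 1


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------


def test_embed_rdm_reproduces_distances(feature_model_rdm, rng):
    pats = embed_rdm(feature_model_rdm, n_channels=16, rng=rng)
    got = np.array([((pats[i] - pats[j]) ** 2).sum() for i, j in pair_indices(11)])
    want = feature_model_rdm.values
    scale = got @ want / (want @ want)
    assert np.max(np.abs(got - scale * want)) <= 1e-6 * want.max()


def test_embed_rdm_too_few_channels(feature_model_rdm, rng):
    with pytest.raises(ValueError):
        embed_rdm(feature_model_rdm, n_channels=5, rng=rng)


def test_embed_rejects_non_euclidean(rng):
    # a 4-point "RDM" violating Euclidean embeddability as squared distances
    bad = RDM(labels=list("abcd"), values=[1, 1, 16, 1, 1, 1], metric="bad")
    with pytest.raises(ValueError):
        embed_rdm(bad, n_channels=8, rng=rng)


def test_random_spd_covariance_properties(rng):
    cov = random_spd_covariance(12, rng, condition_number=10.0)
    w = np.linalg.eigvalsh(cov)
    assert w.min() > 0
    assert w.max() / w.min() <= 10.0 + 1e-9
    assert np.trace(cov) == pytest.approx(12.0)


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------


def small_spec(feature_model_rdm, regularity, snr=0.5, sfreq=125.0):
    early = random_geometry_rdm(feature_model_rdm.labels, rng_seed=77)
    return SimulationSpec(
        rdm_early=early,
        rdm_late=feature_model_rdm,
        regularity=regularity,
        snr=snr,
        n_channels=16,
        sampling_rate=sfreq,
    )


def test_simulate_epochs_metadata_complete(feature_model_rdm, regularity_scores):
    spec = small_spec(feature_model_rdm, regularity_scores)
    ep = simulate_epochs(spec, n_runs=2, rng_seed=0)
    assert ep.n_epochs == 2 * 11 * 30
    md = ep.metadata
    assert set(md["run"]) == {1, 2}
    assert md.groupby("block")["is_oddball"].sum().eq(4).all()
    assert md["within_block_pos"].between(1, 30).all()
    # oddballs never occupy the first six positions
    assert (md.loc[md["is_oddball"], "within_block_pos"] > 6).all()


def test_simulate_epochs_deterministic(feature_model_rdm, regularity_scores):
    spec = small_spec(feature_model_rdm, regularity_scores)
    a = simulate_epochs(spec, n_runs=2, rng_seed=4)
    b = simulate_epochs(spec, n_runs=2, rng_seed=4)
    assert np.array_equal(a.data, b.data)
    assert a.metadata.equals(b.metadata)


def test_simulate_epochs_low_noise_window_geometry(feature_model_rdm, regularity_scores):
    """With tiny noise, the crossnobis RDM inside each window correlates
    almost perfectly with its planted model."""
    spec = small_spec(feature_model_rdm, regularity_scores, snr=50.0)
    ep = simulate_epochs(spec, n_runs=4, rng_seed=2)
    labels, pats = epoch_condition_patterns(ep)
    series = crossnobis_time_series(pats, labels)
    times = ep.times

    def mean_corr(model, lo, hi):
        win = (times >= lo) & (times < hi)
        mv = model.subset(labels).values.astype(float)
        rs = [np.corrcoef(series[:, t], mv)[0, 1] for t in np.flatnonzero(win)]
        return np.mean(rs)

    # early window contains early geometry + (overlap) late geometry;
    # isolate pure segments of each window
    assert mean_corr(spec.rdm_early, 60, 128) > 0.99
    assert mean_corr(spec.rdm_late, 320, 400) > 0.99


def test_simulate_epochs_window_validation(feature_model_rdm, regularity_scores):
    with pytest.raises(ValueError):
        SimulationSpec(
            rdm_early=feature_model_rdm,
            rdm_late=feature_model_rdm,
            regularity=regularity_scores,
            window_early_ms=(-500.0, 200.0),
        )
    with pytest.raises(ValueError):
        SimulationSpec(
            rdm_early=feature_model_rdm,
            rdm_late=feature_model_rdm,
            regularity=regularity_scores,
            snr=-1.0,
        )


# ---------------------------------------------------------------------------
# beta volumes
# ---------------------------------------------------------------------------


def test_simulate_beta_volumes_region_swap_symmetry():
    labels = [f"s{i}" for i in range(5)]
    a = random_geometry_rdm(labels, rng_seed=1)
    b = random_geometry_rdm(labels, rng_seed=2)
    grid = (10, 10, 10)
    ra = synth.box_mask(grid, (1, 1, 1), (4, 4, 4))
    rb = synth.box_mask(grid, (6, 6, 6), (9, 9, 9))
    v1 = simulate_beta_volumes(a, b, ra, rb, n_runs=2, snr=100.0, rng_seed=3)[0]
    v2 = simulate_beta_volumes(b, a, rb, ra, n_runs=2, snr=100.0, rng_seed=3)[0]
    # swapping regions together with models plants the same geometries
    from geomrep.searchlight import searchlight_rsa

    m1 = searchlight_rsa(v1, [a], radius_voxels=2)[0]
    m2 = searchlight_rsa(v2, [a], radius_voxels=2)[0]
    assert np.nanmean(m1[ra]) > 0.8
    assert np.nanmean(m2[ra]) > 0.8


def test_simulate_beta_volumes_validation():
    labels = ["a", "b", "c"]
    m = random_geometry_rdm(labels, rng_seed=0)
    grid = (6, 6, 6)
    ra = synth.box_mask(grid, (0, 0, 0), (3, 3, 3))
    with pytest.raises(ValueError):
        simulate_beta_volumes(m, m, ra, ra, rng_seed=0)  # overlapping regions
    mask = np.zeros(grid, dtype=bool)
    rb = synth.box_mask(grid, (4, 4, 4), (6, 6, 6))
    with pytest.raises(ValueError):
        simulate_beta_volumes(m, m, ra, rb, mask=mask, rng_seed=0)  # outside mask
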