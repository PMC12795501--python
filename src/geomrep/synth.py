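"""Synthetic data with planted representational structure.

Generators for every input the pipeline consumes:

* oddball miniblock designs (30 items, 4 oddballs, none in the first 6
  positions, never two in a row);
* intruder-display layouts (6 shapes on two half-circles);
* visual-search trial tables whose pooled statistics encode a
  ground-truth dissimilarity structure;
* MEG-like epoch arrays in which condition-pattern geometry follows one
  model RDM in an early time window and another in a late window, and
  oddball responses grow and accelerate with geometric regularity;
* fMRI-like per-run beta volumes with two planted regions expressing the
  two model geometries.

Model RDMs are realized as channel- or voxel-space patterns by classical
multidimensional scaling: RDM entries are treated as squared Euclidean
distances, so the generated patterns reproduce the target RDM exactly
(up to one global scale) whenever it is Euclidean-realizable — which
holds in particular for Hamming distances between binary feature
vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoding import EpochSet, default_times, DEFAULT_SFREQ
from .rsa import RDM, vector_to_squareform
from .searchlight import BetaVolume
from .stimuli import (
    SCANNER_ROTATIONS_DEG,
    SCANNER_SCALES,
    sample_transforms,
)

# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

N_BLOCK_ITEMS = 30
N_BLOCK_ODDBALLS = 4
N_PROTECTED = 6  # leading items that can never be oddballs


@dataclass
class DesignBlock:
    """One oddball miniblock: a reference shape shown 30 times with 4
    embedded deviants."""

    shape: str
    items: list  # dicts: scale, rotation_deg, is_oddball, oddball_direction
    block_index: int = 0

    def __post_init__(self):
        odd = [i for i, it in enumerate(self.items) if it["is_oddball"]]
        if len(odd) != sum(1 for it in self.items if it["is_oddball"]):
            raise ValueError("inconsistent oddball flags")
        if any(i < N_PROTECTED for i in odd):
            raise ValueError("oddball within the protected initial items")
        if any(b - a == 1 for a, b in zip(odd, odd[1:])):
            raise ValueError("two consecutive oddballs")

    @property
    def oddball_positions(self) -> list[int]:
        return [i for i, it in enumerate(self.items) if it["is_oddball"]]


def make_miniblock_design(
    shape: str,
    n_items: int = N_BLOCK_ITEMS,
    n_oddballs: int = N_BLOCK_ODDBALLS,
    rng_seed: int | np.random.Generator = 0,
    block_index: int = 0,
) -> DesignBlock:
    """Sample a miniblock uniformly over the valid oddball placements.

    Valid placements: oddballs only after the first 6 items and never on
    consecutive positions.  Sampling is by rejection from the uniform
    distribution over position subsets, which is uniform over the valid
    configuration set.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    candidates = np.arange(N_PROTECTED, n_items)
    if n_oddballs > 0:
        if len(candidates) < 2 * n_oddballs - 1:
            raise ValueError("oddball constraints unsatisfiable")
        while True:
            pos = np.sort(rng.choice(candidates, size=n_oddballs, replace=False))
            if n_oddballs < 2 or np.all(np.diff(pos) > 1):
                break
        positions = set(int(p) for p in pos)
    else:
        positions = set()

    items = []
    for i in range(n_items):
        scale = float(rng.choice(SCANNER_SCALES))
        rot = float(rng.choice(SCANNER_ROTATIONS_DEG))
        is_odd = i in positions
        items.append(
            {
                "scale": scale,
                "rotation_deg": rot,
                "is_oddball": bool(is_odd),
                "oddball_direction": int(rng.integers(1, 5)) if is_odd else None,
            }
        )
    return DesignBlock(shape=shape, items=items, block_index=block_index)


def make_run_design(
    shapes: list[str], rng_seed: int | np.random.Generator = 0, run_index: int = 0
) -> list[DesignBlock]:
    """One run: one miniblock per shape, in random order."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    order = list(rng.permutation(list(shapes)))
    return [
        make_miniblock_design(s, rng_seed=rng, block_index=run_index * len(shapes) + k)
        for k, s in enumerate(order)
    ]


# ---------------------------------------------------------------------------
# intruder displays
# ---------------------------------------------------------------------------

DISPLAY_CIRCLE_RADIUS_PX = 120.0
DISPLAY_SHIFT_PX = 100.0


def display_positions() -> np.ndarray:
    """The 6 display positions: two half-circles of radius 120 px shifted
    100 px outward; three leftmost slots then three rightmost slots."""
    angles = [0.0, math.pi / 2, math.pi]
    pos = []
    for side in (-1.0, 1.0):
        for th in angles:
            pos.append(
                (
                    side * (DISPLAY_SHIFT_PX + DISPLAY_CIRCLE_RADIUS_PX * math.sin(th)),
                    DISPLAY_CIRCLE_RADIUS_PX * math.cos(th),
                )
            )
    return np.array(pos)


def make_intruder_display(
    reference: str,
    intruder: str,
    rng_seed: int | np.random.Generator = 0,
    previous_intruder_slot: int | None = None,
) -> list[dict]:
    """Six placed shapes, exactly one intruder, distinct transforms.

    Scale and rotation are drawn without replacement from the 6-value
    scanner sets, so no two shapes in a display share either.  The
    intruder slot is uniform over the six positions, excluding the
    previous display's slot when given.
    """
    if reference == intruder:
        raise ValueError("reference and intruder must differ")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    transforms = sample_transforms(
        6, SCANNER_SCALES, SCANNER_ROTATIONS_DEG, rng_seed=rng
    )
    slots = [s for s in range(6) if s != previous_intruder_slot]
    intruder_slot = int(rng.choice(slots))
    positions = display_positions()
    return [
        {
            "slot": s,
            "position_px": tuple(positions[s]),
            "shape": intruder if s == intruder_slot else reference,
            "is_intruder": s == intruder_slot,
            "scale": transforms[s][0],
            "rotation_deg": transforms[s][1],
        }
        for s in range(6)
    ]


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsychometricParams:
    """Links ground-truth dissimilarity to accuracy and RT.

    P(correct) = logistic(accuracy_slope * d + accuracy_offset);
    RT = exp(log_rt_mu - rt_slope * d + noise), with d the z-scored
    ground-truth dissimilarity.  Defaults give roughly 60–95% accuracy
    and 1–2.5 s RTs over a unit-spread dissimilarity range.
    """

    accuracy_slope: float = 1.2
    accuracy_offset: float = 1.0
    log_rt_mu: float = math.log(1500.0)  # ms
    rt_slope: float = 0.25
    rt_sigma: float = 0.30

    def __post_init__(self):
        # accuracy must increase and RT decrease with dissimilarity
        if not (self.accuracy_slope > 0 and self.rt_slope > 0 and self.rt_sigma >= 0):
            raise ValueError("psychometric parameters give a degenerate task model")


def ordered_pair_sequence(labels: list[str], rng: np.random.Generator) -> list[tuple]:
    """All ordered (reference, intruder) pairs in a randomized order with
    the task's constraints: consecutive trials never share a reference,
    and a trial's intruder differs from the previous reference."""
    pairs = [(r, i) for r in labels for i in labels if r != i]
    for _ in range(1000):  # randomized greedy with restart on dead ends
        remaining = [pairs[k] for k in rng.permutation(len(pairs))]
        order = []
        while remaining:
            prev_ref = order[-1][0] if order else None
            ok = [
                k
                for k, (r, i) in enumerate(remaining)
                if prev_ref is None or (r != prev_ref and i != prev_ref)
            ]
            if not ok:
                break
            k = ok[int(rng.integers(len(ok)))]
            order.append(remaining.pop(k))
        if not remaining:
            return order
    raise RuntimeError("could not satisfy trial-ordering constraints")


def simulate_behavior(
    ground_truth: RDM,
    n_participants: int = 330,
    params: PsychometricParams = PsychometricParams(),
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Visual-search trial table: one trial per ordered pair per
    participant, accuracy increasing and RT decreasing in dissimilarity."""
    rng = np.random.default_rng(rng_seed)
    labels = ground_truth.labels
    sq = ground_truth.to_square()
    off = sq[~np.eye(len(labels), dtype=bool)]
    mu, sd = off.mean(), off.std()
    if sd == 0:
        raise ValueError("ground-truth RDM has zero variance")

    rows = []
    for p in range(n_participants):
        for ref, intr in ordered_pair_sequence(labels, rng):
            d = (sq[labels.index(ref), labels.index(intr)] - mu) / sd
            p_correct = 1.0 / (1.0 + math.exp(-(params.accuracy_slope * d + params.accuracy_offset)))
            correct = bool(rng.random() < p_correct)
            rt = math.exp(
                params.log_rt_mu - params.rt_slope * d + params.rt_sigma * rng.standard_normal()
            )
            rows.append((f"p{p:04d}", ref, intr, int(correct), rt))
    return pd.DataFrame(
        rows, columns=["participant_id", "reference", "intruder", "correct", "rt"]
    )


# ---------------------------------------------------------------------------
# RDM -> pattern embedding
# ---------------------------------------------------------------------------


def embed_rdm(rdm: RDM, n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """Realize an RDM as condition patterns (conditions x channels).

    Classical MDS: RDM entries are squared Euclidean distances; the
    double-centered Gram matrix is eigendecomposed and the patterns are
    rotated into channel space by a random orthogonal map.  Exact for
    Euclidean-realizable RDMs (small negative eigenvalues from numerical
    noise are clipped).
    """
    n = rdm.n_conditions
    if n - 1 > n_channels:
        raise ValueError("more conditions than channels + 1: embedding impossible")
    d2 = vector_to_squareform(rdm.values, n)
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(gram)
    if w.min() < -1e-6 * max(w.max(), 1.0):
        raise ValueError("RDM is not Euclidean-realizable (large negative eigenvalue)")
    w = np.clip(w, 0.0, None)
    x = v * np.sqrt(w)  # n x n, columns ordered by eigenvalue ascending
    x = x[:, ::-1][:, : min(n - 1, n_channels)]
    # random orthogonal rotation into channel space
    a = rng.standard_normal((n_channels, x.shape[1]))
    q, _ = np.linalg.qr(a)
    return x @ q.T


def random_geometry_rdm(
    labels: list[str], dim: int = 8, rng_seed: int | np.random.Generator = 0
) -> RDM:
    """Euclidean-realizable random geometry: squared pairwise distances of
    i.i.d. Gaussian condition points (useful as a control model RDM)."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    pts = rng.standard_normal((len(labels), dim))
    from .rsa import pair_indices

    vals = [((pts[i] - pts[j]) ** 2).sum() for i, j in pair_indices(len(labels))]
    return RDM(labels=list(labels), values=np.array(vals), metric="random-geometry")


def random_spd_covariance(
    p: int, rng: np.random.Generator, condition_number: float = 10.0
) -> np.ndarray:
    """Random SPD covariance with bounded condition number, trace = p."""
    a = rng.standard_normal((p, p))
    q, _ = np.linalg.qr(a)
    eig = np.linspace(1.0, condition_number, p)
    cov = (q * eig) @ q.T
    return cov * (p / np.trace(cov))


# ---------------------------------------------------------------------------
# MEG-like epochs
# ---------------------------------------------------------------------------


@dataclass
class SimulationSpec:
    """Planted two-stage representational structure for epoch simulation.

    Geometry A (e.g. a CNN-like model RDM) shapes the condition patterns
    in an early window, geometry B (e.g. the geometric-feature RDM) in a
    late window.  Oddball epochs add a deviance component along a common
    channel direction whose amplitude grows and whose onset latency
    shrinks with the reference shape's regularity.
    """

    rdm_early: RDM
    rdm_late: RDM
    regularity: dict
    window_early_ms: tuple = (60.0, 320.0)
    window_late_ms: tuple = (128.0, 400.0)
    snr: float = 0.5
    n_channels: int = 16
    sampling_rate: float = DEFAULT_SFREQ
    oddball_amp_base: float = 1.0
    oddball_amp_slope: float = 0.15  # per feature of regularity
    oddball_latency_base_ms: float = 260.0
    oddball_latency_slope_ms: float = 5.0  # earlier per feature
    oddball_duration_ms: float = 300.0
    noise_condition_number: float = 10.0

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if sorted(self.rdm_early.labels) != sorted(self.rdm_late.labels):
            raise ValueError("the two model RDMs must share a label set")
        times = default_times(self.sampling_rate)
        for w in (self.window_early_ms, self.window_late_ms):
            if not (times[0] <= w[0] < w[1] <= times[-1]):
                raise ValueError(f"window {w} outside the epoch span")
        missing = set(self.rdm_early.labels) - set(self.regularity)
        if missing:
            raise ValueError(f"regularity missing for shapes: {sorted(missing)}")


def simulate_epochs(
    spec: SimulationSpec,
    n_runs: int = 8,
    rng_seed: int = 0,
    designs: list[list[DesignBlock]] | None = None,
) -> EpochSet:
    """Simulate one participant's oddball session as an EpochSet.

    One epoch per design item; condition patterns realize the early/late
    model geometries inside their windows (scaled to ``snr`` relative to
    unit-variance channel noise); oddball deviance amplitude and onset
    follow the regularity of the block's reference shape; additive noise
    is drawn with a random well-conditioned spatial covariance.
    """
    rng = np.random.default_rng(rng_seed)
    labels = list(spec.rdm_early.labels)
    if designs is None:
        designs = [make_run_design(labels, rng_seed=rng, run_index=r) for r in range(n_runs)]

    times = default_times(spec.sampling_rate)
    n_times = times.size
    p = spec.n_channels

    pat_a = embed_rdm(spec.rdm_early, p, rng)
    pat_b = embed_rdm(spec.rdm_late.subset(labels), p, rng)

    # scale so the RMS channel amplitude of each geometry is snr
    def rms_scale(x):
        r = np.sqrt((x**2).mean())
        return spec.snr / r if r > 0 else 1.0

    pat_a = pat_a * rms_scale(pat_a)
    pat_b = pat_b * rms_scale(pat_b)

    u = rng.standard_normal(p)
    u *= spec.snr / np.sqrt((u**2).mean())  # deviance direction

    win_a = (times >= spec.window_early_ms[0]) & (times < spec.window_early_ms[1])
    win_b = (times >= spec.window_late_ms[0]) & (times < spec.window_late_ms[1])

    cov = random_spd_covariance(p, rng, spec.noise_condition_number)
    chol = np.linalg.cholesky(cov)

    reg = {k: float(v) for k, v in spec.regularity.items()}

    data = []
    meta = []
    for r, run in enumerate(designs):
        for block in run:
            c = labels.index(block.shape)
            amp = spec.oddball_amp_base + spec.oddball_amp_slope * reg[block.shape]
            onset = (
                spec.oddball_latency_base_ms
                - spec.oddball_latency_slope_ms * reg[block.shape]
            )
            win_o = (times >= onset) & (times < onset + spec.oddball_duration_ms)
            for pos, item in enumerate(block.items, start=1):
                sig = np.zeros((p, n_times))
                sig[:, win_a] += pat_a[c][:, None]
                sig[:, win_b] += pat_b[c][:, None]
                if item["is_oddball"]:
                    sig[:, win_o] += (amp * u)[:, None]
                noise = chol @ rng.standard_normal((p, n_times))
                data.append(sig + noise)
                meta.append(
                    {
                        "shape": block.shape,
                        "is_oddball": bool(item["is_oddball"]),
                        "run": r + 1,
                        "block": block.block_index,
                        "within_block_pos": pos,
                        "oddball_direction": item["oddball_direction"],
                        "scale": item["scale"],
                        "rotation_deg": item["rotation_deg"],
                    }
                )
    return EpochSet(
        data=np.stack(data),
        times=times,
        metadata=pd.DataFrame(meta),
        sampling_rate=spec.sampling_rate,
    )


# ---------------------------------------------------------------------------
# fMRI-like beta volumes
# ---------------------------------------------------------------------------


def box_mask(shape: tuple, lo: tuple, hi: tuple) -> np.ndarray:
    """Axis-aligned box region [lo, hi) as a boolean mask."""
    m = np.zeros(shape, dtype=bool)
    m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return m


def simulate_beta_volumes(
    rdm_a: RDM,
    rdm_b: RDM,
    region_a: np.ndarray,
    region_b: np.ndarray,
    mask: np.ndarray | None = None,
    n_runs: int = 4,
    n_subjects: int = 1,
    snr: float = 0.25,
    voxel_size_mm: float = 2.0,
    rng_seed: int = 0,
) -> list[BetaVolume]:
    """Per-subject beta volumes with a planted double dissociation.

    Voxels in region A carry condition patterns realizing model A's RDM,
    region B realizes model B, all other voxels are pure noise; run-wise
    noise is independent, patterns are consistent across runs within a
    subject and re-drawn across subjects.
    """
    region_a = np.asarray(region_a, dtype=bool)
    region_b = np.asarray(region_b, dtype=bool)
    if (region_a & region_b).any():
        raise ValueError("planted regions overlap")
    if mask is None:
        mask = np.ones(region_a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if ((region_a | region_b) & ~mask).any():
        raise ValueError("planted regions extend outside the mask")
    labels = list(rdm_a.labels)
    if sorted(labels) != sorted(rdm_b.labels):
        raise ValueError("the two model RDMs must share a label set")
    n_cond = len(labels)
    rng = np.random.default_rng(rng_seed)

    out = []
    for _ in range(n_subjects):
        pat_a = embed_rdm(rdm_a, int(region_a.sum()), rng)
        pat_b = embed_rdm(rdm_b.subset(labels), int(region_b.sum()), rng)
        for pat in (pat_a, pat_b):
            r = np.sqrt((pat**2).mean())
            if r > 0:
                pat *= snr / r
        data = rng.standard_normal((n_runs,) + region_a.shape + (n_cond,))
        for run in range(n_runs):
            for c in range(n_cond):
                vol = data[run, ..., c]
                vol[region_a] += pat_a[c]
                vol[region_b] += pat_b[c]
        out.append(
            BetaVolume(
                data=data,
                mask=mask,
                condition_labels=labels,
                voxel_size_mm=voxel_size_mm,
            )
        )
    return out
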