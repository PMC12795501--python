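"""Time-resolved oddball decoding of MEG-like epoch data.

A logistic-regression decoder is trained at each timepoint to classify
epochs as reference or oddball, pooled over shapes, and tested per shape
with the imbalance-robust ROC area under the curve.  Cross-validation
follows a six-split scheme over the 8 runs (even/odd, first/second half,
runs {1,2,5,6}/{3,4,7,8}, each direction), so that the classifier never
sees test runs during training.  Decoding time courses can be smoothed
with a centered uniform window, correlated with geometric regularity
across shapes, and summarized by the latency at which performance first
exceeds a threshold (57% by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress, rankdata, t as t_dist
from sklearn.linear_model import LogisticRegression

from .cluster import ClusterConfig, TEMPORAL_DEFAULTS, temporal_cluster_test

#: epoch window in ms at the default 250 Hz sampling
DEFAULT_TMIN_MS = -150.0
DEFAULT_TMAX_MS = 1150.0
DEFAULT_SFREQ = 250.0

#: the three run partitions of the fold scheme (1-based run ids); each is
#: used in both directions, yielding 6 train/test splits.
RUN_PARTITIONS = (
    ({2, 4, 6, 8}, {1, 3, 5, 7}),  # even vs odd
    ({1, 2, 3, 4}, {5, 6, 7, 8}),  # first vs second half
    ({1, 2, 5, 6}, {3, 4, 7, 8}),
)

METADATA_COLUMNS = ("shape", "is_oddball", "run", "block", "within_block_pos")


def default_times(sfreq: float = DEFAULT_SFREQ) -> np.ndarray:
    step = 1000.0 / sfreq
    return np.arange(DEFAULT_TMIN_MS, DEFAULT_TMAX_MS + step / 2, step)


@dataclass
class EpochSet:
    """epochs x channels x timepoints array with per-epoch metadata."""

    data: np.ndarray
    times: np.ndarray  # milliseconds
    metadata: pd.DataFrame
    sampling_rate: float = DEFAULT_SFREQ

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x timepoints")
        if self.data.shape[2] != self.times.size:
            raise ValueError("times length must match the time axis")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata length must equal epoch count")
        missing = set(METADATA_COLUMNS) - set(self.metadata.columns)
        if missing:
            raise ValueError(f"missing metadata columns: {sorted(missing)}")
        wbp = self.metadata["within_block_pos"]
        if ((wbp < 1) | (wbp > 30)).any():
            raise ValueError("within_block_pos must lie in [1, 30]")
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            times=self.times,
            metadata=self.metadata.loc[mask].reset_index(drop=True),
            sampling_rate=self.sampling_rate,
        )

    def shapes(self) -> list[str]:
        return sorted(self.metadata["shape"].unique())


def epoch_condition_patterns(
    epochs: EpochSet, references_only: bool = True
) -> tuple[list[str], np.ndarray]:
    """Average epochs into per-(shape, run) patterns for temporal RSA.

    Returns (labels, array conditions x runs x channels x timepoints);
    runs act as the cross-validation folds.  Oddball epochs are dropped
    by default.  Every condition must appear in every run.
    """
    sub = epochs.select(~epochs.metadata["is_oddball"].to_numpy()) if references_only else epochs
    labels = sub.shapes()
    runs = sorted(sub.metadata["run"].unique())
    n_ch, n_t = sub.data.shape[1], sub.data.shape[2]
    out = np.empty((len(labels), len(runs), n_ch, n_t))
    meta = sub.metadata
    for ci, s in enumerate(labels):
        for ri, r in enumerate(runs):
            sel = ((meta["shape"] == s) & (meta["run"] == r)).to_numpy()
            if not sel.any():
                raise ValueError(f"condition {s!r} missing from run {r}")
            out[ci, ri] = sub.data[sel].mean(axis=0)
    return labels, out


@dataclass(frozen=True)
class DecodeConfig:
    """Settings for the time-resolved oddball decoder."""

    latency_threshold: float = 0.57  # AUC units
    smooth_window_ms: float = 100.0
    per_shape_training: bool = False
    normalization: str = "per-timepoint"  # or "whole-window"
    ridge_c: float = 1.0  # inverse L2 penalty for numerical stability

    def __post_init__(self):
        if not (0.5 < self.latency_threshold < 1):
            raise ValueError("latency_threshold must lie in (0.5, 1)")
        if self.smooth_window_ms < 0:
            raise ValueError("smooth_window_ms must be >= 0")
        if self.normalization not in {"per-timepoint", "whole-window"}:
            raise ValueError("normalization must be 'per-timepoint' or 'whole-window'")


def drop_block_initial(epochs: EpochSet, k: int = 6) -> EpochSet:
    """Remove the first k epochs of every block (never oddballs by design,
    and 'oddballs' relative to the previous block's shape)."""
    if k == 0:
        return epochs
    return epochs.select((epochs.metadata["within_block_pos"] > k).to_numpy())


def enumerate_folds(runs_present=None) -> list[tuple[set, set]]:
    """The 6 (train_runs, test_runs) splits of the fold scheme."""
    folds = []
    for a, b in RUN_PARTITIONS:
        folds.append((set(a), set(b)))
        folds.append((set(b), set(a)))
    if runs_present is not None:
        present = set(int(r) for r in runs_present)
        folds = [(tr & present, te & present) for tr, te in folds]
        if any(not tr or not te for tr, te in folds):
            raise ValueError("fold scheme needs epochs in every run group 1..8")
    return folds


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC area under the curve via the rank-sum (Mann-Whitney) identity.

    Ties in the scores receive average ranks, matching the trapezoidal
    ROC convention; invariant to strictly monotone score transforms.
    """
    y_true = np.asarray(y_true).astype(bool)
    n1 = int(y_true.sum())
    n0 = y_true.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(np.asarray(scores, dtype=float))
    return float((ranks[y_true].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def _normalize_epochs(data: np.ndarray, mode: str) -> np.ndarray:
    """z-score each epoch across channels, per timepoint or whole-window."""
    if mode == "per-timepoint":
        mu = data.mean(axis=1, keepdims=True)
        sd = data.std(axis=1, keepdims=True)
    else:
        mu = data.mean(axis=(1, 2), keepdims=True)
        sd = data.std(axis=(1, 2), keepdims=True)
    return (data - mu) / np.where(sd > 0, sd, 1.0)


def time_resolved_oddball_decode(
    epochs: EpochSet,
    config: DecodeConfig = DecodeConfig(),
    shapes: list[str] | None = None,
) -> np.ndarray:
    """AUC array (shape x timepoint) for reference-vs-oddball decoding.

    Training pools all shapes (or trains one decoder per shape with
    ``per_shape_training``); testing is always per shape on runs disjoint
    from the training runs; the score is the ROC AUC averaged over the 6
    splits.  Test cells with a single class are NaN, never imputed.
    """
    shapes = shapes or epochs.shapes()
    meta = epochs.metadata
    y = meta["is_oddball"].to_numpy().astype(int)
    run = meta["run"].to_numpy().astype(int)
    shape_arr = meta["shape"].to_numpy()
    folds = enumerate_folds(runs_present=run)
    data = _normalize_epochs(epochs.data, config.normalization)
    n_times = data.shape[2]

    auc = np.full((len(shapes), n_times, len(folds)), np.nan)
    clf = LogisticRegression(C=config.ridge_c, max_iter=500, tol=1e-4)
    for f, (train_runs, test_runs) in enumerate(folds):
        train = np.isin(run, list(train_runs))
        test = np.isin(run, list(test_runs))
        train_sets = (
            {s: train & (shape_arr == s) for s in shapes}
            if config.per_shape_training
            else {None: train}
        )
        for t in range(n_times):
            xt = data[:, :, t]
            fitted = {}
            for key, tr_mask in train_sets.items():
                if len(np.unique(y[tr_mask])) < 2:
                    fitted[key] = None
                    continue
                clf.fit(xt[tr_mask], y[tr_mask])
                fitted[key] = (clf.coef_.copy(), clf.intercept_.copy())
            for s_idx, s in enumerate(shapes):
                key = s if config.per_shape_training else None
                if fitted[key] is None:
                    continue
                te = test & (shape_arr == s)
                if len(np.unique(y[te])) < 2:
                    continue  # undefined cell, flagged as NaN
                coef, intercept = fitted[key]
                scores = xt[te] @ coef.ravel() + intercept[0]
                auc[s_idx, t, f] = roc_auc(y[te], scores)
    return np.nanmean(auc, axis=2)


def sliding_average(series: np.ndarray, window_ms: float, sfreq: float) -> np.ndarray:
    """Centered uniform moving average along the last axis.

    Window edges are truncated (the average is over the available
    samples), so length is preserved and a constant series is unchanged.
    """
    series = np.asarray(series, dtype=float)
    if window_ms <= 0:
        return series.copy()
    w = int(round(window_ms / 1000.0 * sfreq))
    if w < 1:
        raise ValueError("window shorter than the sample spacing")
    half = (w - 1) // 2
    n = series.shape[-1]
    out = np.empty_like(series)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + (w - half))
        out[..., i] = np.nanmean(series[..., lo:hi], axis=-1)
    return out


def regularity_correlation(
    auc_stack: np.ndarray,
    regularity: np.ndarray,
    config: ClusterConfig = TEMPORAL_DEFAULTS,
    seed: int = 0,
):
    """Correlate decoding performance with regularity, with cluster stats.

    ``auc_stack`` is participants x shapes x timepoints; ``regularity``
    one value per shape.  Returns (r array participants x timepoints,
    cluster results from the one-tailed sign-flip permutation test).
    """
    auc_stack = np.asarray(auc_stack, dtype=float)
    regularity = np.asarray(regularity, dtype=float)
    if auc_stack.ndim != 3:
        raise ValueError("auc_stack must be participants x shapes x timepoints")
    if auc_stack.shape[1] != regularity.size or regularity.size < 3:
        raise ValueError("need one regularity value per shape, >= 3 shapes")
    if np.ptp(regularity) == 0:
        raise ValueError("constant regularity vector")

    n_part, n_shape, n_time = auc_stack.shape
    reg_c = regularity - regularity.mean()
    r = np.empty((n_part, n_time))
    for p in range(n_part):
        x = auc_stack[p]
        xc = x - np.nanmean(x, axis=0, keepdims=True)
        num = np.nansum(xc * reg_c[:, None], axis=0)
        den = np.sqrt(np.nansum(xc**2, axis=0) * (reg_c**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r[p] = np.where(den > 0, num / den, np.nan)
    clusters = temporal_cluster_test(r, config=config, seed=seed)
    return r, clusters


def decode_latency(
    auc: np.ndarray,
    times: np.ndarray,
    threshold: float = 0.57,
    onset_ms: float = 0.0,
) -> np.ndarray:
    """Per-shape latency: first post-onset time with AUC above threshold.

    Shapes never exceeding the threshold get NaN (excluded downstream).
    """
    auc = np.atleast_2d(np.asarray(auc, dtype=float))
    times = np.asarray(times, dtype=float)
    out = np.full(auc.shape[0], np.nan)
    eligible = times >= onset_ms
    for s in range(auc.shape[0]):
        above = eligible & (auc[s] > threshold)
        if above.any():
            out[s] = times[np.argmax(above)]
    return out


def slope_test(latencies: np.ndarray, regularity: np.ndarray):
    """One-tailed group test of latency-on-regularity slopes against 0.

    ``latencies`` is participants x shapes (NaN = undefined latency).
    Participants with fewer than 3 defined latencies are excluded.  The
    alternative is "more regular -> earlier", i.e. mean slope < 0.
    Returns (slopes, t statistic, one-tailed p).
    """
    latencies = np.asarray(latencies, dtype=float)
    regularity = np.asarray(regularity, dtype=float)
    slopes = []
    for row in latencies:
        ok = np.isfinite(row)
        if ok.sum() < 3 or np.ptp(regularity[ok]) == 0:
            continue  # excluded participant
        slopes.append(linregress(regularity[ok], row[ok]).slope)
    slopes = np.asarray(slopes)
    if slopes.size < 2:
        raise ValueError("fewer than 2 participants with defined latencies")
    n = slopes.size
    tstat = slopes.mean() / (slopes.std(ddof=1) / np.sqrt(n))
    p_one = float(t_dist.cdf(tstat, df=n - 1))  # H1: slope < 0
    return slopes, float(tstat), p_one
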