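"""RDM data model and cross-validated Mahalanobis (crossnobis) RSA.

The representational dissimilarity matrix (RDM) stores only the upper
triangle of the symmetric condition-by-condition dissimilarity matrix.
Crossnobis distances are computed across independent data folds, which
makes them unbiased estimates of the squared Mahalanobis distance:
within-condition distances have expectation zero and estimates may be
negative, which is deliberate and never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations, permutations

import numpy as np
from scipy.linalg import sqrtm


def n_pairs(n_conditions: int) -> int:
    return n_conditions * (n_conditions - 1) // 2


def pair_indices(n_conditions: int) -> list[tuple[int, int]]:
    """Upper-triangle (i, j) pairs, i < j, row-major order."""
    return list(combinations(range(n_conditions), 2))


def squareform_to_vector(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    n = mat.shape[0]
    return np.array([mat[i, j] for i, j in pair_indices(n)])


def vector_to_squareform(vec: np.ndarray, n_conditions: int) -> np.ndarray:
    mat = np.zeros((n_conditions, n_conditions))
    for (i, j), v in zip(pair_indices(n_conditions), np.asarray(vec, dtype=float)):
        mat[i, j] = mat[j, i] = v
    return mat


@dataclass
class RDM:
    """Labeled condition set with a vector of pairwise dissimilarities.

    ``precision`` optionally carries a per-entry precision matrix used for
    whitened RDM comparison (identity assumed when absent).
    """

    labels: list[str]
    values: np.ndarray
    metric: str = "unknown"
    precision: np.ndarray | None = None

    def __post_init__(self):
        self.labels = list(self.labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate condition labels")
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != n_pairs(len(self.labels)):
            raise ValueError(
                f"expected {n_pairs(len(self.labels))} dissimilarities for "
                f"{len(self.labels)} conditions, got {self.values.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite dissimilarities")
        if self.precision is not None:
            self.precision = np.asarray(self.precision, dtype=float)
            m = self.values.size
            if self.precision.shape not in {(m,), (m, m)}:
                raise ValueError("precision must be per-entry vector or matrix")

    @property
    def n_conditions(self) -> int:
        return len(self.labels)

    def to_square(self) -> np.ndarray:
        return vector_to_squareform(self.values, self.n_conditions)

    @classmethod
    def from_square(cls, labels, mat, metric="unknown", atol=1e-9) -> "RDM":
        mat = np.asarray(mat, dtype=float)
        if not np.allclose(mat, mat.T, atol=atol):
            raise ValueError("square RDM input is asymmetric")
        mat = 0.5 * (mat + mat.T)
        return cls(labels=labels, values=squareform_to_vector(mat), metric=metric)

    def entry(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        if i == j:
            return 0.0
        i, j = min(i, j), max(i, j)
        return float(self.to_square()[i, j])

    def subset(self, labels) -> "RDM":
        """Restrict to a label subset (order as given)."""
        labels = list(labels)
        missing = set(labels) - set(self.labels)
        if missing:
            raise KeyError(f"labels not in RDM: {sorted(missing)}")
        sq = self.to_square()
        idx = [self.labels.index(l) for l in labels]
        return RDM(
            labels=labels,
            values=squareform_to_vector(sq[np.ix_(idx, idx)]),
            metric=self.metric,
        )

    def zscored(self) -> "RDM":
        """z-score the off-diagonal entries (all-equal entries map to zeros)."""
        v = self.values
        sd = v.std(ddof=0)
        if sd == 0:
            z = np.zeros_like(v)
        else:
            z = (v - v.mean()) / sd
        return replace(self, values=z, metric=self.metric + "-z")


@dataclass
class PatternSet:
    """conditions x folds x channels measurement array with fold labels.

    ``residuals`` (samples x channels), when present, feed the noise
    covariance used by the Mahalanobis metric.
    """

    data: np.ndarray
    condition_labels: list[str]
    fold_labels: list | None = None
    residuals: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be conditions x folds x channels")
        n_cond, n_fold, n_chan = self.data.shape
        if n_fold < 2:
            raise ValueError("crossnobis needs at least 2 folds")
        if n_chan < 1:
            raise ValueError("at least one channel required")
        if len(self.condition_labels) != n_cond:
            raise ValueError("condition label count mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite patterns")
        if self.fold_labels is None:
            self.fold_labels = list(range(n_fold))

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def n_folds(self) -> int:
        return self.data.shape[1]


def noise_covariance(
    residuals: np.ndarray | None,
    n_channels: int | None = None,
    shrinkage: str | float = "auto",
) -> np.ndarray:
    """Shrinkage-regularized noise covariance (P x P).

    Shrinks the sample covariance toward its own diagonal with a
    Ledoit–Wolf-style analytic weight when ``shrinkage="auto"``; a float in
    [0, 1] fixes the weight (1 keeps the diagonal only).  With no residuals
    the identity is returned and Mahalanobis degrades to Euclidean.
    """
    if residuals is None:
        if n_channels is None:
            raise ValueError("n_channels required when residuals are absent")
        return np.eye(n_channels)
    x = np.asarray(residuals, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite residuals")
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("residuals must be samples x channels, >= 2 samples")
    n, p = x.shape
    xc = x - x.mean(axis=0)
    s = xc.T @ xc / n
    target = np.diag(np.diag(s))
    if shrinkage == "auto":
        # Ledoit–Wolf-style weight for a diagonal target: ratio of the
        # estimation variance of the off-diagonal entries to their energy.
        var_s = (xc[:, :, None] * xc[:, None, :] - s) ** 2
        phi = var_s.sum(axis=0).sum() / n**2
        gamma = ((s - target) ** 2).sum()
        lam = 1.0 if gamma == 0 else float(np.clip(phi / gamma, 0.0, 1.0))
    else:
        lam = float(shrinkage)
        if not (0 <= lam <= 1):
            raise ValueError("fixed shrinkage must lie in [0, 1]")
    cov = (1 - lam) * s + lam * target
    # Guard positive definiteness for downstream inversion.
    jitter = 1e-10 * np.trace(cov) / p
    return cov + jitter * np.eye(p)


def crossnobis_rdm(
    patterns: PatternSet,
    scheme: str = "leave-one-out",
    normalize_by_channels: bool = True,
) -> RDM:
    """Cross-validated Mahalanobis RDM across folds.

    d(i,j) = mean over independent fold pairs (m != n) of
    (x_i^m - x_j^m)' Sigma^-1 (x_i^n - x_j^n) / P.  With
    ``scheme="leave-one-out"`` fold m is compared against the mean of the
    remaining folds; ``"all-fold-pairs"`` averages all ordered fold pairs.
    Both are unbiased; estimates may be negative.
    """
    if scheme not in {"leave-one-out", "all-fold-pairs"}:
        raise ValueError(f"unknown cross-validation scheme {scheme!r}")
    data = patterns.data
    n_cond, n_fold, p = data.shape
    sigma = noise_covariance(patterns.residuals, n_channels=p)
    sigma_inv = np.linalg.inv(sigma)
    denom = p if normalize_by_channels else 1.0

    pairs = pair_indices(n_cond)
    deltas = np.stack([data[i] - data[j] for i, j in pairs])  # pairs x folds x P
    white = deltas @ sigma_inv  # pairs x folds x P

    if scheme == "all-fold-pairs":
        terms = []
        for m, n in permutations(range(n_fold), 2):
            terms.append(np.einsum("kp,kp->k", white[:, m], deltas[:, n]))
        vals = np.mean(terms, axis=0) / denom
    else:  # leave-one-out: fold m vs mean of the others
        total = deltas.sum(axis=1)
        terms = []
        for m in range(n_fold):
            rest = (total - deltas[:, m]) / (n_fold - 1)
            terms.append(np.einsum("kp,kp->k", white[:, m], rest))
        vals = np.mean(terms, axis=0) / denom

    return RDM(labels=list(patterns.condition_labels), values=vals, metric="crossnobis")


def rdm_entry_precision(
    pattern_sets: list[PatternSet] | PatternSet, scheme: str = "leave-one-out"
) -> np.ndarray:
    """Diagonal entry-precision estimate from fold-resampled crossnobis RDMs.

    Leaves out each fold in turn, recomputes the RDM on the remaining
    folds, and inverts the per-entry variance across the leave-outs.
    """
    ps = pattern_sets if isinstance(pattern_sets, PatternSet) else None
    if ps is None:
        raise TypeError("pass a single PatternSet")
    if ps.n_folds < 3:
        raise ValueError("entry-precision estimation needs >= 3 folds")
    rdms = []
    for m in range(ps.n_folds):
        keep = [k for k in range(ps.n_folds) if k != m]
        sub = PatternSet(
            data=ps.data[:, keep],
            condition_labels=ps.condition_labels,
            fold_labels=[ps.fold_labels[k] for k in keep],
            residuals=ps.residuals,
        )
        rdms.append(crossnobis_rdm(sub, scheme=scheme).values)
    var = np.var(np.stack(rdms), axis=0, ddof=1)
    floor = max(var[var > 0].min() if np.any(var > 0) else 1.0, 1e-12)
    var = np.maximum(var, floor)
    return 1.0 / var


def crossnobis_time_series(
    data: np.ndarray,
    labels: list[str],
    normalize_by_channels: bool = True,
) -> np.ndarray:
    """Leave-one-out crossnobis RDM vector at each timepoint.

    ``data`` is conditions x folds x channels x timepoints (identity
    noise covariance); returns a pairs x timepoints array, vectorized
    over time.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError("data must be conditions x folds x channels x timepoints")
    n_cond, n_fold, p, _ = data.shape
    if n_fold < 2:
        raise ValueError("need at least 2 folds")
    pairs = pair_indices(n_cond)
    if len(labels) != n_cond:
        raise ValueError("label count mismatch")
    deltas = np.stack([data[i] - data[j] for i, j in pairs])  # K x F x P x T
    total = deltas.sum(axis=1)
    acc = np.zeros((len(pairs), data.shape[3]))
    for m in range(n_fold):
        rest = (total - deltas[:, m]) / (n_fold - 1)
        acc += np.einsum("kpt,kpt->kt", deltas[:, m], rest)
    denom = n_fold * (p if normalize_by_channels else 1.0)
    return acc / denom


def whitened_rdm_similarity(empirical: RDM, model: RDM) -> float:
    """Pearson correlation of two RDM vectors after entry whitening.

    Both vectors are multiplied by the matrix square root of the empirical
    RDM's entry-precision estimate; identity precision reduces to plain
    Pearson.  Invariant to positive rescaling of either RDM.
    """
    if empirical.labels != model.labels:
        raise ValueError("RDMs must share an identical ordered label set")
    x = empirical.values
    y = model.values
    prec = empirical.precision
    if prec is not None:
        if prec.ndim == 1:
            w = np.sqrt(prec)
            xw, yw = x * w, y * w
        else:
            w = np.real(sqrtm(prec))
            xw, yw = w @ x, w @ y
    else:
        xw, yw = x, y
    xw = xw - xw.mean()
    yw = yw - yw.mean()
    nx, ny = np.linalg.norm(xw), np.linalg.norm(yw)
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance whitened RDM vector")
    return float(np.clip(xw @ yw / (nx * ny), -1.0, 1.0))


def compare_models_separately(
    empirical_series: list[RDM], models: list[RDM]
) -> np.ndarray:
    """Whitened similarity of each model to each empirical RDM in a series.

    Returns an array models x len(series); models are compared one at a
    time (no cross-model partialling), appropriate when the model RDMs are
    effectively orthogonal.
    """
    out = np.empty((len(models), len(empirical_series)))
    for j, emp in enumerate(empirical_series):
        for i, model in enumerate(models):
            out[i, j] = whitened_rdm_similarity(emp, model)
    return out
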