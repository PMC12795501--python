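"""Behavioral dissimilarity estimation from visual-search trials.

In the visual-search task a participant looks for one intruder shape
among exemplars of a reference shape.  The dissimilarity of a shape pair
is estimated as mean success rate divided by mean response time — easy
search (high accuracy, fast) means dissimilar shapes.  Ordered pairs are
averaged into an unordered RDM and z-scored.  The module also provides
RDM multiple regression on model RDMs, non-metric (ordinal) MDS
embedding, and projection of a per-shape property into the MDS plane
with bootstrap significance.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import orthogonal_procrustes
from scipy.stats import ttest_rel
from sklearn.manifold import MDS

from .rsa import RDM, n_pairs, pair_indices


@dataclass(frozen=True)
class TrialRecord:
    """One visual-search trial."""

    participant_id: str
    reference: str
    intruder: str
    correct: bool
    rt: float  # milliseconds

    def __post_init__(self):
        if self.reference == self.intruder:
            raise ValueError("reference and intruder must differ")
        if not (np.isfinite(self.rt) and self.rt > 0):
            raise ValueError("rt must be finite and positive")


@dataclass
class BehavioralRDM:
    """Empirical RDM with raw (rate/time) and z-scored values."""

    labels: list[str]
    raw_values: np.ndarray  # 1/ms, unordered upper triangle
    z_values: np.ndarray
    n_trials: np.ndarray  # trials contributing per unordered cell

    def as_rdm(self, z: bool = True) -> RDM:
        return RDM(
            labels=self.labels,
            values=self.z_values if z else self.raw_values,
            metric="search-rate-over-rt" + ("-z" if z else ""),
        )


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in trials],
            "reference": [t.reference for t in trials],
            "intruder": [t.intruder for t in trials],
            "correct": [int(t.correct) for t in trials],
            "rt": [t.rt for t in trials],
        }
    )


def empirical_rdm(
    trials: list[TrialRecord] | pd.DataFrame,
    pool_participants: bool = True,
    labels: list[str] | None = None,
    include_error_rts: bool = True,
) -> BehavioralRDM:
    """Estimate the empirical dissimilarity RDM from search trials.

    Each ordered pair (reference, intruder) is scored as
    mean(correct) / mean(rt); the two ordered estimates are averaged into
    the unordered cell, and the unordered values are finally z-scored.
    With ``pool_participants`` trials are pooled across participants
    before the ratio is formed (the ratio of pooled means, not the mean
    of ratios).  ``include_error_rts=False`` restricts the RT average to
    correct trials (cells whose trials are all errors then contribute 0).
    """
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    if len(df) == 0:
        raise ValueError("no trials")
    if not pool_participants and df["participant_id"].nunique() > 1:
        raise ValueError(
            "pool_participants=False requires trials from a single participant"
        )
    if labels is None:
        labels = sorted(set(df["reference"]) | set(df["intruder"]))
    lab_idx = {l: k for k, l in enumerate(labels)}
    n = len(labels)

    acc_sum = np.zeros((n, n))
    rt_sum = np.zeros((n, n))
    rt_cnt = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for ref, intr, corr, rt in zip(df["reference"], df["intruder"], df["correct"], df["rt"]):
        i, j = lab_idx[ref], lab_idx[intr]
        acc_sum[i, j] += corr
        cnt[i, j] += 1
        if include_error_rts or corr:
            rt_sum[i, j] += rt
            rt_cnt[i, j] += 1

    pairs = pair_indices(n)
    raw = np.empty(n_pairs(n))
    ntr = np.empty(n_pairs(n), dtype=int)
    for k, (i, j) in enumerate(pairs):
        vals = []
        for a, b in ((i, j), (j, i)):
            if cnt[a, b] == 0:
                continue
            acc = acc_sum[a, b] / cnt[a, b]
            if rt_cnt[a, b] == 0:  # all-error cell with error RTs excluded
                vals.append(0.0)
            else:
                vals.append(acc / (rt_sum[a, b] / rt_cnt[a, b]))
        if not vals:
            raise ValueError(f"empty cell for pair ({labels[i]}, {labels[j]})")
        raw[k] = np.mean(vals)
        ntr[k] = int(cnt[i, j] + cnt[j, i])

    sd = raw.std(ddof=0)
    if sd == 0:
        warnings.warn("all dissimilarity estimates identical; z-scores set to 0")
        z = np.zeros_like(raw)
    else:
        z = (raw - raw.mean()) / sd
    return BehavioralRDM(labels=list(labels), raw_values=raw, z_values=z, n_trials=ntr)


@dataclass
class RdmRegressionResult:
    model_names: list[str]
    coefficients: np.ndarray
    intercept: float
    r_squared: float
    pvalues: np.ndarray
    per_unit_coefficients: pd.DataFrame | None = None
    coef_difference_t: float | None = None
    coef_difference_p: float | None = None

    @property
    def weight_ratio(self) -> float:
        """coef[0] / coef[1] (first model relative to second)."""
        return float(self.coefficients[0] / self.coefficients[1])


def rdm_regression(
    empirical: RDM,
    models: list[RDM],
    model_names: list[str] | None = None,
    per_unit: list[RDM] | None = None,
) -> RdmRegressionResult:
    """Multiple OLS regression of an empirical RDM on model RDMs.

    All RDMs must share the empirical label set (models are re-ordered via
    subsetting).  When ``per_unit`` supplies one empirical RDM per
    participant, the regression is also fitted per participant and the
    first two models' coefficients are compared with a paired t-test.
    """
    if model_names is None:
        model_names = [m.metric for m in models]
    x = np.column_stack([m.subset(empirical.labels).values for m in models])
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient model design")
    fit = sm.OLS(empirical.values, design).fit()

    per_coefs = None
    t_diff = p_diff = None
    if per_unit is not None:
        rows = []
        for unit_rdm in per_unit:
            f = sm.OLS(unit_rdm.subset(empirical.labels).values, design).fit()
            rows.append(f.params[1:])
        per_coefs = pd.DataFrame(rows, columns=model_names)
        if len(models) >= 2 and len(rows) >= 2:
            t_diff, p_diff = ttest_rel(per_coefs.iloc[:, 0], per_coefs.iloc[:, 1])
            t_diff, p_diff = float(t_diff), float(p_diff)

    return RdmRegressionResult(
        model_names=list(model_names),
        coefficients=np.asarray(fit.params[1:]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        pvalues=np.asarray(fit.pvalues[1:]),
        per_unit_coefficients=per_coefs,
        coef_difference_t=t_diff,
        coef_difference_p=p_diff,
    )


def mds_embed(
    rdm: RDM,
    dims: int = 2,
    n_restarts: int = 32,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Two-dimensional ordinal (non-metric) MDS embedding of an RDM.

    Runs ``n_restarts`` seeded random initializations and returns the
    configuration with the lowest normalized stress.  Deterministic for a
    given seed.
    """
    n = rdm.n_conditions
    if n < dims + 1:
        raise ValueError("need more conditions than embedding dimensions")
    d = rdm.to_square()
    d = d - d.min()  # non-metric MDS uses ranks; shift for nonnegativity
    np.fill_diagonal(d, 0.0)
    best = (None, np.inf)
    seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31)]
    for s in seeds:
        mds = MDS(
            n_components=dims,
            metric_mds=False,
            metric="precomputed",
            init="random",
            n_init=1,
            random_state=s,
            normalized_stress=True,
            max_iter=500,
            eps=1e-9,
        )
        coords = mds.fit_transform(d)
        if mds.stress_ < best[1]:
            best = (coords, float(mds.stress_))
    return best


def project_property(coords: np.ndarray, prop: np.ndarray) -> dict:
    """Regress a per-condition property on the MDS axes.

    Returns the per-axis coefficients, the (unit) direction of the
    property gradient in the plane, and the fit R^2.
    """
    coords = np.asarray(coords, dtype=float)
    prop = np.asarray(prop, dtype=float)
    if len(prop) != coords.shape[0]:
        raise ValueError("property length must equal the number of conditions")
    if np.ptp(prop) == 0:
        raise ValueError("zero-variance property")
    fit = sm.OLS(prop, sm.add_constant(coords)).fit()
    coefs = np.asarray(fit.params[1:])
    norm = np.linalg.norm(coefs)
    direction = coefs / norm if norm > 0 else coefs
    return {
        "coefficients": coefs,
        "direction": direction,
        "r_squared": float(fit.rsquared),
    }


def project_property_bootstrap(
    trials: pd.DataFrame | list[TrialRecord],
    prop_by_label: dict[str, float],
    n_resamples: int = 200,
    seed: int = 0,
    dims: int = 2,
    n_restarts: int = 8,
) -> dict:
    """Property projection with bootstrap-over-participants significance.

    Each resample redraws participants with replacement, recomputes the
    pooled empirical RDM, re-embeds it (aligning to the point-estimate
    configuration by orthogonal Procrustes), and re-projects the
    property.  Two-sided p per axis = fraction of bootstrap coefficients
    crossing 0.
    """
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    labels = sorted(set(df["reference"]) | set(df["intruder"]))
    prop = np.array([prop_by_label[l] for l in labels], dtype=float)

    base_rdm = empirical_rdm(df, labels=labels).as_rdm()
    base_coords, stress = mds_embed(base_rdm, dims=dims, n_restarts=n_restarts, seed=seed)
    base_proj = project_property(base_coords, prop)

    rng = np.random.default_rng(seed)
    participants = df["participant_id"].unique()
    groups = dict(tuple(df.groupby("participant_id")))
    boot = np.empty((n_resamples, dims))
    for b in range(n_resamples):
        drawn = rng.choice(participants, size=len(participants), replace=True)
        sample = pd.concat([groups[p] for p in drawn], ignore_index=True)
        rdm_b = empirical_rdm(sample, labels=labels).as_rdm()
        coords_b, _ = mds_embed(
            rdm_b, dims=dims, n_restarts=n_restarts, seed=int(rng.integers(2**31))
        )
        coords_bc = coords_b - coords_b.mean(axis=0)
        rot, _ = orthogonal_procrustes(coords_bc, base_coords - base_coords.mean(axis=0))
        boot[b] = project_property(coords_bc @ rot, prop)["coefficients"]

    p_axes = np.array(
        [2 * min((boot[:, k] <= 0).mean(), (boot[:, k] >= 0).mean()) for k in range(dims)]
    )
    return {
        "coordinates": base_coords,
        "stress": stress,
        "coefficients": base_proj["coefficients"],
        "direction": base_proj["direction"],
        "p_axes": p_axes,
        "bootstrap_coefficients": boot,
        "labels": labels,
    }
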