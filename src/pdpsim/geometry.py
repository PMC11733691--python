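"""State-space characterization of population activity.

Works on a RatePatternSet: a (patterns x neurons) matrix of time-averaged
firing rates with per-pattern metadata (trajectory, subspace pixel, odor
concentrations).  Provides PCA, the participation ratio (an eigenvalue-based
effective dimensionality), angles between edges connecting a pure-odor
response to its neighboring mixture responses, and the Mahalanobis distance
between an activity vector and a reference class of patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .odors import StimulusSchedule, pattern_correlation, time_averaged_rates
from .simulation import SimResult

__all__ = [
    "RatePatternSet", "SpectrumSummary", "pca", "participation_ratio",
    "edge_angles", "mahalanobis", "mahalanobis_subsampled",
]


@dataclass
class RatePatternSet:
    """Time-averaged activity patterns plus stimulus metadata."""

    rates: np.ndarray            # (n_patterns, n_neurons), Hz
    meta: pd.DataFrame           # one row per pattern

    def __post_init__(self) -> None:
        if len(self.meta) != len(self.rates):
            raise ValueError("metadata rows must match patterns")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @classmethod
    def from_simresult(cls, result: SimResult, window: float | None = None,
                       half_windows: bool = False) -> "RatePatternSet":
        """Per-epoch rate patterns from a simulation.

        ``window`` limits averaging to the first ``window`` s of each epoch.
        With ``half_windows`` two patterns per epoch are produced (first and
        second half of the window), as used to enlarge classifier training
        sets.
        """
        sch = result.schedule
        rows, rates = [], []
        for k, ep in enumerate(sch.epochs):
            w = ep.duration if window is None else min(window, ep.duration)
            spans = ([(ep.t_on, ep.t_on + w / 2), (ep.t_on + w / 2, ep.t_on + w)]
                     if half_windows else [(ep.t_on, ep.t_on + w)])
            for h, (a, b) in enumerate(spans):
                t, ids = result.spikes_e
                sel = (t >= a) & (t < b)
                rates.append(np.bincount(ids[sel], minlength=result.n_e) / (b - a))
                rows.append({"epoch": k, "half": h, **ep.label})
        return cls(rates=np.array(rates), meta=pd.DataFrame(rows))

    @classmethod
    def from_schedule_ob(cls, schedule: StimulusSchedule,
                         window: float = 1.0) -> "RatePatternSet":
        """Noiseless OB (input-side) patterns for the same stimuli."""
        rows, rates = [], []
        for k, ep in enumerate(schedule.epochs):
            rates.append(time_averaged_rates(ep.pattern, min(window, ep.duration)))
            rows.append({"epoch": k, **ep.label})
        return cls(rates=np.array(rates), meta=pd.DataFrame(rows))

    @property
    def n_patterns(self) -> int:
        return len(self.rates)


@dataclass(frozen=True)
class SpectrumSummary:
    eigenvalues: np.ndarray      # variance per PC, descending
    participation_ratio: float
    components: np.ndarray = field(repr=False)   # (n_pc, n_neurons)
    projections: np.ndarray = field(repr=False)  # (n_patterns, n_pc)
    mean: np.ndarray = field(repr=False)


def pca(patterns: RatePatternSet | np.ndarray,
        n_components: int | None = None) -> SpectrumSummary:
    """PCA of mean-centered activity patterns (patterns as observations).

    Eigenvalues are the variances along the PCs (descending); the
    participation ratio is computed from the full spectrum regardless of
    ``n_components``.
    """
    x = patterns.rates if isinstance(patterns, RatePatternSet) else np.asarray(patterns)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least two patterns")
    mu = x.mean(axis=0)
    xc = x - mu
    # SVD of the centered data; eigenvalues of the covariance = s^2/(n-1)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    lam = s ** 2 / (x.shape[0] - 1)
    if n_components is not None:
        if n_components > len(lam):
            raise ValueError(
                f"requested {n_components} components, only {len(lam)} available")
        keep = n_components
    else:
        keep = len(lam)
    return SpectrumSummary(
        eigenvalues=lam,
        participation_ratio=participation_ratio(lam),
        components=vt[:keep],
        projections=(u * s)[:, :keep],
        mean=mu,
    )


def participation_ratio(eigenvalues: np.ndarray) -> float:
    """PR = (sum lambda)^2 / sum lambda^2, in [1, #nonzero]."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < -1e-12 * max(1.0, np.abs(lam).max())):
        raise ValueError("eigenvalues must be non-negative")
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total == 0.0:
        raise ValueError("all-zero spectrum")
    return float(total ** 2 / np.sum(lam ** 2))


def edge_angles(projections: np.ndarray, pure_idx: int,
                neighbor_idx: np.ndarray) -> np.ndarray:
    """Angles (rad) between edges from a pure-odor response to neighbors.

    ``projections``: (n_patterns, n_pc) PC-space coordinates (typically the
    first 400 PCs).  For every unordered pair of neighbors (s_y, s_z) the
    angle at the pure-odor vertex p is
    arccos((s_y - p).(s_z - p) / (|s_y - p||s_z - p|)).  Zero-length edges
    are excluded.
    """
    p = projections[pure_idx]
    vecs = projections[np.asarray(neighbor_idx)] - p
    norms = np.linalg.norm(vecs, axis=1)
    keep = norms > 0
    vecs, norms = vecs[keep], norms[keep]
    out = []
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            c = vecs[i] @ vecs[j] / (norms[i] * norms[j])
            out.append(np.arccos(np.clip(c, -1.0, 1.0)))
    return np.asarray(out)


def most_similar_mixtures(ob_patterns: RatePatternSet, pure_row: np.ndarray,
                          n_neighbors: int = 7,
                          exclude: np.ndarray | None = None) -> np.ndarray:
    """Indices of the mixtures with the highest input correlation to a pure
    odor (computed on OB rate vectors)."""
    cors = np.array([
        pattern_correlation(pure_row, r) for r in ob_patterns.rates])
    if exclude is not None:
        cors[np.asarray(exclude)] = -np.inf
    return np.argsort(-cors)[:n_neighbors]


def mahalanobis(v: np.ndarray, class_patterns: np.ndarray) -> float:
    """Mahalanobis distance between vector ``v`` and a class of patterns.

    sqrt((v - mu)^T S^-1 (v - mu)) with the class sample mean and
    covariance.  Raises if the covariance is singular (the caller may
    subsample fewer neurons).
    """
    q = np.asarray(class_patterns, dtype=float)
    v = np.asarray(v, dtype=float)
    mu = q.mean(axis=0)
    s = np.cov(q, rowvar=False)
    s = np.atleast_2d(s)
    sign, logdet = np.linalg.slogdet(s)
    if sign <= 0 or not np.isfinite(logdet):
        raise np.linalg.LinAlgError(
            f"singular class covariance (rank {np.linalg.matrix_rank(s)} < "
            f"{s.shape[0]}); reduce the neuron count")
    d = v - mu
    return float(np.sqrt(d @ np.linalg.solve(s, d)))


def mahalanobis_subsampled(v_full: np.ndarray, class_full: np.ndarray,
                           pool: np.ndarray, seed, n_neurons: int = 80,
                           n_draws: int = 50) -> float:
    """d_M averaged over random draws of ``n_neurons`` from ``pool``.

    ``v_full`` and ``class_full`` are indexed over all neurons; each draw
    selects ``n_neurons`` (without replacement) from ``pool``, computes the
    Mahalanobis distance in that subspace and the results are averaged.
    Draws with singular covariance are skipped (at least one draw must
    succeed).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = np.asarray(pool)
    vals = []
    for _ in range(n_draws):
        sub = rng.choice(pool, size=n_neurons, replace=False)
        try:
            vals.append(mahalanobis(v_full[sub], class_full[:, sub]))
        except np.linalg.LinAlgError:
            continue
    if not vals:
        raise np.linalg.LinAlgError("covariance singular in every draw")
    return float(np.mean(vals))
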