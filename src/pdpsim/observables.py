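"""Constraint observables and E/I co-tuning metrics.

All quantities are measured in the E population and, unless noted, time-
averaged over the first 1.5 s of each odor presentation.  Conductance
observables subtract, per neuron, the time-averaged conductance during the
500 ms preceding odor onset (baseline subtraction may leave small negative
changes; these are retained, as the quantities are change measures).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulation import SimResult

__all__ = [
    "ObservableSummary", "CotuningResult", "firing_rates",
    "conductance_summary", "odor_conductances", "cotuning_correlation",
    "balanced_axis_ratio", "time_binned_pattern_correlation", "amplification",
    "mean_pattern_correlation",
]


@dataclass(frozen=True)
class ObservableSummary:
    """Population-averaged constraint observables of one run."""

    baseline_rate: float      # Hz
    odor_rate: float          # Hz
    g_OE: float               # nS, odor-evoked afferent conductance change
    g_syn: float              # nS, total odor-evoked conductance change
    pct_recurrent: float      # %, g_EE / (g_EE + g_OE) * 100
    mean_output_correlation: float
    n_valid: int              # neurons entering the pct_recurrent average
    per_neuron: pd.DataFrame | None = None


@dataclass(frozen=True)
class CotuningResult:
    per_neuron_r: np.ndarray   # Pearson r of E vs I conductance across odors
    mean_r: float
    slope: float               # balanced-axis I/E ratio
    sd_ratio: float            # SD(balanced) / SD(counter-balanced)
    n_excluded: int


def firing_rates(spikes: tuple[np.ndarray, np.ndarray], n_neurons: int,
                 window: tuple[float, float]) -> np.ndarray:
    """Spike count per neuron in ``window`` divided by its duration (Hz)."""
    a, b = window
    if b <= a:
        raise ValueError("empty rate window")
    t, ids = spikes
    sel = (t >= a) & (t < b)
    return np.bincount(ids[sel], minlength=n_neurons) / (b - a)


def odor_conductances(result: SimResult, response: float = 1.5) -> pd.DataFrame:
    """Per-neuron, per-epoch odor-evoked conductance changes (tidy frame).

    Requires the run to carry the auto-installed (baseline, response) window
    pairs.  Columns: epoch, neuron, g_OE, g_EE, g_IE, g_exc, g_syn.
    """
    if result.window_means is None or result.schedule is None:
        raise ValueError("run has no conductance windows recorded")
    wm = result.window_means
    rows = []
    n_epochs = len(result.schedule.epochs)
    for k in range(n_epochs):
        base, resp = 2 * k, 2 * k + 1
        d_oe = wm["g_OE"][resp] - wm["g_OE"][base]
        d_ee = wm["g_EE"][resp] - wm["g_EE"][base]
        d_ie = wm["g_IE"][resp] - wm["g_IE"][base]
        rows.append(pd.DataFrame({
            "epoch": k,
            "neuron": np.arange(result.n_e),
            "g_OE": d_oe, "g_EE": d_ee, "g_IE": d_ie,
        }))
    df = pd.concat(rows, ignore_index=True)
    df["g_exc"] = df["g_OE"] + df["g_EE"]
    df["g_syn"] = df["g_exc"] + df["g_IE"]
    return df


def conductance_summary(result: SimResult, response: float = 1.5,
                        min_exc: float = 1e-3) -> ObservableSummary:
    """The five constraint observables of a multi-odor run.

    ``min_exc`` flags neurons whose odor-evoked excitatory conductance
    change is too small for the recurrent fraction to be meaningful; they
    are excluded from that average (count reported).
    """
    sch = result.schedule
    df = odor_conductances(result, response)
    base_windows = [(ep.t_on - 0.5, ep.t_on) for ep in sch.epochs]
    resp_windows = [(ep.t_on, ep.t_on + min(response, ep.duration))
                    for ep in sch.epochs]
    base_rate = float(np.mean([
        firing_rates(result.spikes_e, result.n_e, w).mean() for w in base_windows]))
    odor_rate = float(np.mean([
        firing_rates(result.spikes_e, result.n_e, w).mean() for w in resp_windows]))
    ok = df["g_exc"] > min_exc
    pct = 100.0 * df.loc[ok, "g_EE"] / df.loc[ok, "g_exc"]
    rates = [firing_rates(result.spikes_e, result.n_e, w) for w in resp_windows]
    return ObservableSummary(
        baseline_rate=base_rate,
        odor_rate=odor_rate,
        g_OE=float(df["g_OE"].mean()),
        g_syn=float(df["g_syn"].mean()),
        pct_recurrent=float(pct.mean()),
        mean_output_correlation=mean_pattern_correlation(np.array(rates)),
        n_valid=int(ok.sum()),
        per_neuron=df,
    )


def mean_pattern_correlation(rates: np.ndarray) -> float:
    """Mean Pearson correlation over all pairs of activity patterns.

    ``rates``: (n_patterns, n_neurons).  Patterns with zero variance are
    excluded.
    """
    keep = rates.std(axis=1) > 0
    r = rates[keep]
    if len(r) < 2:
        return float("nan")
    c = np.corrcoef(r)
    iu = np.triu_indices(len(r), k=1)
    return float(c[iu].mean())


def cotuning_correlation(g_e: np.ndarray, g_i: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-neuron Pearson correlation between E and I conductances across odors.

    ``g_e``, ``g_i``: (n_odors, n_neurons) time-averaged odor-evoked
    conductances.  Neurons with zero variance in either signal are excluded
    (NaN); the count of exclusions is returned.
    """
    if g_e.shape != g_i.shape or g_e.shape[0] < 3:
        raise ValueError("need matching (n_odors >= 3, n_neurons) arrays")
    ge = g_e - g_e.mean(axis=0)
    gi = g_i - g_i.mean(axis=0)
    se = ge.std(axis=0)
    si = gi.std(axis=0)
    ok = (se > 0) & (si > 0)
    r = np.full(g_e.shape[1], np.nan)
    r[ok] = (ge[:, ok] * gi[:, ok]).mean(axis=0) / (se[ok] * si[ok])
    return r, int((~ok).sum())


def balanced_axis_ratio(g_e: np.ndarray, g_i: np.ndarray,
                        ratio_cap: float = 100.0) -> tuple[float, float]:
    """Balanced-axis slope and dispersion ratio of joint (E, I) conductances.

    The balanced axis is the no-intercept least-squares fit of I on E
    conductance over all neuron-odor pairs (its slope is the network's I/E
    ratio); the counter-balanced axis is orthogonal to it.  Per neuron, the
    odor-wise (gE, gI) pairs are projected on both axes and the ratio of the
    standard deviations (balanced / counter-balanced) is averaged across
    neurons.  Degenerate neurons (zero counter-balanced dispersion) are
    reported at ``ratio_cap``.

    Returns (slope, mean SD ratio).
    """
    ge = np.asarray(g_e, dtype=float).ravel()
    gi = np.asarray(g_i, dtype=float).ravel()
    if ge.size < 2 or ge.shape != gi.shape:
        raise ValueError("need >= 2 matching conductance pairs")
    denom = float(ge @ ge)
    if denom == 0.0:
        raise ValueError("all-zero E conductances")
    slope = float(ge @ gi) / denom
    u = np.array([1.0, slope]) / np.hypot(1.0, slope)
    v = np.array([-u[1], u[0]])
    g_e2 = np.atleast_2d(g_e)
    g_i2 = np.atleast_2d(g_i)
    ratios = []
    for x in range(g_e2.shape[1]):
        pts = np.column_stack([g_e2[:, x], g_i2[:, x]])
        if len(pts) < 2:
            continue
        sb = float(np.std(pts @ u))
        sc = float(np.std(pts @ v))
        if sb == 0.0 and sc == 0.0:
            continue
        ratios.append(min(sb / sc, ratio_cap) if sc > 0 else ratio_cap)
    return slope, float(np.mean(ratios))


def time_binned_pattern_correlation(result: list[SimResult] | SimResult,
                                    t_window: tuple[float, float],
                                    bin_s: float = 0.1) -> np.ndarray:
    """Mean pairwise correlation of E activity vectors across time bins.

    Activity vectors are per-neuron rates in 100 ms bins.  Entry (i, j) is
    the mean Pearson correlation between bin-i and bin-j vectors from
    different trials (and same-trial pairs for i != j); the diagonal uses
    different-trial pairs only.  Pass one result per trial.
    """
    results = [result] if isinstance(result, SimResult) else list(result)
    if len(results) < 2:
        raise ValueError("need >= 2 trials for the diagonal rule")
    a, b = t_window
    edges = np.arange(a, b + bin_s / 2, bin_s)
    n_bins = len(edges) - 1
    mats = []
    for res in results:
        binned = np.stack([
            firing_rates(res.spikes_e, res.n_e, (edges[i], edges[i + 1]))
            for i in range(n_bins)])
        mats.append(binned)
    out = np.full((n_bins, n_bins), np.nan)
    for i in range(n_bins):
        for j in range(i, n_bins):
            vals = []
            for ti in range(len(mats)):
                for tj in range(len(mats)):
                    if i == j and ti >= tj:
                        continue
                    if ti == tj and i >= j:
                        continue
                    x, y = mats[ti][i], mats[tj][j]
                    if x.std() == 0 or y.std() == 0:
                        continue
                    vals.append(np.corrcoef(x, y)[0, 1])
            if vals:
                out[i, j] = out[j, i] = float(np.mean(vals))
    return out


def amplification(structured_rates: np.ndarray, rand_rates: np.ndarray,
                  members: np.ndarray) -> tuple[float, float]:
    """Firing-rate amplification inside and outside an assembly.

    Ratio of mean rates (structured / rand) over the same neuron sets;
    returns NaN for a zero denominator.
    """
    members = np.asarray(members)
    outside = np.setdiff1d(np.arange(len(rand_rates)), members)

    def ratio(sel):
        d = rand_rates[sel].mean()
        return float(structured_rates[sel].mean() / d) if d > 0 else float("nan")

    return ratio(members), ratio(outside)


def rank_compare(a: np.ndarray, b: np.ndarray, alternative: str = "greater"):
    """Wilcoxon rank-sum comparison used for across-network contrasts."""
    return stats.ranksums(a, b, alternative=alternative)
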