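"""Forward-Euler integration of the conductance-based adaptive LIF network.

State variables per neuron: membrane potential V (mV), three synaptic
conductances (nS) split by source population (OB afferent, recurrent E,
recurrent I), and for excitatory neurons an adaptation current z (pA).

Dynamics (dt = 0.1 ms by default):

* a presynaptic spike through a synapse of strength w makes the matching
  conductance jump by w; between spikes each conductance decays
  exponentially with its synaptic time constant (30 ms for excitatory
  sources, 10 ms for inhibitory ones),
* ``g_rest * tau_m * dV/dt = g_rest (E_rest - V) + g_OB (E_exc - V)
  + g_E (E_exc - V) + g_I (E_inh - V) - z``,
* ``tau_a * dz/dt = a (V - E_rest) - z`` and ``z -> z + b`` after each spike
  (E neurons only),
* threshold crossing emits a spike, resets V to the reset potential and
  clamps it there for the refractory period; conductances keep evolving.

The integration loop is JIT-compiled; spike propagation is event-driven
(source-major adjacency), so the cost per time step is dominated by the
element-wise state update and the simulation of ~20 s of biological time of
the full-size network takes on the order of a minute on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .connectivity import WeightMatrices
from .odors import StimulusSchedule, _rate_matrix
from .params import NeuronParams

DEFAULT_DT_MS = 0.1
#: hard per-population spike budget (Hz averaged over the run); hitting it
#: truncates the run and marks the result as runaway
SPIKE_CAP_HZ = 80.0


class SimulationDiverged(RuntimeError):
    """Raised when a state variable becomes non-finite."""


@dataclass
class SimResult:
    """Spikes, traces and windowed conductance averages from one run."""

    spikes_e: tuple[np.ndarray, np.ndarray]  # (times s, neuron ids)
    spikes_i: tuple[np.ndarray, np.ndarray]
    n_e: int
    n_i: int
    dt: float                                # s
    t_end: float                             # s
    schedule: StimulusSchedule | None
    trace_ids: np.ndarray | None = None      # E neurons with full traces
    traces: dict | None = None               # keys g_OE, g_EE, g_IE, V; (n_rec, n_samples)
    trace_dt: float | None = None            # s
    windows: np.ndarray | None = None        # (n_win, 2) start/stop in s
    window_means: dict | None = None         # keys g_OE,g_EE,g_IE; (n_win, n_e)
    truncated: bool = False                  # spike budget exhausted (runaway)
    meta: dict = field(default_factory=dict)

    def e_rates(self, t_start: float, t_stop: float) -> np.ndarray:
        """Per-E-neuron firing rate (Hz) in [t_start, t_stop)."""
        t, ids = self.spikes_e
        sel = (t >= t_start) & (t < t_stop)
        return np.bincount(ids[sel], minlength=self.n_e) / (t_stop - t_start)

    def i_rates(self, t_start: float, t_stop: float) -> np.ndarray:
        t, ids = self.spikes_i
        sel = (t >= t_start) & (t < t_stop)
        return np.bincount(ids[sel], minlength=self.n_i) / (t_stop - t_start)


def _csc_arrays(net: WeightMatrices, pathway: str):
    """Source-major adjacency (indptr, targets, weights in nS)."""
    m = net.mats[pathway].T.tocsr()  # rows = sources
    w = m.data.astype(np.float64) * (net.w_scale[pathway] * 1e-3)
    return m.indptr.astype(np.int64), m.indices.astype(np.int64), w


def _neuron_param_vec(p: NeuronParams) -> np.ndarray:
    return np.array([
        p.tau_m, p.g_rest, p.e_rest, p.e_exc, p.e_inh, p.v_th, p.e_reset,
        p.tau_ref, p.tau_a, p.a, p.b, 1.0 if p.adapt else 0.0,
    ])


@njit(cache=True)
def _kernel(n_steps, dt, eP, iP,
            obe_ptr, obe_tgt, obe_w, obi_ptr, obi_tgt, obi_w,
            ee_ptr, ee_tgt, ee_w, ei_ptr, ei_tgt, ei_w,
            ie_ptr, ie_tgt, ie_w, ii_ptr, ii_tgt, ii_w,
            ob_ptr, ob_cells,
            frozen_i, fi_ptr, fi_cells,
            v_e0, v_i0, tau_syn_e, tau_syn_i,
            rec_ids, rec_stride,
            snap_steps,
            cap_e, cap_i):
    n_e = v_e0.size
    n_i = v_i0.size

    v_e = v_e0.copy()
    v_i = v_i0.copy()
    z_e = np.zeros(n_e)
    gob_e = np.zeros(n_e); ge_e = np.zeros(n_e); gi_e = np.zeros(n_e)
    gob_i = np.zeros(n_i); ge_i = np.zeros(n_i); gi_i = np.zeros(n_i)
    ref_e = np.zeros(n_e, dtype=np.int64)
    ref_i = np.zeros(n_i, dtype=np.int64)

    de = 1.0 - dt / tau_syn_e
    di = 1.0 - dt / tau_syn_i
    nref_e = int(round(eP[7] / dt))
    nref_i = int(round(iP[7] / dt))

    sp_e_t = np.empty(cap_e, dtype=np.float64)
    sp_e_id = np.empty(cap_e, dtype=np.int64)
    sp_i_t = np.empty(cap_i, dtype=np.float64)
    sp_i_id = np.empty(cap_i, dtype=np.int64)
    ne_sp = 0
    ni_sp = 0

    spiked_e = np.empty(n_e, dtype=np.int64)
    spiked_i = np.empty(n_i, dtype=np.int64)
    n_spiked_e = 0
    n_spiked_i = 0

    n_rec = rec_ids.size
    n_samp = (n_steps + rec_stride - 1) // rec_stride if n_rec > 0 else 0
    tr_gob = np.zeros((n_rec, n_samp))
    tr_ge = np.zeros((n_rec, n_samp))
    tr_gi = np.zeros((n_rec, n_samp))
    tr_v = np.zeros((n_rec, n_samp))

    # cumulative per-neuron conductance sums, snapshotted at window edges
    cum_gob = np.zeros(n_e); cum_ge = np.zeros(n_e); cum_gi = np.zeros(n_e)
    n_snap = snap_steps.size
    snap_out = np.zeros((n_snap, 3, n_e))
    snap_i = 0

    truncated_at = -1

    for step in range(n_steps):
        # --- propagate spikes: OB spikes of this step, network spikes of the
        # previous step (conductances jump by w)
        for k in range(ob_ptr[step], ob_ptr[step + 1]):
            c = ob_cells[k]
            for e in range(obe_ptr[c], obe_ptr[c + 1]):
                gob_e[obe_tgt[e]] += obe_w[e]
            for e in range(obi_ptr[c], obi_ptr[c + 1]):
                gob_i[obi_tgt[e]] += obi_w[e]
        for s in range(n_spiked_e):
            c = spiked_e[s]
            for e in range(ee_ptr[c], ee_ptr[c + 1]):
                ge_e[ee_tgt[e]] += ee_w[e]
            for e in range(ei_ptr[c], ei_ptr[c + 1]):
                ge_i[ei_tgt[e]] += ei_w[e]
        if frozen_i:
            n_spiked_i = 0
            for k in range(fi_ptr[step], fi_ptr[step + 1]):
                spiked_i[n_spiked_i] = fi_cells[k]
                n_spiked_i += 1
        for s in range(n_spiked_i):
            c = spiked_i[s]
            for e in range(ie_ptr[c], ie_ptr[c + 1]):
                gi_e[ie_tgt[e]] += ie_w[e]
            for e in range(ii_ptr[c], ii_ptr[c + 1]):
                gi_i[ii_tgt[e]] += ii_w[e]
        n_spiked_e = 0
        n_spiked_i = 0

        # --- record traces / cumulative sums (pre-update state of this step)
        if n_rec > 0 and step % rec_stride == 0:
            samp = step // rec_stride
            for r in range(n_rec):
                x = rec_ids[r]
                tr_gob[r, samp] = gob_e[x]
                tr_ge[r, samp] = ge_e[x]
                tr_gi[r, samp] = gi_e[x]
                tr_v[r, samp] = v_e[x]
        if snap_i < n_snap and snap_steps[snap_i] == step:
            for x in range(n_e):
                snap_out[snap_i, 0, x] = cum_gob[x]
                snap_out[snap_i, 1, x] = cum_ge[x]
                snap_out[snap_i, 2, x] = cum_gi[x]
            snap_i += 1
        for x in range(n_e):
            cum_gob[x] += gob_e[x]
            cum_ge[x] += ge_e[x]
            cum_gi[x] += gi_e[x]

        # --- integrate E neurons
        cm_e = eP[1] * eP[0]
        for x in range(n_e):
            if ref_e[x] > 0:
                ref_e[x] -= 1
                v_e[x] = eP[6]
                z_e[x] += dt * (eP[9] * (v_e[x] - eP[2]) - z_e[x]) / eP[8]
            else:
                dv = (eP[1] * (eP[2] - v_e[x])
                      + gob_e[x] * (eP[3] - v_e[x])
                      + ge_e[x] * (eP[3] - v_e[x])
                      + gi_e[x] * (eP[4] - v_e[x])
                      - z_e[x]) / cm_e
                if eP[11] > 0.0:
                    z_e[x] += dt * (eP[9] * (v_e[x] - eP[2]) - z_e[x]) / eP[8]
                v_e[x] += dt * dv
                if not np.isfinite(v_e[x]):
                    return (sp_e_t[:ne_sp], sp_e_id[:ne_sp], sp_i_t[:ni_sp],
                            sp_i_id[:ni_sp], tr_gob, tr_ge, tr_gi, tr_v,
                            snap_out, step, x, -2)
                if v_e[x] >= eP[5]:
                    if ne_sp >= cap_e:
                        truncated_at = step
                        break
                    sp_e_t[ne_sp] = step * dt
                    sp_e_id[ne_sp] = x
                    ne_sp += 1
                    spiked_e[n_spiked_e] = x
                    n_spiked_e += 1
                    v_e[x] = eP[6]
                    ref_e[x] = nref_e
                    z_e[x] += eP[10]
        if truncated_at >= 0:
            break

        # --- integrate I neurons (skipped when inhibition is replayed)
        if not frozen_i:
            cm_i = iP[1] * iP[0]
            for x in range(n_i):
                if ref_i[x] > 0:
                    ref_i[x] -= 1
                    v_i[x] = iP[6]
                else:
                    dv = (iP[1] * (iP[2] - v_i[x])
                          + gob_i[x] * (iP[3] - v_i[x])
                          + ge_i[x] * (iP[3] - v_i[x])
                          + gi_i[x] * (iP[4] - v_i[x])) / cm_i
                    v_i[x] += dt * dv
                    if not np.isfinite(v_i[x]):
                        return (sp_e_t[:ne_sp], sp_e_id[:ne_sp], sp_i_t[:ni_sp],
                                sp_i_id[:ni_sp], tr_gob, tr_ge, tr_gi, tr_v,
                                snap_out, step, x, -3)
                    if v_i[x] >= iP[5]:
                        if ni_sp >= cap_i:
                            truncated_at = step
                            break
                        sp_i_t[ni_sp] = step * dt
                        sp_i_id[ni_sp] = x
                        ni_sp += 1
                        spiked_i[n_spiked_i] = x
                        n_spiked_i += 1
                        v_i[x] = iP[6]
                        ref_i[x] = nref_i
        if truncated_at >= 0:
            break

        # --- decay conductances (forward Euler)
        for x in range(n_e):
            gob_e[x] *= de; ge_e[x] *= de; gi_e[x] *= di
        for x in range(n_i):
            gob_i[x] *= de; ge_i[x] *= de; gi_i[x] *= di

    return (sp_e_t[:ne_sp], sp_e_id[:ne_sp], sp_i_t[:ni_sp], sp_i_id[:ni_sp],
            tr_gob, tr_ge, tr_gi, tr_v, snap_out, truncated_at, -1, 0)


def ob_spike_events(schedule: StimulusSchedule, t_total: float, dt: float,
                    rng: np.random.Generator, t_offset: float = 0.0):
    """Per-step OB spike lists over [−t_offset, schedule end].

    Returns (indptr, cells) with one slot per integration step; ``t_offset``
    prepends baseline-only warm-up time.  Rates follow the schedule: baseline
    between epochs, the epoch pattern's latency/decay profile within.
    """
    n_mc = schedule.n_mc
    n_steps = int(round(t_total / dt))
    base_p = schedule.baseline_rate * dt
    counts = np.zeros(n_steps, dtype=np.int64)
    step_cells = []
    chunk = max(1, int(round(1.0 / dt)) // 2)
    epochs = sorted(schedule.epochs, key=lambda e: e.t_on)
    for start in range(0, n_steps, chunk):
        stop = min(start + chunk, n_steps)
        tmid = (np.arange(start, stop) + 0.5) * dt - t_offset
        rates = np.full((n_mc, stop - start), schedule.baseline_rate)
        for ep in epochs:
            if ep.t_on >= tmid[-1] + dt or ep.t_on + ep.duration <= tmid[0] - dt:
                continue
            sel = (tmid >= ep.t_on) & (tmid < ep.t_on + ep.duration)
            if sel.any():
                rates[:, sel] = _rate_matrix(ep.pattern, tmid[sel] - ep.t_on)
        p = rates * dt
        if p.max() > 1.0:
            raise ValueError("rate*dt > 1; decrease dt")
        cells, steps = np.nonzero(rng.random(rates.shape) < p)
        order = np.argsort(steps, kind="stable")
        cells, steps = cells[order], steps[order]
        np.add.at(counts, steps + start, 1)
        step_cells.append((steps + start, cells))
    indptr = np.zeros(n_steps + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    all_cells = np.empty(indptr[-1], dtype=np.int64)
    fill = indptr[:-1].copy()
    for steps, cells in step_cells:
        for s, c in zip(steps, cells):
            all_cells[fill[s]] = c
            fill[s] += 1
    return indptr, all_cells


def simulate(net: WeightMatrices, schedule: StimulusSchedule, seed,
             dt_ms: float = DEFAULT_DT_MS,
             warmup: float = 0.5,
             record_ids=None,
             trace_dt_ms: float = 1.0,
             windows: str | np.ndarray | None = "auto",
             frozen_i_spikes: tuple[np.ndarray, np.ndarray] | None = None,
             spike_cap_hz: float = SPIKE_CAP_HZ) -> SimResult:
    """Integrate the network through a stimulus schedule.

    A ``warmup`` period of baseline OB drive precedes the schedule and is
    discarded (spike times are reported relative to schedule time zero).
    ``record_ids`` selects E neurons for full conductance/voltage traces.
    ``windows`` = "auto" installs, per epoch, a 500 ms pre-onset baseline
    window and a response window covering the first 1.5 s (or the epoch
    duration, if shorter); per-window per-E-neuron mean conductances are
    returned in ``window_means``.  ``frozen_i_spikes`` replays the given
    (times, ids) as the inhibitory population instead of simulating it.
    Identical arguments and seed give bit-identical results.
    """
    spec = net.spec
    dt = dt_ms * 1e-3
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_total = warmup + schedule.t_end
    n_steps = int(round(t_total / dt))

    ob_ptr, ob_cells = ob_spike_events(schedule, t_total, dt, rng, t_offset=warmup)

    if frozen_i_spikes is not None:
        ft, fid = frozen_i_spikes
        # +1: a spike detected at step n first reaches its targets at n+1,
        # so injected spikes reproduce a recorded simulation exactly
        steps = np.round((ft + warmup) / dt).astype(np.int64) + 1
        ok = (steps >= 0) & (steps < n_steps)
        steps, fid = steps[ok], fid[ok].astype(np.int64)
        order = np.argsort(steps, kind="stable")
        steps, fid = steps[order], fid[order]
        fi_ptr = np.zeros(n_steps + 1, dtype=np.int64)
        np.cumsum(np.bincount(steps, minlength=n_steps), out=fi_ptr[1:])
        fi_cells = fid
        frozen = True
    else:
        fi_ptr = np.zeros(n_steps + 1, dtype=np.int64)
        fi_cells = np.empty(0, dtype=np.int64)
        frozen = False

    # initial conditions: V uniform within 5 mV above rest, g = z = 0
    v_e0 = spec.e_params.e_rest + 5.0 * rng.random(spec.n_e)
    v_i0 = spec.i_params.e_rest + 5.0 * rng.random(spec.n_i)

    if record_ids is None:
        rec_ids = np.empty(0, dtype=np.int64)
    else:
        rec_ids = np.asarray(record_ids, dtype=np.int64)
    rec_stride = max(1, int(round(trace_dt_ms / dt_ms)))

    if isinstance(windows, str) and windows == "auto":
        win = _auto_windows(schedule)
    elif windows is None:
        win = np.empty((0, 2))
    else:
        win = np.asarray(windows, dtype=float)
    # snapshot steps: all window edges (shifted by warmup), plus the edge at
    # the end of the run so every window can be closed
    edges = np.unique(np.round((win.ravel() + warmup) / dt).astype(np.int64)) \
        if win.size else np.empty(0, dtype=np.int64)
    edges = edges[(edges >= 0) & (edges < n_steps)]

    cap_e = int(spike_cap_hz * spec.n_e * t_total) + 1000
    cap_i = int(spike_cap_hz * spec.n_i * t_total) + 1000

    args = [_csc_arrays(net, p) for p in
            ("OB->E", "OB->I", "E->E", "E->I", "I->E", "I->I")]
    flat = [a for trip in args for a in trip]

    out = _kernel(
        n_steps, dt_ms, _neuron_param_vec(spec.e_params),
        _neuron_param_vec(spec.i_params), *flat,
        ob_ptr, ob_cells, frozen, fi_ptr, fi_cells,
        v_e0, v_i0, spec.tau_syn_e, spec.tau_syn_i,
        rec_ids, rec_stride, edges, cap_e, cap_i,
    )
    (et, eid, it, iid, tr_gob, tr_ge, tr_gi, tr_v, snaps,
     trunc_step, bad_neuron, err) = out
    if err == -2 or err == -3:
        pop = "E" if err == -2 else "I"
        raise SimulationDiverged(
            f"non-finite membrane potential: {pop} neuron {bad_neuron} at "
            f"t={trunc_step * dt - warmup:.4f} s")

    # convert kernel times (ms steps -> s relative to schedule zero)
    et = et * 1e-3 - warmup
    it = it * 1e-3 - warmup
    keep_e, keep_i = et >= 0, it >= 0

    window_means = None
    if win.size:
        window_means = _window_means_from_snaps(win, warmup, dt, edges, snaps)

    traces = None
    if rec_ids.size:
        traces = {"g_OE": tr_gob, "g_EE": tr_ge, "g_IE": tr_gi, "V": tr_v}

    return SimResult(
        spikes_e=(et[keep_e], eid[keep_e]),
        spikes_i=(it[keep_i], iid[keep_i]),
        n_e=spec.n_e, n_i=spec.n_i, dt=dt,
        t_end=schedule.t_end, schedule=schedule,
        trace_ids=rec_ids if rec_ids.size else None,
        traces=traces,
        trace_dt=rec_stride * dt,
        windows=win if win.size else None,
        window_means=window_means,
        truncated=trunc_step >= 0,
        meta={"warmup": warmup, "frozen_i": frozen},
    )


def _auto_windows(schedule: StimulusSchedule,
                  baseline: float = 0.5, response: float = 1.5) -> np.ndarray:
    win = []
    for ep in schedule.epochs:
        win.append((ep.t_on - baseline, ep.t_on))
        win.append((ep.t_on, ep.t_on + min(response, ep.duration)))
    return np.asarray(win)


def _window_means_from_snaps(win, warmup, dt, edges, snaps):
    """Per-window mean conductance per E neuron from cumulative snapshots."""
    edge_of = {int(e): i for i, e in enumerate(edges)}
    n_win = len(win)
    n_e = snaps.shape[2]
    out = {k: np.full((n_win, n_e), np.nan) for k in ("g_OE", "g_EE", "g_IE")}
    for wi, (a, b) in enumerate(win):
        sa = int(round((a + warmup) / dt))
        sb = int(round((b + warmup) / dt))
        if sa not in edge_of or sb not in edge_of or sb <= sa:
            continue
        ia, ib = edge_of[sa], edge_of[sb]
        span = sb - sa
        out["g_OE"][wi] = (snaps[ib, 0] - snaps[ia, 0]) / span
        out["g_EE"][wi] = (snaps[ib, 1] - snaps[ia, 1]) / span
        out["g_IE"][wi] = (snaps[ib, 2] - snaps[ia, 2]) / span
    return out


def measure_psp(w_ps: float, pathway: str, target: NeuronParams,
                tau_syn: float | None = None, dt_ms: float = DEFAULT_DT_MS,
                t_max_ms: float = 600.0) -> float:
    """Peak deflection (mV) of a resting neuron to one presynaptic spike.

    ``pathway`` is "excitatory" or "inhibitory"; ``tau_syn`` defaults to
    30 ms (excitatory) or 10 ms (inhibitory).  Raises if the response
    reaches threshold.
    """
    if pathway not in ("excitatory", "inhibitory"):
        raise ValueError("pathway must be 'excitatory' or 'inhibitory'")
    exc = pathway == "excitatory"
    if tau_syn is None:
        tau_syn = 30.0 if exc else 10.0
    e_rev = target.e_exc if exc else target.e_inh
    g = w_ps * 1e-3  # nS
    v = target.e_rest
    z = 0.0
    peak = 0.0
    cm = target.g_rest * target.tau_m
    n = int(round(t_max_ms / dt_ms))
    for _ in range(n):
        dv = (target.g_rest * (target.e_rest - v) + g * (e_rev - v) - z) / cm
        if target.adapt:
            z += dt_ms * (target.a * (v - target.e_rest) - z) / target.tau_a
        v += dt_ms * dv
        g *= 1.0 - dt_ms / tau_syn
        if v >= target.v_th:
            raise ValueError("suprathreshold unitary input")
        peak = max(peak, abs(v - target.e_rest))
    return peak


def detect_runaway(result: SimResult, rate_threshold: float = 10.0,
                   sustain: float = 0.2, bin_s: float = 0.01) -> bool:
    """True if the E-population rate stays above ``rate_threshold`` Hz for
    ``sustain`` s (or the run hit the spike budget, which implies it)."""
    if result.truncated:
        return True
    t, _ = result.spikes_e
    if t.size == 0:
        return False
    n_bins = max(1, int(np.ceil(result.t_end / bin_s)))
    counts = np.bincount(
        np.clip((t / bin_s).astype(int), 0, n_bins - 1), minlength=n_bins)
    rate = counts / (result.n_e * bin_s)
    need = max(1, int(round(sustain / bin_s)))
    above = rate > rate_threshold
    run = 0
    for a in above:
        run = run + 1 if a else 0
        if run >= need:
            return True
    return False


def shuffle_spike_times(spikes: tuple[np.ndarray, np.ndarray],
                        t_window: tuple[float, float], rng,
                        n_neurons: int) -> tuple[np.ndarray, np.ndarray]:
    """Redistribute each neuron's spikes uniformly within ``t_window``.

    Spike counts per neuron are preserved; spikes outside the window are kept
    untouched.  This destroys the temporal alignment of inhibition with the
    excitatory population while preserving every neuron's rate.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    t, ids = spikes
    a, b = t_window
    inside = (t >= a) & (t < b)
    new_t = t.copy()
    new_t[inside] = a + (b - a) * rng.random(int(inside.sum()))
    order = np.argsort(new_t, kind="stable")
    return new_t[order], ids[order]


def shuffled_inhibition_probe(net: WeightMatrices, odor_patterns, seed,
                              odor_duration: float = 2.0,
                              lead_in: float = 1.0,
                              rate_threshold: float = 10.0,
                              sustain: float = 0.2) -> dict:
    """Runaway probability under within-odor shuffling of inhibitory spikes.

    For each odor: run a control simulation, redistribute every I neuron's
    spike times uniformly over the recording, then replay the shuffled
    inhibition as frozen input while the E population and OB drive evolve
    freely.  Because inhibitory firing is locked to the odor (I cells are
    nearly silent at baseline), the shuffle both decorrelates inhibition
    from the excitatory population and spreads it beyond the odor window,
    so a network whose recurrent excitation is kept in check only by
    reactive inhibition ignites.  Returns the fraction of probes whose
    replay shows runaway activity (plus per-odor flags and control-run
    flags).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flags, control_flags = [], []
    for k, pat in enumerate(odor_patterns):
        sch = StimulusSchedule.from_odors(
            [pat], odor_duration=odor_duration, gap=lead_in, labels=[{"odor": k}])
        control = simulate(net, sch, rng, windows=None)
        control_flags.append(detect_runaway(control, rate_threshold, sustain))
        shuffled = shuffle_spike_times(
            control.spikes_i, (0.0, sch.t_end), rng, net.spec.n_i)
        replay = simulate(net, sch, rng, windows=None, frozen_i_spikes=shuffled)
        flags.append(detect_runaway(replay, rate_threshold, sustain))
    return {
        "probability": float(np.mean(flags)),
        "runaway": np.asarray(flags),
        "control_runaway": np.asarray(control_flags),
    }
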