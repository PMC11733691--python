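"""Headline-quantity reproductions: seeded, self-contained computations.

Each function rebuilds its inputs from scratch (networks, odors, schedules),
runs the simulator or the connectivity-level analysis, and returns the
measured quantity together with the problem size used.  They are the
substance behind the acceptance script and the corresponding tests.
"""

from __future__ import annotations

import numpy as np

from .assemblies import build_structured, select_assembly_e
from .connectivity import build_connectivity
from .observables import balanced_axis_ratio, conductance_summary, odor_conductances
from .odors import (ADJACENT_PAIRS, StimulusSchedule, make_correlated_quartet,
                    make_odor, pattern_correlation, time_averaged_rates)
from .params import CONNECTIVITY_SETS, E_NEURON
from .simulation import measure_psp, shuffled_inhibition_probe, simulate


def rand_network_rates(seed: int, network_set: str = "A", n_odors: int = 5,
                       baseline_s: float = 5.0) -> dict:
    """Baseline rate, odor-evoked rate and recurrent-input fraction of one
    random network.

    One network (given parameter set), ``baseline_s`` seconds of 6 Hz OB
    drive followed by ``n_odors`` uncorrelated odors (2 s each, 1 s gaps).
    Rates are E-population means (odors: first 1.5 s window); the recurrent
    percentage averages g_EE / (g_EE + g_OE) over neurons and odors after
    baseline subtraction.
    """
    rng = np.random.default_rng(seed)
    spec = CONNECTIVITY_SETS[network_set]
    net = build_connectivity(spec, rng)
    pats = [make_odor(rng) for _ in range(n_odors)]
    sch = StimulusSchedule.from_odors(
        pats, odor_duration=2.0, gap=1.0, lead_in=baseline_s + 0.5)
    res = simulate(net, sch, rng)
    summ = conductance_summary(res)
    baseline = float(res.e_rates(0.0, baseline_s).mean())
    return {
        "baseline_rate_hz": baseline,
        "odor_rate_hz": summ.odor_rate,
        "pct_recurrent": summ.pct_recurrent,
        "mean_output_correlation": summ.mean_output_correlation,
        "n": n_odors,
    }


def runaway_probability(seed: int, network_sets=("A", "B", "C", "D"),
                        n_odors: int = 5) -> dict:
    """Probability of runaway activity after shuffling inhibitory spikes.

    One network per parameter set; per odor, a control run is recorded,
    every I neuron's spike times are redistributed uniformly over the
    recording, and the shuffled inhibition is replayed frozen.
    """
    rng = np.random.default_rng(seed)
    flags = []
    for name in network_sets:
        net = build_connectivity(CONNECTIVITY_SETS[name], rng)
        pats = [make_odor(rng) for _ in range(n_odors)]
        out = shuffled_inhibition_probe(net, pats, rng)
        flags.extend(out["runaway"].tolist())
    return {"probability": float(np.mean(flags)),
            "n": len(flags)}


def unitary_epsp(network_set: str = "A") -> dict:
    """Peak EPSP (mV) of a resting E neuron for one E->E spike."""
    w = CONNECTIVITY_SETS[network_set].pathways["E->E"].w
    spec = CONNECTIVITY_SETS[network_set]
    amp = measure_psp(w, "excitatory", spec.e_params,
                      tau_syn=spec.tau_syn_e)
    return {"amplitude_mv": float(amp), "n": 1}


def assembly_overlap_correlated(seed: int, n_nets: int = 5) -> dict:
    """Mean % of shared E neurons between assemblies of two correlated odors.

    Per connectivity seed, two pure odors sharing half of their activated
    and inhibited mitral cells are built and each odor's 100-neuron assembly
    selected by afferent-density ranking.
    """
    rng = np.random.default_rng(seed)
    spec = CONNECTIVITY_SETS["A"]
    shared = []
    for _ in range(n_nets):
        net = build_connectivity(spec, rng)
        quartet = make_correlated_quartet(rng)
        a = select_assembly_e(net, quartet[0], seed=rng)
        b = select_assembly_e(net, quartet[1], seed=rng)
        shared.append(len(np.intersect1d(a, b)))
    return {"pct_shared": float(np.mean(shared)), "n": n_nets}


def assembly_union_fraction(seed: int, n_nets: int = 5,
                            n_odors: int = 15) -> dict:
    """% of E neurons belonging to at least one of 15 assemblies."""
    rng = np.random.default_rng(seed)
    spec = CONNECTIVITY_SETS["A"]
    fracs = []
    for _ in range(n_nets):
        net = build_connectivity(spec, rng)
        members = [select_assembly_e(net, make_odor(rng), seed=rng)
                   for _ in range(n_odors)]
        union = np.unique(np.concatenate(members))
        fracs.append(100.0 * len(union) / spec.n_e)
    return {"pct_union": float(np.mean(fracs)), "n": n_nets}


def correlated_min_input_correlation(seed: int, n_seeds: int = 10,
                                     window: float = 2.0) -> dict:
    """Smallest adjacent-pure-odor OB pattern correlation, averaged over
    odor-set seeds (correlated quartets, time-averaged rate vectors)."""
    rng = np.random.default_rng(seed)
    mins = []
    for _ in range(n_seeds):
        q = make_correlated_quartet(rng)
        rates = [time_averaged_rates(p, window) for p in q]
        mins.append(min(pattern_correlation(rates[i], rates[j])
                        for i, j in ADJACENT_PAIRS))
    return {"min_adjacent_r": float(np.mean(mins)), "n": n_seeds}


def balance_slope(seed: int, n_assemblies: int = 15,
                  n_learned_presented: int = 10) -> dict:
    """No-intercept I-vs-E conductance slope of a Tuned E+I network.

    Builds one Tuned E+I network (published defaults), presents learned
    odors, collects per-neuron time-averaged E and I conductance changes
    per odor and fits gI = k * gE over all neuron-odor pairs.
    """
    rng = np.random.default_rng(seed)
    spec = CONNECTIVITY_SETS["A"]
    net = build_connectivity(spec, rng)
    pats = [make_odor(rng) for _ in range(n_assemblies)]
    sn = build_structured(net, pats, "TunedEI", rng)
    sch = StimulusSchedule.from_odors(
        pats[:n_learned_presented], odor_duration=2.0, gap=1.0)
    res = simulate(sn.net, sch, rng)
    df = odor_conductances(res)
    ge = df.pivot_table(index="epoch", columns="neuron", values="g_exc").to_numpy()
    gi = df.pivot_table(index="epoch", columns="neuron", values="g_IE").to_numpy()
    slope, sd_ratio = balanced_axis_ratio(ge, gi)
    return {"slope": float(slope), "sd_ratio": float(sd_ratio),
            "n": ge.size}
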