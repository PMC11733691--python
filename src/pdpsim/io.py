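"""Serialization: odors as JSON, simulation results as HDF5, summaries as CSV."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .odors import Epoch, MitralCellPattern, StimulusSchedule
from .simulation import SimResult


def pattern_to_dict(p: MitralCellPattern) -> dict:
    return {
        "n_mc": p.n_mc,
        "baseline_rate": p.baseline_rate,
        "activated": p.activated.tolist(),
        "onset_rates": p.onset_rates.tolist(),
        "act_latencies": p.act_latencies.tolist(),
        "decay_taus": p.decay_taus.tolist(),
        "inhibited": p.inhibited.tolist(),
        "inh_rates": p.inh_rates.tolist(),
        "inh_latencies": p.inh_latencies.tolist(),
    }


def pattern_from_dict(d: dict) -> MitralCellPattern:
    return MitralCellPattern(
        n_mc=int(d["n_mc"]),
        baseline_rate=float(d.get("baseline_rate", 6.0)),
        activated=np.asarray(d["activated"], dtype=int),
        onset_rates=np.asarray(d["onset_rates"], dtype=float),
        act_latencies=np.asarray(d["act_latencies"], dtype=float),
        decay_taus=np.asarray(d["decay_taus"], dtype=float),
        inhibited=np.asarray(d["inhibited"], dtype=int),
        inh_rates=np.asarray(d["inh_rates"], dtype=float),
        inh_latencies=np.asarray(d["inh_latencies"], dtype=float),
    )


def save_odors(path, patterns) -> None:
    data = [pattern_to_dict(p) for p in patterns]
    Path(path).write_text(json.dumps(data))


def load_odors(path) -> list[MitralCellPattern]:
    return [pattern_from_dict(d) for d in json.loads(Path(path).read_text())]


def save_result(path, result: SimResult) -> None:
    """SimResult to HDF5 (spikes, traces, windows, schedule metadata)."""
    with h5py.File(path, "w") as f:
        f.attrs["n_e"] = result.n_e
        f.attrs["n_i"] = result.n_i
        f.attrs["dt"] = result.dt
        f.attrs["t_end"] = result.t_end
        f.attrs["truncated"] = result.truncated
        f.create_dataset("spikes_e/t", data=result.spikes_e[0])
        f.create_dataset("spikes_e/id", data=result.spikes_e[1])
        f.create_dataset("spikes_i/t", data=result.spikes_i[0])
        f.create_dataset("spikes_i/id", data=result.spikes_i[1])
        if result.traces is not None:
            g = f.create_group("traces")
            g.attrs["trace_dt"] = result.trace_dt
            g.create_dataset("ids", data=result.trace_ids)
            for k, v in result.traces.items():
                g.create_dataset(k, data=v)
        if result.windows is not None:
            f.create_dataset("windows", data=result.windows)
            g = f.create_group("window_means")
            for k, v in result.window_means.items():
                g.create_dataset(k, data=v)
        if result.schedule is not None:
            sch = result.schedule
            g = f.create_group("schedule")
            g.attrs["t_end"] = sch.t_end
            g.attrs["n_mc"] = sch.n_mc
            g.attrs["baseline_rate"] = sch.baseline_rate
            g.create_dataset("t_on", data=[ep.t_on for ep in sch.epochs])
            g.create_dataset("duration", data=[ep.duration for ep in sch.epochs])
            g.create_dataset(
                "labels", data=json.dumps([
                    {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in ep.label.items()} for ep in sch.epochs]))
            g.create_dataset(
                "patterns",
                data=json.dumps([pattern_to_dict(ep.pattern) for ep in sch.epochs]))


def load_result(path) -> SimResult:
    with h5py.File(path, "r") as f:
        traces = None
        trace_ids = None
        trace_dt = None
        if "traces" in f:
            g = f["traces"]
            trace_ids = g["ids"][()]
            trace_dt = float(g.attrs["trace_dt"])
            traces = {k: g[k][()] for k in g if k != "ids"}
        windows = f["windows"][()] if "windows" in f else None
        window_means = ({k: f["window_means"][k][()] for k in f["window_means"]}
                        if "window_means" in f else None)
        schedule = None
        if "schedule" in f:
            g = f["schedule"]
            labels = json.loads(g["labels"][()].decode())
            pats = [pattern_from_dict(d) for d in json.loads(g["patterns"][()].decode())]
            labels = [
                {k: (tuple(v) if isinstance(v, list) else v) for k, v in lab.items()}
                for lab in labels]
            epochs = [
                Epoch(t_on=float(t), duration=float(d), pattern=p, label=lab)
                for t, d, p, lab in zip(g["t_on"][()], g["duration"][()], pats, labels)]
            schedule = StimulusSchedule(
                epochs=epochs, t_end=float(g.attrs["t_end"]),
                n_mc=int(g.attrs["n_mc"]),
                baseline_rate=float(g.attrs["baseline_rate"]))
        return SimResult(
            spikes_e=(f["spikes_e/t"][()], f["spikes_e/id"][()]),
            spikes_i=(f["spikes_i/t"][()], f["spikes_i/id"][()]),
            n_e=int(f.attrs["n_e"]), n_i=int(f.attrs["n_i"]),
            dt=float(f.attrs["dt"]), t_end=float(f.attrs["t_end"]),
            schedule=schedule, trace_ids=trace_ids, traces=traces,
            trace_dt=trace_dt, windows=windows, window_means=window_means,
            truncated=bool(f.attrs["truncated"]),
        )


def save_network(path, net, assemblies=None) -> None:
    """WeightMatrices (+ optional assemblies) to HDF5."""
    import scipy.sparse as sp

    with h5py.File(path, "w") as f:
        f.attrs["spec"] = json.dumps(_spec_to_dict(net.spec))
        for key, m in net.mats.items():
            g = f.create_group(f"pathways/{key.replace('->', '_')}")
            m = m.tocsr()
            g.attrs["key"] = key
            g.attrs["w_scale"] = net.w_scale[key]
            g.attrs["shape"] = m.shape
            g.create_dataset("indptr", data=m.indptr)
            g.create_dataset("indices", data=m.indices)
            g.create_dataset("data", data=m.data)
        if assemblies:
            g = f.create_group("assemblies")
            for a in assemblies:
                ga = g.create_group(f"a{a.odor_id}")
                ga.create_dataset("e_members", data=a.e_members)
                if a.i_members is not None:
                    ga.create_dataset("i_members", data=a.i_members)


def load_network(path):
    import scipy.sparse as sp

    from .assemblies import Assembly
    from .connectivity import WeightMatrices

    with h5py.File(path, "r") as f:
        spec = _spec_from_dict(json.loads(f.attrs["spec"]))
        mats, w_scale = {}, {}
        for name in f["pathways"]:
            g = f[f"pathways/{name}"]
            key = g.attrs["key"]
            mats[key] = sp.csr_matrix(
                (g["data"][()], g["indices"][()], g["indptr"][()]),
                shape=tuple(g.attrs["shape"]))
            w_scale[key] = float(g.attrs["w_scale"])
        net = WeightMatrices(spec=spec, mats=mats, w_scale=w_scale)
        assemblies = []
        if "assemblies" in f:
            for name in sorted(f["assemblies"], key=lambda s: int(s[1:])):
                g = f[f"assemblies/{name}"]
                assemblies.append(Assembly(
                    odor_id=int(name[1:]),
                    e_members=g["e_members"][()],
                    i_members=g["i_members"][()] if "i_members" in g else None))
        return net, assemblies


def _spec_to_dict(spec) -> dict:
    import dataclasses
    d = dataclasses.asdict(spec)
    return d


def _spec_from_dict(d: dict):
    from .params import ConnectivitySpec, NeuronParams, PathwayParams
    d = dict(d)
    d["pathways"] = {k: PathwayParams(**v) for k, v in d["pathways"].items()}
    d["e_params"] = NeuronParams(**d["e_params"])
    d["i_params"] = NeuronParams(**d["i_params"])
    return ConnectivitySpec(**d)


def save_spikes_csv(path, spikes: tuple[np.ndarray, np.ndarray]) -> None:
    """Two-column CSV (neuron_id, time_s)."""
    t, ids = spikes
    with open(path, "w") as f:
        f.write("neuron_id,time_s\n")
        for i, tt in zip(ids, t):
            f.write(f"{i},{tt:.6f}\n")
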