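"""Shared fixtures: down-scaled networks and cached simulation runs.

Session-scoped fixtures keep total runtime low: the expensive objects (mini
networks, multi-variant runs, subspace trajectories) are built once and
shared by every test that needs them.
"""

import dataclasses

import numpy as np
import pytest

from pdpsim import odors
from pdpsim.assemblies import build_structured
from pdpsim.connectivity import build_connectivity
from pdpsim.params import CONNECTIVITY_SETS, STRUCTURE_DEFAULTS
from pdpsim.presets import mini_spec
from pdpsim.simulation import simulate

MINI_SCALE = 0.25


@pytest.fixture(scope="session")
def mini_conn_spec():
    return mini_spec("A", MINI_SCALE)


@pytest.fixture(scope="session")
def mini_net(mini_conn_spec):
    return build_connectivity(mini_conn_spec, 0)


@pytest.fixture(scope="session")
def mini_odor_set(mini_conn_spec):
    rng = np.random.default_rng(2)
    learned = [odors.make_odor(rng, n_mc=mini_conn_spec.n_ob) for _ in range(4)]
    novel = odors.make_odor(rng, n_mc=mini_conn_spec.n_ob)
    return learned, novel


@pytest.fixture(scope="session")
def mini_schedule(mini_odor_set):
    learned, novel = mini_odor_set
    return odors.StimulusSchedule.from_odors(
        learned + [novel], odor_duration=2.0, gap=1.0)


@pytest.fixture(scope="session")
def mini_structured(mini_net, mini_odor_set):
    """Structured mini networks (4 assemblies) for every variant."""
    learned, _ = mini_odor_set
    out = {"rand": None}
    for variant in ("ScaledI", "TunedI", "TunedEI"):
        cfg = dataclasses.replace(
            STRUCTURE_DEFAULTS[variant].scaled(MINI_SCALE), n_assemblies=4)
        out[variant] = build_structured(mini_net, learned, cfg, 3)
    return out


@pytest.fixture(scope="session")
def mini_runs(mini_net, mini_structured, mini_schedule):
    """One five-odor run per variant (learned odors 0-3, novel odor 4)."""
    runs = {"rand": simulate(mini_net, mini_schedule, 11)}
    for variant in ("ScaledI", "TunedI", "TunedEI"):
        runs[variant] = simulate(mini_structured[variant].net, mini_schedule, 11)
    return runs


@pytest.fixture(scope="session")
def mini_subspace(mini_conn_spec):
    """Four pure odors and a two-trajectory subspace schedule (242 epochs)."""
    rng = np.random.default_rng(5)
    pures = [odors.make_odor(rng, n_mc=mini_conn_spec.n_ob) for _ in range(4)]
    sch = odors.make_trajectories(pures, 2, rng)
    return pures, sch


@pytest.fixture(scope="session")
def mini_structured_subspace(mini_net, mini_subspace, mini_conn_spec):
    """Structured minis whose first two assemblies match subspace pure odors.

    Pure odors 0 and 1 are 'learned' (have assemblies), 2 and 3 'novel';
    two further assemblies represent unrelated odors.
    """
    pures, _ = mini_subspace
    rng = np.random.default_rng(8)
    extra = [odors.make_odor(rng, n_mc=mini_conn_spec.n_ob) for _ in range(2)]
    learned = [pures[0], pures[1]] + extra
    out = {}
    for variant in ("ScaledI", "TunedEI"):
        cfg = dataclasses.replace(
            STRUCTURE_DEFAULTS[variant].scaled(MINI_SCALE), n_assemblies=4)
        out[variant] = build_structured(mini_net, learned, cfg, 3)
    return out


@pytest.fixture(scope="session")
def mini_subspace_runs(mini_net, mini_structured_subspace, mini_subspace):
    """Subspace responses of the rand / ScaledI / TunedEI mini networks."""
    _, sch = mini_subspace
    return {
        "rand": simulate(mini_net, sch, 9, windows=None),
        "ScaledI": simulate(
            mini_structured_subspace["ScaledI"].net, sch, 9, windows=None),
        "TunedEI": simulate(
            mini_structured_subspace["TunedEI"].net, sch, 9, windows=None),
    }


@pytest.fixture(scope="session")
def full_net_a():
    """Full-size set-A random network (connectivity-level tests only)."""
    return build_connectivity(CONNECTIVITY_SETS["A"], 0)
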