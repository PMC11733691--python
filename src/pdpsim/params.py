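"""Model parameters: neuron constants, connectivity sets, and assembly structure configs.

Units follow the conventions used throughout the package: time constants in
ms, conductances in nS, potentials in mV, synaptic unit weights in pS,
spike-triggered adaptation increments in pA.  The effective membrane
capacitance of a neuron is ``g_rest * tau_m`` (nS * ms = pF), so the membrane
equation can be integrated entirely in these units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

PATHWAYS = ("OB->E", "OB->I", "E->E", "E->I", "I->E", "I->I")

#: source population of each pathway ("OB", "E" or "I")
PATHWAY_SOURCE = {p: p.split("->")[0] for p in PATHWAYS}
#: target population of each pathway ("E" or "I")
PATHWAY_TARGET = {p: p.split("->")[1] for p in PATHWAYS}


@dataclass(frozen=True)
class NeuronParams:
    """Adaptive conductance-based leaky integrate-and-fire parameters."""

    tau_m: float        # membrane time constant, ms
    g_rest: float       # resting (leak) conductance, nS
    e_rest: float       # resting potential, mV
    e_exc: float        # excitatory reversal potential, mV
    e_inh: float        # inhibitory reversal potential, mV
    v_th: float         # spiking threshold, mV
    e_reset: float      # reset potential, mV
    tau_ref: float      # refractory period, ms
    tau_a: float        # adaptation time constant, ms (ignored if not adapt)
    a: float            # subthreshold adaptation, nS
    b: float            # spike-triggered adaptation, pA
    adapt: bool = True  # inhibitory neurons carry no adaptation current

    def __post_init__(self) -> None:
        if not (self.e_inh <= self.e_rest < self.v_th < self.e_exc):
            raise ValueError(
                "require e_inh <= e_rest < v_th < e_exc, got "
                f"{self.e_inh}, {self.e_rest}, {self.v_th}, {self.e_exc}"
            )
        if min(self.tau_m, self.tau_ref) <= 0 or (self.adapt and self.tau_a <= 0):
            raise ValueError("time constants must be positive")


E_NEURON = NeuronParams(
    tau_m=85.0, g_rest=1.35, e_rest=-60.0, e_exc=0.0, e_inh=-70.0,
    v_th=-38.0, e_reset=-60.0, tau_ref=8.0, tau_a=40.0, a=1.0, b=10.0,
)

I_NEURON = NeuronParams(
    tau_m=50.0, g_rest=0.9, e_rest=-65.0, e_exc=0.0, e_inh=-70.0,
    v_th=-45.0, e_reset=-65.0, tau_ref=8.0, tau_a=1.0, a=0.0, b=0.0,
    adapt=False,
)

# "simple" variant: E and I neurons share one biophysical parameter set
# (adaptation is still absent from I neurons).
SIMPLE_E_NEURON = NeuronParams(
    tau_m=68.0, g_rest=1.1, e_rest=-62.0, e_exc=0.0, e_inh=-70.0,
    v_th=-41.0, e_reset=-62.0, tau_ref=8.0, tau_a=20.0, a=0.5, b=5.0,
)
SIMPLE_I_NEURON = replace(SIMPLE_E_NEURON, adapt=False, a=0.0, b=0.0, tau_a=1.0)


@dataclass(frozen=True)
class PathwayParams:
    p: float  # connection probability
    w: float  # unit synaptic strength, pS

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"connection probability must be in (0, 1], got {self.p}")
        if self.w <= 0:
            raise ValueError("synaptic strength must be positive")


@dataclass(frozen=True)
class ConnectivitySpec:
    """Population sizes, pathway statistics and synaptic kinetics of one network."""

    name: str
    n_e: int = 4000
    n_i: int = 1000
    n_ob: int = 1500
    pathways: dict[str, PathwayParams] = field(default_factory=dict)
    tau_syn_e: float = 30.0  # ms, excitatory synapses (OB and E sources)
    tau_syn_i: float = 10.0  # ms, inhibitory synapses
    e_params: NeuronParams = E_NEURON
    i_params: NeuronParams = I_NEURON

    def __post_init__(self) -> None:
        missing = [p for p in PATHWAYS if p not in self.pathways]
        if missing:
            raise ValueError(f"missing pathway parameters: {missing}")

    def n_pop(self, pop: str) -> int:
        return {"OB": self.n_ob, "E": self.n_e, "I": self.n_i}[pop]

    def in_degree(self, pathway: str) -> int:
        """Number of inputs each target neuron receives through ``pathway``."""
        par = self.pathways[pathway]
        return int(round(par.p * self.n_pop(PATHWAY_SOURCE[pathway])))

    def scaled(self, scale: float, name: str | None = None) -> "ConnectivitySpec":
        """Down-scaled variant preserving per-neuron in-degrees.

        Population sizes shrink by ``scale`` and connection probabilities grow
        by ``1/scale`` so that every neuron keeps the full model's input
        counts (and hence its input statistics).  Intended for fast tests.
        """
        if not (0.0 < scale <= 1.0):
            raise ValueError("scale must be in (0, 1]")
        new_paths = {}
        for key, par in self.pathways.items():
            p = min(1.0, par.p / scale)
            new_paths[key] = PathwayParams(p=p, w=par.w)
        return replace(
            self,
            name=name or f"{self.name}-x{scale:g}",
            n_e=int(round(self.n_e * scale)),
            n_i=int(round(self.n_i * scale)),
            n_ob=int(round(self.n_ob * scale)),
            pathways=new_paths,
        )


def _spec(name, obe, obi, ee, ei, ie, ii, **kw) -> ConnectivitySpec:
    keys = PATHWAYS
    vals = [obe, obi, ee, ei, ie, ii]
    return ConnectivitySpec(
        name=name,
        pathways={k: PathwayParams(*v) for k, v in zip(keys, vals)},
        **kw,
    )


#: The five published connectivity parameter sets {p, w(pS)}.
CONNECTIVITY_SETS: dict[str, ConnectivitySpec] = {
    "A": _spec("A", (0.02, 128), (0.01, 68), (0.05, 128), (0.04, 68), (0.05, 480), (0.04, 250)),
    "B": _spec("B", (0.02, 128), (0.01, 66), (0.05, 128), (0.04, 66), (0.05, 450), (0.04, 210)),
    "C": _spec("C", (0.02, 128), (0.01, 68), (0.05, 108), (0.02, 80), (0.05, 520), (0.02, 310)),
    "D": _spec("D", (0.03, 95), (0.02, 42), (0.05, 128), (0.04, 58), (0.05, 590), (0.04, 270)),
    "simple": _spec(
        "simple",
        (0.03, 160), (0.03, 160), (0.025, 370), (0.025, 370), (0.1, 1010), (0.1, 1010),
        tau_syn_e=10.0, tau_syn_i=10.0,
        e_params=SIMPLE_E_NEURON, i_params=SIMPLE_I_NEURON,
    ),
}

VARIANTS = (
    "rand", "ScaledI", "TunedI", "TunedEI", "Scaled_adjust", "Tuned_adjust",
)


@dataclass(frozen=True)
class StructureConfig:
    """Assembly structure of a network variant.

    alpha scales the within-assembly E->E connection probability, beta the
    I->E probability from assembly I neurons to assembly E neurons, gamma the
    E->I probability in the reverse direction, and chi globally scales all
    I->E weights (Scaled I networks only).
    """

    variant: str = "rand"
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    chi: float = 1.0
    n_assemblies: int = 15
    assembly_e: int = 100  # E neurons per assembly
    assembly_i: int = 25   # I neurons per assembly (Tuned variants)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if min(self.alpha, self.beta, self.gamma, self.chi) < 1.0:
            raise ValueError("structure factors must be >= 1")

    def scaled(self, scale: float) -> "StructureConfig":
        """Shrink assembly sizes in proportion to a down-scaled network."""
        return replace(
            self,
            assembly_e=max(2, int(round(self.assembly_e * scale))),
            assembly_i=max(1, int(round(self.assembly_i * scale))),
        )


#: Published defaults of the structured-network variants.
STRUCTURE_DEFAULTS: dict[str, StructureConfig] = {
    "rand": StructureConfig("rand"),
    "ScaledI": StructureConfig("ScaledI", alpha=5.0, chi=1.4),
    "TunedI": StructureConfig("TunedI", alpha=5.0, beta=18.0),
    "TunedEI": StructureConfig("TunedEI", alpha=5.0, beta=4.0, gamma=3.0),
    "Scaled_adjust": StructureConfig("Scaled_adjust", alpha=3.7, chi=1.07),
    "Tuned_adjust": StructureConfig("Tuned_adjust", alpha=5.0, beta=11.5, gamma=3.0),
}
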