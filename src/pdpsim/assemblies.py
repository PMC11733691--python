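"""Memory assemblies: selection of member neurons and degree-preserving rewiring.

An assembly representing an odor contains the 100 E neurons receiving the
highest density of inputs from the odor's activated mitral cells, and (in
Tuned variants) the 25 I neurons most densely connected to those E neurons.
Rewiring raises the connection probability inside an assembly by a factor
(alpha for E->E, beta for I->E, gamma for E->I) by adding connections between
assembly members and deleting, per target neuron, an equal number of inputs
from outside the assembly — so every neuron's per-pathway in-degree is
conserved exactly.  An added connection that lands on an existing pair
increments its multiplicity, i.e. doubles the effective synaptic weight.

Scaled I networks instead scale all I->E weights globally by a factor chi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .connectivity import WeightMatrices
from .odors import MitralCellPattern
from .params import PATHWAY_SOURCE, StructureConfig, STRUCTURE_DEFAULTS


@dataclass(frozen=True)
class Assembly:
    odor_id: int
    e_members: np.ndarray
    i_members: np.ndarray | None = None


@dataclass
class StructuredNetwork:
    """A rewired network plus its assembly bookkeeping."""

    net: WeightMatrices
    config: StructureConfig
    assemblies: list[Assembly] = field(default_factory=list)

    @property
    def variant(self) -> str:
        return self.config.variant

    def assembly_union(self) -> np.ndarray:
        if not self.assemblies:
            return np.empty(0, dtype=int)
        return np.unique(np.concatenate([a.e_members for a in self.assemblies]))


def _top_k(scores: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of the k largest scores; ties broken uniformly at random."""
    jitter = rng.random(scores.size)
    order = np.lexsort((jitter, -scores))
    return np.sort(order[:k])


def select_assembly_e(net: WeightMatrices, odor: MitralCellPattern,
                      n_members: int = 100, seed=None) -> np.ndarray:
    """The E neurons most densely connected to the odor's activated cells.

    Density is the multiplicity-weighted count of OB->E connections from the
    odor's activated mitral cells.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub = net.mats["OB->E"][:, odor.activated]
    scores = np.asarray(sub.sum(axis=1)).ravel()
    return _top_k(scores, n_members, rng)


def select_assembly_i(net: WeightMatrices, e_members: np.ndarray,
                      n_members: int = 25, seed=None) -> np.ndarray:
    """The I neurons receiving the most E->I connections from ``e_members``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub = net.mats["E->I"][:, np.sort(np.asarray(e_members))]
    scores = np.asarray(sub.sum(axis=1)).ravel()
    return _top_k(scores, n_members, rng)


def rewire_within(net: WeightMatrices, pathway: str, pre_set: np.ndarray,
                  post_set: np.ndarray, factor: float, seed) -> WeightMatrices:
    """Raise the within-group connection probability to ``factor * base_p``.

    Per post-set neuron, connections from ``pre_set`` are added (uniform
    draws over the group; repeated draws increment multiplicity) until the
    multiplicity-weighted within-group input count reaches
    ``round(factor * base_p * |pre_set|)``, and an equal number of existing
    inputs from outside ``pre_set`` are deleted at random.  In-degrees are
    conserved exactly; returns a new WeightMatrices.
    """
    if factor < 1.0:
        raise ValueError("rewiring factor must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base_p = net.spec.pathways[pathway].p
    pre_set = np.sort(np.asarray(pre_set))
    post_set = np.asarray(post_set)
    recurrent = PATHWAY_SOURCE[pathway] == pathway.split("->")[1]

    out = net.copy()
    m = out.mats[pathway].tolil()
    _rewire_lil(m, pre_set, post_set, factor, base_p, recurrent, rng)
    m = m.tocsr()
    m.eliminate_zeros()
    out.mats[pathway] = m
    return out


def _rewire_lil(m, pre_set, post_set, factor, base_p, recurrent,
                rng: np.random.Generator) -> None:
    """In-place within-group rewiring of a LIL multiplicity matrix.

    The within-group connection probability is multiplied by ``factor``.
    The reference point is the group's *current* mean within-connectivity:
    for unbiased memberships this equals ``base_p``, but when members were
    selected for dense connectivity (the assembly I neurons receive far more
    E inputs from their assembly than chance), the factor scales that
    selection-enriched density — otherwise the rewiring could be a no-op.
    A factor of exactly 1 leaves the matrix untouched.
    """
    if factor == 1.0:
        return
    cur = 0
    for post in post_set:
        row_ids = np.asarray(m.rows[post], dtype=int)
        row_dat = np.asarray(m.data[post], dtype=int)
        cur += int(row_dat[np.isin(row_ids, pre_set)].sum())
    mean_cur = max(cur / len(post_set), base_p * pre_set.size)
    target = int(round(factor * mean_cur))
    for post in post_set:
        row_ids = np.asarray(m.rows[post], dtype=int)
        row_dat = np.asarray(m.data[post], dtype=int)
        inside = np.isin(row_ids, pre_set)
        cur = int(row_dat[inside].sum())
        need = target - cur
        if need <= 0:
            continue
        cand = pre_set[pre_set != post] if recurrent else pre_set
        if cand.size == 0:
            raise ValueError("empty candidate pre-set")
        add = rng.choice(cand, size=need, replace=True)
        # delete an equal number of outside-source inputs (multiplicity-
        # weighted uniform choice)
        outside_ids = row_ids[~inside]
        outside_mult = row_dat[~inside]
        n_out = int(outside_mult.sum())
        if n_out < need:
            raise ValueError(
                f"neuron {post}: only {n_out} outside inputs available, "
                f"{need} deletions required")
        units = np.repeat(outside_ids, outside_mult)
        drop = rng.choice(units.size, size=need, replace=False)
        drop_ids, drop_cnt = np.unique(units[drop], return_counts=True)
        for a in add:
            m[post, a] = m[post, a] + 1
        for d, c in zip(drop_ids, drop_cnt):
            m[post, d] = m[post, d] - c


def scale_ie(net: WeightMatrices, chi: float) -> WeightMatrices:
    """Globally scale all I->E weights by chi (topology unchanged)."""
    if chi < 1.0:
        raise ValueError("chi must be >= 1")
    out = net.copy()
    out.w_scale["I->E"] = out.w_scale["I->E"] * chi
    return out


def build_structured(rand_net: WeightMatrices, odor_patterns, config, seed,
                     ) -> StructuredNetwork:
    """Apply one variant's assembly recipe to a random network.

    ``config`` may be a StructureConfig or a variant name (Table-default
    parameters).  One assembly is created per odor; memberships are selected
    on the unmodified random network, then rewiring is applied assembly by
    assembly.  ``rand`` returns pseudo-assemblies (memberships only, no
    rewiring).
    """
    if isinstance(config, str):
        config = STRUCTURE_DEFAULTS[config]
    if len(odor_patterns) != config.n_assemblies:
        config = __import__("dataclasses").replace(
            config, n_assemblies=len(odor_patterns))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    assemblies = []
    for k, odor in enumerate(odor_patterns):
        e_m = select_assembly_e(rand_net, odor, config.assembly_e, rng)
        i_m = select_assembly_i(rand_net, e_m, config.assembly_i, rng)
        assemblies.append(Assembly(odor_id=k, e_members=e_m, i_members=i_m))

    net = rand_net.copy()
    variant = config.variant
    if variant == "rand":
        return StructuredNetwork(net=net, config=config, assemblies=assemblies)

    def rewire_all(pathway, factor, pre_of, post_of):
        base_p = net.spec.pathways[pathway].p
        recurrent = pathway in ("E->E", "I->I")
        m = net.mats[pathway].tolil()
        for asm in assemblies:
            _rewire_lil(m, np.sort(pre_of(asm)), post_of(asm), factor,
                        base_p, recurrent, rng)
        m = m.tocsr()
        m.eliminate_zeros()
        net.mats[pathway] = m

    rewire_all("E->E", config.alpha, lambda a: a.e_members, lambda a: a.e_members)
    if variant in ("ScaledI", "Scaled_adjust"):
        net.w_scale["I->E"] = net.w_scale["I->E"] * config.chi
    elif variant in ("TunedI", "TunedEI", "Tuned_adjust"):
        rewire_all("I->E", config.beta, lambda a: a.i_members, lambda a: a.e_members)
        if variant in ("TunedEI", "Tuned_adjust"):
            rewire_all("E->I", config.gamma, lambda a: a.e_members, lambda a: a.i_members)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return StructuredNetwork(net=net, config=config, assemblies=assemblies)
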