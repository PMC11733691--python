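"""Random network construction with exact in-degrees and regular out-degrees.

Each target neuron receives exactly ``round(p_YX * N_Y)`` inputs through every
pathway (sampled uniformly without replacement, no self-connections).  Because
plain fixed-in-degree sampling leaves binomial spread in the out-degrees, the
out-degrees are then regularized: edges of over-connected source neurons are
reassigned to under-connected sources (keeping every target's in-degree
unchanged) until all out-degrees lie within +/- 5% of the pathway mean.

Connections are stored as sparse integer multiplicity matrices; assembly
rewiring may raise a pair's multiplicity above one, which doubles (triples,
...) the effective synaptic weight of that pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .params import PATHWAYS, PATHWAY_SOURCE, PATHWAY_TARGET, ConnectivitySpec

OUTDEGREE_TOL = 0.05


@dataclass
class WeightMatrices:
    """Sparse multiplicity matrices (targets x sources) for all six pathways.

    ``w_scale[pathway]`` is the effective unit weight in pS; the total weight
    of a connection is ``multiplicity * w_scale``.  A global weight scaling
    (the Scaled I networks' chi factor) is folded into ``w_scale``.
    """

    spec: ConnectivitySpec
    mats: dict[str, sp.csr_matrix]
    w_scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in PATHWAYS:
            self.w_scale.setdefault(key, self.spec.pathways[key].w)

    def copy(self) -> "WeightMatrices":
        return WeightMatrices(
            spec=self.spec,
            mats={k: m.copy() for k, m in self.mats.items()},
            w_scale=dict(self.w_scale),
        )

    def in_degrees(self, pathway: str) -> np.ndarray:
        """Multiplicity-weighted input count per target neuron."""
        return np.asarray(self.mats[pathway].sum(axis=1)).ravel()

    def out_degrees(self, pathway: str) -> np.ndarray:
        return np.asarray(self.mats[pathway].sum(axis=0)).ravel()

    def effective(self, pathway: str) -> sp.csr_matrix:
        """Weight matrix in pS (multiplicity times unit weight)."""
        return self.mats[pathway].astype(float) * self.w_scale[pathway]


def build_connectivity(spec: ConnectivitySpec, seed) -> WeightMatrices:
    """Draw all six pathways of a random (rand) network."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mats = {}
    for key in PATHWAYS:
        src, tgt = PATHWAY_SOURCE[key], PATHWAY_TARGET[key]
        n_src, n_tgt = spec.n_pop(src), spec.n_pop(tgt)
        k = spec.in_degree(key)
        if k < 1:
            raise ValueError(f"pathway {key}: p*N = {spec.pathways[key].p * n_src} < 1")
        recurrent = src == tgt
        pre = _sample_fixed_indegree(n_src, n_tgt, k, recurrent, rng)
        pre = _regularize_outdegree(pre, n_src, recurrent, rng)
        post = np.repeat(np.arange(n_tgt), k)
        m = sp.csr_matrix(
            (np.ones(pre.size, dtype=np.int32), (post, pre.ravel())),
            shape=(n_tgt, n_src),
        )
        m.sum_duplicates()
        mats[key] = m
    return WeightMatrices(spec=spec, mats=mats)


def _sample_fixed_indegree(n_src: int, n_tgt: int, k: int, recurrent: bool,
                           rng: np.random.Generator) -> np.ndarray:
    """(n_tgt, k) presynaptic partners, distinct per row, no autapses."""
    pre = np.empty((n_tgt, k), dtype=np.int64)
    for t in range(n_tgt):
        row = rng.choice(n_src - 1 if recurrent else n_src, size=k, replace=False)
        if recurrent:
            row[row >= t] += 1  # skip self
        pre[t] = row
    return pre


def _regularize_outdegree(pre: np.ndarray, n_src: int, recurrent: bool,
                          rng: np.random.Generator,
                          tol: float = OUTDEGREE_TOL,
                          max_moves: int | None = None) -> np.ndarray:
    """Move edges from over- to under-connected sources, in-degrees untouched."""
    n_tgt, k = pre.shape
    mean = k * n_tgt / n_src
    lo = int(np.ceil(mean * (1 - tol)))
    hi = int(np.floor(mean * (1 + tol)))
    outdeg = np.bincount(pre.ravel(), minlength=n_src)
    if max_moves is None:
        max_moves = 100 * n_tgt * k

    # membership sets per target for O(1) duplicate checks
    members = [set(row.tolist()) for row in pre]
    # slots[s] = list of (target, column) positions currently sourced by s
    slots: list[list] = [[] for _ in range(n_src)]
    for t in range(n_tgt):
        for c in range(k):
            slots[pre[t, c]].append((t, c))

    def receivers():
        return np.nonzero(outdeg < lo)[0]

    moves = 0
    over = list(np.nonzero(outdeg > hi)[0])
    rng.shuffle(over)
    while over:
        s_hi = over.pop()
        while outdeg[s_hi] > hi:
            if moves > max_moves:
                raise RuntimeError("out-degree regularization did not converge")
            under = receivers()
            if len(under) == 0:
                under = np.nonzero(outdeg < hi)[0]
            # try candidate receivers until one fits the chosen edge's target
            done = False
            for _ in range(64):
                idx = rng.integers(len(slots[s_hi]))
                t, c = slots[s_hi][idx]
                cand = under[rng.integers(len(under))]
                if cand != s_hi and cand not in members[t] and not (recurrent and cand == t):
                    # reassign edge (s_hi -> t) to (cand -> t)
                    last = slots[s_hi].pop()
                    if last != (t, c):
                        slots[s_hi][idx] = last
                    slots[cand].append((t, c))
                    members[t].discard(s_hi)
                    pre[t, c] = cand
                    members[t].add(cand)
                    outdeg[s_hi] -= 1
                    outdeg[cand] += 1
                    moves += 1
                    done = True
                    break
            if not done:
                raise RuntimeError("could not find a valid edge reassignment")
    # raise deficient sources by stealing from the most-connected ones
    under = receivers()
    while len(under):
        if moves > max_moves:
            raise RuntimeError("out-degree regularization did not converge")
        s_lo = under[0]
        while outdeg[s_lo] < lo:
            donors = np.nonzero(outdeg > mean)[0]
            done = False
            for _ in range(64):
                s_hi = donors[rng.integers(len(donors))]
                idx = rng.integers(len(slots[s_hi]))
                t, c = slots[s_hi][idx]
                if s_lo != s_hi and s_lo not in members[t] and not (recurrent and s_lo == t):
                    last = slots[s_hi].pop()
                    if last != (t, c):
                        slots[s_hi][idx] = last
                    slots[s_lo].append((t, c))
                    members[t].discard(s_hi)
                    pre[t, c] = s_lo
                    members[t].add(s_lo)
                    outdeg[s_hi] -= 1
                    outdeg[s_lo] += 1
                    moves += 1
                    done = True
                    break
            if not done:
                raise RuntimeError("could not find a valid edge reassignment")
        under = receivers()
    return pre
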