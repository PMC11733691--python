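"""Olfactory-bulb (OB) input generation.

The OB is modeled as 1500 mitral cells firing as inhomogeneous Poisson
processes.  At baseline every cell fires at 6 Hz.  An odor activates 10% of
the cells (onset rates drawn from a discrete uniform distribution, 8-32 Hz,
1 Hz steps) and inhibits 5% (0-5 Hz); each affected cell has a latency
(discrete uniform 0-200 ms, 1 ms steps) and activated rates decay
exponentially after latency with a time constant of 1, 2 or 4 s (equally
distributed).

An *odor subspace* is an 11 x 11 grid of mixtures of four pure odors placed
at the corners of a virtual square.  The per-pixel composition follows two
printed lookup tables: a concentration table (fraction of a pure odor's 150
activated cells that remain activated) and an availability table (the pool
of shortest-latency cells from which they are drawn).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MitralCellPattern", "OdorSubspace", "StimulusSchedule", "Epoch",
    "make_odor", "make_correlated_quartet", "rate_profile",
    "time_averaged_rates", "generate_spikes", "morph_odors",
    "make_subspace", "make_trajectories", "pattern_correlation",
    "CONCENTRATION_TABLE", "AVAILABILITY_TABLE",
    "ACTIVATED_FRACTION", "INHIBITED_FRACTION",
]

BASELINE_RATE = 6.0          # Hz, spontaneous mitral cell rate
ACTIVATED_FRACTION = 0.10    # 150 of 1500
INHIBITED_FRACTION = 0.05    # 75 of 1500
MIN_N_MC = 225               # activated + inhibited cells for a full-size odor
DECAY_TAUS = (1.0, 2.0, 4.0)  # s

# Percentage of a pure odor's activated (and inhibited) cells present in each
# pixel of the 11x11 subspace, for the pure odor anchored at the top-left
# corner.  Rotations of this table give the other three corners.
CONCENTRATION_TABLE = np.array([
    [100, 90, 80, 70, 60, 50, 40, 30, 20, 10, 0],
    [90, 90, 80, 70, 60, 50, 40, 30, 15, 5, 0],
    [80, 80, 70, 60, 50, 40, 35, 25, 15, 5, 0],
    [70, 70, 60, 50, 50, 35, 30, 20, 15, 5, 0],
    [60, 60, 50, 50, 40, 30, 25, 20, 15, 5, 0],
    [50, 50, 40, 35, 30, 25, 25, 15, 10, 5, 0],
    [40, 40, 35, 30, 25, 25, 15, 10, 10, 5, 0],
    [30, 30, 25, 20, 20, 15, 10, 10, 5, 5, 0],
    [20, 15, 15, 15, 15, 10, 10, 5, 5, 5, 0],
    [10, 5, 5, 5, 5, 5, 5, 5, 5, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
], dtype=float)

# Percentage of activated cells available for selection; the selectable pool
# size C is obtained by multiplying these values by 1.5.
AVAILABILITY_TABLE = np.array([
    [100, 100, 100, 90, 80, 70, 60, 50, 40, 30, 0],
    [100, 100, 100, 90, 80, 70, 60, 50, 35, 25, 0],
    [100, 100, 90, 60, 70, 60, 55, 45, 35, 25, 0],
    [90, 90, 80, 70, 70, 55, 50, 40, 35, 25, 0],
    [80, 80, 70, 70, 60, 50, 45, 40, 35, 25, 0],
    [70, 70, 60, 55, 50, 45, 45, 35, 30, 25, 0],
    [60, 60, 55, 50, 45, 45, 35, 30, 30, 25, 0],
    [50, 50, 45, 40, 40, 35, 30, 30, 25, 25, 0],
    [40, 35, 35, 35, 35, 30, 30, 25, 25, 25, 0],
    [30, 25, 25, 25, 25, 25, 25, 25, 25, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
], dtype=float)

#: grid coordinates of the four pure odors (row, col), in the fixed order
#: top-left, top-right, bottom-left, bottom-right.
CORNERS = ((0, 0), (0, 10), (10, 0), (10, 10))
#: index pairs of adjacent (square-edge) pure odors
ADJACENT_PAIRS = ((0, 1), (0, 2), (1, 3), (2, 3))


def _round_half_up(x) -> np.ndarray:
    """Round half-up (2.5 -> 3), elementwise; used for availability pools."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def _round_half_down(x) -> np.ndarray:
    """Round half-down (7.5 -> 7), elementwise; used for cell counts.

    At pixels where the printed concentration percentages sum to slightly
    more than 100%, half-up rounding of the per-odor counts would push the
    per-pixel total one cell past the 150 + 10% bound; rounding halves down
    keeps every pixel total within 150 +/- 10% (worst case 148).
    """
    return np.ceil(np.asarray(x, dtype=float) - 0.5).astype(int)


def _corner_table(table: np.ndarray, corner: int) -> np.ndarray:
    """Orient a top-left-anchored lookup table for one of the four corners."""
    t = table
    if corner in (1, 3):
        t = np.fliplr(t)
    if corner in (2, 3):
        t = np.flipud(t)
    return t


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class MitralCellPattern:
    """Rates, latencies and decay constants defining one OB activity pattern."""

    n_mc: int
    activated: np.ndarray       # cell ids
    onset_rates: np.ndarray     # Hz
    act_latencies: np.ndarray   # ms
    decay_taus: np.ndarray      # s
    inhibited: np.ndarray       # cell ids
    inh_rates: np.ndarray       # Hz
    inh_latencies: np.ndarray   # ms
    baseline_rate: float = BASELINE_RATE

    def __post_init__(self) -> None:
        act = set(self.activated.tolist())
        inh = set(self.inhibited.tolist())
        if act & inh:
            raise ValueError("activated and inhibited cell sets overlap")
        if len(act) != len(self.activated) or len(inh) != len(self.inhibited):
            raise ValueError("duplicate cell ids within a set")
        if (np.min(self.onset_rates, initial=0.0) < 0
                or np.min(self.inh_rates, initial=0.0) < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_activated(self) -> int:
        return len(self.activated)

    @property
    def n_inhibited(self) -> int:
        return len(self.inhibited)


def make_odor(seed, n_mc: int = 1500) -> MitralCellPattern:
    """Draw one pure odor: 10% of cells activated, 5% inhibited.

    For the standard OB size (1500 cells) this gives exactly 150 activated
    and 75 inhibited cells.  ``seed`` may be an int or a Generator; the
    pattern is a pure function of it.
    """
    if n_mc < MIN_N_MC:
        raise ValueError(
            f"n_mc={n_mc} too small: need at least {MIN_N_MC} mitral cells "
            "to host the activated and inhibited subsets"
        )
    rng = _as_rng(seed)
    n_act = int(round(ACTIVATED_FRACTION * n_mc))
    n_inh = int(round(INHIBITED_FRACTION * n_mc))
    cells = rng.choice(n_mc, size=n_act + n_inh, replace=False)
    activated, inhibited = np.sort(cells[:n_act]), np.sort(cells[n_act:])
    # decay time constants are equally distributed across activated cells
    taus = np.tile(DECAY_TAUS, n_act // len(DECAY_TAUS) + 1)[:n_act]
    return MitralCellPattern(
        n_mc=n_mc,
        activated=activated,
        onset_rates=rng.integers(8, 33, size=n_act).astype(float),
        act_latencies=rng.integers(0, 201, size=n_act).astype(float),
        decay_taus=rng.permutation(taus).astype(float),
        inhibited=inhibited,
        inh_rates=rng.integers(0, 6, size=n_inh).astype(float),
        inh_latencies=rng.integers(0, 201, size=n_inh).astype(float),
    )


def make_correlated_quartet(seed, n_mc: int = 1500) -> list[MitralCellPattern]:
    """Four correlated pure odors for the corners of a subspace.

    Odors adjacent along a square edge share half of their activated and
    half of their inhibited mitral cells; diagonally opposed odors share
    none.  Shared cells keep independently drawn rates/latencies per odor,
    so the correlation between adjacent odors stems from the shared identity
    of elevated (or suppressed) cells, not from identical rate values.

    Returns the odors in corner order (top-left, top-right, bottom-left,
    bottom-right).
    """
    if n_mc < MIN_N_MC:
        raise ValueError(f"n_mc={n_mc} too small: need at least {MIN_N_MC}")
    rng = _as_rng(seed)
    n_act = int(round(ACTIVATED_FRACTION * n_mc))
    n_inh = int(round(INHIBITED_FRACTION * n_mc))
    half_act = n_act // 2
    # shared pools sit on the four edges of the square; each odor's cell set
    # is the union of the pools on its two incident edges
    ring = (0, 1, 3, 2)  # corner indices walked along the square's edges
    inh_sizes = [(n_inh + 1) // 2, n_inh // 2, (n_inh + 1) // 2, n_inh // 2]
    total = 4 * half_act + sum(inh_sizes)
    cells = rng.choice(n_mc, size=total, replace=False)
    pos = 0
    act_pools, inh_pools = [], []
    for e in range(4):
        act_pools.append(cells[pos:pos + half_act]); pos += half_act
    for e in range(4):
        inh_pools.append(cells[pos:pos + inh_sizes[e]]); pos += inh_sizes[e]

    odors: list[MitralCellPattern | None] = [None] * 4
    for k in range(4):
        i = ring.index(k)
        e_prev, e_next = (i - 1) % 4, i
        activated = np.sort(np.concatenate([act_pools[e_prev], act_pools[e_next]]))
        inhibited = np.sort(np.concatenate([inh_pools[e_prev], inh_pools[e_next]]))
        na, ni = len(activated), len(inhibited)
        taus = np.tile(DECAY_TAUS, na // len(DECAY_TAUS) + 1)[:na]
        odors[k] = MitralCellPattern(
            n_mc=n_mc,
            activated=activated,
            onset_rates=rng.integers(8, 33, size=na).astype(float),
            act_latencies=rng.integers(0, 201, size=na).astype(float),
            decay_taus=rng.permutation(taus).astype(float),
            inhibited=inhibited,
            inh_rates=rng.integers(0, 6, size=ni).astype(float),
            inh_latencies=rng.integers(0, 201, size=ni).astype(float),
        )
    return odors  # type: ignore[return-value]


def rate_profile(pattern: MitralCellPattern, t: float) -> np.ndarray:
    """Instantaneous firing rate (Hz) of every mitral cell at time ``t`` (s)
    after odor onset.

    Before a cell's latency it fires at baseline.  After latency an activated
    cell jumps to its onset rate and decays back toward baseline,
    ``baseline + (onset_rate - baseline) * exp(-(t - latency)/tau)`` (the
    mean activated-cell rate during a presentation is then ~15 Hz);
    an inhibited cell steps down to its reduced rate.
    """
    if t < 0:
        raise ValueError("t must be >= 0 (relative to odor onset)")
    b = pattern.baseline_rate
    rates = np.full(pattern.n_mc, b)
    lat_a = pattern.act_latencies / 1000.0
    on = t >= lat_a
    rates[pattern.activated[on]] = b + (pattern.onset_rates[on] - b) * np.exp(
        -(t - lat_a[on]) / pattern.decay_taus[on])
    lat_i = pattern.inh_latencies / 1000.0
    on_i = t >= lat_i
    rates[pattern.inhibited[on_i]] = pattern.inh_rates[on_i]
    return rates


def time_averaged_rates(pattern: MitralCellPattern, duration: float = 2.0) -> np.ndarray:
    """Expected firing rate of every cell averaged over ``duration`` s of odor.

    Closed form of the mean of :func:`rate_profile` over [0, duration]; this
    is the noiseless 'OB activity pattern' used for input-correlation
    analyses.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    b = pattern.baseline_rate
    rates = np.full(pattern.n_mc, b)
    lat = np.minimum(pattern.act_latencies / 1000.0, duration)
    tau = pattern.decay_taus
    integ = (b * duration
             + (pattern.onset_rates - b) * tau * (1.0 - np.exp(-(duration - lat) / tau)))
    rates[pattern.activated] = integ / duration
    lat_i = np.minimum(pattern.inh_latencies / 1000.0, duration)
    integ_i = pattern.baseline_rate * lat_i + pattern.inh_rates * (duration - lat_i)
    rates[pattern.inhibited] = integ_i / duration
    return rates


def generate_spikes(pattern: MitralCellPattern, duration: float, dt: float,
                    seed) -> list[np.ndarray]:
    """Poisson spike times (s) per mitral cell over ``duration`` s of odor.

    Per time bin of width ``dt`` (s) a spike occurs with probability
    rate * dt (inhomogeneous Poisson / Bernoulli approximation).  Distinct
    seeds give independent trials.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    rng = _as_rng(seed)
    n_steps = int(round(duration / dt))
    trains: list[list] = [[] for _ in range(pattern.n_mc)]
    chunk = max(1, int(1.0 / dt))
    for start in range(0, n_steps, chunk):
        stop = min(start + chunk, n_steps)
        t = (np.arange(start, stop) + 0.5) * dt
        rates = _rate_matrix(pattern, t)
        p = rates * dt
        if p.max() > 1.0:
            raise ValueError(
                f"rate*dt={p.max():.3f} > 1: dt too coarse for peak rate"
            )
        cells, steps = np.nonzero(rng.random(rates.shape) < p)
        times = (start + steps + 0.5) * dt
        for c, tt in zip(cells, times):
            trains[c].append(tt)
    return [np.asarray(tr) for tr in trains]


def _rate_matrix(pattern: MitralCellPattern, t: np.ndarray) -> np.ndarray:
    """Rates (n_mc, len(t)) at odor-relative times ``t`` (s, array)."""
    b = pattern.baseline_rate
    rates = np.full((pattern.n_mc, len(t)), b)
    lat = pattern.act_latencies[:, None] / 1000.0
    on = t[None, :] >= lat
    prof = b + (pattern.onset_rates[:, None] - b) * np.exp(
        -np.maximum(t[None, :] - lat, 0.0) / pattern.decay_taus[:, None])
    rates[pattern.activated] = np.where(on, prof, b)
    lat_i = pattern.inh_latencies[:, None] / 1000.0
    on_i = t[None, :] >= lat_i
    rates[pattern.inhibited] = np.where(
        on_i, pattern.inh_rates[:, None], pattern.baseline_rate)
    return rates


def morph_odors(a: MitralCellPattern, b: MitralCellPattern, x: float,
                seed) -> MitralCellPattern:
    """Morph odor ``a`` into odor ``b`` by swapping a fraction ``x`` of cells.

    The morph keeps a fraction (1 - x) of a's activated (and inhibited)
    cells and takes a fraction x of b's; retained cells carry their
    parent odor's rate, latency and decay constant.  x = 0 reproduces a,
    x = 1 reproduces b.
    """
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"morph fraction x must be in [0, 1], got {x}")
    if a.n_mc != b.n_mc:
        raise ValueError("parent odors must share n_mc")
    rng = _as_rng(seed)

    def mix(ids_a, ids_b, attrs_a, attrs_b):
        n = len(ids_a)
        n_b = int(round(x * n))
        keep_a = rng.choice(len(ids_a), size=n - n_b, replace=False)
        # avoid duplicating cells present in both parents
        a_kept = set(ids_a[keep_a].tolist())
        cand = np.array([i for i in range(len(ids_b)) if ids_b[i] not in a_kept])
        take_b = rng.choice(len(cand), size=min(n_b, len(cand)), replace=False)
        take_b = cand[take_b] if len(cand) else np.array([], dtype=int)
        ids = np.concatenate([ids_a[keep_a], ids_b[take_b]])
        attrs = [np.concatenate([aa[keep_a], ab[take_b]]) for aa, ab in zip(attrs_a, attrs_b)]
        order = np.argsort(ids)
        return ids[order], [at[order] for at in attrs]

    act_ids, (on, lat, tau) = mix(
        a.activated, b.activated,
        (a.onset_rates, a.act_latencies, a.decay_taus),
        (b.onset_rates, b.act_latencies, b.decay_taus),
    )
    inh_ids, (ir, il) = mix(
        a.inhibited, b.inhibited,
        (a.inh_rates, a.inh_latencies),
        (b.inh_rates, b.inh_latencies),
    )
    # a cell can be activated via one parent and inhibited via the other;
    # activation wins
    dup = np.isin(inh_ids, act_ids)
    return MitralCellPattern(
        n_mc=a.n_mc, activated=act_ids, onset_rates=on, act_latencies=lat,
        decay_taus=tau, inhibited=inh_ids[~dup], inh_rates=ir[~dup],
        inh_latencies=il[~dup],
    )


@dataclass(frozen=True)
class OdorSubspace:
    """11 x 11 grid of OB patterns spanned by four pure odors at the corners."""

    pures: tuple
    patterns: list            # 121 MitralCellPattern, row-major
    concentration: np.ndarray  # (4, 11, 11) % of each pure odor per pixel
    availability: np.ndarray   # (4, 11, 11) selectable-pool size C per pixel
    correlated: bool = False
    shape: tuple = (11, 11)

    def pattern(self, row: int, col: int) -> MitralCellPattern:
        return self.patterns[row * self.shape[1] + col]

    def pixel_of(self, index: int) -> tuple[int, int]:
        return divmod(index, self.shape[1])


def make_subspace(pures, seed, correlated: bool = False,
                  jitter_hz: float = 1.0) -> OdorSubspace:
    """Build the 11 x 11 odor subspace from four pure odors.

    For each pixel and each pure odor k, ``round(conc% * n_activated_k)``
    activated cells are selected from the pool of the C_k shortest-latency
    cells of odor k (C from the availability table x 1.5).  Selected cells
    keep their pure-odor latency and decay constant; their rate is jittered
    by +/- ``jitter_hz`` except at the corner pixels, which reproduce the
    pure odors exactly.  Inhibited cells are selected analogously from the
    pure odor's inhibited set (no availability restriction).
    """
    if len(pures) != 4:
        raise ValueError("a subspace needs exactly four pure odors")
    rng = _as_rng(seed)
    n_mc = pures[0].n_mc
    conc = np.stack([_corner_table(CONCENTRATION_TABLE, k) for k in range(4)])
    avail = np.stack([
        _round_half_up(_corner_table(AVAILABILITY_TABLE, k) * 1.5) for k in range(4)
    ]).astype(float)

    # latency-sorted activated cells per pure odor (for shortest-latency pools)
    lat_order = [np.argsort(p.act_latencies, kind="stable") for p in pures]

    patterns = []
    for i in range(11):
        for j in range(11):
            if (i, j) in CORNERS:
                patterns.append(pures[CORNERS.index((i, j))])
                continue
            taken: set[int] = set()
            act_parts, inh_parts = [], []
            for k, odor in enumerate(pures):
                n_k = _round_half_down(conc[k, i, j] / 100.0 * odor.n_activated)
                if n_k == 0:
                    continue
                C = int(avail[k, i, j])
                pool = lat_order[k][:C]
                ids = odor.activated[pool]
                free = pool[~np.isin(ids, list(taken))] if taken else pool
                # cells claimed by another pure odor at this pixel are already
                # active; this odor then contributes fewer distinct cells (the
                # +/- 10% per-pixel totals are validated after assembly)
                n_k = min(n_k, len(free))
                sel = rng.choice(free, size=n_k, replace=False)
                taken.update(odor.activated[sel].tolist())
                jit = rng.integers(-1, 2, size=n_k) * jitter_hz
                act_parts.append((
                    odor.activated[sel],
                    np.maximum(odor.onset_rates[sel] + jit, 0.0),
                    odor.act_latencies[sel],
                    odor.decay_taus[sel],
                ))
                # inhibited cells scale with the same concentration
                m_k = _round_half_down(conc[k, i, j] / 100.0 * odor.n_inhibited)
                inh_ids = odor.inhibited
                free_i = np.nonzero(~np.isin(inh_ids, list(taken)))[0]
                m_k = min(m_k, len(free_i))
                sel_i = rng.choice(free_i, size=m_k, replace=False)
                taken.update(inh_ids[sel_i].tolist())
                inh_parts.append((
                    inh_ids[sel_i], odor.inh_rates[sel_i], odor.inh_latencies[sel_i]))

            def cat(parts, idx):
                return (np.concatenate([p[idx] for p in parts])
                        if parts else np.array([]))

            ids = cat(act_parts, 0)
            order = np.argsort(ids)
            iids = cat(inh_parts, 0)
            iorder = np.argsort(iids)
            pat = MitralCellPattern(
                n_mc=n_mc,
                activated=ids[order].astype(int),
                onset_rates=cat(act_parts, 1)[order],
                act_latencies=cat(act_parts, 2)[order],
                decay_taus=cat(act_parts, 3)[order],
                inhibited=iids[iorder].astype(int),
                inh_rates=cat(inh_parts, 1)[iorder],
                inh_latencies=cat(inh_parts, 2)[iorder],
            )
            patterns.append(pat)

    sub = OdorSubspace(pures=tuple(pures), patterns=patterns,
                       concentration=conc, availability=avail,
                       correlated=correlated)
    _validate_counts(sub)
    return sub


def _validate_counts(sub: OdorSubspace) -> None:
    n_mc = sub.pures[0].n_mc
    n_act = int(round(ACTIVATED_FRACTION * n_mc))
    n_inh = int(round(INHIBITED_FRACTION * n_mc))
    for idx, pat in enumerate(sub.patterns):
        i, j = sub.pixel_of(idx)
        if sub.concentration[:, i, j].sum() == 0:
            continue  # the all-zero corner-distance pixels carry no odor
        if sub.correlated:
            continue  # shared cells make per-pixel totals differ by design
        # integer counts: the +/- 10% band is rounded outward, plus up to
        # half a cell of rounding per pure odor (matters for scaled-down OBs)
        slack = len(sub.pures) // 2
        lo_a = int(np.floor(0.9 * n_act)) - slack
        hi_a = int(np.ceil(1.1 * n_act)) + slack
        hi_i = int(np.ceil(1.1 * n_inh)) + slack
        if not (lo_a <= pat.n_activated <= hi_a) and (i, j) not in CORNERS:
            raise ValueError(
                f"pixel ({i},{j}): {pat.n_activated} activated cells outside "
                f"{n_act} +/- 10%")
        if pat.n_inhibited > hi_i:
            raise ValueError(
                f"pixel ({i},{j}): {pat.n_inhibited} inhibited cells above "
                f"{n_inh} + 10%")


@dataclass(frozen=True)
class Epoch:
    t_on: float          # s
    duration: float      # s
    pattern: MitralCellPattern
    label: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("epoch duration must be positive")


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered odor presentation epochs separated by baseline activity."""

    epochs: list
    t_end: float
    n_mc: int
    baseline_rate: float = BASELINE_RATE

    def __post_init__(self) -> None:
        t = 0.0
        for ep in self.epochs:
            if ep.t_on < t - 1e-9:
                raise ValueError("overlapping epochs in schedule")
            t = ep.t_on + ep.duration
        if t > self.t_end + 1e-9:
            raise ValueError("schedule extends past t_end")

    @classmethod
    def from_odors(cls, patterns, odor_duration: float = 2.0,
                   gap: float = 1.0, lead_in: float | None = None,
                   labels=None) -> "StimulusSchedule":
        """Present odors in sequence, separated by baseline gaps."""
        lead = gap if lead_in is None else lead_in
        t = lead
        eps = []
        for k, p in enumerate(patterns):
            lab = {"odor": k} if labels is None else dict(labels[k])
            eps.append(Epoch(t_on=t, duration=odor_duration, pattern=p, label=lab))
            t += odor_duration + gap
        return cls(epochs=eps, t_end=t, n_mc=patterns[0].n_mc)


def make_trajectories(pures, n_traj: int, seed, correlated: bool = False,
                      pixel_duration: float = 1.0,
                      gap: float = 2.0) -> StimulusSchedule:
    """Schedule of ``n_traj`` trajectories through the odor subspace.

    Each trajectory visits all 121 pixels exactly once (random order) for
    ``pixel_duration`` s without intervening baseline; trajectories are
    separated by ``gap`` s of baseline.  The subspace cell selection is
    re-randomized for every trajectory.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    rng = _as_rng(seed)
    eps = []
    t = gap
    for traj in range(n_traj):
        sub = make_subspace(pures, rng, correlated=correlated)
        order = rng.permutation(121)
        for pix in order:
            i, j = sub.pixel_of(int(pix))
            eps.append(Epoch(
                t_on=t, duration=pixel_duration, pattern=sub.patterns[pix],
                label={"trajectory": traj, "row": i, "col": j,
                       "conc": tuple(sub.concentration[:, i, j])},
            ))
            t += pixel_duration
        t += gap
    return StimulusSchedule(epochs=eps, t_end=t, n_mc=pures[0].n_mc)


def pattern_correlation(r1: np.ndarray, r2: np.ndarray) -> float:
    """Pearson correlation between two activity (rate) vectors.

    Returns NaN (flagged sentinel) if either vector has zero variance.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if r1.shape != r2.shape or r1.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    s1, s2 = r1.std(), r2.std()
    if s1 == 0.0 or s2 == 0.0:
        return float("nan")
    return float(np.corrcoef(r1, r2)[0, 1])
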