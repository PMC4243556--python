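"""Ground-truth networks and stimulus-evoked ensemble spike-train simulation.

This module plays the role of the recording rig: it produces trial-aligned
binary spike rasters from a *known* directed, delayed, signed connectivity, so
that every downstream inference step can be validated against a planted truth.

Neurons follow an inhomogeneous Bernoulli/Poisson model at Δ = 1 ms resolution:
the probability that neuron ``i`` fires in bin ``t`` is

    p_i(t) = clip( p_background
                   + stimulus gain for i's barrel while a trial of that
                     barrel's whisker is ongoing
                   + Σ_edges  weight · sign · r_pre(t − delay) ,  0, 1)

with delays in 1..5 bins — the same lag range the structure-learning step
searches over.  A whisker-pairing manipulation (:func:`apply_pairing`) modifies
the ground truth between simulated recording sessions, planting the kind of
cross-population change the plasticity statistics are designed to detect.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

_PAIRING_MODES = ("add_cross_edges", "strengthen_cross_edges", "correlate_inputs")

#: electrode array layout used to assign units to sites (8 shanks x 4 sites)
N_SHANKS = 8
SITES_PER_SHANK = 4


@dataclass(frozen=True)
class Edge:
    """Directed coupling ``pre -> post`` acting after ``delay`` bins.

    ``weight`` is a per-bin spike-probability increment; ``sign`` is +1 for
    excitatory and -1 for inhibitory couplings.
    """

    pre: int
    post: int
    delay: int
    weight: float
    sign: int


@dataclass
class GroundTruthNetwork:
    """Planted connectivity plus per-neuron context (barrel, background rate)."""

    n_neurons: int
    edges: list[Edge]
    barrel_assignment: dict[int, str]
    background_rate: float = 3.0  # spikes/s
    #: optional stimulus cross-talk: barrel -> {whisker: fraction of this
    #: barrel's own gain delivered when that (other) whisker is deflected}
    stimulus_bleed: dict[str, dict[str, float]] = field(default_factory=dict)
    #: optional attenuation of a barrel's response to its own whisker
    #: (receptive-field redistribution under pairing); default 1.0
    stimulus_gain_scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.edges:
            if not 1 <= e.delay <= 5:
                raise ValueError(f"edge delay {e.delay} outside [1, 5] bins")

    @property
    def barrels(self) -> list[str]:
        seen: dict[str, None] = {}
        for i in range(self.n_neurons):
            seen.setdefault(self.barrel_assignment[i], None)
        return list(seen)

    def neurons_in(self, barrel: str) -> np.ndarray:
        return np.array(
            [i for i in range(self.n_neurons) if self.barrel_assignment[i] == barrel],
            dtype=np.int64,
        )

    def edge_pairs(self) -> set[tuple[int, int]]:
        return {(e.pre, e.post) for e in self.edges}

    def mean_in_degree(self) -> float:
        return len(self.edges) / self.n_neurons


@dataclass
class StimulusProtocol:
    """Whisker-deflection protocol: 100-ms deflections at 1 Hz by default.

    The evoked-rate profile is a latency-then-exponential-decay gain added to
    the per-bin spike probability of neurons in the deflected whisker's barrel:
    ``gain(t) = peak_gain * exp(-(t - latency)/decay)`` for ``t >= latency``
    within the trial window, in probability-per-bin units.
    """

    whiskers: tuple[str, ...] = ("D4", "D5", "D6")
    trials_per_whisker: int = 900
    trial_window: int = 100  # ms
    baseline_window: int = 100  # ms
    inter_trial_interval: int = 900  # ms
    #: probability/bin at the profile peak; a scalar, or a per-whisker map to
    #: model heterogeneous barrel responsiveness
    peak_gain: float | dict[str, float] = 0.1
    gain_latency: float = 5.0  # ms
    gain_decay: float = 20.0  # ms

    def __post_init__(self) -> None:
        if self.baseline_window > self.inter_trial_interval:
            raise ValueError(
                "baseline_window exceeds inter_trial_interval: consecutive "
                "trial windows would overlap "
                f"({self.baseline_window} > {self.inter_trial_interval})"
            )
        if isinstance(self.peak_gain, dict):
            missing = set(self.whiskers) - set(self.peak_gain)
            if missing:
                raise ValueError(f"peak_gain map missing whiskers {sorted(missing)}")

    @property
    def period(self) -> int:
        """Bin spacing between consecutive trial onsets (1 Hz -> 1000 ms)."""
        return self.trial_window + self.inter_trial_interval

    def peak_gain_of(self, whisker: str) -> float:
        if isinstance(self.peak_gain, dict):
            return float(self.peak_gain[whisker])
        return float(self.peak_gain)

    def gain_profile(self, whisker: str | None = None) -> np.ndarray:
        peak = (
            self.peak_gain_of(whisker)
            if whisker is not None
            else (
                float(np.mean(list(self.peak_gain.values())))
                if isinstance(self.peak_gain, dict)
                else float(self.peak_gain)
            )
        )
        t = np.arange(self.trial_window, dtype=float)
        return np.where(
            t < self.gain_latency,
            0.0,
            peak * np.exp(-(t - self.gain_latency) / self.gain_decay),
        )


@dataclass
class PairingEffect:
    """Whisker-pairing manipulation applied to a ground-truth network.

    ``strength`` in [0, 1] scales the manipulation; 0 reproduces the input
    network edge-for-edge.  ``convergence_modifier`` is a signed fraction
    applied to the total edge count (hence to mean in-degree): +0.3 adds 30%
    more edges anywhere in the network, -0.1 removes 10% of non-cross edges.
    """

    paired_barrels: tuple[str, str]
    strength: float
    mode: str = "strengthen_cross_edges"
    convergence_modifier: float = 0.0
    cross_weight: float = 0.4
    #: fraction of missing cross-barrel pairs added at strength 1 in
    #: strengthen_cross_edges mode (add_cross_edges mode adds all of them)
    cross_add_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError(f"pairing strength {self.strength} outside [0, 1]")
        if self.mode not in _PAIRING_MODES:
            raise ValueError(f"unknown pairing mode {self.mode!r}; choose from {_PAIRING_MODES}")


@dataclass
class TrialEnsemble:
    """Binned, trial-aligned binary spike raster with trial bookkeeping.

    ``raster[i, t] = 1`` means a spike of neuron ``i`` in 1-ms bin ``t``.
    """

    raster: np.ndarray  # (n_neurons, n_bins) uint8
    trial_onsets: np.ndarray  # bin index per trial, time-ordered
    whisker_of_trial: list[str]
    unit_ids: np.ndarray
    site_ids: np.ndarray
    trial_window: int = 100
    baseline_window: int = 100
    bin_ms: float = 1.0

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=np.uint8)
        if self.raster.ndim != 2:
            raise ValueError("raster must be 2-D (neurons x bins)")
        bad = ~np.isin(self.raster, (0, 1))
        if bad.any():
            raise ValueError("raster entries must be 0/1")
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=np.int64)
        if len(self.trial_onsets) != len(self.whisker_of_trial):
            raise ValueError("trial_onsets and whisker_of_trial lengths differ")
        if len(self.trial_onsets) and self.trial_onsets.min() < self.baseline_window:
            raise ValueError("every trial needs a full baseline window before onset")

    @property
    def n_neurons(self) -> int:
        return self.raster.shape[0]

    @property
    def n_bins(self) -> int:
        return self.raster.shape[1]

    @property
    def whiskers(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.whisker_of_trial:
            seen.setdefault(w, None)
        return list(seen)

    def trials_of(self, whisker: str) -> np.ndarray:
        """Indices (into trial_onsets) of the trials of one whisker."""
        return np.array(
            [k for k, w in enumerate(self.whisker_of_trial) if w == whisker],
            dtype=np.int64,
        )


def generate_network(
    n_neurons: int,
    connectivity_ratio: float = 0.10,
    delay_range: tuple[int, int] = (1, 5),
    inhibitory_fraction: float = 0.2,
    seed: int = 0,
    *,
    barrels: tuple[str, ...] = ("D4", "D5", "D6"),
    weight: float = 0.08,
    background_rate: float = 3.0,
    max_parents: int | None = None,
    locality: float = 5.0,
) -> GroundTruthNetwork:
    """Sample a random planted network with the given edge density.

    The directed-edge count is exactly ``round(connectivity_ratio * n * (n-1))``
    (no self-edges).  Neurons are split evenly across ``barrels`` in index
    order; a fraction of neurons is inhibitory and all their outgoing edges
    carry sign -1 (Dale's principle).  Connectivity is predominantly local:
    the edge budget is split between within- and cross-barrel strata in
    proportion ``locality : 1`` per ordered pair, balanced across barrels and
    uniform within each stratum (``locality=1`` matches uniform sampling in
    expectation).  Deterministic given ``seed``.
    """
    if n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    if not 0.0 <= connectivity_ratio <= 1.0:
        raise ValueError("connectivity_ratio must lie in [0, 1]")
    if locality <= 0:
        raise ValueError("locality must be positive")
    lo, hi = delay_range
    if not (1 <= lo <= hi <= 5):
        raise ValueError("delay_range must be within [1, 5] bins")

    n_edges = int(round(connectivity_ratio * n_neurons * (n_neurons - 1)))
    if max_parents is not None:
        capacity = n_neurons * min(max_parents, n_neurons - 1)
        if n_edges > capacity:
            raise ValueError(
                f"connectivity_ratio {connectivity_ratio} implies {n_edges} edges "
                f"but max_parents {max_parents} caps the network at {capacity}"
            )

    assignment: dict[int, str] = {}
    for b, block in zip(barrels, np.array_split(np.arange(n_neurons), len(barrels))):
        for i in block:
            assignment[int(i)] = b

    rng = np.random.default_rng(seed)
    by_barrel: dict[str, list[tuple[int, int]]] = {b: [] for b in barrels}
    cross_pairs: list[tuple[int, int]] = []
    for i in range(n_neurons):
        for j in range(n_neurons):
            if i == j:
                continue
            if assignment[i] == assignment[j]:
                by_barrel[assignment[i]].append((i, j))
            else:
                cross_pairs.append((i, j))
    n_in_pairs = sum(len(v) for v in by_barrel.values())
    share_in = locality * n_in_pairs / (locality * n_in_pairs + len(cross_pairs))
    n_in = min(int(round(share_in * n_edges)), n_in_pairs)

    # balanced allocation of within-barrel edges across barrels
    order_b = [barrels[k] for k in rng.permutation(len(barrels))]
    quota = {b: 0 for b in barrels}
    k = 0
    while sum(quota.values()) < n_in:
        b = order_b[k % len(order_b)]
        if quota[b] < len(by_barrel[b]):
            quota[b] += 1
        k += 1

    candidates: list[tuple[int, int]] = []
    for b in barrels:
        pick = rng.permutation(len(by_barrel[b]))[: quota[b]]
        candidates.extend(by_barrel[b][p] for p in pick)
    pick = rng.permutation(len(cross_pairs))
    candidates.extend(cross_pairs[p] for p in pick)

    n_inh = int(round(inhibitory_fraction * n_neurons))
    inhibitory = set(rng.choice(n_neurons, size=n_inh, replace=False).tolist())

    in_deg = np.zeros(n_neurons, dtype=np.int64)
    chosen: list[tuple[int, int]] = []
    for i, j in candidates:
        if len(chosen) == n_edges:
            break
        if max_parents is not None and in_deg[j] >= max_parents:
            continue
        chosen.append((i, j))
        in_deg[j] += 1
    if len(chosen) < n_edges:  # pragma: no cover - capacity check above prevents this
        raise ValueError("could not place requested edge count under max_parents")

    delays = rng.integers(lo, hi + 1, size=n_edges)
    edges = [
        Edge(pre=i, post=j, delay=int(d), weight=weight, sign=-1 if i in inhibitory else 1)
        for (i, j), d in zip(chosen, delays)
    ]

    return GroundTruthNetwork(
        n_neurons=n_neurons,
        edges=edges,
        barrel_assignment=assignment,
        background_rate=background_rate,
    )


def _sim_kernel_py(base, pre, post, wsig, delay, u, r, t0, t1, refractory):
    """Reference pure-python simulation loop (slow; used as numba fallback)."""
    n = base.shape[0]
    n_edges = pre.shape[0]
    n_clip = 0
    acc = np.zeros(n)
    for t in range(t0, t1):
        for e in range(n_edges):
            td = t - delay[e]
            if td >= 0 and r[pre[e], td]:
                acc[post[e]] += wsig[e]
        for i in range(n):
            p = base[i, t] + acc[i]
            acc[i] = 0.0
            if refractory and t > 0 and r[i, t - 1]:
                p = 0.0
            if p > 1.0:
                n_clip += 1
                p = 1.0
            elif p < 0.0:
                p = 0.0
            if u[i, t - t0] < p:
                r[i, t] = 1
    return n_clip


try:  # compiled inner loop: sessions are millions of 1-ms bins
    from numba import njit

    _sim_kernel = njit(cache=False)(_sim_kernel_py)
except ImportError:  # pragma: no cover
    _sim_kernel = _sim_kernel_py

_CHUNK_BINS = 500_000


def simulate_session(
    network: GroundTruthNetwork,
    protocol: StimulusProtocol,
    seed: int = 0,
    *,
    refractory: bool = False,
) -> TrialEnsemble:
    """Simulate one recording session under the given protocol.

    Trials are delivered in one block per whisker (onsets ``period`` bins
    apart); each neuron spikes per bin with the clipped linear conditional
    intensity described in the module docstring.  Deterministic given ``seed``.
    """
    if set(protocol.whiskers) != set(network.barrels):
        raise ValueError(
            f"protocol whiskers {sorted(protocol.whiskers)} and network barrels "
            f"{sorted(network.barrels)} must use the same labels"
        )
    n = network.n_neurons
    K = len(protocol.whiskers)
    per = protocol.period
    block = protocol.trials_per_whisker * per
    T = K * block + protocol.baseline_window

    base = np.full((n, T), network.background_rate / 1000.0)  # spikes/s -> prob per 1-ms bin
    # each barrel responds with its own whisker's gain profile, both to its
    # whisker's deflection and (scaled) to cross-talk from a paired whisker
    profiles = {w: protocol.gain_profile(w) for w in protocol.whiskers}
    W = protocol.trial_window

    onsets: list[int] = []
    whisker_of_trial: list[str] = []
    for b, w in enumerate(protocol.whiskers):
        # barrel -> gain fraction (of the barrel's own profile)
        targets: dict[str, float] = {w: network.stimulus_gain_scale.get(w, 1.0)}
        for barrel, bleed in network.stimulus_bleed.items():
            if w in bleed:
                targets[barrel] = targets.get(barrel, 0.0) + bleed[w]
        rows = {barrel: network.neurons_in(barrel) for barrel in targets}
        for k in range(protocol.trials_per_whisker):
            onset = b * block + protocol.baseline_window + k * per
            onsets.append(onset)
            whisker_of_trial.append(w)
            for barrel, frac in targets.items():
                base[np.ix_(rows[barrel], np.arange(onset, onset + W))] += (
                    frac * profiles[barrel]
                )

    pre = np.array([e.pre for e in network.edges], dtype=np.int64)
    post = np.array([e.post for e in network.edges], dtype=np.int64)
    wsig = np.array([e.weight * e.sign for e in network.edges], dtype=np.float64)
    delay = np.array([e.delay for e in network.edges], dtype=np.int64)

    rng = np.random.default_rng(seed)
    r = np.zeros((n, T), dtype=np.uint8)
    n_clip = 0
    for t0 in range(0, T, _CHUNK_BINS):
        t1 = min(t0 + _CHUNK_BINS, T)
        u = rng.random((n, t1 - t0))
        n_clip += _sim_kernel(base, pre, post, wsig, delay, u, r, t0, t1, refractory)
    if n_clip:
        log.warning("per-bin spike probability exceeded 1 in %d bins; clipped", n_clip)

    unit_ids = np.arange(n, dtype=np.int64)
    site_ids = unit_ids % (N_SHANKS * SITES_PER_SHANK)
    return TrialEnsemble(
        raster=r,
        trial_onsets=np.array(onsets, dtype=np.int64),
        whisker_of_trial=whisker_of_trial,
        unit_ids=unit_ids,
        site_ids=site_ids,
        trial_window=protocol.trial_window,
        baseline_window=protocol.baseline_window,
    )


def apply_pairing(
    network: GroundTruthNetwork, effect: PairingEffect, seed: int = 0
) -> GroundTruthNetwork:
    """Return a modified copy of ``network`` emulating whisker pairing.

    Modes
    -----
    add_cross_edges
        At strength ``s``, the first ``round(s * n_candidates)`` of a
        seed-shuffled list of missing cross-barrel pairs become excitatory
        edges; strength 1 saturates every candidate.
    strengthen_cross_edges (default)
        Existing cross-barrel edge weights are scaled by ``1 + s`` and a
        ``s * cross_add_fraction`` prefix of the candidate list is added.
    correlate_inputs
        No structural change; the paired barrels' receptive fields mix.
        Each barrel responds at fraction ``s/2`` of its own gain to the
        *other* paired whisker and at ``1 - s/2`` to its own, conserving the
        total evoked drive; at ``s = 1`` the two whiskers deliver identical
        stimulus conditions (cortically transmitted co-activation with
        homeostatic scaling).

    The candidate order and per-candidate delays are drawn once per seed, so
    for a fixed seed the cross edges added at a smaller strength are a subset
    of those added at any larger strength.  ``convergence_modifier`` then adds
    (positive) or removes (negative, sparing cross-barrel edges) a fraction of
    the original edge count.  ``strength == 0`` with zero modifier returns an
    edge-for-edge identical copy.
    """
    a, b = effect.paired_barrels
    known = set(network.barrels)
    for lbl in (a, b):
        if lbl not in known:
            raise ValueError(f"unknown barrel label {lbl!r}; network has {sorted(known)}")

    new = replace(
        network,
        edges=list(network.edges),
        barrel_assignment=dict(network.barrel_assignment),
        stimulus_bleed={k: dict(v) for k, v in network.stimulus_bleed.items()},
        stimulus_gain_scale=dict(network.stimulus_gain_scale),
    )
    ss = np.random.SeedSequence(seed)
    r_cross, r_conv = (np.random.default_rng(c) for c in ss.spawn(2))

    neurons_a = network.neurons_in(a)
    neurons_b = network.neurons_in(b)
    existing = network.edge_pairs()
    cross_all = sorted(
        {(int(i), int(j)) for i in neurons_a for j in neurons_b}
        | {(int(j), int(i)) for i in neurons_a for j in neurons_b}
    )
    candidates = [p for p in cross_all if p not in existing]
    # draw permutation + delays for the FULL candidate list so that the edges
    # added at strength s are a prefix independent of s (monotonicity)
    perm = r_cross.permutation(len(candidates))
    cand_delays = r_cross.integers(1, 6, size=len(candidates))
    ordered = [(candidates[k], int(cand_delays[k])) for k in perm]

    s = effect.strength
    if s > 0:
        if effect.mode == "add_cross_edges":
            n_add = int(round(s * len(ordered)))
        elif effect.mode == "strengthen_cross_edges":
            n_add = int(round(s * effect.cross_add_fraction * len(ordered)))
            cross_set = set(cross_all)
            new.edges = [
                replace(e, weight=e.weight * (1.0 + s))
                if (e.pre, e.post) in cross_set
                else e
                for e in new.edges
            ]
        else:  # correlate_inputs: drive-conserving receptive-field mixing
            n_add = 0
            for barrel, whisker in ((a, b), (b, a)):
                new.stimulus_bleed.setdefault(barrel, {})
                new.stimulus_bleed[barrel][whisker] = (
                    new.stimulus_bleed[barrel].get(whisker, 0.0) + s / 2.0
                )
                new.stimulus_gain_scale[barrel] = (
                    new.stimulus_gain_scale.get(barrel, 1.0) - s / 2.0
                )
        for (i, j), d in ordered[:n_add]:
            new.edges.append(Edge(pre=i, post=j, delay=d, weight=effect.cross_weight, sign=1))

    c = effect.convergence_modifier
    if c:
        n_change = int(round(abs(c) * len(network.edges)))
        if c > 0:
            present = {(e.pre, e.post) for e in new.edges}
            cand_set = set(candidates)
            free = sorted(
                (i, j)
                for i in range(network.n_neurons)
                for j in range(network.n_neurons)
                if i != j and (i, j) not in present and (i, j) not in cand_set
            )
            pick = r_conv.permutation(len(free))[:n_change]
            delays = r_conv.integers(1, 6, size=len(pick))
            base_w = float(np.mean([e.weight for e in network.edges])) if network.edges else effect.cross_weight
            for k, d in zip(pick, delays):
                i, j = free[k]
                new.edges.append(Edge(pre=i, post=j, delay=int(d), weight=base_w, sign=1))
        else:
            cross_set = set(cross_all)
            removable = [k for k, e in enumerate(new.edges) if (e.pre, e.post) not in cross_set]
            drop = set(
                r_conv.choice(removable, size=min(n_change, len(removable)), replace=False).tolist()
            )
            new.edges = [e for k, e in enumerate(new.edges) if k not in drop]

    return new
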