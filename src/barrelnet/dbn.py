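"""Dynamic Bayesian Network structure learning over binned spike trains.

A structure is a set of lagged directed edges ``(pre, post, lag)`` with lags
in 1..L bins; because all edges cross time slices, any parent assignment is
acyclic, and the Bayesian Dirichlet equivalent (BDe) log marginal likelihood
decomposes into one term per child neuron ("family").  For child ``i`` with
parent configuration counts ``Z_ijk`` (child state ``j`` in {0, 1}, parent
configuration ``k``) and Dirichlet pseudo-counts ``Z'``:

    log Pr(D|G) = sum_{i,k} [ log Gamma(Z'_ik) - log Gamma(Z'_ik + Z_ik)
                              + sum_j log Gamma(Z'_ijk + Z_ijk)
                                       - log Gamma(Z'_ijk) ]

The prior is the uninformative BDeu choice: equivalent sample size ``a`` with
``Z'_ijk = a / (2 * 2^{|parents|})``.  Structures are searched by simulated
annealing over add/delete/reverse moves (an exhaustive per-family enumeration
is provided as an oracle for small instances), and multi-lag edges of one
ordered pair are collapsed onto the largest inferred lag.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln


@dataclass(frozen=True)
class LaggedEdge:
    pre: int
    post: int
    lag: int


@dataclass
class LaggedNetwork:
    """DBN structure: lagged inter-slice edges with a per-child parent cap."""

    n_neurons: int
    edges: frozenset[LaggedEdge] = frozenset()
    max_lag: int = 5
    max_parents: int = 10

    def __post_init__(self) -> None:
        self.edges = frozenset(
            e if isinstance(e, LaggedEdge) else LaggedEdge(*e) for e in self.edges
        )
        for e in self.edges:
            if not 1 <= e.lag <= self.max_lag:
                raise ValueError(f"edge lag {e.lag} outside [1, {self.max_lag}]")
        for j in range(self.n_neurons):
            if len(self.parents_of(j)) > self.max_parents:
                raise ValueError(f"child {j} exceeds max_parents={self.max_parents}")

    def parents_of(self, child: int) -> tuple[tuple[int, int], ...]:
        """Sorted (parent index, lag) pairs of one child."""
        return tuple(sorted((e.pre, e.lag) for e in self.edges if e.post == child))


@dataclass
class FamilyStatistics:
    """Sufficient statistics of one child/parent-set family.

    ``counts[k, j]`` is ``Z_ijk`` for parent configuration ``k`` (binary tuple
    of lagged parent values read as an integer, first parent = lowest bit) and
    child state ``j``.
    """

    child: int
    parents: tuple[tuple[int, int], ...]
    counts: np.ndarray  # (2^B, 2) int64
    alpha_jk: float  # Z'_ijk, identical across (j, k) under the uniform prior
    t_effective: int

    @property
    def alpha_k(self) -> float:
        return 2.0 * self.alpha_jk


@dataclass
class ScoredStructure:
    network: LaggedNetwork
    log_score: float
    family_scores: dict[int, float] = field(default_factory=dict)


@dataclass
class CollapsedAdjacency:
    """Binary lag-collapsed connectivity with the retained (largest) lag."""

    matrix: np.ndarray  # (n, n) uint8, diagonal 0
    lags: np.ndarray  # (n, n) int64, 0 where no edge


@dataclass
class AnnealConfig:
    """Simulated-annealing search settings.

    ``iterations`` is the total proposal budget, split evenly over
    ``restarts``; temperature restarts at ``initial_temperature`` each restart
    and cools geometrically per proposal.
    """

    max_parents: int = 10
    lags: tuple[int, int] = (1, 5)
    initial_temperature: float = 1.0
    cooling: float = 0.9995
    iterations: int = 200_000
    restarts: int = 3
    random_init: bool = False
    init_density: float = 0.05
    ess: float = 1.0
    mask_seams: bool = False


def _as_raster(data) -> np.ndarray:
    raster = getattr(data, "raster", data)
    return np.asarray(raster, dtype=np.uint8)


def _seams(data) -> np.ndarray:
    s = getattr(data, "seams", None)
    return np.asarray(s, dtype=np.int64) if s is not None else np.empty(0, np.int64)


class FamilyScorer:
    """Caches BDe family scores for one dataset.

    Precomputes an int64 copy of the raster so that parent configurations can
    be assembled with shifted views and bit operations; scores are memoised by
    (child, parent set).
    """

    def __init__(self, data, max_lag: int = 5, ess: float = 1.0, mask_seams: bool = False):
        self.X = _as_raster(data).astype(np.int64)
        self.n, self.T = self.X.shape
        self.max_lag = max_lag
        self.ess = ess
        self.seam_starts = _seams(data) if mask_seams else np.empty(0, np.int64)
        self.mask_seams = mask_seams
        self._cache: dict[tuple[int, tuple[tuple[int, int], ...]], float] = {}

    def statistics(self, child: int, parents) -> FamilyStatistics:
        parents = tuple(sorted(tuple(p) for p in parents))
        if len(set(parents)) != len(parents):
            raise ValueError("duplicate (parent, lag) entries")
        B = len(parents)
        lmax = max((l for _, l in parents), default=0)
        alpha_jk = self.ess / (2.0 * (1 << B))
        if self.T <= lmax:
            return FamilyStatistics(child, parents, np.zeros(((1 << B), 2), np.int64), alpha_jk, 0)
        child_vec = self.X[child, lmax : self.T]
        if B:
            kvec = np.zeros(self.T - lmax, dtype=np.int64)
            for b, (p, lag) in enumerate(parents):
                np.add(kvec, self.X[p, lmax - lag : self.T - lag] << b, out=kvec)
            idx = (kvec << 1) | child_vec
        else:
            idx = child_vec
        if self.mask_seams and self.seam_starts.size and lmax:
            keep = np.ones(self.T - lmax, dtype=bool)
            for s in self.seam_starts:
                keep[max(s - lmax, 0) : max(s - lmax + self.max_lag, 0)] = False
            idx = idx[keep]
        counts = np.bincount(idx, minlength=2 << B).reshape(1 << B, 2)
        return FamilyStatistics(child, parents, counts, alpha_jk, int(counts.sum()))

    def score(self, child: int, parents) -> float:
        key = (child, tuple(sorted(tuple(p) for p in parents)))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        val = bde_family_score(self.statistics(child, key[1]))
        self._cache[key] = val
        return val


def family_statistics(data, child: int, parents, ess: float = 1.0, *,
                      max_lag: int = 5, mask_seams: bool = False) -> FamilyStatistics:
    """Count ``Z_ijk`` for one child and (parent, lag) set over a dataset.

    Bins whose lagged parents would fall before the dataset start are dropped
    (family-specific effective length); with ``mask_seams`` the first
    ``max_lag`` bins after every trial-concatenation seam are dropped too.
    """
    return FamilyScorer(data, max_lag=max_lag, ess=ess, mask_seams=mask_seams).statistics(
        child, parents
    )


def bde_family_score(stats: FamilyStatistics) -> float:
    """BDe log score of one family from its sufficient statistics."""
    a_jk, a_k = stats.alpha_jk, stats.alpha_k
    if a_jk <= 0.0:
        raise ValueError("Dirichlet pseudo-counts must be positive")
    c = stats.counts
    z_k = c.sum(axis=1)
    val = float(
        np.sum(gammaln(a_k) - gammaln(a_k + z_k))
        + np.sum(gammaln(a_jk + c) - gammaln(a_jk))
    )
    return val


def total_score(data, network: LaggedNetwork, ess: float = 1.0, *,
                mask_seams: bool = False) -> ScoredStructure:
    """Sum of BDe family scores over all children (decomposable)."""
    scorer = FamilyScorer(data, max_lag=network.max_lag, ess=ess, mask_seams=mask_seams)
    fam = {j: scorer.score(j, network.parents_of(j)) for j in range(network.n_neurons)}
    return ScoredStructure(network=network, log_score=sum(fam.values()), family_scores=fam)


# ---------------------------------------------------------------------------
# simulated-annealing search
# ---------------------------------------------------------------------------


def _decode_pair(pid: int, n: int) -> tuple[int, int]:
    i = pid // (n - 1)
    off = pid % (n - 1)
    return i, off if off < i else off + 1


def anneal_search(
    data,
    config: AnnealConfig | None = None,
    seed: int = 0,
    trace: list | None = None,
) -> ScoredStructure:
    """Search structures by simulated annealing over add/delete/reverse moves.

    Proposals are uniform over the legal moves (uniform sampling over the move
    superset with rejection of illegal draws); a move is accepted with
    probability ``min(1, exp(delta / T))`` under geometric cooling.  The
    best-ever structure across all restarts is returned.  Deterministic given
    ``seed``; the parent cap is enforced by move legality.
    """
    cfg = config or AnnealConfig()
    X = _as_raster(data)
    n, T = X.shape
    lag_lo, lag_hi = cfg.lags
    L = lag_hi - lag_lo + 1
    if T <= lag_hi:
        raise ValueError(f"dataset has {T} bins; need more than max lag {lag_hi}")
    scorer = FamilyScorer(data, max_lag=lag_hi, ess=cfg.ess, mask_seams=cfg.mask_seams)
    rng = np.random.default_rng(seed)

    npairs = n * (n - 1)
    superset = npairs * (L + 2)  # adds (pair x lag), deletes, reverses
    per_restart = max(cfg.iterations // max(cfg.restarts, 1), 0)

    best_total = -math.inf
    best_parents: list[dict[int, int]] | None = None

    for _restart in range(max(cfg.restarts, 1)):
        parents: list[dict[int, int]] = [dict() for _ in range(n)]  # child -> {pre: lag}
        if cfg.random_init:
            for pid in range(npairs):
                if rng.random() < cfg.init_density:
                    i, j = _decode_pair(pid, n)
                    if len(parents[j]) < cfg.max_parents:
                        parents[j][i] = int(rng.integers(lag_lo, lag_hi + 1))
        fam = [scorer.score(j, tuple(sorted(parents[j].items()))) for j in range(n)]
        total = float(sum(fam))
        if total > best_total:
            best_total = total
            best_parents = [dict(p) for p in parents]
        temp = cfg.initial_temperature

        for it in range(per_restart):
            move = None
            for _try in range(1000):
                z = int(rng.integers(superset))
                if z < npairs * L:
                    pid, lag = divmod(z, L)
                    i, j = _decode_pair(pid, n)
                    if i not in parents[j] and len(parents[j]) < cfg.max_parents:
                        move = ("add", i, j, lag_lo + lag)
                        break
                elif z < npairs * (L + 1):
                    i, j = _decode_pair(z - npairs * L, n)
                    if i in parents[j]:
                        move = ("del", i, j, parents[j][i])
                        break
                else:
                    i, j = _decode_pair(z - npairs * (L + 1), n)
                    if i in parents[j] and j not in parents[i] and len(parents[i]) < cfg.max_parents:
                        move = ("rev", i, j, parents[j][i])
                        break
            if move is None:  # no legal move found; keep current best
                break

            kind, i, j, lag = move
            if kind == "rev":
                pj = dict(parents[j]); del pj[i]
                pi = dict(parents[i]); pi[j] = lag
                new_j = scorer.score(j, tuple(sorted(pj.items())))
                new_i = scorer.score(i, tuple(sorted(pi.items())))
                delta = (new_j - fam[j]) + (new_i - fam[i])
            else:
                pj = dict(parents[j])
                if kind == "add":
                    pj[i] = lag
                else:
                    del pj[i]
                new_j = scorer.score(j, tuple(sorted(pj.items())))
                delta = new_j - fam[j]

            accept = delta >= 0 or (temp > 0 and rng.random() < math.exp(delta / temp))
            if accept:
                if kind == "add":
                    parents[j][i] = lag
                    fam[j] = new_j
                elif kind == "del":
                    del parents[j][i]
                    fam[j] = new_j
                else:
                    del parents[j][i]
                    parents[i][j] = lag
                    fam[j], fam[i] = new_j, new_i
                total += delta
                if total > best_total + 1e-12:
                    best_total = total
                    best_parents = [dict(p) for p in parents]
            if trace is not None:
                trace.append(
                    {"iteration": it, "temperature": temp, "score": total, "accepted": bool(accept)}
                )
            temp *= cfg.cooling

    assert best_parents is not None
    edges = frozenset(
        LaggedEdge(pre=i, post=j, lag=lag)
        for j, ps in enumerate(best_parents)
        for i, lag in ps.items()
    )
    net = LaggedNetwork(n_neurons=n, edges=edges, max_lag=lag_hi, max_parents=cfg.max_parents)
    fams = {j: scorer.score(j, net.parents_of(j)) for j in range(n)}
    return ScoredStructure(network=net, log_score=float(sum(fams.values())), family_scores=fams)


def exhaustive_search(
    data,
    lags: tuple[int, int] = (1, 5),
    max_parents: int = 10,
    ess: float = 1.0,
    *,
    mask_seams: bool = False,
    max_sets_per_child: int = 100_000,
) -> ScoredStructure:
    """Globally optimal structure by per-family enumeration (small n only).

    Valid because every edge crosses time slices: families are independent,
    so the global optimum is the per-child best parent set.  Each potential
    parent contributes (L + 1) options (absent, or one lag), at most one lag
    per ordered pair.
    """
    X = _as_raster(data)
    n, _T = X.shape
    lag_lo, lag_hi = lags
    L = lag_hi - lag_lo + 1
    n_sets = (L + 1) ** (n - 1)
    if n > 4 or n_sets > max_sets_per_child:
        raise ValueError(
            f"exhaustive enumeration needs n <= 4 and <= {max_sets_per_child} parent "
            f"sets per child; got n={n} with ~{n_sets} sets"
        )
    scorer = FamilyScorer(data, max_lag=lag_hi, ess=ess, mask_seams=mask_seams)
    lag_options = [None] + list(range(lag_lo, lag_hi + 1))
    edges: set[LaggedEdge] = set()
    fams: dict[int, float] = {}
    for j in range(n):
        others = [i for i in range(n) if i != j]
        best, best_set = -math.inf, ()
        for combo in itertools.product(lag_options, repeat=len(others)):
            pset = tuple((i, lag) for i, lag in zip(others, combo) if lag is not None)
            if len(pset) > max_parents:
                continue
            s = scorer.score(j, pset)
            if s > best:
                best, best_set = s, pset
        fams[j] = best
        edges.update(LaggedEdge(pre=i, post=j, lag=lag) for i, lag in best_set)
    net = LaggedNetwork(n_neurons=n, edges=frozenset(edges), max_lag=lag_hi, max_parents=max_parents)
    return ScoredStructure(network=net, log_score=float(sum(fams.values())), family_scores=fams)


def collapse_lags(network: LaggedNetwork) -> CollapsedAdjacency:
    """Collapse multi-lag edges of one ordered pair onto the largest lag.

    Returns the binary adjacency ``A[i, j] = 1`` iff any lagged edge i -> j
    exists, annotated with the retained (largest) lag; self-edges are dropped.
    """
    n = network.n_neurons
    A = np.zeros((n, n), dtype=np.uint8)
    lags = np.zeros((n, n), dtype=np.int64)
    for e in network.edges:
        if e.pre == e.post:
            continue
        A[e.pre, e.post] = 1
        lags[e.pre, e.post] = max(lags[e.pre, e.post], e.lag)
    return CollapsedAdjacency(matrix=A, lags=lags)
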