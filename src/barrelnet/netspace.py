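"""Network feature space and ensemble-level plasticity statistics.

Inferred networks are compared in a PCA-derived feature space: each binary
adjacency matrix is vectorised (off-diagonal entries, fixed row-major order),
the vectors of all networks under comparison are stacked and mean-centred,
and PCA projects them onto ``p`` principal axes (default 2).  The distance
between two networks is the Euclidean distance between their projections; the
average distance between the networks of two whiskers w1, w2 is

    D_bar(w1, w2) = (2 / M^2) * sum_l sum_m || q_l^{w1} - q_m^{w2} ||

(the 2/M^2 factor applied literally; ``strict_mean`` switches to the plain
mean 1/M^2 — the choice cancels in the normalised similarity).  Similarity is
1 minus D_bar normalised by the maximum D_bar over the compared whisker
pairs.  Pre-synaptic convergence is the mean inferred in-degree per neuron,
optionally as a fraction of the n - 1 possible parents.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)


@dataclass
class AdjacencyMatrix:
    """Lag-collapsed binary connectivity of one inferred network."""

    matrix: np.ndarray
    whisker: str = ""
    dataset_index: int = 0
    session: str = ""
    subject: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(np.diag(self.matrix)):
            raise ValueError("adjacency diagonal must be 0")


@dataclass
class NetworkFeatureSpace:
    """Stacked vectorised adjacencies projected onto principal axes."""

    projections: np.ndarray  # (N, p)
    labels: pd.DataFrame  # columns: session, whisker, dataset, subject
    vectors: np.ndarray  # (N, n^2 - n) centred off-diagonal vectorisations
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    degenerate: bool = False


@dataclass
class SimilarityReport:
    """Per (session, whisker pair): average distance and similarity.

    ``samples[(session, w1, w2)]`` holds per-dataset similarity values (one
    per dataset on each side of the pair) whose mean equals the pair's
    reported similarity; these are the samples for session comparisons.
    """

    table: pd.DataFrame
    samples: dict[tuple[str, str, str], np.ndarray]
    norm_const: float
    degenerate: bool = False


@dataclass
class ConvergenceSummary:
    per_network: pd.DataFrame  # session, whisker, dataset, subject, value
    by_session: pd.DataFrame  # session, mean, sd, n
    normalized: bool = True


@dataclass
class TTestResult:
    t: float
    p: float
    flagged: bool = False


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Silicon-array layout: site = shank * sites_per_shank + depth index."""

    n_shanks: int = 8
    sites_per_shank: int = 4
    shank_pitch_um: float = 200.0
    site_pitch_um: float = 100.0

    def separation(self, site_a: int, site_b: int) -> tuple[float, float]:
        sa, da = divmod(int(site_a), self.sites_per_shank)
        sb, db = divmod(int(site_b), self.sites_per_shank)
        return abs(sa - sb) * self.shank_pitch_um, abs(da - db) * self.site_pitch_um


def _vectorize(adjacencies: list[AdjacencyMatrix]) -> np.ndarray:
    n = adjacencies[0].matrix.shape[0]
    for a in adjacencies:
        if a.matrix.shape[0] != n:
            raise ValueError("all adjacency matrices must have the same size")
    mask = ~np.eye(n, dtype=bool)  # row-major off-diagonal order
    return np.stack([a.matrix[mask].astype(float) for a in adjacencies])


def build_feature_space(adjacencies: list[AdjacencyMatrix], p: int = 2) -> NetworkFeatureSpace:
    """Vectorise, stack, mean-centre and project adjacencies onto p axes."""
    if len(adjacencies) < 2:
        raise ValueError("need at least 2 networks")
    if len(adjacencies) < p:
        raise ValueError(f"fewer networks ({len(adjacencies)}) than components ({p})")
    V = _vectorize(adjacencies)
    labels = pd.DataFrame(
        {
            "session": [a.session for a in adjacencies],
            "whisker": [a.whisker for a in adjacencies],
            "dataset": [a.dataset_index for a in adjacencies],
            "subject": [a.subject for a in adjacencies],
        }
    )
    centred = V - V.mean(axis=0, keepdims=True)
    total_var = float((centred**2).sum())
    if total_var == 0.0:
        log.warning("all networks identical; feature space is degenerate")
        return NetworkFeatureSpace(
            projections=np.zeros((len(adjacencies), p)),
            labels=labels,
            vectors=centred,
            components=np.zeros((p, V.shape[1])),
            explained_variance_ratio=np.zeros(p),
            degenerate=True,
        )
    pca = PCA(n_components=p, svd_solver="full")
    proj = pca.fit_transform(V)
    return NetworkFeatureSpace(
        projections=proj,
        labels=labels,
        vectors=centred,
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def network_distance(q_l: np.ndarray, q_m: np.ndarray) -> float:
    """Euclidean distance between two feature-space projections."""
    q_l = np.asarray(q_l, dtype=float)
    q_m = np.asarray(q_m, dtype=float)
    if q_l.shape != q_m.shape:
        raise ValueError(f"projection dimensions differ: {q_l.shape} vs {q_m.shape}")
    return float(np.linalg.norm(q_l - q_m))


def _select(space: NetworkFeatureSpace, whisker: str, session: str | None) -> np.ndarray:
    sel = space.labels["whisker"] == whisker
    if session is not None:
        sel &= space.labels["session"] == session
    return space.projections[sel.to_numpy()]


def average_pair_distance(
    space: NetworkFeatureSpace,
    w1: str,
    w2: str,
    session: str | None = None,
    strict_mean: bool = False,
    allow_unequal: bool = False,
) -> float:
    """Average cross-pair projection distance between two whiskers' networks.

    Applies the (2 / M^2) prefactor literally; ``strict_mean`` uses 1 / M^2.
    Unequal dataset counts are rejected unless ``allow_unequal`` generalises
    the prefactor to 2 / (M1 * M2).
    """
    Q1, Q2 = _select(space, w1, session), _select(space, w2, session)
    if len(Q1) == 0 or len(Q2) == 0:
        raise ValueError(f"no networks for whisker pair ({w1}, {w2})")
    if len(Q1) != len(Q2) and not allow_unequal:
        raise ValueError(f"unequal dataset counts: {len(Q1)} vs {len(Q2)}")
    factor = 1.0 if strict_mean else 2.0
    return float(factor * cdist(Q1, Q2).sum() / (len(Q1) * len(Q2)))


def similarity_report(
    space: NetworkFeatureSpace,
    pairs: list[tuple[str, str]] | None = None,
    by: tuple[str, ...] = ("session",),
    strict_mean: bool = False,
) -> SimilarityReport:
    """Similarity = 1 - D_bar / max D_bar over all compared groups and pairs.

    Groups are the unique combinations of the ``by`` label columns (default:
    one group per session; pass ``("subject", "session")`` for per-subject
    rows).  One common normalisation constant across all groups keeps
    similarities comparable group-to-group (the feature space is likewise
    shared).  Per-dataset samples: for dataset l of w1, its average distance
    to all of w2's datasets (and symmetrically), passed through the same
    normalisation; keyed by the group tuple + (w1, w2).
    """
    lab = space.labels
    if pairs is None:
        whiskers = list(dict.fromkeys(lab["whisker"]))
        pairs = [(a, b) for i, a in enumerate(whiskers) for b in whiskers[i + 1 :]]
    if not pairs:
        raise ValueError("no whisker pairs to compare")

    factor = 1.0 if strict_mean else 2.0
    rows = []
    raw_samples: dict[tuple, np.ndarray] = {}
    groups = lab[list(by)].drop_duplicates().itertuples(index=False, name=None)
    for grp in groups:
        sel_g = np.ones(len(lab), dtype=bool)
        for col, val in zip(by, grp):
            sel_g &= (lab[col] == val).to_numpy()
        for w1, w2 in pairs:
            s1 = sel_g & (lab["whisker"] == w1).to_numpy()
            s2 = sel_g & (lab["whisker"] == w2).to_numpy()
            Q1, Q2 = space.projections[s1], space.projections[s2]
            if len(Q1) == 0 or len(Q2) == 0:
                continue
            D = cdist(Q1, Q2)
            dbar = float(factor * D.sum() / (len(Q1) * len(Q2)))
            per_l = factor * D.mean(axis=1)  # one value per w1 dataset
            per_m = factor * D.mean(axis=0)  # one value per w2 dataset
            rows.append(dict(zip(by, grp)) | {"w1": w1, "w2": w2, "mean_distance": dbar})
            raw_samples[grp + (w1, w2)] = np.concatenate([per_l, per_m])
    if not rows:
        raise ValueError("no (group, whisker pair) combinations found in the space")
    table = pd.DataFrame(rows)
    norm = float(table["mean_distance"].max())
    degenerate = norm == 0.0
    if degenerate:
        log.warning("all average pair distances are 0; similarities degenerate to 1")
        table["normalized_distance"] = 0.0
        table["similarity"] = 1.0
        samples = {k: np.ones_like(v) for k, v in raw_samples.items()}
    else:
        table["normalized_distance"] = table["mean_distance"] / norm
        table["similarity"] = 1.0 - table["normalized_distance"]
        samples = {k: 1.0 - v / norm for k, v in raw_samples.items()}
    return SimilarityReport(table=table, samples=samples, norm_const=norm, degenerate=degenerate)


def presynaptic_convergence(
    adjacencies: list[AdjacencyMatrix], normalize: bool = True
) -> ConvergenceSummary:
    """Mean inferred in-degree per neuron, aggregated per session.

    With ``normalize`` the per-network value is divided by (n - 1), i.e. the
    fraction of possible parents per neuron.
    """
    rows = []
    for a in adjacencies:
        n = a.matrix.shape[0]
        val = float(a.matrix.sum(axis=0).mean())
        if normalize:
            val /= n - 1
        rows.append(
            {
                "session": a.session,
                "whisker": a.whisker,
                "dataset": a.dataset_index,
                "subject": a.subject,
                "value": val,
            }
        )
    per_network = pd.DataFrame(rows)
    by_session = (
        per_network.groupby("session", sort=False)["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return ConvergenceSummary(per_network=per_network, by_session=by_session, normalized=normalize)


def connection_probability_by_separation(
    adjacencies: list[AdjacencyMatrix],
    unit_sites: np.ndarray,
    geometry: ElectrodeGeometry | None = None,
) -> pd.DataFrame:
    """Connection probability vs horizontal/vertical electrode separation.

    For each (dh, dv) separation bin: the fraction of unordered unit pairs at
    that separation that are connected in either direction, averaged over
    networks.  Bins with no pairs are omitted.
    """
    geometry = geometry or ElectrodeGeometry()
    n = adjacencies[0].matrix.shape[0]
    unit_sites = np.asarray(unit_sites)
    if unit_sites.shape[0] != n:
        missing = list(range(unit_sites.shape[0], n))
        raise ValueError(f"units without a site mapping: {missing}")
    either = np.mean(
        [(a.matrix | a.matrix.T).astype(float) for a in adjacencies], axis=0
    )
    acc: dict[tuple[float, float], list[float]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            key = geometry.separation(unit_sites[i], unit_sites[j])
            acc.setdefault(key, []).append(either[i, j])
    rows = [
        {
            "horizontal_um": dh,
            "vertical_um": dv,
            "probability": float(np.mean(v)),
            "n_pairs": len(v),
        }
        for (dh, dv), v in sorted(acc.items())
    ]
    return pd.DataFrame(rows)


def compare_sessions(
    values_a: np.ndarray, values_b: np.ndarray, equal_var: bool = True
) -> TTestResult:
    """Two-sample t-test (pooled variance by default; Welch optional)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        log.warning("zero variance in both samples with equal means; p = 1 by convention")
        return TTestResult(t=0.0, p=1.0, flagged=True)
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(t=float(t), p=float(p))


def plot_feature_space(space: NetworkFeatureSpace, path: str, sessions: list[str] | None = None):
    """Scatter the first two projection axes, one panel per session."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lab = space.labels
    sessions = sessions or list(dict.fromkeys(lab["session"]))
    fig, axes = plt.subplots(1, len(sessions), figsize=(4 * len(sessions), 4), squeeze=False)
    for ax, ses in zip(axes[0], sessions):
        sel_ses = (lab["session"] == ses).to_numpy()
        for w in dict.fromkeys(lab["whisker"]):
            sel = sel_ses & (lab["whisker"] == w).to_numpy()
            ax.scatter(space.projections[sel, 0], space.projections[sel, 1], s=12, label=w)
        ax.set_title(ses)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
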