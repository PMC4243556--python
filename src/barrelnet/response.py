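"""Trial windowing, dataset assembly and single-neuron response metrics.

The analysis unit is an 18-s *dataset*: the concatenated 100-ms post-onset
windows of 180 trials sampled uniformly without replacement from the 900
recorded trials of one whisker.  Single-neuron response is summarised per
trial by the baseline-corrected evoked spike count and the first-spike
latency; cross-whisker similarity of either metric is 1 minus the per-neuron
absolute difference normalised by the maximum absolute difference across
neurons.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import TrialEnsemble

log = logging.getLogger(__name__)


@dataclass
class AnalysisDataset:
    """Concatenated post-onset raster windows for one whisker.

    ``raster`` has shape (n_neurons, trials_per_dataset * trial_window) bins;
    seams between source trials fall every ``trial_window`` bins.
    """

    raster: np.ndarray
    trial_indices: np.ndarray  # indices into the source ensemble's trial list
    whisker: str
    index: int
    trial_window: int = 100
    bin_ms: float = 1.0

    @property
    def n_neurons(self) -> int:
        return self.raster.shape[0]

    @property
    def n_bins(self) -> int:
        return self.raster.shape[1]

    @property
    def seams(self) -> np.ndarray:
        """Bin indices where a new source trial starts (excluding bin 0)."""
        k = self.n_bins // self.trial_window
        return np.arange(1, k) * self.trial_window


@dataclass
class SimilarityTable:
    """Per-neuron similarity in [0, 1] for one whisker pair and metric."""

    similarity: np.ndarray
    norm_const: float
    metric: str = ""


def assemble_datasets(
    ensemble: TrialEnsemble,
    whisker: str,
    n_datasets: int = 100,
    trials_per_dataset: int = 180,
    seed: int = 0,
) -> list[AnalysisDataset]:
    """Assemble ``n_datasets`` concatenated-trial datasets for one whisker.

    Trials are sampled uniformly without replacement within each dataset and
    independently across datasets.  Deterministic given ``seed``.
    """
    trials = ensemble.trials_of(whisker)
    if len(trials) < trials_per_dataset:
        raise ValueError(
            f"whisker {whisker!r} has {len(trials)} trials; "
            f"{trials_per_dataset} needed per dataset"
        )
    W = ensemble.trial_window
    rng = np.random.default_rng(seed)
    out: list[AnalysisDataset] = []
    for m in range(n_datasets):
        pick = trials[rng.choice(len(trials), size=trials_per_dataset, replace=False)]
        segs = [
            ensemble.raster[:, o : o + W]
            for o in ensemble.trial_onsets[pick]
        ]
        out.append(
            AnalysisDataset(
                raster=np.concatenate(segs, axis=1),
                trial_indices=pick,
                whisker=whisker,
                index=m,
                trial_window=W,
                bin_ms=ensemble.bin_ms,
            )
        )
    return out


def evoked_count(ensemble: TrialEnsemble, neuron: int, trial: int) -> int | None:
    """Baseline-corrected evoked spike count for one neuron and trial.

    Spikes in [onset, onset + window) minus spikes in [onset - baseline,
    onset); may be negative.  Returns ``None`` (trial excluded, logged) when
    the baseline window would start before the recording.
    """
    onset = int(ensemble.trial_onsets[trial])
    W, B = ensemble.trial_window, ensemble.baseline_window
    if onset < B:
        log.warning("trial %d has no full baseline; excluded", trial)
        return None
    row = ensemble.raster[neuron]
    return int(row[onset : onset + W].sum()) - int(row[onset - B : onset].sum())


def first_spike_latency(ensemble: TrialEnsemble, neuron: int, trial: int) -> float | None:
    """Latency (ms) of the first spike in [onset, onset + window), or None.

    The onset bin counts (a spike exactly at onset has latency 0 ms); trials
    without a spike in the window are undefined and excluded from means.
    """
    onset = int(ensemble.trial_onsets[trial])
    win = ensemble.raster[neuron, onset : onset + ensemble.trial_window]
    hit = np.flatnonzero(win)
    if hit.size == 0:
        return None
    return float(hit[0]) * ensemble.bin_ms


def response_summary(ensemble: TrialEnsemble, whiskers: list[str] | None = None) -> pd.DataFrame:
    """Per-(neuron, whisker) mean evoked count and first-spike latency.

    Columns: neuron, whisker, evoked_count_mean, latency_mean_ms,
    n_trials_with_spike, n_latency_excluded.  Latency means exclude trials
    without a spike; neurons silent in every trial get latency NaN.
    """
    whiskers = whiskers if whiskers is not None else ensemble.whiskers
    W, B = ensemble.trial_window, ensemble.baseline_window
    rows = []
    for w in whiskers:
        tr = ensemble.trials_of(w)
        onsets = ensemble.trial_onsets[tr]
        onsets = onsets[onsets >= B]
        if len(onsets) < len(tr):
            log.warning("%d trial(s) of %s lacked a full baseline; excluded", len(tr) - len(onsets), w)
        # (n_neurons, n_trials, W) windows, vectorized over trials
        win_idx = onsets[:, None] + np.arange(W)[None, :]
        base_idx = onsets[:, None] + np.arange(-B, 0)[None, :]
        win = ensemble.raster[:, win_idx]  # (n, trials, W)
        base = ensemble.raster[:, base_idx]
        evoked = win.sum(axis=2).astype(np.int64) - base.sum(axis=2).astype(np.int64)
        any_spike = win.any(axis=2)
        # first spike bin via argmax on the window (valid where any_spike)
        first = win.argmax(axis=2).astype(float) * ensemble.bin_ms
        for i in range(ensemble.n_neurons):
            defined = any_spike[i]
            rows.append(
                {
                    "neuron": i,
                    "whisker": w,
                    "evoked_count_mean": float(evoked[i].mean()),
                    "latency_mean_ms": float(first[i][defined].mean()) if defined.any() else np.nan,
                    "n_trials_with_spike": int(defined.sum()),
                    "n_latency_excluded": int((~defined).sum()),
                }
            )
    return pd.DataFrame(rows)


def neuron_similarity(values_w1: np.ndarray, values_w2: np.ndarray, metric: str = "") -> SimilarityTable:
    """Per-neuron similarity = 1 - |v1 - v2| / max_j |v1_j - v2_j|.

    Neurons whose metric is undefined (NaN) for either whisker are excluded
    from the normalisation and get NaN similarity.  If the maximum absolute
    difference is 0, every similarity is 1.
    """
    v1 = np.asarray(values_w1, dtype=float)
    v2 = np.asarray(values_w2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("both whiskers must cover the same neuron set")
    if v1.size == 0:
        raise ValueError("empty neuron set")
    diff = np.abs(v1 - v2)
    defined = ~np.isnan(diff)
    if not defined.any():
        raise ValueError("no neuron has the metric defined for both whiskers")
    norm = float(np.max(diff[defined]))
    if v1.size == 1:
        log.warning("single-neuron similarity is degenerate (the neuron attains the max)")
    sim = np.full_like(diff, np.nan)
    if norm == 0.0:
        sim[defined] = 1.0
    else:
        sim[defined] = 1.0 - diff[defined] / norm
    return SimilarityTable(similarity=sim, norm_const=norm, metric=metric)
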