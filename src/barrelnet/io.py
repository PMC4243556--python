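"""Plain-text serialisation: spike/trial tables, ground truth and networks.

Schemas
-------
spikes.csv   unit_id, time_ms, site_id
trials.csv   whisker, onset_ms
meta.yaml    bin_ms, trial_window_ms, baseline_window_ms, duration_ms,
             unit_ids, site_ids, optional seed/config_hash
edges.csv    pre, post, delay_bins, weight, sign       (ground truth)
lagged edge-list CSV: pre, post, lag                    (inferred structures)
GraphML      via networkx, edge attribute "lag" (inferred) or
             delay/weight/sign (ground truth)
"""
from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .dbn import LaggedEdge, LaggedNetwork
from .synth import Edge, GroundTruthNetwork, TrialEnsemble

log = logging.getLogger(__name__)


def write_ensemble(ensemble: TrialEnsemble, outdir: str | Path, extra_meta: dict | None = None):
    """Write spikes.csv, trials.csv and meta.yaml for one session."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    units, bins = np.nonzero(ensemble.raster)
    pd.DataFrame(
        {
            "unit_id": ensemble.unit_ids[units],
            "time_ms": bins * ensemble.bin_ms,
            "site_id": ensemble.site_ids[units],
        }
    ).to_csv(outdir / "spikes.csv", index=False)
    pd.DataFrame(
        {
            "whisker": ensemble.whisker_of_trial,
            "onset_ms": ensemble.trial_onsets * ensemble.bin_ms,
        }
    ).to_csv(outdir / "trials.csv", index=False)
    meta = {
        "bin_ms": float(ensemble.bin_ms),
        "trial_window_ms": int(ensemble.trial_window),
        "baseline_window_ms": int(ensemble.baseline_window),
        "duration_ms": float(ensemble.n_bins * ensemble.bin_ms),
        "unit_ids": [int(u) for u in ensemble.unit_ids],
        "site_ids": [int(s) for s in ensemble.site_ids],
    }
    meta.update(extra_meta or {})
    (outdir / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return outdir


def load_recording(
    spikes_file: str | Path, trials_file: str | Path, meta_file: str | Path
) -> TrialEnsemble:
    """Load and validate a recording; synthetic output round-trips loss-free.

    Trials whose onset precedes a full baseline window are excluded (logged);
    unknown unit ids are rejected with the offending CSV line numbers.
    """
    meta = yaml.safe_load(Path(meta_file).read_text())
    for key in ("bin_ms", "trial_window_ms", "baseline_window_ms", "duration_ms", "unit_ids", "site_ids"):
        if key not in meta:
            raise ValueError(f"meta file missing required key {key!r}")
    spikes = pd.read_csv(spikes_file)
    trials = pd.read_csv(trials_file)
    for df, path, cols in (
        (spikes, spikes_file, ["unit_id", "time_ms", "site_id"]),
        (trials, trials_file, ["whisker", "onset_ms"]),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")

    bin_ms = float(meta["bin_ms"])
    unit_ids = np.asarray(meta["unit_ids"], dtype=np.int64)
    site_ids = np.asarray(meta["site_ids"], dtype=np.int64)
    unit_row = {int(u): k for k, u in enumerate(unit_ids)}

    unknown = ~spikes["unit_id"].isin(unit_row)
    if unknown.any():
        lines = (spikes.index[unknown] + 2).tolist()[:10]  # 1-based incl. header
        raise ValueError(
            f"{spikes_file}: unknown unit_id values {sorted(spikes['unit_id'][unknown].unique())} "
            f"(lines {lines}{'...' if unknown.sum() > 10 else ''})"
        )

    n_bins = int(round(meta["duration_ms"] / bin_ms))
    bins = np.floor(spikes["time_ms"].to_numpy() / bin_ms).astype(np.int64)
    out_of_range = (bins < 0) | (bins >= n_bins)
    if out_of_range.any():
        lines = (spikes.index[out_of_range] + 2).tolist()[:10]
        raise ValueError(f"{spikes_file}: spike times outside recording (lines {lines})")
    raster = np.zeros((len(unit_ids), n_bins), dtype=np.uint8)
    rows = spikes["unit_id"].map(unit_row).to_numpy()
    raster[rows, bins] = 1

    onset_bins = np.floor(trials["onset_ms"].to_numpy() / bin_ms).astype(np.int64)
    baseline_bins = int(round(meta["baseline_window_ms"] / bin_ms))
    ok = onset_bins >= baseline_bins
    if not ok.all():
        log.warning(
            "%d trial(s) excluded: onset precedes a full baseline window (lines %s)",
            int((~ok).sum()),
            (trials.index[~ok] + 2).tolist(),
        )
    return TrialEnsemble(
        raster=raster,
        trial_onsets=onset_bins[ok],
        whisker_of_trial=trials["whisker"][ok].tolist(),
        unit_ids=unit_ids,
        site_ids=site_ids,
        trial_window=int(round(meta["trial_window_ms"] / bin_ms)),
        baseline_window=baseline_bins,
        bin_ms=bin_ms,
    )


def write_ground_truth(network: GroundTruthNetwork, csv_path: str | Path,
                       graphml_path: str | Path | None = None):
    """Write planted connectivity as edges.csv and optionally GraphML."""
    df = pd.DataFrame(
        [
            {"pre": e.pre, "post": e.post, "delay_bins": e.delay, "weight": e.weight, "sign": e.sign}
            for e in network.edges
        ],
        columns=["pre", "post", "delay_bins", "weight", "sign"],
    )
    df.to_csv(csv_path, index=False)
    if graphml_path is not None:
        g = nx.DiGraph()
        for i in range(network.n_neurons):
            g.add_node(i, barrel=network.barrel_assignment[i])
        for e in network.edges:
            g.add_edge(e.pre, e.post, delay=e.delay, weight=e.weight, sign=e.sign)
        nx.write_graphml(g, graphml_path)
    return csv_path


def read_ground_truth(csv_path: str | Path, barrel_assignment: dict[int, str],
                      n_neurons: int, background_rate: float = 3.0) -> GroundTruthNetwork:
    df = pd.read_csv(csv_path)
    edges = [
        Edge(pre=int(r.pre), post=int(r.post), delay=int(r.delay_bins),
             weight=float(r.weight), sign=int(r.sign))
        for r in df.itertuples()
    ]
    return GroundTruthNetwork(
        n_neurons=n_neurons, edges=edges,
        barrel_assignment=barrel_assignment, background_rate=background_rate,
    )


def write_lagged_network(network: LaggedNetwork, csv_path: str | Path,
                         graphml_path: str | Path | None = None):
    """Write an inferred structure as edge-list CSV and optionally GraphML."""
    df = pd.DataFrame(
        sorted((e.pre, e.post, e.lag) for e in network.edges),
        columns=["pre", "post", "lag"],
    )
    df.to_csv(csv_path, index=False)
    if graphml_path is not None:
        g = nx.DiGraph()
        g.add_nodes_from(range(network.n_neurons))
        for e in network.edges:
            g.add_edge(e.pre, e.post, lag=e.lag)
        nx.write_graphml(g, graphml_path)
    return csv_path


def read_lagged_network(csv_path: str | Path, n_neurons: int, max_lag: int = 5,
                        max_parents: int = 10) -> LaggedNetwork:
    df = pd.read_csv(csv_path)
    edges = frozenset(
        LaggedEdge(pre=int(r.pre), post=int(r.post), lag=int(r.lag)) for r in df.itertuples()
    )
    return LaggedNetwork(n_neurons=n_neurons, edges=edges, max_lag=max_lag, max_parents=max_parents)


def write_search_trace(trace: list[dict], path: str | Path):
    """Write an annealing trace (iteration, temperature, score, accepted) as JSONL."""
    import json

    with Path(path).open("w") as fh:
        for rec in trace:
            fh.write(json.dumps(rec) + "\n")
    return path
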