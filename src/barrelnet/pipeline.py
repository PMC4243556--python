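"""Config-driven orchestration of the full experiment emulation.

One experiment = several simulated subjects, each recorded in three sessions
(control and two post-pairing sessions) under the same whisker-deflection
protocol.  Per subject and session the pipeline simulates spiking, assembles
per-whisker datasets, infers one DBN structure per dataset, collapses lags to
adjacency matrices, and finally builds one feature space shared by all
subjects and sessions to quantify network similarity, convergence and connection-probability
geometry, plus the classical single-neuron response similarities.  All
randomness flows from one seed; a config hash is written with every output.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .dbn import AnnealConfig, anneal_search, collapse_lags
from .netspace import (
    AdjacencyMatrix,
    ElectrodeGeometry,
    SimilarityReport,
    build_feature_space,
    compare_sessions,
    connection_probability_by_separation,
    presynaptic_convergence,
    similarity_report,
)
from .response import assemble_datasets, neuron_similarity, response_summary
from .synth import (
    GroundTruthNetwork,
    PairingEffect,
    StimulusProtocol,
    apply_pairing,
    generate_network,
    simulate_session,
)

log = logging.getLogger(__name__)

load_recording = bio.load_recording  # recordings and synthetic output are interchangeable


@dataclass
class ExperimentConfig:
    """All parameters of one experiment emulation (YAML round-trippable)."""

    # population / ground truth
    n_neurons: int = 23
    connectivity_ratio: float = 0.10
    inhibitory_fraction: float = 0.2
    coupling_weight: float = 0.08
    background_rate_hz: float = 3.0
    # stimulus protocol
    whiskers: tuple[str, ...] = ("D4", "D5", "D6")
    trials_per_whisker: int = 900
    trial_window_ms: int = 100
    baseline_window_ms: int = 100
    inter_trial_interval_ms: int = 900
    peak_gain: float | dict[str, float] = 0.1
    gain_latency_ms: float = 5.0
    gain_decay_ms: float = 20.0
    # pairing manipulation (session label -> strength / convergence modifier)
    paired_whiskers: tuple[str, str] = ("D4", "D5")
    pairing_mode: str = "correlate_inputs"
    session_strengths: dict[str, float] = field(
        default_factory=lambda: {"control": 0.0, "post_1_2d": 0.45, "post_6_7d": 1.0}
    )
    session_convergence: dict[str, float] = field(
        default_factory=lambda: {"control": 0.0, "post_1_2d": 0.15, "post_6_7d": -0.25}
    )
    cross_weight: float = 0.4
    cross_add_fraction: float = 0.25
    # analysis
    n_subjects: int = 4
    #: subjects share one planted circuit and differ in recording noise,
    #: sampling and search seeds; set False for a fresh circuit per subject
    shared_ground_truth: bool = True
    n_datasets: int = 100
    trials_per_dataset: int = 180
    max_lag: int = 5
    max_parents: int = 10
    ess: float = 0.25
    n_components: int = 2
    anneal_iterations: int = 200_000
    anneal_restarts: int = 3
    anneal_t0: float = 1.0
    anneal_cooling: float = 0.9995
    # bookkeeping
    seed: int = 1
    outdir: str = "results"

    @property
    def sessions(self) -> list[str]:
        return list(self.session_strengths)

    def protocol(self) -> StimulusProtocol:
        return StimulusProtocol(
            whiskers=tuple(self.whiskers),
            trials_per_whisker=self.trials_per_whisker,
            trial_window=self.trial_window_ms,
            baseline_window=self.baseline_window_ms,
            inter_trial_interval=self.inter_trial_interval_ms,
            peak_gain=self.peak_gain,
            gain_latency=self.gain_latency_ms,
            gain_decay=self.gain_decay_ms,
        )

    def anneal(self) -> AnnealConfig:
        return AnnealConfig(
            max_parents=self.max_parents,
            lags=(1, self.max_lag),
            initial_temperature=self.anneal_t0,
            cooling=self.anneal_cooling,
            iterations=self.anneal_iterations,
            restarts=self.anneal_restarts,
            ess=self.ess,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["whiskers"] = list(d["whiskers"])
        d["paired_whiskers"] = list(d["paired_whiskers"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in ("whiskers", "paired_whiskers"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def reduced(cls, seed: int = 1, **overrides) -> "ExperimentConfig":
        """Desk-scale experiment: same structure, smaller sizes.

        15 neurons, 300 trials/whisker, 20 datasets of 150 concatenated
        trials (15 s), a 4k-proposal annealing budget — sized so a full
        3-session, 4-subject run completes in minutes on one CPU while
        keeping every stage of the full-scale analysis.
        """
        base = dict(
            n_neurons=15,
            inhibitory_fraction=0.0,
            peak_gain={"D4": 0.13, "D5": 0.08, "D6": 0.10},
            trials_per_whisker=300,
            n_datasets=20,
            trials_per_dataset=150,
            anneal_iterations=4000,
            anneal_restarts=2,
            anneal_cooling=0.998,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def null_control(cls, seed: int = 1, **overrides) -> "ExperimentConfig":
        """Tiny two-session configuration with zero pairing everywhere.

        Used to check the false-positive rate of the session comparison: both
        sessions are fresh simulations of the *same* ground truth.
        """
        base = dict(
            n_neurons=8,
            inhibitory_fraction=0.0,
            peak_gain={"D4": 0.13, "D5": 0.08, "D6": 0.10},
            n_subjects=4,
            trials_per_whisker=100,
            n_datasets=6,
            trials_per_dataset=30,
            anneal_iterations=1500,
            anneal_restarts=2,
            anneal_cooling=0.997,
            session_strengths={"control": 0.0, "post_6_7d": 0.0},
            session_convergence={"control": 0.0, "post_6_7d": 0.0},
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class ResultBundle:
    """In-memory results of one experiment run (also written as CSVs)."""

    config: ExperimentConfig
    adjacencies: list[AdjacencyMatrix]
    similarity: SimilarityReport
    similarity_samples: dict[str, np.ndarray]  # session -> per-dataset samples
    convergence_by_session: pd.DataFrame
    convergence_per_network: pd.DataFrame
    session_comparisons: pd.DataFrame
    response_similarity: pd.DataFrame
    connection_probability: pd.DataFrame
    projections: pd.DataFrame
    ground_truth: dict[tuple[int, str], GroundTruthNetwork]


def _subject_seeds(config: ExperimentConfig, subject: int) -> dict[str, int]:
    ss = np.random.SeedSequence([config.seed, subject])
    names = ["network", "pairing"] + [f"sim:{s}" for s in config.sessions]
    state = ss.generate_state(len(names) + 4 * len(config.sessions) * len(config.whiskers))
    seeds = {name: int(state[k] % (2**31)) for k, name in enumerate(names)}
    k = len(names)
    for s in config.sessions:
        for w in config.whiskers:
            seeds[f"assemble:{s}:{w}"] = int(state[k] % (2**31)); k += 1
            seeds[f"search:{s}:{w}"] = int(state[k] % (2**31)); k += 1
    return seeds


def run_experiment(config: ExperimentConfig, outdir: str | Path | None = None) -> ResultBundle:
    """Run the full emulation and write the result bundle to ``outdir``.

    Stages per subject: ground truth -> pairing per session -> simulated
    session -> per-whisker datasets -> per-dataset DBN search -> adjacency
    collapse; then one feature space per subject over every session and
    whisker jointly, similarity/convergence/geometry statistics pooled across
    subjects, and two-sample t-tests between sessions.  Idempotent given the
    config (bit-identical CSV outputs on rerun).
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log = outdir / "run_log.jsonl"
    run_log.write_text("")
    t_start = time.time()

    def stage(name: str):
        log.info("stage %s", name)
        with run_log.open("a") as fh:
            fh.write(json.dumps({"stage": name, "t": round(time.time() - t_start, 3)}) + "\n")

    cfg_hash = config.config_hash()
    config.to_yaml(outdir / "config.yaml")
    (outdir / "config_hash.txt").write_text(cfg_hash + "\n")
    protocol = config.protocol()
    anneal_cfg = config.anneal()
    paired = tuple(config.paired_whiskers)

    adjacencies: list[AdjacencyMatrix] = []
    ground_truth: dict[tuple[int, str], GroundTruthNetwork] = {}
    response_rows: list[pd.DataFrame] = []
    inferred_edges_rows: list[dict] = []
    unit_sites = None
    current_stage = "setup"
    try:
        for subject in range(config.n_subjects):
            seeds = _subject_seeds(config, subject)
            if config.shared_ground_truth:
                shared = _subject_seeds(config, 0)
                seeds["network"], seeds["pairing"] = shared["network"], shared["pairing"]
            current_stage = f"subject{subject}:ground_truth"
            stage(current_stage)
            base_net = generate_network(
                config.n_neurons,
                config.connectivity_ratio,
                (1, config.max_lag),
                config.inhibitory_fraction,
                seed=seeds["network"],
                barrels=tuple(config.whiskers),
                weight=config.coupling_weight,
                background_rate=config.background_rate_hz,
                max_parents=config.max_parents,
            )
            for session in config.sessions:
                current_stage = f"subject{subject}:{session}"
                stage(current_stage)
                effect = PairingEffect(
                    paired_barrels=paired,
                    strength=config.session_strengths[session],
                    mode=config.pairing_mode,
                    convergence_modifier=config.session_convergence.get(session, 0.0),
                    cross_weight=config.cross_weight,
                    cross_add_fraction=config.cross_add_fraction,
                )
                net = apply_pairing(base_net, effect, seed=seeds["pairing"])
                ground_truth[(subject, session)] = net
                ensemble = simulate_session(net, protocol, seed=seeds[f"sim:{session}"])
                if unit_sites is None:
                    unit_sites = ensemble.site_ids
                rs = response_summary(ensemble, list(paired))
                rs["session"], rs["subject"] = session, subject
                response_rows.append(rs)
                for whisker in config.whiskers:
                    datasets = assemble_datasets(
                        ensemble,
                        whisker,
                        config.n_datasets,
                        config.trials_per_dataset,
                        seed=seeds[f"assemble:{session}:{whisker}"],
                    )
                    search_seed = seeds[f"search:{session}:{whisker}"]
                    for ds in datasets:
                        scored = anneal_search(ds, anneal_cfg, seed=search_seed + ds.index)
                        col = collapse_lags(scored.network)
                        adjacencies.append(
                            AdjacencyMatrix(
                                matrix=col.matrix,
                                whisker=whisker,
                                dataset_index=ds.index,
                                session=session,
                                subject=subject,
                            )
                        )
                        for e in sorted((e.pre, e.post, e.lag) for e in scored.network.edges):
                            inferred_edges_rows.append(
                                {
                                    "subject": subject,
                                    "session": session,
                                    "whisker": whisker,
                                    "dataset": ds.index,
                                    "pre": e[0],
                                    "post": e[1],
                                    "lag": e[2],
                                }
                            )

        current_stage = "feature_space"
        stage(current_stage)
        # one common feature space over all subjects, sessions and whiskers:
        # axes fitted per subject are unstable at desk scale, and distances in
        # a shared space are directly comparable across subjects and sessions
        space = build_feature_space(adjacencies, p=config.n_components)
        rep_subj = similarity_report(space, by=("subject", "session"))
        similarity_all = rep_subj.table
        # pair-level report pooled over subjects
        pooled = (
            similarity_all.groupby(["session", "w1", "w2"], sort=False)
            .agg(mean_distance=("mean_distance", "mean"),
                 normalized_distance=("normalized_distance", "mean"),
                 similarity=("similarity", "mean"),
                 similarity_sd=("similarity", "std"))
            .reset_index()
        )
        sim_samples = {
            s: np.concatenate(
                [rep_subj.samples[(subj, s) + paired]
                 for subj in range(config.n_subjects)
                 if (subj, s) + paired in rep_subj.samples]
            )
            for s in config.sessions
        }
        rep_pooled = SimilarityReport(
            table=pooled,
            samples={(s,) + paired: v for s, v in sim_samples.items()},
            norm_const=rep_subj.norm_const,
        )
        proj_frames = [space.labels.copy()]
        for k in range(config.n_components):
            proj_frames[0][f"q{k + 1}"] = space.projections[:, k]

        current_stage = "statistics"
        stage(current_stage)
        conv = presynaptic_convergence(adjacencies, normalize=True)
        comparisons = []
        sess = config.sessions
        # session comparisons use one value per subject (per-dataset values
        # within a session share that session's realised cluster geometry and
        # would make the t-test anticonservative)
        paired_rows = similarity_all[(similarity_all["w1"] == paired[0])
                                     & (similarity_all["w2"] == paired[1])]
        sim_by_subject = {
            s: paired_rows.loc[paired_rows["session"] == s, "similarity"].to_numpy()
            for s in sess
        }
        conv_subj = (
            conv.per_network.groupby(["session", "subject"], sort=False)["value"]
            .mean()
            .reset_index()
        )
        conv_by_subject = {
            s: conv_subj.loc[conv_subj["session"] == s, "value"].to_numpy() for s in sess
        }
        for metric, by_session in (
            ("network_similarity", sim_by_subject),
            ("convergence", conv_by_subject),
        ):
            for ia, sa in enumerate(sess):
                for sb in sess[ia + 1 :]:
                    if len(by_session.get(sa, ())) < 2 or len(by_session.get(sb, ())) < 2:
                        log.warning("skipping %s %s-vs-%s: need >= 2 subjects", metric, sa, sb)
                        continue
                    r = compare_sessions(by_session[sa], by_session[sb])
                    comparisons.append(
                        {"metric": metric, "session_a": sa, "session_b": sb,
                         "t": r.t, "p": r.p, "flagged": r.flagged}
                    )
        response_all = pd.concat(response_rows, ignore_index=True)
        resp_sim_rows = []
        resp_samples: dict[tuple[str, str], np.ndarray] = {}
        for session in sess:
            for metric, col in (("evoked_count", "evoked_count_mean"), ("latency", "latency_mean_ms")):
                vals = []
                for subject in range(config.n_subjects):
                    sub = response_all[(response_all["session"] == session)
                                       & (response_all["subject"] == subject)]
                    v1 = sub[sub["whisker"] == paired[0]].sort_values("neuron")[col].to_numpy()
                    v2 = sub[sub["whisker"] == paired[1]].sort_values("neuron")[col].to_numpy()
                    tab2 = neuron_similarity(v1, v2, metric=metric)
                    vals.append(tab2.similarity)
                pooled_vals = np.concatenate(vals)
                resp_samples[(session, metric)] = pooled_vals
                resp_sim_rows.append(
                    {"session": session, "metric": metric,
                     "similarity_mean": float(np.nanmean(pooled_vals)),
                     "similarity_sd": float(np.nanstd(pooled_vals, ddof=1)),
                     "n_neurons": int(np.isfinite(pooled_vals).sum())}
                )
        for metric in ("evoked_count", "latency"):
            for ia, sa in enumerate(sess):
                for sb in sess[ia + 1 :]:
                    a = resp_samples[(sa, metric)]
                    b = resp_samples[(sb, metric)]
                    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
                    if len(a) >= 2 and len(b) >= 2:
                        r = compare_sessions(a, b)
                        comparisons.append(
                            {"metric": f"response_{metric}", "session_a": sa, "session_b": sb,
                             "t": r.t, "p": r.p, "flagged": r.flagged}
                        )
        comparisons_df = pd.DataFrame(comparisons)
        geom_df = connection_probability_by_separation(
            [a for a in adjacencies if a.session == sess[0]], unit_sites, ElectrodeGeometry()
        )
        projections_df = pd.concat(proj_frames, ignore_index=True)

        current_stage = "write_outputs"
        stage(current_stage)
        float_fmt = "%.10g"
        pooled.assign(config_hash=cfg_hash).to_csv(
            outdir / "similarity_report.csv", index=False, float_format=float_fmt)
        similarity_all.assign(config_hash=cfg_hash).to_csv(
            outdir / "similarity_by_subject.csv", index=False, float_format=float_fmt)
        conv.by_session.assign(config_hash=cfg_hash).to_csv(
            outdir / "convergence.csv", index=False, float_format=float_fmt)
        conv.per_network.assign(config_hash=cfg_hash).to_csv(
            outdir / "convergence_per_network.csv", index=False, float_format=float_fmt)
        comparisons_df.assign(config_hash=cfg_hash).to_csv(
            outdir / "session_comparisons.csv", index=False, float_format=float_fmt)
        pd.DataFrame(resp_sim_rows).assign(config_hash=cfg_hash).to_csv(
            outdir / "response_similarity.csv", index=False, float_format=float_fmt)
        response_all.assign(config_hash=cfg_hash).to_csv(
            outdir / "response_summary.csv", index=False, float_format=float_fmt)
        geom_df.assign(config_hash=cfg_hash).to_csv(
            outdir / "connection_probability.csv", index=False, float_format=float_fmt)
        projections_df.assign(config_hash=cfg_hash).to_csv(
            outdir / "projections.csv", index=False, float_format=float_fmt)
        pd.DataFrame(inferred_edges_rows).to_csv(outdir / "inferred_edges.csv", index=False)
        for (subject, session), net in ground_truth.items():
            bio.write_ground_truth(net, outdir / f"ground_truth_s{subject}_{session}.csv")
        stage("done")
    except Exception:
        stage(f"FAILED:{current_stage}")
        log.exception("experiment aborted during stage %r; partial outputs kept in %s",
                      current_stage, outdir)
        raise

    return ResultBundle(
        config=config,
        adjacencies=adjacencies,
        similarity=rep_pooled,
        similarity_samples=sim_samples,
        convergence_by_session=conv.by_session,
        convergence_per_network=conv.per_network,
        session_comparisons=comparisons_df,
        response_similarity=pd.DataFrame(resp_sim_rows),
        connection_probability=geom_df,
        projections=projections_df,
        ground_truth=ground_truth,
    )
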