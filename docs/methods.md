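# Methods

This note documents the models, numerical choices and limitations of
`barrelnet`.  It is written for a reader who wants to know exactly what the
package computes, which knobs matter, and what passing tests do and do not
demonstrate about real recordings.

## Spiking simulator (`synth`)

Neurons are binary per 1-ms bin.  The conditional intensity is a clipped
linear link:

    p_i(t) = clip( r_bg·Δ + g_b(t) + Σ_e w_e · s_e · r_pre(e)(t − d_e), 0, 1 )

with background rate r_bg (spikes/s), per-barrel stimulus gain g_b(t)
(probability/bin), and signed, delayed couplings (d_e ∈ 1..5 bins).  This is
the simplest link consistent with an inhomogeneous-Poisson description at
1-ms resolution; bins whose pre-clip probability exceeds 1 are clipped and
counted (a warning reports the count).  There is no refractoriness by
default (pure Bernoulli per bin); a 1-bin refractory flag exists.

The stimulus gain is latency-then-exponential-decay: zero before
`gain_latency` (default 5 ms), then `peak_gain · exp(−(t−latency)/decay)`
(defaults 0.1/bin and 20 ms), integrating to ~2 evoked spikes per 100-ms
deflection — a realistic layer-V evoked response.  Trials are delivered in
one block per whisker at 1 Hz (100-ms deflection, 900-ms inter-trial
interval), 900 trials/whisker by default, with a full 100-ms baseline before
every onset.

Ground-truth networks have exactly `round(ratio · n(n−1))` directed edges
(default ratio 0.10, matching the ~10% connectivity of the tissue), delays
uniform in 1..5 bins, and a configurable inhibitory fraction applied
per-neuron (all outgoing edges of an inhibitory neuron carry sign −1).
Connectivity is predominantly local, as in cortex: the edge budget is split
between within- and cross-barrel strata in proportion `locality` (default 5)
to 1 per ordered pair, balanced across barrels and placed uniformly within
each stratum, preserving the exact edge count.  Without this, small circuits
often draw a barrel with almost no internal edges, which has no
condition-specific network signature.
Neurons split evenly across barrels in index order; units map to electrode
sites in index order on an 8-shank × 4-site array.

**Coupling regime.**  The default coupling weight (0.08 probability/bin) and
background rate (3 spikes/s) are deliberately *weak*: a BDe score gain of a
lagged edge is roughly (presynaptic spike count) × (per-spike information),
so at these values an edge is reliably detected only when its presynaptic
neuron is stimulus-driven, and near the detection threshold when it fires at
background rate alone.  This is the regime the analysis is designed for —
inferred networks are sparse (convergence ≈ 0.1 of possible parents) and
*condition-specific*, so the networks inferred during different whiskers'
stimulation form distinct clusters in the feature space.  With much stronger
couplings every edge is detected in every condition and whisker-specific
clusters collapse onto each other.

## Pairing emulation

`apply_pairing` modifies a ground-truth network with strength s ∈ [0, 1];
s = 0 reproduces the network edge-for-edge.  Three mechanisms are
implemented:

- `add_cross_edges`: a seed-shuffled list of missing cross-barrel ordered
  pairs is drawn once; strength s adds the first `round(s · N)` of them as
  excitatory edges.  The prefix construction makes the added edge set nested
  across strengths for a fixed seed.
- `strengthen_cross_edges` (default): existing cross-barrel weights scale by
  (1 + s) and a `s · cross_add_fraction` prefix of the candidate list is
  added with weight `cross_weight`.
- `correlate_inputs`: no structural change; the paired barrels' receptive
  fields mix.  Each barrel responds at fraction s/2 of its own gain to the
  *other* paired whisker and at 1 − s/2 to its own, so the total evoked
  drive per barrel is conserved and at s = 1 the two whiskers deliver
  statistically identical stimulus conditions.  This is a phenomenological
  stand-in for cortically transmitted co-activation balanced by homeostatic
  synaptic scaling; conservation matters because extra drive would inflate
  the spurious-edge rate and hence the feature-space dispersion floor at
  late sessions.

In the structural modes the added cross edges are strong (`cross_weight`
0.4 by default, versus 0.08 for background couplings): they appear directly
in the inferred networks and also transmit stimulus-evoked activity between
the paired barrels.  A signed `convergence_modifier` independently adds
(positive) or removes (negative) a fraction of the original edge count,
emulating the early-rise/late-fall of pre-synaptic convergence; the
pipeline defaults are +0.15 for the early session and −0.25 for the late
one.

The pipeline's default pairing mode is `correlate_inputs` with session
strengths (0, 0.45, 1.0) and convergence modifiers (0, +0.15, −0.25) for the
control / early / late sessions.  The main calibration fact behind the mode
choice: structural cross-edge strengthening alone does not yield a monotone
similarity increase at desk scale — a cross edge is only reliably detected
when its presynaptic barrel is stimulus-driven, so whisker-A networks gain
A→B entries while whisker-B networks gain B→A entries (different matrix
positions) and the paired clusters move apart as often as together.
Receptive-field mixing instead interpolates the two stimulus conditions
themselves and is monotone by construction.

The synthetic experiment emulates what it is designed to emulate: planted
*directions* of change (similarity up with pairing duration, convergence up
then down), not the magnitudes printed for the in-vivo recordings, which
depend on biological parameters no simulator of this simplicity constrains.

## Dataset assembly and response metrics (`response`)

Datasets concatenate the 100-ms post-onset windows of trials sampled
uniformly **without replacement within a dataset** and independently across
datasets (180 of the 900 trials → 18 s by default).  Windows are half-open
`[onset, onset+100)` with a 0-based, inclusive onset bin; these conventions
are fixed so tests can be bit-exact.

Evoked count = spikes in the trial window minus spikes in the 100-ms
baseline; negative values are retained (it is a difference, not a rectified
rate).  First-spike latency is the first spike bin after onset (onset bin
counts as 0 ms); trials without a spike are excluded from the mean rather
than imputed, and the number excluded is reported.  Cross-whisker similarity
of either metric is 1 − |difference|/max|difference| across neurons; if
every difference is zero all similarities are 1.

## DBN scoring and search (`dbn`)

Counts for a family (child + lagged parent set) run over all t whose lagged
parents lie inside the dataset (family-specific effective length).  Lags may
cross trial-concatenation seams by default — the assembled 18-s datasets are
plain concatenations, and the few seam-crossing bins are part of that
construction; a `mask_seams` flag excludes the first `max_lag` bins after
each seam to quantify the artifact.

The prior is BDeu with a uniform prior structure: Z′_ijk = a/(2·2^{|π|})
with equivalent sample size a.  The scoring functions default to the
textbook a = 1; the experiment pipeline uses a = 0.25.  The choice matters
because BDeu's complexity penalty weakens as a grows: on pure-noise rasters
of this size, annealing under a = 1 admits roughly 14 spurious edges per
12-neuron network, versus 1–2 at a = 0.25 (and ~44 at a = 4).  At a = 1 the
inferred networks are mostly noise, which both inflates pre-synaptic
convergence far above the ~0.1 scale expected of sparse cortical circuits
and buries the condition-specific cluster structure that the similarity
statistic measures.  Scores use log-Gamma arithmetic throughout; a family
with zero counts scores exactly 0.

Simulated annealing proposes uniformly among legal add/delete/reverse moves
(uniform draws over the move superset, rejecting illegal ones — this is
exactly uniform over the legal subset), accepts with min(1, exp(Δ/T)),
and cools geometrically.  At most one lag per ordered pair is kept during
search; adds and reversals that would exceed the 10-parent cap are illegal,
so the cap holds at every intermediate structure.  The search starts from an
empty structure by default (a random-init flag exists); the best-ever
structure across restarts is returned, which makes the result insensitive to
the start on the tested instances.  The iteration budget (default 2×10⁵
proposals split over 3 restarts) replaces any wall-clock stopping rule for
hardware-independent reproducibility.  Family scores are memoised per
dataset, so revisited parent sets cost a dictionary lookup.

`exhaustive_search` enumerates parent sets per child independently — valid
because all edges cross time slices, so any parent assignment is acyclic —
and is restricted to n ≤ 4.

## Feature space and statistics (`netspace`)

Adjacency matrices are vectorised in fixed row-major order with the diagonal
excluded (self-edges are not part of between-neuron connectivity), stacked,
mean-centred and projected by PCA (p = 2).  PCA is fitted jointly on all
sessions, whiskers and subjects being compared — one common space — because
distances computed in separately fitted spaces are not comparable, and with
only two retained components separately fitted axes are themselves a large
noise source (at desk scale, per-subject axes changed pair distances by a
factor of two between recordings of the same circuit).  If the stacked
networks are all identical the space is degenerate: projections are zero and
flagged.

The average pair distance applies the 2/M² prefactor literally (a
`strict_mean` flag gives the plain mean 1/M²); since similarity normalises
by the maximum average distance over the compared pairs, the prefactor
cancels there.  Per-dataset similarity samples (one per dataset on each side
of a pair) are defined so their mean equals the pair similarity; they are
the inputs to the two-sample t-tests.  The t-test uses pooled variance by
default (Welch optional); two constant equal samples return p = 1 by
convention, flagged.

**Statistical unit for session comparisons.**  Per-dataset similarity values
within a session all share that session's realised cluster geometry (one
set of cluster centroids), so treating them as independent samples in a
two-sample t-test inflates the effective sample size by more than an order
of magnitude — on null replicates with pairing disabled such a test rejected
at ~45% instead of 5%.  The pipeline therefore feeds one value per *subject*
(independent recordings) and session to the t-test; per-dataset samples are
still computed and reported for descriptive statistics.
For the same reason, simulated subjects share one planted circuit by default
(`shared_ground_truth`), differing in recording noise, trial sampling and
search seeds: with a fresh random circuit per subject, circuit-to-circuit
variation in cluster geometry dominates the similarity baseline and four
subjects cannot resolve the planted effect; the shared-circuit design is a
repeated-measures benchmark of the *pipeline's* sensitivity, not a claim
about generalisation across circuits (set the flag off for that).

Pre-synaptic convergence is the mean inferred in-degree per neuron, by
default divided by n−1 (fraction of possible parents — the scale of the
printed values); both normalised and raw values are available.  Connection
probability by electrode separation bins unordered unit pairs by
(horizontal, vertical) distance on the 8×4 array (200/100 µm pitches) and
averages either-direction connectivity over networks.

## Desk-scale configurations

Full-scale defaults (23 neurons, 900 trials/whisker, M = 100 datasets of
18 s, 2×10⁵ proposals) are hours of compute.  Two scaled-down
configurations are packaged as the study conditions for validation:

- `ExperimentConfig.reduced()` — 15 neurons, 3 whiskers, 300 trials/whisker,
  M = 20 datasets of 150 trials (15 s), 4 subjects, 4000 proposals / 2
  restarts: a full three-session pairing experiment in minutes.
- `ExperimentConfig.null_control()` — 8 neurons, two sessions with pairing
  strength 0 everywhere, M = 6 of 30 trials, 4 subjects: a cheap replicate
  for estimating the session comparison's false-positive rate.

Both desk-scale configurations use excitation-only planted circuits
(inhibitory fraction 0): inhibitory edges are undetectable at these rates
(see limitations), so at 13-edge scale they contribute nothing but
circuit-to-circuit variance.  The full-scale defaults keep a 20% inhibitory
fraction.  Desk-scale stimulus gains are heterogeneous across whiskers
(peaks 0.13 / 0.08 / 0.10 probability/bin), emulating the response-strength
differences between principal whiskers that real recordings show.

Problem sizes were chosen so the complete validation (unit tests, recovery
benchmark, pairing experiment, 20 null replicates) runs on one CPU in well
under an hour.

## Known limitations

- Inhibitory couplings onto low-rate neurons are nearly undetectable in
  principle: suppressing a 3–5 Hz baseline removes almost no information per
  presynaptic spike.  The structure-recovery benchmark therefore uses an
  excitation-only planted network; sensitivity claims do not extend to
  inhibitory edges at low rates.
- The simulator is Bernoulli with a linear clipped link: no conductances, no
  refractoriness by default, no spike waveforms or sorting noise.  Passing
  recovery tests shows the inference works when the generative model matches
  its assumptions, not that it is robust to sorting errors or bursting.
- The session comparison tests subjects (n = 4 by default), so its power is
  limited; the null-control replicates quantify its type-I rate empirically
  rather than assuming it.
- Network similarity is normalised within the compared set, so it
  is a relative measure: values depend on which whisker pairs and sessions
  are pooled (the package always pools all sessions of a subject).
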