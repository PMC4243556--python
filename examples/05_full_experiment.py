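"""Full plasticity experiment emulation at desk scale.

Three sessions (control and two post-pairing), several simulated subjects:
the pairing manipulation strengthens cross-barrel connectivity between the
paired whiskers' populations with session-dependent strength.  The pipeline
reports (i) network similarity of the paired whiskers per session — expected
to rise with pairing duration, (ii) pre-synaptic convergence — expected to
peak early, and (iii) single-neuron response similarities, with two-sample
t-tests between sessions.  Takes a few minutes.
"""
from barrelnet.pipeline import ExperimentConfig, run_experiment

config = ExperimentConfig.reduced(seed=1, n_subjects=2)
bundle = run_experiment(config, "scratch/example_experiment")

print("== network similarity per session (paired whiskers D4-D5)")
tab = bundle.similarity.table
print(tab[(tab.w1 == "D4") & (tab.w2 == "D5")].to_string(index=False))

print("\n== pre-synaptic convergence per session (fraction of possible parents)")
print(bundle.convergence_by_session.to_string(index=False))

print("\n== session comparisons (two-sample t-tests)")
print(bundle.session_comparisons.to_string(index=False))
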