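"""Network feature space: whisker-specific clusters and their similarity.

Infers several networks per whisker, projects their adjacency matrices onto
two principal components and reports the average pairwise distance and the
normalised similarity per whisker pair.  Whiskers whose network clusters
overlap score close to 1; the most dissimilar pair scores 0.
"""
import barrelnet as bn

net = bn.generate_network(n_neurons=8, connectivity_ratio=0.10, seed=3)
ensemble = bn.simulate_session(net, bn.StimulusProtocol(trials_per_whisker=150), seed=4)

cfg = bn.AnnealConfig(iterations=4000, restarts=2, cooling=0.998)
adjacencies = []
for whisker in ("D4", "D5", "D6"):
    for ds in bn.assemble_datasets(ensemble, whisker, n_datasets=6,
                                   trials_per_dataset=60, seed=7):
        scored = bn.anneal_search(ds, cfg, seed=100 + ds.index)
        adjacencies.append(bn.AdjacencyMatrix(
            matrix=bn.collapse_lags(scored.network).matrix,
            whisker=whisker, dataset_index=ds.index, session="control"))

space = bn.build_feature_space(adjacencies, p=2)
print("explained variance of the 2 principal axes:",
      [f"{v:.2f}" for v in space.explained_variance_ratio])

report = bn.similarity_report(space)
print(report.table.to_string(index=False))
print("(similarity = 1 - mean distance / max mean distance over pairs)")
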