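"""Clustering-agreement metrics between a reference and a predicted labeling.

Clusters the inferred cell-topic mixtures with k-means and scores them
against the simulator's true dominant-topic labels with every metric the
package provides.
"""

from sklearn.cluster import KMeans

import topicimpute as ti

sim = ti.simulate(ti.SimulationConfig(seed=0))
counts = ti.filter_qc(sim.observed_counts)
norm = ti.normalize(counts)
state, posterior = ti.train(norm, ti.TopicModelConfig(n_topics=3, epochs=300, seed=0))

predicted = KMeans(3, n_init=10, random_state=0).fit_predict(posterior.theta)
scores = ti.all_partition_metrics(sim.labels, predicted)
for name, value in scores.items():
    print(f"{name}: {value:.4f}")
# ARI and AMI are chance-corrected (0 for random labelings, 1 for a perfect
# match up to renaming); RI/NMI/FMS are their uncorrected counterparts, and
# MI is in nats.
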