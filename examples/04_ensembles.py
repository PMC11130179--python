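"""Cellular-resolution ensemble analysis on a planted population.

Simulates 40 neurons of which three groups of 10 form co-activation clusters,
deconvolves the AR(1) calcium traces, builds the Pearson correlation network,
detects overlapping clusters by cohesiveness optimization, and compares the
weighted clustering coefficient of ensemble members against background
neurons.
"""

import numpy as np

from glioscope import ensembles as en
from glioscope import synth

spec = synth.PopulationSpec(
    n_neurons=40, n_clusters=3, cluster_sizes=[10, 10, 10],
    within_cluster_coactivation_prob=0.9, background_rate=0.1,
    ar_decay=0.9, transient_amplitude=1.0, noise_sd=0.1,
    frame_rate_hz=10.0, duration_s=200.0, seed=8)
dff, spikes, memberships, positions = synth.generate_population(spec)
print(f"planted clusters: {[sorted(m) for m in memberships]}")

ddff = en.deconvolve_matrix(dff, gamma=0.9, noise_sd=0.1)
graph = en.correlation_graph(ddff)
clusters = en.detect_clusters(graph)
print(f"\ndetected clusters ({len(clusters)}):")
for c in clusters:
    print(" ", sorted(c))
for planted in memberships:
    p = frozenset(planted)
    j = max((len(p & c) / len(p | c) for c in clusters), default=0.0)
    print(f"best Jaccard vs planted {sorted(p)[:3]}...: {j:.2f}")

table = en.neuron_metrics_table(ddff, frame_rate=10.0, graph=graph)
members = sorted(set().union(*memberships))
background = sorted(set(range(40)) - set(members))
cc = table["clustering_coefficient"]
print(f"\nmean clustering coefficient: ensemble members {cc[members].mean():.3f}"
      f" vs background {cc[background].mean():.3f}")
print(f"mean event rate (events/s): {table['events_per_sec'].mean():.3f}")
print("\nHigher CC for planted members reflects the triangle structure that"
      "\nco-activation imprints on the functional network.")
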