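"""Invulnerability analysis: natural connectivity under random node removal.

Natural connectivity, ln((1/N) sum exp(lambda_i)) over adjacency eigenvalues,
log-counts closed walks of every length and so measures the redundancy of
alternative paths.  Removing 0..200 nodes at random from the
specialized-function (nitrogen-cycle) network and watching the decline gives
the functional-redundancy verdict: a straight decline means no redundancy; a
gentle-then-steep decline would mean redundancy in the early stage.
"""

from redunet import (AbundanceTable, SyntheticDesign, build_network,
                     classify_trend, correlation_matrix, generate,
                     natural_connectivity, prevalence_filter,
                     removal_experiment, rmt_threshold)

table, catalog, metadata, _ = generate(SyntheticDesign(seed=4, replicates=8))

spec_genes = catalog.frame.index[catalog.frame["func_class"] == "specialized"]
spec = prevalence_filter(AbundanceTable(table.data[list(spec_genes)].copy(),
                                        "gene", table.unit))
corr = correlation_matrix(spec)
net = build_network(corr, rmt_threshold(corr))
print(f"specialized-function network: {net.n_nodes} nodes, {net.n_links} links")
print(f"intact natural connectivity: {natural_connectivity(net):.3f}")

traj = removal_experiment(net, m_max=200, replicates=25, seed=4)
trend, fit = classify_trend(traj)
print(f"\nafter removing 100 nodes: {traj.mean[100]:.3f}   "
      f"after 200: {traj.mean[200]:.3f}")
print(f"trend verdict: {trend}   (linear slope {fit['slope_linear']:.4f} "
      f"per removed node)")
print("A 'linear' verdict reads as NO functional redundancy: alternative "
      "paths vanish in proportion to the nodes lost, with no early buffer.")
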