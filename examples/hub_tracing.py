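"""Trace high-degree hubs down a nested Louvain hierarchy to motifs.

Generates a planted network whose ground truth is known (three hubs
forming a triangle buried under nested community shells), decomposes it,
and prints each hub's trace: the community it occupies at every level,
its P_KR share of that community's edges, and the key-regulator call.
"""

from hubtrace import decompose, key_regulators, pkr_profile, planted_hub_hierarchy

net, truth = planted_hub_hierarchy(rng_seed=0)
print(f"network: {net.n_nodes} nodes, {net.n_edges} edges; "
      f"planted hubs: {sorted(truth.planted_hub_ids)}")

tree = decompose(net, hub_threshold=truth.hub_degree_floor, rng_seed=0)
print(f"hub degree floor {truth.hub_degree_floor}; "
      f"decomposition depth {tree.max_level} levels")

for gene, trace in sorted(tree.traces.items()):
    steps = " -> ".join(
        f"L{lvl}:{len(tree.community(cid).members)}n"
        for cid, (lvl, _) in zip(trace.path, trace.x_by_level))
    print(f"  {gene} (degree {trace.degree_in_root}): {steps}"
          f"{'  [motif]' if trace.is_motif_localized else ''}")
    pkr = ", ".join(f"L{s}={p:.3f}" for s, p in pkr_profile(tree, gene))
    print(f"     P_KR: {pkr}")

print(f"key regulators: {sorted(key_regulators(tree))}")
print("-> P_KR rises toward 2/3 at the terminal triangle: the hub's grip "
      "on its community tightens with depth.")
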