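"""Inducing the disease subgraph on a merged protein-interaction network.

Edge lists from two interaction databases are merged into one simple
undirected graph; the disease feature set is then restricted to its induced
subgraph, and the connectivity filter removes features with no interaction to
another feature. Interaction evidence acts as an orthogonal filter on the
statistically derived gene list.
"""

from mibcnet import interactome as net

# -- two source edge lists (symbol_a, symbol_b, source_db); note the
#    duplicate FGFR3-TP53 edge across databases and the EGFR self-loop
db1 = [("EGFR", "TP53", "intact"), ("FGFR3", "TP53", "intact"),
       ("EGFR", "EGFR", "intact"), ("CCND1", "CDK4", "intact")]
db2 = [("TP53", "FGFR3", "biogrid"), ("ERBB2", "GRB2", "biogrid")]

g = net.merge_networks([db1, db2])
print(f"merged network: {g.number_of_nodes()} proteins, "
      f"{g.number_of_edges()} interactions (duplicates and self-loops removed)")
print(f"FGFR3-TP53 edge provenance: {sorted(g.edges['FGFR3', 'TP53']['sources'])}")

# -- disease feature set: CCND1 has its only partner OUTSIDE the feature set,
#    EGFR has only its self-interaction, MYCN is absent from the network
features = {"EGFR", "TP53", "FGFR3", "CCND1", "MYCN"}
sub = net.induce_subgraph(g, features)
print(f"\ninduced subgraph: {len(sub.members)}/{len(features)} features present "
      f"in the network (absent: {', '.join(sorted(sub.dropped_absent))})")

filtered = net.drop_isolated(sub)
print(f"connectivity filter: {len(filtered.retained)} features keep >=1 "
      f"interaction to another feature "
      f"(dropped isolated: {', '.join(sorted(filtered.dropped_isolated))})")
print("\nmembership table:")
print(filtered.membership_frame().to_string(index=False))
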