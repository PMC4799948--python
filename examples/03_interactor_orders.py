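"""Classify interactor order from a query gene in a filtered PPI graph.

Builds the small motif around RACGAP1 seen in gastric-cancer network
analyses — AURKA as a direct partner, the Wnt targets CTNNB1 and CDKN1A
two steps away via CCNB1 and PLK1 — and reports shortest-path orders.
"""

import networkx as nx

from activemod.ppi import filter_by_confidence, interaction_order

g = nx.Graph()
for u, v, conf in [
    ("AURKA", "RACGAP1", 0.95),
    ("RACGAP1", "CCNB1", 0.92),
    ("CCNB1", "CTNNB1", 0.90),
    ("RACGAP1", "PLK1", 0.97),
    ("PLK1", "CDKN1A", 0.88),
    ("RACGAP1", "NOISE", 0.40),  # low-confidence edge, removed below
]:
    g.add_edge(u, v, confidence=conf)

g = filter_by_confidence(g, 0.850)
report = interaction_order(g, "RACGAP1", ["AURKA", "CTNNB1", "CDKN1A"])
for target, order in sorted(report.orders.items()):
    path = " -> ".join(report.paths[target])
    print(f"{target}: order {order}   witness path: {path}")
# Order 1 = direct interactor; order 2 = second-order, reached through one
# intermediate partner (the witness path names it).
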