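"""Hypergeometric enrichment of a module and weighted-Jaccard module overlap.

Builds a toy gene-set collection, tests a module for enrichment (upper-tail
hypergeometric, Benjamini-Hochberg adjusted across sets), and compares two
weighted modules with the weighted Jaccard similarity.
"""

from nblatent import GeneSetCollection, hypergeom_enrich, weighted_jaccard

universe = {f"g{i}" for i in range(500)}
collection = GeneSetCollection(
    sets={
        "cell_cycle": {f"g{i}" for i in range(0, 40)},
        "immune_response": {f"g{i}" for i in range(200, 260)},
        "ribosome": {f"g{i}" for i in range(400, 430)},
    },
    universe=universe,
)

# a module overlapping the cell-cycle set heavily and the others not at all
module = {f"g{i}" for i in range(10, 35)} | {f"g{i}" for i in range(450, 455)}
table = hypergeom_enrich(module, collection)
print(table.to_string(index=False))
print("(p is the upper-tail hypergeometric probability of the overlap;")
print(" p_adj the BH-adjusted value; significant flags p_adj < 0.05)\n")

module_a = {"g1": 2.0, "g2": 1.0, "g3": 0.5}
module_b = {"g2": 1.0, "g3": 1.5, "g4": 2.0}
sim = weighted_jaccard(module_a, module_b)
print(f"weighted Jaccard(module_a, module_b) = {sim:.3f}")
print("(1 = identical weighted gene sets, 0 = disjoint supports)")
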