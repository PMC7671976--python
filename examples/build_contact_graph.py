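"""Build a residue contact graph and compare variant similarities.

The contact graph is the structural backbone of every kernel in this
package: nodes are residues (represented by their C-beta atom, C-alpha
for glycine), and edges connect residues within a distance threshold.
This example uses a generated toy structure; `read_structure(path, chain)`
produces the same coordinate triples from a real PDB file.
"""

import deraml as d

# a compact self-avoiding chain standing in for a real aldolase structure
graph = d.generate_toy_structure(n_residues=120, seed=0)
print(f"structure: {len(graph)} residues, {len(graph.edges)} contacts "
      f"within {graph.threshold:.1f} A")
print(f"mean contact degree: {2 * len(graph.edges) / len(graph):.1f}")

# residues near a hypothetical active site (the catalytic shell)
centers = [graph.positions[40], graph.positions[80]]
shell = d.active_site_shell(graph, centers, radius=10.0)
print(f"{len(shell)} residues within 10 A of the two active-site centers")

# variant similarity under one substitution model: a conservative
# substitution scores higher than a drastic one at the same position
models = d.load_substitution_models()
exchange = next(m for m in models if m.name == "exchangeability")
pos = graph.positions[40]
wt = graph.amino_acid_at(pos)
conservative = "I" if wt != "I" else "L"
drastic = "P" if wt != "P" else "G"
for mut in (conservative, drastic):
    v = d.Variant.parse(f"{wt}{pos}{mut}")
    k = d.variant_kernel(d.WILD_TYPE, v, graph, exchange)
    print(f"k(WT, {v}) = {k:.4f} under the exchangeability kernel")
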