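"""Call cell-type-specific genes with the median/MAD + 1.5 x IQR rule.

Generates a small synthetic expression compendium with known planted
(gene, cell type) specificities, normalizes each gene by its cross-cell
median and MAD, and calls a gene specific where |e| >= 1.5 x IQR of its
normalized profile.
"""

from multimorbinet import (
    call_specific_genes,
    generate_expression,
    generate_interactome,
    normalize_expression,
)

net = generate_interactome(n_genes=300, mean_degree=6, seed=1)
cells = [f"cell_{i + 1}" for i in range(8)]
expr, truth = generate_expression(net, cells, seed=1)

norm = normalize_expression(expr)
calls = call_specific_genes(norm, k=1.5)

planted = {(g, c) for c, gs in truth.items() for g in gs}
called = {(g, c) for c, gs in calls.by_cell.items() for g in gs}
sens = len(planted & called) / len(planted)
fp = len(called - planted) / (len(expr.genes) * len(cells) - len(planted))

print(f"genes: {len(expr.genes)}, cell types: {len(cells)}")
print(f"specificity calls: {len(called)} (planted: {len(planted)})")
print(f"sensitivity: {sens:.3f}  false-positive rate: {fp:.3f}")
print("-> nearly all planted cell-type-specific genes are recovered; the")
print("   planted columns inflate each gene's own IQR threshold, so noise-")
print("   driven false calls are rare.")
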