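"""Quantify cell-type-resolved multimorbidity between disease pairs.

For one cell network: propagate each disease's seed genes (score =
geometrically decaying proximity, horizon repetitions x iterations),
z-standardize, take the top-scoring set S (z >= 1), and compute the
Multimorbidity Score MS = 2|S1 n S2| / (|S1| + |S2|) with a degree-matched
permutation p-value.
"""

from itertools import combinations

from multimorbinet import (
    ScenarioConfig,
    call_specific_genes,
    generate_scenario,
    induce_cell_network,
    ms_permutation_test,
    multimorbidity_score,
    normalize_expression,
    propagate,
    select_top_scoring,
    standardize_scores,
)

scenario = generate_scenario(ScenarioConfig(), seed=3)
calls = call_specific_genes(normalize_expression(scenario.expression))

for cell in scenario.cell_types[:3]:
    cn = induce_cell_network(scenario.network, calls.genes_for(cell), cell)
    if cn.n_nodes < 5:
        print(f"{cell}: network too small, skipped")
        continue
    tops = {}
    for d in scenario.diseases.diseases:
        seeds = scenario.diseases.genes_by_disease[d] & cn.nodes
        gsv = standardize_scores(propagate(cn, seeds, disease=d))
        tops[d] = select_top_scoring(gsv)
    print(f"{cell} ({cn.n_nodes} genes):")
    for a, b in combinations(scenario.diseases.diseases, 2):
        ms = multimorbidity_score([tops[a], tops[b]])
        seeds_by = {d: scenario.diseases.genes_by_disease[d] & cn.nodes for d in (a, b)}
        res = ms_permutation_test(cn, seeds_by, ms, n_perm=200, rng=7)
        print(f"  MS({a}, {b}) = {ms:.3f}  (|S|={len(tops[a])}/{len(tops[b])},"
              f" permutation p = {res.p_value:.4f})")
print()
print("-> in the multimorbid cell types (cell_1, cell_2) the diseases' top-")
print("   scoring sets overlap strongly (MS 0.5-0.7); elsewhere the modules")
print("   are not co-expressed and MS collapses to 0. The permutation p asks")
print("   a harder question - whether the overlap beats random degree-matched")
print("   seeds in the *same* module-bearing network - so it is small only")
print("   when the overlap is extreme for that network.")
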