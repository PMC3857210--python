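"""Full pipeline on user-supplied study data (expression + STRING links).

This driver reruns the original analysis design on real inputs, which are
not bundled (the expression series and the interaction-network release must
be downloaded by the user):

  python analysis/05_reproduce_study.py EXPR.tsv GROUPS.tsv LINKS.tsv [OUT_DIR]

EXPR.tsv    gene-level (or probe-level, pre-collapsed) linear intensities,
            genes x samples, TSV with header
GROUPS.tsv  sample_id<TAB>group with group A = non-responders,
            B = responders
LINKS.tsv   STRING-style links table with experimental / database /
            textmining channel scores

Steps: quantile normalization, group-wise means, 0.85 channel filter,
link scores, condensation to the 16 most up- and 16 most down-regulated
interactions, interaction- and gene-level Welch/BH tests, indicator matrix,
and K=8 extraction with an L sweep including the minimal L for a 5-gene
subnetwork.
"""

import json
import sys
from pathlib import Path

from netcondense import (
    build_indicator_matrix,
    components,
    compute_link_scores,
    group_means,
    map_expression_to_network,
    min_L_for_size,
    quantile_normalize,
    read_expression,
    read_groups,
    read_string_edges,
    select_top_links,
    solve_ines_greedy,
    standardize_samples,
    test_gene_de,
    test_interaction_shifts,
)
from netcondense.network import InteractionNetwork

if len(sys.argv) < 4:
    sys.exit(__doc__)
expr_path, groups_path, links_path = sys.argv[1:4]
out = Path(sys.argv[4]) if len(sys.argv) > 4 else Path("results/study")
out.mkdir(parents=True, exist_ok=True)

matrix = quantile_normalize(read_expression(expr_path))
labels = read_groups(groups_path)
net = read_string_edges(links_path, threshold=0.85)
gm = group_means(matrix, labels)
annotated = map_expression_to_network(net, gm)
print(f"expression mapped to {len(annotated.nodes)} network genes")

scores = compute_link_scores(annotated)
condensed = select_top_links(scores, k_up=16, k_down=16, node_means=gm)
scores.to_csv(out / "link_scores.tsv", sep="\t", index=False)
edge_tests = test_interaction_shifts(matrix, labels, condensed.edges)
gene_tests, frac = test_gene_de(matrix, labels, condensed.genes)
edge_tests.to_csv(out / "edge_tests.tsv", sep="\t")
gene_tests.to_csv(out / "gene_tests.tsv", sep="\t")
print(f"condensed subnetwork: {condensed.n_genes} genes, "
      f"{int(edge_tests['significant'].sum())}/{len(edge_tests)} interactions "
      f"significant, {frac:.0%} of genes significantly DE")

ind = build_indicator_matrix(standardize_samples(matrix, log2=True), labels)
mapped = InteractionNetwork(
    net.graph.subgraph(set(net.graph.nodes) & set(ind.gene_ids)).copy()
)
sweep = {}
for L in (10, 20, 30, 34, 38):
    sols = solve_ines_greedy(mapped, ind, K=8, L=L, seed=17)
    sweep[L] = sols[0].size if sols else 0
    print(f"  K=8, L={L}: "
          + ("empty network" if not sols else f"{sols[0].size} genes"))
min_l5 = min_L_for_size(mapped, ind, K=8, target_size=5, solver="greedy", seed=17)
print(f"minimal L for a 5-gene subnetwork: {min_l5}")

(out / "summary.json").write_text(json.dumps({
    "mapped_genes": len(annotated.nodes),
    "condensed_genes": condensed.n_genes,
    "component_sizes": [len(c) for c in components(condensed)],
    "significant_interactions": int(edge_tests["significant"].sum()),
    "fraction_genes_de": frac,
    "kpm_best_size_by_L": sweep,
    "min_L_for_5_genes": min_l5,
}, indent=2))
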