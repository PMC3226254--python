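"""GO semantic similarity gene networks and hypergeometric enrichment.

A toy ontology and gene annotations are generated; gene-pair similarity
uses Schlicker's Rel measure (best-match average over MF and BP), pairs
above a threshold form gene networks, and the network genes are tested
for GO term over-representation against the annotated background.
"""

from cnvnet import (enrich, gene_network, gene_sim_matrix,
                    simulate_annotation, term_ic)

ann = simulate_annotation([f"rs{i:03d}" for i in range(60)], seed=5)
genes = sorted(ann.corpus.annotations)
print(f"toy corpus: {len(genes)} genes, "
      f"{sum(len(t) for t in ann.corpus.annotations.values())} direct "
      f"annotations over {len(ann.dag.terms)} terms")

tic = term_ic(ann.dag, ann.corpus)
sims = gene_sim_matrix(genes, ann.dag, tic, ann.corpus)
vals = sorted(sims.values())
print(f"pairwise similarities: {len(sims)} pairs, "
      f"range {vals[0]:.3f} - {vals[-1]:.3f}, median {vals[len(vals)//2]:.3f}")

threshold = 0.5
net = gene_network(sims, threshold)
print(f"\ngene networks at similarity > {threshold}: {net.n_networks} "
      f"networks, {net.n_pairs} pairs, {len(net.genes)} genes")

if net.genes:
    results = enrich(list(net.genes), genes, ann.dag, ann.corpus,
                     p_threshold=0.05)
    print(f"GO terms enriched in the network genes at P < 0.05: "
          f"{len(results)}")
    for r in results[:5]:
        print(f"  {r.term} [{r.namespace}] {r.format_counts()} "
              f"genes={','.join(r.annotated_query_genes)}")
    print("counts read q/m|t/k(p): q of k query genes vs m of t background "
          "genes carry the term (directly or via a descendant).")
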