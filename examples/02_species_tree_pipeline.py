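"""The full divide-and-conquer pipeline on simulated coalescent data.

Simulates a 10-taxon Yule species tree (root height 20 N generations),
draws 1000 gene trees under the multispecies coalescent, then runs:
AGID distance matrix -> NJ starting tree -> centroid decomposition ->
NJ subset trees -> NJMerge.  Prints the RF error against the true species
tree (0.0 means exact recovery) and the serialized runtime breakdown
t_P = t_D + sum_i t_T(i) + t_M.
"""

from njmerge import (
    MSCModel,
    PipelineConfig,
    PipelineInputs,
    aggregate_runtime,
    msc_gene_trees,
    rf_error,
    run_pipeline,
    write_newick,
    yule_species_tree,
)

species_tree = yule_species_tree(10, height_gens=4_000_000, seed=11)
model = MSCModel(species_tree, pop_size=200_000)
gene_trees = msc_gene_trees(model, count=1000, seed=12)

config = PipelineConfig(distance="agid", max_subset_size=5)
estimate, ledger, result = run_pipeline(
    config, PipelineInputs(gene_trees=gene_trees))

print("true tree :", write_newick(species_tree.unrooted_copy(),
                                  with_lengths=False))
print("estimate  :", write_newick(estimate, with_lengths=False))
print("RF error  :", rf_error(species_tree.unrooted_copy(), estimate))
print(f"subsets   : {ledger.n_subsets}")
print(f"t_D={ledger.t_distance:.3f}s  "
      f"sum t_T={sum(ledger.t_subtrees):.3f}s  "
      f"t_M={ledger.t_merge:.3f}s  "
      f"serial total={aggregate_runtime(ledger):.3f}s")
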