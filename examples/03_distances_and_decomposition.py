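"""Distance matrices and centroid decomposition.

Shows the two distance estimators — AGID from gene-tree topologies and
paralinear (log-det) from a Jukes-Cantor alignment — and the centroid-edge
decomposition used to cut a starting tree into disjoint subsets.
"""

from njmerge import (
    agid_matrix,
    centroid_decompose,
    jc_sequences,
    logdet_matrix,
    nj_tree,
    parse_newick,
    random_binary_tree,
)

# AGID: mean number of internal nodes on the path between two taxa
genes = [parse_newick("((A,B),(C,D));"), parse_newick("((A,C),(B,D));")]
D = agid_matrix(genes)
print("AGID d(A,B) over the two quartets:", D.get("A", "B"))  # (1 + 2) / 2

# log-det: consistent estimate of substitutions/site under Jukes-Cantor
pair = parse_newick("(X:0.15,Y:0.15);")  # true distance 0.3
aln = jc_sequences(pair, length=100_000, seed=5)
print("log-det estimate of a 0.3-substitutions/site pair:",
      round(logdet_matrix(aln).get("X", "Y"), 4))

# centroid decomposition: disjoint subsets, each at most max_size taxa
tree = random_binary_tree(100, seed=8)
dec = centroid_decompose(tree, max_size=30)
print("100 taxa, bound 30 ->", len(dec), "subsets of sizes",
      sorted(len(s) for s in dec.subsets))
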