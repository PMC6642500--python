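"""Constrained neighbor joining on a worked 8-taxon example.

Builds an additive distance matrix for the reference tree
(((A,B),(C,D)),E,(F,(G,H))) and merges two constraint trees under it.
With no constraints NJMerge is exactly NJ and returns the reference tree;
with a constraint in which G and H are non-siblings, the greedy (G, H)
join is rejected and G pairs with F instead — yet the output still agrees
with every constraint tree (it is a compatibility supertree).
"""

from njmerge import (
    additive_matrix,
    is_compatibility_supertree,
    njmerge,
    parse_newick,
    write_newick,
)

truth = parse_newick("(((A:1,B:1):1,(C:1,D:1):1):1,E:1,(F:1,(G:1,H:1):1):1);")
D = additive_matrix(truth)

unconstrained = njmerge([], D)
print("no constraints :", write_newick(unconstrained.tree, with_lengths=False))

constraint = parse_newick("((F,G),(E,H));")  # G and H are NOT siblings here
result = njmerge([constraint], D)
print("with constraint:", write_newick(result.tree, with_lengths=False))
print("join log       :", [(x, y) for x, y, _ in result.join_log])
print("is compatibility supertree:",
      is_compatibility_supertree(result.tree, [constraint]))

# The caterpillar on A..H agrees with both quartets AC|EG and BD|FH even
# though neither forms a clade in it.
caterpillar = parse_newick("(A,(B,(C,(D,(E,(F,(G,H)))))));")
forest = [parse_newick("((A,C),(E,G));"), parse_newick("((B,D),(F,H));")]
print("caterpillar is a supertree of {AC|EG, BD|FH}:",
      is_compatibility_supertree(caterpillar, forest))
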