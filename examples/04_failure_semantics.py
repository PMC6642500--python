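"""When the pairwise-compatibility heuristic fails — and when it cannot.

The merge screens each proposal only against *pairs* of constraint trees,
and pairwise compatibility does not imply joint compatibility, so an early
greedy join can strand the merge: no remaining pair is acceptable and the
algorithm raises NJMergeFailure instead of emitting a wrong tree.

`adversarial_forest` searches random instances (conflicting constraint
trees over a noise matrix) and returns one certified to fail.  Replacing
the constraints with restrictions of a single tree — here the NJ tree of
the same matrix — removes the conflict and the merge succeeds.
"""

from njmerge import (
    adversarial_forest,
    is_compatibility_supertree,
    nj_tree,
    njmerge,
    restrict,
    write_newick,
)
from njmerge.errors import NJMergeFailure

forest, D = adversarial_forest(seed=1)
print("constraint trees:")
for t in forest:
    print("  ", write_newick(t, with_lengths=False))

try:
    njmerge(forest, D)
    print("unexpected success")
except NJMergeFailure as exc:
    print(f"merge failed after {len(exc.join_log)} accepted joins: {exc}")

guide = nj_tree(D)
agreeing = [restrict(guide, t.leaf_labels()) for t in forest]
result = njmerge(agreeing, D)
print("agreeing constraints (from one supertree) succeed:",
      is_compatibility_supertree(result.tree, agreeing))
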