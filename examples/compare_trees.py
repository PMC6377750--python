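"""Tree comparison toolbox: edit distance, Robinson-Foulds, SPR.

Demonstrates the three metrics on small hand-built trees: the tree edit
distance (minimal-cost node deletions/insertions/renames, computed on
canonically ordered trees), the Robinson-Foulds clade distance, and the
exact rooted SPR distance via maximum agreement forests.
"""

import taxograsp as tg
from taxograsp.phylo import PhyloTree

a = PhyloTree((("large diameter", "medium wrap"),
               ("tip pinch", "prismatic pinch")))
b = PhyloTree(((("large diameter", "tip pinch"), "medium wrap"),
               "prismatic pinch"))

print("tree a:", a.newick())
print("tree b:", b.newick())

ted = tg.tree_edit_distance(a, b)
rf = tg.robinson_foulds(a, b)
maf = tg.spr_distance(a, b)
print(f"tree edit distance (unit costs): {ted}")
print(f"Robinson-Foulds distance:        {rf}")
print(f"rooted SPR distance:             {maf.k}")
print("agreement forest components:     ",
      [sorted(c) for c in maf.components])

result = tg.build_supertree([a, a, b])
print("supertree of {a, a, b}:", result.tree.newick(),
      f"(total SPR distance {result.total_spr})")

# The SPR distance counts prune-and-regraft moves between the trees; its
# agreement forest shows which grasp groups the two trees agree on.  The
# supertree sides with the majority topology here.
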