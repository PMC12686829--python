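"""How many true somatic mutations does pseudo-bulk filtering remove?

Germline filtering against two random colonies also removes the early
embryonic mutations the colony of interest shares with them.  The loss is
estimated by resampling tip triples from reference phylogenies with
mutation-count branch lengths.
"""

from hsctrace import estimate_filtered_fetal_mutations
from hsctrace.fetal import shared_variants_for_triple
from hsctrace.trees import Tree

# A small worked tree: t1 and t2 share the 5-mutation edge above their
# common ancestor; t3 attaches at the root.
tree = Tree.from_newick("((t1:3,t2:4)A:5,t3:10)root:0;")
print("triple (interest=t1, pseudo-bulk={t2,t3}):",
      shared_variants_for_triple(tree, "t1", ("t2", "t3")), "shared mutations")

# Two reference trees with embryonic structure; the estimate is the mean of
# the per-tree medians over resampled triples.
trees = [
    Tree.from_newick("(((a:120,b:130)x:6,(c:115,d:125)y:4)z:3,e:140)root:1;"),
    Tree.from_newick("((a:110,b:110)x:8,(c:120,(d:100,e:105)y:5)z:2)root:0;"),
]
estimate, medians = estimate_filtered_fetal_mutations(
    trees, n_iter=1000, seed=7, round_result=True
)
print("per-tree median shared mutations:", medians)
print("filtered fetal mutation estimate:", estimate)
# This count is added back to the root branch before time scaling and to
# each colony's burden before normalization.
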