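"""Minimum-change reconstruction of intron evolution.

Per-species intron presence/absence characters (a position is present when
any gene copy of the species carries it) are reconstructed on the species
tree, giving the minimum number of gains+losses and the optimal ancestral
gene structure.
"""

import pandas as pd

from gfd import fitch_parsimony, read_newick

tree = read_newick("(((v1:1,v2:1):1,(v3:1,v4:1):1):2,(o1:1,o2:1):2);")
# one ancestral early intron (after residue 10) kept by most lineages, a
# late intron (after residue 100) gained within the v-clade, and one lineage
# (v2) that lost everything
chars = pd.DataFrame(
    {
        "intron_after_aa10": [1, 0, 1, 1, 1, 1],
        "intron_after_aa100": [1, 0, 1, 0, 0, 0],
    },
    index=["v1", "v2", "v3", "v4", "o1", "o2"],
)
rec = fitch_parsimony(tree, chars)
print(chars)
print("minimum total changes:", rec.min_changes)
print("optimal root states per character:", [sorted(s) for s in rec.root_states])
# Root state {1} for the early intron and {0} for the late one reads as an
# ancestral two-exon gene with a single intron near the start, followed by a
# lineage-restricted gain and independent losses.
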