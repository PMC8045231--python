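"""From a Newick tree to the Brownian-motion covariance used by the models.

Parses a small rooted ultrametric tree, prints the raw shared-path covariance
(diagonals are root-to-tip depths) and its normalized unit-diagonal form, and
shows that pruning preserves the shared-path structure.
"""

from phylofa import prune_to, tree_from_string, vcv

tree = tree_from_string("(((A:1,B:1):1,C:2):1,D:3);")

raw = vcv(tree)
norm = vcv(tree, normalize=True)
print("raw shared-path covariance:")
print(raw.to_dataframe().round(3).to_string())
print("\nnormalized (correlation) form:")
print(norm.to_dataframe().round(3).to_string())

pruned = vcv(prune_to(tree, ["A", "C", "D"]))
print("\nafter pruning to {A, C, D} (a submatrix of the full covariance):")
print(pruned.to_dataframe().round(3).to_string())
print("\nEntry (i, j) is the depth of the species pair's last common "
      "ancestor — the expected trait covariance under Brownian motion.")
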