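"""From a bare topology to residual covariance matrices.

Shows the node-height branch-length convention (internal node height =
descendant tip count - 1) applied to a topology without lengths, and how
the OU parameter d interpolates the implied residual covariance between a
star phylogeny (identity, d -> 0) and the Brownian tree matrix (d = 1).
"""

import numpy as np

from phyloancova import (
    assign_pagel_branch_lengths,
    bm_covariance,
    ou_covariance,
    parse_newick,
    write_newick,
)

topology = parse_newick("((A,B),(C,(D,E)));")
tree = assign_pagel_branch_lengths(topology)
print("input topology:", write_newick(topology))
print("with node-height lengths:", write_newick(tree))
print(f"root height = n_tips - 1 = {tree.height:.0f}; ultrametric: {tree.is_ultrametric()}")

unit = tree.rescaled_to_unit_height()
np.set_printoptions(precision=3, suppress=True)
print("\nBrownian covariance (entry = shared root-to-tip path, height-1 tree):")
print(bm_covariance(unit).matrix)
for d in (0.1, 0.5, 1.0):
    print(f"\nOU covariance at d = {d} (d->0 is a star/OLS, d=1 is Brownian):")
    print(ou_covariance(unit, d).matrix)
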