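"""Convert an expression profile into a sparse co-expression network.

Uses the synthetic generator's profile (module genes share a latent factor)
and shows that positive top-k Pearson sparsification concentrates edges
inside the planted modules: the within-module mean edge weight should be
clearly above the between-module mean.
"""

import numpy as np
import scipy.sparse as sp

from funcnet import FixtureSpec, generate_fixture, profile_to_network

fixture = generate_fixture(FixtureSpec(seed=3))
net = profile_to_network(fixture.profile, fixture.universe, k=10)

print(f"genes: {len(fixture.universe)}, samples: {len(fixture.profile.sample_names)}")
print(f"co-expression edges kept (top-10 union): {net.nnz_pairs}")

upper = sp.triu(net.adjacency, 1).tocoo()
same = fixture.module_of[upper.row] >= 0
same &= fixture.module_of[upper.row] == fixture.module_of[upper.col]
print(f"within-module edges: {int(same.sum())}, mean weight {upper.data[same].mean():.3f}")
print(f"between/background edges: {int((~same).sum())}, mean weight {upper.data[~same].mean():.3f}")
print("(edge weight = Pearson r; the module factor drives the within-module excess)")
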