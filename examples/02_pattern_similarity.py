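"""Pattern-similarity constructs from simulated voxel patterns.

Generates four PVT sessions of voxel patterns for one participant, builds
the pre/post similarity matrices, the change matrix, and the per-object
cross-day reorganization table, and embeds the pre-encoding matrix with MDS.
"""

import numpy as np

from psmem import GeneratorParams, generate_design, generate_patterns
from psmem.rsa import mds_embed, ps_change, reorganization, within_day_matrix

design = generate_design(seed=2)
pats = generate_patterns(design, GeneratorParams(seed=2))
s = pats.sessions

pre = within_day_matrix(s["pre1"], s["pre2"], day="pre")
post = within_day_matrix(s["post1"], s["post2"], day="post")
change = ps_change(pre, post)
print("pair rows per matrix:", len(pre.pair_values()))  # 276 = C(24, 2)

cats = np.array([o.category for o in design.objects])
iu = np.triu_indices(24, 1)
same = (cats[:, None] == cats[None, :])[iu]
z = pre.values[iu]
print(f"pre-encoding Fisher-z similarity: same-category {z[same].mean():.3f}, "
      f"different-category {z[~same].mean():.3f}")
# same-category objects share a pattern component, so their similarity is higher.

table = reorganization((s["pre1"], s["pre2"]), (s["post1"], s["post2"]), design)
print("cross-day self-similarity (reorganization z):")
print(table.groupby("congruent")["reorg_z"].mean())
# incongruent objects retain less of their pre-encoding pattern: lower z
# means greater representational reorganization after encoding.

coords = mds_embed(pre)
print("MDS embedding shape:", coords.shape, "- centered:", coords.mean(0).round(12))
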