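"""Protein similarity profiles by random walk with restart.

Builds a toy two-module PPI network, seeds a walk on each drug's target
proteins, and shows how diffusion scores concentrate around the seeds and
how the resulting profiles separate drugs that act on different modules.
"""

import numpy as np

from ddifuse import (
    DrugProteinMap,
    ProteinNetwork,
    build_psp,
    drug_diffusion_profiles,
)
from ddifuse.network import diffusion_similarity

# two dense 4-protein modules joined by one weak bridge
edges = []
for base in (0, 4):
    for i in range(4):
        for j in range(i + 1, 4):
            edges.append((f"P{base+i}", f"P{base+j}", 900.0))
edges.append(("P3", "P4", 700.0))
network = ProteinNetwork([f"P{i}" for i in range(8)], edges)

drug_map = DrugProteinMap({
    "drugA": {"P0", "P1"},     # module 1
    "drugB": {"P2"},           # module 1
    "drugC": {"P5", "P6"},     # module 2
})
profiles = drug_diffusion_profiles(drug_map, network, restart=0.5)

for p in profiles:
    top = np.argsort(p.scores)[::-1][:3]
    peaks = ", ".join(f"{network.protein_ids[i]}={p.scores[i]:.3f}" for i in top)
    print(f"{p.drug_id}: converged in {p.iterations} iterations; top scores {peaks}")

S = diffusion_similarity(profiles)
print("\ncosine similarity of diffusion profiles:")
for i, d in enumerate(drug_map.mapping):
    print("  " + d + "  " + "  ".join(f"{v:.3f}" for v in S[i]))
print("Drugs seeded in the same module score near 1; across modules the "
      "weak bridge keeps similarity low. PCA of this matrix is the PSP feature:")
print(build_psp(profiles, k=2).components.round(3))
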