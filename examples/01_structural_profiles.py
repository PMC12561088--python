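"""Structural similarity profiles from SMILES.

Fingerprints a few familiar drugs, prints their pairwise Tanimoto
similarities, and reduces the profile matrix with PCA. High values mean the
two molecules share many circular substructures (the NSAIDs pair up;
caffeine stands apart).
"""

from ddifuse import build_ssp, fingerprint_from_smiles, reduce_pca

DRUGS = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "naproxen": "COc1ccc2cc(ccc2c1)C(C)C(=O)O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
}

fingerprints = [
    fingerprint_from_smiles(smiles, radius=2, n_bits=2048, drug_id=name)
    for name, smiles in DRUGS.items()
]
ssp = build_ssp(fingerprints)

print("pairwise Tanimoto similarity (ECFP4, 2048 bits):")
header = "          " + "".join(f"{d:>11}" for d in ssp.drug_ids)
print(header)
for i, d in enumerate(ssp.drug_ids):
    row = "".join(f"{v:11.3f}" for v in ssp.values[i])
    print(f"{d:>10}{row}")

reduced = reduce_pca(ssp, k=2)
print(f"\nPCA to k=2: retained variance {reduced.cumulative_variance:.3f} "
      f"(low-variance flag: {reduced.low_variance})")
print("Each drug's row of the Tanimoto matrix is its structural profile; "
      "PCA compresses those profiles into the model's SSP feature.")
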