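"""Synthetic multimodal DDI datasets with planted cluster structure.

The generator emulates the statistical shape of the real inputs without any
downloads: drugs fall into latent clusters; each cluster draws SMILES from
a distinct scaffold template family (so within-cluster Tanimoto exceeds
between-cluster), owns a dense module of the PPI graph (so diffusion
profiles separate clusters), and stamps a cluster keyword into templated
descriptions (consumed by the mock embedding provider). Ordered pair labels
are a fixed injective map from cluster pairs to class ids, with a
``label_noise`` fraction flipped uniformly. Everything is deterministic
given the seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pairs import DDIPair

# Scaffold template families: hard-coded valid SMILES cores with enumerated
# decorations, guaranteeing parseability and within-family substructure overlap.
_SCAFFOLDS = [
    "c1ccccc1",          # benzenes
    "CCCCCC",            # aliphatic chains
    "c1ccc2ccccc2c1",    # fused aromatics (naphthalenes)
    "C1CCNCC1",          # piperidines
    "c1ccsc1",           # thiophenes
    "C1CCCCC1",          # cyclohexanes
]
_DECORATIONS = [
    "C", "CC", "CCC", "O", "OC", "N", "NC", "Cl", "F", "Br",
    "OCC", "NCC", "C(=O)O", "C(=O)N", "N#C", "S", "SC", "OCCO",
    "FC(F)(F)", "CCN",
]


def scaffold_family(family_idx: int, n: int) -> list[str]:
    """Enumerate ``n`` distinct SMILES of one scaffold family.

    Variants are decoration + linker-chain + scaffold; decorations and
    linker lengths cycle deterministically.
    """
    scaffold = _SCAFFOLDS[family_idx % len(_SCAFFOLDS)]
    out = [scaffold]
    k = 0
    for linker in range(4):
        for dec in _DECORATIONS:
            if len(out) >= n:
                return out[:n]
            out.append(dec + "C" * linker + scaffold)
            k += 1
    if len(out) < n:
        raise ValueError(f"cannot enumerate {n} variants of family {family_idx}")
    return out[:n]


@dataclass
class SyntheticConfig:
    n_drugs: int = 60
    n_proteins: int = 120
    n_clusters: int = 4
    n_classes: int = 8
    pairs_per_class: int = 400  # capped by the ordered pairs available per cell
    label_noise: float = 0.05
    modality_informativeness: dict = field(
        default_factory=lambda: {"smiles": 0.9, "ppi": 0.9, "text": 0.9}
    )
    proteins_per_drug: int = 3
    p_intra_module: float = 0.3
    p_inter_module: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_classes > self.n_clusters**2:
            raise ValueError(
                f"n_classes={self.n_classes} exceeds n_clusters^2={self.n_clusters**2}"
            )
        if not (0.0 <= self.label_noise < 1.0):
            raise ValueError("label_noise must lie in [0, 1)")
        if self.pairs_per_class < 5:
            raise ValueError("pairs_per_class must be >= 5")


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    drugs: pd.DataFrame | None          # drug_id, name, smiles, description
    ppi: pd.DataFrame | None            # protein_a, protein_b, score
    associations: pd.DataFrame | None   # drug_id, protein_id
    pairs: pd.DataFrame                 # drug_a, drug_b, class_id
    cluster_of: dict[str, int]          # ground truth
    class_map: dict[tuple[int, int], int]  # injective cluster-pair -> class
    keyword_map: dict[str, int]         # cluster keyword -> embedding axis
    feature_scale: dict[str, float] = field(
        default_factory=lambda: {"smiles": 1.0, "ppi": 1.0, "text": 1.0}
    )

    def ddi_pairs(self) -> list[DDIPair]:
        return [
            DDIPair(a, b, int(c))
            for a, b, c in zip(self.pairs["drug_a"], self.pairs["drug_b"], self.pairs["class_id"])
        ]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.drugs is not None:
            self.drugs.to_csv(out / "drugs.tsv", sep="\t", index=False)
        if self.ppi is not None:
            self.ppi.to_csv(out / "ppi.tsv", sep="\t", index=False)
        if self.associations is not None:
            self.associations.to_csv(out / "associations.tsv", sep="\t", index=False)
        self.pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
        truth = pd.DataFrame(
            {"drug_id": list(self.cluster_of), "cluster": list(self.cluster_of.values())}
        )
        truth.to_csv(out / "clusters.tsv", sep="\t", index=False)


_TEMPLATES_WITH_NAME = [
    "{name} is a {kw} agent indicated for condition C{x}.",
    "{name}, a {kw} compound, modulates pathway P{x} in clinical use.",
]
_TEMPLATES_WITHOUT_NAME = [
    "A {kw} small molecule evaluated against target T{x}.",
    "This {kw} therapeutic acts on receptor R{x}.",
]


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Build one complete dataset from the config; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    nC = config.n_clusters
    drug_ids = [f"D{i:04d}" for i in range(config.n_drugs)]
    names = [f"Drugon{i:04d}" for i in range(config.n_drugs)]
    cluster_of = {d: i % nC for i, d in enumerate(drug_ids)}

    inform = config.modality_informativeness

    # --- SMILES: per-cluster scaffold families, occasional off-cluster draws
    members_per_cluster = int(np.ceil(config.n_drugs / nC))
    libraries = [scaffold_family(c, members_per_cluster + nC) for c in range(nC)]
    used: list[set[int]] = [set() for _ in range(nC)]
    smiles_list = []
    for i, d in enumerate(drug_ids):
        c = cluster_of[d]
        fam = c
        if rng.random() >= inform.get("smiles", 1.0):
            fam = int(rng.integers(nC - 1))
            fam = fam if fam < c else fam + 1  # a different family, uniformly
        lib = libraries[fam]
        # next unused variant of that family; reuse from the start if exhausted
        free = [j for j in range(len(lib)) if j not in used[fam]]
        j = free[0] if free else int(rng.integers(len(lib)))
        used[fam].add(j)
        smiles_list.append(lib[j])

    # --- descriptions: templated sentences carrying the cluster keyword
    keywords = [f"ddikw{c}x" for c in range(nC)]
    keyword_map = {kw: 7 * c + 3 for c, kw in enumerate(keywords)}  # distinct axes
    descriptions = []
    for i, d in enumerate(drug_ids):
        c = cluster_of[d]
        kw_cluster = c
        if rng.random() >= inform.get("text", 1.0):
            kw_cluster = int(rng.integers(nC - 1))
            kw_cluster = kw_cluster if kw_cluster < c else kw_cluster + 1
        pool = _TEMPLATES_WITH_NAME if i % 2 == 0 else _TEMPLATES_WITHOUT_NAME
        tpl = pool[int(rng.integers(len(pool)))]
        descriptions.append(
            tpl.format(name=names[i], kw=keywords[kw_cluster], x=int(rng.integers(100)))
        )
    drugs = pd.DataFrame(
        {"drug_id": drug_ids, "name": names, "smiles": smiles_list, "description": descriptions}
    )

    # --- PPI: dense modules per cluster, sparse inter-module edges
    protein_ids = [f"P{i:04d}" for i in range(config.n_proteins)]
    module_of = np.array([i % nC for i in range(config.n_proteins)])
    edges = []
    for c in range(nC):
        mem = [protein_ids[i] for i in np.flatnonzero(module_of == c)]
        for k in range(len(mem)):  # ring keeps every module connected
            a, b = mem[k], mem[(k + 1) % len(mem)]
            edges.append((a, b, int(rng.integers(800, 1000))))
        for k in range(len(mem)):
            for l in range(k + 2, len(mem)):
                if rng.random() < config.p_intra_module:
                    edges.append((mem[k], mem[l], int(rng.integers(700, 1000))))
    for i in range(config.n_proteins):
        for j in range(i + 1, config.n_proteins):
            if module_of[i] != module_of[j] and rng.random() < config.p_inter_module:
                edges.append((protein_ids[i], protein_ids[j], int(rng.integers(700, 850))))
    ppi = pd.DataFrame(edges, columns=["protein_a", "protein_b", "score"])

    # --- associations: CTET sets sampled from the drug's cluster module
    assoc_rows = []
    for d in drug_ids:
        c = cluster_of[d]
        mod = c
        if rng.random() >= inform.get("ppi", 1.0):
            mod = int(rng.integers(nC - 1))
            mod = mod if mod < c else mod + 1
        candidates = np.flatnonzero(module_of == mod)
        chosen = rng.choice(candidates, size=min(config.proteins_per_drug, len(candidates)),
                            replace=False)
        for p in chosen:
            assoc_rows.append((d, protein_ids[int(p)]))
    associations = pd.DataFrame(assoc_rows, columns=["drug_id", "protein_id"])

    # --- pair labels: injective map from ordered cluster pairs to classes
    cluster_pairs = [(i, j) for i in range(nC) for j in range(nC)]
    order = rng.permutation(len(cluster_pairs))
    chosen_cells = [cluster_pairs[int(o)] for o in order[: config.n_classes]]
    class_map = {cell: cls for cls, cell in enumerate(chosen_cells)}
    by_cluster: dict[int, list[str]] = {}
    for d, c in cluster_of.items():
        by_cluster.setdefault(c, []).append(d)
    rows = []
    for (ci, cj), cls in class_map.items():
        cell = [
            (a, b)
            for a in by_cluster.get(ci, [])
            for b in by_cluster.get(cj, [])
            if a != b
        ]
        take = min(config.pairs_per_class, len(cell))
        idx = rng.choice(len(cell), size=take, replace=False)
        for t in idx:
            rows.append((*cell[int(t)], cls))
    pairs = pd.DataFrame(rows, columns=["drug_a", "drug_b", "class_id"])

    # --- label noise: flip a fraction to a uniformly random other class
    n_flip = int(round(config.label_noise * len(pairs)))
    if n_flip:
        flip_idx = rng.choice(len(pairs), size=n_flip, replace=False)
        for t in flip_idx:
            old = int(pairs.iloc[int(t)]["class_id"])
            new = int(rng.integers(config.n_classes - 1))
            pairs.iloc[int(t), pairs.columns.get_loc("class_id")] = (
                new if new < old else new + 1
            )

    return SyntheticDataset(
        config=config,
        drugs=drugs,
        ppi=ppi,
        associations=associations,
        pairs=pairs,
        cluster_of=cluster_of,
        class_map=class_map,
        keyword_map=keyword_map,
    )


def degrade(dataset: SyntheticDataset, which: str, mode: str, factor: float = 100.0,
            seed: int | None = None) -> SyntheticDataset:
    """Return a degraded copy of the dataset.

    ``shuffle`` permutes the modality's drug assignment (destroys the
    cluster signal, preserves marginals); ``scale`` multiplies the features
    derived from that modality by ``factor`` (exercises projection-layer
    re-weighting); ``drop`` removes the modality's data so featurizers fail
    loudly.
    """
    if which not in ("smiles", "ppi", "text"):
        raise ValueError(f"unknown modality {which!r}")
    if mode not in ("shuffle", "scale", "drop"):
        raise ValueError(f"unknown degradation mode {mode!r}")
    ds = copy.deepcopy(dataset)
    rng = np.random.default_rng(dataset.config.seed + 7919 if seed is None else seed)
    if mode == "scale":
        ds.feature_scale[which] *= factor
        return ds
    if mode == "drop":
        if which == "smiles":
            ds.drugs = ds.drugs.drop(columns=["smiles"])
        elif which == "text":
            ds.drugs = ds.drugs.drop(columns=["description"])
        else:
            ds.ppi = None
            ds.associations = None
        return ds
    # shuffle
    perm = rng.permutation(len(ds.drugs))
    if which == "smiles":
        ds.drugs["smiles"] = ds.drugs["smiles"].to_numpy()[perm]
    elif which == "text":
        ds.drugs["description"] = ds.drugs["description"].to_numpy()[perm]
    else:
        old_ids = ds.drugs["drug_id"].to_numpy()
        remap = dict(zip(old_ids, old_ids[perm]))
        ds.associations["drug_id"] = ds.associations["drug_id"].map(remap)
    return ds
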