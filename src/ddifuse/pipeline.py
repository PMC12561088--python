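"""End-to-end orchestration: featurize, split, train, evaluate.

Glues the per-modality featurizers into a :class:`FeatureStore`, runs the
stratified split and the two-stage trainer, and provides the ablation
harness that sweeps modality combinations and the projection switch across
seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chem import build_ssp, fingerprint_from_smiles, reduce_pca
from .evaluation import MetricsReport, compute_metrics
from .model import (
    FeatureStore,
    FusionMLP,
    ModelConfig,
    TrainingHistory,
    assemble_matrix,
    train_stage1,
    train_two_stage,
)
from .network import (
    build_psp,
    drug_diffusion_profiles,
    load_associations,
    network_from_frame,
)
from .pairs import DEFAULT_RATIOS, DDIPair, stratified_split
from .synth import SyntheticDataset
from .text import MockEmbeddingProvider, embed, prepare_text


class MissingModalityError(ValueError):
    """Raised when a requested modality's input data is absent."""


@dataclass
class FeaturizeConfig:
    radius: int = 2
    n_bits: int = 2048
    k_ssp: int = 200
    k_psp: int = 300
    restart: float = 0.5
    min_confidence: float = 700.0
    rwr_tol: float = 1e-6
    rwr_max_iter: int = 1000
    embed_noise: float = 0.1
    embed_seed: int = 0


def featurize(
    dataset: SyntheticDataset,
    modalities: tuple[str, ...],
    config: FeaturizeConfig | None = None,
) -> FeatureStore:
    """Build per-drug features for the requested modalities.

    ``ssp`` needs the drug table's smiles column, ``psp`` the PPI edge list
    plus associations, ``emb`` the name/description columns; a missing
    input raises :class:`MissingModalityError`.
    """
    cfg = config or FeaturizeConfig()
    drugs = dataset.drugs
    if drugs is None or "drug_id" not in drugs.columns:
        raise MissingModalityError("drug table missing")
    drug_ids = list(drugs["drug_id"])
    store = FeatureStore(drug_ids)
    scale = dataset.feature_scale

    if "ssp" in modalities:
        if "smiles" not in drugs.columns:
            raise MissingModalityError("ssp requested but the drug table has no smiles column")
        fps = [
            fingerprint_from_smiles(s, radius=cfg.radius, n_bits=cfg.n_bits, drug_id=d)
            for d, s in zip(drugs["drug_id"], drugs["smiles"])
        ]
        sim = build_ssp(fps)
        sim.values = sim.values * scale.get("smiles", 1.0)
        k = min(cfg.k_ssp, len(drug_ids) - 1)
        store.add("ssp", reduce_pca(sim, k=k).components)

    if "psp" in modalities:
        if dataset.ppi is None or dataset.associations is None:
            raise MissingModalityError("psp requested but PPI edges or associations are missing")
        network = network_from_frame(dataset.ppi, min_confidence=cfg.min_confidence)
        drug_map = load_associations(dataset.associations, network)
        # every drug needs a profile row, even if it has no associations
        for d in drug_ids:
            drug_map.mapping.setdefault(d, set())
        profiles = drug_diffusion_profiles(
            drug_map, network, restart=cfg.restart, tol=cfg.rwr_tol, max_iter=cfg.rwr_max_iter
        )
        by_id = {p.drug_id: p for p in profiles}
        ordered = [by_id[d] for d in drug_ids]
        for p in ordered:
            p.scores = p.scores * scale.get("ppi", 1.0)
        k = min(cfg.k_psp, len(drug_ids) - 1)
        store.add("psp", build_psp(ordered, k=k).components)

    if "emb" in modalities:
        if "description" not in drugs.columns:
            raise MissingModalityError("emb requested but the drug table has no description column")
        texts = [
            prepare_text(n, desc, drug_id=d)
            for d, n, desc in zip(drugs["drug_id"], drugs["name"], drugs["description"])
        ]
        provider = MockEmbeddingProvider(
            seed=cfg.embed_seed, keyword_map=dataset.keyword_map, noise=cfg.embed_noise
        )
        vectors = embed(texts, provider)
        store.add("emb", np.stack([v.values for v in vectors]) * scale.get("text", 1.0))

    return store


@dataclass
class ExperimentResult:
    metrics: MetricsReport
    config: ModelConfig
    history1: TrainingHistory
    history2: TrainingHistory | None
    split_sizes: dict[str, int]
    model: FusionMLP

    @property
    def test_accuracy(self) -> float:
        return self.metrics.accuracy


def run_experiment(
    dataset: SyntheticDataset,
    modalities: tuple[str, ...] = ("ssp", "emb"),
    use_projection: bool = True,
    seed: int = 0,
    featurize_config: FeaturizeConfig | None = None,
    model_config: ModelConfig | None = None,
    store: FeatureStore | None = None,
    two_stage: bool = False,
    permute_labels: bool = False,
) -> ExperimentResult:
    """Featurize, split, train and evaluate one model on one dataset.

    ``permute_labels`` shuffles training/validation/test labels jointly —
    the chance-level control. A pre-built ``store`` skips featurization
    (useful when sweeping model settings over fixed features).
    """
    if store is None:
        store = featurize(dataset, modalities, featurize_config)
    pairs = dataset.ddi_pairs()
    n_classes = int(dataset.pairs["class_id"].max()) + 1
    if permute_labels:
        rng = np.random.default_rng(seed + 13)
        labels = rng.permutation([p.class_id for p in pairs])
        pairs = [DDIPair(p.drug_a, p.drug_b, int(c)) for p, c in zip(pairs, labels)]
    split = stratified_split(pairs, DEFAULT_RATIOS, seed=seed)
    parts = {name: split.pairs_in(name) for name in ("train", "val", "test")}
    Xtr, ytr = assemble_matrix(parts["train"], store, modalities)
    Xva, yva = assemble_matrix(parts["val"], store, modalities)
    Xte, yte = assemble_matrix(parts["test"], store, modalities)

    base = model_config or ModelConfig(
        hidden_dim=128, max_epochs_stage1=60, early_stop_after=60, max_epochs_stage2=20
    )
    cfg = replace(
        base,
        modalities=tuple(modalities),
        use_projection=use_projection,
        n_classes=n_classes,
        seed=seed,
        input_dim=0,
    ).resolve_input_dim(store)
    if cfg.zscore:
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr, Xva, Xte = (Xtr - mu) / sd, (Xva - mu) / sd, (Xte - mu) / sd

    model = FusionMLP(cfg)
    if two_stage:
        h1, h2 = train_two_stage(model, Xtr, ytr, Xva, yva, cfg)
    else:
        h1 = train_stage1(model, Xtr, ytr, Xva, yva, cfg)
        model.load_state_dict(h1.best_state)
        h2 = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small test sets may miss classes
        metrics = compute_metrics(yte, model.predict_proba(Xte), n_classes=n_classes)
    return ExperimentResult(
        metrics=metrics,
        config=cfg,
        history1=h1,
        history2=h2,
        split_sizes={k: len(v) for k, v in parts.items()},
        model=model,
    )


def run_ablation(
    dataset: SyntheticDataset,
    combos: list[tuple[str, ...]],
    seeds: list[int],
    use_projection: bool | str = True,
    featurize_config: FeaturizeConfig | None = None,
    model_config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Sweep modality combinations (and optionally the projection switch).

    ``use_projection`` may be True, False, or "both". Features are built
    once per combination and shared across seeds. Returns one row per run
    with test accuracy and macro metrics.
    """
    proj_settings = [True, False] if use_projection == "both" else [bool(use_projection)]
    rows = []
    all_modalities = tuple(sorted({m for combo in combos for m in combo}))
    store = featurize(dataset, all_modalities, featurize_config)
    for combo in combos:
        for proj in proj_settings:
            for seed in seeds:
                res = run_experiment(
                    dataset,
                    modalities=combo,
                    use_projection=proj,
                    seed=seed,
                    store=store,
                    model_config=model_config,
                )
                rows.append(
                    {
                        "modalities": "+".join(combo),
                        "projection": proj,
                        "seed": seed,
                        "test_accuracy": res.metrics.accuracy,
                        "macro_f1": res.metrics.macro_f1,
                        "macro_auroc": res.metrics.macro_auroc,
                        "macro_aupr": res.metrics.macro_aupr,
                    }
                )
    return pd.DataFrame(rows)
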