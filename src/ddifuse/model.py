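"""Multimodal fusion classifier for directional DDI types.

Per-drug features from any subset of the three modalities (``ssp``
structural profile, ``psp`` protein diffusion profile, ``emb`` text
embedding) are concatenated drug-major into a pair vector. The classifier
is a multilayer perceptron with an optional square projection layer — a
learnable linear map with the same input and output size as the
concatenated feature, which re-weights and linearly mixes dimensions to
absorb cross-modal scale mismatches before compression:

    [projection (d -> d)] -> ReLU -> dropout
    -> hidden (d -> h)    -> ReLU -> dropout
    -> output (h -> C logits)

Training is a two-stage schedule: stage 1 trains from scratch with Adam and
cross-entropy (early stopping on validation accuracy, patience 20,
activated only after a configurable epoch); stage 2 resumes from the best
stage-1 checkpoint and fine-tunes with a reduce-on-plateau learning-rate
schedule (mode=max, factor 0.1, patience 5, floor 1e-6). Test metrics are
taken from the best validation checkpoint of stage 2.

The trainer is pure NumPy and bit-reproducible on a single device for a
fixed seed; across hardware it promises statistical, not bit,
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .pairs import DDIPair

MODALITY_DIMS = {"ssp": 200, "psp": 300, "emb": 768}  # full-scale defaults


# ---------------------------------------------------------------------------
# feature store and pair assembly


class FeatureStore:
    """Per-modality drug feature matrices over one shared drug index."""

    def __init__(self, drug_ids: Sequence[str]):
        self.drug_ids = list(drug_ids)
        self._row = {d: i for i, d in enumerate(self.drug_ids)}
        if len(self._row) != len(self.drug_ids):
            raise ValueError("duplicate drug_id in store index")
        self._matrices: dict[str, np.ndarray] = {}

    def add(self, modality: str, matrix: np.ndarray) -> None:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape[0] != len(self.drug_ids):
            raise ValueError(
                f"{modality}: {matrix.shape[0]} rows for {len(self.drug_ids)} drugs"
            )
        self._matrices[modality] = matrix

    @property
    def modalities(self) -> set[str]:
        return set(self._matrices)

    def dim(self, modality: str) -> int:
        return self._matrices[modality].shape[1]

    def features(self, drug_id: str, modality: str) -> np.ndarray:
        if modality not in self._matrices:
            raise KeyError(f"modality {modality!r} not in store (drug {drug_id!r})")
        if drug_id not in self._row:
            raise KeyError(f"drug {drug_id!r} not in store (modality {modality!r})")
        return self._matrices[modality][self._row[drug_id]]

    def pair_dim(self, modalities: Sequence[str]) -> int:
        return 2 * sum(self.dim(m) for m in modalities)


def assemble_pair_vector(
    pair: DDIPair, store: FeatureStore, modalities: Sequence[str]
) -> np.ndarray:
    """Concatenate drug_a's modality blocks then drug_b's (drug-major).

    Order-sensitive: vector(A, B) != vector(B, A) whenever features differ.
    """
    blocks = [store.features(pair.drug_a, m) for m in modalities]
    blocks += [store.features(pair.drug_b, m) for m in modalities]
    return np.concatenate(blocks)


def assemble_matrix(
    pairs: Sequence[DDIPair], store: FeatureStore, modalities: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pair-vector assembly; returns (X, y)."""
    mats = [store._matrices[m] for m in modalities]
    ia = np.array([store._row[p.drug_a] for p in pairs])
    ib = np.array([store._row[p.drug_b] for p in pairs])
    X = np.concatenate([m[ia] for m in mats] + [m[ib] for m in mats], axis=1)
    y = np.array([p.class_id for p in pairs], dtype=int)
    return X, y


# ---------------------------------------------------------------------------
# configuration and model


@dataclass
class ModelConfig:
    modalities: tuple[str, ...] = ("ssp", "emb")
    input_dim: int = 0  # 2 * sum of modality dims; filled from the store if 0
    use_projection: bool = True
    hidden_dim: int = 512
    dropout: float = 0.3
    learning_rate: float = 1e-3
    n_classes: int = 79
    seed: int = 0
    batch_size: int = 256
    max_epochs_stage1: int = 300
    early_stop_after: int = 200  # patience counting starts only past this epoch
    patience: int = 20
    max_epochs_stage2: int = 100
    plateau_factor: float = 0.1
    plateau_patience: int = 5
    min_lr: float = 1e-6
    zscore: bool = False  # off by default: the projection layer handles scale

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")

    def resolve_input_dim(self, store: FeatureStore) -> "ModelConfig":
        dim = store.pair_dim(self.modalities)
        if self.input_dim and self.input_dim != dim:
            raise ValueError(f"input_dim {self.input_dim} != store pair dim {dim}")
        return replace(self, input_dim=dim)


@dataclass
class EpochRecord:
    stage: int
    epoch: int
    train_loss: float
    val_accuracy: float
    lr: float


@dataclass
class TrainingHistory:
    records: list[EpochRecord] = field(default_factory=list)
    best_val_accuracy: float = -np.inf
    best_epoch: int = -1
    best_state: dict[str, np.ndarray] | None = None
    stopped_early: bool = False


def _he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)


class FusionMLP:
    """Projection-layer MLP over ordered drug-pair feature vectors."""

    def __init__(self, config: ModelConfig):
        if config.hidden_dim <= 0:
            raise ValueError("hidden_dim must be positive")
        if config.input_dim <= 0:
            raise ValueError("input_dim must be set (use config.resolve_input_dim)")
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, h, c = config.input_dim, config.hidden_dim, config.n_classes
        self.params: dict[str, np.ndarray] = {}
        if config.use_projection:
            self.params["Wp"] = _he_init(rng, d, d)
            self.params["bp"] = np.zeros(d)
        self.params["Wh"] = _he_init(rng, d, h)
        self.params["bh"] = np.zeros(h)
        self.params["Wo"] = _he_init(rng, h, c)
        self.params["bo"] = np.zeros(c)

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        if set(state) != set(self.params):
            raise ValueError("checkpoint does not match model architecture")
        self.params = {k: v.copy() for k, v in state.items()}

    # forward -----------------------------------------------------------
    def _forward(
        self, X: np.ndarray, rng: np.random.Generator | None
    ) -> tuple[np.ndarray, dict]:
        """Logits plus the cache needed for backprop; rng=None means eval
        mode (no dropout)."""
        p = self.params
        drop = self.config.dropout
        cache: dict = {"X": X}
        a = X
        if "Wp" in p:
            zp = a @ p["Wp"] + p["bp"]
            ap = np.maximum(zp, 0.0)
            mp = self._dropout_mask(ap.shape, rng)
            ap = ap * mp
            cache.update(zp=zp, ap=ap, mp=mp)
            a = ap
        zh = a @ p["Wh"] + p["bh"]
        ah = np.maximum(zh, 0.0)
        mh = self._dropout_mask(ah.shape, rng)
        ah = ah * mh
        cache.update(zh=zh, ah=ah, mh=mh, a_in=a)
        logits = ah @ p["Wo"] + p["bo"]
        return logits, cache

    def _dropout_mask(self, shape, rng) -> np.ndarray | float:
        drop = self.config.dropout
        if rng is None or drop == 0.0:
            return 1.0
        return (rng.random(shape) >= drop) / (1.0 - drop)

    def logits(self, X: np.ndarray) -> np.ndarray:
        out, _ = self._forward(np.asarray(X, float), rng=None)
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax class probabilities; each row sums to 1 within 1e-6."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected (n, {self.config.input_dim}) input, got {X.shape}"
            )
        z = self.logits(X)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        # np.argmax takes the first (lowest class id) on ties
        return np.argmax(self.predict_proba(X), axis=1)

    # backward ----------------------------------------------------------
    def _loss_and_grads(
        self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
    ) -> tuple[float, dict[str, np.ndarray]]:
        n = X.shape[0]
        logits, cache = self._forward(X, rng)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
        p = self.params
        g: dict[str, np.ndarray] = {}
        dlogits = probs
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        g["Wo"] = cache["ah"].T @ dlogits
        g["bo"] = dlogits.sum(axis=0)
        dah = dlogits @ p["Wo"].T
        dzh = dah * cache["mh"] * (cache["zh"] > 0)
        g["Wh"] = cache["a_in"].T @ dzh
        g["bh"] = dzh.sum(axis=0)
        if "Wp" in p:
            dap = dzh @ p["Wh"].T
            dzp = dap * cache["mp"] * (cache["zp"] > 0)
            g["Wp"] = cache["X"].T @ dzp
            g["bp"] = dzp.sum(axis=0)
        return loss, g


def build_model(config: ModelConfig) -> FusionMLP:
    """Construct a seeded classifier from a resolved config."""
    return FusionMLP(config)


# ---------------------------------------------------------------------------
# Adam optimizer


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training loops

ValMetricFn = Callable[[FusionMLP, np.ndarray, np.ndarray], float]


def _accuracy_metric(model: FusionMLP, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(model.predict(X) == y))


def _run_epoch(
    model: FusionMLP,
    optimizer: Adam,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> float:
    n = X.shape[0]
    order = rng.permutation(n)
    bs = model.config.batch_size
    losses = []
    for start in range(0, n, bs):
        idx = order[start : start + bs]
        loss, grads = model._loss_and_grads(X[idx], y[idx], rng)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training loss diverged (loss={loss})")
        optimizer.step(model.params, grads)
        losses.append(loss)
    return float(np.mean(losses))


def train_stage1(
    model: FusionMLP,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: ModelConfig | None = None,
    val_metric_fn: ValMetricFn = _accuracy_metric,
) -> TrainingHistory:
    """Stage 1: train from scratch with Adam and cross-entropy.

    Early stopping monitors validation accuracy with the configured patience
    but cannot trigger before ``early_stop_after`` epochs have passed; the
    best-validation checkpoint is kept on the history.
    """
    cfg = config or model.config
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params, lr=cfg.learning_rate)
    hist = TrainingHistory()
    stagnant = 0
    for epoch in range(1, cfg.max_epochs_stage1 + 1):
        loss = _run_epoch(model, opt, X_train, y_train, rng)
        val_acc = val_metric_fn(model, X_val, y_val)
        hist.records.append(EpochRecord(1, epoch, loss, val_acc, opt.lr))
        if val_acc > hist.best_val_accuracy:
            hist.best_val_accuracy = val_acc
            hist.best_epoch = epoch
            hist.best_state = model.state_dict()
        if epoch > cfg.early_stop_after:
            stagnant = 0 if hist.best_epoch == epoch else stagnant + 1
            if stagnant >= cfg.patience:
                hist.stopped_early = True
                break
    return hist


def fine_tune_stage2(
    checkpoint: dict[str, np.ndarray],
    model: FusionMLP,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: ModelConfig | None = None,
    val_metric_fn: ValMetricFn = _accuracy_metric,
) -> TrainingHistory:
    """Stage 2: resume from the stage-1 checkpoint and fine-tune.

    The learning rate is multiplied by ``plateau_factor`` whenever
    validation accuracy fails to improve for ``plateau_patience``
    consecutive epochs (then the plateau counter resets), floored at
    ``min_lr``; early stopping uses the configured patience from the start
    of the stage. Test metrics should be read from this stage's best
    checkpoint.
    """
    if checkpoint is None:
        raise ValueError("stage-1 checkpoint missing")
    cfg = config or model.config
    model.load_state_dict(checkpoint)
    rng = np.random.default_rng(cfg.seed + 2)
    opt = Adam(model.params, lr=cfg.learning_rate)
    hist = TrainingHistory()
    # the resumed checkpoint is the baseline the fine-tune must beat
    hist.best_state = model.state_dict()
    hist.best_epoch = 0
    hist.best_val_accuracy = val_metric_fn(model, X_val, y_val)
    plateau = 0
    stagnant = 0
    for epoch in range(1, cfg.max_epochs_stage2 + 1):
        loss = _run_epoch(model, opt, X_train, y_train, rng)
        val_acc = val_metric_fn(model, X_val, y_val)
        hist.records.append(EpochRecord(2, epoch, loss, val_acc, opt.lr))
        if val_acc > hist.best_val_accuracy:
            hist.best_val_accuracy = val_acc
            hist.best_epoch = epoch
            hist.best_state = model.state_dict()
            plateau = 0
            stagnant = 0
        else:
            plateau += 1
            stagnant += 1
            if plateau >= cfg.plateau_patience:
                new_lr = opt.lr * cfg.plateau_factor
                # snap to the floor within float rounding of the decay chain
                opt.lr = cfg.min_lr if new_lr <= cfg.min_lr * (1 + 1e-9) else new_lr
                plateau = 0
            if stagnant >= cfg.patience:
                hist.stopped_early = True
                break
    return hist


def train_two_stage(
    model: FusionMLP,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: ModelConfig | None = None,
) -> tuple[TrainingHistory, TrainingHistory]:
    """Run both stages; leaves the model at the stage-2 best checkpoint."""
    cfg = config or model.config
    h1 = train_stage1(model, X_train, y_train, X_val, y_val, cfg)
    h2 = fine_tune_stage2(h1.best_state, model, X_train, y_train, X_val, y_val, cfg)
    model.load_state_dict(h2.best_state)
    return h1, h2
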