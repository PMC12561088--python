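"""Drug text preparation and 768-dimensional semantic embeddings.

Texts follow a simple rule: if a drug's name already occurs in its
description the description is used as provided, otherwise the name is
prepended. Embedding itself goes through a pluggable provider; the
deterministic mock provider is the test backend, and a transformer backend
(biomedical BERT-style encoder, [CLS]-token hidden state) can be plugged in
where the ``transformers`` library is installed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol

import numpy as np

EMBED_DIM = 768
TOKEN_LIMIT = 512  # whitespace tokens for the mock; model tokens for a transformer


@dataclass(frozen=True)
class DrugText:
    drug_id: str
    name: str
    description: str
    prepared: str


@dataclass(frozen=True)
class EmbeddingVector:
    drug_id: str
    values: np.ndarray
    truncated: bool = False

    def __post_init__(self):
        if self.values.shape != (EMBED_DIM,):
            raise ValueError(f"embedding must have length {EMBED_DIM}, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite embedding for {self.drug_id!r}")


def prepare_text(name: str, description: str, drug_id: str = "") -> DrugText:
    """Apply the name-prepend rule.

    The name match is case-insensitive on the exact name string. An empty
    description degenerates to the bare name.
    """
    if not name:
        raise ValueError("drug name must be non-empty")
    if not description:
        prepared = name
    elif name.lower() in description.lower():
        prepared = description
    else:
        prepared = f"{name}. {description}"
    return DrugText(drug_id=drug_id, name=name, description=description, prepared=prepared)


class EmbeddingProvider(Protocol):
    name: str

    def embed_text(self, text: str) -> tuple[np.ndarray, bool]:
        """Return (length-768 vector, truncated flag)."""
        ...


def _stable_hash(text: str, salt: int) -> int:
    h = hashlib.sha256(f"{salt}:{text}".encode()).digest()
    return int.from_bytes(h[:8], "little")


class MockEmbeddingProvider:
    """Deterministic keyword-anchored test backend.

    The vector is the unit basis direction of the first keyword found in the
    text, scaled by (1 - noise), plus noise-scaled pseudo-random unit noise
    derived from a stable hash of the text; texts with no keyword get pure
    hash noise. Same seed and text always give the same vector.
    """

    name = "mock"

    def __init__(
        self,
        seed: int = 0,
        keyword_map: dict[str, int] | None = None,
        noise: float = 0.1,
    ):
        if not (0.0 <= noise < 1.0):
            raise ValueError("noise must lie in [0, 1)")
        self.seed = seed
        self.keyword_map = dict(keyword_map or {})
        self.noise = noise

    def embed_text(self, text: str) -> tuple[np.ndarray, bool]:
        tokens = text.split()
        truncated = len(tokens) > TOKEN_LIMIT
        if truncated:
            text = " ".join(tokens[:TOKEN_LIMIT])
        low = text.lower()
        direction = None
        best_pos = None
        for kw, axis in self.keyword_map.items():
            pos = low.find(kw.lower())
            if pos >= 0 and (best_pos is None or pos < best_pos):
                best_pos = pos
                direction = axis % EMBED_DIM
        rng = np.random.default_rng(_stable_hash(text, self.seed) % (2**63))
        noise_vec = rng.standard_normal(EMBED_DIM)
        noise_vec /= np.linalg.norm(noise_vec)
        if direction is None:
            vec = noise_vec
        else:
            vec = np.zeros(EMBED_DIM)
            vec[direction] = 1.0 - self.noise
            vec += self.noise * noise_vec
        return vec, truncated


class HashingEmbeddingProvider:
    """Keyword-free fallback: a seeded random projection of token hashes.

    Gives texts sharing vocabulary similar vectors without any pretrained
    weights; useful for smoke-testing pipelines on arbitrary descriptions.
    """

    name = "hashing"

    def __init__(self, seed: int = 0):
        self.seed = seed

    def embed_text(self, text: str) -> tuple[np.ndarray, bool]:
        tokens = text.lower().split()
        truncated = len(tokens) > TOKEN_LIMIT
        tokens = tokens[:TOKEN_LIMIT]
        vec = np.zeros(EMBED_DIM)
        for t in tokens:
            rng = np.random.default_rng(_stable_hash(t, self.seed) % (2**63))
            vec += rng.standard_normal(EMBED_DIM)
        n = np.linalg.norm(vec)
        if n > 0:
            vec /= n
        return vec, truncated


class TransformerEmbeddingProvider:
    """Optional real backend: [CLS]-token hidden state of a pretrained
    biomedical encoder. Requires the ``transformers`` library and model
    weights on disk; inputs beyond the model's 512-token limit are truncated
    and flagged."""

    name = "transformer"

    def __init__(self, model_name: str = "dmis-lab/biobert-base-cased-v1.1"):
        try:
            from transformers import AutoModel, AutoTokenizer  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError(
                "TransformerEmbeddingProvider requires the optional 'transformers' "
                "library; install it or use the mock/hashing providers"
            ) from exc
        self._tokenizer = AutoTokenizer.from_pretrained(model_name)
        self._model = AutoModel.from_pretrained(model_name)
        self._model.eval()

    def embed_text(self, text: str) -> tuple[np.ndarray, bool]:  # pragma: no cover
        import torch  # type: ignore

        enc_full = self._tokenizer(text, return_tensors="pt", truncation=False)
        truncated = enc_full["input_ids"].shape[1] > TOKEN_LIMIT
        enc = self._tokenizer(
            text, return_tensors="pt", truncation=True, max_length=TOKEN_LIMIT
        )
        with torch.no_grad():
            out = self._model(**enc)
        cls = out.last_hidden_state[0, 0].numpy()
        return cls.astype(float), truncated


def embed(texts: list[DrugText], provider: EmbeddingProvider) -> list[EmbeddingVector]:
    """Embed prepared texts, one 768-vector per drug."""
    out: list[EmbeddingVector] = []
    for t in texts:
        try:
            vec, truncated = provider.embed_text(t.prepared)
        except Exception as exc:
            raise RuntimeError(f"embedding provider failed for drug {t.drug_id!r}: {exc}") from exc
        out.append(EmbeddingVector(drug_id=t.drug_id, values=np.asarray(vec, float), truncated=truncated))
    return out
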