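"""Labeled ordered drug pairs: class catalog, filtering, stratified split.

Pairs are directional — (A, B) and (B, A) are distinct records because the
interaction sentences are directional ("the serum concentration of Drug B
can be increased..."). Classes with too few pairs are dropped and the
survivors re-indexed contiguously; the train/validation/test split is
stratified per class with largest-remainder apportionment so every class
matches the global 0.64/0.16/0.20 ratios as closely as integers allow.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

PARTITIONS = ("train", "val", "test")
DEFAULT_RATIOS = (0.64, 0.16, 0.20)


@dataclass(frozen=True)
class DDIPair:
    drug_a: str
    drug_b: str
    class_id: int

    def __post_init__(self):
        if self.drug_a == self.drug_b:
            raise ValueError(f"self-pair not allowed: {self.drug_a!r}")


@dataclass
class ClassCatalog:
    """class_id -> description, with per-class counts and the original-id map
    retained across filtering/re-indexing."""

    descriptions: dict[int, str]
    counts: dict[int, int]
    original_ids: dict[int, int] = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return len(self.descriptions)


@dataclass
class SplitAssignment:
    partition_of: dict[DDIPair, str]
    seed: int
    ratios: tuple[float, float, float]

    def pairs_in(self, partition: str) -> list[DDIPair]:
        return [p for p, part in self.partition_of.items() if part == partition]


def largest_remainder(total: int, ratios: tuple[float, ...]) -> list[int]:
    """Apportion ``total`` items by ``ratios`` with the largest-remainder rule.

    Floors are assigned first; leftover units go to the largest fractional
    remainders (ties broken by position, earlier ratio wins).
    """
    quotas = [total * r for r in ratios]
    floors = [int(np.floor(q)) for q in quotas]
    leftover = total - sum(floors)
    remainders = sorted(
        range(len(ratios)), key=lambda i: (-(quotas[i] - floors[i]), i)
    )
    for i in remainders[:leftover]:
        floors[i] += 1
    return floors


def filter_classes(
    pairs: list[DDIPair],
    min_count: int = 5,
    descriptions: dict[int, str] | None = None,
) -> tuple[list[DDIPair], ClassCatalog]:
    """Drop classes with fewer than ``min_count`` pairs; re-index survivors.

    Returns the surviving pairs (classes renumbered contiguously, order of
    pairs preserved) and a catalog that records the original ids and the
    per-class counts after filtering.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = Counter(p.class_id for p in pairs)
    survivors = sorted(c for c, n in counts.items() if n >= min_count)
    if not survivors:
        raise ValueError(f"no class has >= {min_count} pairs; nothing survives filtering")
    new_id = {old: new for new, old in enumerate(survivors)}
    kept = [
        DDIPair(p.drug_a, p.drug_b, new_id[p.class_id])
        for p in pairs
        if p.class_id in new_id
    ]
    descriptions = descriptions or {}
    catalog = ClassCatalog(
        descriptions={new_id[c]: descriptions.get(c, f"class {c}") for c in survivors},
        counts={new_id[c]: counts[c] for c in survivors},
        original_ids={new_id[c]: c for c in survivors},
    )
    return kept, catalog


def stratified_split(
    pairs: list[DDIPair],
    ratios: tuple[float, float, float] = DEFAULT_RATIOS,
    seed: int = 0,
) -> SplitAssignment:
    """Stratified train/val/test split with exact per-class apportionment.

    Within every class the partition sizes are the largest-remainder
    apportionment of the class size by ``ratios``; membership is decided by
    a seeded within-class shuffle, so the same seed reproduces the same
    assignment bit for bit.
    """
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    by_class: dict[int, list[DDIPair]] = {}
    for p in pairs:
        by_class.setdefault(p.class_id, []).append(p)
    for c, members in by_class.items():
        if len(members) < 3:
            raise ValueError(
                f"class {c} has {len(members)} < 3 pairs; run filter_classes first"
            )
    rng = np.random.default_rng(seed)
    assignment: dict[DDIPair, str] = {}
    for c in sorted(by_class):
        members = list(by_class[c])
        order = rng.permutation(len(members))
        counts = largest_remainder(len(members), ratios)
        bounds = np.cumsum(counts)
        for rank, idx in enumerate(order):
            part = PARTITIONS[int(np.searchsorted(bounds, rank, side="right"))]
            assignment[members[idx]] = part
    return SplitAssignment(partition_of=assignment, seed=seed, ratios=tuple(ratios))
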