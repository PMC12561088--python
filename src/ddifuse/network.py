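"""Protein similarity profiles (PSP) from network diffusion.

A weighted protein-protein interaction (PPI) network is loaded from a
STRING-style edge list, a column-stochastic transition matrix is formed, and
a random walk with restart (RWR) is run from each drug's seed set of
carrier/transporter/enzyme/target (CTET) proteins. The stationary diffusion
score vector of each drug captures indirect functional connections; pairwise
cosine similarity between diffusion vectors, PCA-reduced, gives the PSP
feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .chem import ReducedProfile, reduce_pca


@dataclass
class ProteinNetwork:
    """Undirected weighted PPI network; each unordered pair stored once."""

    protein_ids: list[str]
    edges: list[tuple[str, str, float]]
    dropped_below_threshold: int = 0
    dropped_self_loops: int = 0
    dropped_duplicates: int = 0

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.protein_ids)}


@dataclass
class DrugProteinMap:
    """drug_id -> set of associated CTET protein ids.

    Proteins absent from the network are moved to ``dropped_proteins``;
    drugs left with an empty set are listed in ``flagged_drugs``.
    """

    mapping: dict[str, set[str]]
    dropped_proteins: dict[str, set[str]] = field(default_factory=dict)
    flagged_drugs: list[str] = field(default_factory=list)


@dataclass
class DiffusionProfile:
    """RWR stationary distribution of one drug over the network proteins."""

    drug_id: str
    scores: np.ndarray
    restart: float
    converged: bool
    iterations: int
    empty_seed: bool = False


def load_ppi(edge_file: str | Path, min_confidence: float = 700.0) -> ProteinNetwork:
    """Load a TSV edge list (protein_a, protein_b, score) into a network.

    Edges below ``min_confidence`` are dropped, duplicate unordered pairs are
    collapsed keeping the maximum score, and self-loops are removed; counts
    of each are recorded on the returned network.
    """
    path = Path(edge_file)
    df = pd.read_csv(path, sep="\t", dtype=str)
    return network_from_frame(df, min_confidence=min_confidence, source=str(path))


def network_from_frame(
    df: pd.DataFrame, min_confidence: float = 700.0, source: str = "<frame>"
) -> ProteinNetwork:
    """Build a :class:`ProteinNetwork` from an in-memory edge table."""
    path = source
    df = df.astype(str)
    required = {"protein_a", "protein_b", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = df.index[scores.isna() | df["protein_a"].isna() | df["protein_b"].isna()]
    if len(bad) > 0:
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: malformed row at line {int(bad[0]) + 2}")
    dropped_thr = int((scores < min_confidence).sum())
    keep = scores >= min_confidence
    best: dict[tuple[str, str], float] = {}
    self_loops = 0
    dups = 0
    for a, b, s in zip(df.loc[keep, "protein_a"], df.loc[keep, "protein_b"], scores[keep]):
        if a == b:
            self_loops += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key in best:
            dups += 1
            best[key] = max(best[key], float(s))
        else:
            best[key] = float(s)
    if not best:
        raise ValueError(f"{path}: network empty after filtering at min_confidence={min_confidence}")
    proteins = sorted({p for pair in best for p in pair})
    edges = [(a, b, w) for (a, b), w in sorted(best.items())]
    return ProteinNetwork(
        protein_ids=proteins,
        edges=edges,
        dropped_below_threshold=dropped_thr,
        dropped_self_loops=self_loops,
        dropped_duplicates=dups,
    )


def load_associations(
    assoc_file: str | Path | pd.DataFrame, network: ProteinNetwork
) -> DrugProteinMap:
    """Load a drug->protein association TSV (or frame) aligned to the network."""
    if isinstance(assoc_file, pd.DataFrame):
        df = assoc_file.astype(str)
    else:
        df = pd.read_csv(assoc_file, sep="\t", dtype=str)
    if not {"drug_id", "protein_id"}.issubset(df.columns):
        raise ValueError(f"{assoc_file}: expected columns drug_id, protein_id")
    in_net = set(network.protein_ids)
    mapping: dict[str, set[str]] = {}
    dropped: dict[str, set[str]] = {}
    for d, p in zip(df["drug_id"], df["protein_id"]):
        if p in in_net:
            mapping.setdefault(d, set()).add(p)
        else:
            dropped.setdefault(d, set()).add(p)
            mapping.setdefault(d, set())
    flagged = sorted(d for d, ps in mapping.items() if not ps)
    if flagged:
        warnings.warn(f"{len(flagged)} drugs have no mapped network proteins", stacklevel=2)
    return DrugProteinMap(mapping=mapping, dropped_proteins=dropped, flagged_drugs=flagged)


def transition_matrix(network: ProteinNetwork) -> sp.csr_matrix:
    """Column-stochastic M×M transition matrix of the weighted network.

    Entry (i, j) = w(i, j) / Σ_i w(i, j). Isolated nodes yield all-zero
    columns (none can arise from ``load_ppi`` output, but raw networks may
    contain them).
    """
    if network.n_proteins == 0:
        raise ValueError("empty network")
    idx = network.index()
    m = network.n_proteins
    rows, cols, vals = [], [], []
    for a, b, w in network.edges:
        i, j = idx[a], idx[b]
        rows.extend((i, j))
        cols.extend((j, i))
        vals.extend((w, w))
    A = sp.csr_matrix((vals, (rows, cols)), shape=(m, m))
    col_sums = np.asarray(A.sum(axis=0)).ravel()
    inv = np.divide(1.0, col_sums, out=np.zeros_like(col_sums), where=col_sums > 0)
    return (A @ sp.diags(inv)).tocsr()


def rwr(
    W: sp.spmatrix | np.ndarray,
    seed: np.ndarray,
    restart: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, bool, int]:
    """Random walk with restart: iterate p <- (1-r) W p + r seed from p = seed.

    Returns (scores, converged, iterations). Stops when the L1 change drops
    below ``tol``. For column-stochastic W the scores stay a probability
    distribution at every iteration.
    """
    seed = np.asarray(seed, dtype=float)
    if np.any(seed < 0):
        raise ValueError("seed must be non-negative")
    s = seed.sum()
    if s <= 0:
        raise ValueError("seed sums to 0; handle empty seed sets before calling rwr")
    if not np.isclose(s, 1.0, atol=1e-8):
        raise ValueError(f"seed must sum to 1, got {s}")
    if not (0.0 < restart < 1.0):
        raise ValueError(f"restart must lie in (0, 1), got {restart}")
    p = seed.copy()
    for it in range(1, max_iter + 1):
        p_next = (1.0 - restart) * (W @ p) + restart * seed
        delta = float(np.abs(p_next - p).sum())
        p = p_next
        if delta < tol:
            return p, True, it
    return p, False, max_iter


def rwr_closed_form(
    W: sp.spmatrix | np.ndarray, seed: np.ndarray, restart: float
) -> np.ndarray:
    """Dense linear solve of the RWR fixed point r (I - (1-r) W)^-1 seed."""
    Wd = W.toarray() if sp.issparse(W) else np.asarray(W, dtype=float)
    m = Wd.shape[0]
    return restart * np.linalg.solve(np.eye(m) - (1.0 - restart) * Wd, np.asarray(seed, float))


def drug_diffusion_profiles(
    drug_map: DrugProteinMap,
    network: ProteinNetwork,
    restart: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> list[DiffusionProfile]:
    """Run RWR for every drug, seeding uniform mass on its mapped proteins.

    Drugs with no mapped network proteins receive an all-zero profile with
    ``empty_seed`` set — kept, not dropped, so downstream models may exclude
    or impute them.
    """
    W = transition_matrix(network)
    idx = network.index()
    m = network.n_proteins
    out: list[DiffusionProfile] = []
    cache: dict[frozenset[str], tuple[np.ndarray, bool, int]] = {}
    for drug_id in sorted(drug_map.mapping):
        proteins = frozenset(p for p in drug_map.mapping[drug_id] if p in idx)
        if not proteins:
            out.append(
                DiffusionProfile(drug_id, np.zeros(m), restart, True, 0, empty_seed=True)
            )
            continue
        if proteins not in cache:
            seed = np.zeros(m)
            seed[[idx[p] for p in proteins]] = 1.0 / len(proteins)
            cache[proteins] = rwr(W, seed, restart=restart, tol=tol, max_iter=max_iter)
        scores, conv, it = cache[proteins]
        out.append(DiffusionProfile(drug_id, scores.copy(), restart, conv, it))
    return out


def diffusion_similarity(profiles: list[DiffusionProfile]) -> np.ndarray:
    """Pairwise cosine similarity of diffusion score vectors.

    Zero-profile drugs get similarity 0 to every other drug and 1 to self.
    """
    X = np.stack([p.scores for p in profiles])
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    Xn = X / safe[:, None]
    S = Xn @ Xn.T
    np.fill_diagonal(S, 1.0)
    S = np.clip(S, -1.0, 1.0)
    return S


def build_psp(
    profiles: list[DiffusionProfile], k: int = 300, mode: str = "cosine"
) -> ReducedProfile:
    """PCA-reduced protein similarity profile.

    ``mode="cosine"`` (default) mirrors the SSP construction: the N×N cosine
    similarity matrix of diffusion vectors is reduced. ``mode="raw"`` reduces
    the drugs × proteins diffusion matrix directly.
    """
    ids = [p.drug_id for p in profiles]
    if mode == "cosine":
        X = diffusion_similarity(profiles)
    elif mode == "raw":
        X = np.stack([p.scores for p in profiles])
    else:
        raise ValueError(f"unknown PSP mode {mode!r}")
    return reduce_pca(X, k=k, drug_ids=ids)
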