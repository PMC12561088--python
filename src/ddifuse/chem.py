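"""Structural similarity profiles (SSP).

Each drug's SMILES is converted to an extended-connectivity fingerprint
(ECFP4 by default, ECFP6 optional), pairwise structural similarity is the
Tanimoto coefficient over fingerprint bit sets, and a drug's SSP vector is
its row of the all-vs-all Tanimoto matrix, compressed by PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")  # parse failures are raised, not printed


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


@dataclass(frozen=True)
class Fingerprint:
    """Binary circular-substructure fingerprint of a single drug.

    ``on_bits`` holds the indices set after folding the circular hashes into
    ``n_bits``; an empty set marks a degenerate molecule and is flagged.
    """

    drug_id: str
    on_bits: frozenset[int]
    radius: int
    n_bits: int

    def __post_init__(self):
        if self.radius not in (2, 3):
            raise ValueError(f"radius must be 2 (ECFP4) or 3 (ECFP6), got {self.radius}")
        if self.on_bits and max(self.on_bits) >= self.n_bits:
            raise ValueError("on_bits index exceeds n_bits")

    @property
    def is_empty(self) -> bool:
        return len(self.on_bits) == 0


@dataclass
class SimilarityMatrix:
    """Symmetric all-vs-all drug similarity matrix with values in [0, 1]."""

    drug_ids: list[str]
    values: np.ndarray

    def row(self, drug_id: str) -> np.ndarray:
        return self.values[self.drug_ids.index(drug_id)]


@dataclass
class ReducedProfile:
    """PCA-compressed per-drug profile.

    ``low_variance`` is a validation flag (not an error) raised when the
    retained components explain less than 95% of the variance.
    """

    drug_ids: list[str]
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    k: int
    low_variance: bool = field(default=False)

    @property
    def cumulative_variance(self) -> float:
        return float(np.sum(self.explained_variance_ratio))


def fingerprint_from_smiles(
    smiles: str, radius: int = 2, n_bits: int = 2048, drug_id: str = ""
) -> Fingerprint:
    """Compute the ECFP bit set of one SMILES string.

    The SMILES is canonicalized first so equivalent notations (aromatic vs
    Kekulé, atom orderings from different source databases) map to identical
    fingerprints. Deterministic: identical inputs always yield identical bits.

    Raises
    ------
    SmilesParseError
        If the SMILES cannot be parsed. Never returns a silent empty
        fingerprint for bad input.
    """
    if not smiles:
        raise SmilesParseError(smiles)
    if radius not in (2, 3):
        raise ValueError(f"radius must be 2 or 3, got {radius}")
    if n_bits < 1024 or (n_bits & (n_bits - 1)) != 0:
        raise ValueError(f"n_bits must be a power of two >= 1024, got {n_bits}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    # round-trip through canonical SMILES for a source-independent form
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(
        drug_id=drug_id,
        on_bits=frozenset(bv.GetOnBits()),
        radius=radius,
        n_bits=n_bits,
    )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| between two fingerprints.

    Both-empty fingerprints give 0 with a warning: an empty fingerprint
    carries no evidence of similarity, so 0/0 is defined as 0.
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"n_bits mismatch: {a.n_bits} vs {b.n_bits}")
    if a.is_empty and b.is_empty:
        warnings.warn(
            f"Tanimoto of two empty fingerprints ({a.drug_id!r}, {b.drug_id!r}) defined as 0",
            stacklevel=2,
        )
        return 0.0
    inter = len(a.on_bits & b.on_bits)
    union = len(a.on_bits | b.on_bits)
    return inter / union


def build_ssp(fingerprints: list[Fingerprint]) -> SimilarityMatrix:
    """All-vs-all Tanimoto matrix; row i is drug i's raw SSP vector."""
    ids = [fp.drug_id for fp in fingerprints]
    seen: set[str] = set()
    for d in ids:
        if d in seen:
            raise ValueError(f"duplicate drug_id: {d!r}")
        seen.add(d)
    n = len(fingerprints)
    values = np.ones((n, n), dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-empty pairs already flagged upstream
        for i in range(n):
            if fingerprints[i].is_empty:
                values[i, i] = 0.0
            for j in range(i + 1, n):
                s = tanimoto(fingerprints[i], fingerprints[j])
                values[i, j] = s
                values[j, i] = s
    return SimilarityMatrix(drug_ids=ids, values=values)


def reduce_pca(
    matrix: SimilarityMatrix | np.ndarray,
    k: int,
    drug_ids: list[str] | None = None,
    variance_threshold: float = 0.95,
    fit_rows: list[int] | None = None,
) -> ReducedProfile:
    """Project mean-centered profile rows onto the top-k principal axes.

    Accepts either a :class:`SimilarityMatrix` or a raw (N, D) array with
    ``drug_ids``. Flags (does not reject) reductions that retain < 95% of
    the variance. By default the axes are fit on all rows (the transductive
    construction similarity profiles normally use); passing ``fit_rows``
    restricts the fit to those rows — the leakage-safe alternative — while
    still transforming every row.
    """
    if isinstance(matrix, SimilarityMatrix):
        X = matrix.values
        ids = list(matrix.drug_ids)
    else:
        X = np.asarray(matrix, dtype=float)
        ids = list(drug_ids) if drug_ids is not None else [str(i) for i in range(len(X))]
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 rows")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(n_rows, n_cols)={min(X.shape)}")
    pca = PCA(n_components=k, svd_solver="full")
    if fit_rows is None:
        comps = pca.fit_transform(X)
    else:
        if k > min(len(fit_rows), X.shape[1]):
            raise ValueError(f"k={k} exceeds the fit subset's rank bound")
        pca.fit(X[np.asarray(fit_rows, dtype=int)])
        comps = pca.transform(X)
    evr = pca.explained_variance_ratio_
    cum = float(np.sum(evr))
    low = cum < variance_threshold
    if low:
        warnings.warn(
            f"retained {k} components explain {cum:.3f} < {variance_threshold:.2f} of variance",
            stacklevel=2,
        )
    return ReducedProfile(
        drug_ids=ids,
        components=comps,
        explained_variance_ratio=evr,
        k=k,
        low_variance=low,
    )
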