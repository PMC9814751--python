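"""Fingerprints, Tanimoto distances and chemical-space coverage.

A molecule m_j is *covered* by a selected molecule m_i when their Tanimoto
distance over ECFP6 fingerprints is strictly below the threshold D_TH
(default 0.3).  Coverage of a selected set is the weighted fraction of the
space lying within one hop (order 1) or two hops (order 2) of the set in
this neighbor relation.  The cover function is a weighted set cover, hence
monotone submodular, which is what licenses greedy maximization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chemspace import Molecule

logger = logging.getLogger(__name__)

DEFAULT_D_TH = 0.3
DEFAULT_NBITS = 2048
ECFP6_RADIUS = 3  # diameter 6 bonds


@dataclass(frozen=True)
class Fingerprint:
    """A hashed binary circular fingerprint as a set of on-bit indices."""

    bits: frozenset[int]
    nbits: int
    radius: int = ECFP6_RADIUS

    def __post_init__(self) -> None:
        if any(b < 0 or b >= self.nbits for b in self.bits):
            raise ValueError("bit index outside [0, nbits)")


def ecfp6(mol: Molecule | Chem.Mol | str, nbits: int = DEFAULT_NBITS) -> Fingerprint:
    """ECFP6 (Morgan radius 3) hashed fingerprint.

    Accepts a :class:`Molecule`, an RDKit Mol or a SMILES string; any SMILES
    spelling of the same molecule yields the same bits.
    """
    if isinstance(mol, Molecule):
        rdmol = mol.to_rdkit()
    elif isinstance(mol, str):
        rdmol = Chem.MolFromSmiles(mol)
        if rdmol is None:
            raise ValueError(f"unparseable SMILES: {mol!r}")
    else:
        rdmol = mol
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=ECFP6_RADIUS, fpSize=nbits)
    bv = gen.GetFingerprint(rdmol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), nbits=nbits)


def tanimoto_distance(a: Fingerprint, b: Fingerprint) -> float:
    """d = 1 - |a ∩ b| / |a ∪ b|; two empty fingerprints count as identical."""
    if a.nbits != b.nbits:
        raise ValueError("fingerprints have different bit lengths")
    union = len(a.bits | b.bits)
    if union == 0:
        logger.warning("Tanimoto distance of two empty fingerprints: defined as 0")
        return 0.0
    return 1.0 - len(a.bits & b.bits) / union


def _bit_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    nbits = fps[0].nbits
    X = np.zeros((len(fps), nbits), dtype=np.float32)
    for i, fp in enumerate(fps):
        if fp.nbits != nbits:
            raise ValueError("inconsistent fingerprint lengths")
        X[i, list(fp.bits)] = 1.0
    return X


def tanimoto_distance_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Dense pairwise Tanimoto distance matrix (float32, n x n)."""
    X = _bit_matrix(fps)
    inter = X @ X.T
    counts = X.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0  # pairs of empty fingerprints
    np.fill_diagonal(d, 0.0)
    return d.astype(np.float32)


class MolecularSpace:
    """The molecule set over which coverage and selection are defined.

    Parameters
    ----------
    fingerprints:
        One :class:`Fingerprint` per molecule.
    d_th:
        Tanimoto distance threshold D_TH in [0, 1]; ``d_ij < d_th`` (strict)
        makes i and j neighbors.  Every molecule is its own neighbor since
        d_ii = 0, provided d_th > 0.
    molecules:
        Optional :class:`Molecule` records (synthetic spaces may omit them).
    weights:
        Per-molecule weights w(m_j); default 1 for every molecule, so the
        total weight W_tot equals the molecule count NMOL.
    """

    def __init__(self, fingerprints: Sequence[Fingerprint], d_th: float = DEFAULT_D_TH,
                 molecules: Optional[Sequence[Molecule]] = None,
                 weights: Optional[Sequence[float]] = None) -> None:
        if not fingerprints:
            raise ValueError("empty molecular space")
        if not 0.0 <= d_th <= 1.0:
            raise ValueError(f"d_th must be in [0, 1], got {d_th}")
        if molecules is not None and len(molecules) != len(fingerprints):
            raise ValueError("molecules/fingerprints length mismatch")
        self.fingerprints = list(fingerprints)
        self.molecules = list(molecules) if molecules is not None else None
        self.d_th = float(d_th)
        self.nmol = len(self.fingerprints)
        w = np.ones(self.nmol) if weights is None else np.asarray(weights, dtype=float)
        if w.shape != (self.nmol,) or np.any(w < 0):
            raise ValueError("weights must be nonnegative, one per molecule")
        self.weights = w
        self.w_tot = float(w.sum())
        self._distances: Optional[np.ndarray] = None
        self._adjacency: Optional[np.ndarray] = None

    @classmethod
    def from_molecules(cls, molecules: Sequence[Molecule], d_th: float = DEFAULT_D_TH,
                       nbits: int = DEFAULT_NBITS,
                       weights: Optional[Sequence[float]] = None) -> "MolecularSpace":
        fps = [ecfp6(m, nbits=nbits) for m in molecules]
        return cls(fps, d_th=d_th, molecules=molecules, weights=weights)

    # -- geometry -----------------------------------------------------------

    @property
    def distances(self) -> np.ndarray:
        if self._distances is None:
            self._distances = tanimoto_distance_matrix(self.fingerprints)
        return self._distances

    @property
    def adjacency(self) -> np.ndarray:
        """Boolean neighbor matrix A[i, j] = (d_ij < d_th); symmetric."""
        if self._adjacency is None:
            self._adjacency = self.distances < self.d_th
        return self._adjacency

    def ids(self) -> list[str]:
        if self.molecules is not None:
            return [m.id for m in self.molecules]
        return [str(i) for i in range(self.nmol)]

    def neighbors(self, i: int, subset: Optional[Iterable[int]] = None) -> set[int]:
        """C_subset(m_i): indices j in ``subset`` with d_ij < d_th.

        ``subset`` defaults to the whole space.  The inequality is strict, so
        d_th = 0 yields the empty set even for i itself.
        """
        row = np.flatnonzero(self.adjacency[i])
        if subset is None:
            return set(row.tolist())
        return set(row.tolist()) & set(subset)

    # -- coverage -----------------------------------------------------------

    def covered_mask(self, selected: Iterable[int], order: int = 1) -> np.ndarray:
        """Boolean mask of molecules within ``order`` hops of ``selected``."""
        if order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        sel = np.fromiter(selected, dtype=int)
        mask = np.zeros(self.nmol, dtype=bool)
        if sel.size == 0:
            return mask
        A = self.adjacency
        mask = A[sel].any(axis=0)
        if order == 2:
            mask = A[mask].any(axis=0) | mask
        return mask

    def coverage(self, selected: Iterable[int], order: int = 1) -> float:
        """Weighted covered fraction of the space, in [0, 1]."""
        mask = self.covered_mask(selected, order=order)
        if self.w_tot == 0:
            return 0.0
        return float(self.weights[mask].sum() / self.w_tot)

    def f_cov(self, selected: Iterable[int]) -> float:
        """The (unnormalized) cover-function value: total weight covered."""
        return float(self.weights[self.covered_mask(selected, order=1)].sum())


def neighbors(space: MolecularSpace, i: int, subset: Optional[Iterable[int]] = None) -> set[int]:
    """Functional alias for :meth:`MolecularSpace.neighbors`."""
    return space.neighbors(i, subset)


def coverage(space: MolecularSpace, selected: Iterable[int], order: int = 1) -> float:
    """Functional alias for :meth:`MolecularSpace.coverage`."""
    return space.coverage(selected, order=order)


def neighbor_graph_table(space: MolecularSpace):
    """Edge list (i, j, d_ij) for all neighbor pairs, as a DataFrame."""
    import pandas as pd

    D = space.distances
    A = space.adjacency
    ii, jj = np.nonzero(A)
    return pd.DataFrame({"i": ii, "j": jj, "d_ij": D[ii, jj]})
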