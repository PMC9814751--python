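"""Molecule prioritization over a molecular space.

Three rankers are provided:

* ``rank_sfmmol`` — greedy maximization of a submodular cover objective with
  a penalty that suppresses re-covering the neighborhoods of molecules
  already evaluated.  At the default settings (unit weights, unit penalty on
  evaluated molecules, penalty balance λ = 1) the marginal score of a
  candidate m_i reduces to::

      score(m_i) = |{uncovered neighbors of m_i}|
                   - NMOL * |{evaluated neighbors of m_i}|

  so the penalty term (magnitude NMOL per evaluated neighbor) always
  dominates the reward term, steering selection away from any region that
  already contains an evaluated molecule.

* ``rank_random`` — uniform random permutation prefix.

* ``rank_unc`` — uncertainty sampling: at each step fit a Gaussian-process
  posterior on the evaluated molecules (Tanimoto-similarity kernel on the
  fingerprints, unit prior variance, small jitter) and pick the candidate
  with the largest posterior variance (least-confident selection).  The
  posterior variance depends only on the evaluated inputs, never on response
  values, so no measured property is needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .simgraph import DEFAULT_D_TH, MolecularSpace

logger = logging.getLogger(__name__)


@dataclass
class SFMParams:
    """Settings for the greedy cover selection.

    lam is the penalty balance λ in [0, 1] (1 = full penalty weight);
    n_select is the ranking length; tie_rule breaks score ties
    deterministically ("index" = lowest index; "smiles" = lowest canonical
    SMILES, falling back to index for spaces without structures).
    """

    lam: float = 1.0
    d_th: float = DEFAULT_D_TH
    n_select: int = 1000
    tie_rule: Literal["index", "smiles"] = "smiles"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")


@dataclass
class SelectionState:
    """Evaluated / covered / not-covered bookkeeping during greedy selection."""

    nmol: int
    evaluated: list[int] = field(default_factory=list)
    covered: set[int] = field(default_factory=set)

    @property
    def not_covered(self) -> set[int]:
        return set(range(self.nmol)) - self.covered

    def penalties(self) -> np.ndarray:
        p = np.zeros(self.nmol)
        p[self.evaluated] = 1.0
        return p


@dataclass
class Ranking:
    """An ordered priority list with the marginal score at each pick."""

    order: list[str]
    indices: list[int]
    scores: list[float]
    algorithm: Literal["sfmmol", "random", "unc"]
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.order)


def _tie_key(space: MolecularSpace, params: SFMParams) -> np.ndarray:
    """Permutation rank per index; ties resolve to the lowest rank."""
    if params.tie_rule == "smiles" and space.molecules is not None:
        order = sorted(range(space.nmol),
                       key=lambda i: (space.molecules[i].smiles, i))
        rank = np.empty(space.nmol, dtype=int)
        rank[order] = np.arange(space.nmol)
        return rank
    return np.arange(space.nmol)


def sfmmol_score(space: MolecularSpace, state: SelectionState, i: int,
                 params: SFMParams) -> float:
    """Marginal objective of candidate ``i`` given the current state.

    General form: sum of weights over uncovered neighbors of i, minus
    λ · W_tot · (sum of penalties over neighbors of i).  With unit weights
    and penalties only on evaluated molecules this is the signed count
    ``|uncovered ∩ N(i)| - NMOL · |evaluated ∩ N(i)|``.
    """
    if i in state.evaluated:
        raise ValueError(f"candidate {i} already evaluated")
    A = space.adjacency
    nbrs = A[i]
    uncovered = np.ones(space.nmol, dtype=bool)
    uncovered[list(state.covered)] = False
    reward = float(space.weights[nbrs & uncovered].sum())
    penalty = float((state.penalties() * nbrs).sum())
    return reward - params.lam * space.w_tot * penalty


def rank_sfmmol(space: MolecularSpace, params: Optional[SFMParams] = None) -> Ranking:
    """Greedy cover maximization with the evaluated-neighborhood penalty.

    Each step picks the candidate with the largest marginal score (ties
    broken by ``params.tie_rule``), marks it evaluated and marks its
    neighborhood covered.  Deterministic.
    """
    params = params or SFMParams(d_th=space.d_th)
    if abs(params.d_th - space.d_th) > 1e-12:
        raise ValueError("params.d_th disagrees with the space's threshold; "
                         "rebuild the space or the params")
    n = space.nmol
    n_select = params.n_select
    if n_select > n:
        warnings.warn(f"n_select={n_select} exceeds NMOL={n}; truncating")
        n_select = n

    A = space.adjacency
    Af = A.astype(np.float32)
    w = space.weights.astype(np.float32)
    tie = _tie_key(space, params)

    uncovered = np.ones(n, dtype=bool)
    evaluated_mask = np.zeros(n, dtype=bool)
    pen = np.zeros(n, dtype=np.float32)  # p(m_j): 1 on evaluated molecules
    order: list[int] = []
    scores: list[float] = []

    for _ in range(n_select):
        reward = Af @ (w * uncovered)
        penalty = Af @ pen
        score = reward - params.lam * space.w_tot * penalty
        score[evaluated_mask] = -np.inf
        best = np.max(score)
        cand = np.flatnonzero(score == best)
        pick = int(cand[np.argmin(tie[cand])])
        order.append(pick)
        scores.append(float(best))
        evaluated_mask[pick] = True
        pen[pick] = 1.0
        uncovered &= ~A[pick]

    ids = space.ids()
    return Ranking(order=[ids[i] for i in order], indices=order,
                   scores=scores, algorithm="sfmmol")


def rank_random(space: MolecularSpace, n_select: int, seed: int = 0) -> Ranking:
    """Uniform random permutation prefix of length ``n_select``."""
    n_select = min(n_select, space.nmol)
    rng = np.random.default_rng(seed)
    # Equivalent to ranking by i.i.d. Uniform(0, 1) priority draws.
    perm = rng.permutation(space.nmol)[:n_select]
    ids = space.ids()
    return Ranking(order=[ids[i] for i in perm], indices=[int(i) for i in perm],
                   scores=[float("nan")] * n_select, algorithm="random", seed=seed)


def rank_unc(space: MolecularSpace, n_select: int, prior_variance: float = 1.0,
             jitter: float = 1e-6) -> Ranking:
    """Gaussian-process uncertainty sampling (least-confident selection).

    Kernel: Tanimoto similarity k(i, j) = 1 - d_ij scaled by
    ``prior_variance``; posterior variance of a candidate given the
    evaluated set E is  k_xx - k_xE (K_EE + jitter·I)^-1 k_Ex, maintained
    with a streaming Cholesky factor so each step costs O(|E|·n).  The first
    pick is the molecule with the largest summed distance to all others.
    """
    n = space.nmol
    n_select = min(n_select, n)
    D = space.distances.astype(np.float64)
    if n > 1 and float(D.max()) == 0.0:
        raise ValueError("degenerate kernel: all fingerprints identical")
    K = prior_variance * (1.0 - D)

    first = int(np.argmax(D.sum(axis=1)))
    order = [first]
    scores = [float(prior_variance)]
    picked = np.zeros(n, dtype=bool)
    picked[first] = True

    # Streaming Cholesky of K_EE + jitter I and Z = L^-1 K_E,all
    L = np.zeros((n_select, n_select))
    Z = np.zeros((n_select, n))
    L[0, 0] = np.sqrt(K[first, first] + jitter)
    Z[0] = K[first] / L[0, 0]

    for step in range(1, n_select):
        var = np.diag(K) + jitter - (Z[:step] ** 2).sum(axis=0)
        var[picked] = -np.inf
        pick = int(np.argmax(var))
        order.append(pick)
        scores.append(float(var[pick]))
        picked[pick] = True
        if step == n_select - 1:
            break
        # extend the factor with the new row/column
        b = Z[:step, pick]
        diag = K[pick, pick] + jitter - b @ b
        lnn = np.sqrt(max(diag, jitter))
        L[step, :step] = b
        L[step, step] = lnn
        Z[step] = (K[pick] - b @ Z[:step]) / lnn

    ids = space.ids()
    return Ranking(order=[ids[i] for i in order], indices=order,
                   scores=scores, algorithm="unc")


def coverage_curve(space: MolecularSpace, ranking: Ranking,
                   order: int = 2) -> list[tuple[int, float]]:
    """Coverage after each prefix of the ranking, starting at (0, 0.0)."""
    curve = [(0, 0.0)]
    covered = np.zeros(space.nmol, dtype=bool)
    A = space.adjacency
    for k, idx in enumerate(ranking.indices, start=1):
        covered |= A[idx]
        if order == 2:
            mask = A[covered].any(axis=0) | covered
        else:
            mask = covered
        curve.append((k, float(space.weights[mask].sum() / space.w_tot)))
    return curve
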