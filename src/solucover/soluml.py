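"""Solubility models for molecule-solvent pairs.

Two supervised tasks over the evaluation table:

* classification of "good solvents" (category 3 or 4);
* regression of the relative indicators FWHM_r and Area_r.

Both use random forests under a repeated-split protocol: for each of
``n_iterations`` iterations, draw a fresh random 80/20 train/test split,
grid-search ``n_estimators`` in {100, 300, 500} and ``max_depth`` in
{2..10} by 5-fold cross-validation on the training part, refit the best
model and record train/test metrics.  Feature relevance uses a Boruta-style
shadow-feature procedure: permuted copies of every feature are appended and
a feature is confirmed only when its forest importance beats the best
shadow importance significantly more often than chance across repeated
forests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import (accuracy_score, f1_score, mean_absolute_error,
                             precision_score, r2_score, recall_score)
from sklearn.model_selection import GridSearchCV, train_test_split

from .chemspace import Molecule
from .simgraph import ecfp6

logger = logging.getLogger(__name__)

Task = Literal["classify_good", "regress_fwhm_r", "regress_area_r"]
FeatureMode = Literal["ecfp", "descriptors"]

#: Open 2-D descriptor set used in "descriptors" mode (analogues of the
#: commercial descriptor variables: MW, AMW, H fraction/count, logP,
#: volume/surface and VSA-style terms).
_DESCRIPTOR_NAMES = (
    "MolWt", "HeavyAtomMolWt", "NumHDonors", "NumHAcceptors", "MolLogP",
    "MolMR", "TPSA", "LabuteASA", "FractionCSP3", "NumRotatableBonds",
    "RingCount", "NumAromaticRings", "HeavyAtomCount", "NHOHCount",
    "NOCount", "qed",
)


def _descriptor_vector(smiles_or_mol) -> np.ndarray:
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    mol = (Chem.MolFromSmiles(smiles_or_mol)
           if isinstance(smiles_or_mol, str) else smiles_or_mol)
    if mol is None:
        raise ValueError(f"unparseable structure: {smiles_or_mol!r}")
    values = [getattr(Descriptors, name)(mol) for name in _DESCRIPTOR_NAMES]
    # hydrogen count and percentage, matching the AMW/H%/nH style variables
    molh = Chem.AddHs(mol)
    n_h = sum(1 for a in molh.GetAtoms() if a.GetAtomicNum() == 1)
    n_atoms = molh.GetNumAtoms()
    values += [n_h, 100.0 * n_h / max(n_atoms, 1),
               Descriptors.MolWt(mol) / max(n_atoms, 1)]  # nH, H%, AMW
    return np.asarray(values, dtype=float)


DESCRIPTOR_FEATURE_NAMES = tuple(_DESCRIPTOR_NAMES) + ("nH", "H_percent", "AMW")


@dataclass
class PairFeatures:
    """Concatenated molecule-block + solvent-block feature vector."""

    molecule_id: str
    solvent_id: str
    vector: np.ndarray
    mode: FeatureMode
    molecule_block_len: int

    @property
    def solvent_block(self) -> np.ndarray:
        return self.vector[self.molecule_block_len:]

    @property
    def molecule_block(self) -> np.ndarray:
        return self.vector[: self.molecule_block_len]


def pair_features(mol: Molecule | str, solvent: Molecule | str,
                  mode: FeatureMode = "ecfp", nbits: int = 1024,
                  molecule_id: str = "", solvent_id: str = "") -> PairFeatures:
    """Featurize one molecule-solvent pair.

    ``ecfp`` mode concatenates the ECFP6 bit vectors of molecule and solvent;
    ``descriptors`` mode concatenates open 2-D descriptor vectors.
    """
    def _smiles(x):
        return x.smiles if isinstance(x, Molecule) else x

    if isinstance(mol, Molecule) and not molecule_id:
        molecule_id = mol.id
    if isinstance(solvent, Molecule) and not solvent_id:
        solvent_id = solvent.id

    if mode == "ecfp":
        def _bits(s):
            fp = ecfp6(s, nbits=nbits)
            v = np.zeros(nbits)
            v[list(fp.bits)] = 1.0
            return v
        mol_block = _bits(_smiles(mol))
        solv_block = _bits(_smiles(solvent))
    elif mode == "descriptors":
        mol_block = _descriptor_vector(_smiles(mol))
        solv_block = _descriptor_vector(_smiles(solvent))
    else:
        raise ValueError(f"unknown feature mode: {mode!r}")

    return PairFeatures(molecule_id, solvent_id,
                        np.concatenate([mol_block, solv_block]),
                        mode, len(mol_block))


def solvent_block_collisions(features: Sequence[PairFeatures]) -> list[tuple[str, str]]:
    """Pairs of distinct solvents whose feature blocks are identical.

    Coarse fingerprint bits can fail to discriminate chemically distinct
    solvents; such collisions are reported so downstream interpretation can
    account for them.
    """
    blocks: dict[str, np.ndarray] = {}
    for f in features:
        blocks.setdefault(f.solvent_id, f.solvent_block)
    ids = sorted(blocks)
    collisions = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]
                  if np.array_equal(blocks[a], blocks[b])]
    for a, b in collisions:
        logger.warning("solvent feature collision: %s and %s share identical blocks", a, b)
    return collisions


def drop_constant_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove constant-valued columns; returns (X_reduced, kept_column_indices)."""
    keep = np.flatnonzero(np.ptp(X, axis=0) > 0)
    return X[:, keep], keep


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------

@dataclass
class MLProtocol:
    """The repeated-split evaluation protocol."""

    n_iterations: int = 100
    test_fraction: float = 0.2
    cv_folds: int = 5
    n_estimators_grid: tuple[int, ...] = (100, 300, 500)
    max_depth_grid: tuple[int, ...] = tuple(range(2, 11))
    seed: int = 0
    grid_search_each_iteration: bool = True

    def __post_init__(self) -> None:
        if not self.n_estimators_grid or not self.max_depth_grid:
            raise ValueError("hyperparameter grids must be nonempty")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


_CLS_METRICS = ("accuracy", "precision", "recall", "f1")
_REG_METRICS = ("r2", "mae")


@dataclass
class ModelReport:
    """Per-iteration metric distributions and their summaries."""

    task: Task
    mode: FeatureMode
    metrics: pd.DataFrame  # one row per iteration, columns like train_accuracy
    best_params: list[dict]

    @property
    def summary(self) -> pd.DataFrame:
        q = self.metrics.quantile([0.25, 0.5, 0.75])
        out = pd.DataFrame({
            "mean": self.metrics.mean(),
            "sd": self.metrics.std(ddof=1),
            "q25": q.loc[0.25],
            "median": q.loc[0.5],
            "q75": q.loc[0.75],
        })
        return out

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "mode": self.mode,
            "n_iterations": int(len(self.metrics)),
            "per_iteration": {c: self.metrics[c].tolist() for c in self.metrics},
            "summary": {c: self.summary.loc[c].to_dict() for c in self.summary.index},
            "best_params": self.best_params,
        }


def _target(dataset: pd.DataFrame, task: Task) -> np.ndarray:
    if task == "classify_good":
        return dataset["label_good"].to_numpy().astype(int)
    if task == "regress_fwhm_r":
        return dataset["fwhm_r"].to_numpy(dtype=float)
    if task == "regress_area_r":
        return dataset["area_r"].to_numpy(dtype=float)
    raise ValueError(f"unknown task: {task!r}")


def _make_estimator(task: Task, seed: int, **params):
    if task == "classify_good":
        return RandomForestClassifier(random_state=seed, **params)
    return RandomForestRegressor(random_state=seed, **params)


def _score_split(task: Task, model, X, y, prefix: str) -> dict[str, float]:
    pred = model.predict(X)
    if task == "classify_good":
        return {
            f"{prefix}_accuracy": accuracy_score(y, pred),
            f"{prefix}_precision": precision_score(y, pred, zero_division=0),
            f"{prefix}_recall": recall_score(y, pred, zero_division=0),
            f"{prefix}_f1": f1_score(y, pred, zero_division=0),
        }
    return {
        f"{prefix}_r2": r2_score(y, pred),
        f"{prefix}_mae": mean_absolute_error(y, pred),
    }


def run_protocol(features: Sequence[PairFeatures] | np.ndarray,
                 table: pd.DataFrame, task: Task,
                 protocol: Optional[MLProtocol] = None) -> ModelReport:
    """Run the repeated-split random-forest protocol for one task.

    ``features`` gives one vector per row of ``table`` (an evaluation table
    with fwhm_r / area_r / label_good columns).  Returns per-iteration train
    and test metrics plus summaries.  Iterations whose training split is
    single-class (classification only) are resampled with a shifted seed and
    logged.
    """
    protocol = protocol or MLProtocol()
    if isinstance(features, np.ndarray):
        X = np.asarray(features, dtype=float)
        mode: FeatureMode = "ecfp"
    else:
        X = np.vstack([f.vector for f in features])
        mode = features[0].mode
    y = _target(table, task)
    if len(X) != len(y):
        raise ValueError("features/table length mismatch")
    if len(X) < 25:
        raise ValueError("dataset too small: need at least 25 rows")
    if task == "classify_good" and len(np.unique(y)) < 2:
        raise ValueError("classification labels are single-class")

    grid = {"n_estimators": list(protocol.n_estimators_grid),
            "max_depth": list(protocol.max_depth_grid)}
    scoring = "accuracy" if task == "classify_good" else "neg_mean_absolute_error"

    rows: list[dict[str, float]] = []
    best_params: list[dict] = []
    cached_params: Optional[dict] = None
    for it in range(protocol.n_iterations):
        seed = protocol.seed + it
        for attempt in range(20):
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, test_size=protocol.test_fraction,
                random_state=seed + 100_000 * attempt)
            if task != "classify_good" or len(np.unique(ytr)) > 1:
                break
            logger.info("iteration %d: single-class training split, resampling", it)
        if protocol.grid_search_each_iteration or cached_params is None:
            search = GridSearchCV(
                _make_estimator(task, seed), grid, cv=protocol.cv_folds,
                scoring=scoring, n_jobs=1)
            search.fit(Xtr, ytr)
            params = dict(search.best_params_)
            cached_params = params
            model = search.best_estimator_
        else:
            params = cached_params
            model = _make_estimator(task, seed, **params).fit(Xtr, ytr)
        best_params.append(params)
        row = _score_split(task, model, Xtr, ytr, "train")
        row.update(_score_split(task, model, Xte, yte, "test"))
        rows.append(row)

    return ModelReport(task=task, mode=mode, metrics=pd.DataFrame(rows),
                       best_params=best_params)


# ---------------------------------------------------------------------------
# Boruta-style feature relevance
# ---------------------------------------------------------------------------

@dataclass
class FeatureDecision:
    index: int
    name: str
    hits: int
    trials: int
    status: Literal["confirmed", "tentative", "rejected"]
    mean_importance: float


def important_features(features: Sequence[PairFeatures] | np.ndarray,
                       table: pd.DataFrame, task: Task,
                       n_trials: int = 25, alpha: float = 0.05,
                       n_estimators: int = 200, max_depth: Optional[int] = 7,
                       seed: int = 0,
                       feature_names: Optional[Sequence[str]] = None,
                       ) -> list[FeatureDecision]:
    """Boruta-style shadow-feature relevance ranking.

    Each trial appends a column-permuted "shadow" copy of every feature,
    fits a random forest, and scores a *hit* for each real feature whose
    importance exceeds the maximum shadow importance.  After ``n_trials``
    forests, a binomial test at level ``alpha`` against p = 0.5 classifies
    each feature as confirmed (more hits than chance), rejected (fewer), or
    tentative.  Returned sorted by mean importance, descending.
    """
    if isinstance(features, np.ndarray):
        X = np.asarray(features, dtype=float)
    else:
        X = np.vstack([f.vector for f in features])
    y = _target(table, task)
    n, p = X.shape
    names = (list(feature_names) if feature_names is not None
             else [f"f{i}" for i in range(p)])
    if len(names) != p:
        raise ValueError("feature_names length mismatch")

    rng = np.random.default_rng(seed)
    hits = np.zeros(p, dtype=int)
    mean_imp = np.zeros(p)
    for t in range(n_trials):
        shadow = X.copy()
        for j in range(p):
            shadow[:, j] = shadow[rng.permutation(n), j]
        Xa = np.hstack([X, shadow])
        model = _make_estimator(task, seed=seed + t,
                                n_estimators=n_estimators, max_depth=max_depth)
        model.fit(Xa, y)
        imp = model.feature_importances_
        shadow_max = imp[p:].max()
        hits += imp[:p] > shadow_max
        mean_imp += imp[:p]
    mean_imp /= n_trials

    decisions = []
    for j in range(p):
        test = binomtest(int(hits[j]), n_trials, 0.5)
        if test.pvalue < alpha and hits[j] > n_trials / 2:
            status = "confirmed"
        elif test.pvalue < alpha and hits[j] < n_trials / 2:
            status = "rejected"
        else:
            status = "tentative"
        decisions.append(FeatureDecision(j, names[j], int(hits[j]), n_trials,
                                         status, float(mean_imp[j])))
    decisions.sort(key=lambda d: -d.mean_importance)
    return decisions
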