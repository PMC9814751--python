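import numpy as np
import pytest

from solucover.chemspace import _molecule_from_smiles
from solucover.simgraph import Fingerprint, MolecularSpace


def space_from_distances(D: np.ndarray, d_th: float) -> MolecularSpace:
    """A MolecularSpace with an explicit distance matrix (graph-topology
    tests); fingerprints are placeholders."""
    n = len(D)
    fps = [Fingerprint(frozenset({i}), nbits=max(n, 2)) for i in range(n)]
    sp = MolecularSpace(fps, d_th=d_th)
    sp._distances = np.asarray(D, dtype=np.float32)
    return sp


def path_graph_space(n: int = 6) -> MolecularSpace:
    """Adjacency is a path 0-1-...-(n-1): d = |i-j|/n, threshold 1.5/n."""
    idx = np.arange(n)
    D = np.abs(idx[:, None] - idx[None, :]) / n
    return space_from_distances(D, d_th=1.5 / n)


def star_graph_space(n_leaves: int = 5) -> MolecularSpace:
    """Node 0 is a hub adjacent to every leaf; leaves are mutually far."""
    n = n_leaves + 1
    D = np.ones((n, n)) * 0.9
    D[0, :] = D[:, 0] = 0.2
    np.fill_diagonal(D, 0.0)
    return space_from_distances(D, d_th=0.3)


def random_space(rng: np.random.Generator, n_max: int = 64) -> MolecularSpace:
    """A random fingerprint space with a threshold that yields mixed degrees."""
    n = int(rng.integers(5, n_max + 1))
    nbits = 64
    bits = rng.random((n, nbits)) < 0.2
    fps = [Fingerprint(frozenset(np.flatnonzero(r).tolist()), nbits) for r in bits]
    d_th = float(rng.uniform(0.5, 0.95))
    return MolecularSpace(fps, d_th=d_th)


def mol(smiles: str, mol_id: str = "m", role: str = "accessible"):
    return _molecule_from_smiles(smiles, mol_id, role)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
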