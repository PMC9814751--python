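"""Synthetic inputs with known ground truth.

Three generators let every pipeline stage be exercised and scored without
any external dataset:

* clustered binary-fingerprint molecule spaces (planted cluster labels),
  emulating the clumpy structure of a combinatorial library in which many
  products share a core and differ by a small substituent;
* Gaussian-peaked absorption spectra with optional blue-side shoulder
  components and i.i.d. noise, emulating Soret-band spectra;
* molecule-solvent evaluation tables whose indicators and labels follow a
  planted linear structure-solubility rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simgraph import Fingerprint, MolecularSpace
from .spectra import (GAUSS_AREA_FACTOR, GAUSS_FWHM_FACTOR, PeakFit, Spectrum)

#: A small set of simple substituted benzenes for end-to-end runs that need
#: real, parseable structures (cores with acid/alcohol handles, substituents
#: with amine/alcohol/halide handles).
REAL_SMILES_FIXTURE: tuple[tuple[str, str], ...] = (
    ("benzoic_acid", "OC(=O)c1ccccc1"),
    ("terephthalic_acid", "OC(=O)c1ccc(C(=O)O)cc1"),
    ("salicylic_acid", "OC(=O)c1ccccc1O"),
    ("phenol", "Oc1ccccc1"),
    ("hydroquinone", "Oc1ccc(O)cc1"),
    ("catechol", "Oc1ccccc1O"),
    ("benzyl_alcohol", "OCc1ccccc1"),
    ("p_toluic_acid", "Cc1ccc(C(=O)O)cc1"),
    ("anisic_acid", "COc1ccc(C(=O)O)cc1"),
    ("p_cresol", "Cc1ccc(O)cc1"),
    ("methylamine", "CN"),
    ("ethylamine", "CCN"),
    ("dimethylamine", "CNC"),
    ("aniline", "Nc1ccccc1"),
    ("benzylamine", "NCc1ccccc1"),
    ("methanol", "CO"),
    ("ethanol", "CCO"),
    ("isopropanol", "CC(C)O"),
    ("methyl_iodide", "CI"),
    ("ethyl_bromide", "CCBr"),
    ("benzyl_chloride", "ClCc1ccccc1"),
)


# ---------------------------------------------------------------------------
# Clustered fingerprint spaces
# ---------------------------------------------------------------------------

@dataclass
class SpaceSpec:
    """Parameters of a planted-cluster fingerprint space.

    ``intra_cluster_flip`` is the per-bit flip probability applied
    independently to every bit of a member's prototype.  ``d_th`` defaults
    to 0.5, chosen so that at the default flip rate (0.05) within-cluster
    pairs fall below the threshold and between-cluster pairs far above it.
    """

    n_molecules: int = 500
    n_clusters: int = 20
    nbits: int = 512
    n_on: int = 64
    intra_cluster_flip: float = 0.05
    d_th: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_molecules:
            raise ValueError("n_clusters must not exceed n_molecules")
        if not 0.0 <= self.intra_cluster_flip < 0.5:
            raise ValueError("flip probability must be in [0, 0.5)")
        if self.n_on > self.nbits:
            raise ValueError("n_on must not exceed nbits")


def synth_space(spec: SpaceSpec,
                prototypes: Optional[Sequence[frozenset[int]]] = None,
                ) -> tuple[MolecularSpace, np.ndarray]:
    """Generate a clustered fingerprint space with planted labels.

    Cluster prototypes are random ``n_on``-bit sets (or the explicit
    ``prototypes``, e.g. disjoint supports for guaranteed separation);
    members copy their prototype and then flip every bit independently with
    probability ``intra_cluster_flip``.  Returns the space and the planted
    cluster assignment.
    """
    rng = np.random.default_rng(spec.seed)
    if prototypes is None:
        prototypes = [frozenset(rng.choice(spec.nbits, size=spec.n_on,
                                           replace=False).tolist())
                      for _ in range(spec.n_clusters)]
    elif len(prototypes) != spec.n_clusters:
        raise ValueError("need one prototype per cluster")

    assignment = np.sort(rng.permuted(
        np.arange(spec.n_molecules) % spec.n_clusters))
    proto_rows = np.zeros((spec.n_clusters, spec.nbits), dtype=bool)
    for c, proto in enumerate(prototypes):
        proto_rows[c, list(proto)] = True

    bits = proto_rows[assignment]
    flips = rng.random((spec.n_molecules, spec.nbits)) < spec.intra_cluster_flip
    bits = bits ^ flips

    fps = [Fingerprint(bits=frozenset(np.flatnonzero(row).tolist()),
                       nbits=spec.nbits) for row in bits]
    return MolecularSpace(fps, d_th=spec.d_th), assignment


# ---------------------------------------------------------------------------
# Gaussian-peaked spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectrumSpec:
    """Parameters of a synthetic absorption spectrum.

    ``components`` is a list of (center nm, height, fwhm nm); the tallest
    component is treated as the main peak for the ground truth.  The grid
    defaults to 350-700 nm in 1 nm steps, bracketing the Soret search
    window.
    """

    components: tuple[tuple[float, float, float], ...] = ()
    noise_sd: float = 0.0
    grid: tuple[float, float, float] = (350.0, 700.0, 1.0)
    seed: int = 0
    molecule_id: str = ""
    solvent_id: str = ""


def synth_spectrum(spec: SpectrumSpec) -> tuple[Spectrum, PeakFit]:
    """Sum-of-Gaussians spectrum plus its analytic ground-truth indicators.

    Truth comes from the tallest (main) component: lambda_max = its center,
    intensity = its height, FWHM = its width, and
    Area = height * FWHM * sqrt(pi / (4 ln 2)).  With no components the
    truth is peak_found = False.
    """
    lo, hi, step = spec.grid
    wl = np.arange(lo, hi + step / 2, step)
    ab = np.zeros_like(wl)
    for center, height, fwhm in spec.components:
        if not lo <= center <= hi:
            raise ValueError(f"component center {center} outside grid")
        if height < 0 or fwhm <= 0:
            raise ValueError("component heights must be >= 0 and widths > 0")
        sigma = fwhm / GAUSS_FWHM_FACTOR
        ab += height * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        ab = ab + rng.normal(0.0, spec.noise_sd, size=wl.shape)

    spectrum = Spectrum(wl, ab, molecule_id=spec.molecule_id,
                        solvent_id=spec.solvent_id)

    live = [c for c in spec.components if c[1] > 0]
    if not live:
        truth = PeakFit(peak_found=False, reason="no components")
    else:
        center, height, fwhm = max(live, key=lambda c: c[1])
        truth = PeakFit(peak_found=True, lambda_max=center, intensity=height,
                        fwhm=fwhm, area=height * fwhm * GAUSS_AREA_FACTOR,
                        components=[(h, c, f / GAUSS_FWHM_FACTOR)
                                    for c, h, f in spec.components])
    return spectrum, truth


def synth_spectrum_panel(n_molecules: int = 15, n_solvents: int = 16,
                         n_insoluble: int = 25, noise_sd: float = 0.002,
                         seed: int = 0) -> tuple[list[Spectrum], pd.DataFrame]:
    """A full molecule x solvent spectrum design with planted categories.

    Emulates the study design: a 15 x 16 panel (240 pairs) in which 25
    pairs are insoluble (flat, no main peak) and the rest show a Soret-like
    main peak whose sharpness and size vary from aggregated-broad to
    sharp-and-large, with a blue shoulder on part of the panel.  Returns
    the spectra and a truth table (molecule_id, solvent_id, soluble,
    center, height, fwhm, area).
    """
    rng = np.random.default_rng(seed)
    n_pairs = n_molecules * n_solvents
    if n_insoluble > n_pairs:
        raise ValueError("more insoluble pairs than pairs")
    insoluble = set(rng.choice(n_pairs, size=n_insoluble, replace=False).tolist())

    specs: list[Spectrum] = []
    truth_rows = []
    pair = 0
    for m in range(n_molecules):
        for s in range(n_solvents):
            mol_id, solv_id = f"M{m + 1}", f"S{s + 1}"
            if pair in insoluble:
                sp, _ = synth_spectrum(SpectrumSpec(
                    components=(), noise_sd=noise_sd, seed=seed + pair,
                    molecule_id=mol_id, solvent_id=solv_id))
                truth_rows.append(dict(molecule_id=mol_id, solvent_id=solv_id,
                                       soluble=False, center=np.nan,
                                       height=np.nan, fwhm=np.nan, area=np.nan))
            else:
                center = float(rng.uniform(410.0, 425.0))
                # solubility regimes: aggregated/broad, less-soluble/small,
                # and sharp-and-large good solvents
                regime = rng.random()
                if regime < 0.2:      # aggregated: broad, moderate height
                    height = float(rng.uniform(0.2, 0.5))
                    fwhm = float(rng.uniform(30.0, 45.0))
                elif regime < 0.4:    # less soluble: sharp but small
                    height = float(rng.uniform(0.05, 0.25))
                    fwhm = float(rng.uniform(10.0, 16.0))
                else:                 # well dissolved: sharp and large
                    height = float(rng.uniform(0.6, 1.2))
                    fwhm = float(rng.uniform(9.0, 15.0))
                comps = [(center, height, fwhm)]
                if rng.random() < 0.5:  # blue shoulder
                    comps.append((center - float(rng.uniform(10.0, 20.0)),
                                  0.3 * height, fwhm * 1.2))
                sp, _ = synth_spectrum(SpectrumSpec(
                    components=tuple(comps), noise_sd=noise_sd,
                    seed=seed + pair, molecule_id=mol_id, solvent_id=solv_id))
                truth_rows.append(dict(
                    molecule_id=mol_id, solvent_id=solv_id, soluble=True,
                    center=center, height=height, fwhm=fwhm,
                    area=height * fwhm * GAUSS_AREA_FACTOR))
            specs.append(sp)
            pair += 1
    return specs, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Labeled molecule-solvent tables
# ---------------------------------------------------------------------------

def synth_solubility_table(space: MolecularSpace, n_solvents: int,
                           rule: np.ndarray, noise: float = 0.0, seed: int = 0,
                           n_solvent_bits: int = 16,
                           threshold: Optional[float] = None,
                           ) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Evaluation table whose labels follow a planted linear rule.

    Pair features are molecule fingerprint bits concatenated with random
    binary solvent blocks of length ``n_solvent_bits``.  The continuous
    score rule . features is squashed through a logistic centered at
    ``threshold`` (the median score when None) to yield fwhm_r = area_r in
    [0, 1]; categories follow fixed thresholds {0.2, 0.4, 0.6, 0.8} on the
    squashed value, label_good = category in {3, 4}, and labels are flipped
    independently with probability ``noise``.

    Returns (features matrix, evaluation table, truth dict with the clean
    scores/labels and the rule).
    """
    rule = np.asarray(rule, dtype=float)
    if not np.any(rule):
        raise ValueError("degenerate rule: all zero weights")
    rng = np.random.default_rng(seed)

    nbits = space.fingerprints[0].nbits
    if rule.shape != (nbits + n_solvent_bits,):
        raise ValueError(f"rule length {rule.shape[0]} != pair-feature length "
                         f"{nbits + n_solvent_bits}")

    mol_bits = np.zeros((space.nmol, nbits))
    for i, fp in enumerate(space.fingerprints):
        mol_bits[i, list(fp.bits)] = 1.0
    solv_bits = (rng.random((n_solvents, n_solvent_bits)) < 0.5).astype(float)

    rows = []
    X = np.zeros((space.nmol * n_solvents, nbits + n_solvent_bits))
    k = 0
    for i in range(space.nmol):
        for s in range(n_solvents):
            X[k] = np.concatenate([mol_bits[i], solv_bits[s]])
            k += 1
    scores = X @ rule
    center = float(np.median(scores)) if threshold is None else float(threshold)
    scale = float(np.std(scores)) or 1.0
    squashed = 1.0 / (1.0 + np.exp(-(scores - center) / (0.25 * scale)))
    categories = np.minimum(np.digitize(squashed, [0.2, 0.4, 0.6, 0.8]), 4)
    clean_good = categories >= 3
    flips = rng.random(len(X)) < noise
    labels = clean_good ^ flips

    k = 0
    for i in range(space.nmol):
        for s in range(n_solvents):
            rows.append(dict(molecule_id=str(i), solvent_id=f"S{s + 1}",
                             peak_found=bool(categories[k] > 0),
                             fwhm_r=float(squashed[k]), area_r=float(squashed[k]),
                             category=int(categories[k]),
                             label_good=bool(labels[k])))
            k += 1
    table = pd.DataFrame(rows)
    truth = dict(rule=rule, scores=scores, squashed=squashed,
                 clean_label=clean_good, flipped=flips,
                 solvent_blocks=solv_bits, threshold=center)
    return X, table, truth
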