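"""UV-Vis spectrum reduction to solubility indicators.

Each molecule-solvent absorption spectrum is reduced to four indicators of
the main (Soret-band) peak near 420 nm:

* lambda_max — peak position (nm), from a single-Gaussian fit;
* Intensity  — peak height (absorbance), from the same fit;
* FWHM       — full width at half maximum (nm); broadening signals
  aggregation of the dye;
* Area       — analytic area of the *main* component of a two-Gaussian fit
  (main peak + shorter-wavelength shoulder), proportional to the number of
  dissolved molecules.

Per molecule the indicators are rescaled relative to its most suitable
solvent: FWHM_r = FWHM_min / FWHM and Area_r = Area / Area_max, both in
[0, 1] with (1, 1) marking the best solvent.  K-means (K = 5) over the
(FWHM_r, Area_r) plane assigns each molecule-solvent pair a category 0-4
(0 insoluble, 1 aggregated, 2 less-soluble, 3 slightly aggregated, 4 good
solvent); categories 3 and 4 are "good solvents".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (380.0, 470.0)  # Soret region, nm
GAUSS_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # fwhm = factor * sigma
#: area of a Gaussian of height h and width fwhm: h * fwhm * sqrt(pi / (4 ln 2))
GAUSS_AREA_FACTOR = float(np.sqrt(np.pi / (4.0 * np.log(2.0))))

EV_NM = 1239.842  # E[eV] = EV_NM / lambda[nm]


def nm_to_ev(wavelength_nm: float) -> float:
    """Photon energy (eV) of a wavelength (nm)."""
    return EV_NM / wavelength_nm


def fwhm_nm_to_ev(lambda_max_nm: float, fwhm_nm: float) -> float:
    """FWHM expressed in eV, from the band edges around lambda_max."""
    lo = lambda_max_nm - fwhm_nm / 2.0
    hi = lambda_max_nm + fwhm_nm / 2.0
    return nm_to_ev(lo) - nm_to_ev(hi)


@dataclass(frozen=True)
class Spectrum:
    """One absorption spectrum on an ascending wavelength grid (nm)."""

    wavelength: np.ndarray
    absorbance: np.ndarray
    molecule_id: str = ""
    solvent_id: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wl.shape != ab.shape or wl.ndim != 1:
            raise ValueError("wavelength and absorbance must be equal-length 1-D")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(ab))):
            raise ValueError("non-finite values in spectrum")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "absorbance", ab)


@dataclass
class PeakFit:
    """Result of fitting the main peak of one spectrum."""

    peak_found: bool
    lambda_max: Optional[float] = None
    intensity: Optional[float] = None
    fwhm: Optional[float] = None
    area: Optional[float] = None
    components: list[tuple[float, float, float]] = field(default_factory=list)
    fit_residual: float = float("nan")
    reason: str = ""


@dataclass
class Solvent:
    id: str
    name: str
    epsilon: float

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("dielectric constant must be positive")


#: The 16-solvent panel spanning dielectric constants from n-hexane to water
#: (epsilon values from the Gaussian-16 SCRF solvent table).
DEFAULT_SOLVENTS: tuple[Solvent, ...] = (
    Solvent("S1", "water", 78.36),
    Solvent("S2", "dimethyl sulfoxide", 46.83),
    Solvent("S3", "N,N-dimethylformamide", 37.22),
    Solvent("S4", "acetonitrile", 35.69),
    Solvent("S5", "methanol", 32.61),
    Solvent("S6", "ethanol", 24.85),
    Solvent("S7", "acetone", 20.49),
    Solvent("S8", "2-propanol", 19.26),
    Solvent("S9", "dichloromethane", 8.93),
    Solvent("S10", "1,2-dichloroethane", 10.13),
    Solvent("S11", "tetrahydrofuran", 7.43),
    Solvent("S12", "chloroform", 4.71),
    Solvent("S13", "toluene", 2.37),
    Solvent("S14", "1,4-dioxane", 2.21),
    Solvent("S15", "cyclohexane", 2.02),
    Solvent("S16", "n-hexane", 1.88),
)

#: SMILES of the solvent panel, for fingerprint/descriptor featurization.
SOLVENT_SMILES: dict[str, str] = {
    "S1": "O", "S2": "CS(C)=O", "S3": "CN(C)C=O", "S4": "CC#N",
    "S5": "CO", "S6": "CCO", "S7": "CC(C)=O", "S8": "CC(C)O",
    "S9": "ClCCl", "S10": "ClCCCl", "S11": "C1CCOC1", "S12": "ClC(Cl)Cl",
    "S13": "Cc1ccccc1", "S14": "C1COCCO1", "S15": "C1CCCCC1", "S16": "CCCCCC",
}


# ---------------------------------------------------------------------------
# Peak fitting
# ---------------------------------------------------------------------------

def _gauss(x: np.ndarray, h: float, mu: float, sigma: float) -> np.ndarray:
    return h * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _two_gauss(x, h1, mu1, s1, h2, delta, s2):
    # shoulder center parametrized as mu1 - delta, delta >= 0, to keep it on
    # the shorter-wavelength side of the main component
    return _gauss(x, h1, mu1, s1) + _gauss(x, h2, mu1 - delta, s2)


def fit_main_peak(spec: Spectrum, window: tuple[float, float] = DEFAULT_WINDOW,
                  min_height: float = 0.005, snr_factor: float = 5.0) -> PeakFit:
    """Fit the main peak inside ``window`` (nm).

    A single Gaussian provides lambda_max, Intensity and FWHM; a two-Gaussian
    fit (main + blue-shifted shoulder) provides Area as the analytic area of
    the main component.  ``peak_found`` is False when the fit fails to
    converge, the fitted height falls below ``snr_factor`` times the RMS fit
    residual, the height falls below ``min_height`` absorbance, or the fitted
    center leaves the window.
    """
    lo, hi = window
    wl, ab = spec.wavelength, spec.absorbance
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(f"window {window} outside spectrum range "
                         f"({wl[0]}, {wl[-1]})")
    sel = (wl >= lo) & (wl <= hi)
    if sel.sum() < 10:
        raise ValueError("fewer than 10 grid points in the fit window")
    x, y = wl[sel], ab[sel]

    i0 = int(np.argmax(y))
    h0 = max(float(y[i0]), 1e-6)
    mu0 = float(x[i0])
    s0 = max((hi - lo) / 20.0, 2.0)
    # a real band must be resolvable: several grid points / > 1.5 nm sigma,
    # otherwise the fit can collapse onto a single noise spike
    step = float(np.median(np.diff(x)))
    s_min = max(1.5, 1.5 * step)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gauss, x, y, p0=[h0, mu0, max(s0, s_min)],
                bounds=([0.0, lo, s_min], [np.inf, hi, (hi - lo)]),
                maxfev=5000)
    except (RuntimeError, ValueError) as exc:
        return PeakFit(peak_found=False, reason=f"single-Gaussian fit failed: {exc}")

    h1, mu1, s1 = (float(v) for v in popt)
    resid = y - _gauss(x, h1, mu1, s1)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    if h1 < min_height:
        return PeakFit(peak_found=False, fit_residual=rms,
                       reason=f"height {h1:.4g} below floor {min_height}")
    if h1 < snr_factor * rms:
        return PeakFit(peak_found=False, fit_residual=rms,
                       reason=f"height {h1:.4g} below {snr_factor}x RMS residual")
    if not (lo < mu1 < hi):
        return PeakFit(peak_found=False, fit_residual=rms,
                       reason="fitted center at window edge")
    if s1 <= s_min * 1.02:
        return PeakFit(peak_found=False, fit_residual=rms,
                       reason="fitted width pinned at resolution floor")

    fwhm = GAUSS_FWHM_FACTOR * s1

    # Two-Gaussian fit for Area: main initialized from the single fit,
    # shoulder 15 nm blue-shifted at 30% height, at least 3 nm to the blue.
    # The two-component model is adopted only when it clearly improves the
    # residual; otherwise one Gaussian already explains the peak and the
    # two-component split is unidentifiable, so the single-fit area is kept.
    area = h1 * fwhm * GAUSS_AREA_FACTOR
    components = [(h1, mu1, s1)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt2, _ = curve_fit(
                _two_gauss, x, y,
                p0=[h1, mu1, s1, 0.3 * h1, 15.0, s1],
                bounds=([0.0, lo, s_min, 0.0, 3.0, s_min],
                        [np.inf, hi, hi - lo, np.inf, hi - lo, hi - lo]),
                maxfev=8000)
        h1b, mu1b, s1b, h2b, delta_b, s2b = (float(v) for v in popt2)
        rms2 = float(np.sqrt(np.mean((y - _two_gauss(x, *popt2)) ** 2)))
        if rms2 < 0.7 * rms and h1b >= h2b:
            main_fwhm = GAUSS_FWHM_FACTOR * s1b
            area = h1b * main_fwhm * GAUSS_AREA_FACTOR
            components = [(h1b, mu1b, s1b), (h2b, mu1b - delta_b, s2b)]
    except (RuntimeError, ValueError):
        logger.debug("two-Gaussian fit failed for %s/%s; Area from single fit",
                     spec.molecule_id, spec.solvent_id)

    return PeakFit(peak_found=True, lambda_max=mu1, intensity=h1, fwhm=fwhm,
                   area=area, components=components, fit_residual=rms)


# ---------------------------------------------------------------------------
# Relative indicators and categorization
# ---------------------------------------------------------------------------

def relative_indicators(fits: Sequence[PeakFit]) -> list[tuple[float, float]]:
    """Per-molecule relative indicators (FWHM_r, Area_r) for one molecule's
    solvent series.

    FWHM_r = FWHM_min / FWHM and Area_r = Area / Area_max over the solvents
    where a peak was found; no-peak entries get (0, 0).  If no solvent shows
    a peak all entries are (0, 0) with a warning.
    """
    found = [f for f in fits if f.peak_found]
    if not found:
        warnings.warn("no peak found in any solvent; all relative indicators 0")
        return [(0.0, 0.0)] * len(fits)
    fwhm_min = min(f.fwhm for f in found)
    area_max = max(f.area for f in found)
    out = []
    for f in fits:
        if not f.peak_found:
            out.append((0.0, 0.0))
        else:
            out.append((fwhm_min / f.fwhm, f.area / area_max if area_max > 0 else 0.0))
    return out


@dataclass
class Evaluation:
    """Indicators, relative indicators and category for one pair."""

    molecule_id: str
    solvent_id: str
    peak_found: bool
    lambda_max: Optional[float]
    intensity: Optional[float]
    fwhm: Optional[float]
    area: Optional[float]
    fwhm_r: float
    area_r: float
    category: int = 0

    @property
    def label_good(self) -> bool:
        return self.category in (3, 4)


def categorize(evals: Sequence[Evaluation], k: int = 5, seed: int = 0,
               include_no_peak: bool = False) -> list[Evaluation]:
    """Assign categories 0..k-1 by K-means on the (FWHM_r, Area_r) plane.

    Clusters are ordered by ascending centroid coordinate sum, so the cluster
    nearest the origin becomes category 0 and the cluster nearest (1, 1)
    becomes category k-1.  Pairs with no detected peak are forced to category
    0 (insoluble) unless ``include_no_peak``, in which case their (0, 0)
    points take part in the clustering too.
    """
    if include_no_peak:
        cluster_idx = list(range(len(evals)))
    else:
        cluster_idx = [i for i, e in enumerate(evals) if e.peak_found]

    pts = np.array([[evals[i].fwhm_r, evals[i].area_r] for i in cluster_idx])
    n_distinct = len({tuple(p) for p in pts}) if len(pts) else 0
    if n_distinct < k:
        raise ValueError(
            f"only {n_distinct} distinct (FWHM_r, Area_r) points for k={k}; "
            "use a smaller k")

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(pts)
    order = np.argsort(km.cluster_centers_.sum(axis=1), kind="stable")
    to_category = np.empty(k, dtype=int)
    to_category[order] = np.arange(k)

    out = []
    lab = dict(zip(cluster_idx, (int(to_category[l]) for l in labels)))
    for i, e in enumerate(evals):
        cat = 0 if not e.peak_found else lab.get(i, 0)
        out.append(Evaluation(e.molecule_id, e.solvent_id, e.peak_found,
                              e.lambda_max, e.intensity, e.fwhm, e.area,
                              e.fwhm_r, e.area_r, category=cat))
    return out


def indicator_table(specs: Sequence[Spectrum],
                    window: tuple[float, float] = DEFAULT_WINDOW,
                    k: int = 5, seed: int = 0,
                    include_no_peak: bool = False,
                    **fit_kwargs) -> pd.DataFrame:
    """Full pipeline: fit every spectrum, form per-molecule relative
    indicators, categorize, and return one row per molecule-solvent pair.

    The returned frame has columns molecule_id, solvent_id, peak_found,
    lambda_max, intensity, fwhm, area, fwhm_r, area_r, category, label_good.
    """
    fits = [fit_main_peak(s, window=window, **fit_kwargs) for s in specs]

    by_mol: dict[str, list[int]] = {}
    for i, s in enumerate(specs):
        by_mol.setdefault(s.molecule_id, []).append(i)

    rel = [(0.0, 0.0)] * len(specs)
    for mol, idxs in by_mol.items():
        for j, pair in zip(idxs, relative_indicators([fits[i] for i in idxs])):
            rel[j] = pair

    evals = [Evaluation(s.molecule_id, s.solvent_id, f.peak_found,
                        f.lambda_max, f.intensity, f.fwhm, f.area,
                        rel[i][0], rel[i][1])
             for i, (s, f) in enumerate(zip(specs, fits))]
    evals = categorize(evals, k=k, seed=seed, include_no_peak=include_no_peak)

    n_found = sum(e.peak_found for e in evals)
    logger.info("indicator table: %d pairs, %d with main peak, %d without",
                len(evals), n_found, len(evals) - n_found)

    return pd.DataFrame([{
        "molecule_id": e.molecule_id, "solvent_id": e.solvent_id,
        "peak_found": e.peak_found, "lambda_max": e.lambda_max,
        "intensity": e.intensity, "fwhm": e.fwhm, "area": e.area,
        "fwhm_r": e.fwhm_r, "area_r": e.area_r, "category": e.category,
        "label_good": e.label_good,
    } for e in evals])
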