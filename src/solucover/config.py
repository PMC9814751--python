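"""Run configuration and the end-to-end pipeline driver.

A :class:`RunConfig` collects every tunable the stages expose (all defaults
equal the study settings: D_TH 0.3, λ 1, K 5, the two hyperparameter
grids).  ``run_pipeline`` executes the configured stages in order —
enumeration → ranking → spectrum reduction → model training — writing each
artifact with a sidecar metadata file carrying the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as sio
from .chemspace import (DEFAULT_TEMPLATES, build_molspace, enumerate_products,
                        filter_substituents, load_molecules)
from .selector import SFMParams, coverage_curve, rank_random, rank_sfmmol, rank_unc
from .simgraph import MolecularSpace
from .soluml import MLProtocol, pair_features, run_protocol
from .spectra import indicator_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated settings for a pipeline run; YAML-loadable."""

    # chemical space
    cores_path: Optional[str] = None
    substituents_path: Optional[str] = None
    mw_limit: float = 200.0
    site_mode: str = "all_sites"
    # similarity graph / selection
    dth: float = 0.3
    lam: float = 1.0
    nbits: int = 2048
    n_select: int = 1000
    algo: str = "sfmmol"
    # spectra
    spectra_dir: Optional[str] = None
    window: tuple[float, float] = (380.0, 470.0)
    k: int = 5
    # ML
    train: bool = False
    feature_mode: str = "ecfp"
    protocol: MLProtocol = field(default_factory=MLProtocol)
    # shared
    seed: int = 0
    out_dir: str = "solucover_out"

    def validate(self) -> None:
        """Check every field against its stage's preconditions up front."""
        if not 0.0 <= self.dth <= 1.0:
            raise ValueError(f"dth must be in [0, 1], got {self.dth}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        if self.nbits < 16:
            raise ValueError("nbits too small")
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")
        if self.mw_limit < 0:
            raise ValueError("mw_limit must be nonnegative")
        if self.site_mode not in ("all_sites", "single_site"):
            raise ValueError(f"unknown site_mode {self.site_mode!r}")
        if self.algo not in ("sfmmol", "random", "unc"):
            raise ValueError(f"unknown algo {self.algo!r}")
        if self.window[0] >= self.window[1]:
            raise ValueError("window must be (lo, hi) with lo < hi")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.feature_mode not in ("ecfp", "descriptors"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = list(self.window)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        protocol = MLProtocol(**raw.pop("protocol", {}))
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        cfg = cls(protocol=protocol, **raw)
        return cfg


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; returns the artifact paths written.

    Any stage failure aborts with the stage name attached to the exception.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    cfg_dict = config.to_dict()

    def _emit(name: str, path: Path) -> None:
        artifacts[name] = path
        sio.write_sidecar_metadata(path, cfg_dict, config.seed)

    space: Optional[MolecularSpace] = None
    try:
        stage = "genspace"
        if config.cores_path:
            cores = load_molecules(config.cores_path, "accessible")
            subs = load_molecules(config.substituents_path, "substituent")
            subs = filter_substituents(subs, config.mw_limit)
            generated = enumerate_products(cores, subs, DEFAULT_TEMPLATES,
                                           site_mode=config.site_mode)
            molecules = build_molspace(cores, generated)
            space_path = out / "molspace.csv"
            sio.write_molspace(molecules, space_path)
            _emit("molspace", space_path)
            space = MolecularSpace.from_molecules(molecules, d_th=config.dth,
                                                  nbits=config.nbits)

        stage = "rank"
        if space is not None:
            if config.algo == "sfmmol":
                ranking = rank_sfmmol(space, SFMParams(
                    lam=config.lam, d_th=config.dth, n_select=config.n_select))
            elif config.algo == "random":
                ranking = rank_random(space, config.n_select, seed=config.seed)
            else:
                ranking = rank_unc(space, config.n_select)
            rank_path = out / "ranking.csv"
            sio.write_ranking(ranking, rank_path)
            _emit("ranking", rank_path)
            curves = {o: coverage_curve(space, ranking, order=o) for o in (1, 2)}
            curve_path = out / "curve.csv"
            sio.write_coverage_curve(curves, curve_path)
            _emit("curve", curve_path)

        stage = "spectra"
        evals = None
        if config.spectra_dir:
            specs = sio.read_spectra_dir(config.spectra_dir)
            evals = indicator_table(specs, window=config.window,
                                    k=config.k, seed=config.seed)
            evals_path = out / "evals.csv"
            sio.write_evaluations(evals, evals_path)
            _emit("evals", evals_path)

        stage = "train"
        if config.train:
            if evals is None:
                raise ValueError("training requested but no spectra provided")
            if space is None:
                raise ValueError("training requested but no molecular space")
            smiles_by_id = {m.id: m.smiles for m in (space.molecules or [])}
            from .spectra import SOLVENT_SMILES
            feats = [pair_features(smiles_by_id[r.molecule_id],
                                   SOLVENT_SMILES[r.solvent_id],
                                   mode=config.feature_mode,
                                   molecule_id=r.molecule_id,
                                   solvent_id=r.solvent_id)
                     for r in evals.itertuples()]
            report = run_protocol(feats, evals, "classify_good", config.protocol)
            report_path = out / "report.json"
            sio.write_report_json(report.to_dict(), report_path)
            _emit("report", report_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return artifacts
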