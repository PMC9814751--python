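"""Readers and writers for the CSV formats shared across stages.

All writers produce plain CSV readable back by the matching reader with no
field loss; spectra travel either as one two-column file per pair
(``<mol>__<solv>.csv``) or as a single long-format table.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chemspace import Molecule, Provenance
from .selector import Ranking
from .simgraph import MolecularSpace, neighbor_graph_table
from .spectra import Solvent, Spectrum

MANIFEST_COLUMNS = ["id", "smiles", "role", "mw",
                    "core_id", "substituent_id", "reaction_id"]


def write_molspace(molecules: Sequence[Molecule], path: str | Path) -> None:
    """Write the MOLSPACE manifest CSV (id, smiles, role, mw, provenance)."""
    rows = []
    for m in molecules:
        prov = m.provenance
        rows.append({
            "id": m.id, "smiles": m.smiles, "role": m.role, "mw": m.mw,
            "core_id": prov.core_id if prov else "",
            "substituent_id": prov.substituent_id if prov else "",
            "reaction_id": prov.reaction_id if prov else "",
        })
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_molspace(path: str | Path) -> list[Molecule]:
    df = pd.read_csv(path, dtype={c: str for c in MANIFEST_COLUMNS if c != "mw"},
                     keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        prov = (Provenance(r["core_id"], r["substituent_id"], r["reaction_id"])
                if r["reaction_id"] else None)
        out.append(Molecule(id=r["id"], smiles=r["smiles"], mw=float(r["mw"]),
                            role=r["role"], provenance=prov))
    return out


def write_neighbor_graph(space: MolecularSpace, path: str | Path) -> None:
    neighbor_graph_table(space).to_csv(path, index=False)


def write_ranking(ranking: Ranking, path: str | Path) -> None:
    pd.DataFrame({
        "rank": np.arange(1, len(ranking) + 1),
        "molecule_id": ranking.order,
        "score": ranking.scores,
    }).to_csv(path, index=False)


def read_ranking(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"molecule_id": str})


def write_coverage_curve(curves: dict[int, list[tuple[int, float]]],
                         path: str | Path) -> None:
    """Write order-1/order-2 coverage curves side by side."""
    base = {n for order in curves.values() for n, _ in order}
    frame = pd.DataFrame({"n": sorted(base)})
    for order, curve in sorted(curves.items()):
        series = dict(curve)
        frame[f"coverage_order{order}"] = [series.get(n, np.nan) for n in frame["n"]]
    frame.to_csv(path, index=False)


def write_solvent_table(solvents: Sequence[Solvent], path: str | Path) -> None:
    pd.DataFrame([{"id": s.id, "name": s.name, "epsilon": s.epsilon}
                  for s in solvents]).to_csv(path, index=False)


def read_solvent_table(path: str | Path) -> list[Solvent]:
    df = pd.read_csv(path, dtype={"id": str, "name": str})
    return [Solvent(r["id"], r["name"], float(r["epsilon"]))
            for _, r in df.iterrows()]


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"wavelength_nm": spec.wavelength,
                  "absorbance": spec.absorbance}).to_csv(path, index=False)


def read_spectrum(path: str | Path, molecule_id: str = "",
                  solvent_id: str = "") -> Spectrum:
    df = pd.read_csv(path)
    if not molecule_id:
        stem = Path(path).stem
        if "__" in stem:
            molecule_id, solvent_id = stem.split("__", 1)
    return Spectrum(df["wavelength_nm"].to_numpy(),
                    df["absorbance"].to_numpy(),
                    molecule_id=molecule_id, solvent_id=solvent_id)


def read_spectra_dir(directory: str | Path) -> list[Spectrum]:
    """All ``<mol>__<solv>.csv`` spectra in a directory, sorted by filename."""
    paths = sorted(Path(directory).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no spectrum CSVs under {directory}")
    return [read_spectrum(p) for p in paths]


def write_spectra_long(specs: Sequence[Spectrum], path: str | Path) -> None:
    frames = [pd.DataFrame({"molecule_id": s.molecule_id,
                            "solvent_id": s.solvent_id,
                            "wavelength_nm": s.wavelength,
                            "absorbance": s.absorbance}) for s in specs]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectra_long(path: str | Path) -> list[Spectrum]:
    df = pd.read_csv(path, dtype={"molecule_id": str, "solvent_id": str})
    out = []
    for (mol, solv), grp in df.groupby(["molecule_id", "solvent_id"], sort=True):
        grp = grp.sort_values("wavelength_nm")
        out.append(Spectrum(grp["wavelength_nm"].to_numpy(),
                            grp["absorbance"].to_numpy(),
                            molecule_id=mol, solvent_id=solv))
    return out


def write_evaluations(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_evaluations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"molecule_id": str, "solvent_id": str})


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))


def write_sidecar_metadata(artifact_path: str | Path, config: dict,
                           seed: Optional[int]) -> Path:
    """Drop a ``<artifact>.meta.json`` recording the config hash and seed."""
    blob = json.dumps(config, sort_keys=True, default=str)
    meta = {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "config": config,
    }
    meta_path = Path(str(artifact_path) + ".meta.json")
    meta_path.write_text(json.dumps(meta, indent=2, default=str))
    return meta_path
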