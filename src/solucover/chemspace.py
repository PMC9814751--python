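"""Construction of the targeted chemical space (MOLSPACE).

The space is the union of a small set of accessible molecules (commercial
tetraphenylporphyrin derivatives and close relatives) and a virtual library
generated by applying three one-step reactions — amide formation,
esterification and Williamson ether synthesis — between those cores and
small commercial substituents (MW < 200).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Descriptors

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # RDKit is chatty on sanitization failures

Role = Literal["accessible", "generated", "substituent", "solvent"]


@dataclass(frozen=True)
class Provenance:
    """How a generated molecule was produced: (core, substituent, reaction)."""

    core_id: str
    substituent_id: str
    reaction_id: str


@dataclass(frozen=True)
class Molecule:
    """A molecule with canonical SMILES, average molecular weight and a role."""

    id: str
    smiles: str
    mw: float
    role: Role
    provenance: Optional[Provenance] = None

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # pragma: no cover - smiles was canonicalized at build
            raise ValueError(f"stored SMILES no longer parses: {self.smiles!r}")
        return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES, or raise ValueError if the string does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _molecule_from_smiles(smiles: str, mol_id: str, role: Role,
                          provenance: Optional[Provenance] = None) -> Molecule:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Molecule(
        id=mol_id,
        smiles=Chem.MolToSmiles(mol),
        mw=Descriptors.MolWt(mol),
        role=role,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Reaction templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionTemplate:
    """A one-step coupling between a core handle and a substituent handle.

    ``transform`` is a two-reactant SMARTS transform (core first, substituent
    second).  ``core_handle`` / ``substituent_handle`` are the functional-group
    queries that must match for the template to apply at all.
    """

    id: str
    transform: str
    core_handle: str
    substituent_handle: str

    def to_rdkit(self) -> AllChem.ChemicalReaction:
        rxn = AllChem.ReactionFromSmarts(self.transform)
        if rxn is None or rxn.GetNumReactantTemplates() != 2:
            raise ValueError(f"transform failed to compile: {self.transform!r}")
        return rxn


_ACID = "[CX3](=O)[OX2H1]"
_AMINE = "[NX3;H2,H1;!$(N[C,S]=[O,S,N]);!$(N=*);!$([N]-[O,N])]"
_ALCOHOL = "[OX2H1][#6;!$([CX3]=[OX1])]"
_HALIDE = "[CX4;!$(C(F)(F)F)][Cl,Br,I]"

#: The three reactions used to build the virtual library.  Free carboxylic
#: acids are assumed on the acid side; the Williamson ether is enumerated in
#: both orientations (core alcohol + substituent halide and vice versa) and
#: the products deduplicated.
DEFAULT_TEMPLATES: tuple[ReactionTemplate, ...] = (
    ReactionTemplate(
        id="amide",
        transform="[CX3:1](=[OX1:2])[OX2H1]."
                  "[NX3;H2,H1;!$(N[C,S]=[O,S,N]);!$(N=*);!$([N]-[O,N]):3]"
                  ">>[C:1](=[O:2])[N:3]",
        core_handle=_ACID,
        substituent_handle=_AMINE,
    ),
    ReactionTemplate(
        id="ester",
        transform="[CX3:1](=[OX1:2])[OX2H1].[OX2H1:3][#6;!$([CX3]=[OX1]):4]"
                  ">>[C:1](=[O:2])[O:3][#6:4]",
        core_handle=_ACID,
        substituent_handle=_ALCOHOL,
    ),
    ReactionTemplate(
        id="ether",
        transform="[OX2H1:1][#6;!$([CX3]=[OX1]):2].[CX4;!$(C(F)(F)F):3][Cl,Br,I]"
                  ">>[#6:2][O:1][C:3]",
        core_handle=_ALCOHOL,
        substituent_handle=_HALIDE,
    ),
    ReactionTemplate(
        id="ether_rev",
        transform="[CX4;!$(C(F)(F)F):1][Cl,Br,I].[OX2H1:2][#6;!$([CX3]=[OX1]):3]"
                  ">>[#6:3][O:2][C:1]",
        core_handle=_HALIDE,
        substituent_handle=_ALCOHOL,
    ),
)


# ---------------------------------------------------------------------------
# Loading and filtering
# ---------------------------------------------------------------------------

@dataclass
class ParseFailure:
    line_number: int
    text: str
    reason: str


def load_molecules(path: str | Path, role: Role,
                   failures: Optional[list[ParseFailure]] = None) -> list[Molecule]:
    """Read a SMILES file (one ``SMILES [id]`` per line).

    Records that fail to parse are reported (logged, and appended to
    ``failures`` when given) with their line numbers rather than aborting.
    Missing explicit ids are auto-assigned from the role and line number.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If no line yields a valid molecule, or two lines carry the same
        explicit id.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)

    out: list[Molecule] = []
    seen_ids: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        explicit_id = parts[1] if len(parts) > 1 else None
        mol_id = explicit_id if explicit_id is not None else f"{role}_{lineno}"
        try:
            record = _molecule_from_smiles(smiles, mol_id, role)
        except ValueError as exc:
            failure = ParseFailure(lineno, line, str(exc))
            logger.warning("line %d: %s", lineno, failure.reason)
            if failures is not None:
                failures.append(failure)
            continue
        if explicit_id is not None and explicit_id in seen_ids:
            raise ValueError(f"duplicate explicit id {explicit_id!r} at line {lineno}")
        seen_ids.add(mol_id)
        out.append(record)

    if not out:
        raise ValueError(f"zero valid records in {path}")
    return out


def filter_substituents(mols: Sequence[Molecule], mw_limit: float = 200.0) -> list[Molecule]:
    """Keep molecules with average MW strictly below ``mw_limit`` (g/mol)."""
    return [m for m in mols if m.mw < mw_limit]


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def _sanitized_smiles(mol: Chem.Mol) -> Optional[str]:
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def _react_single_site(rxn: AllChem.ChemicalReaction, core: Chem.Mol,
                       sub: Chem.Mol) -> set[str]:
    products: set[str] = set()
    for prods in rxn.RunReactants((core, sub)):
        smi = _sanitized_smiles(prods[0])
        if smi is not None:
            products.add(smi)
    return products


def _react_all_sites(rxn: AllChem.ChemicalReaction, core: Chem.Mol, sub: Chem.Mol,
                     core_handle: Chem.Mol, max_rounds: int = 16) -> set[str]:
    """Apply the transform until no core handle remains (full conversion).

    Symmetric cores (e.g. tetra-acid porphyrins) are converted at every arm,
    matching one-pot syntheses run with excess substituent.
    """
    frontier = {Chem.MolToSmiles(core)}
    finished: set[str] = set()
    for _ in range(max_rounds):
        nxt: set[str] = set()
        for smi in frontier:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            step = _react_single_site(rxn, mol, sub)
            if not step:
                continue
            for prod in step:
                pmol = Chem.MolFromSmiles(prod)
                if pmol is None:
                    continue
                if pmol.HasSubstructMatch(core_handle):
                    nxt.add(prod)
                else:
                    finished.add(prod)
        if not nxt:
            break
        frontier = nxt
    return finished


def enumerate_products(cores: Sequence[Molecule], substituents: Sequence[Molecule],
                       templates: Iterable[ReactionTemplate] = DEFAULT_TEMPLATES,
                       site_mode: Literal["all_sites", "single_site"] = "all_sites",
                       ) -> list[Molecule]:
    """Enumerate the virtual library over (core, substituent, template) triples.

    In ``all_sites`` mode each matching site of the core is converted (the
    product no longer bears the core handle); in ``single_site`` mode one
    product is emitted per distinct reactive site.  Products are
    canonicalized, deduplicated by canonical SMILES (first provenance wins)
    and products failing valence sanitization are logged and skipped.
    """
    if site_mode not in ("all_sites", "single_site"):
        raise ValueError(f"unknown site_mode: {site_mode!r}")

    compiled = []
    for tpl in templates:
        rxn = tpl.to_rdkit()  # raises on a malformed transform
        core_q = Chem.MolFromSmarts(tpl.core_handle)
        sub_q = Chem.MolFromSmarts(tpl.substituent_handle)
        compiled.append((tpl, rxn, core_q, sub_q))

    products: dict[str, Molecule] = {}
    n_dropped = 0
    for core in cores:
        core_mol = core.to_rdkit()
        for tpl, rxn, core_q, sub_q in compiled:
            if not core_mol.HasSubstructMatch(core_q):
                continue
            for sub in substituents:
                sub_mol = sub.to_rdkit()
                if not sub_mol.HasSubstructMatch(sub_q):
                    continue
                if site_mode == "all_sites":
                    smis = _react_all_sites(rxn, core_mol, sub_mol, core_q)
                else:
                    smis = _react_single_site(rxn, core_mol, sub_mol)
                for smi in sorted(smis):
                    if smi in products:
                        continue
                    prov = Provenance(core.id, sub.id, tpl.id)
                    try:
                        rec = _molecule_from_smiles(
                            smi, f"gen_{len(products)}", "generated", prov)
                    except ValueError:
                        n_dropped += 1
                        logger.warning("product failed sanitization: %s", smi)
                        continue
                    products[rec.smiles] = rec
    if n_dropped:
        logger.info("dropped %d products failing valence checks", n_dropped)
    return list(products.values())


# ---------------------------------------------------------------------------
# MOLSPACE assembly
# ---------------------------------------------------------------------------

def build_molspace(accessible: Sequence[Molecule],
                   generated: Sequence[Molecule]) -> list[Molecule]:
    """Union of accessible and generated molecules, merged by canonical SMILES.

    When a generated molecule duplicates an accessible one the accessible
    record wins (it is the one that can actually be bought).  Raises on an
    empty union.
    """
    merged: dict[str, Molecule] = {}
    for mol in generated:
        merged.setdefault(mol.smiles, mol)
    for mol in accessible:
        merged[mol.smiles] = mol  # accessible role wins on collision
    if not merged:
        raise ValueError("empty MOLSPACE: no molecules in either list")
    ordered: list[Molecule] = []
    acc_smiles: set[str] = set()
    for mol in accessible:
        if mol.smiles not in acc_smiles:
            acc_smiles.add(mol.smiles)
            ordered.append(merged[mol.smiles])
    ordered += [m for m in merged.values() if m.smiles not in acc_smiles]
    return ordered
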