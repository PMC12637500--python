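"""Reading, writing and standardizing solvated RNA ensembles.

Multi-model coordinate files (PDB or mmCIF) are parsed into light-weight
:class:`AtomSite` records grouped per model.  After parsing, every residue is
assigned a *species* tag (RNA, water, or one of the assessed ion types) and
solvent far from the RNA is trimmed away, so that downstream density
generation only sees the assessment zone around the molecule.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

# species tags
RNA = "RNA"
WATER = "water"
MG = "Mg2+"
NA = "Na+"
CL = "Cl-"
K = "K+"

SOLVENT_SPECIES = (WATER, MG, NA, CL, K)

#: residue-name -> species mapping applied by :func:`standardize_species`.
#: Any residue name not present here is assigned as water.
DEFAULT_SPECIES_MAP: dict[str, str] = {
    # canonical ribonucleotides and common aliases
    **{name: RNA for name in (
        "A", "C", "G", "U",
        "RA", "RC", "RG", "RU",
        "ADE", "CYT", "GUA", "URA", "URI",
        "A3", "A5", "C3", "C5", "G3", "G5", "U3", "U5",
    )},
    "HOH": WATER, "WAT": WATER, "H2O": WATER, "TIP3": WATER, "SPC": WATER,
    "MG": MG, "NA": NA, "CL": CL, "K": K,
}

#: maps a recognized RNA residue name to its one-letter base code.
BASE_CODE: dict[str, str] = {}
for _name, _sp in DEFAULT_SPECIES_MAP.items():
    if _sp == RNA:
        BASE_CODE[_name] = [c for c in _name if c in "ACGU"][0]


class EnsembleError(ValueError):
    """Raised for unreadable or structurally invalid ensemble input."""


@dataclass
class AtomSite:
    """A single atom with its residue identity and species tag.

    ``b_factor`` is carried through I/O but never used in any density or
    score computation.
    """

    element: str
    atom_name: str
    residue_name: str
    residue_index: int
    chain_id: str
    coords: np.ndarray
    species: str | None = None
    b_factor: float = 0.0

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class EnsembleModel:
    """One frame of an ensemble: an ordered list of atoms."""

    model_index: int
    atoms: list[AtomSite] = field(default_factory=list)

    def rna_atoms(self, heavy_only: bool = True) -> list[AtomSite]:
        return [a for a in self.atoms
                if a.species == RNA and (a.is_heavy or not heavy_only)]

    def solvent_atoms(self) -> list[AtomSite]:
        return [a for a in self.atoms if a.species in SOLVENT_SPECIES]


@dataclass
class SolventEnsemble:
    """A set of frames submitted as one prediction."""

    models: list[EnsembleModel]
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.models)


@dataclass
class ReferenceStructure:
    """The single reference RNA model the assessment is anchored to."""

    atoms: list[AtomSite]
    excluded_residues: frozenset[int] = frozenset()

    def residue_indices(self) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_index, None)
        return list(seen)

    def heavy_coords(self) -> np.ndarray:
        return coords_array([a for a in self.atoms if a.is_heavy])

    def atoms_by_residue(self) -> dict[int, list[AtomSite]]:
        out: dict[int, list[AtomSite]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_index, []).append(a)
        return out


def coords_array(atoms: Sequence[AtomSite]) -> np.ndarray:
    """Stack atom coordinates into an (n, 3) float array."""
    if not atoms:
        return np.zeros((0, 3))
    return np.array([a.coords for a in atoms], dtype=float)


def parse_excluded_residues(text: str) -> frozenset[int]:
    """Parse an exclusion list like ``"63-88,229-245"`` into residue indices."""
    out: set[int] = set()
    for chunk in text.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "-" in chunk[1:]:
            lo, hi = chunk.rsplit("-", 1)
            out.update(range(int(lo), int(hi) + 1))
        else:
            out.add(int(chunk))
    return frozenset(out)


def _dedupe_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy altloc per atom name; ties -> first seen."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > best[atom.name].occ:
            best[atom.name] = atom
    return [best[name] for name in order]


def _model_from_gemmi(gmodel: gemmi.Model, model_index: int) -> EnsembleModel:
    atoms: list[AtomSite] = []
    for chain in gmodel:
        for residue in chain:
            if residue.seqid.icode not in (" ", "", "\x00"):
                raise EnsembleError(
                    f"insertion codes are not supported: chain {chain.name} "
                    f"residue {residue.seqid.num}{residue.seqid.icode}"
                )
            for atom in _dedupe_altlocs(residue):
                atoms.append(AtomSite(
                    element=atom.element.name,
                    atom_name=atom.name,
                    residue_name=residue.name.strip(),
                    residue_index=residue.seqid.num,
                    chain_id=chain.name,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    b_factor=atom.b_iso,
                ))
    return EnsembleModel(model_index=model_index, atoms=atoms)


def read_ensemble(path: str | Path, fmt: str | None = None) -> SolventEnsemble:
    """Read a multi-model PDB or mmCIF file into a :class:`SolventEnsemble`.

    One :class:`EnsembleModel` is created per MODEL record (PDB) or per model
    number (mmCIF); atom order within a model is preserved.  Species tags are
    left unassigned until :func:`standardize_species` is applied.
    """
    path = Path(path)
    try:
        if fmt == "pdb":
            structure = gemmi.read_pdb(str(path))
        elif fmt in ("cif", "mmcif"):
            structure = gemmi.read_structure(str(path),
                                             format=gemmi.CoorFormat.Mmcif)
        else:
            structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise EnsembleError(f"cannot parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise EnsembleError(f"{path} contains no models")
    models = [_model_from_gemmi(gm, i + 1) for i, gm in enumerate(structure)]
    if all(len(m.atoms) == 0 for m in models):
        raise EnsembleError(f"{path} contains no atoms")
    return SolventEnsemble(models=models, source_label=path.stem)


def read_reference(path: str | Path,
                   excluded_residues: Iterable[int] | str = (),
                   fmt: str | None = None) -> ReferenceStructure:
    """Read the single-model reference structure; keeps RNA atoms only."""
    ensemble = read_ensemble(path, fmt=fmt)
    model = standardize_species(ensemble.models[0])
    rna = [a for a in model.atoms if a.species == RNA]
    if not rna:
        raise EnsembleError(f"{path} contains no RNA atoms")
    if isinstance(excluded_residues, str):
        excluded = parse_excluded_residues(excluded_residues)
    else:
        excluded = frozenset(int(i) for i in excluded_residues)
    return ReferenceStructure(atoms=rna, excluded_residues=excluded)


def standardize_species(model: EnsembleModel,
                        mapping: Mapping[str, str] | None = None
                        ) -> EnsembleModel:
    """Assign a species tag to every atom from its residue name.

    Recognized RNA codes map to RNA, water names to water, and the four ion
    residue names to their ions; every other residue code is assigned as
    water.  The function is total (never raises) and idempotent.
    """
    table = DEFAULT_SPECIES_MAP if mapping is None else dict(mapping)
    atoms = [replace(a, coords=a.coords.copy(),
                     species=table.get(a.residue_name.upper(), WATER))
             for a in model.atoms]
    return EnsembleModel(model_index=model.model_index, atoms=atoms)


def trim_solvent(model: EnsembleModel, cutoff: float = 5.0) -> EnsembleModel:
    """Remove solvent farther than ``cutoff`` from this model's own RNA.

    Distances are measured between heavy atoms only; the boundary is
    inclusive.  Water residues are kept or removed as whole residues, keyed
    on their oxygen atom so that any hydrogens follow the oxygen.  RNA atoms
    are never removed.
    """
    rna_heavy = coords_array([a for a in model.atoms
                              if a.species == RNA and a.is_heavy])
    if rna_heavy.shape[0] == 0:
        raise EnsembleError(
            f"model {model.model_index} has no RNA atoms to trim against")
    tree = cKDTree(rna_heavy)

    def _within(atom: AtomSite) -> bool:
        d, _ = tree.query(atom.coords)
        return bool(d <= cutoff)

    # decide each water residue once, keyed on its oxygen
    water_keep: dict[tuple[str, int, str], bool] = {}
    for a in model.atoms:
        if a.species != WATER:
            continue
        key = (a.chain_id, a.residue_index, a.residue_name)
        if a.element.upper() == "O":
            water_keep[key] = _within(a)
    kept: list[AtomSite] = []
    for a in model.atoms:
        if a.species == RNA:
            kept.append(a)
        elif a.species == WATER:
            key = (a.chain_id, a.residue_index, a.residue_name)
            if key not in water_keep:       # water with no oxygen recorded
                water_keep[key] = _within(a)
            if water_keep[key]:
                kept.append(a)
        else:
            if not a.is_heavy or _within(a):
                kept.append(a)
    return EnsembleModel(model_index=model.model_index, atoms=kept)


def prepare_ensemble(ensemble: SolventEnsemble, cutoff: float = 5.0,
                     mapping: Mapping[str, str] | None = None
                     ) -> SolventEnsemble:
    """Standardize species and trim solvent for every model."""
    models = [trim_solvent(standardize_species(m, mapping), cutoff)
              for m in ensemble.models]
    return SolventEnsemble(models=models, source_label=ensemble.source_label)


def _to_gemmi(ensemble: SolventEnsemble) -> gemmi.Structure:
    structure = gemmi.Structure()
    structure.name = ensemble.source_label or "ensemble"
    for model in ensemble.models:
        gmodel = gemmi.Model(model.model_index)
        chains: dict[str, gemmi.Chain] = {}
        current: dict[str, tuple[int, str] | None] = {}
        for a in model.atoms:
            if a.chain_id not in chains:
                chains[a.chain_id] = gemmi.Chain(a.chain_id)
                current[a.chain_id] = None
            chain = chains[a.chain_id]
            if current[a.chain_id] != (a.residue_index, a.residue_name):
                residue = gemmi.Residue()
                residue.name = a.residue_name
                residue.seqid = gemmi.SeqId(a.residue_index, " ")
                residue.het_flag = "A" if a.species == RNA else "H"
                chain.add_residue(residue)
                current[a.chain_id] = (a.residue_index, a.residue_name)
            atom = gemmi.Atom()
            atom.name = a.atom_name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.coords)
            atom.b_iso = a.b_factor
            atom.occ = 1.0
            chain[-1].add_atom(atom)
        for chain in chains.values():
            gmodel.add_chain(chain)
        structure.add_model(gmodel)
    return structure


def write_ensemble(ensemble: SolventEnsemble, path: str | Path,
                   fmt: str | None = None) -> None:
    """Write an ensemble as a multi-model PDB (default) or mmCIF file."""
    path = Path(path)
    if fmt is None:
        fmt = "cif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    structure = _to_gemmi(ensemble)
    if fmt == "pdb":
        structure.write_pdb(str(path))
    elif fmt in ("cif", "mmcif"):
        structure.setup_entities()
        structure.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_reference(ref: ReferenceStructure, path: str | Path) -> None:
    """Write the reference RNA as a single-model PDB file."""
    model = EnsembleModel(model_index=1, atoms=list(ref.atoms))
    write_ensemble(SolventEnsemble(models=[model], source_label="reference"),
                   path, fmt="pdb")
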