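"""Per-residue local superposition of ensemble frames onto the reference RNA.

Globally aligning every frame of an ensemble would let RNA conformational
drift blur the solvent signal, so each residue gets its own *neighborhood*
(all residues with at least one atom within a radius of it, measured on the
reference structure).  For every (frame, neighborhood) pair the model RNA is
superposed onto the reference RNA with the Kabsch algorithm and the solvent
within the capture radius of the neighborhood is carried through the same
rigid transform into the reference frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .ensemble_io import (
    RNA,
    AtomSite,
    BASE_CODE,
    ReferenceStructure,
    SolventEnsemble,
    coords_array,
)

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CU")

#: default backbone atom set for the ``backbone`` alignment selection
BACKBONE_ATOMS = frozenset({
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'", "C2'", "C1'",
    "O4'", "O2'",
})

ATOM_SELECTIONS = ("all_heavy", "backbone", "five_atom", "three_atom")


class AlignmentError(ValueError):
    """Raised when a superposition is impossible (too few/degenerate atoms)."""


@dataclass(frozen=True)
class Neighborhood:
    """A center residue and the residues aligned together with it."""

    center_residue: int
    member_residues: frozenset[int]
    radius: float
    selection: str = "all_heavy"


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class LocalSolventCloud:
    """Solvent of one frame, carried into the reference frame of one region."""

    center_residue: int
    model_index: int
    solvent_atoms: list[AtomSite]
    rmsd: float
    transform: RigidTransform
    rna_atoms: list[AtomSite] = field(default_factory=list)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Point sets must be corresponded row-by-row.  The returned rotation is
    proper (det = +1); reflections are excluded by the usual sign correction
    on the smallest singular vector.

    Raises
    ------
    AlignmentError
        For fewer than 3 points or (near-)collinear configurations, where
        the rotation is not determined.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise AlignmentError("point sets must be corresponded (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise AlignmentError(f"need at least 3 points, got {n}")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, s, vt = np.linalg.svd(h)
    # collinear sets leave rotation about the line undetermined
    scale = max(np.linalg.norm(mobile - cm), 1.0)
    if s[1] <= 1e-8 * scale**2:
        raise AlignmentError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = ct - rotation @ cm
    return RigidTransform(rotation=rotation, translation=translation)


def superpose_rmsd(mobile: np.ndarray, target: np.ndarray,
                   transform: RigidTransform) -> float:
    """RMSD between transformed mobile points and the target points."""
    moved = transform.apply(mobile)
    return float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))


def build_neighborhoods(ref: ReferenceStructure, radius: float = 10.0,
                        selection: str = "all_heavy") -> list[Neighborhood]:
    """One neighborhood per reference residue.

    Residue *j* belongs to the neighborhood of *i* iff the minimum heavy-atom
    distance between the two residues is <= ``radius``; the relation is
    symmetric and every residue is a member of its own neighborhood.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if selection not in ATOM_SELECTIONS:
        raise ValueError(f"unknown atom selection {selection!r}")
    by_res = ref.atoms_by_residue()
    residues = sorted(by_res)
    heavy = [a for a in ref.atoms if a.is_heavy]
    all_coords = coords_array(heavy)
    res_of_atom = np.array([a.residue_index for a in heavy])
    tree = cKDTree(all_coords)
    out = []
    for res in residues:
        pts = coords_array([a for a in by_res[res] if a.is_heavy])
        hits = tree.query_ball_point(pts, r=radius)
        members = {res}
        for lst in hits:
            members.update(res_of_atom[lst].tolist())
        out.append(Neighborhood(center_residue=res,
                                member_residues=frozenset(members),
                                radius=radius, selection=selection))
    return out


def _selection_atom_names(residue_name: str, selection: str) -> set[str] | None:
    """Atom names used for alignment in one residue; None = all heavy atoms."""
    if selection == "all_heavy":
        return None
    if selection == "backbone":
        return set(BACKBONE_ATOMS)
    base = BASE_CODE.get(residue_name.upper())
    if base in PURINES:
        glyco, extra = "N9", "C6"
    else:  # pyrimidines and unrecognized codes use the pyrimidine convention
        glyco, extra = "N1", "C4"
    if selection == "five_atom":
        return {"P", "C4'", "C2", glyco, extra}
    if selection == "three_atom":
        return {"P", "C4'", glyco}
    raise ValueError(f"unknown atom selection {selection!r}")


def select_alignment_atoms(model_atoms: Sequence[AtomSite],
                           ref_atoms: Sequence[AtomSite],
                           member_residues: frozenset[int] | set[int],
                           selection: str = "all_heavy",
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Corresponded (mobile, target) coordinate arrays for one neighborhood.

    Atoms are matched by (residue_index, atom_name); only heavy atoms present
    on BOTH sides are used, in reference order.  Unmatched atoms are dropped.
    """
    model_map = {(a.residue_index, a.atom_name): a for a in model_atoms
                 if a.residue_index in member_residues and a.is_heavy}
    mobile, target = [], []
    for a in ref_atoms:
        if a.residue_index not in member_residues or not a.is_heavy:
            continue
        wanted = _selection_atom_names(a.residue_name, selection)
        if wanted is not None and a.atom_name not in wanted:
            continue
        match = model_map.get((a.residue_index, a.atom_name))
        if match is None:
            continue
        mobile.append(match.coords)
        target.append(a.coords)
    if len(mobile) < 3:
        raise AlignmentError(
            f"fewer than 3 common alignment atoms ({len(mobile)}) "
            f"for residues {sorted(member_residues)}")
    return np.array(mobile), np.array(target)


def extract_local_solvent(ensemble: SolventEnsemble,
                          neighborhoods: Sequence[Neighborhood],
                          ref: ReferenceStructure,
                          capture_radius: float = 5.0,
                          include_rna: bool = False,
                          ) -> tuple[list[LocalSolventCloud], list[dict]]:
    """Align each frame locally and carry its solvent into the reference frame.

    For every (model, neighborhood) pair the member-residue RNA is superposed
    onto the reference, and the model's solvent atoms within
    ``capture_radius`` of the member-residue RNA (measured in the model frame,
    inclusive) are transformed with the fitted rigid transform.

    Returns the clouds plus a list of skip records for neighborhoods whose
    alignment was impossible in some model; a failed region is skipped and
    logged, never fatal.
    """
    clouds: list[LocalSolventCloud] = []
    skipped: list[dict] = []
    for model in ensemble.models:
        model_rna = model.rna_atoms()
        solvent = model.solvent_atoms()
        solvent_xyz = coords_array(solvent)
        rna_xyz = coords_array(model_rna)
        rna_res = np.array([a.residue_index for a in model_rna]) \
            if model_rna else np.zeros(0, dtype=int)
        solvent_tree = cKDTree(solvent_xyz) if len(solvent) else None
        for hood in neighborhoods:
            try:
                mobile, target = select_alignment_atoms(
                    model_rna, ref.atoms, hood.member_residues, hood.selection)
                transform = kabsch(mobile, target)
            except AlignmentError as exc:
                logger.warning("model %d, residue %d: %s",
                               model.model_index, hood.center_residue, exc)
                skipped.append({"model_index": model.model_index,
                                "center_residue": hood.center_residue,
                                "reason": str(exc)})
                continue
            rmsd = superpose_rmsd(mobile, target, transform)
            member_mask = np.isin(rna_res, list(hood.member_residues))
            member_xyz = rna_xyz[member_mask]
            picked: list[AtomSite] = []
            if solvent_tree is not None and member_xyz.shape[0]:
                idx = solvent_tree.query_ball_point(member_xyz,
                                                    r=capture_radius)
                sel = sorted({i for lst in idx for i in lst})
                if sel:
                    moved = transform.apply(solvent_xyz[sel])
                    picked = [replace(solvent[i], coords=moved[j])
                              for j, i in enumerate(sel)]
            rna_out: list[AtomSite] = []
            if include_rna and member_xyz.shape[0]:
                member_atoms = [a for a, m in zip(model_rna, member_mask) if m]
                moved = transform.apply(member_xyz)
                rna_out = [replace(a, coords=moved[j])
                           for j, a in enumerate(member_atoms)]
            clouds.append(LocalSolventCloud(
                center_residue=hood.center_residue,
                model_index=model.model_index,
                solvent_atoms=picked, rmsd=rmsd,
                transform=transform, rna_atoms=rna_out))
    return clouds, skipped
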