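"""Desk-scale synthetic inputs with the statistics the assessment assumes.

The generator builds an idealized A-form-like RNA helix, plants solvent
sites (waters and ions) at coordination distances from it with controllable
occupancy and positional jitter, surrounds them with uniform bulk water,
applies per-model global rigid drift, and renders pseudo-experimental
reference maps through the same renderer used for scoring.  Everything is a
pure function of a :class:`FixtureSpec` (seed included), so fixtures are
reproducible and carry known ground truth; they are statistical stand-ins,
not physically realistic solvent models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .assessment import spawn_seed
from .density_builder import (
    DensityConfig,
    DensityGrid,
    MapSet,
    default_lattice,
    ensemble_to_map,
)
from .ensemble_io import (
    CL,
    K,
    MG,
    NA,
    RNA,
    WATER,
    AtomSite,
    EnsembleModel,
    ReferenceStructure,
    SolventEnsemble,
    coords_array,
)
from .shell_mask import compute_shell

#: residue name / element for each solvent species
_SOLVENT_RES = {WATER: ("HOH", "O"), MG: ("MG", "Mg"), NA: ("NA", "Na"),
                CL: ("CL", "Cl"), K: ("K", "K")}

#: default ion-vs-water composition of planted sites: water dominates,
#: divalent and monovalent cations next, anions rare
SPECIES_WEIGHTS = {WATER: 0.70, MG: 0.12, NA: 0.10, CL: 0.05, K: 0.03}

# helix geometry: A-form-like rise/twist with the phosphate at ~9.4 Å radius
_RISE = 2.81
_TWIST_DEG = 32.7

# (atom_name, radius, phase_deg, dz) template for the sugar-phosphate backbone
_BACKBONE = [
    ("P", 9.4, 0.0, 0.0), ("OP1", 10.3, 3.0, 0.6), ("OP2", 10.0, -5.0, -0.7),
    ("O5'", 8.6, 5.0, 0.9), ("C5'", 8.6, 11.0, 1.7), ("C4'", 8.2, 16.0, 1.3),
    ("O4'", 7.2, 19.0, 1.9), ("C3'", 8.4, 22.0, 0.4), ("O3'", 9.0, 27.0, 0.2),
    ("C2'", 7.5, 23.0, -0.5), ("O2'", 7.6, 29.0, -1.2), ("C1'", 6.7, 20.0, 0.8),
]
_PURINE_BASE = [
    ("N9", 5.5, 19.0, 0.6), ("C8", 5.2, 27.0, 0.2), ("N7", 4.3, 28.0, 0.0),
    ("C5", 3.9, 19.0, 0.3), ("C4", 4.6, 14.0, 0.6), ("N3", 4.3, 7.0, 0.8),
    ("C2", 3.4, 8.0, 0.8), ("N1", 2.7, 14.0, 0.6), ("C6", 3.0, 20.0, 0.4),
]
_PYRIMIDINE_BASE = [
    ("N1", 5.5, 19.0, 0.6), ("C2", 4.6, 14.0, 0.7), ("N3", 3.7, 17.0, 0.5),
    ("C4", 3.7, 25.0, 0.2), ("C5", 4.6, 29.0, 0.1), ("C6", 5.5, 26.0, 0.3),
]
_ELEMENT = {"P": "P"}
for _n, *_ in _BACKBONE + _PURINE_BASE + _PYRIMIDINE_BASE:
    _ELEMENT[_n] = _n[0] if _n[0] in "CNOP" else _n[0]


@dataclass(frozen=True)
class SolventSiteSpec:
    """A planted solvent site: where, what, how often, how fuzzy."""

    position: tuple[float, float, float]
    species: str = WATER
    occupancy: float = 1.0
    jitter_sd: float = 0.0


@dataclass
class FixtureSpec:
    """Fully seeded recipe for one synthetic ensemble and its maps."""

    n_residues: int = 12
    n_models: int = 25
    n_sites: int | None = None            # default 3 per residue
    sites: list[SolventSiteSpec] = field(default_factory=list)
    site_jitter_sd: float = 0.6           # thermal spread of planted sites
    jitter_sd: float = 0.0                # positional ERROR added in quadrature
    occupancy_range: tuple[float, float] = (0.55, 1.0)
    bulk_waters_per_model: int | None = None   # default ~1.3 per residue
    global_motion_deg: float = 0.0        # max per-model rigid rotation
    global_motion_trans: float = 0.0      # max per-model translation, Å
    hinge_deg: float = 0.0                # optional per-model domain rotation
    truth_models: int = 150               # frames behind the reference map
    map_noise_frac: float = 0.12          # noise sd / in-shell signal sd
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureSpec":
        raw = json.loads(Path(path).read_text())
        raw["sites"] = [SolventSiteSpec(position=tuple(s["position"]),
                                        species=s["species"],
                                        occupancy=s["occupancy"],
                                        jitter_sd=s["jitter_sd"])
                        for s in raw.get("sites", [])]
        for key in ("occupancy_range",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def make_toy_rna(n_residues: int = 12, seed: int = 0) -> ReferenceStructure:
    """Idealized A-form-like RNA helix with all alignment atoms present.

    Each residue carries the full backbone atom set plus a purine or
    pyrimidine base skeleton, so every alignment selection (all-heavy,
    backbone, 5-atom, 3-atom) is resolvable.  The sequence is drawn from the
    seed; identical seeds give bit-identical structures.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(spawn_seed(seed, 20))
    sequence = rng.choice(list("ACGU"), size=n_residues)
    atoms: list[AtomSite] = []
    for i, base in enumerate(sequence):
        theta0 = math.radians(i * _TWIST_DEG)
        z0 = i * _RISE
        template = _BACKBONE + (_PURINE_BASE if base in "AG"
                                else _PYRIMIDINE_BASE)
        for name, radius, phase, dz in template:
            ang = theta0 + math.radians(phase)
            pos = np.array([radius * math.cos(ang), radius * math.sin(ang),
                            z0 + dz])
            atoms.append(AtomSite(element=_ELEMENT[name], atom_name=name,
                                  residue_name=str(base), residue_index=i + 1,
                                  chain_id="A", coords=pos, species=RNA))
    return ReferenceStructure(atoms=atoms)


def make_sites(ref: ReferenceStructure, n_sites: int, seed: int = 0,
               occupancy_range: tuple[float, float] = (0.55, 1.0),
               jitter_sd: float = 0.0,
               species_weights: dict[str, float] | None = None,
               ) -> list[SolventSiteSpec]:
    """Plant solvent sites at first-shell coordination distances from the RNA.

    Each site sits 2.0-3.0 Å from a randomly chosen RNA heavy atom (so it
    falls inside the default 1.8-3.2 Å assessment shell), at least 2 Å from
    every other site, with species drawn from the ion-composition weights
    and occupancy drawn uniformly from ``occupancy_range``.
    """
    weights = species_weights or SPECIES_WEIGHTS
    rng = np.random.default_rng(spawn_seed(seed, 21))
    heavy = ref.heavy_coords()
    tree = cKDTree(heavy)
    names = list(weights)
    probs = np.array([weights[n] for n in names], dtype=float)
    probs /= probs.sum()
    sites: list[SolventSiteSpec] = []
    placed: list[np.ndarray] = []
    attempts = 0
    while len(sites) < n_sites and attempts < 200 * n_sites:
        attempts += 1
        anchor = heavy[rng.integers(0, len(heavy))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = anchor + rng.uniform(2.0, 3.0) * direction
        d, _ = tree.query(pos)
        if not (1.9 <= d <= 3.1):
            continue
        if placed and min(np.linalg.norm(pos - p) for p in placed) < 2.0:
            continue
        placed.append(pos)
        sites.append(SolventSiteSpec(
            position=tuple(np.round(pos, 6).tolist()),
            species=str(rng.choice(names, p=probs)),
            occupancy=float(rng.uniform(*occupancy_range)),
            jitter_sd=jitter_sd))
    return sites


def _random_rigid(rng: np.random.Generator, max_deg: float, max_trans: float,
                  pivot: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Random rotation (<= max_deg about a random axis through pivot) + shift."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = math.radians(rng.uniform(0.0, max_deg))
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rot = np.eye(3) + math.sin(ang) * k + (1 - math.cos(ang)) * (k @ k)
    shift = rng.normal(size=3)
    shift *= (rng.uniform(0.0, max_trans) / max(np.linalg.norm(shift), 1e-12))
    trans = pivot - rot @ pivot + shift
    return rot, trans


def resolve_sites(ref: ReferenceStructure, spec: FixtureSpec
                  ) -> list[SolventSiteSpec]:
    """The spec's explicit sites, or freshly planted ones from its seed."""
    if spec.sites:
        sites = list(spec.sites)
    else:
        n_sites = spec.n_sites or max(3, 3 * spec.n_residues)
        sites = make_sites(ref, n_sites, seed=spec.seed,
                           occupancy_range=spec.occupancy_range,
                           jitter_sd=spec.site_jitter_sd)
    if spec.jitter_sd:
        sites = [SolventSiteSpec(position=s.position, species=s.species,
                                 occupancy=s.occupancy,
                                 jitter_sd=math.hypot(s.jitter_sd,
                                                      spec.jitter_sd))
                 for s in sites]
    return sites


def make_solvent_ensemble(ref: ReferenceStructure, spec: FixtureSpec,
                          n_models: int | None = None,
                          seed_tag: int = 22) -> SolventEnsemble:
    """Generate an ensemble of frames realizing the planted solvent sites.

    Per frame: each site is present with probability = its occupancy and
    displaced by isotropic Gaussian jitter; bulk waters are placed uniformly
    in the 1.8-5.0 Å zone; the whole frame (RNA + solvent) then receives a
    random global rigid transform and, optionally, a hinge rotation of the
    second half of the helix applied before the solvent placement.
    """
    n_models = n_models or spec.n_models
    sites = resolve_sites(ref, spec)
    n_bulk = (spec.bulk_waters_per_model
              if spec.bulk_waters_per_model is not None
              else max(4, (4 * spec.n_residues) // 3))
    heavy = ref.heavy_coords()
    pivot = heavy.mean(axis=0)
    lo, hi = heavy.min(axis=0) - 5.0, heavy.max(axis=0) + 5.0
    models: list[EnsembleModel] = []
    hinge_res = spec.n_residues // 2 + 1
    for m in range(n_models):
        rng = np.random.default_rng(spawn_seed(spec.seed, seed_tag, m))
        rna_atoms = [AtomSite(element=a.element, atom_name=a.atom_name,
                              residue_name=a.residue_name,
                              residue_index=a.residue_index,
                              chain_id=a.chain_id, coords=a.coords.copy(),
                              species=RNA)
                     for a in ref.atoms]
        if spec.hinge_deg > 0.0:
            hinge_pivot = coords_array(
                [a for a in ref.atoms if a.residue_index == hinge_res]
            ).mean(axis=0)
            rot, trans = _random_rigid(rng, spec.hinge_deg, 0.0, hinge_pivot)
            for a in rna_atoms:
                if a.residue_index >= hinge_res:
                    a.coords = rot @ a.coords + trans
        model_heavy = coords_array([a for a in rna_atoms if a.is_heavy])
        tree = cKDTree(model_heavy)
        solvent: list[AtomSite] = []
        res_idx = 1001
        for site in sites:
            if rng.random() > site.occupancy:
                continue
            pos = np.asarray(site.position, dtype=float)
            if site.jitter_sd > 0.0:
                pos = pos + rng.normal(0.0, site.jitter_sd, size=3)
            res_name, element = _SOLVENT_RES[site.species]
            solvent.append(AtomSite(element=element, atom_name=element.upper(),
                                    residue_name=res_name,
                                    residue_index=res_idx, chain_id="S",
                                    coords=pos, species=site.species))
            res_idx += 1
        placed_bulk = 0
        while placed_bulk < n_bulk:
            pos = rng.uniform(lo, hi)
            d, _ = tree.query(pos)
            if not (1.8 <= d <= 5.0):
                continue
            solvent.append(AtomSite(element="O", atom_name="O",
                                    residue_name="HOH",
                                    residue_index=res_idx, chain_id="S",
                                    coords=pos, species=WATER))
            res_idx += 1
            placed_bulk += 1
        atoms = rna_atoms + solvent
        if spec.global_motion_deg > 0.0 or spec.global_motion_trans > 0.0:
            rot, trans = _random_rigid(rng, spec.global_motion_deg,
                                       spec.global_motion_trans, pivot)
            for a in atoms:
                a.coords = rot @ a.coords + trans
        models.append(EnsembleModel(model_index=m + 1, atoms=atoms))
    return SolventEnsemble(models=models, source_label=f"fixture_seed{spec.seed}")


def ground_truth_ensemble(ref: ReferenceStructure, spec: FixtureSpec
                          ) -> SolventEnsemble:
    """The many-frame ensemble that defines the fixture's true density."""
    return make_solvent_ensemble(ref, spec, n_models=spec.truth_models,
                                 seed_tag=23)


def make_clean_map(ref: ReferenceStructure, spec: FixtureSpec,
                   config: DensityConfig | None = None) -> MapSet:
    """Noise-free rendering of the ground-truth ensemble."""
    truth = ground_truth_ensemble(ref, spec)
    return ensemble_to_map(truth, ref, config)


def make_reference_map(ref: ReferenceStructure, spec: FixtureSpec,
                       seed: int = 0, noise_sd: float | None = None,
                       clean: DensityGrid | None = None,
                       config: DensityConfig | None = None) -> DensityGrid:
    """Pseudo-experimental map: ground-truth density plus voxel noise.

    With ``noise_sd`` unset, the noise level is ``map_noise_frac`` times the
    standard deviation of the clean map inside the default solvent shell.
    Different seeds give independent noise realizations — the second
    realization plays the role of the independent map.
    """
    if clean is None:
        clean = make_clean_map(ref, spec, config).total
    if noise_sd is None:
        mask = compute_shell(ref, clean.lattice, excluded=())
        noise_sd = spec.map_noise_frac * float(np.std(mask.extract(clean)))
    rng = np.random.default_rng(spawn_seed(seed, 24))
    noisy = clean.values + rng.normal(0.0, noise_sd, size=clean.values.shape)
    return DensityGrid(clean.lattice, noisy, species_label=clean.species_label)


DEGRADATION_JITTERS = (0.0, 0.5, 1.0, 2.0)


def degradation_suite(ref: ReferenceStructure, base_spec: FixtureSpec,
                      jitters: tuple[float, ...] = DEGRADATION_JITTERS,
                      ) -> list[tuple[str, float, SolventEnsemble]]:
    """Ensembles of decreasing fidelity: growing site-position jitter.

    Returns (label, jitter_sd, ensemble) triples in degradation order; the
    fidelity ranking (smaller jitter = more faithful) is known a priori.
    All levels share the base spec's planted sites.
    """
    sites = resolve_sites(ref, base_spec)
    out = []
    for level, jit in enumerate(jitters):
        spec = FixtureSpec(**{**asdict(base_spec),
                              "sites": sites, "jitter_sd": jit,
                              "seed": spawn_seed(base_spec.seed, 25, level)})
        spec.sites = [SolventSiteSpec(position=s.position, species=s.species,
                                      occupancy=s.occupancy,
                                      jitter_sd=math.hypot(s.jitter_sd, jit))
                      for s in sites]
        spec.jitter_sd = 0.0  # already folded into the site specs
        ensemble = make_solvent_ensemble(ref, spec)
        ensemble.source_label = f"jitter_{jit:g}"
        out.append((ensemble.source_label, jit, ensemble))
    return out
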