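"""Multi-ensemble assessment: bootstrap, floor/ceiling references, rankings.

Each ensemble's map is scored against the reference map in the default
solvent shell; bootstrap resampling of models gives a per-ensemble score
variance, a shuffled reference gives the performance floor, an independent
map gives the experimental-uncertainty ceiling, and cross-ensemble Z-scores
(clipped at zero so below-average metrics are not penalized) give the final
ranking.  Per-residue Z-score matrices localize where ensembles differ.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .density_builder import (
    DensityConfig,
    DensityGrid,
    MapSet,
    ensemble_to_map,
    read_mrc,
    resample_onto,
)
from .ensemble_io import (
    ReferenceStructure,
    SolventEnsemble,
    prepare_ensemble,
    read_ensemble,
    read_reference,
)
from .scoring import METRICS, ScoreSet, score_pair, score_vectors
from .shell_mask import (
    DEFAULT_BAND,
    ShellMask,
    compute_shell,
    per_residue_regions,
)

logger = logging.getLogger(__name__)


def spawn_seed(base_seed: int, *path: int) -> int:
    """Derive a sub-task seed from a global seed and a task counter path.

    Counter-based fan-out: the same (seed, path) always yields the same
    child seed, and distinct paths decorrelate.
    """
    ss = np.random.SeedSequence(int(base_seed), spawn_key=tuple(path))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class BootstrapReplicate:
    """One resample-with-replacement of an ensemble's models."""

    replicate_index: int
    model_indices: list[int]
    scores: ScoreSet


def bootstrap_scores(ensemble: SolventEnsemble, ref_map: DensityGrid,
                     ref: ReferenceStructure, mask: ShellMask,
                     config: DensityConfig | None = None,
                     n_reps: int = 5, seed: int = 0,
                     ) -> tuple[list[BootstrapReplicate], dict[str, float | None]]:
    """Score ``n_reps`` bootstrap resamples of the ensemble's models.

    Each replicate draws ``len(models)`` models with replacement, rebuilds
    the density map from scratch and rescores it.  The per-metric standard
    deviation across replicates is the sampling-variance estimate; for a
    single-model ensemble it is undefined (None).
    """
    n = len(ensemble.models)
    replicates: list[BootstrapReplicate] = []
    for rep in range(n_reps):
        rng = np.random.default_rng(spawn_seed(seed, 0, rep))
        picks = rng.integers(0, n, size=n)
        models = [ensemble.models[i] for i in picks]
        sample = SolventEnsemble(
            models=models, source_label=f"{ensemble.source_label}_boot{rep}")
        maps = ensemble_to_map(sample, ref, config)
        scores = score_pair(maps.total, ref_map, mask,
                            seed=spawn_seed(seed, 1, rep))
        replicates.append(BootstrapReplicate(
            replicate_index=rep + 1,
            model_indices=[int(i) + 1 for i in picks], scores=scores))
    sds: dict[str, float | None] = {}
    for metric in METRICS:
        vals = [r.scores.get(metric) for r in replicates]
        if n < 2 or any(v is None for v in vals):
            sds[metric] = None
        else:
            sds[metric] = float(np.std(np.asarray(vals, dtype=float)))
    return replicates, sds


def shuffle_floor(ref_vector: np.ndarray, seed: int = 0,
                  n_shuffles: int = 1, sigma_mult: float = 3.0,
                  min_voxels_mi: int = 50) -> ScoreSet | list[ScoreSet]:
    """Performance floor: shuffled reference values scored against ordered.

    The masked reference values are randomly permuted and the permutation is
    scored as if it were a prediction of the ordered vector (the positive
    class is defined on the ordered reference).  With ``n_shuffles`` > 1 a
    list of ScoreSets is returned, one per shuffle.
    """
    ref_vector = np.asarray(ref_vector, dtype=float).ravel()
    out: list[ScoreSet] = []
    for i in range(n_shuffles):
        rng = np.random.default_rng(spawn_seed(seed, 2, i))
        shuffled = rng.permutation(ref_vector)
        out.append(score_vectors(shuffled, ref_vector,
                                 seed=spawn_seed(seed, 3, i),
                                 sigma_mult=sigma_mult,
                                 min_voxels_mi=min_voxels_mi))
    return out[0] if n_shuffles == 1 else out


def ceiling_from_independent_map(ref_map: DensityGrid,
                                 indep_map: DensityGrid,
                                 mask: ShellMask, seed: int = 0) -> ScoreSet:
    """Experimental-uncertainty ceiling: independent map vs reference map.

    The independent map is resampled onto the reference lattice by trilinear
    interpolation, then scored on the same shell voxels with the same
    metrics as any prediction.
    """
    resampled = resample_onto(indep_map, ref_map.lattice)
    return score_pair(resampled, ref_map, mask, seed=spawn_seed(seed, 4))


def rank_ensembles(scores: Mapping[str, ScoreSet]) -> pd.DataFrame:
    """Cross-ensemble Z-scores per metric, clipped at zero and summed.

    Z = (score - mean over ensembles) / population sd over ensembles.
    Negative Z values are clipped to zero so below-average performance on a
    metric is not penalized; an ensemble missing a metric is excluded from
    that metric's mean/sd and contributes zero for it.  Returns a DataFrame
    with one Z column per metric and a ``total`` column, sorted descending.
    """
    if len(scores) < 3:
        raise ValueError("ranking requires at least 3 ensembles")
    labels = list(scores)
    table = pd.DataFrame(index=labels, dtype=float)
    for metric in METRICS:
        vals = pd.Series({lb: scores[lb].get(metric) for lb in labels},
                         dtype=float)
        ok = vals.dropna()
        sd = float(ok.std(ddof=0)) if len(ok) else 0.0
        if sd == 0.0:
            z = pd.Series(0.0, index=labels)
        else:
            z = (vals - ok.mean()) / sd
        table[f"z_{metric}"] = z
    clipped = table.clip(lower=0.0).fillna(0.0)
    table["total"] = clipped.sum(axis=1)
    return table.sort_values("total", ascending=False)


def per_residue_assessment(ensemble_maps: Mapping[str, DensityGrid],
                           ref_map: DensityGrid, mask: ShellMask,
                           metric: str = "pearson_cc", seed: int = 0,
                           min_voxels_mi: int = 50,
                           ) -> tuple[pd.DataFrame, dict[str, dict[int, ScoreSet]]]:
    """Score every (ensemble, residue region) and build the Z-score matrix.

    The default shell is partitioned by nearest residue; each region is
    scored per ensemble, and for the chosen metric a residue-wise Z-score
    across ensembles is computed (rows = ensembles, columns = residues,
    sorted by total positive Z as in the group-level ranking).
    """
    regions = per_residue_regions(mask)
    per_scores: dict[str, dict[int, ScoreSet]] = {}
    for i, (label, grid) in enumerate(ensemble_maps.items()):
        per_scores[label] = {}
        for res, region in regions.items():
            per_scores[label][res] = score_pair(
                grid, ref_map, region, seed=spawn_seed(seed, 5, i, res),
                min_voxels_mi=min_voxels_mi)
    matrix = pd.DataFrame(
        {res: {lb: per_scores[lb][res].get(metric) for lb in ensemble_maps}
         for res in regions}, dtype=float)
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=0).replace(0.0, np.nan)
    zmat = (matrix - mean) / sd
    order = zmat.clip(lower=0.0).fillna(0.0).sum(axis=1)
    zmat = zmat.loc[order.sort_values(ascending=False).index]
    return zmat, per_scores


# ---------------------------------------------------------------------------
# full-run orchestration (used by the CLI)

@dataclass
class AssessmentConfig:
    """Inputs and settings for one multi-ensemble assessment run."""

    reference_path: str
    ref_map_path: str
    ensemble_paths: dict[str, str] = field(default_factory=dict)
    indep_map_path: str | None = None
    excluded_residues: str = ""
    band: tuple[float, float] = DEFAULT_BAND
    density: DensityConfig = field(default_factory=DensityConfig)
    n_bootstrap: int = 5
    sigma_mult: float = 3.0
    min_voxels_mi: int = 50
    seed: int = 0
    per_residue: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "AssessmentConfig":
        raw = json.loads(Path(path).read_text())
        density = DensityConfig(**raw.pop("density", {}))
        band = tuple(raw.pop("band", DEFAULT_BAND))
        return cls(density=density, band=band, **raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def assess(config: AssessmentConfig) -> dict:
    """Run the full assessment and return a JSON-serializable report.

    The report is a pure function of the inputs and the seed: rerunning with
    identical config produces a byte-identical serialization.
    """
    ref = read_reference(config.reference_path,
                         excluded_residues=config.excluded_residues)
    ref_map = read_mrc(config.ref_map_path)
    density = DensityConfig(**{**config.density.__dict__,
                               "lattice": ref_map.lattice})
    mask = compute_shell(ref, ref_map.lattice, *config.band)
    ref_vec = mask.extract(ref_map)

    report: dict = {
        "cryoshell_version": __version__,
        "seed": config.seed,
        "band": list(config.band),
        "n_mask_voxels": len(mask),
        "inputs": {
            "reference": _sha256(config.reference_path),
            "ref_map": _sha256(config.ref_map_path),
            "ensembles": {lb: _sha256(p)
                          for lb, p in sorted(config.ensemble_paths.items())},
        },
        "ensembles": {},
    }

    scores: dict[str, ScoreSet] = {}
    maps: dict[str, DensityGrid] = {}
    for i, (label, path) in enumerate(sorted(config.ensemble_paths.items())):
        ensemble = prepare_ensemble(read_ensemble(path))
        mapset = ensemble_to_map(ensemble, ref, density)
        maps[label] = mapset.total
        entry: dict = {"n_models": len(ensemble.models)}
        sset = score_pair(mapset.total, ref_map, mask,
                          seed=spawn_seed(config.seed, 10, i),
                          sigma_mult=config.sigma_mult,
                          min_voxels_mi=config.min_voxels_mi)
        scores[label] = sset
        entry["scores"] = sset.as_dict()
        if len(ensemble.models) >= 2 and config.n_bootstrap > 0:
            reps, sds = bootstrap_scores(
                ensemble, ref_map, ref, mask, density,
                n_reps=config.n_bootstrap,
                seed=spawn_seed(config.seed, 11, i))
            entry["bootstrap_sd"] = sds
            entry["bootstrap_model_indices"] = \
                [r.model_indices for r in reps]
        else:
            entry["bootstrap_sd"] = {m: None for m in METRICS}
            entry["bootstrap_flag"] = "single_model"
        report["ensembles"][label] = entry

    floor = shuffle_floor(ref_vec, seed=config.seed,
                          sigma_mult=config.sigma_mult,
                          min_voxels_mi=config.min_voxels_mi)
    report["floor"] = floor.as_dict()
    if config.indep_map_path:
        indep = read_mrc(config.indep_map_path)
        report["inputs"]["indep_map"] = _sha256(config.indep_map_path)
        ceiling = ceiling_from_independent_map(ref_map, indep, mask,
                                               seed=config.seed)
        report["ceiling"] = ceiling.as_dict()
    if len(scores) >= 3:
        ranking = rank_ensembles(scores)
        report["ranking"] = {
            lb: {col: (None if pd.isna(v) else float(v))
                 for col, v in row.items()}
            for lb, row in ranking.iterrows()}
        report["ranking_order"] = list(ranking.index)
    if config.per_residue and maps:
        zmat, _ = per_residue_assessment(
            maps, ref_map, mask, seed=config.seed,
            min_voxels_mi=config.min_voxels_mi)
        report["per_residue_z"] = {
            lb: {str(res): (None if pd.isna(v) else float(v))
                 for res, v in row.items()}
            for lb, row in zmat.iterrows()}
    return _round_floats(report)


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a report deterministically (sorted keys, fixed precision)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def scores_to_csv(report: dict, path: str | Path) -> None:
    """Flatten per-ensemble scores into a CSV table."""
    rows = []
    for label, entry in report.get("ensembles", {}).items():
        for metric in METRICS:
            rows.append({
                "ensemble": label,
                "metric": metric,
                "score": entry["scores"][metric],
                "bootstrap_sd": entry.get("bootstrap_sd", {}).get(metric),
                "reason": entry["scores"]["reasons"].get(metric, ""),
            })
    pd.DataFrame(rows).to_csv(path, index=False)
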