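"""Comparison metrics between predicted and reference densities on a mask.

Four metrics: Pearson correlation (the cryo-EM real-space CC), Spearman rank
correlation, a k-nearest-neighbor mutual-information estimate, and the area
under the precision-recall curve for recovering high-occupancy (> 3 sigma)
reference voxels.  Metrics that cannot be computed on a given vector pair
carry a typed reason code instead of a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.feature_selection import mutual_info_regression

from .density_builder import DensityGrid
from .shell_mask import ShellMask

# reason codes for metrics that cannot be computed
CONSTANT_INPUT = "constant_input"
TOO_FEW_VOXELS = "too_few_voxels"
SINGLE_CLASS = "single_class"
NO_POSITIVES = "no_positive_class"

METRICS = ("pearson_cc", "spearman_rho", "mutual_info", "auc_pr")


class UndefinedMetric(ValueError):
    """A metric is undefined for this input; carries a reason code."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass
class PRCurve:
    """Precision-recall curve over descending thresholds of the prediction."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    false_positive_rate: np.ndarray
    auc_pr: float


@dataclass
class ScoreSet:
    """The four comparison metrics, each optionally absent with a reason."""

    pearson_cc: float | None = None
    spearman_rho: float | None = None
    mutual_info: float | None = None
    auc_pr: float | None = None
    reasons: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"pearson_cc": self.pearson_cc,
                "spearman_rho": self.spearman_rho,
                "mutual_info": self.mutual_info,
                "auc_pr": self.auc_pr,
                "reasons": dict(self.reasons)}

    def get(self, metric: str) -> float | None:
        return getattr(self, metric)


def _as_vector(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if v.size < 2:
        raise UndefinedMetric(TOO_FEW_VOXELS, f"length {v.size}")
    return v


def pearson_cc(x, xo) -> float:
    """Real-space cross-correlation = Pearson correlation of voxel values.

    CC = sum((x - mean x)(xo - mean xo)) / sqrt(sum((x - mean x)^2)
    sum((xo - mean xo)^2)) over the compared voxel set.
    """
    x, xo = _as_vector(x), _as_vector(xo)
    if x.size != xo.size:
        raise ValueError("vectors must have equal length")
    dx = x - x.mean()
    dxo = xo - xo.mean()
    nx = np.sqrt(np.sum(dx * dx))
    nxo = np.sqrt(np.sum(dxo * dxo))
    if nx == 0.0 or nxo == 0.0:
        raise UndefinedMetric(CONSTANT_INPUT, "zero variance vector")
    return float(np.sum(dx * dxo) / (nx * nxo))


def spearman_rho(x, xo) -> float:
    """Spearman correlation: Pearson CC of midrank vectors."""
    x, xo = _as_vector(x), _as_vector(xo)
    return pearson_cc(rankdata(x), rankdata(xo))


def mutual_information(x, xo, k: int = 6, seed: int = 0) -> float:
    """kNN (Kraskov-type) mutual information estimate, in nats.

    Uses the continuous-variable estimator with neighborhood size ``k``;
    exact value ties are broken by the estimator's internal tiny seeded
    noise (magnitude 1e-10 of the value scale).  Clipped at 0.
    """
    x, xo = _as_vector(x), _as_vector(xo)
    if x.size <= k + 1:
        raise UndefinedMetric(
            TOO_FEW_VOXELS, f"need more than {k + 1} voxels, got {x.size}")
    est = mutual_info_regression(x.reshape(-1, 1), xo, n_neighbors=k,
                                 random_state=int(seed) % (2 ** 31))
    return float(max(est[0], 0.0))


def classify_high_density(xo, sigma_mult: float = 3.0) -> np.ndarray:
    """Label reference voxels with density above ``sigma_mult`` sigma.

    Sigma is the population standard deviation of the reference values over
    the compared voxel set; a voxel is positive iff value > sigma_mult*sigma.
    """
    xo = _as_vector(xo)
    sigma = float(np.std(xo))
    if sigma == 0.0:
        raise UndefinedMetric(CONSTANT_INPUT, "zero-variance reference")
    return xo > sigma_mult * sigma


def pr_curve(x, labels) -> PRCurve:
    """Precision-recall curve sweeping descending predicted-density cutoffs.

    At each distinct predicted value t (descending), voxels with x >= t are
    predicted high-density;
    precision = correctly predicted high-density voxels / predicted,
    recall    = correctly predicted high-density voxels / actual positives.
    AUC-PR is the right-continuous step sum  sum_i (R_i - R_{i-1}) P_i.
    """
    x = _as_vector(x)
    labels = np.asarray(labels, dtype=bool).ravel()
    if labels.size != x.size:
        raise ValueError("labels must match prediction length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0:
        raise UndefinedMetric(NO_POSITIVES, "no positive voxels")
    if n_neg == 0:
        raise UndefinedMetric(SINGLE_CLASS, "all voxels positive")
    order = np.argsort(-x, kind="stable")
    sorted_x = x[order]
    tp = np.cumsum(labels[order])
    fp = np.cumsum(~labels[order])
    # last index of each run of equal predicted values = the threshold cut
    cut = np.nonzero(np.diff(sorted_x, append=-np.inf) != 0)[0]
    thresholds = sorted_x[cut]
    tp_c, fp_c = tp[cut], fp[cut]
    precision = tp_c / (tp_c + fp_c)
    recall = tp_c / n_pos
    fpr = fp_c / n_neg
    auc = float(np.sum(np.diff(recall, prepend=0.0) * precision))
    return PRCurve(thresholds=thresholds, precision=precision, recall=recall,
                   false_positive_rate=fpr, auc_pr=auc)


def auc_pr_vs_reference_threshold(x, xo,
                                  sigma_mults: Sequence[float] = (1, 2, 3, 4, 5),
                                  ) -> list[tuple[float, float | None, str | None]]:
    """AUC-PR when the positive class is defined at several sigma cutoffs.

    Returns (sigma_mult, auc_pr, reason) triples; thresholds with an
    undefined curve are flagged with the reason code, never fabricated.
    """
    out = []
    for mult in sigma_mults:
        try:
            labels = classify_high_density(xo, sigma_mult=mult)
            out.append((float(mult), pr_curve(x, labels).auc_pr, None))
        except UndefinedMetric as exc:
            out.append((float(mult), None, exc.reason))
    return out


def score_vectors(x, xo, k: int = 6, seed: int = 0,
                  sigma_mult: float = 3.0,
                  min_voxels_mi: int = 50) -> ScoreSet:
    """All four metrics on a pair of density value vectors."""
    scores = ScoreSet()
    try:
        scores.pearson_cc = pearson_cc(x, xo)
    except UndefinedMetric as exc:
        scores.reasons["pearson_cc"] = exc.reason
    try:
        scores.spearman_rho = spearman_rho(x, xo)
    except UndefinedMetric as exc:
        scores.reasons["spearman_rho"] = exc.reason
    try:
        if np.asarray(x).size < min_voxels_mi:
            raise UndefinedMetric(
                TOO_FEW_VOXELS,
                f"fewer than min_voxels_mi={min_voxels_mi} voxels")
        scores.mutual_info = mutual_information(x, xo, k=k, seed=seed)
    except UndefinedMetric as exc:
        scores.reasons["mutual_info"] = exc.reason
    try:
        labels = classify_high_density(xo, sigma_mult=sigma_mult)
        scores.auc_pr = pr_curve(x, labels).auc_pr
    except UndefinedMetric as exc:
        scores.reasons["auc_pr"] = exc.reason
    return scores


def score_pair(pred: DensityGrid, ref: DensityGrid, mask: ShellMask,
               k: int = 6, seed: int = 0, sigma_mult: float = 3.0,
               min_voxels_mi: int = 50) -> ScoreSet:
    """Score a predicted map against a reference map on a shell mask."""
    x = mask.extract(pred)
    xo = mask.extract(ref)
    return score_vectors(x, xo, k=k, seed=seed, sigma_mult=sigma_mult,
                         min_voxels_mi=min_voxels_mi)
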