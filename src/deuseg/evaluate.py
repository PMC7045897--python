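"""Segmentation metrics, cross-validation management, and the
dual-vs-single-sequence input comparison.

Metrics are the standard voxel-overlap triple — Dice similarity coefficient
DSC = 2TP/(2TP+FP+FN), sensitivity TP/(TP+FN), precision TP/(TP+FP) —
computed per patient on the pooled 3D volume.  Cross-validation partitions
patients (never slices) so no patient contributes to both train and test of
a fold.  The input comparison trains three models (channel-1 only,
channel-2 only, dual) under identical folds and seeds and compares per-fold
DSC with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold

from .model import DEUConfig, DEUNetwork, NetworkHandle, build_deu, build_single_sequence
from .phantom import PairedStudy
from .postprocess import postprocess_probability

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "FoldResult",
    "confusion_counts",
    "dsc",
    "sensitivity",
    "precision",
    "evaluate_patient",
    "kfold_split",
    "mann_whitney_u",
    "run_input_comparison",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxelwise tallies from which all three metrics derive."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary {{0, 1}}")
    return arr.astype(bool)


def confusion_counts(pred: np.ndarray, gold: np.ndarray) -> ConfusionCounts:
    """TP/FP/FN/TN tallies of a predicted mask against the gold standard."""
    p = _as_binary(pred, "pred")
    g = _as_binary(gold, "gold")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gold {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient 2TP / (FP + 2TP + FN).

    When both masks are empty (2TP+FP+FN = 0) the declared convention is
    perfect agreement on absence: DSC = 1, logged.
    """
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        logger.info("DSC of two empty masks: returning 1.0 by convention")
        return 1.0
    return 2 * c.tp / denom


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN (missing) when the gold mask is empty."""
    if c.tp + c.fn == 0:
        return math.nan
    return c.tp / (c.tp + c.fn)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); NaN (missing) when the prediction is empty."""
    if c.tp + c.fp == 0:
        return math.nan
    return c.tp / (c.tp + c.fp)


def evaluate_patient(pred: np.ndarray, gold: np.ndarray) -> dict[str, float]:
    """All three metrics of one patient's 3D prediction."""
    c = confusion_counts(pred, gold)
    return {"dsc": dsc(c), "sensitivity": sensitivity(c), "precision": precision(c)}


def kfold_split(patient_ids: list[str], k: int, seed: int):
    """Patient-level k-fold partition: shuffled, balanced (sizes differ by
    at most 1), deterministic given the seed."""
    ids = list(patient_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k = {k} exceeds the number of patients ({len(ids)})")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in kf.split(ids):
        folds.append(([ids[i] for i in train_idx], [ids[i] for i in test_idx]))
    return folds


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U rank-sum test with tie correction.

    Returns (U, p) with U reported under the min convention
    (U = min(U_a, U_b)).  For small tie-free samples (each n <= 8) the exact
    null distribution is used; otherwise the tie-corrected normal
    approximation.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    small = a.size <= 8 and b.size <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    u = min(u_a, a.size * b.size - u_a)
    return u, float(res.pvalue)


@dataclass
class FoldResult:
    """Per-fold evaluation of one model configuration."""

    fold_index: int
    model_label: str
    patient_ids: list[str]
    metrics: list[dict[str, float]]  # one triple per test patient

    def mean(self, key: str) -> float:
        vals = [m[key] for m in self.metrics if not math.isnan(m[key])]
        return float(np.mean(vals)) if vals else math.nan

    def aggregate(self) -> dict[str, float]:
        return {k: self.mean(k) for k in ("dsc", "sensitivity", "precision")}


_MODEL_CHANNELS = {"t1": [0], "t2": [1], "dual": [0, 1]}


def studies_to_samples(studies, channels) -> list[tuple[np.ndarray, np.ndarray]]:
    """Flatten preprocessed studies into per-slice (input, mask) samples."""
    samples = []
    for st in studies:
        stack = np.stack([st.t1w.values, st.t2w.values], axis=0)  # (2, S, H, W)
        for s in range(st.gold.shape[0]):
            x = stack[channels, s].astype(np.float32)
            y = st.gold.values[s].astype(np.float32)
            samples.append((x, y))
    return samples


def predict_study(handle: NetworkHandle, study: PairedStudy, channels) -> np.ndarray:
    """Per-slice forward passes stacked into a probability volume."""
    stack = np.stack([st for st in (study.t1w.values, study.t2w.values)], axis=0)
    probs = [
        handle.predict(stack[channels, s].astype(np.float32))
        for s in range(study.gold.shape[0])
    ]
    return np.stack(probs, axis=0)


def run_input_comparison(dataset: list[PairedStudy], k: int, seed: int,
                         model_configs: dict[str, DEUConfig],
                         train_config=None,
                         threshold: float = 0.5, connectivity: int = 26):
    """Train and evaluate the three input variants under identical folds.

    ``dataset`` must already be preprocessed (shared grids, input-size
    slices).  ``model_configs`` maps labels from {"t1", "t2", "dual"} to
    architecture configs (dual_input must match the label).  Returns a
    report dict with per-model fold results, a summary table
    (mean ± sd of the per-fold means, Table-1 shaped), and Mann-Whitney
    comparisons of per-fold DSC between the dual model and each single.
    """
    from .training import TrainConfig, train  # local import to avoid cycle

    train_config = train_config or TrainConfig()
    ids = [st.patient_id for st in dataset]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids in dataset")
    by_id = {st.patient_id: st for st in dataset}
    folds = kfold_split(ids, k, seed)

    results: dict[str, list[FoldResult]] = {}
    for label, cfg in model_configs.items():
        if label not in _MODEL_CHANNELS:
            raise ValueError(f"unknown model label {label!r}")
        channels = _MODEL_CHANNELS[label]
        if cfg.dual_input != (label == "dual"):
            raise ValueError(f"model {label!r}: dual_input flag does not match label")
        fold_results = []
        for fi, (train_ids, test_ids) in enumerate(folds):
            builder = build_deu if cfg.dual_input else build_single_sequence
            handle = builder(cfg, seed=seed + fi)
            samples = studies_to_samples([by_id[i] for i in train_ids], channels)
            handle, _history = train(handle, samples, train_config)
            metrics = []
            for pid in test_ids:
                prob = predict_study(handle, by_id[pid], channels)
                pred = postprocess_probability(prob, threshold, connectivity)
                metrics.append(evaluate_patient(pred, by_id[pid].gold.values))
            fold_results.append(FoldResult(fold_index=fi, model_label=label,
                                           patient_ids=list(test_ids), metrics=metrics))
            logger.info("model=%s fold=%d mean DSC=%.3f", label, fi,
                        fold_results[-1].mean("dsc"))
        results[label] = fold_results

    summary = {}
    for label, frs in results.items():
        summary[label] = {}
        for key in ("dsc", "sensitivity", "precision"):
            per_fold = np.array([fr.mean(key) for fr in frs])
            per_fold = per_fold[~np.isnan(per_fold)]
            per_patient = np.array([m[key] for fr in frs for m in fr.metrics
                                    if not math.isnan(m[key])])
            summary[label][key] = {
                "mean": float(per_fold.mean()) if per_fold.size else math.nan,
                "sd_over_folds": float(per_fold.std(ddof=1)) if per_fold.size > 1 else 0.0,
                "sd_over_patients": float(per_patient.std(ddof=1)) if per_patient.size > 1 else 0.0,
                "median_over_patients": float(np.median(per_patient)) if per_patient.size else math.nan,
            }

    tests = {}
    if "dual" in results:
        dual_dsc = [fr.mean("dsc") for fr in results["dual"]]
        for label in results:
            if label == "dual":
                continue
            single_dsc = [fr.mean("dsc") for fr in results[label]]
            u, p = mann_whitney_u(single_dsc, dual_dsc)
            tests[f"{label}_vs_dual"] = {"U": u, "p": p}

    return {"folds": folds, "results": results, "summary": summary,
            "mann_whitney": tests, "seed": seed, "k": k}
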