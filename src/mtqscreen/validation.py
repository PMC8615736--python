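"""Model validation battery.

Confusion-matrix statistics (Sn, Sp, Acc, F1, MCC), the random-accuracy
baseline

    Accrnd = 100 · ((TP+FN)(TP+FP) + (TN+FN)(TN+FP)) / N² ,

rank-based AUROC with ROC points, Yc-randomization (joint scrambling of the
response and the condition triples before recomputing the moving-average
descriptors and refitting), condition-wise accuracy tables, and the
standardization-approach applicability domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from . import boxjenkins, lda_engine
from .boxjenkins import AverageTable, DescriptorBlock, tag_column
from .core_data import ELEMENTS, Dataset
from .errors import DataError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "YcResult",
    "ADResult",
    "confusion",
    "metrics",
    "random_accuracy",
    "auroc",
    "yc_randomization",
    "conditionwise",
    "applicability_domain",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise DataError("confusion counts must be non-negative")
        if self.N < 1:
            raise DataError("confusion counts sum to zero")

    @property
    def N(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Cross-tabulate ±1 labels with +1 as the positive class."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.size != p.size:
        raise DataError(f"length mismatch: {t.size} true vs {p.size} predicted")
    if t.size == 0:
        raise DataError("empty label vectors")
    if set(np.unique(t)) - {1, -1} or set(np.unique(p)) - {1, -1}:
        raise DataError("labels must be ±1")
    return ConfusionCounts(
        TP=int(np.sum((t == 1) & (p == 1))),
        TN=int(np.sum((t == -1) & (p == -1))),
        FP=int(np.sum((t == -1) & (p == 1))),
        FN=int(np.sum((t == 1) & (p == -1))),
    )


@dataclass
class MetricsReport:
    """Percent-scale classification statistics plus MCC and Accrnd."""

    Sn: float
    Sp: float
    Acc: float
    F1: float
    MCC: float
    Accrnd: float
    AUROC: float | None = None
    counts: ConfusionCounts | None = None

    def to_dict(self) -> dict:
        d = {
            "Sn": self.Sn,
            "Sp": self.Sp,
            "Acc": self.Acc,
            "F1": self.F1,
            "MCC": self.MCC,
            "Accrnd": self.Accrnd,
            "AUROC": self.AUROC,
        }
        if self.counts is not None:
            d.update(
                TP=self.counts.TP, TN=self.counts.TN,
                FP=self.counts.FP, FN=self.counts.FN,
            )
        return d


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def random_accuracy(counts: ConfusionCounts) -> float:
    """Random-accuracy baseline (percent): the accuracy expected from the
    marginal class and prediction counts alone."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    n = counts.N
    return 100.0 * ((tp + fn) * (tp + fp) + (tn + fn) * (tn + fp)) / (n * n)


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Derive Sn/Sp/Acc/F1 (percent), MCC and Accrnd from counts.

    A zero MCC denominator (a degenerate margin) yields MCC = 0 by
    convention.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    mcc_den = float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den) if mcc_den > 0 else 0.0
    return MetricsReport(
        Sn=100.0 * _safe_ratio(tp, tp + fn),
        Sp=100.0 * _safe_ratio(tn, tn + fp),
        Acc=100.0 * (tp + tn) / counts.N,
        F1=100.0 * _safe_ratio(2 * tp, 2 * tp + fp + fn),
        MCC=float(mcc),
        Accrnd=random_accuracy(counts),
        counts=counts,
    )


def auroc(
    scores: Sequence[float], y_true: Sequence[int]
) -> tuple[float, list[tuple[float, float]]]:
    """Rank-based (Mann–Whitney, ties ½) AUROC and ROC sweep points.

    Returns the AUROC and a list of (FPR, TPR) points from thresholding at
    every unique score.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len({1, -1} & set(np.unique(y))) < 2:
        raise DataError("AUROC needs both classes present")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


@dataclass
class YcResult:
    """Mean Wilks lambda and sub-training accuracy over randomized refits."""

    lambda_r: float
    accuracy_r: float
    n_runs: int
    seed: int
    per_run: list[dict] = field(default_factory=list)


def yc_randomization(
    raw_block: DescriptorBlock,
    dataset: Dataset,
    feature_names: Sequence[str],
    training_rows: Sequence[int],
    sub_training_rows: Sequence[int],
    n_runs: int = 100,
    seed: int = 0,
    joint: bool = True,
    priors: str = "empirical",
) -> YcResult:
    """Scramble the response and condition elements, rebuild, refit.

    Per run the (label, bt, me, at) tuples are permuted across rows relative
    to the raw descriptor matrix (jointly by default; independently with
    ``joint=False``), the training-active averages and modified descriptors
    are recomputed from the permuted data, and the *same* modified-feature
    set is refit on the sub-training rows.  Reported are the mean Wilks
    lambda and mean sub-training accuracy (percent) over runs — for a
    genuine model both should collapse toward 1 and the majority-class rate.

    The randomized refits use class-frequency priors by default: with no
    signal left, such a discriminant degenerates to predicting the majority
    class, which is the correct no-information accuracy baseline (an
    equal-priors boundary would drift toward a 50% split instead).
    """
    if n_runs < 1:
        raise DataError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    records = dataset.records
    per_run: list[dict] = []
    sub_rows = np.asarray(sub_training_rows, dtype=int)

    for run in range(n_runs):
        import dataclasses as _dc

        if joint:
            perm = rng.permutation(n)
            shuffled = [
                _dc.replace(
                    records[i],
                    label=records[perm[i]].label,
                    condition=records[perm[i]].condition,
                )
                for i in range(n)
            ]
        else:
            perm_lab = rng.permutation(n)
            perm_cond = rng.permutation(n)
            shuffled = [
                _dc.replace(
                    records[i],
                    label=records[perm_lab[i]].label,
                    condition=records[perm_cond[i]].condition,
                )
                for i in range(n)
            ]
        scrambled = Dataset(shuffled)
        averages = boxjenkins.fit_averages(raw_block, scrambled, training_rows)
        modified = boxjenkins.transform(
            raw_block, scrambled, averages, fallback_global=True
        )
        sub_block = modified.take(sub_rows).select(list(feature_names))
        y_sub = scrambled.labels()[sub_rows]
        try:
            model = lda_engine.fit(sub_block, y_sub, priors=priors)
        except DataError:
            continue  # a degenerate scramble (e.g. collinear); skip, keep count honest
        pred = lda_engine.classify(model, sub_block)
        per_run.append(
            {
                "run": run,
                "wilks": model.wilks_lambda,
                "accuracy": 100.0 * float(np.mean(pred == y_sub)),
            }
        )
    if not per_run:
        raise DataError("every randomized refit failed")
    return YcResult(
        lambda_r=float(np.mean([r["wilks"] for r in per_run])),
        accuracy_r=float(np.mean([r["accuracy"] for r in per_run])),
        n_runs=len(per_run),
        seed=seed,
        per_run=per_run,
    )


def conditionwise(
    predictions: Sequence[int], dataset: Dataset, set_label: str = ""
) -> pd.DataFrame:
    """Per-(me, at, bt) instance counts and percent accuracy.

    Row order follows the first occurrence of each condition in the dataset.
    Instance-weighted, the reported accuracies recompose the overall
    accuracy exactly.
    """
    pred = np.asarray(predictions, dtype=int)
    if pred.size != len(dataset):
        raise DataError("predictions not aligned with dataset")
    y = dataset.labels()
    rows = []
    for k, cond in enumerate(dataset.conditions(), start=1):
        mask = np.asarray([r.condition == cond for r in dataset.records])
        n_inst = int(mask.sum())
        acc = 100.0 * float(np.mean(pred[mask] == y[mask]))
        rows.append(
            {
                "condition": k,
                "me": cond.me,
                "at": cond.at,
                "bt": cond.bt,
                "set": set_label,
                "n_instances": n_inst,
                "accuracy_pct": acc,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ADResult:
    inside: bool
    z_scores: dict[str, float]


def applicability_domain(
    feature_stats: Mapping[str, Mapping[str, float]],
    query: Mapping[str, float],
    z_max: float = 3.0,
    k: float = 1.28,
) -> ADResult:
    """Standardization-approach structural-outlier check.

    z_i = |x_i − mean_i| / SD_i over the model descriptors.  All z ≤ z_max
    ⇒ inside; min z > z_max ⇒ outlier; otherwise inside iff
    mean(z) + k·SD(z) ≤ z_max (sample SD).
    """
    if not feature_stats:
        raise DataError("no applicability-domain statistics available")
    missing = [f for f in feature_stats if f not in query]
    if missing:
        raise DataError(f"query is missing model descriptor(s): {missing}")
    z: dict[str, float] = {}
    for f, st in feature_stats.items():
        dev = abs(float(query[f]) - st["mean"])
        if st["sd"] > 0:
            z[f] = dev / st["sd"]
        else:
            z[f] = 0.0 if dev == 0.0 else float("inf")
    zv = np.array(list(z.values()))
    if np.all(zv <= z_max):
        inside = True
    elif np.min(zv) > z_max:
        inside = False
    else:
        spread = float(zv.std(ddof=1)) if zv.size > 1 else 0.0
        inside = float(zv.mean()) + k * spread <= z_max
    return ADResult(inside=inside, z_scores=z)


def ad_flags_matrix(
    feature_stats: Mapping[str, Mapping[str, float]],
    block: DescriptorBlock,
    z_max: float = 3.0,
    k: float = 1.28,
) -> np.ndarray:
    """Vectorized applicability-domain check: True where the row is inside."""
    names = list(feature_stats)
    X = block.select(names).values
    mean = np.array([feature_stats[f]["mean"] for f in names])
    sd = np.array([feature_stats[f]["sd"] for f in names])
    dev = np.abs(X - mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = np.where(sd > 0, dev / np.where(sd > 0, sd, 1.0), np.where(dev == 0, 0.0, np.inf))
    all_in = np.all(Z <= z_max, axis=1)
    all_out = np.min(Z, axis=1) > z_max
    if Z.shape[1] > 1:
        borderline_in = Z.mean(axis=1) + k * Z.std(axis=1, ddof=1) <= z_max
    else:
        borderline_in = np.zeros(Z.shape[0], dtype=bool)
    return np.where(all_in, True, np.where(all_out, False, borderline_in))
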