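"""Post-selection similarity-search-based modification (PS3M).

Iterative refinement of a fitted linear discriminant by single-descriptor
substitution.  For each descriptor in the reference model the ``m`` nearest
columns of the pretreated modified-descriptor block — by Euclidean distance
d(D1, D2) = sqrt(Σ(D1i − D2i)²) over the modeling rows, excluding
near-duplicates with ED ≈ 0 — form a candidate pool, giving up to m·p
alternative single-swap models per round.  An alternative is eligible only
if its sub-training MCC does not fall below the reference's; the eligible
alternative with the highest mean of sub-training and test MCC is accepted
when it strictly beats the reference mean, becomes the new reference, and
the process repeats until a fixed point (the test set acts purely as a
calibration set; external data is never seen).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import lda_engine, validation
from .boxjenkins import DescriptorBlock
from .errors import ConfigurationError, DataError
from .lda_engine import LinearDiscriminantModel


@dataclass
class PS3MConfig:
    m: int = 10
    epsilon_zero: float = 1e-8
    max_rounds: int = 50

    def __post_init__(self):
        if self.m < 1:
            raise ConfigurationError("m must be >= 1")
        if self.epsilon_zero < 0:
            raise ConfigurationError("epsilon_zero must be >= 0")


def column_distance(d1: np.ndarray, d2: np.ndarray) -> float:
    """Euclidean distance between two descriptor columns."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape:
        raise DataError(f"column length mismatch: {d1.shape} vs {d2.shape}")
    return float(np.linalg.norm(d1 - d2))


def neighbor_pool(
    features: Sequence[str],
    block: DescriptorBlock,
    config: PS3MConfig | None = None,
    standardize: bool = False,
) -> dict[str, list[tuple[str, float]]]:
    """Per model descriptor: the m ED-nearest candidate columns.

    Candidates with ED ≤ epsilon_zero (effectively duplicates) and columns
    already in the model are excluded.  ``standardize`` optionally computes
    distances on z-scored columns, since raw ED is scale-sensitive
    (default off: distances on the stored column values).
    """
    config = config or PS3MConfig()
    features = list(features)
    missing = [f for f in features if f not in block.column_names]
    if missing:
        raise DataError(f"model feature(s) not in block: {missing}")
    X = block.values
    if standardize:
        sd = X.std(axis=0, ddof=1)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    names = block.column_names
    in_model = set(features)
    pools: dict[str, list[tuple[str, float]]] = {}
    for f in features:
        ref = X[:, names.index(f)]
        dists = np.linalg.norm(X - ref[:, None], axis=0)
        order = np.argsort(dists, kind="stable")
        pool: list[tuple[str, float]] = []
        for j in order:
            cand = names[j]
            if cand in in_model or dists[j] <= config.epsilon_zero:
                continue
            pool.append((cand, float(dists[j])))
            if len(pool) == config.m:
                break
        pools[f] = pool
    return pools


@dataclass
class PS3MRound:
    round_index: int
    replaced: str
    replacement: str
    mean_mcc_before: float
    mean_mcc_after: float
    sub_mcc: float
    test_mcc: float
    sub_acc: float
    test_acc: float


@dataclass
class PS3MTrace:
    rounds: list[PS3MRound] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rounds])


def _evaluate(
    features: list[str],
    block: DescriptorBlock,
    labels: np.ndarray,
    sub_rows: np.ndarray,
    test_rows: np.ndarray,
):
    """Refit on sub-training rows; MCC and accuracy on sub and test rows."""
    sub_block = block.take(sub_rows).select(features)
    model = lda_engine.fit(sub_block, labels[sub_rows])
    out = {}
    for name, rows in (("sub", sub_rows), ("test", test_rows)):
        b = block.take(rows).select(features)
        pred = lda_engine.classify(model, b)
        rep = validation.metrics(validation.confusion(labels[rows], pred))
        out[name] = rep
    return model, out


def refine(
    model: LinearDiscriminantModel,
    block: DescriptorBlock,
    labels: np.ndarray,
    sub_training_rows: Sequence[int],
    test_rows: Sequence[int],
    config: PS3MConfig | None = None,
    standardize: bool = False,
) -> tuple[LinearDiscriminantModel, PS3MTrace]:
    """Hill-climb over ED-neighbor single swaps until no better model exists.

    Acceptance: sub-training MCC must not drop below the current reference's,
    and the mean of sub-training and test MCC must strictly increase.  Ties
    among equal-mean candidates break toward the smaller ED, then the
    lexicographically smaller replacement name.
    """
    config = config or PS3MConfig()
    labels = np.asarray(labels, dtype=int)
    sub_rows = np.asarray(sub_training_rows, dtype=int)
    test_rows = np.asarray(test_rows, dtype=int)

    features = list(model.feature_names)
    current_model, reps = _evaluate(features, block, labels, sub_rows, test_rows)
    ref_sub, ref_test = reps["sub"].MCC, reps["test"].MCC
    ref_mean = (ref_sub + ref_test) / 2.0
    trace = PS3MTrace()

    for round_index in range(1, config.max_rounds + 1):
        pools = neighbor_pool(features, block, config, standardize=standardize)
        if all(len(p) == 0 for p in pools.values()):
            import warnings

            warnings.warn("PS3M: no substitution candidates; refinement is a no-op")
            break
        best = None  # (mean, -ed, replaced, cand, model, reps)
        for pos, feat in enumerate(features):
            for cand, ed in pools[feat]:
                alt = list(features)
                alt[pos] = cand
                try:
                    alt_model, alt_reps = _evaluate(alt, block, labels, sub_rows, test_rows)
                except DataError:
                    continue
                sub_mcc = alt_reps["sub"].MCC
                if sub_mcc < ref_sub:  # never compromise the sub-training fit
                    continue
                mean_mcc = (sub_mcc + alt_reps["test"].MCC) / 2.0
                key = (-mean_mcc, ed, cand)
                if best is None or key < best[0]:
                    best = (key, feat, cand, pos, alt_model, alt_reps)
        if best is None or -best[0][0] <= ref_mean:
            break
        _, replaced, cand, pos, current_model, reps = best
        features[pos] = cand
        new_mean = (reps["sub"].MCC + reps["test"].MCC) / 2.0
        trace.rounds.append(
            PS3MRound(
                round_index=round_index,
                replaced=replaced,
                replacement=cand,
                mean_mcc_before=ref_mean,
                mean_mcc_after=new_mean,
                sub_mcc=reps["sub"].MCC,
                test_mcc=reps["test"].MCC,
                sub_acc=reps["sub"].Acc,
                test_acc=reps["test"].Acc,
            )
        )
        ref_sub, ref_test, ref_mean = reps["sub"].MCC, reps["test"].MCC, new_mean

    return current_model, trace
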