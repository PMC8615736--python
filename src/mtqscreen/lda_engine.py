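"""Two-class linear discriminant modeling on modified descriptors.

The discriminant is the classical Fisher direction ``w ∝ Sw⁻¹(μ₊ − μ₋)``
with pooled within-class covariance and (by default) equal priors, so the
decision boundary sits at the pooled class-mean midpoint and a record is
classified by the sign of the affine score

    score(x) = w·x − w·(μ₊ + μ₋)/2 .

Goodness of fit is summarized by the Wilks lambda of the one-dimensional
discriminant scores (within-group over total sum of squares), the associated
F statistic ``F = ((1−λ)/λ)·(N−p−1)/p`` for two groups with p predictors,
and its upper-tail p-value.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .boxjenkins import DescriptorBlock, ModifiedBlock
from .errors import ConfigurationError, DataError


def pretreat(
    block: ModifiedBlock,
    variance_cutoff: float = 0.001,
    correlation_cutoff: float = 0.95,
) -> tuple[ModifiedBlock, list[dict]]:
    """Drop near-constant then highly inter-correlated columns.

    Columns with sample variance below ``variance_cutoff`` are removed first;
    the survivors are scanned left to right and any later column whose
    absolute Pearson correlation with an already-retained column exceeds
    ``correlation_cutoff`` is removed (first retained wins).  Returns the
    reduced block and a removal log.
    """
    X = block.values
    names = block.column_names
    log: list[dict] = []

    variances = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    keep_var = []
    for j, name in enumerate(names):
        if variances[j] < variance_cutoff:
            log.append(
                {"column": name, "cause": "low_variance", "variance": float(variances[j])}
            )
        else:
            keep_var.append(j)
    if not keep_var:
        raise DataError("pretreatment removed every column (all near-constant)")

    sub = X[:, keep_var]
    # correlations among variance survivors, computed once
    corr = np.corrcoef(sub, rowvar=False)
    if corr.ndim == 0:  # single surviving column
        corr = np.ones((1, 1))
    retained: list[int] = []
    for local_j in range(sub.shape[1]):
        offender = None
        for r in retained:
            if abs(corr[local_j, r]) > correlation_cutoff:
                offender = r
                break
        if offender is None:
            retained.append(local_j)
        else:
            log.append(
                {
                    "column": names[keep_var[local_j]],
                    "cause": "correlated",
                    "with": names[keep_var[offender]],
                    "r": float(corr[local_j, offender]),
                }
            )
    kept_names = [names[keep_var[j]] for j in retained]
    return block.select(kept_names), log


@dataclass
class LinearDiscriminantModel:
    """A fitted two-class linear discriminant.

    ``feature_stats`` carries the per-feature training mean and sample SD,
    used for standardized coefficients and applicability-domain checks.
    """

    feature_names: list[str]
    intercept: float
    coefficients: dict[str, float]
    wilks_lambda: float
    f_stat: float
    p_value: float
    standardized_coefficients: dict[str, float]
    feature_stats: dict[str, dict[str, float]]
    training_fingerprint: str
    n_training: int
    priors: str = "equal"

    def ranked_standardized(self) -> list[tuple[str, float]]:
        """(name, |standardized coefficient|) sorted descending, for the
        descriptor-importance bar output."""
        return sorted(
            self.standardized_coefficients.items(), key=lambda kv: (-kv[1], kv[0])
        )

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "wilks_lambda": self.wilks_lambda,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "standardized_coefficients": dict(self.standardized_coefficients),
            "feature_stats": {k: dict(v) for k, v in self.feature_stats.items()},
            "training_fingerprint": self.training_fingerprint,
            "n_training": self.n_training,
            "priors": self.priors,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinearDiscriminantModel":
        return cls(
            feature_names=list(d["feature_names"]),
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            wilks_lambda=float(d.get("wilks_lambda", 1.0)),
            f_stat=float(d.get("f_stat", 0.0)),
            p_value=float(d.get("p_value", 1.0)),
            standardized_coefficients={
                k: float(v)
                for k, v in d.get("standardized_coefficients", {}).items()
            },
            feature_stats={
                k: {kk: float(vv) for kk, vv in v.items()}
                for k, v in d.get("feature_stats", {}).items()
            },
            training_fingerprint=str(d.get("training_fingerprint", "")),
            n_training=int(d.get("n_training", 0)),
            priors=str(d.get("priors", "equal")),
        )


def _collinear_feature_names(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name columns beyond the numerical rank (rank-revealing QR pivots)."""
    from scipy.linalg import qr

    _, r, piv = qr(X - X.mean(axis=0), mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    return sorted(names[j] for j in piv[rank:])


def goodness_of_fit(
    scores: np.ndarray, labels: np.ndarray, n_features: int = 1
) -> tuple[float, float, float]:
    """Wilks lambda, F statistic and p-value of discriminant scores.

    lambda = within-group SS / total SS of the scores; for two groups with
    p predictors, ``F = ((1−λ)/λ)·(N−p−1)/p`` on (p, N−p−1) degrees of
    freedom.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {1, -1}:
        raise DataError("labels must be ±1")
    if len({1, -1} & set(np.unique(labels))) < 2:
        raise DataError("both classes must be present")
    total_ss = float(np.sum((scores - scores.mean()) ** 2))
    if total_ss == 0.0:
        raise DataError("scores have zero total variance")
    within_ss = 0.0
    for g in (1, -1):
        s = scores[labels == g]
        within_ss += float(np.sum((s - s.mean()) ** 2))
    lam = within_ss / total_ss
    n = scores.size
    p = max(int(n_features), 1)
    df2 = n - p - 1
    if df2 <= 0:
        raise DataError(f"too few rows (N={n}) for {p} predictors")
    f_stat = ((1.0 - lam) / lam) * (df2 / p) if lam > 0 else np.inf
    p_value = float(stats.f.sf(f_stat, p, df2))
    return float(lam), float(f_stat), p_value


def fit(
    block: DescriptorBlock,
    labels: np.ndarray,
    features: Sequence[str] | None = None,
    priors: str = "equal",
) -> LinearDiscriminantModel:
    """Fit the Fisher discriminant on the given rows and feature subset.

    ``priors="empirical"`` shifts the intercept by ``ln(n₊/n₋)`` scaled to
    the discriminant, mimicking class-frequency priors; the default keeps
    the boundary at the pooled midpoint.
    """
    if priors not in ("equal", "empirical"):
        raise ConfigurationError(f"priors must be 'equal' or 'empirical'; got {priors!r}")
    features = list(features) if features is not None else list(block.column_names)
    if not features:
        raise DataError("cannot fit a model with no features")
    sub = block.select(features)
    X = sub.values
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.size:
        raise DataError("labels not aligned with block rows")
    if set(np.unique(y)) != {1, -1}:
        raise DataError("fit requires both classes, labels ±1")

    pos, neg = X[y == 1], X[y == -1]
    n_pos, n_neg, n = pos.shape[0], neg.shape[0], X.shape[0]
    mu_pos, mu_neg = pos.mean(axis=0), neg.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0.0):
        bad = [f for f, s in zip(features, sds) if s == 0.0]
        raise DataError(f"constant feature(s) within the fit rows: {bad}")

    # pooled within-class covariance
    sw = (
        (pos - mu_pos).T @ (pos - mu_pos) + (neg - mu_neg).T @ (neg - mu_neg)
    ) / (n - 2)
    try:
        w = np.linalg.solve(sw, mu_pos - mu_neg)
    except np.linalg.LinAlgError:
        w = None
    if w is None or not np.all(np.isfinite(w)) or np.linalg.cond(sw) > 1e12:
        bad = _collinear_feature_names(X, features)
        raise DataError(
            f"singular pooled covariance; collinear feature(s): {bad or features}"
        )

    intercept = -float(w @ (mu_pos + mu_neg) / 2.0)
    if priors == "empirical":
        intercept += float(np.log(n_pos / n_neg))

    scores = X @ w + intercept
    lam, f_stat, p_value = goodness_of_fit(scores, y, n_features=len(features))
    std_coef = {f: abs(float(c) * float(s)) for f, c, s in zip(features, w, sds)}
    stats_map = {
        f: {"mean": float(m), "sd": float(s)}
        for f, m, s in zip(features, X.mean(axis=0), sds)
    }
    digest = hashlib.sha256()
    digest.update(np.ascontiguousarray(X).tobytes())
    digest.update(np.ascontiguousarray(y).tobytes())
    return LinearDiscriminantModel(
        feature_names=features,
        intercept=intercept,
        coefficients={f: float(c) for f, c in zip(features, w)},
        wilks_lambda=lam,
        f_stat=f_stat,
        p_value=p_value,
        standardized_coefficients=std_coef,
        feature_stats=stats_map,
        training_fingerprint=digest.hexdigest()[:16],
        n_training=n,
        priors=priors,
    )


def score(model: LinearDiscriminantModel, block: DescriptorBlock) -> np.ndarray:
    """Apply the affine discriminant row-wise."""
    missing = [f for f in model.feature_names if f not in block.column_names]
    if missing:
        raise DataError(f"block is missing model feature(s): {missing}")
    X = block.select(model.feature_names).values
    w = np.array([model.coefficients[f] for f in model.feature_names])
    return X @ w + model.intercept


def classify(model: LinearDiscriminantModel, block: DescriptorBlock) -> np.ndarray:
    """Predicted ±1 labels: +1 where score > 0, else −1."""
    return np.where(score(model, block) > 0, 1, -1)


def standardized_coefficients(
    model: LinearDiscriminantModel, block: DescriptorBlock | None = None
) -> list[tuple[str, float]]:
    """|coefficient × training SD| per feature, sorted descending.

    With ``block`` given, SDs are recomputed from it (it must be the model's
    training block); otherwise the SDs stored at fit time are used.
    """
    if block is None:
        return model.ranked_standardized()
    sub = block.select(model.feature_names)
    sds = sub.values.std(axis=0, ddof=1)
    pairs = [
        (f, abs(model.coefficients[f] * float(s)))
        for f, s in zip(model.feature_names, sds)
    ]
    return sorted(pairs, key=lambda kv: (-kv[1], kv[0]))


def wilks_lambda_features(
    X: np.ndarray, y: np.ndarray, feature_idx: Sequence[int]
) -> float:
    """Multivariate Wilks lambda det(W)/det(T) for a column subset.

    Returns NaN when the subset is numerically singular (the caller should
    treat such subsets as invalid candidates).  An empty subset has
    lambda = 1 (the null model).
    """
    idx = list(feature_idx)
    if not idx:
        return 1.0
    Xs = np.asarray(X)[:, idx]
    y = np.asarray(y)
    total_dev = Xs - Xs.mean(axis=0)
    T = total_dev.T @ total_dev
    W = np.zeros_like(T)
    for g in (1, -1):
        grp = Xs[y == g]
        if grp.shape[0] < 2:
            return float("nan")
        dev = grp - grp.mean(axis=0)
        W += dev.T @ dev
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        return float("nan")
    return float(np.exp(logdet_w - logdet_t))
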