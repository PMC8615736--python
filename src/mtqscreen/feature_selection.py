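"""Descriptor-subset selection for the linear discriminant model.

Three schemes are provided, all capped at ``max_features`` descriptors:

* :func:`fs_stepwise` — fast stepwise discriminant analysis driven by the
  partial-Wilks-lambda F test (p-to-enter / p-to-remove, both 0.05 by
  default);
* :func:`sfs` — greedy sequential forward selection maximizing a refit
  accuracy or AUROC score;
* :func:`ga_select` — a genetic algorithm over subsets, minimizing the
  multivariate Wilks lambda, with the best model kept across independent
  runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from . import lda_engine
from .boxjenkins import DescriptorBlock
from .errors import ConfigurationError, DataError
from .lda_engine import wilks_lambda_features


@dataclass
class SelectionConfig:
    """Hyper-parameters shared by the three selectors.

    Defaults follow the stepwise p-to-enter/p-to-remove of 0.05, a cap of 10
    descriptors, and the genetic-algorithm settings of 100 equations per
    generation, 30 survivors, mutation probability 0.3 and 20 independent
    runs.
    """

    max_features: int = 10
    p_enter: float = 0.05
    p_remove: float = 0.05
    sfs_scorer: str = "accuracy"
    ga_population: int = 100
    ga_keep: int = 30
    ga_mutation: float = 0.3
    ga_runs: int = 20
    ga_generations: int = 100
    seed: int = 0

    def __post_init__(self):
        for name in ("p_enter", "p_remove", "ga_mutation"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1); got {v}")
        if not (self.ga_population >= self.ga_keep >= 1):
            raise ConfigurationError("need ga_population >= ga_keep >= 1")
        if self.max_features < 1:
            raise ConfigurationError("max_features must be >= 1")
        if self.sfs_scorer not in ("accuracy", "auroc"):
            raise ConfigurationError(
                f"sfs_scorer must be 'accuracy' or 'auroc'; got {self.sfs_scorer!r}"
            )


def _check_inputs(block: DescriptorBlock, labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if y.size != block.n_rows:
        raise DataError("labels not aligned with block rows")
    if set(np.unique(y)) != {1, -1}:
        raise DataError("selection requires both classes, labels ±1")
    return y


def _partial_f_p(lam_full: float, lam_reduced: float, n: int, k_reduced: int):
    """F and p for adding one variable to a k_reduced-variable 2-group model."""
    partial = lam_full / lam_reduced if lam_reduced > 0 else np.nan
    df2 = n - 2 - k_reduced
    if not np.isfinite(partial) or partial < 0 or df2 <= 0:
        return np.nan, np.nan
    if partial == 0.0:  # perfect separation
        return np.inf, 0.0
    f = df2 * (1.0 - partial) / partial
    return f, float(stats.f.sf(f, 1, df2))


def fs_stepwise(
    block: DescriptorBlock, labels: np.ndarray, config: SelectionConfig | None = None
) -> tuple[list[str], list[dict]]:
    """Fast stepwise discriminant selection.

    At each step the candidate minimizing the model's Wilks lambda enters if
    its F-to-enter p-value is below ``p_enter``; after every entry, included
    features whose F-to-remove p-value exceeds ``p_remove`` are dropped
    (worst first).  Stops at ``max_features`` or when no candidate
    qualifies.  Returns the selected names and a step log.
    """
    config = config or SelectionConfig()
    y = _check_inputs(block, labels)
    X = block.values
    n, n_cols = X.shape
    included: list[int] = []
    lam_current = 1.0
    log: list[dict] = []
    seen_states: set[frozenset] = set()
    step = 0

    while len(included) < config.max_features:
        best = None  # (lam, col, f, p)
        for j in range(n_cols):
            if j in included:
                continue
            lam_j = wilks_lambda_features(X, y, included + [j])
            if not np.isfinite(lam_j):
                continue
            f, p = _partial_f_p(lam_j, lam_current, n, len(included))
            if not np.isfinite(p):
                continue
            if best is None or (lam_j, j) < (best[0], best[1]):
                best = (lam_j, j, f, p)
        if best is None or best[3] >= config.p_enter:
            break
        lam_current, entered, f, p = best
        included.append(entered)
        step += 1
        log.append(
            {
                "step": step,
                "action": "enter",
                "feature": block.column_names[entered],
                "wilks": lam_current,
                "F": f,
                "p": p,
            }
        )

        # backward phase: drop any included feature that no longer earns its place
        while len(included) > 1:
            worst = None  # (p, lam_without, k)
            for k in included:
                others = [i for i in included if i != k]
                lam_without = wilks_lambda_features(X, y, others)
                if not np.isfinite(lam_without):
                    continue
                f_k, p_k = _partial_f_p(lam_current, lam_without, n, len(others))
                if not np.isfinite(p_k):
                    continue
                if worst is None or (-p_k, k) < (-worst[0], worst[2]):
                    worst = (p_k, lam_without, k)
            if worst is None or worst[0] <= config.p_remove:
                break
            p_k, lam_current, removed = worst
            included.remove(removed)
            step += 1
            log.append(
                {
                    "step": step,
                    "action": "remove",
                    "feature": block.column_names[removed],
                    "wilks": lam_current,
                    "F": np.nan,
                    "p": p_k,
                }
            )

        state = frozenset(included)
        if state in seen_states:  # cycle guard for p_enter == p_remove edge cases
            break
        seen_states.add(state)

    return [block.column_names[j] for j in included], log


def _refit_score(
    X: np.ndarray, y: np.ndarray, idx: Sequence[int], names: list[str], scorer: str
) -> float:
    sub = DescriptorBlock(
        column_names=[names[j] for j in idx], values=X[:, list(idx)]
    )
    try:
        model = lda_engine.fit(sub, y)
    except DataError:
        return -np.inf
    s = lda_engine.score(model, sub)
    if scorer == "auroc":
        return float(roc_auc_score(y, s))
    return float(np.mean(np.where(s > 0, 1, -1) == y))


def sfs(
    block: DescriptorBlock, labels: np.ndarray, config: SelectionConfig | None = None
) -> list[str]:
    """Greedy sequential forward selection by refit score.

    Adds the feature that most improves the scorer ('accuracy' or 'auroc')
    of a model refit on the given rows; stops when no strict improvement is
    possible or at ``max_features``.  Ties break toward the lower column
    index.
    """
    config = config or SelectionConfig()
    y = _check_inputs(block, labels)
    X = block.values
    included: list[int] = []
    best_score = -np.inf
    while len(included) < config.max_features:
        best = None  # (score, col)
        for j in range(X.shape[1]):
            if j in included:
                continue
            s = _refit_score(X, y, included + [j], block.column_names, config.sfs_scorer)
            if best is None or (-s, j) < (-best[0], best[1]):
                best = (s, j)
        if best is None or best[0] <= best_score:
            break
        best_score = best[0]
        included.append(best[1])
    return [block.column_names[j] for j in included]


def _dedupe(genes: Sequence[int]) -> list[int]:
    out: list[int] = []
    for g in genes:
        if g not in out:
            out.append(g)
    return out


def _random_genome(rng: np.random.Generator, n_cols: int, config: SelectionConfig):
    hi = min(config.max_features, n_cols)
    lo = min(2, hi)
    size = int(rng.integers(lo, hi + 1))
    return list(rng.choice(n_cols, size=size, replace=False))


def _crossover_mutate(
    rng: np.random.Generator, a: list[int], b: list[int], n_cols: int,
    config: SelectionConfig,
) -> list[int]:
    # uniform crossover: each slot drawn from either parent's gene at that slot
    length = len(a) if rng.random() < 0.5 else len(b)
    child: list[int] = []
    for i in range(length):
        pool = [p[i] for p in (a, b) if i < len(p)]
        child.append(pool[int(rng.integers(len(pool)))])
    child = _dedupe(child)
    # per-gene mutation: replace the gene with a random unused column
    for i in range(len(child)):
        if rng.random() < config.ga_mutation:
            free = np.setdiff1d(np.arange(n_cols), child)
            if free.size:
                child[i] = int(rng.choice(free))
    child = _dedupe(child)
    while len(child) < min(2, n_cols):
        free = np.setdiff1d(np.arange(n_cols), child)
        child.append(int(rng.choice(free)))
    return child[: config.max_features]


def _ga_single_run(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator, config: SelectionConfig,
    cache: dict,
) -> tuple[float, tuple[int, ...]]:
    n_cols = X.shape[1]

    def fitness(genome: Sequence[int]) -> float:
        key = frozenset(genome)
        if key not in cache:
            lam = wilks_lambda_features(X, y, sorted(key))
            cache[key] = lam if np.isfinite(lam) else np.inf
        return cache[key]

    population = [_random_genome(rng, n_cols, config) for _ in range(config.ga_population)]
    best_lam, best_genome = np.inf, tuple()
    for _ in range(config.ga_generations + 1):
        scored = sorted(
            ((fitness(g), tuple(sorted(g)), g) for g in population),
            key=lambda t: (t[0], t[1]),
        )
        if scored[0][0] < best_lam or (
            scored[0][0] == best_lam and scored[0][1] < best_genome
        ):
            best_lam, best_genome = scored[0][0], scored[0][1]
        survivors = [t[2] for t in scored[: config.ga_keep]]
        population = list(survivors)
        while len(population) < config.ga_population:
            i, j = rng.integers(len(survivors)), rng.integers(len(survivors))
            population.append(
                _crossover_mutate(rng, survivors[int(i)], survivors[int(j)], n_cols, config)
            )
    return best_lam, best_genome


def ga_select(
    block: DescriptorBlock, labels: np.ndarray, config: SelectionConfig | None = None
) -> tuple[list[str], list[dict]]:
    """Genetic-algorithm subset selection minimizing Wilks lambda.

    A genome is a variable-length list of column indices (one gene per
    equation term).  Each generation keeps the ``ga_keep`` fittest genomes
    and refills the population by uniform crossover of random survivor pairs
    with per-gene mutation.  The best subset over ``ga_runs`` independent
    runs is returned, together with a per-run log; fully reproducible from
    ``config.seed``.
    """
    config = config or SelectionConfig()
    y = _check_inputs(block, labels)
    X = block.values
    cache: dict = {}
    run_log: list[dict] = []
    best_lam, best_genome = np.inf, tuple()
    seeds = np.random.SeedSequence(config.seed).spawn(config.ga_runs)
    for run, ss in enumerate(seeds):
        lam, genome = _ga_single_run(X, y, np.random.default_rng(ss), config, cache)
        run_log.append(
            {
                "run": run,
                "wilks": lam,
                "features": [block.column_names[j] for j in genome],
            }
        )
        if lam < best_lam or (lam == best_lam and genome < best_genome):
            best_lam, best_genome = lam, genome
    return [block.column_names[j] for j in best_genome], run_log
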