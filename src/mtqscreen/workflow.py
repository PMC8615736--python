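"""End-to-end training and prediction pipelines.

``run_train`` executes the stages in modeling order: label assignment →
duplicate curation → external/test/sub-training split → training-active
moving averages → descriptor modification → pretreatment → feature
selection → discriminant fit → PS3M refinement → full validation
(sub-training / test / external metrics, condition-wise tables,
Yc-randomization) → artifact and reports on disk.  ``run_predict`` applies
a saved artifact to a new compound table across conditions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import boxjenkins, feature_selection, lda_engine, ps3m, screening, validation
from .artifact import ModelArtifact
from .boxjenkins import DescriptorBlock, read_descriptor_matrix
from .core_data import (
    DEFAULT_CUTOFFS,
    Dataset,
    SplitSpec,
    assign_labels,
    curate,
    load_activity_table,
    split_random,
)
from .errors import ConfigurationError, DataError
from .feature_selection import SelectionConfig
from .ps3m import PS3MConfig

logger = logging.getLogger("mtqscreen")

SELECTORS = ("stepwise", "sfs", "ga")


@dataclass
class RunConfig:
    """Validated configuration for a full training run."""

    activity_table: str
    descriptor_matrix: str
    out_dir: str
    selector: str = "stepwise"
    cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    split: SplitSpec = field(default_factory=SplitSpec)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    ps3m: PS3MConfig = field(default_factory=PS3MConfig)
    run_ps3m: bool = True
    yc_runs: int = 100
    yc_seed: int = 0
    fallback_global: bool = False
    variance_cutoff: float = 0.001
    correlation_cutoff: float = 0.95

    def __post_init__(self):
        if self.selector not in SELECTORS:
            raise ConfigurationError(
                f"unknown selector {self.selector!r}; expected one of {SELECTORS}"
            )
        if self.yc_runs < 0:
            raise ConfigurationError("yc_runs must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class TrainResult:
    artifact: ModelArtifact
    metrics: dict  # set name -> MetricsReport dict
    conditionwise: dict  # set name -> DataFrame
    yc: validation.YcResult | None
    trace: ps3m.PS3MTrace | None
    selection_log: list
    pretreat_log: list
    paths: dict


def _align(dataset: Dataset, block: DescriptorBlock) -> tuple[Dataset, DescriptorBlock]:
    """Subset the descriptor matrix to the dataset rows and renumber
    positions 0..n-1 so later row indices address both objects."""
    positions = dataset.row_indices
    sub = block.take(positions)
    renumbered = Dataset(
        [dataclasses.replace(r, row_index=i) for i, r in enumerate(dataset.records)]
    )
    return renumbered, sub


def run_train(config: RunConfig) -> TrainResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    dataset = load_activity_table(config.activity_table)
    block = read_descriptor_matrix(config.descriptor_matrix)
    if block.n_rows != len(dataset):
        raise DataError(
            f"descriptor matrix has {block.n_rows} rows but activity table has "
            f"{len(dataset)} records"
        )
    logger.info("loaded %d records, %d raw descriptors", len(dataset), len(block.column_names))

    dataset, excluded = assign_labels(dataset, config.cutoffs)
    dataset, curation = curate(dataset)
    logger.info(
        "labels assigned (%d ambiguous excluded); curation removed %d conflicts",
        len(excluded), len(curation.conflicts_removed),
    )
    dataset, block = _align(dataset, block)

    sub_ds, test_ds, ext_ds = split_random(dataset, config.split)
    sub_rows = sub_ds.row_indices
    test_rows = test_ds.row_indices
    ext_rows = ext_ds.row_indices
    training_rows = np.concatenate([sub_rows, test_rows])
    logger.info(
        "split: sub-training %d / test %d / external %d",
        len(sub_rows), len(test_rows), len(ext_rows),
    )

    averages = boxjenkins.fit_averages(block, dataset, training_rows)
    modified = boxjenkins.transform(
        block, dataset, averages, fallback_global=config.fallback_global
    )

    reduced_train, pretreat_log = lda_engine.pretreat(
        modified.take(training_rows),
        variance_cutoff=config.variance_cutoff,
        correlation_cutoff=config.correlation_cutoff,
    )
    reduced = modified.select(reduced_train.column_names)
    logger.info(
        "pretreatment kept %d of %d modified columns",
        len(reduced.column_names), len(modified.column_names),
    )

    labels = dataset.labels()
    sub_block = reduced.take(sub_rows)
    sub_labels = labels[sub_rows]
    if config.selector == "stepwise":
        features, sel_log = feature_selection.fs_stepwise(
            sub_block, sub_labels, config.selection
        )
    elif config.selector == "sfs":
        features = feature_selection.sfs(sub_block, sub_labels, config.selection)
        sel_log = [{"selector": "sfs", "features": features}]
    else:
        features, sel_log = feature_selection.ga_select(
            sub_block, sub_labels, config.selection
        )
    if not features:
        raise DataError("feature selection returned an empty model")
    logger.info("selected %d features via %s", len(features), config.selector)

    model = lda_engine.fit(sub_block, sub_labels, features)

    trace = None
    if config.run_ps3m:
        train_block = reduced.take(training_rows)
        model, trace = ps3m.refine(
            model,
            train_block,
            labels[training_rows],
            sub_training_rows=np.arange(len(sub_rows)),
            test_rows=np.arange(len(sub_rows), len(training_rows)),
            config=config.ps3m,
        )
        logger.info("PS3M accepted %d substitution round(s)", len(trace.rounds))

    # full validation battery
    metrics_out: dict[str, dict] = {}
    condwise: dict[str, pd.DataFrame] = {}
    for name, rows, ds in (
        ("sub_training", sub_rows, sub_ds),
        ("test", test_rows, test_ds),
        ("external", ext_rows, ext_ds),
    ):
        b = reduced.take(rows)
        scores = lda_engine.score(model, b)
        pred = np.where(scores > 0, 1, -1)
        rep = validation.metrics(validation.confusion(labels[rows], pred))
        rep.AUROC = validation.auroc(scores, labels[rows])[0]
        metrics_out[name] = rep.to_dict()
        condwise[name] = validation.conditionwise(pred, ds, set_label=name)

    yc = None
    if config.yc_runs > 0:
        yc = validation.yc_randomization(
            block,
            dataset,
            model.feature_names,
            training_rows,
            sub_rows,
            n_runs=config.yc_runs,
            seed=config.yc_seed,
        )
        logger.info("Yc-randomization: lambda_r=%.3f acc_r=%.2f%%", yc.lambda_r, yc.accuracy_r)

    art = ModelArtifact(
        model=model,
        averages=averages,
        conditions=dataset.conditions(),
        metadata={
            "selector": config.selector,
            "ps3m_rounds": len(trace.rounds) if trace else 0,
            "split": dataclasses.asdict(config.split),
            "n_records": len(dataset),
            "curation": {
                "ambiguous_excluded": len(excluded),
                "duplicates_collapsed": len(curation.duplicates_collapsed),
                "conflicts_removed": len(curation.conflicts_removed),
            },
        },
    )

    paths = {"artifact": str(out_dir / "model.json")}
    art.save(paths["artifact"])
    (out_dir / "metrics.json").write_text(json.dumps(metrics_out, indent=2, default=float))
    paths["metrics"] = str(out_dir / "metrics.json")
    for name, df in condwise.items():
        p = out_dir / f"conditionwise_{name}.csv"
        df.to_csv(p, index=False)
        paths[f"conditionwise_{name}"] = str(p)
    if trace is not None:
        trace.to_frame().to_csv(out_dir / "ps3m_trace.csv", index=False)
        paths["ps3m_trace"] = str(out_dir / "ps3m_trace.csv")
    if yc is not None:
        (out_dir / "yc_randomization.json").write_text(
            json.dumps(
                {
                    "lambda_r": yc.lambda_r,
                    "accuracy_r": yc.accuracy_r,
                    "n_runs": yc.n_runs,
                    "seed": yc.seed,
                },
                indent=2,
            )
        )
        paths["yc"] = str(out_dir / "yc_randomization.json")
    pd.DataFrame(pretreat_log).to_csv(out_dir / "pretreatment_log.csv", index=False)
    pd.DataFrame(sel_log).to_csv(out_dir / "selection_log.csv", index=False)
    (out_dir / "run_config.json").write_text(
        json.dumps(config.to_dict(), indent=2, default=str)
    )
    paths["run_config"] = str(out_dir / "run_config.json")

    return TrainResult(
        artifact=art,
        metrics=metrics_out,
        conditionwise=condwise,
        yc=yc,
        trace=trace,
        selection_log=sel_log,
        pretreat_log=pretreat_log,
        paths=paths,
    )


def run_predict(
    artifact: ModelArtifact,
    library_block: DescriptorBlock,
    conditions=None,
    fallback_global: bool = False,
) -> pd.DataFrame:
    """Score a compound table across conditions with a saved artifact.

    Returns one row per (compound, condition) with score, predicted ±1
    label and, when the artifact carries AD statistics, the outlier flag.
    """
    table = screening.screen(
        artifact, library_block, conditions, fallback_global=fallback_global
    )
    return table.rows


def score_modified_rows(artifact: ModelArtifact, block: DescriptorBlock) -> pd.DataFrame:
    """Score rows that are already modified descriptors (tagged columns).

    This is the route for coefficient-only artifacts such as the packaged
    reference equation, which cannot recenter raw descriptors.
    """
    scores = lda_engine.score(artifact.model, block)
    return pd.DataFrame(
        {
            "id": block.row_ids or list(range(block.n_rows)),
            "score": scores,
            "predicted": np.where(scores > 0, 1, -1),
        }
    )
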