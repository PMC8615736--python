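"""Multi-condition virtual screening and hit triage.

A library is crossed with every experimental condition the model covers,
recentered with the model's training-active averages, scored, classified
(+1 where the discriminant score is positive) and flagged against the
applicability domain.  Hit rules: pan-inhibitors must be predicted active
in at least ``min_active`` of the conditions with no structural-outlier
condition; isoform-specific hits must be active in enough on-target
conditions and in none of the off-target ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import boxjenkins, lda_engine, validation
from .artifact import ModelArtifact
from .boxjenkins import DescriptorBlock, split_column
from .core_data import ExperimentalCondition
from .errors import ConfigurationError, DataError, DomainError


@dataclass
class ScreeningTable:
    """Per-(compound, condition) scores plus a per-compound summary."""

    rows: pd.DataFrame  # compound_id, bt, me, at, score, predicted, ad_outlier
    summary: pd.DataFrame  # compound_id, n_conditions, n_active, n_outlier


def required_raw_columns(artifact: ModelArtifact) -> list[str]:
    """Raw descriptor names the model's modified features derive from."""
    seen: dict[str, None] = {}
    for f in artifact.model.feature_names:
        seen.setdefault(split_column(f)[0], None)
    return list(seen)


def screen(
    artifact: ModelArtifact,
    library_block: DescriptorBlock,
    conditions: Sequence[ExperimentalCondition] | None = None,
    fallback_global: bool = False,
) -> ScreeningTable:
    """Score every (library compound, condition) pair with the model.

    ``conditions`` defaults to the artifact's covered condition list.
    Deterministic: identical inputs give identical tables.
    """
    if not artifact.has_averages:
        raise DataError(
            "artifact carries no average table; cannot recenter raw descriptors"
        )
    conditions = list(conditions) if conditions is not None else list(artifact.conditions)
    if not conditions:
        raise ConfigurationError("no screening conditions given or stored in artifact")

    needed = required_raw_columns(artifact)
    missing = [c for c in needed if c not in library_block.column_names]
    if missing:
        raise DomainError(
            f"library descriptor matrix is missing raw column(s) {missing} "
            f"required by the model's modified features"
        )
    slim = library_block.select(needed)
    modified, index = boxjenkins.expand_conditions(
        slim, conditions, artifact.averages, fallback_global=fallback_global
    )
    if len(index) == 0:
        rows = pd.DataFrame(
            columns=["compound_id", "bt", "me", "at", "score", "predicted", "ad_outlier"]
        )
        summary = pd.DataFrame(
            columns=["compound_id", "n_conditions", "n_active", "n_outlier"]
        )
        return ScreeningTable(rows=rows, summary=summary)

    scores = lda_engine.score(artifact.model, modified)
    predicted = np.where(scores > 0, 1, -1)
    if artifact.ad_stats:
        inside = validation.ad_flags_matrix(artifact.ad_stats, modified)
        outlier = ~inside
    else:
        outlier = np.zeros(len(index), dtype=bool)

    rows = pd.DataFrame(
        {
            "compound_id": [cid for cid, _ in index],
            "bt": [c.bt for _, c in index],
            "me": [c.me for _, c in index],
            "at": [c.at for _, c in index],
            "score": scores,
            "predicted": predicted,
            "ad_outlier": outlier,
        }
    )
    summary = (
        rows.assign(active=rows.predicted == 1)
        .groupby("compound_id", sort=False)
        .agg(
            n_conditions=("predicted", "size"),
            n_active=("active", "sum"),
            n_outlier=("ad_outlier", "sum"),
        )
        .reset_index()
    )
    return ScreeningTable(rows=rows, summary=summary)


def select_pan_hits(
    table: ScreeningTable, min_active: int = 4, exclude_outliers: bool = True
) -> list[str]:
    """Compounds active in ≥ min_active conditions (and, by default, never
    outside the applicability domain), sorted by active count descending
    then compound id."""
    s = table.summary
    if s.empty:
        return []
    mask = s.n_active >= min_active
    if exclude_outliers:
        mask &= s.n_outlier == 0
    hits = s[mask].sort_values(
        ["n_active", "compound_id"], ascending=[False, True], kind="stable"
    )
    return hits.compound_id.tolist()


def select_isoform_hits(
    table: ScreeningTable,
    target_bt: str,
    off_bt: str,
    min_active: int = 4,
) -> list[str]:
    """Isoform-selective hits: active in ≥ min_active on-target conditions
    and in zero off-target conditions."""
    if target_bt == off_bt:
        raise ConfigurationError("target_bt and off_bt must differ")
    rows = table.rows
    for bt, role in ((target_bt, "target"), (off_bt, "off-target")):
        if rows.empty or not (rows.bt == bt).any():
            raise DataError(f"no screening conditions with {role} isoform {bt!r}")
    per = (
        rows.assign(active=rows.predicted == 1)
        .groupby(["compound_id", "bt"], sort=False)["active"]
        .sum()
        .unstack(fill_value=0)
    )
    on = per.get(target_bt, pd.Series(0, index=per.index))
    off = per.get(off_bt, pd.Series(0, index=per.index))
    keep = per.index[(on >= min_active) & (off == 0)]
    counts = on.loc[keep]
    order = sorted(keep, key=lambda cid: (-int(counts[cid]), cid))
    return list(order)
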