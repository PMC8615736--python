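"""Box-Jenkins moving-average descriptor modification.

The transform recenters every raw descriptor ``Di`` against the arithmetic
mean of the *training-set active* compounds sharing one ontology-element
value with the record:

    delta(Di)_e = Di - avg(Di | element e = record's value, label = +1)

One modified column is emitted per raw column and ontology element (bt, me,
at), so a record's descriptor vector carries its experimental context: the
same compound measured under two conditions yields two distinct modified
rows.  Averages are fitted on training actives only and applied unchanged to
test, external-validation and screening rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import ELEMENTS, Dataset, ExperimentalCondition
from .errors import DataError, DomainError

#: Separator between a raw descriptor name and its ontology-element tag.
TAG_SEP = "__"


def tag_column(raw_name: str, element: str) -> str:
    return f"{raw_name}{TAG_SEP}{element}"


def split_column(name: str) -> tuple[str, str]:
    """Invert :func:`tag_column`: ``"C-012__me" -> ("C-012", "me")``."""
    raw, _, element = name.rpartition(TAG_SEP)
    if not raw or element not in ELEMENTS:
        raise DataError(f"{name!r} is not a tagged modified-descriptor name")
    return raw, element


@dataclass
class DescriptorBlock:
    """A named numeric matrix, one row per record."""

    column_names: list[str]
    values: np.ndarray
    row_ids: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("descriptor values must be a 2-D matrix")
        if self.values.shape[1] != len(self.column_names):
            raise DataError(
                f"{len(self.column_names)} column names for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.column_names)) != len(self.column_names):
            raise DataError("descriptor column names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise DataError("descriptor matrix contains non-finite entries")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        try:
            return self.values[:, self.column_names.index(name)]
        except ValueError as exc:
            raise DomainError(f"descriptor column {name!r} not in block") from exc

    def take(self, row_indices: Sequence[int]) -> "DescriptorBlock":
        idx = np.asarray(row_indices, dtype=int)
        return DescriptorBlock(
            column_names=list(self.column_names),
            values=self.values[idx],
            row_ids=[self.row_ids[i] for i in idx] if self.row_ids else None,
        )

    def select(self, names: Sequence[str]) -> "DescriptorBlock":
        idx = [self.column_names.index(n) for n in names]
        return DescriptorBlock(
            column_names=list(names),
            values=self.values[:, idx],
            row_ids=self.row_ids,
        )


#: A ModifiedBlock is structurally a DescriptorBlock whose columns are tagged.
ModifiedBlock = DescriptorBlock


def read_descriptor_matrix(path: str | Path) -> DescriptorBlock:
    """Read a delimited descriptor matrix; first column = record id."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected an id column plus descriptor columns")
    ids = df.iloc[:, 0].astype(str).tolist()
    body = df.iloc[:, 1:]
    try:
        values = body.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataError(f"{path}: non-numeric descriptor entries") from exc
    return DescriptorBlock(
        column_names=[str(c) for c in body.columns], values=values, row_ids=ids
    )


def write_descriptor_matrix(block: DescriptorBlock, path: str | Path, sep: str = ","):
    ids = block.row_ids or [str(i) for i in range(block.n_rows)]
    df = pd.DataFrame(block.values, columns=block.column_names)
    df.insert(0, "id", ids)
    df.to_csv(path, index=False, sep=sep)


@dataclass
class AverageTable:
    """Training-active descriptor means keyed by (descriptor, element, value).

    ``entries[descriptor][element][value]`` is the arithmetic mean of that
    descriptor over training-set records with label +1 whose condition has
    that element value.  ``global_means`` holds the all-training-actives mean
    per descriptor, used only by the optional missing-coverage fallback.
    """

    entries: dict[str, dict[str, dict[str, float]]]
    global_means: dict[str, float] = field(default_factory=dict)

    def lookup(self, descriptor: str, element: str, value: str) -> float | None:
        return self.entries.get(descriptor, {}).get(element, {}).get(value)

    def covered_values(self, element: str) -> set[str]:
        out: set[str] = set()
        for per_elem in self.entries.values():
            out.update(per_elem.get(element, {}))
        return out

    def covers(self, condition: ExperimentalCondition) -> bool:
        return all(
            condition.element(e) in self.covered_values(e) for e in ELEMENTS
        )

    def to_dict(self) -> dict:
        return {"entries": self.entries, "global_means": self.global_means}

    @classmethod
    def from_dict(cls, d: Mapping) -> "AverageTable":
        return cls(
            entries={
                desc: {e: dict(v) for e, v in per.items()}
                for desc, per in d["entries"].items()
            },
            global_means=dict(d.get("global_means", {})),
        )


def fit_averages(
    block: DescriptorBlock, dataset: Dataset, training_rows: Sequence[int]
) -> AverageTable:
    """Compute per-element training-active means for every raw descriptor.

    ``training_rows`` indexes rows of ``block``/``dataset`` (positions, not
    original row ids) and must exclude the external-validation partition:
    held-out rows take part neither in model fitting nor in descriptor
    recentering.
    """
    training_rows = np.asarray(training_rows, dtype=int)
    labels = dataset.labels()[training_rows]
    active_rows = training_rows[labels == 1]
    if active_rows.size == 0:
        raise DataError("no active (+1) records among the training rows")

    active_values = block.values[active_rows]
    entries: dict[str, dict[str, dict[str, float]]] = {
        name: {e: {} for e in ELEMENTS} for name in block.column_names
    }
    for element in ELEMENTS:
        elem_vals = dataset.element_values(element)[active_rows]
        for value in np.unique(elem_vals):
            means = active_values[elem_vals == value].mean(axis=0)
            for name, m in zip(block.column_names, means):
                entries[name][element][str(value)] = float(m)
    global_means = {
        name: float(m)
        for name, m in zip(block.column_names, active_values.mean(axis=0))
    }
    return AverageTable(entries=entries, global_means=global_means)


def _element_mean_matrix(
    block: DescriptorBlock,
    element: str,
    elem_vals: np.ndarray,
    averages: AverageTable,
    fallback_global: bool,
) -> np.ndarray:
    """Per-row matrix of conditioned means, aligned with block columns."""
    out = np.empty_like(block.values)
    for value in np.unique(elem_vals):
        mask = elem_vals == value
        row = np.empty(len(block.column_names))
        for j, name in enumerate(block.column_names):
            m = averages.lookup(name, element, str(value))
            if m is None:
                if fallback_global and name in averages.global_means:
                    m = averages.global_means[name]
                else:
                    raise DomainError(
                        f"no training-active average for element {element}="
                        f"{value!r} (descriptor {name!r}); enable the global-"
                        f"mean fallback or extend the training data"
                    )
            row[j] = m
        out[mask] = row
    return out


def transform(
    block: DescriptorBlock,
    dataset: Dataset,
    averages: AverageTable,
    fallback_global: bool = False,
) -> ModifiedBlock:
    """Emit the modified block: 3 tagged columns per raw column.

    Pure function of its inputs; training, test and external rows are all
    transformed with the same training-active averages.
    """
    if block.n_rows != len(dataset):
        raise DataError(
            f"block has {block.n_rows} rows but dataset has {len(dataset)} records"
        )
    names: list[str] = []
    pieces: list[np.ndarray] = []
    for element in ELEMENTS:
        elem_vals = dataset.element_values(element)
        means = _element_mean_matrix(block, element, elem_vals, averages, fallback_global)
        pieces.append(block.values - means)
        names.extend(tag_column(n, element) for n in block.column_names)
    # interleave so the 3 tags of a raw column sit together
    order = [
        k * len(block.column_names) + j
        for j in range(len(block.column_names))
        for k in range(len(ELEMENTS))
    ]
    stacked = np.hstack(pieces)[:, order]
    return ModifiedBlock(
        column_names=[names[i] for i in order],
        values=stacked,
        row_ids=block.row_ids,
    )


def expand_conditions(
    library_block: DescriptorBlock,
    conditions: Sequence[ExperimentalCondition],
    averages: AverageTable,
    fallback_global: bool = False,
) -> tuple[ModifiedBlock, list[tuple[str, ExperimentalCondition]]]:
    """Cross a screening library with a condition list.

    Every library compound is replicated once per condition and transformed
    with the modeling averages, yielding ``n_compounds * n_conditions``
    modified rows plus a row index of (compound_id, condition) pairs.
    """
    for c in conditions:
        if not averages.covers(c):
            raise DomainError(
                f"condition {c.to_dict()} is not covered by the fitted averages"
            )
    ids = library_block.row_ids or [str(i) for i in range(library_block.n_rows)]
    n, k = library_block.n_rows, len(conditions)
    if n == 0 or k == 0:
        empty = np.empty((0, len(library_block.column_names) * len(ELEMENTS)))
        names = [
            tag_column(name, e) for name in library_block.column_names for e in ELEMENTS
        ]
        return ModifiedBlock(column_names=names, values=empty, row_ids=[]), []

    from .core_data import ActivityRecord  # local import to avoid cycle noise

    records = []
    index: list[tuple[str, ExperimentalCondition]] = []
    for i in range(n):
        for c in conditions:
            records.append(
                ActivityRecord(
                    compound_id=ids[i], condition=c, label=1, row_index=len(records)
                )
            )
            index.append((ids[i], c))
    tiled = np.repeat(library_block.values, k, axis=0)
    big = DescriptorBlock(
        column_names=list(library_block.column_names),
        values=tiled,
        row_ids=[cid for cid, _ in index],
    )
    modified = transform(big, Dataset(records), averages, fallback_global)
    return modified, index
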