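"""Data model for multi-condition activity data.

Every activity measurement is keyed by an experimental-condition triple
``(bt, me, at)``: the biological target (e.g. the kinase isoform assayed),
the measure of effect (IC50, Ki or Kd) and the assay type (binding ``B`` or
functional ``F``).  Compounds are classified as active (+1) or inactive (-1)
against a per-measure potency cutoff in nM, curated for duplicates, and split
into sub-training / test / external-validation partitions.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

MEASURE_KINDS = ("IC50", "Ki", "Kd")
ASSAY_TYPES = ("B", "F")
#: Ontology element names, in canonical order.
ELEMENTS = ("bt", "me", "at")

#: Default activity cutoffs (nM): a compound is active when its measured
#: value is at or below the cutoff for its measure kind.
DEFAULT_CUTOFFS = {"IC50": 100.0, "Ki": 300.0, "Kd": 300.0}


@dataclass(frozen=True)
class ExperimentalCondition:
    """The (biological target, measure, assay type) triple keying a record."""

    bt: str
    me: str
    at: str

    def __post_init__(self):
        for name in ELEMENTS:
            if not getattr(self, name):
                raise DataError(f"condition element {name!r} must be non-empty")
        if self.me not in MEASURE_KINDS:
            raise DataError(
                f"unknown measure kind {self.me!r}; expected one of {MEASURE_KINDS}"
            )
        if self.at not in ASSAY_TYPES:
            raise DataError(
                f"unknown assay type {self.at!r}; expected one of {ASSAY_TYPES}"
            )

    def element(self, name: str) -> str:
        if name not in ELEMENTS:
            raise ConfigurationError(f"unknown ontology element {name!r}")
        return getattr(self, name)

    def to_dict(self) -> dict:
        return {"bt": self.bt, "me": self.me, "at": self.at}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentalCondition":
        return cls(bt=d["bt"], me=d["me"], at=d["at"])


@dataclass
class ActivityRecord:
    """One compound tested under one experimental condition."""

    compound_id: str
    condition: ExperimentalCondition
    smiles: str | None = None
    value_nM: float | None = None
    relation: str = "="
    label: int | None = None
    #: Row position in the originally loaded table; used to align the record
    #: with its row in an external descriptor matrix.
    row_index: int | None = None

    def __post_init__(self):
        if self.relation not in ("=", "<", ">"):
            raise DataError(f"relation must be one of =, <, >; got {self.relation!r}")
        if self.value_nM is not None and not self.value_nM > 0:
            raise DataError(f"value_nM must be positive; got {self.value_nM}")
        if self.label is not None and self.label not in (1, -1):
            raise DataError(f"label must be +1 or -1; got {self.label}")
        if self.label is None and self.value_nM is None:
            raise DataError(
                f"record {self.compound_id!r} has neither a label nor a value"
            )


@dataclass
class Dataset:
    """Ordered activity records, row-aligned with an external descriptor matrix."""

    records: list[ActivityRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def row_indices(self) -> np.ndarray:
        """Original-table row positions, for descriptor-matrix alignment."""
        idx = [r.row_index for r in self.records]
        if any(i is None for i in idx):
            raise DataError("dataset contains records without a row_index")
        return np.asarray(idx, dtype=int)

    def labels(self) -> np.ndarray:
        lab = [r.label for r in self.records]
        if any(v is None for v in lab):
            raise DataError("dataset contains unlabeled records")
        return np.asarray(lab, dtype=int)

    def element_values(self, element: str) -> np.ndarray:
        return np.asarray([r.condition.element(element) for r in self.records])

    def conditions(self) -> list[ExperimentalCondition]:
        """Unique conditions in first-occurrence order."""
        seen: dict[ExperimentalCondition, None] = {}
        for r in self.records:
            seen.setdefault(r.condition, None)
        return list(seen)

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset([self.records[int(i)] for i in indices])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "compound_id": r.compound_id,
                    "smiles": r.smiles,
                    "bt": r.condition.bt,
                    "me": r.condition.me,
                    "at": r.condition.at,
                    "value_nM": r.value_nM,
                    "relation": r.relation,
                    "label": r.label,
                    "row_index": r.row_index,
                }
            )
        return pd.DataFrame(rows)


#: Logical field -> default column name in an activity table.
DEFAULT_DIALECT = {
    "compound_id": "compound_id",
    "smiles": "smiles",
    "bt": "bt",
    "me": "me",
    "at": "at",
    "value": "value_nM",
    "relation": "relation",
    "label": "label",
}

_REQUIRED_FIELDS = ("compound_id", "bt", "me", "at")


def _parse_value(token: str) -> tuple[float, str]:
    """Parse ``"<100"`` / ``">1e3"`` / ``"50"`` into (value, relation)."""
    token = token.strip()
    relation = "="
    if token[:1] in ("<", ">"):
        relation, token = token[0], token[1:].strip()
    try:
        value = float(token)
    except ValueError as exc:
        raise DataError(f"unparseable activity value {token!r}") from exc
    return value, relation


def load_activity_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> Dataset:
    """Read a delimited activity table (comma or tab, auto-detected).

    ``dialect`` maps the logical field names (``compound_id``, ``smiles``,
    ``bt``, ``me``, ``at``, ``value``, ``relation``, ``label``) to the actual
    column names in the file.  Rows may carry an activity value in nM (with
    optional ``<``/``>`` qualifier, inline or in a relation column), a
    precomputed ±1 label, or both.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise ConfigurationError(f"unknown dialect fields: {sorted(unknown)}")
        colmap.update(dialect)

    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for f in _REQUIRED_FIELDS:
        if colmap[f] not in df.columns:
            raise ConfigurationError(
                f"required column {colmap[f]!r} (field {f!r}) missing from {path}"
            )
    has_value = colmap["value"] in df.columns
    has_label = colmap["label"] in df.columns
    if not has_value and not has_label:
        raise ConfigurationError(
            f"{path}: need a value column ({colmap['value']!r}) or a label "
            f"column ({colmap['label']!r})"
        )
    has_smiles = colmap["smiles"] in df.columns
    has_relation = colmap["relation"] in df.columns

    records: list[ActivityRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        line = i + 2  # header is line 1
        try:
            condition = ExperimentalCondition(
                bt=str(row[colmap["bt"]]).strip(),
                me=str(row[colmap["me"]]).strip(),
                at=str(row[colmap["at"]]).strip(),
            )
            value = relation = None
            if has_value and pd.notna(row[colmap["value"]]):
                value, relation = _parse_value(str(row[colmap["value"]]))
            if has_relation and pd.notna(row[colmap["relation"]]):
                rel = str(row[colmap["relation"]]).strip()
                if relation not in (None, "=") and rel != relation:
                    raise DataError(
                        f"conflicting relation qualifiers {relation!r} and {rel!r}"
                    )
                relation = rel
            label = None
            if has_label and pd.notna(row[colmap["label"]]):
                label = int(float(row[colmap["label"]]))
            records.append(
                ActivityRecord(
                    compound_id=str(row[colmap["compound_id"]]).strip(),
                    condition=condition,
                    smiles=(
                        str(row[colmap["smiles"]]).strip()
                        if has_smiles and pd.notna(row[colmap["smiles"]])
                        else None
                    ),
                    value_nM=value,
                    relation=relation or "=",
                    label=label,
                    row_index=i,
                )
            )
        except DataError as exc:
            raise DataError(f"{path}, line {line}: {exc}") from exc
    return Dataset(records)


def assign_labels(
    dataset: Dataset, cutoffs: Mapping[str, float] | None = None
) -> tuple[Dataset, list[dict]]:
    """Assign ±1 activity classes from values against per-measure cutoffs.

    A record is active (+1) when its value is at or below the cutoff for its
    measure kind, inactive (-1) otherwise.  Censored records whose qualifier
    contradicts the cutoff side (``<`` above the cutoff, ``>`` below it) are
    ambiguous: they are excluded and reported, never guessed.  Records that
    already carry a label are passed through untouched.

    Returns the labeled dataset and the exclusion report (one dict per
    excluded record).
    """
    cutoffs = dict(DEFAULT_CUTOFFS if cutoffs is None else cutoffs)
    missing = {
        r.condition.me
        for r in dataset
        if r.label is None and r.condition.me not in cutoffs
    }
    if missing:
        raise ConfigurationError(
            f"no cutoff configured for measure kind(s) {sorted(missing)}"
        )

    kept: list[ActivityRecord] = []
    excluded: list[dict] = []
    for r in dataset:
        if r.label is not None:
            kept.append(r)
            continue
        if r.value_nM is None:
            raise DataError(f"record {r.compound_id!r} has no value to label from")
        cut = float(cutoffs[r.condition.me])
        label = None
        if r.relation == "=":
            label = 1 if r.value_nM <= cut else -1
        elif r.relation == "<":
            # true value < reported bound: conclusive only at/below the cutoff
            label = 1 if r.value_nM <= cut else None
        else:  # ">"
            label = -1 if r.value_nM >= cut else None
        if label is None:
            excluded.append(
                {
                    "compound_id": r.compound_id,
                    "condition": r.condition.to_dict(),
                    "value_nM": r.value_nM,
                    "relation": r.relation,
                    "reason": "censored value ambiguous against cutoff",
                }
            )
            continue
        kept.append(dataclasses.replace(r, label=label))
    return Dataset(kept), excluded


@dataclass
class CurationReport:
    """What duplicate curation removed."""

    duplicates_collapsed: list[dict] = field(default_factory=list)
    conflicts_removed: list[dict] = field(default_factory=list)


def curate(dataset: Dataset) -> tuple[Dataset, CurationReport]:
    """Collapse exact duplicates and drop label-conflicting duplicates.

    Two records are duplicates when they share (compound_id, condition).
    Same label: the first occurrence is kept.  Conflicting labels: all
    occurrences are removed and reported (conflicts are undefined data, not
    a vote).
    """
    groups: dict[tuple[str, ExperimentalCondition], list[ActivityRecord]] = {}
    for r in dataset:
        if r.label is None:
            raise DataError("curate requires labels to be assigned first")
        groups.setdefault((r.compound_id, r.condition), []).append(r)

    report = CurationReport()
    kept: list[ActivityRecord] = []
    conflict_keys = set()
    for key, members in groups.items():
        labels = {m.label for m in members}
        if len(labels) > 1:
            conflict_keys.add(key)
            report.conflicts_removed.append(
                {
                    "compound_id": key[0],
                    "condition": key[1].to_dict(),
                    "labels": sorted(labels),
                    "n_records": len(members),
                }
            )
        elif len(members) > 1:
            report.duplicates_collapsed.append(
                {
                    "compound_id": key[0],
                    "condition": key[1].to_dict(),
                    "n_records": len(members),
                }
            )

    seen = set()
    for r in dataset:
        key = (r.compound_id, r.condition)
        if key in conflict_keys or key in seen:
            continue
        seen.add(key)
        kept.append(r)
    return Dataset(kept), report


@dataclass(frozen=True)
class SplitSpec:
    """Seeded two-stage random split specification.

    The external-validation set is drawn first as ``external_fraction`` of
    all rows; the test set is then ``test_fraction`` of the remainder; the
    rest is the sub-training set.  Set sizes use nearest-integer rounding
    with ties rounded up.
    """

    seed: int = 2
    external_fraction: float = 0.30
    test_fraction: float = 0.20

    def __post_init__(self):
        for name in ("external_fraction", "test_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1); got {v}")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_random(
    dataset: Dataset, spec: SplitSpec
) -> tuple[Dataset, Dataset, Dataset]:
    """Partition into (sub_training, test, external_validation).

    Exhaustive, pairwise disjoint, reproducible from ``spec.seed``.
    """
    n = len(dataset)
    n_ext = _round_half_up(n * spec.external_fraction)
    n_rest = n - n_ext
    n_test = _round_half_up(n_rest * spec.test_fraction)
    n_sub = n_rest - n_test
    if min(n_ext, n_test, n_sub) < 1:
        raise DataError(
            f"split of N={n} with fractions "
            f"({spec.external_fraction}, {spec.test_fraction}) yields an empty set"
        )
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    ext = np.sort(perm[:n_ext])
    test = np.sort(perm[n_ext : n_ext + n_test])
    sub = np.sort(perm[n_ext + n_test :])
    return dataset.subset(sub), dataset.subset(test), dataset.subset(ext)


def save_dataset(dataset: Dataset, prefix: str | Path, sidecar: dict | None = None):
    """Persist a dataset as ``<prefix>.csv`` plus a ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    dataset.to_frame().to_csv(prefix.with_suffix(".csv"), index=False)
    meta = {"n_records": len(dataset)}
    if sidecar:
        meta.update(sidecar)
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_dataset(prefix: str | Path) -> tuple[Dataset, dict]:
    """Load a dataset bundle written by :func:`save_dataset`."""
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"))
    records = []
    for _, row in df.iterrows():
        records.append(
            ActivityRecord(
                compound_id=str(row["compound_id"]),
                condition=ExperimentalCondition(
                    bt=str(row["bt"]), me=str(row["me"]), at=str(row["at"])
                ),
                smiles=None if pd.isna(row.get("smiles")) else str(row["smiles"]),
                value_nM=None if pd.isna(row["value_nM"]) else float(row["value_nM"]),
                relation=str(row["relation"]) if pd.notna(row["relation"]) else "=",
                label=None if pd.isna(row["label"]) else int(row["label"]),
                row_index=None if pd.isna(row["row_index"]) else int(row["row_index"]),
            )
        )
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return Dataset(records), meta
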