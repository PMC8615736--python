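"""The persisted model artifact: everything screening needs in one JSON.

Bundles the fitted linear discriminant (coefficients, goodness of fit,
per-feature training statistics for the applicability domain), the
training-active average table that defines the descriptor recentering, and
the condition list the model covers.  A transcribed reference equation for
a published two-isoform kinase model ships as ``reference_models/
mnk_final.json``; it carries coefficients only (no averages or AD
statistics), so it can score pre-modified descriptor rows but cannot
recenter raw ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .boxjenkins import AverageTable
from .core_data import ExperimentalCondition
from .errors import DataError
from .lda_engine import LinearDiscriminantModel

SCHEMA_VERSION = 1


@dataclass
class ModelArtifact:
    model: LinearDiscriminantModel
    averages: AverageTable | None = None
    conditions: list[ExperimentalCondition] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def has_averages(self) -> bool:
        return self.averages is not None

    @property
    def ad_stats(self) -> dict:
        return self.model.feature_stats

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "model": self.model.to_dict(),
            "averages": self.averages.to_dict() if self.averages else None,
            "conditions": [c.to_dict() for c in self.conditions],
            "metadata": self.metadata,
        }

    def save(self, path: str | Path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "ModelArtifact":
        version = d.get("schema_version", SCHEMA_VERSION)
        if version > SCHEMA_VERSION:
            raise DataError(f"artifact schema version {version} is newer than supported")
        return cls(
            model=LinearDiscriminantModel.from_dict(d["model"]),
            averages=(
                AverageTable.from_dict(d["averages"]) if d.get("averages") else None
            ),
            conditions=[
                ExperimentalCondition.from_dict(c) for c in d.get("conditions", [])
            ],
            metadata=dict(d.get("metadata", {})),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ModelArtifact":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_reference_model(name: str = "mnk_final") -> ModelArtifact:
    """Load a packaged reference model artifact by name."""
    ref = resources.files("mtqscreen").joinpath(f"reference_models/{name}.json")
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:
        raise DataError(f"no packaged reference model named {name!r}") from exc
    return ModelArtifact.from_dict(json.loads(text))
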