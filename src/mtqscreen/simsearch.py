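"""Fingerprint similarity search between virtual hits and known inhibitors.

Structures are encoded as extended-connectivity circular fingerprints of
diameter 4 (Morgan radius 2) folded to a fixed bit length, and compared by
Tanimoto similarity |A∩B| / |A∪B|.  A target matches a query when the
similarity is strictly greater than the cutoff; per query the report
carries the match count, the mean similarity and the mean reported activity
over matches, with left-censored ("<x nM") activities floored at the
configured value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass
class FingerprintSet:
    """id -> fixed-length boolean bit vector, with encoding parameters."""

    bits: dict[str, np.ndarray]
    radius: int = 2
    n_bits: int = 2048
    skipped: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.bits)


def fingerprint(
    smiles: Mapping[str, str] | Sequence[tuple[str, str]], n_bits: int = 2048
) -> FingerprintSet:
    """Circular fingerprints (radius 2, i.e. diameter-4 neighborhoods).

    Invalid or empty SMILES are skipped and reported in ``skipped``; at
    least one structure must survive.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    items = list(smiles.items()) if isinstance(smiles, Mapping) else list(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    bits: dict[str, np.ndarray] = {}
    skipped: list[dict] = []
    RDLogger.DisableLog("rdApp.error")
    try:
        for cid, smi in items:
            if not smi or not str(smi).strip():
                skipped.append({"id": cid, "smiles": smi, "reason": "empty SMILES"})
                continue
            mol = Chem.MolFromSmiles(str(smi))
            if mol is None:
                skipped.append({"id": cid, "smiles": smi, "reason": "unparseable SMILES"})
                continue
            fp = gen.GetFingerprint(mol)
            arr = np.zeros(n_bits, dtype=bool)
            arr[list(fp.GetOnBits())] = True
            bits[str(cid)] = arr
    finally:
        RDLogger.EnableLog("rdApp.error")
    if not bits:
        raise DataError("no valid structures to fingerprint")
    return FingerprintSet(bits=bits, radius=2, n_bits=n_bits, skipped=skipped)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a∧b| / |a∨b|; two all-zero vectors give 0 by convention."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise DataError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return int(np.sum(a & b)) / union


def _parse_activity(value) -> tuple[float, str]:
    if isinstance(value, tuple):
        return float(value[0]), value[1]
    if isinstance(value, str):
        s = value.strip()
        if s[:1] in ("<", ">"):
            return float(s[1:]), s[0]
        return float(s), "="
    return float(value), "="


@dataclass
class SimilarityReport:
    """Per-query aggregation plus the per-match detail rows."""

    per_query: pd.DataFrame  # query_id, n_matches, mean_similarity, mean_activity_nM
    matches: pd.DataFrame  # query_id, target_id, tanimoto, activity_nM, relation


def search(
    queries: FingerprintSet,
    targets: FingerprintSet,
    activities: Mapping[str, object],
    cutoff: float = 0.3,
    activity_floor: float = 100.0,
) -> SimilarityReport:
    """Tanimoto search with the count/activity aggregation rules.

    A match requires similarity strictly greater than ``cutoff``.  In the
    per-query mean activity, left-censored values ("<x") count as
    ``activity_floor`` nM; ">" records are excluded from the mean with a
    warning.  Queries are ranked by match count descending, then id; means
    over empty match sets are reported as NaN.
    """
    if len(targets) == 0:
        raise DataError("empty target fingerprint set")
    if queries.n_bits != targets.n_bits:
        raise DataError("query and target fingerprints use different bit lengths")
    missing = [t for t in targets.bits if t not in activities]
    if missing:
        raise DataError(f"activity map missing target id(s): {missing[:5]}")

    match_rows = []
    per_query_rows = []
    for qid, qfp in queries.bits.items():
        sims = []
        acts = []
        n_excluded = 0
        for tid, tfp in targets.bits.items():
            t = tanimoto(qfp, tfp)
            if t <= cutoff:
                continue
            value, relation = _parse_activity(activities[tid])
            match_rows.append(
                {
                    "query_id": qid,
                    "target_id": tid,
                    "tanimoto": t,
                    "activity_nM": value,
                    "relation": relation,
                }
            )
            sims.append(t)
            if relation == "<":
                acts.append(activity_floor)
            elif relation == ">":
                n_excluded += 1
            else:
                acts.append(value)
        if n_excluded:
            warnings.warn(
                f"query {qid}: {n_excluded} '>'-censored activities excluded "
                f"from the mean"
            )
        per_query_rows.append(
            {
                "query_id": qid,
                "n_matches": len(sims),
                "mean_similarity": float(np.mean(sims)) if sims else np.nan,
                "mean_activity_nM": float(np.mean(acts)) if acts else np.nan,
            }
        )
    per_query = pd.DataFrame(per_query_rows).sort_values(
        ["n_matches", "query_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    matches = pd.DataFrame(
        match_rows,
        columns=["query_id", "target_id", "tanimoto", "activity_nM", "relation"],
    )
    return SimilarityReport(per_query=per_query, matches=matches)


def read_smiles_file(path: str | Path) -> dict[str, str]:
    """Read ``id<TAB>smiles`` lines (or bare SMILES, auto-numbered)."""
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) >= 2:
            out[parts[0].strip()] = parts[1].strip()
        else:
            out[f"Q{i + 1:04d}"] = parts[0]
    if not out:
        raise DataError(f"{path}: no SMILES entries found")
    return out
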