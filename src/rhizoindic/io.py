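"""Plain-text I/O: count tables and pairing manifests as TSV, ground truth as JSON.

Count tables are written with one row per taxon — the first column holds
the semicolon-joined lineage (kingdom;phylum;...;species) — and one
integer column per sample. Pairing manifests are TSV with columns
pair_id, treated_sample, control_sample, treatment_code, time.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError
from .differential import PairedComparison
from .synthetic import GroundTruth
from .tables import LINEAGE_SEP, RANKS, TaxonCountTable

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_manifest",
    "write_manifest",
    "read_ground_truth",
    "write_ground_truth",
]

MANIFEST_COLS = ["pair_id", "treated_sample", "control_sample", "treatment_code", "time"]


def write_count_table(table: TaxonCountTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.index.name = "lineage"
    out.to_csv(path, sep="\t")


def read_count_table(path: str | Path, level: str | None = None) -> TaxonCountTable:
    """Read a lineage-indexed TSV count table.

    The resolution level is inferred from the number of lineage fields
    unless given explicitly.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise DomainError(f"empty count table: {path}")
    split = [str(l).split(LINEAGE_SEP) for l in df.index]
    depths = {len(s) for s in split}
    if len(depths) != 1:
        raise DomainError("inconsistent lineage depth across rows")
    depth = depths.pop()
    if depth > len(RANKS):
        raise DomainError(f"lineages have {depth} fields; at most {len(RANKS)} ranks supported")
    inferred = RANKS[depth - 1]
    if level is not None and level != inferred:
        raise DomainError(f"table rows have {depth} lineage fields ({inferred}), not {level}")
    counts = df.astype(np.int64)
    lin = pd.DataFrame(split, columns=list(RANKS[:depth]), index=df.index)
    return TaxonCountTable(counts=counts, lineages=lin, level=inferred)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest[MANIFEST_COLS].to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> list[PairedComparison]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLS if c not in df.columns]
    if missing:
        raise DomainError(f"manifest lacks columns: {missing}")
    return [
        PairedComparison(
            treated_sample=r.treated_sample,
            control_sample=r.control_sample,
            treatment_code=r.treatment_code,
            time=r.time,
            pair_id=r.pair_id,
        )
        for r in df.itertuples(index=False)
    ]


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "base_proportions": [float(p) for p in truth.base_proportions],
        "effects": {str(k): float(v) for k, v in truth.effects.items()},
        "overdispersion": None if np.isinf(truth.overdispersion) else float(truth.overdispersion),
        "seed": int(truth.seed),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    over = payload.get("overdispersion")
    return GroundTruth(
        base_proportions=np.asarray(payload["base_proportions"], dtype=float),
        effects={int(k): float(v) for k, v in payload["effects"].items()},
        overdispersion=float("inf") if over is None else float(over),
        seed=int(payload.get("seed", 0)),
    )
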