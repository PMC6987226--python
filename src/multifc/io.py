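"""Readers, writers and fixture generation.

Canonical on-disk layout: one TSV per subject and condition (t rows x n
region columns, header row = region ids) with a JSON sidecar holding the
sampling interval and subject id; partitions are JSON objects mapping
region id -> network label; cohorts carry a manifest CSV.  All floats are
written at 17 significant digits so a write/read round trip is exact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .consistency import NetworkPartition
from .errors import ContractError, ParseError
from .measures import BoldMatrix, FCMatrix

_FLOAT_FMT = "%.17g"


def write_bold(bold: BoldMatrix, path, subject_id: str | None = None) -> None:
    """Write a BOLD matrix as TSV plus a ``.json`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(bold.values, columns=list(bold.region_ids))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "sampling_interval_s": bold.sampling_interval,
        "subject_id": subject_id or path.stem,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_bold(path) -> BoldMatrix:
    """Read a BOLD TSV/CSV (header = region ids) with its JSON sidecar."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ParseError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if "sampling_interval_s" not in sidecar:
        raise ParseError(f"sidecar {sidecar_path} lacks sampling_interval_s")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    ids = [h.strip() for h in header]
    if len(set(ids)) != len(ids):
        dupes = sorted({c for c in ids if ids.count(c) > 1})
        raise ParseError(f"duplicate region ids in header: {dupes}")
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    df.columns = ids
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce")
            rows = np.flatnonzero(bad.isna().to_numpy())
            if rows.size:
                raise ParseError(
                    f"non-numeric cell at row {rows[0] + 1}, column {col!r}"
                )
    nan_rows, nan_cols = np.nonzero(~np.isfinite(values.astype(float)))
    if nan_rows.size:
        raise ParseError(
            f"non-finite cell at row {nan_rows[0] + 1}, "
            f"column {ids[nan_cols[0]]!r}"
        )
    try:
        return BoldMatrix(
            values=values.astype(float),
            sampling_interval=float(sidecar["sampling_interval_s"]),
            region_ids=tuple(ids),
        )
    except ContractError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_partition(partition: NetworkPartition, path) -> None:
    Path(path).write_text(
        json.dumps({r: partition.assignment[r] for r in partition.region_ids},
                   indent=2)
    )


def read_partition(path, region_ids=None) -> NetworkPartition:
    """Read a JSON region -> network mapping.  Network order is
    first-appearance order.  If ``region_ids`` is given, every one of them
    must be present."""
    mapping = json.loads(Path(path).read_text())
    if not isinstance(mapping, dict) or not mapping:
        raise ParseError(f"{path}: expected a non-empty JSON object")
    if region_ids is not None:
        missing = [r for r in region_ids if r not in mapping]
        if missing:
            raise ContractError(
                f"regions present in data but absent from partition: {missing}"
            )
        return NetworkPartition(tuple(region_ids),
                                {r: mapping[r] for r in region_ids})
    return NetworkPartition(tuple(mapping.keys()), mapping)


def write_fc_matrix(fc: FCMatrix, path) -> None:
    """FC matrix as TSV with region ids as row/column headers plus a JSON
    metadata sidecar (measure, polarity)."""
    path = Path(path)
    df = pd.DataFrame(fc.values, index=list(fc.region_ids),
                      columns=list(fc.region_ids))
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    meta = {"measure": fc.measure, "polarity": fc.polarity}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_fc_matrix(path) -> FCMatrix:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return FCMatrix(
        values=df.to_numpy(dtype=float),
        measure=meta["measure"],
        polarity=meta["polarity"],
        region_ids=tuple(str(c) for c in df.columns),
    )


def write_cohort(cohort, out_dir) -> Path:
    """Write a synthetic cohort in the canonical layout: per-subject
    TSV/JSON, partition.json, and manifest.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in cohort.subjects:
        write_bold(sub.bold, out_dir / f"{sub.subject_id}.tsv", sub.subject_id)
        rows.append(
            {
                "subject_id": sub.subject_id,
                "group": sub.group,
                "behavior_score": repr(sub.behavior),
                "seed": sub.seed,
            }
        )
    write_partition(cohort.partition, out_dir / "partition.json")
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


def read_cohort(cohort_dir):
    """Load a written cohort: returns (bolds, manifest DataFrame,
    partition)."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv",
                           float_precision="round_trip")
    bolds = [read_bold(cohort_dir / f"{sid}.tsv")
             for sid in manifest["subject_id"]]
    partition = read_partition(cohort_dir / "partition.json",
                               region_ids=bolds[0].region_ids)
    return bolds, manifest, partition


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixtures(out_dir, seed: int = 0, force: bool = False) -> dict:
    """Write a deterministic miniature cohort (6 subjects, 12 regions in 3
    networks, t = 64) plus a checksum manifest; used as the smoke fixture
    for all pipelines.  Refuses a non-empty target directory unless
    ``force``."""
    from .synthetic import CohortSpec, SyntheticSpec, generate_cohort

    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise ContractError(f"{out_dir} is not empty; pass force=True")
    spec = SyntheticSpec(
        network_sizes=(4, 4, 4),
        within_strength=0.6,
        t=64,
        sampling_interval=2.6,
        seed=seed,
    )
    cohort = generate_cohort(
        spec,
        CohortSpec(n_group_a=3, n_group_b=3, effect_networks=("net01",),
                   effect_delta=0.2, behavior_network="net02", seed=seed),
    )
    write_cohort(cohort, out_dir)
    checksums = {
        p.name: _sha256(p)
        for p in sorted(out_dir.iterdir())
        if p.name != "checksums.json"
    }
    (out_dir / "checksums.json").write_text(json.dumps(checksums, indent=2))
    return checksums
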