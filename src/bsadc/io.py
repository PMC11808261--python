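"""File formats: CSV/TSV tables, FASTA sequences, JSON results.

Dialect: delimiter auto-detected from the extension (.csv comma, anything
else tab), decimal point, UTF-8.  Round trips are lossless to float
precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .design import CombinationCandidate, load_ddg_table
from .errors import DataError
from .hydropathy import HydropathyProfile, ProteinSeq, classify_hydrophilic
from .mm import RatePoint
from .stability import ProgressCurve, StabilityProfile

__all__ = [
    "read_progress_csv",
    "write_progress_csv",
    "read_rates_csv",
    "write_rates_csv",
    "read_fasta",
    "write_fasta",
    "read_ddg_tsv",
    "write_results_json",
    "write_profile_tsv",
    "write_stability_tsv",
]


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: no such file")
    try:
        df = pd.read_csv(path, sep=_sep(path))
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: file is empty") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        raise DataError(f"{path}: header only, no data rows")
    for col in required:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise DataError(f"{path}: non-numeric value in column {col!r}, row {row}")
        df[col] = pd.to_numeric(df[col])
    return df


def read_progress_csv(path: str | Path) -> ProgressCurve:
    """Read a progress curve (columns time_min, product_mM, optional label)."""
    df = _read_table(path, ["time_min", "product_mM"])
    label = str(df["label"].iloc[0]) if "label" in df.columns else Path(path).stem
    return ProgressCurve(
        times_min=df["time_min"].to_numpy(float),
        product_mM=df["product_mM"].to_numpy(float),
        label=label,
    )


def write_progress_csv(curve: ProgressCurve, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "time_min": curve.times_min,
            "product_mM": curve.product_mM,
            "label": curve.label,
        }
    ).to_csv(path, sep=_sep(path), index=False)
    return path


def read_rates_csv(path: str | Path) -> list[RatePoint]:
    """Read an initial-rate table (columns S_mM, v_mM_per_min)."""
    df = _read_table(path, ["S_mM", "v_mM_per_min"])
    return [
        RatePoint(S=float(s), v=float(v))
        for s, v in zip(df["S_mM"], df["v_mM_per_min"])
    ]


def write_rates_csv(points: Sequence[RatePoint], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"S_mM": [p.S for p in points], "v_mM_per_min": [p.v for p in points]}
    ).to_csv(path, sep=_sep(path), index=False)
    return path


def read_fasta(path: str | Path) -> list[ProteinSeq]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: no such file")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"{path}: no FASTA records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataError(f"{path}: duplicate FASTA id(s) {dupes}")
    return [ProteinSeq(id=r.id, residues=str(r.seq).upper()) for r in records]


def write_fasta(seqs: Sequence[ProteinSeq], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")
    return path


def read_ddg_tsv(path: str | Path) -> list[CombinationCandidate]:
    return load_ddg_table(path)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def write_results_json(results: dict, path: str | Path, formatted_dp: int = 2) -> Path:
    """Write results with full-precision floats plus a 'formatted' block
    rounded to ``formatted_dp`` decimals for table-style comparison."""
    path = Path(path)
    payload = _jsonable(results)
    formatted = {
        k: (round(v, formatted_dp) if isinstance(v, float) else v)
        for k, v in payload.items()
        if not isinstance(v, (dict, list))
    }
    payload = dict(payload)
    payload["formatted"] = formatted
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def write_profile_tsv(profile: HydropathyProfile, path: str | Path) -> Path:
    """Hydropathy profile as TSV: position, residue, score, hydrophilic flag."""
    path = Path(path)
    mask = classify_hydrophilic(profile)
    pd.DataFrame(
        {
            "position": np.arange(1, len(profile.residues) + 1),
            "residue": list(profile.residues),
            "score": profile.scores,
            "hydrophilic": mask,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def write_stability_tsv(profile: StabilityProfile, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "time_min": profile.eval_times_min,
            "activity_mM_per_min": profile.activity_mM_per_min,
            "residual_pct": profile.residual_pct,
        }
    ).to_csv(path, sep="\t", index=False)
    return path
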