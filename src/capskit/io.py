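"""Readers and writers: FASTA variants, growth/lane CSV tables, reports.

CSV dialect is comma-separated UTF-8 with a mandatory header row and "."
decimal separator.  Writers are deterministic (stable key order, repr
floats) so reports can be diffed byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ValidationError
from .gelquant import LaneDensitometry
from .growth import GrowthCurve
from .restriction import IUPAC_DNA, SequenceVariant


def read_fasta(path) -> list[SequenceVariant]:
    """Parse a multi-record FASTA into sequence variants.

    Sequences are uppercased and whitespace-stripped; duplicate record IDs,
    empty files and non-IUPAC characters are rejected with named errors.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    variants = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate record ID {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace(" ", "")
        for pos, ch in enumerate(seq, start=1):
            if ch not in IUPAC_DNA:
                raise ValidationError(
                    f"{path}: record {rec.id!r} has illegal character {ch!r} "
                    f"at position {pos}"
                )
        variants.append(SequenceVariant(rec.id, seq))
    return variants


def write_fasta(variants: Sequence[SequenceVariant], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for v in variants:
            fh.write(f">{v.id}\n")
            for i in range(0, len(v.sequence), width):
                fh.write(v.sequence[i : i + width] + "\n")


_GROWTH_COLUMNS = ["substrate_uM", "time_h", "od", "replicate"]


def read_growth_csv(path) -> list[GrowthCurve]:
    """Parse a growth table (substrate_uM, time_h, od, replicate).

    Row order is irrelevant; one GrowthCurve per substrate concentration
    with od shaped (times, replicates).  Duplicated (concentration, time,
    replicate) rows and missing cells are rejected.
    """
    df = _read_table(path, _GROWTH_COLUMNS)
    if df[["substrate_uM", "time_h", "od"]].isna().any().any():
        raise ValidationError(f"{path}: non-numeric or missing cell in growth table")
    dup = df.duplicated(subset=["substrate_uM", "time_h", "replicate"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicated (substrate_uM={row.substrate_uM}, "
            f"time_h={row.time_h}, replicate={row.replicate}) row"
        )
    if (df["substrate_uM"] < 0).any():
        raise ValidationError(f"{path}: negative substrate concentration")
    curves = []
    for conc, group in sorted(df.groupby("substrate_uM")):
        pivot = group.pivot(index="time_h", columns="replicate", values="od")
        if pivot.isna().any().any():
            raise ValidationError(
                f"{path}: replicates at {conc} uM do not share the same time grid"
            )
        pivot = pivot.sort_index()
        curves.append(
            GrowthCurve(
                substrate_conc=float(conc),
                times=pivot.index.to_numpy(dtype=float),
                od=pivot.to_numpy(dtype=float),
            )
        )
    return curves


def write_growth_csv(curves: Sequence[GrowthCurve], path) -> None:
    rows = []
    for curve in curves:
        for j in range(curve.n_replicates):
            for t, od in zip(curve.times, curve.od[:, j]):
                rows.append(
                    {"substrate_uM": curve.substrate_conc, "time_h": t,
                     "od": od, "replicate": j + 1}
                )
    pd.DataFrame(rows, columns=_GROWTH_COLUMNS).to_csv(path, index=False)


_LANE_COLUMNS = ["lane", "condition", "band_length", "intensity"]
_REF_COLUMNS = ["lane", "reference_intensity"]


def read_lanes_csv(lanes_path, reference_path) -> list[LaneDensitometry]:
    """Parse band densitometry plus the loading-control reference table."""
    lanes = _read_table(lanes_path, _LANE_COLUMNS)
    refs = _read_table(reference_path, _REF_COLUMNS)
    if refs["lane"].duplicated().any():
        raise ValidationError(f"{reference_path}: duplicated lane in reference table")
    ref_map = dict(zip(refs["lane"].astype(str), refs["reference_intensity"]))
    out = []
    for (lane_id, condition), group in lanes.groupby(["lane", "condition"], sort=True):
        key = str(lane_id)
        if key not in ref_map:
            raise ValidationError(
                f"{lanes_path}: lane {key!r} has no reference intensity"
            )
        bands = [
            (float(r.band_length), float(r.intensity)) for r in group.itertuples()
        ]
        out.append(
            LaneDensitometry(
                lane_id=key,
                condition=str(condition),
                bands=bands,
                reference_intensity=float(ref_map[key]),
            )
        )
    return out


def _read_table(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty CSV file") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    for col in required:
        if col in ("lane", "condition", "replicate"):
            continue
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any():
            raise ValidationError(f"{path}: non-numeric cell in column {col!r}")
    return df


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def write_report(results, path, fmt: str = "json") -> None:
    """Write a results object deterministically as JSON or CSV."""
    path = Path(path)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "csv":
        if not isinstance(results, pd.DataFrame):
            results = pd.DataFrame(_jsonable(results))
        results.to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown report format {fmt!r}")
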