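"""Plain-text I/O: recordings as TSV channel x sample matrices with a JSON
metadata sidecar, behaviour/drug tables and connectivity matrices as
TSV/CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behaviour import ParticipantRecord
from .containers import LEVELS, Recording


def write_recording(recording: Recording, path: str | Path, meta: dict | None = None) -> None:
    """Write a recording as TSV (rows = channels) plus a ``.json`` sidecar
    holding sampling rate, labels, positions and any extra metadata."""
    path = Path(path)
    np.savetxt(path, recording.data, fmt="%.6f", delimiter="\t")
    sidecar = {
        "fs": recording.fs,
        "labels": recording.labels,
        "positions": None
        if recording.positions is None
        else recording.positions.tolist(),
        "units": "uV",
    }
    if meta:
        sidecar.update(meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path) -> Recording:
    """Read a TSV channel x sample matrix with its JSON sidecar."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    positions = sidecar.get("positions")
    return Recording(
        data=data,
        fs=float(sidecar["fs"]),
        labels=list(sidecar["labels"]),
        positions=None if positions is None else np.asarray(positions),
    )


def write_connectivity_matrix(
    matrix: np.ndarray, labels: list[str], path: str | Path
) -> None:
    """Symmetric band matrix as TSV with channel labels on both axes."""
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep="\t")


def read_connectivity_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), list(df.columns)


def behaviour_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Flatten participant records into a tidy per-level table."""
    rows = []
    for rec in records:
        for level in LEVELS:
            if level not in rec.hits:
                continue
            rts = rec.reaction_times.get(level, [])
            rows.append(
                {
                    "participant": rec.participant,
                    "level": level,
                    "hits": rec.hits[level],
                    "trials": rec.trials[level],
                    "hit_rate": rec.hit_rate(level),
                    "median_rt": float(np.median(rts)) if rts else np.nan,
                    "drug_ug_ml": rec.drug.get(level, np.nan),
                    "group": rec.group,
                }
            )
    return pd.DataFrame(rows)


def frame_to_behaviour(df: pd.DataFrame) -> list[ParticipantRecord]:
    records = []
    for pid, sub in df.groupby("participant", sort=False):
        rec = ParticipantRecord(participant=str(pid))
        for _, row in sub.iterrows():
            level = row["level"]
            rec.hits[level] = int(row["hits"])
            rec.trials[level] = int(row["trials"])
            if np.isfinite(row.get("drug_ug_ml", np.nan)):
                rec.drug[level] = float(row["drug_ug_ml"])
        if "group" in sub.columns:
            groups = sub["group"].dropna().unique()
            if len(groups):
                rec.group = str(groups[0])
        records.append(rec)
    return records
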