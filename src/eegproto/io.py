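"""Per-session CSV reading/writing, manifests, and dataset diagnostics."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .records import CHANNELS, LIE, TRUTH, DataFormatError, SessionRecord


def write_session_csv(record: SessionRecord, destination: str | os.PathLike) -> None:
    """Write one session: header of channel names, one row per sample.

    Values are stored in microvolts with 6 significant digits (below the
    noise floor of the recordings this emulates).
    """
    df = pd.DataFrame(record.samples, columns=list(record.channel_names))
    df.to_csv(destination, index=False, float_format="%.6g")


def read_session_csv(
    source: str | os.PathLike,
    fs: float,
    label: int,
    subject_id: str,
    session_id: str,
    column_map: dict[str, str] | None = None,
    sep: str = ",",
) -> SessionRecord:
    """Read a session CSV into canonical channel order (AF3,T7,Pz,T8,AF4).

    ``column_map`` maps canonical channel names to the column names used in
    the file; by default the canonical names themselves are expected. Extra
    columns are ignored. A missing channel column raises
    :class:`DataFormatError`; a non-numeric cell raises a parse error naming
    the offending row.
    """
    try:
        df = pd.read_csv(source, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError(f"{source}: empty file") from exc
    if column_map is None:
        column_map = {ch: ch for ch in CHANNELS}
    missing = [ch for ch in CHANNELS if column_map.get(ch, ch) not in df.columns]
    if missing:
        raise DataFormatError(f"{source}: missing channel column(s) {missing}")
    cols = [column_map.get(ch, ch) for ch in CHANNELS]
    data = df[cols]
    numeric = data.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~data.isna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy().any(axis=1))[0][0])
        raise DataFormatError(f"{source}: non-numeric cell at data row {row}")
    if numeric.isna().to_numpy().any():
        raise DataFormatError(f"{source}: missing values after load")
    if len(numeric) == 0:
        raise DataFormatError(f"{source}: no sample rows")
    return SessionRecord(
        subject_id=subject_id,
        session_id=session_id,
        label=label,
        fs=fs,
        channel_names=CHANNELS,
        samples=numeric.to_numpy(dtype=np.float64),
    )


def write_manifest(manifest: pd.DataFrame, destination: str | os.PathLike) -> None:
    manifest.to_csv(destination, index=False)


def read_manifest(source: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(source)
    required = {"subject_id", "session_id", "label", "file"}
    if not required.issubset(df.columns):
        raise DataFormatError(f"{source}: manifest must have columns {sorted(required)}")
    return df


def load_dataset(
    manifest_path: str | os.PathLike,
    fs: float = 128.0,
    column_map: dict[str, str] | None = None,
    sep: str = ",",
) -> list[SessionRecord]:
    """Load every session listed in a manifest (paths relative to it)."""
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    records = []
    for row in manifest.itertuples(index=False):
        records.append(
            read_session_csv(
                base / row.file,
                fs=fs,
                label=int(row.label),
                subject_id=str(row.subject_id),
                session_id=str(row.session_id),
                column_map=column_map,
                sep=sep,
            )
        )
    return records


def dataset_diagnostics(records: list[SessionRecord]) -> dict:
    """Counts of subjects, sessions, labels, and per-session durations."""
    if not records:
        return {
            "n_subjects": 0,
            "n_sessions": 0,
            "n_lie": 0,
            "n_truth": 0,
            "durations_s": pd.Series(dtype=float),
        }
    durations = pd.Series(
        {r.session_id: r.duration_s for r in records}, name="duration_s"
    )
    labels = [r.label for r in records]
    return {
        "n_subjects": len({r.subject_id for r in records}),
        "n_sessions": len(records),
        "n_lie": sum(1 for y in labels if y == LIE),
        "n_truth": sum(1 for y in labels if y == TRUTH),
        "durations_s": durations,
    }
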