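"""Plain-text trajectory logs.

A log is a single tab-separated file: commented header lines carrying a
JSON echo of the run configuration, the unit system, and the weight-
table history; one row per exchange attempt; and a trailing record-count
marker so truncation is detectable.  Floats are written at full
precision, so a write/read round trip is lossless.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["TrajectoryLog", "write_log", "read_log", "CorruptLogError"]

_FORMAT_TAG = "soltemper-log v1"

RECORD_COLUMNS = [
    "step",
    "time",
    "rung_index",
    "lambda",
    "epp1",
    "epp2",
    "epw",
    "eww",
    "monitor",
    "proposed_rung",
    "delta",
    "accepted",
    "order_param",
]

_INT_COLUMNS = {"step", "rung_index", "proposed_rung", "accepted"}


class CorruptLogError(ValueError):
    """Raised on truncated or inconsistent log files."""

    def __init__(self, message: str, last_good_record: int = -1):
        super().__init__(message)
        self.last_good_record = last_good_record


@dataclass
class TrajectoryLog:
    """Per-exchange-attempt records plus run metadata.

    ``weights_history`` is a list of ``(refresh_step, [w_0 … w_{M−1}])``
    snapshots, the last of which is the final weight table of the run.
    """

    header: dict
    records: pd.DataFrame
    weights_history: list = field(default_factory=list)

    @property
    def unit_system(self) -> str:
        return self.header.get("unit_system", "reduced")

    @property
    def final_weights(self) -> Optional[np.ndarray]:
        if not self.weights_history:
            return None
        return np.asarray(self.weights_history[-1][1], dtype=float)

    def empty(self) -> bool:
        return len(self.records) == 0


def _new_records(n: int = 0) -> pd.DataFrame:
    df = pd.DataFrame({c: [] for c in RECORD_COLUMNS})
    return df


def write_log(log: TrajectoryLog, path) -> None:
    """Write a log as delimited text with a commented header."""
    buf = io.StringIO()
    buf.write(f"# {_FORMAT_TAG}\n")
    buf.write(f"# header: {json.dumps(log.header, sort_keys=True)}\n")
    history = [[int(s), [float(w) for w in ws]] for s, ws in log.weights_history]
    buf.write(f"# weights_history: {json.dumps(history)}\n")
    df = log.records
    buf.write("\t".join(RECORD_COLUMNS) + "\n")
    for row in df.itertuples(index=False):
        fields = []
        for col, v in zip(df.columns, row):
            if col in _INT_COLUMNS:
                fields.append(str(int(v)))
            else:
                fields.append(repr(float(v)))
        buf.write("\t".join(fields) + "\n")
    buf.write(f"# end records={len(df)}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_log(path, unit_system: Optional[str] = None) -> TrajectoryLog:
    """Read a log written by :func:`write_log`.

    Raises :class:`CorruptLogError` (with the index of the last intact
    record) on truncation, and ``ValueError("unit mismatch")`` when
    ``unit_system`` is given and disagrees with the header.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != f"# {_FORMAT_TAG}":
        raise CorruptLogError("corrupt log: missing format tag")
    header: dict = {}
    weights_history: list = []
    data_lines: list[str] = []
    end_count: Optional[int] = None
    for line in lines[1:]:
        if line.startswith("# header: "):
            header = json.loads(line[len("# header: ") :])
        elif line.startswith("# weights_history: "):
            weights_history = [
                (int(s), list(map(float, ws)))
                for s, ws in json.loads(line[len("# weights_history: ") :])
            ]
        elif line.startswith("# end records="):
            end_count = int(line[len("# end records=") :])
        elif line.startswith("#"):
            continue
        else:
            data_lines.append(line)
    if not data_lines:
        raise CorruptLogError("corrupt log: missing column header")
    try:
        records = pd.read_csv(
            io.StringIO("\n".join(data_lines)), sep="\t", float_precision="round_trip"
        )
    except Exception as exc:  # malformed rows
        raise CorruptLogError(f"corrupt log: {exc}") from exc
    if list(records.columns) != RECORD_COLUMNS:
        raise CorruptLogError("corrupt log: unexpected columns")
    if end_count is None or end_count != len(records):
        raise CorruptLogError(
            "corrupt log: truncated records", last_good_record=len(records) - 1
        )
    for col in _INT_COLUMNS:
        records[col] = records[col].astype(np.int64)
    if unit_system is not None and header.get("unit_system") != unit_system:
        raise ValueError("unit mismatch")
    return TrajectoryLog(header=header, records=records, weights_history=weights_history)
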