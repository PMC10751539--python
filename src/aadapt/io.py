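"""CSV / JSON readers and writers and run configuration.

Measurement tables follow the intraoperative protocol: the
hemicircumference is read twice, 10 cm from each end of the segment, and
the segment width is the arithmetic mean of the two readings.  The reader
keeps the exact mean at full precision.

CSV schemas (UTF-8, header required, dot decimal separator):

* measurements: ``segment_id, reading1_cm, reading2_cm, length_cm``
* bench:        ``pouch_id, width_cm, length_cm, effective_ml``
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputError
from .geometry import IlealSegment, PouchPrediction
from .validation import BenchRecord

__all__ = [
    "RunConfig",
    "read_measurements",
    "read_bench",
    "read_widths",
    "emit",
    "bench_to_frame",
]

log = logging.getLogger("aadapt")

MEASUREMENT_COLUMNS = ["segment_id", "reading1_cm", "reading2_cm", "length_cm"]
BENCH_COLUMNS = ["pouch_id", "width_cm", "length_cm", "effective_ml"]


@dataclass
class RunConfig:
    """Run-level options, overridable from a JSON config file.

    ``rounding_mode`` selects which planned length the CLI reports
    (``exact`` at full precision or ``clinical`` ceil-to-whole-cm);
    ``width_warning_bounds`` sets the plausibility band; output defaults
    to human-readable text.
    """

    rounding_mode: str = "clinical"
    width_warning_bounds: tuple[float, float] = (2.0, 3.5)
    log_level: str = "WARNING"
    output_format: str = "text"

    _MODES = ("exact", "clinical")
    _FORMATS = ("text", "json", "csv")

    def __post_init__(self) -> None:
        if self.rounding_mode not in self._MODES:
            raise InputError(f"rounding_mode must be one of {self._MODES}")
        if self.output_format not in self._FORMATS:
            raise InputError(f"output_format must be one of {self._FORMATS}")
        lo, hi = self.width_warning_bounds
        if not lo < hi:
            raise InputError("width_warning_bounds must be ordered (low, high)")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            payload = json.loads(Path(path).read_text(encoding="utf-8"))
        except (OSError, json.JSONDecodeError) as exc:
            raise InputError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(payload, dict):
            raise InputError("config JSON must be an object")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "width_warning_bounds" in payload:
            payload["width_warning_bounds"] = tuple(payload["width_warning_bounds"])
        return cls(**payload)


def _load_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except FileNotFoundError as exc:
        raise InputError(f"no such file: {path}") from exc
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise InputError(f"cannot parse CSV {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")
    return df


def _row_float(row, col: str, path, idx: int) -> float:
    value = row[col]
    try:
        out = float(value)
    except (TypeError, ValueError) as exc:
        raise InputError(f"{path}, row {idx + 2}: {col}={value!r} is not numeric") from exc
    if not math.isfinite(out) or out <= 0:
        raise InputError(f"{path}, row {idx + 2}: {col}={value!r} must be positive")
    return out


def read_measurements(path: str | Path) -> list[IlealSegment]:
    """Read an intraoperative measurement table into segments.

    The segment width is the mean of the two hemicircumference readings.
    Out-of-range widths are logged as warnings but never dropped; a
    malformed row raises :class:`InputError` naming the row.
    """
    df = _load_table(path, MEASUREMENT_COLUMNS)
    segments = []
    for idx, row in df.iterrows():
        r1 = _row_float(row, "reading1_cm", path, idx)
        r2 = _row_float(row, "reading2_cm", path, idx)
        length = _row_float(row, "length_cm", path, idx)
        width = (r1 + r2) / 2.0
        seg = IlealSegment(
            length_cm=length, width_cm=width, segment_id=str(row["segment_id"])
        )
        if not seg.plausible:
            log.warning(
                "segment %s: width %.3f cm or length %.1f cm outside the "
                "usual human range",
                seg.segment_id,
                width,
                length,
            )
        segments.append(seg)
    if not segments:
        raise InputError(f"{path}: no measurement rows")
    return segments


def read_bench(path: str | Path) -> list[BenchRecord]:
    """Read a bench-measurement table; predictions are recomputed."""
    df = _load_table(path, BENCH_COLUMNS)
    records = []
    for idx, row in df.iterrows():
        records.append(
            BenchRecord(
                pouch_id=str(row["pouch_id"]),
                width_cm=_row_float(row, "width_cm", path, idx),
                length_cm=_row_float(row, "length_cm", path, idx),
                effective_ml=_row_float(row, "effective_ml", path, idx),
            )
        )
    if not records:
        raise InputError(f"{path}: no bench rows")
    return records


def read_widths(path: str | Path) -> list[float]:
    """Read a one-column ``width_cm`` CSV (simulator cohort output)."""
    df = _load_table(path, ["width_cm"])
    if df.empty:
        raise InputError(f"{path}: no width rows")
    return [float(x) for x in df["width_cm"]]


def bench_to_frame(records: Iterable[BenchRecord]) -> pd.DataFrame:
    """Bench records as a DataFrame matching the bench CSV schema."""
    return pd.DataFrame(
        [
            {
                "pouch_id": r.pouch_id,
                "width_cm": r.width_cm,
                "length_cm": r.length_cm,
                "effective_ml": r.effective_ml,
                "predicted_ml": r.predicted_ml,
            }
            for r in records
        ]
    )


def _text_line(rec: dict) -> str:
    parts = []
    for key, value in rec.items():
        if key.endswith("_ml"):
            parts.append(f"{key[:-3].replace('_', ' ')}: {value:.0f} ml")
        elif key.endswith("_cm"):
            parts.append(f"{key[:-3].replace('_', ' ')}: {value:.1f} cm")
        elif key.endswith("_cm2"):
            parts.append(f"{key[:-4].replace('_', ' ')}: {value:.1f} cm2")
        elif isinstance(value, float):
            parts.append(f"{key.replace('_', ' ')}: {value:.4f}")
        else:
            parts.append(f"{key.replace('_', ' ')}: {value}")
    return " | ".join(parts)


def emit(results: Sequence[dict], fmt: str = "text") -> str:
    """Serialise result records to text, JSON or CSV.

    Field order is the records' insertion order in every format. Text mode
    rounds volumes to whole ml and lengths to 0.1 cm (the reporting
    granularity of the underlying measurements); JSON and CSV keep full
    float precision.
    """
    records = list(results)
    if not records:
        raise InputError("nothing to emit: results are empty")
    if fmt == "json":
        payload = records[0] if len(records) == 1 else records
        return json.dumps(payload, indent=2)
    if fmt == "csv":
        return pd.DataFrame(records).to_csv(index=False)
    if fmt == "text":
        return "\n".join(_text_line(r) for r in records)
    raise InputError(f"unknown output format {fmt!r} (expected text, json or csv)")


def prediction_record(
    length_cm: float, width_cm: float, prediction: PouchPrediction
) -> dict:
    """The documented JSON schema for one forward-model evaluation."""
    return {
        "length_cm": length_cm,
        "width_cm": width_cm,
        "radius_cm": prediction.radius_cm,
        "surface_area_cm2": prediction.surface_area_cm2,
        "volume_ml": prediction.volume_ml,
    }
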