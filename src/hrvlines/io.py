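"""Reading RR-interval inputs and writing analysis outputs.

Supported inputs are plain RR text (one interval per line; ``#`` comments
and blank lines skipped), CSV with a configurable interval column, and
beat-time sequences from which intervals are differenced.  The package's
contract starts at beat times or RR lists; binary waveform/annotation
parsing belongs to upstream tooling.  Ectopic-labeled beats are retained
by default -- they are the signal the line detectors target -- with an
opt-in label filter for conventional NN-interval comparisons.

All numeric output is serialized with 12 significant digits so repeated
runs with identical inputs and configuration are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import RRSeries
from .detection import PresenceResult, SignatureVector
from .variability import OrderScan

__all__ = [
    "RecordMetadata",
    "read_rr",
    "intervals_from_annotations",
    "write_outputs",
    "FLOAT_FMT",
]

FLOAT_FMT = "%.12g"

#: report row order for signature tables
SIGNATURE_ROW_ORDER = ("A1+", "A1-", "A2+", "A2-", "B1", "B2")


@dataclass(frozen=True)
class RecordMetadata:
    source_path: str
    format: str  # rr_text | csv | annotation_intervals
    unit: str
    beat_labels: tuple | None = None


def read_rr(
    path,
    format: str = "rr_text",
    unit: str | None = None,
    rr_column: str | int = 0,
    comment: str = "#",
) -> RRSeries:
    """Read an RR series from a text or CSV file; result is in seconds.

    With ``unit=None`` milliseconds are auto-detected (median > 10).
    Unparseable lines raise with their 1-based line number.
    """
    path = Path(path)
    if format == "rr_text":
        values = []
        with path.open() as fh:
            for lineno, raw in enumerate(fh, start=1):
                stripped = raw.strip()
                if not stripped or stripped.startswith(comment):
                    continue
                try:
                    values.append(float(stripped))
                except ValueError:
                    raise ValueError(
                        f"{path}: unparseable RR value {stripped!r} on line {lineno}"
                    ) from None
    elif format == "csv":
        df = pd.read_csv(path, comment=comment)
        col = df.columns[rr_column] if isinstance(rr_column, int) else rr_column
        if col not in df.columns:
            raise ValueError(f"{path}: no column {rr_column!r} in {list(df.columns)}")
        values = df[col].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown format {format!r}")
    if len(values) < 2:
        raise ValueError(f"{path}: need at least 2 intervals, found {len(values)}")
    return RRSeries.from_values(values, unit=unit, source_id=str(path))


def intervals_from_annotations(
    beat_times,
    beat_labels=None,
    include_labels: str | set = "all",
    source_id: str = "",
) -> RRSeries:
    """Successive differences of beat times (seconds) as an RR series.

    ``include_labels="all"`` (default) keeps every beat regardless of its
    annotation label -- ectopic beats are the method's signal.  Passing a
    set of labels keeps only those beats (conventional NN filtering).
    """
    t = np.asarray(beat_times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least two beat times")
    if beat_labels is not None and include_labels != "all":
        labels = np.asarray(list(beat_labels))
        if labels.size != t.size:
            raise ValueError("beat_labels must match beat_times in length")
        keep = np.isin(labels, sorted(include_labels))
        t = t[keep]
        if t.size < 2:
            raise ValueError("fewer than two beats remain after label filtering")
    diffs = np.diff(t)
    bad = np.flatnonzero(diffs <= 0)
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"beat times not strictly increasing at index {i + 1} "
            f"(t[{i}]={t[i]!r}, t[{i + 1}]={t[i + 1]!r})"
        )
    return RRSeries(intervals=diffs, source_id=source_id, unit_declared="seconds")


def _fmt(x: float) -> str:
    return FLOAT_FMT % float(x)


def write_outputs(
    out_dir,
    signature: SignatureVector | None = None,
    presence_results: list[PresenceResult] | None = None,
    scan: OrderScan | None = None,
    config: dict | None = None,
) -> list[Path]:
    """Write signature.json/.csv, matches.csv, phi_scan.csv and the config.

    Only the sections whose objects are provided are written.  Output is
    deterministic: fixed row order (signature rows follow the report
    order A1+, A1-, A2+, A2-, B1, B2) and 12-significant-digit floats.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if signature is not None:
        payload = {
            "N": signature.N,
            "M_used": signature.M_used,
            "presences": {
                k: float(_fmt(signature.presences[k]))
                for k in SIGNATURE_ROW_ORDER
                if k in signature.presences
            },
            "phi": float(_fmt(signature.phi)),
        }
        p = out_dir / "signature.json"
        p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(p)

        p = out_dir / "signature.csv"
        lines = ["quantity,value"]
        for k in SIGNATURE_ROW_ORDER:
            if k in signature.presences:
                lines.append(f"{k},{_fmt(signature.presences[k])}")
        lines.append(f"phi,{_fmt(signature.phi)}")
        p.write_text("\n".join(lines) + "\n")
        written.append(p)

    if presence_results is not None:
        p = out_dir / "matches.csv"
        lines = ["beat_index,line,cos_theta,amplitude,window_norm"]
        for res in presence_results:
            for mr in res.matches:
                lines.append(
                    f"{mr.window_index},{mr.line_name},{_fmt(mr.cos_theta)},"
                    f"{_fmt(mr.amplitude)},{_fmt(mr.window_norm)}"
                )
        p.write_text("\n".join(lines) + "\n")
        written.append(p)

    if scan is not None:
        p = out_dir / "phi_scan.csv"
        lines = ["order,phi"]
        for n, phi in zip(scan.orders, scan.phis):
            lines.append(f"{int(n)},{_fmt(phi)}")
        p.write_text("\n".join(lines) + "\n")
        written.append(p)

    if config is not None:
        p = out_dir / "run_config.json"
        p.write_text(json.dumps(config, indent=2, sort_keys=True, default=str) + "\n")
        written.append(p)

    return written
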