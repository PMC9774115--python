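"""CSV/JSON input-output and validation-report assembly.

Panel CSV schema: ``level_label, nominal_ngml, day, replicate, value``
with censored cells written as ``"<0.2"`` / ``">40"``.  Pairs CSV schema:
``sample_id, lab1_ngml, lab2_ngml``.  Reports serialize losslessly to
JSON (full precision) and to a CSV mirroring the published table layout
(presentation-rounded to one decimal).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd

from .core_stats import AssayValError, Measurement
from .method_comparison import PairedMeasurements
from .precision import SpikeLevel, SpikePanel

PANEL_COLUMNS = ["level_label", "nominal_ngml", "day", "replicate", "value"]
PAIRS_COLUMNS = ["sample_id", "lab1_ngml", "lab2_ngml"]


class SchemaError(AssayValError):
    """A CSV file does not match the expected schema."""


def _require_columns(df: pd.DataFrame, columns: "List[str]", path: "str | Path") -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_panel(path: "str | Path", matrix_floor: float = 0.1) -> SpikePanel:
    """Read a spike panel CSV into a :class:`SpikePanel`.

    Censored cell strings are mapped to censored measurements; duplicate
    (level, day, replicate) keys are schema errors reported with their
    row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"value": str}, float_precision="round_trip")
    _require_columns(df, PANEL_COLUMNS, path)
    dup = df.duplicated(subset=["level_label", "day", "replicate"], keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup]]  # +2: header + 1-based
        raise SchemaError(f"{path}: duplicate (level, day, replicate) keys at rows {rows}")
    levels: Dict[str, Dict[str, Any]] = {}
    for i, rec in df.iterrows():
        row_no = int(i) + 2
        try:
            nominal = float(rec["nominal_ngml"])
            day = int(rec["day"])
            meas = Measurement.from_cell(rec["value"])
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: row {row_no}: {exc}") from exc
        entry = levels.setdefault(
            str(rec["level_label"]), {"nominal": nominal, "days": {}}
        )
        if entry["nominal"] != nominal:
            raise SchemaError(
                f"{path}: row {row_no}: level {rec['level_label']} has conflicting nominals"
            )
        entry["days"].setdefault(day, []).append(meas)
    spike_levels = [
        SpikeLevel(
            label=label,
            nominal=entry["nominal"],
            days=[entry["days"][d] for d in sorted(entry["days"])],
        )
        for label, entry in sorted(levels.items(), key=lambda kv: kv[1]["nominal"])
    ]
    return SpikePanel(levels=spike_levels, matrix_floor=matrix_floor)


def write_panel(panel: SpikePanel, path: "str | Path") -> None:
    """Write a panel to CSV; deterministic (byte-identical for equal panels)."""
    lines = [",".join(PANEL_COLUMNS)]
    for lv in panel.levels:
        for d, day in enumerate(lv.days, start=1):
            for r, m in enumerate(day, start=1):
                lines.append(f"{lv.label},{lv.nominal:g},{d},{r},{m.to_cell()}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pairs(path: "str | Path") -> PairedMeasurements:
    """Read paired two-laboratory measurements from CSV."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PAIRS_COLUMNS, path)
    try:
        return PairedMeasurements(
            ids=[str(s) for s in df["sample_id"]],
            lab1=df["lab1_ngml"].to_numpy(dtype=float),
            lab2=df["lab2_ngml"].to_numpy(dtype=float),
        )
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_pairs(pairs: PairedMeasurements, path: "str | Path") -> None:
    """Write paired measurements to CSV; deterministic."""
    lines = [",".join(PAIRS_COLUMNS)]
    for sid, v1, v2 in zip(pairs.ids, pairs.lab1, pairs.lab2):
        lines.append(f"{sid},{float(v1)!r},{float(v2)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def file_sha256(path: "str | Path") -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class ValidationReport:
    """Assembled validation results plus provenance, as JSON-ready sections."""

    precision: Optional[Dict[str, Any]] = None
    linearity: Optional[Dict[str, Any]] = None
    recovery: Optional[Dict[str, Any]] = None
    comparison: Optional[Dict[str, Any]] = None
    total_error: Optional[Dict[str, Any]] = None
    qc: Optional[Dict[str, Any]] = None
    provenance: Dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_results(cls, provenance: Optional[Dict[str, Any]] = None, **sections: Any) -> "ValidationReport":
        """Build a report from result dataclasses (converted losslessly)."""
        return cls(
            provenance=_to_jsonable(provenance or {}),
            **{k: _to_jsonable(v) for k, v in sections.items() if v is not None},
        )

    def to_dict(self) -> Dict[str, Any]:
        out = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if value is not None:
                out[f.name] = value
        return out


def write_report(report: ValidationReport, path: "str | Path", format: str = "json") -> None:
    """Serialize a report; ``json`` is lossless, ``csv`` mirrors the
    published table layout (per-level columns plus an average row,
    rounded to one decimal)."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
        return
    if format != "csv":
        raise ValueError(f"format must be 'json' or 'csv', got {format!r}")
    if report.precision is None:
        raise AssayValError("CSV report requires a precision section")
    prows = {r["label"]: r for r in report.precision["rows"]}
    terows = {r["label"]: r for r in (report.total_error or {}).get("rows", [])}
    srb_rows = {r["label"]: r for r in (report.recovery or {}).get("rows", [])}

    def fmt(v: Any) -> str:
        return "" if v is None else f"{float(v):.1f}"

    lines = ["spiked,measured,within_cv,between_cv,srb,teo_sr,teo_rb,teo_ab"]
    for label, p in prows.items():
        te = terows.get(label, {})
        rec = srb_rows.get(label, {})
        lines.append(
            ",".join(
                [
                    f"{p['nominal']:g}",
                    fmt(p["measured_mean"]),
                    fmt(p["within_cv"]),
                    fmt(p["between_cv"]),
                    fmt(rec.get("srb")),
                    fmt(te.get("teo_sr")),
                    fmt(te.get("teo_rb")),
                    fmt(te.get("teo_ab")),
                ]
            )
        )
    te_tab = report.total_error or {}
    lines.append(
        ",".join(
            [
                "average",
                "",
                fmt(report.precision["average_within_cv"]),
                fmt(report.precision["average_between_cv"]),
                "",
                fmt(te_tab.get("average_sr")),
                fmt(te_tab.get("average_rb")),
                fmt(te_tab.get("average_ab")),
            ]
        )
    )
    path.write_text("\n".join(lines) + "\n")


def read_report(path: "str | Path") -> ValidationReport:
    """Read back a JSON report written by :func:`write_report`."""
    data = json.loads(Path(path).read_text())
    return ValidationReport(**data)
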