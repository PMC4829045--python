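"""CSV readers/writers, bundled fixture access, config files and report rendering.

Schemas
-------
``turtles.csv``: id, date_tagged, scl_tagging_cm, date_otc, date_stranded,
scl_recovery_cm, fibropapilloma.

``bones.csv`` (long, one row per LAG): turtle_id, lag_index,
lag_diameter_mm, is_double, section_diameter_mm, resorption_diameter_mm,
otc_diameter_mm.

Dates are ISO 8601 by preference; the day-month-year dialect of the
printed field tables (``17-10-02``) is also accepted.
"""

from __future__ import annotations

import csv
import datetime as dt
import importlib.resources
from pathlib import Path

import pandas as pd
import yaml

from .chronology import DepositionSeason
from .core import BackCalcParams, BoneProfile, TurtleRecord
from .errors import RowError, SchemaError
from .pipeline import PipelineConfig, PipelineResult
from .simulate import SimTruth

__all__ = [
    "parse_date",
    "read_tables",
    "write_tables",
    "write_truth",
    "bundled_fixture_path",
    "load_config",
    "render_table1",
    "render_table2",
]

_TURTLE_COLS = [
    "id", "date_tagged", "scl_tagging_cm", "date_otc", "date_stranded",
    "scl_recovery_cm", "fibropapilloma",
]
_BONE_COLS = [
    "turtle_id", "lag_index", "lag_diameter_mm", "is_double",
    "section_diameter_mm", "resorption_diameter_mm", "otc_diameter_mm",
]


def parse_date(text: str) -> dt.date:
    """Parse ISO 8601 first, then the printed tables' D-M-Y dialect."""
    text = text.strip()
    try:
        return dt.date.fromisoformat(text)
    except ValueError:
        pass
    for fmt in ("%d-%m-%Y", "%d-%m-%y"):
        try:
            return dt.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"unparseable date {text!r}")


def _require_columns(header: list[str], required: list[str], source: str) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{source}: missing required columns {missing}")


def read_tables(
    turtles_path: str | Path,
    bones_path: str | Path | None = None,
) -> tuple[list[TurtleRecord], list[BoneProfile]]:
    """Read turtle records (and optionally bone profiles) from CSV.

    All malformed rows are collected and reported together in a single
    :class:`RowError` naming each file:line.
    """
    errors: list[str] = []
    records: list[TurtleRecord] = []
    with open(turtles_path, newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames or [], _TURTLE_COLS, str(turtles_path))
        for lineno, row in enumerate(reader, start=2):
            try:
                otc = row.get("date_otc", "").strip()
                records.append(TurtleRecord(
                    id=row["id"].strip(),
                    date_tagged=parse_date(row["date_tagged"]),
                    scl_at_tagging=float(row["scl_tagging_cm"]),
                    date_otc=parse_date(otc) if otc else None,
                    date_stranded=parse_date(row["date_stranded"]),
                    scl_at_recovery=float(row["scl_recovery_cm"]),
                    fibropapilloma=row.get("fibropapilloma", "").strip().lower()
                    in ("1", "true", "yes"),
                ))
            except (ValueError, KeyError) as exc:
                errors.append(f"{turtles_path}:{lineno}: {exc}")

    profiles: list[BoneProfile] = []
    if bones_path is not None:
        grouped: dict[str, list[dict]] = {}
        with open(bones_path, newline="") as fh:
            reader = csv.DictReader(fh)
            _require_columns(reader.fieldnames or [], _BONE_COLS, str(bones_path))
            for lineno, row in enumerate(reader, start=2):
                try:
                    parsed = {
                        "lag_index": int(row["lag_index"]),
                        "lag_diameter_mm": float(row["lag_diameter_mm"]),
                        "is_double": row["is_double"].strip().lower() in ("1", "true", "yes"),
                        "section_diameter_mm": float(row["section_diameter_mm"]),
                        "resorption_diameter_mm": float(row["resorption_diameter_mm"] or 0),
                        "otc_diameter_mm": (
                            float(row["otc_diameter_mm"])
                            if row.get("otc_diameter_mm", "").strip() else None
                        ),
                    }
                except ValueError as exc:
                    errors.append(f"{bones_path}:{lineno}: {exc}")
                    continue
                grouped.setdefault(row["turtle_id"].strip(), []).append(parsed)
        for tid, rows in grouped.items():
            rows.sort(key=lambda r: r["lag_index"])
            profiles.append(BoneProfile(
                turtle_id=tid,
                lag_diameters=[r["lag_diameter_mm"] for r in rows],
                double_flags=[r["is_double"] for r in rows],
                section_diameter=rows[0]["section_diameter_mm"],
                resorption_core_diameter=rows[0]["resorption_diameter_mm"],
                otc_diameter=rows[0]["otc_diameter_mm"],
            ))
    if errors:
        raise RowError(f"{len(errors)} malformed row(s):\n" + "\n".join(errors))
    return records, profiles


def write_tables(
    records: list[TurtleRecord],
    profiles: list[BoneProfile],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write ``turtles.csv`` and ``bones.csv``; lossless at full precision."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tpath, bpath = out / "turtles.csv", out / "bones.csv"
    pd.DataFrame([
        {
            "id": r.id,
            "date_tagged": r.date_tagged.isoformat(),
            "scl_tagging_cm": repr(r.scl_at_tagging),
            "date_otc": r.date_otc.isoformat() if r.date_otc else "",
            "date_stranded": r.date_stranded.isoformat(),
            "scl_recovery_cm": repr(r.scl_at_recovery),
            "fibropapilloma": str(r.fibropapilloma).lower(),
        }
        for r in records
    ]).to_csv(tpath, index=False)
    rows = []
    for b in profiles:
        for k, (d, fl) in enumerate(zip(b.lag_diameters, b.double_flags)):
            rows.append({
                "turtle_id": b.turtle_id,
                "lag_index": k,
                "lag_diameter_mm": repr(d),
                "is_double": str(fl).lower(),
                "section_diameter_mm": repr(b.section_diameter),
                "resorption_diameter_mm": repr(b.resorption_core_diameter),
                "otc_diameter_mm": repr(b.otc_diameter) if b.otc_diameter is not None else "",
            })
    pd.DataFrame(rows, columns=_BONE_COLS).to_csv(bpath, index=False)
    return tpath, bpath


def write_truth(truth: SimTruth, out_dir: str | Path) -> Path:
    """Write per-turtle simulator ground truth to ``truth.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "truth.csv"
    rows = []
    for t in truth.turtles:
        for e in t.lag_events:
            rows.append({
                "turtle_id": t.turtle_id,
                "proportionality": t.proportionality,
                "d_inf_mm": t.d_inf,
                "growth_k": t.growth_k,
                "hatch_date": t.hatch_date.isoformat(),
                "date_tagged": t.date_tagged.isoformat(),
                "date_otc": t.date_otc.isoformat() if t.date_otc else "",
                "date_stranded": t.date_stranded.isoformat(),
                "lag_year": e.calendar_year,
                "lag_date": e.date.isoformat(),
                "lag_diameter_mm": e.diameter,
                "lag_scl_cm": e.scl,
                "resorbed": e.resorbed,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def bundled_fixture_path() -> Path:
    """Path to the bundled printed-table turtle records CSV."""
    return Path(importlib.resources.files("skeletochron") / "data" / "turtles.csv")


def load_config(path: str | Path) -> PipelineConfig:
    """Load pipeline parameter overrides from a key-value YAML file.

    Recognised keys: ``l_op_cm``, ``d_op_mm``, ``slope_b``, ``exponent_c``,
    ``edge_growth_threshold_mm``, ``coincidence_tolerance_cm``,
    ``deposition_window_start_month``, ``deposition_window_end_month``,
    ``nominal_deposition_doy``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {
        "l_op_cm", "d_op_mm", "slope_b", "exponent_c",
        "edge_growth_threshold_mm", "coincidence_tolerance_cm",
        "deposition_window_start_month", "deposition_window_end_month",
        "nominal_deposition_doy",
    }
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    defaults = BackCalcParams()
    params = BackCalcParams(
        hatchling_length=float(raw.get("l_op_cm", defaults.hatchling_length)),
        hatchling_diameter=float(raw.get("d_op_mm", defaults.hatchling_diameter)),
        slope=float(raw.get("slope_b", defaults.slope)),
        exponent=float(raw.get("exponent_c", defaults.exponent)),
    )
    dseason = DepositionSeason()
    season = DepositionSeason(
        start_month=int(raw.get("deposition_window_start_month", dseason.start_month)),
        end_month=int(raw.get("deposition_window_end_month", dseason.end_month)),
        nominal_doy=int(raw.get("nominal_deposition_doy", dseason.nominal_doy)),
    )
    base = PipelineConfig()
    return PipelineConfig(
        params=params, season=season,
        edge_growth_threshold_mm=float(
            raw.get("edge_growth_threshold_mm", base.edge_growth_threshold_mm)
        ),
        coincidence_tolerance_cm=float(
            raw.get("coincidence_tolerance_cm", base.coincidence_tolerance_cm)
        ),
    )


def render_table1(result: PipelineResult) -> str:
    """Human-readable validation table mirroring the printed layout."""
    lines = [
        f"{'ID':<7}{'Stranded':<12}{'SCL str.':>9}  {'Tagged':<12}{'SCL tag':>9}"
        f"{'Est. SCL':>9}{'Year':>6}{'Diff':>7}"
    ]
    for _, r in result.table1.iterrows():
        lines.append(
            f"{r['id']:<7}{r['date_stranded'].isoformat():<12}"
            f"{r['scl_at_stranding']:>9.1f}  {r['date_tagged'].isoformat():<12}"
            f"{r['scl_at_tagging']:>9.1f}{r['estimated_scl']:>9.1f}"
            f"{r['lag_year']:>6d}{r['difference']:>7.1f}"
        )
    v = result.validation
    lines.append(f"Mean absolute difference: {v.mean_abs_difference:.1f} cm")
    if v.wilcoxon_N:
        lines.append(
            f"Wilcoxon signed-rank: T = {v.wilcoxon_T:g}, N = {v.wilcoxon_N}, "
            f"exact two-sided p = {v.wilcoxon_p:.3f}"
        )
    for col, (mean, sd, lo, hi) in v.summary.items():
        lines.append(f"{col}: mean {mean:.1f} +/- SD {sd:.1f}, range {lo:.1f}-{hi:.1f} cm")
    return "\n".join(lines)


def render_table2(result: PipelineResult) -> str:
    """Human-readable OTC timing table with the inferred deposition window."""
    lines = [f"{'ID':<7}{'OTC date':<12}{'OTC SCL':>9}{'LAG SCL':>9}{'Year':>6}  relation"]
    for _, r in result.table2.iterrows():
        lines.append(
            f"{r['id']:<7}{r['otc_date'].isoformat():<12}{r['otc_backcalc_scl']:>9.1f}"
            f"{r['lag_backcalc_scl']:>9.1f}{r['lag_year']:>6d}  {r['relation']}"
        )
    if result.otc_mean_abs_difference is not None:
        lines.append(
            f"Mean absolute difference +/- SE: {result.otc_mean_abs_difference:.1f} "
            f"+/- {result.otc_standard_error:.1f} cm"
        )
    w = result.window
    if w is not None:
        lo = f"after {w.lower_bound[1]} {_MONTH[w.lower_bound[0]]}" if w.lower_bound else "undetermined"
        hi = f"by {w.upper_bound[1]} {_MONTH[w.upper_bound[0]]}" if w.upper_bound else "undetermined"
        lines.append(f"Inferred deposition window: {lo}, {hi}")
    return "\n".join(lines)


_MONTH = {
    1: "January", 2: "February", 3: "March", 4: "April", 5: "May", 6: "June",
    7: "July", 8: "August", 9: "September", 10: "October", 11: "November",
    12: "December",
}
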