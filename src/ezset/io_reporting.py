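"""Readers, writers and report rendering.

The on-disk judgment format is a long (tidy) CSV with header
``station_id,panelist_id,mark_type,mark`` — one row per judgment,
``mark_type`` either ``L`` (highest failing mark) or ``H`` (lowest passing
mark), UTF-8, decimal point.  Reports are written twice: CSV rounded to two
decimals for human review, JSON at full precision for downstream use.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, ez_core
from .errors import ValidationError
from .simulation import PrimaryDataset, SizeGroupTable

logger = logging.getLogger(__name__)

JUDGMENT_COLUMNS = ["station_id", "panelist_id", "mark_type", "mark"]
REPORT_COLUMNS = [
    "station_id",
    "n",
    "x_l",
    "x_h",
    "se_l",
    "se_h",
    "z",
    "cut_score",
    "confidence_pct",
    "degenerate",
    "overlap",
]


def _read_long_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype={"station_id": str, "panelist_id": str})
    missing = [c for c in JUDGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    # +2: header line plus 1-based numbering
    lines = df.index + 2
    bad_type = ~df["mark_type"].isin(["L", "H"])
    if bad_type.any():
        first = int(lines[bad_type][0])
        raise ValidationError(
            f"{path}, line {first}: mark_type must be 'L' or 'H', got "
            f"{df.loc[bad_type.idxmax(), 'mark_type']!r}"
        )
    marks = pd.to_numeric(df["mark"], errors="coerce")
    bad_mark = marks.isna() | ~np.isfinite(marks)
    if bad_mark.any():
        first = int(lines[bad_mark][0])
        raise ValidationError(f"{path}, line {first}: non-numeric or non-finite mark")
    df["mark"] = marks.astype(float)
    dup = df.duplicated(subset=["station_id", "panelist_id", "mark_type"], keep=False)
    if dup.any():
        first = int(lines[dup][0])
        raise ValidationError(
            f"{path}, line {first}: duplicate (station, panelist, mark_type) row"
        )
    return df


def read_judgments(path, require_rectangular: bool = True):
    """Read a long-format judgment CSV.

    With ``require_rectangular`` (needed for resampling input) every
    panelist must supply both marks for every station and a
    :class:`PrimaryDataset` is returned.  Otherwise a dict of per-station
    :class:`~ezset.ez_core.PanelJudgments` is returned and stations may
    have different panels.
    """
    df = _read_long_csv(path)
    wide = df.pivot_table(
        index=["station_id", "panelist_id"],
        columns="mark_type",
        values="mark",
        aggfunc="first",
    )
    if wide.isna().any().any() or set(wide.columns) != {"L", "H"}:
        incomplete = wide[wide.isna().any(axis=1)]
        where = (
            ", ".join(f"{s}/{p}" for s, p in incomplete.index[:3])
            if len(incomplete)
            else "some station"
        )
        raise ValidationError(
            f"{path}: every (station, panelist) needs both an L and an H mark; "
            f"incomplete: {where}"
        )
    stations = sorted(df["station_id"].unique())
    logger.info(
        "%s: %d rows, %d stations, %d panelists",
        path,
        len(df),
        len(stations),
        df["panelist_id"].nunique(),
    )
    if not require_rectangular:
        out = {}
        for s in stations:
            sub = wide.loc[s]
            out[s] = ez_core.PanelJudgments(
                station_id=s,
                lowest_pass_marks=tuple(sub["H"]),
                highest_fail_marks=tuple(sub["L"]),
                panelist_ids=tuple(sub.index),
            )
        return out
    panelists = sorted(df["panelist_id"].unique())
    try:
        l = wide["L"].unstack("station_id").loc[panelists, stations].to_numpy()
        h = wide["H"].unstack("station_id").loc[panelists, stations].to_numpy()
    except KeyError as exc:
        raise ValidationError(f"{path}: non-rectangular design: {exc}") from exc
    if np.isnan(l).any() or np.isnan(h).any():
        raise ValidationError(
            f"{path}: non-rectangular design; every panelist must judge every "
            "station (use require_rectangular=False for per-station input)"
        )
    return PrimaryDataset(
        stations=tuple(stations),
        panelist_ids=tuple(panelists),
        l_marks=l,
        h_marks=h,
    )


def write_judgments(dataset: PrimaryDataset, path) -> None:
    """Write a dataset in the long CSV format (full precision)."""
    rows = []
    for j, s in enumerate(dataset.stations):
        for i, p in enumerate(dataset.panelist_ids):
            rows.append((s, p, "L", repr(float(dataset.l_marks[i, j]))))
            rows.append((s, p, "H", repr(float(dataset.h_marks[i, j]))))
    pd.DataFrame(rows, columns=JUDGMENT_COLUMNS).to_csv(path, index=False)


def ez_report(results: list[ez_core.EZResult]) -> pd.DataFrame:
    """Per-station EZ results as a tidy full-precision DataFrame."""
    rows = []
    for r in results:
        rows.append(
            {
                "station_id": r.station_id,
                "n": r.summary.n,
                "x_l": r.summary.x_l,
                "x_h": r.summary.x_h,
                "se_l": r.summary.se_l,
                "se_h": r.summary.se_h,
                "z": r.z,
                "cut_score": r.cut_score,
                "confidence_pct": r.confidence,
                "degenerate": r.degenerate,
                "overlap": r.overlap,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


@dataclass
class ReportBundle:
    """Everything a run produced, plus the metadata to reproduce it.

    ``metadata`` echoes the full configuration (and seed) of the run; a
    bundle whose metadata cannot re-run the computation is considered
    incomplete and refuses to render.
    """

    ez_report: pd.DataFrame
    size_table: pd.DataFrame | None = None
    series: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.ez_report is None or len(self.ez_report) == 0:
            raise ValidationError("empty report bundle: nothing to render")
        for key in ("config", "seed"):
            if key not in self.metadata:
                raise ValidationError(
                    f"bundle metadata incomplete: missing {key!r}; a report "
                    "must carry enough metadata to re-run its computation"
                )


def run_metadata(config, seed: int) -> dict:
    """Standard metadata block: config echo, its hash, seed, version."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str)
    return {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "ezset_version": __version__,
    }


def _round_df(df: pd.DataFrame, ndigits: int) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].round(ndigits)
    return out


def render_reports(bundle: ReportBundle, out_dir, ndigits: int = 2) -> list[Path]:
    """Write the bundle's tables to ``out_dir``.

    CSV cells are rounded to ``ndigits`` decimals (reporting convention);
    a JSON file with full-precision values and the run metadata is written
    alongside.  Returns the written paths.
    """
    bundle.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(df: pd.DataFrame, name: str, index: bool = False) -> None:
        p = out_dir / f"{name}.csv"
        _round_df(df, ndigits).to_csv(p, index=index)
        written.append(p)

    _write(bundle.ez_report, "ez_report")
    if bundle.size_table is not None:
        _write(bundle.size_table, "size_by_station", index=True)
    if bundle.series is not None:
        _write(bundle.series, "size_group_series")
    payload = {
        "metadata": bundle.metadata,
        "ez_report": bundle.ez_report.to_dict(orient="records"),
    }
    if bundle.series is not None:
        payload["series"] = bundle.series.to_dict(orient="records")
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(payload, indent=2, default=str))
    written.append(json_path)
    logger.info("wrote %d report files to %s", len(written), out_dir)
    return written


def write_simulation_outputs(
    table: SizeGroupTable, out_dir, ndigits: int = 2
) -> list[Path]:
    """Write a simulation run: per-panel rows and per-group aggregates."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    agg_path = out_dir / "size_group_table.csv"
    panels_path = out_dir / "panels.csv"
    _round_df(table.aggregates(), ndigits).to_csv(agg_path, index=False)
    table.panels.to_csv(panels_path, index=False)
    return [agg_path, panels_path]


def plot_z_by_size(table: SizeGroupTable, path) -> Path:
    """Mean z with 95% CI versus panel size, one panel line per station."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = table.aggregates()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for station, grp in agg.groupby("station_id"):
        ax.errorbar(
            grp["panel_size"],
            grp["mean_z"],
            yerr=[grp["mean_z"] - grp["z_ci_lo"], grp["z_ci_hi"] - grp["mean_z"]],
            label=str(station),
            capsize=2,
            alpha=0.7,
        )
    for crit, style in ((1.64, "--"), (1.96, ":")):
        ax.axhline(crit, color="grey", linestyle=style, linewidth=1)
    ax.set_xlabel("panel size")
    ax.set_ylabel("mean z (95% CI)")
    ax.legend(fontsize=7, ncol=3)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
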