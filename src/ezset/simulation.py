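"""Panel-size resampling experiment.

The design question: how many panelists does the equal-Z method need before
the cut score is stable and its built-in confidence (the z-score) is high
enough?  The experiment answers it empirically by drawing many simulated
panels of varying size from a primary judgment dataset — sampling
*panelists* with replacement, so a resampled judge carries their marks for
every station — computing the full EZ output of every panel for every
station, and aggregating z-scores and cut scores by (station, panel size).

Two allocation modes are provided:

* ``total`` (default): a fixed total number of draws, each with its panel
  size drawn uniformly from the size range.  With 1,000 draws over sizes
  5-25 this yields a few dozen panels per (station, size) cell, with
  multinomial dispersion in the per-size counts.
* ``per_size``: the same number of draws at every size — a balanced design
  for calibration and convergence studies.

All randomness flows from a single seeded generator consumed in a fixed,
documented order (sizes first in ``total`` mode, then panelist indices
draw by draw), so any stored panel is reproducible from its recorded
panelist indices and the run as a whole is reproducible from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ez_core
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: z-multiplier for the normal 95% confidence interval on group means.
CI_Z = 1.96

PANEL_COLUMNS = [
    "draw",
    "station_id",
    "panel_size",
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
    "panelist_indices",
]


@dataclass(frozen=True)
class PrimaryDataset:
    """Complete rectangular judgment data: every panelist judged every station.

    ``l_marks`` and ``h_marks`` are arrays of shape
    ``(n_panelists, n_stations)`` holding the highest-fail and lowest-pass
    marks, column order matching ``stations``.
    """

    stations: tuple[str, ...]
    panelist_ids: tuple[str, ...]
    l_marks: np.ndarray
    h_marks: np.ndarray

    def __post_init__(self) -> None:
        l = np.asarray(self.l_marks, dtype=float)
        h = np.asarray(self.h_marks, dtype=float)
        object.__setattr__(self, "l_marks", l)
        object.__setattr__(self, "h_marks", h)
        object.__setattr__(self, "stations", tuple(str(s) for s in self.stations))
        object.__setattr__(
            self, "panelist_ids", tuple(str(p) for p in self.panelist_ids)
        )
        expected = (len(self.panelist_ids), len(self.stations))
        if l.shape != expected or h.shape != expected:
            raise ValidationError(
                f"mark arrays must have shape (n_panelists, n_stations) = "
                f"{expected}; got {l.shape} and {h.shape}"
            )
        if len(self.panelist_ids) < 2:
            raise ValidationError("a primary dataset needs at least 2 panelists")
        if not (np.isfinite(l).all() and np.isfinite(h).all()):
            raise ValidationError("all marks must be finite")

    @property
    def n_panelists(self) -> int:
        return len(self.panelist_ids)

    def station_judgments(self, station_id: str) -> ez_core.PanelJudgments:
        """One station's judgments across the full panel."""
        j = self.stations.index(station_id)
        return ez_core.PanelJudgments(
            station_id=station_id,
            lowest_pass_marks=tuple(self.h_marks[:, j]),
            highest_fail_marks=tuple(self.l_marks[:, j]),
            panelist_ids=self.panelist_ids,
        )


@dataclass(frozen=True)
class ResampleConfig:
    """Design of the resampling experiment."""

    n_samples: int = 1000
    min_size: int = 5
    max_size: int = 25
    mode: str = "total"
    seed: int = 0
    with_replacement: bool = True
    include_flagged: bool = True

    def __post_init__(self) -> None:
        if not 2 <= self.min_size <= self.max_size:
            raise ValidationError("sizes must satisfy 2 <= min_size <= max_size")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.mode not in ("total", "per_size"):
            raise ValidationError("mode must be 'total' or 'per_size'")


class SizeGroupTable:
    """Per-panel EZ results of a resampling run, grouped by (station, size).

    Wraps a long DataFrame with one row per (draw, station) — columns
    ``PANEL_COLUMNS`` — and caches the per-(station, size) aggregation.
    """

    def __init__(self, panels: pd.DataFrame):
        missing = [c for c in PANEL_COLUMNS if c not in panels.columns]
        # panelist_indices is only known for true resampling runs
        if missing and missing != ["panelist_indices"]:
            raise ValidationError(f"panel table missing columns: {missing}")
        self.panels = panels.reset_index(drop=True)
        self._aggregates: pd.DataFrame | None = None

    @classmethod
    def from_records(cls, records: list[dict]) -> "SizeGroupTable":
        return cls(pd.DataFrame.from_records(records))

    @property
    def stations(self) -> list[str]:
        return sorted(self.panels["station_id"].unique())

    @property
    def sizes(self) -> list[int]:
        return sorted(self.panels["panel_size"].unique())

    def group(self, station_id: str, panel_size: int) -> pd.DataFrame:
        p = self.panels
        return p[(p["station_id"] == station_id) & (p["panel_size"] == panel_size)]

    def counts(self) -> pd.DataFrame:
        """Number of resampled panels per (station, size)."""
        return (
            self.panels.groupby(["station_id", "panel_size"])
            .size()
            .rename("n_panels")
            .reset_index()
        )

    def aggregates(self) -> pd.DataFrame:
        if self._aggregates is None:
            self._aggregates = aggregate_by_size(self)
        return self._aggregates


def draw_panel(
    dataset: PrimaryDataset,
    size: int,
    rng: np.random.Generator,
    with_replacement: bool = True,
) -> dict[str, ez_core.PanelJudgments]:
    """Draw one simulated panel and return its judgments for every station.

    The same sampled panelists apply to all stations — a panel assesses the
    whole examination.  Sampling is uniform over panelists, with replacement
    by default (a panelist may be drawn more than once).
    """
    idx = _draw_indices(dataset, size, rng, with_replacement)
    return {
        s: _panel_from_indices(dataset, j, idx)
        for j, s in enumerate(dataset.stations)
    }


def _draw_indices(
    dataset: PrimaryDataset,
    size: int,
    rng: np.random.Generator,
    with_replacement: bool,
) -> np.ndarray:
    if size < 2:
        raise ValidationError("panel size must be >= 2")
    if with_replacement:
        return rng.integers(0, dataset.n_panelists, size)
    if size > dataset.n_panelists:
        raise ValidationError(
            f"cannot draw {size} distinct panelists from {dataset.n_panelists} "
            "without replacement"
        )
    return rng.choice(dataset.n_panelists, size=size, replace=False)


def _panel_from_indices(
    dataset: PrimaryDataset, station_col: int, idx: np.ndarray
) -> ez_core.PanelJudgments:
    return ez_core.PanelJudgments(
        station_id=dataset.stations[station_col],
        lowest_pass_marks=tuple(dataset.h_marks[idx, station_col]),
        highest_fail_marks=tuple(dataset.l_marks[idx, station_col]),
        panelist_ids=tuple(dataset.panelist_ids[i] for i in idx),
        with_replacement=True,
    )


def run_simulation(
    dataset: PrimaryDataset, config: ResampleConfig
) -> SizeGroupTable:
    """Run the full resampling experiment.

    Every drawn panel is pushed through the EZ computation for every
    station.  Degenerate and overlapping panels are retained with their
    flags (their z and cut values are well-defined under the ez_core
    conventions) unless ``config.include_flagged`` is false, in which case
    they are dropped from the table with a logged count — never silently.
    """
    rng = np.random.default_rng(config.seed)
    if config.mode == "total":
        sizes = rng.integers(config.min_size, config.max_size + 1, config.n_samples)
    else:
        sizes = np.repeat(
            np.arange(config.min_size, config.max_size + 1), config.n_samples
        )
    # Indices are drawn one panel at a time, in draw order — the documented
    # RNG contract — then the EZ arithmetic is batched by panel size.
    indices = [
        _draw_indices(dataset, int(size), rng, config.with_replacement)
        for size in sizes
    ]
    k = len(dataset.stations)
    frames = []
    for size in np.unique(sizes):
        draw_nos = np.flatnonzero(sizes == size)
        idx = np.stack([indices[d] for d in draw_nos])  # (m, size)
        m = len(draw_nos)
        # (m, size, k) -> (size, m*k): columns are (draw, station) pairs
        l = np.moveaxis(dataset.l_marks[idx, :], 1, 0).reshape(int(size), m * k)
        h = np.moveaxis(dataset.h_marks[idx, :], 1, 0).reshape(int(size), m * k)
        out = ez_core.batch_ez(l, h)
        frame = pd.DataFrame(out)
        frame.insert(0, "draw", np.repeat(draw_nos, k))
        frame.insert(1, "station_id", np.tile(dataset.stations, m))
        frame.insert(2, "panel_size", int(size))
        frame["panelist_indices"] = np.repeat(
            [",".join(map(str, indices[d])) for d in draw_nos], k
        )
        frames.append(frame)
    panels = (
        pd.concat(frames, ignore_index=True)[PANEL_COLUMNS]
        .sort_values(["draw", "station_id"], kind="stable")
        .reset_index(drop=True)
    )
    n_degen = int(panels["degenerate"].sum())
    n_overlap = int(panels["overlap"].sum())
    logger.info(
        "simulation: %d draws x %d stations; %d degenerate, %d overlapping "
        "station-panels",
        len(sizes),
        len(dataset.stations),
        n_degen,
        n_overlap,
    )
    if not config.include_flagged:
        keep = ~(panels["degenerate"] | panels["overlap"])
        logger.info("excluding %d flagged station-panels", int((~keep).sum()))
        panels = panels[keep]
    return SizeGroupTable(panels)


def _group_ci(values: np.ndarray) -> tuple[float, float, float]:
    mean = float(np.mean(values))
    if len(values) < 2:
        return mean, mean, mean
    sem = float(np.std(values, ddof=1) / np.sqrt(len(values)))
    return mean, mean - CI_Z * sem, mean + CI_Z * sem


def aggregate_by_size(table: SizeGroupTable) -> pd.DataFrame:
    """Mean and 95% CI of cut score and z per (station, panel size).

    The CI is the normal-approximation band mean +/- 1.96 * SEM over the
    resampled panels of the group.  Ordered by station then size; a group
    that received no draws is simply absent (never fabricated).
    """
    rows = []
    for (station, size), grp in table.panels.groupby(
        ["station_id", "panel_size"], sort=True
    ):
        mean_cut, cut_lo, cut_hi = _group_ci(grp["cut_score"].to_numpy())
        finite_z = grp["z"].to_numpy()
        finite_z = finite_z[np.isfinite(finite_z)]
        if len(finite_z) == 0:
            mean_z = z_lo = z_hi = float("inf")
        else:
            mean_z, z_lo, z_hi = _group_ci(finite_z)
        rows.append(
            {
                "station_id": station,
                "panel_size": int(size),
                "n_panels": len(grp),
                "mean_cut": mean_cut,
                "cut_ci_lo": cut_lo,
                "cut_ci_hi": cut_hi,
                "mean_z": mean_z,
                "z_ci_lo": z_lo,
                "z_ci_hi": z_hi,
            }
        )
    return pd.DataFrame(rows).sort_values(["station_id", "panel_size"]).reset_index(
        drop=True
    )


def min_panel_for_confidence(
    table: SizeGroupTable, critical_z: float
) -> dict[str, int | None]:
    """Smallest panel size with a sustained mean-z crossing of ``critical_z``.

    For each station (and, under key ``"overall"``, for the unweighted
    across-station average of the mean-z curve) returns the first size from
    which the mean z stays at or above the critical value through the
    largest simulated size; ``None`` when no size sustains it.
    """
    agg = table.aggregates()
    result: dict[str, int | None] = {}
    curves = {
        station: grp.set_index("panel_size")["mean_z"]
        for station, grp in agg.groupby("station_id")
    }
    overall = (
        agg.pivot(index="panel_size", columns="station_id", values="mean_z")
        .mean(axis=1)
    )
    for name, curve in [*curves.items(), ("overall", overall)]:
        curve = curve.sort_index()
        ok = curve.to_numpy() >= critical_z
        crossing = None
        for size, passed in zip(curve.index, ok):
            if passed and crossing is None:
                crossing = int(size)
            elif not passed:
                crossing = None
        result[str(name)] = crossing
    return result
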