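"""The Equal-Z (EZ) standard-setting method.

A panel of experts supplies, for each examination station, two marks:

* ``L`` — the highest mark that *certainly* indicates an incompetent
  examinee (the highest failing mark), and
* ``H`` — the lowest mark that *certainly* indicates a competent examinee
  (the lowest passing mark).

With panel means :math:`X_L, X_H` and standard errors of those means
:math:`SE_L, SE_H`, the equal Z is the z-score at which the two confidence
intervals around :math:`X_L` and :math:`X_H` meet:

.. math::

    Z \\cdot SE_L + Z \\cdot SE_H = X_H - X_L
    \\quad\\Longrightarrow\\quad
    Z = \\frac{X_H - X_L}{SE_L + SE_H}

The cut score is placed at :math:`X_L + Z\\,SE_L`, which equals
:math:`X_H - Z\\,SE_H`.  The one-sided standard-normal probability
:math:`\\Phi(Z)` expresses the confidence that the cut score is neither a
passing nor a failing mark; a larger borderline range and closer panel
agreement both raise it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import DegeneratePanelError, ValidationError

logger = logging.getLogger(__name__)

#: Conventional critical z values: 1.64 ~ one-sided 90% band edge, 1.96 ~ 95%.
DEFAULT_CRITICAL_ZS = (1.64, 1.96)

#: Relative tolerance below which a panel's pooled dispersion counts as zero.
#: Marks that are identical up to float rounding can leave an O(1e-14)
#: residual standard deviation; such panels are unanimous, not informative.
_DEGENERACY_RTOL = 1e-12


def _is_degenerate(denom, x_l, x_h):
    scale = np.maximum(1.0, np.maximum(np.abs(x_l), np.abs(x_h)))
    return denom <= _DEGENERACY_RTOL * scale


@dataclass(frozen=True)
class PanelJudgments:
    """One station's borderline judgments across a panel.

    Parameters
    ----------
    station_id
        Station label.
    lowest_pass_marks
        One ``H`` mark per panelist, in station score units.
    highest_fail_marks
        One ``L`` mark per panelist, same units and panelist order.
    panelist_ids
        Optional panelist labels.  Duplicates are rejected unless
        ``with_replacement`` is set (a resampled panel may legitimately
        contain the same panelist twice).
    with_replacement
        Marks this object as a with-replacement resample draw.
    """

    station_id: str
    lowest_pass_marks: tuple[float, ...]
    highest_fail_marks: tuple[float, ...]
    panelist_ids: tuple[str, ...] | None = None
    with_replacement: bool = False

    def __post_init__(self) -> None:
        h = tuple(float(v) for v in self.lowest_pass_marks)
        l = tuple(float(v) for v in self.highest_fail_marks)
        object.__setattr__(self, "lowest_pass_marks", h)
        object.__setattr__(self, "highest_fail_marks", l)
        if len(h) != len(l):
            raise ValidationError(
                f"station {self.station_id!r}: {len(l)} highest-fail marks but "
                f"{len(h)} lowest-pass marks; every panelist must supply both"
            )
        if len(h) < 2:
            raise ValidationError(
                f"station {self.station_id!r}: needs at least 2 panelists; "
                "standard error undefined for a single judge"
            )
        for kind, marks in (("L", l), ("H", h)):
            for i, v in enumerate(marks):
                if not math.isfinite(v):
                    who = (
                        self.panelist_ids[i]
                        if self.panelist_ids is not None
                        else f"#{i}"
                    )
                    raise ValidationError(
                        f"station {self.station_id!r}, panelist {who}: "
                        f"non-finite {kind} mark {v!r}"
                    )
        if self.panelist_ids is not None:
            ids = tuple(str(p) for p in self.panelist_ids)
            object.__setattr__(self, "panelist_ids", ids)
            if len(ids) != len(h):
                raise ValidationError(
                    f"station {self.station_id!r}: {len(ids)} panelist ids "
                    f"for {len(h)} judgment pairs"
                )
            if not self.with_replacement and len(set(ids)) != len(ids):
                raise ValidationError(
                    f"station {self.station_id!r}: duplicate panelist ids in a "
                    "panel not flagged as a with-replacement resample"
                )
        # H > L is expected but never enforced; the method tolerates it.
        n_inverted = sum(hv <= lv for hv, lv in zip(h, l))
        if n_inverted:
            logger.warning(
                "station %s: %d panelist(s) gave a lowest-pass mark <= their "
                "highest-fail mark",
                self.station_id,
                n_inverted,
            )

    @property
    def n(self) -> int:
        return len(self.lowest_pass_marks)


@dataclass(frozen=True)
class JudgmentSummary:
    """Panel means and standard errors of the borderline marks."""

    x_l: float
    x_h: float
    se_l: float
    se_h: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("panel summary requires n >= 2")
        if self.se_l < 0 or self.se_h < 0:
            raise ValidationError("standard errors must be non-negative")


@dataclass(frozen=True)
class EZResult:
    """Full EZ output for one station.

    ``degenerate`` marks a panel with zero dispersion in both mark sets
    (``se_l + se_h = 0``); its cut score is the midpoint of the borderline
    range and ``z`` is infinite.  ``overlap`` marks a panel whose mean
    lowest-pass mark does not exceed its mean highest-fail mark
    (``x_h <= x_l``, hence ``z <= 0``); the formula value is still
    returned so that resampling studies can retain such draws.
    """

    summary: JudgmentSummary
    z: float
    cut_score: float
    confidence: float
    degenerate: bool = False
    overlap: bool = False
    station_id: str | None = None


def summarize_judgments(judgments: PanelJudgments) -> JudgmentSummary:
    """Means and standard errors of the panel's L and H marks.

    The standard error is the sample standard deviation (n-1 denominator)
    divided by sqrt(n).
    """
    l = np.asarray(judgments.highest_fail_marks, dtype=float)
    h = np.asarray(judgments.lowest_pass_marks, dtype=float)
    n = judgments.n
    root_n = math.sqrt(n)
    return JudgmentSummary(
        x_l=float(l.mean()),
        x_h=float(h.mean()),
        se_l=float(l.std(ddof=1) / root_n),
        se_h=float(h.std(ddof=1) / root_n),
        n=n,
    )


def solve_z(summary: JudgmentSummary) -> float:
    """The equal Z: ``(x_h - x_l) / (se_l + se_h)``.

    May be zero or negative when the mean lowest-pass mark does not exceed
    the mean highest-fail mark; callers flag that as overlap rather than
    treating it as an error.
    """
    denom = summary.se_l + summary.se_h
    if _is_degenerate(denom, summary.x_l, summary.x_h):
        raise DegeneratePanelError(
            "both standard errors are zero: the panel is unanimous and the "
            "equal Z is undefined"
        )
    return (summary.x_h - summary.x_l) / denom


def confidence_from_z(z: float, round_z: bool = False) -> float:
    """One-sided confidence, percent: ``100 * Phi(z)``.

    With ``round_z`` the z-score is rounded to two decimals before
    evaluating the standard normal CDF — the reporting convention under
    which z = 1.53 yields 93.70%.
    """
    if not math.isfinite(z):
        if math.isinf(z):
            return 100.0 if z > 0 else 0.0
        raise ValidationError(f"non-finite z-score {z!r}")
    if round_z:
        z = round(z, 2)
    return float(100.0 * norm.cdf(z))


def ez_from_summary(
    summary: JudgmentSummary, station_id: str | None = None
) -> EZResult:
    """EZ result from precomputed panel means and standard errors.

    Handles the two non-regular cases explicitly:

    * degenerate (``se_l + se_h = 0``): with a positive borderline gap the
      cut score is the limiting midpoint ``(x_l + x_h) / 2`` with 100%
      confidence; with a zero gap there is no interval to place a cut in
      and an error is raised; with a negative gap the midpoint is returned
      flagged as both degenerate and overlapping, with 0% confidence.
    * overlap (``x_h <= x_l``): the formula value is returned with
      ``overlap=True`` and a logged warning.
    """
    gap = summary.x_h - summary.x_l
    if _is_degenerate(summary.se_l + summary.se_h, summary.x_l, summary.x_h):
        if gap == 0.0:
            raise DegeneratePanelError(
                "panel unanimous and contradictory-free interval empty: "
                "x_h equals x_l with zero dispersion"
            )
        z = math.inf if gap > 0 else -math.inf
        return EZResult(
            summary=summary,
            z=z,
            cut_score=(summary.x_l + summary.x_h) / 2.0,
            confidence=confidence_from_z(z),
            degenerate=True,
            overlap=gap < 0,
            station_id=station_id,
        )
    z = solve_z(summary)
    overlap = z <= 0.0
    if overlap:
        logger.warning(
            "station %s: mean lowest-pass mark (%.4g) does not exceed mean "
            "highest-fail mark (%.4g); z = %.4g",
            station_id,
            summary.x_h,
            summary.x_l,
            z,
        )
    return EZResult(
        summary=summary,
        z=z,
        cut_score=summary.x_l + z * summary.se_l,
        confidence=confidence_from_z(z),
        overlap=overlap,
        station_id=station_id,
    )


def compute_ez(judgments: PanelJudgments) -> EZResult:
    """Full pipeline: summarize the panel, solve for Z, place the cut score.

    The cut score is computed from the full-precision z; rounding is a
    reporting concern only.
    """
    summary = summarize_judgments(judgments)
    return ez_from_summary(summary, station_id=judgments.station_id)


@dataclass(frozen=True)
class ThresholdFlag:
    """Whether a result's z reaches one critical z, with the CDF alongside.

    Both of the common reporting conventions stay visible: the inclusive
    comparison ``z >= critical_z`` and the one-sided confidence
    ``100 * Phi(z)``.
    """

    critical_z: float
    passed: bool
    confidence_pct: float


def threshold_check(
    result: EZResult,
    critical_zs: tuple[float, ...] = DEFAULT_CRITICAL_ZS,
) -> list[ThresholdFlag]:
    """Flag, for each critical z, whether the result's z reaches it."""
    if not critical_zs:
        raise ValidationError("critical_zs must be non-empty")
    conf = confidence_from_z(result.z)
    return [
        ThresholdFlag(critical_z=float(c), passed=result.z >= c, confidence_pct=conf)
        for c in critical_zs
    ]


def batch_ez(
    l_marks: np.ndarray, h_marks: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorised EZ over many panels at once.

    ``l_marks`` and ``h_marks`` have shape ``(panel_size, k)`` — one column
    per panel (or per station of a panel).  Returns arrays of length ``k``
    with the same conventions as :func:`ez_from_summary`: degenerate
    columns get the midpoint cut and infinite z; overlap columns keep the
    formula value.  The scalar and batch paths share these formulas and are
    cross-checked in the test suite.
    """
    l_marks = np.asarray(l_marks, dtype=float)
    h_marks = np.asarray(h_marks, dtype=float)
    if l_marks.shape != h_marks.shape or l_marks.ndim != 2:
        raise ValidationError("l_marks and h_marks must share a 2-D shape")
    n = l_marks.shape[0]
    if n < 2:
        raise ValidationError("panel size must be >= 2")
    root_n = math.sqrt(n)
    x_l = l_marks.mean(axis=0)
    x_h = h_marks.mean(axis=0)
    se_l = l_marks.std(axis=0, ddof=1) / root_n
    se_h = h_marks.std(axis=0, ddof=1) / root_n
    denom = se_l + se_h
    degenerate = _is_degenerate(denom, x_l, x_h)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x_h - x_l) / denom
        z = np.where(degenerate, np.sign(x_h - x_l) * np.inf, z)
        cut = np.where(degenerate, (x_l + x_h) / 2.0, x_l + z * se_l)
        overlap = np.where(degenerate, x_h < x_l, z <= 0.0)
    confidence = 100.0 * norm.cdf(np.clip(z, -np.inf, np.inf))
    confidence = np.where(np.isposinf(z), 100.0, confidence)
    confidence = np.where(np.isneginf(z), 0.0, confidence)
    return {
        "n": np.full(l_marks.shape[1], n, dtype=int),
        "x_l": x_l,
        "x_h": x_h,
        "se_l": se_l,
        "se_h": se_h,
        "z": z,
        "cut_score": cut,
        "confidence_pct": confidence,
        "degenerate": degenerate,
        "overlap": overlap,
    }
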