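"""Synthetic panel-judgment datasets.

The primary data this package's simulation design was built for — a panel
of senior clinicians each giving a highest-fail (L) and lowest-pass (H)
mark for every station of a multi-station OSCE — is typically confidential
and unpublished.  This module generates datasets with the statistical
structure that the equal-Z machinery assumes: for each station, panelists'
L and H marks are independent draws from normal distributions truncated to
the station score scale,

    L ~ TruncNormal(mu_l, sigma_l; [0, score_max])
    H ~ TruncNormal(mu_h, sigma_h; [0, score_max]),

optionally with a within-panelist correlation between L and H, and
optionally redrawn until H > L.

As the panel grows, the standard errors shrink as sigma/sqrt(n), so the EZ
cut score converges to the closed-form limit

    cut -> mu_l + (mu_h - mu_l) * sigma_l / (sigma_l + sigma_h)

(:func:`asymptotic_cut`), and the population mean-z curve grows as
sqrt(n) * (mu_h - mu_l) / (sigma_l + sigma_h).  Those two facts drive both
the preset design and the parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from .errors import ValidationError
from .simulation import PrimaryDataset

#: Mean-z growth coefficient of the bundled preset: the nominal mean-z curve
#: is ``DEFAULT_Z_COEF * sqrt(n)``, which first reaches 1.64 at panel size 10.
DEFAULT_Z_COEF = 0.52

#: Asymptotic cut-score targets of the "table1-like" preset on a 0-20 scale.
_PRESET_CUTS = (
    10.9, 17.9, 17.9, 14.7, 13.2, 15.8, 13.4, 15.0, 15.2, 14.5, 12.8, 12.9,
)


@dataclass(frozen=True)
class StationModel:
    """Generating distribution of one station's borderline judgments."""

    station_id: str
    mu_l: float
    mu_h: float
    sigma_l: float
    sigma_h: float
    score_max: float = 20.0

    def __post_init__(self) -> None:
        if not (self.mu_l < self.mu_h):
            raise ValidationError(
                f"station {self.station_id!r}: mu_l must be < mu_h"
            )
        if self.sigma_l <= 0 or self.sigma_h <= 0:
            raise ValidationError(
                f"station {self.station_id!r}: sigmas must be positive"
            )
        if not (0 <= self.mu_l and self.mu_h <= self.score_max):
            raise ValidationError(
                f"station {self.station_id!r}: means must lie on [0, score_max]"
            )


@dataclass(frozen=True)
class SyntheticConfig:
    """Design of a synthetic primary dataset."""

    station_models: tuple[StationModel, ...]
    n_panelists: int = 31
    seed: int = 0
    enforce_h_gt_l: bool = False
    lh_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_panelists < 2:
            raise ValidationError("n_panelists must be >= 2")
        if not self.station_models:
            raise ValidationError("station_models must be non-empty")
        if not (-1.0 < self.lh_correlation < 1.0):
            raise ValidationError("lh_correlation must be in (-1, 1)")


def asymptotic_cut(model: StationModel) -> float:
    """Large-panel limit of the EZ cut score for a station model.

    Both standard errors shrink as 1/sqrt(n), so their ratio is fixed and
    the cut settles at ``mu_l + (mu_h - mu_l) * sigma_l / (sigma_l + sigma_h)``.
    Truncation at the scale bounds perturbs this slightly; the limit is exact
    for untruncated normals.
    """
    w = model.sigma_l / (model.sigma_l + model.sigma_h)
    return model.mu_l + (model.mu_h - model.mu_l) * w


def table1_like_preset(
    score_max: float = 20.0, z_coef: float = DEFAULT_Z_COEF
) -> tuple[StationModel, ...]:
    """Twelve stations on a 0-20 scale with realistically spread cut scores.

    Each station's asymptotic cut score is pinned to a target between ~11
    and ~18, and the panelist dispersion is set so that the nominal mean-z
    curve is ``z_coef * sqrt(n)`` — crossing 1.64 (one-sided 90%) near panel
    size 10 and 1.96 (95%) near 15.  Concretely: the borderline gap
    ``mu_h - mu_l`` is 1.0 point for extreme stations and 1.2 otherwise,
    ``sigma_l + sigma_h = gap / z_coef``, and the share of dispersion put on
    the L side grows with the cut height so that high-cut stations keep the
    H distribution well clear of the scale top (negligible truncation).
    """
    models = []
    lo, hi = min(_PRESET_CUTS), max(_PRESET_CUTS)
    for i, cut in enumerate(_PRESET_CUTS, start=1):
        gap = 1.0 if (cut > 17.0 or cut < 11.5) else 1.2
        sigma_sum = gap / z_coef
        f_l = 0.35 + 0.30 * (cut - lo) / (hi - lo)
        models.append(
            StationModel(
                station_id=f"S{i:02d}",
                mu_l=cut - gap * f_l,
                mu_h=cut + gap * (1.0 - f_l),
                sigma_l=sigma_sum * f_l,
                sigma_h=sigma_sum * (1.0 - f_l),
                score_max=score_max,
            )
        )
    return tuple(models)


def calibrated_station(
    z_coef: float = DEFAULT_Z_COEF,
    mu_l: float = 42.0,
    gap: float = 18.0,
    sigma_share_l: float = 0.5,
    score_max: float = 100.0,
    station_id: str = "CAL",
) -> StationModel:
    """Single station whose nominal mean-z curve is ``z_coef * sqrt(n)``.

    The dispersion is set from the gap: ``sigma_l + sigma_h = gap / z_coef``.
    This is the calibration used for minimum-panel-size benchmarks; note the
    *realized* mean of per-panel z at small n exceeds the nominal curve by
    the factor quantified in :func:`expected_mean_z` (sample SDs in the
    denominator are biased low).
    """
    sigma_sum = gap / z_coef
    return StationModel(
        station_id=station_id,
        mu_l=mu_l,
        mu_h=mu_l + gap,
        sigma_l=sigma_sum * sigma_share_l,
        sigma_h=sigma_sum * (1.0 - sigma_share_l),
        score_max=score_max,
    )


def _truncnorm_draws(
    mu: float, sigma: float, score_max: float, size, rng: np.random.Generator
) -> np.ndarray:
    a = (0.0 - mu) / sigma
    b = (score_max - mu) / sigma
    return truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def _correlated_draws(
    model: StationModel, n: int, rho: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated (L, H) pairs, rejection-sampled onto the score scale."""
    cov = [
        [model.sigma_l**2, rho * model.sigma_l * model.sigma_h],
        [rho * model.sigma_l * model.sigma_h, model.sigma_h**2],
    ]
    out_l = np.empty(n)
    out_h = np.empty(n)
    filled = 0
    for _ in range(1000):
        draw = rng.multivariate_normal([model.mu_l, model.mu_h], cov, size=2 * n)
        ok = ((draw >= 0.0) & (draw <= model.score_max)).all(axis=1)
        draw = draw[ok]
        take = min(n - filled, len(draw))
        out_l[filled : filled + take] = draw[:take, 0]
        out_h[filled : filled + take] = draw[:take, 1]
        filled += take
        if filled == n:
            return out_l, out_h
    raise ValidationError(
        f"station {model.station_id!r}: could not draw {n} in-scale correlated "
        "pairs within the attempt cap; distribution mass is mostly off-scale"
    )


def generate_dataset(config: SyntheticConfig) -> PrimaryDataset:
    """Draw a complete rectangular panelists x stations judgment dataset.

    Deterministic under ``config.seed``.  With ``enforce_h_gt_l`` each
    panelist's (L, H) pair is redrawn until H > L, up to 1,000 attempts per
    station, after which the constraint is deemed infeasible and an error is
    raised.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_panelists
    l_cols = []
    h_cols = []
    for model in config.station_models:
        if config.lh_correlation != 0.0:
            l, h = _correlated_draws(model, n, config.lh_correlation, rng)
        else:
            l = _truncnorm_draws(model.mu_l, model.sigma_l, model.score_max, n, rng)
            h = _truncnorm_draws(model.mu_h, model.sigma_h, model.score_max, n, rng)
        if config.enforce_h_gt_l:
            for attempt in range(1000):
                bad = h <= l
                if not bad.any():
                    break
                k = int(bad.sum())
                if config.lh_correlation != 0.0:
                    l[bad], h[bad] = _correlated_draws(
                        model, k, config.lh_correlation, rng
                    )
                else:
                    l[bad] = _truncnorm_draws(
                        model.mu_l, model.sigma_l, model.score_max, k, rng
                    )
                    h[bad] = _truncnorm_draws(
                        model.mu_h, model.sigma_h, model.score_max, k, rng
                    )
            else:
                raise ValidationError(
                    f"station {model.station_id!r}: H > L constraint "
                    "infeasible within 1,000 redraw attempts"
                )
        l_cols.append(l)
        h_cols.append(h)
    return PrimaryDataset(
        stations=tuple(m.station_id for m in config.station_models),
        panelist_ids=tuple(f"P{i + 1:02d}" for i in range(n)),
        l_marks=np.column_stack(l_cols),
        h_marks=np.column_stack(h_cols),
    )


def expected_mean_z(
    model: StationModel,
    size: int,
    reps: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate of E[z] for iid panels of a given size.

    The nominal curve ``sqrt(n) * (mu_h - mu_l) / (sigma_l + sigma_h)``
    understates the realized mean of per-panel z at small n: sample SDs are
    biased low (chi-distribution mean factor c4(n) < 1) and 1/x is convex,
    so E[1/(S_L + S_H)] > 1/(sigma_l + sigma_h).  This independent estimate
    — plain iid sampling, no panel resampling machinery — serves as the
    oracle for minimum-panel-size predictions.
    """
    if size < 2:
        raise ValidationError("size must be >= 2")
    rng = np.random.default_rng(seed)
    l = _truncnorm_draws(model.mu_l, model.sigma_l, model.score_max, (reps, size), rng)
    h = _truncnorm_draws(model.mu_h, model.sigma_h, model.score_max, (reps, size), rng)
    root_n = np.sqrt(size)
    se = l.std(axis=1, ddof=1) / root_n + h.std(axis=1, ddof=1) / root_n
    return float(np.mean((h.mean(axis=1) - l.mean(axis=1)) / se))
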