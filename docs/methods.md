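# Methods

## The equal-Z model

For one station, each of *n* judges supplies a highest certainly-failing
mark *L* and a lowest certainly-passing mark *H*. The package treats the
panel's marks as two samples, summarizes them by their means X̄_L, X̄_H and
standard errors SE = s/√n (sample SD, n−1 denominator — the unbiased-variance
convention appropriate for small panels), and solves

    Z = (X̄_H − X̄_L) / (SE_L + SE_H),
    cut = X̄_L + Z·SE_L = X̄_H − Z·SE_H.

The two placements are algebraically identical; the implementation computes
the cut from the full-precision Z and the test suite checks both forms to
1e−9. Reported confidence is the one-sided normal probability 100·Φ(Z); a
reporting option rounds Z to two decimals before evaluating Φ (so Z = 1.53
reports 93.70% rather than the full-precision 93.65%), which is the default
in rendered reports but not in internal arithmetic.

Two confidence conventions circulate in the standard-setting literature:
Φ(Z) directly, and fixed critical values (1.64 ↔ "one-sided 90%",
1.96 ↔ "95%") that come from the *two*-sided 90%/95% normal quantiles.
`ezset` does not pick a winner: `confidence_from_z` implements Φ, and
`threshold_check` reports inclusive crossings of arbitrary critical values
(default 1.64 and 1.96) alongside Φ(Z), so both readings stay visible.

### Non-regular panels

- **Degenerate** (SE_L + SE_H = 0, positive gap): the formula's symmetric
  limit is the interval midpoint; returned with `degenerate=True`,
  confidence 100%, Z = +∞. Dispersion within 1e−12 (relative to mark
  magnitude) counts as zero, so marks identical up to float rounding are
  classified as unanimous rather than producing astronomically large Z.
- **Degenerate with zero gap**: no interval exists; raised as an error.
- **Overlap** (X̄_H ≤ X̄_L): Z ≤ 0 and the formula value are returned with
  `overlap=True` and a logged warning rather than raising — small resampled
  panels produce these occasionally and the simulator must not crash.
  Whether an operational standard-setting exercise would accept such a
  panel is a policy question the package leaves to the caller.
- Per-judge inversions (a judge's H ≤ their own L) are logged, never
  rejected: the method uses only the two panel means and SEs.

## The panel-size experiment

`run_simulation` draws simulated panels from a complete rectangular
dataset (every panelist judged every station). The sampling unit is the
**panelist**: one draw selects panelist indices uniformly with replacement,
and the same panelists are applied to all stations, because a panel assesses
the whole examination. Two allocations:

- `total` (default): `n_samples` draws (default 1,000), each with its size
  uniform on {min_size, …, max_size} (default 5–25). Per-(station, size)
  cell counts are then Multinomial — a few dozen panels per cell at the
  defaults, mirroring the unbalanced designs such exercises report.
- `per_size`: `n_samples` draws at every size; the balanced design used for
  convergence and calibration work.

All randomness comes from one `numpy` generator seeded by the config; sizes
are drawn first (total mode), then panel indices draw by draw, so runs are
bit-reproducible and every stored panel lists its panelist indices. The EZ
arithmetic is vectorized by grouping draws of equal size; the batch and
scalar paths share formulas and are cross-checked in the tests.

Aggregation reports, per (station, size), the mean and normal 95% CI
(mean ± 1.96·SEM) of both cut scores and z-scores. Degenerate/overlap
panels are retained with flags by default (`include_flagged=False` drops
them, with a logged count); infinite z values are excluded from z averages
but their midpoint cut scores are kept.

`min_panel_for_confidence` returns, per station and for the unweighted
across-station mean-z curve, the first size from which the mean z stays at
or above the critical value through the largest simulated size (a sustained
crossing — a transient dip resets it), or "not reached".

### Small-sample behaviour of the mean z

Because SEs shrink as 1/√n, the *population* z-curve grows as
√n·(μ_H−μ_L)/(σ_L+σ_H). The mean of per-panel z-scores exceeds that curve
at small n by the factor k(n) = (σ_L+σ_H)·E[1/(S_L+S_H)] > 1 (sample SDs
are biased low — the χ-distribution factor c₄(n) — and 1/x is convex):
k(5) ≈ 1.16, k(10) ≈ 1.06, k(20) ≈ 1.03 for normal marks. Consequences
worth knowing:

- the observed ratio z̄(20)/z̄(5) converges to 2·k(20)/k(5) ≈ 1.77, not the
  idealized 2;
- a generator calibrated so the *nominal* curve is 0.52·√n (first sustaining
  1.64 at n = 10) realizes its crossing one size earlier, around n = 9.

`expected_mean_z` provides an independent iid Monte-Carlo estimate of
E[z̄(n)] so that resampling results can be checked against it; the
simulation tests use it as the oracle for crossing predictions, bracketing
the crossing with the Monte-Carlo tolerance because by construction the
curve passes within noise of the critical value there.

## Cut-score stability ANOVA

Per station, per-panel cut scores grouped by panel size (a categorical
factor) enter a fixed-effects one-way ANOVA: F = MSB/MSW from the standard
unbalanced decomposition, p from the F upper tail. Identical-everything
groups yield F = 0, p = 1 with a degeneracy flag; zero within-group variance
with distinct means yields F = ∞, p = 0. No post-hoc tests and no
multiple-testing correction across stations are applied.

The resampling design is intrinsically **heteroscedastic**: Var(cut) scales
roughly as 1/size across groups, which violates the classical equal-variance
assumption and inflates the type-I error of the omnibus F (about 11%
rejection at nominal 5% under the bundled preset's null). A Welch
(variance-weighted) variant with Satterthwaite degrees of freedom is
provided (`welch=True`; about 7% under the same conditions) but is off by
default, matching the conventional reporting of such analyses. Users making
stability claims from these p-values should prefer the Welch option or
interpret marginal rejections cautiously.

## The synthetic generator

`generate_dataset` emulates a complete standard-setting exercise: for each
station, judges' L and H are independent normals truncated to the station
scale [0, score_max], optionally correlated within judge (Gaussian pairs,
rejection-sampled onto the scale) and optionally redrawn until H > L
(capped at 1,000 attempts). Defaults: 31 panelists, independence, no H > L
enforcement.

The `table1-like` preset builds 12 stations on a 0–20 scale whose
asymptotic cut scores (closed form: μ_L + (μ_H−μ_L)·σ_L/(σ_L+σ_H)) spread
over ≈ 10.9–17.9, the range typical of published station-level cut scores
on that scale. The borderline gap is 1.0–1.2 points; σ_L + σ_H = gap/0.52
so the nominal mean-z curve is 0.52·√n, crossing 1.64 near panel size 10
and 1.96 near 15; and the share of dispersion assigned to the L side grows
with the cut height so every station keeps ≥ 2.5 SDs of headroom to the
scale bounds, making truncation bias negligible (verified < 1% on the
means).

What the generator does *not* model — and hence what passing tests do not
establish about real panels: skewed or heavy-tailed judgment noise,
judge-specific severity (random judge effects shared across stations),
station-by-judge interaction, and any L–H correlation by default. Claims
validated on synthetic data are claims about the EZ machinery under its own
assumptions, not about any particular panel's data.

## Problem sizes and numerical choices

The test and acceptance suites run the full protocol (1,000 draws, sizes
5–25, 12 stations) across 20 generator seeds, 2,000-panel-per-size
calibration runs, and single panels of size 5,000 for parameter recovery —
sizes chosen so every statistical check has comfortable Monte-Carlo margin
while the whole suite stays interactive. Degeneracy tolerance is 1e−12
relative; CI multiplier 1.96 throughout; CSV reports round to 2 decimals
while JSON keeps full precision; ties at a critical z count as crossings
(the "≥" convention).

## Known limitations

- The ANOVA stability check inherits the heteroscedasticity caveat above.
- `mode=total` reproduces the *kind* of unbalanced per-cell counts seen in
  published panel-size studies; exact published count ranges depend on
  allocation details those studies do not state.
- Resampling from a small primary panel (e.g. 31 judges) estimates
  sampling variability around *that panel's* consensus, not around the
  broader population of potential judges — a limitation of the resampling
  design itself, not of this implementation.
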