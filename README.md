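# ezset — equal-Z standard setting and panel-size analysis

Setting a pass/fail cut score for a high-stakes examination (an OSCE, a
licensing paper) usually means convening a panel of expert judges. `ezset`
implements the **equal-Z (EZ) method** of standard setting and the
simulation machinery needed to answer its key operational question: *how
many panelists are enough?*

It is written for psychometricians and assessment units: compute cut scores
from panel judgment files, resample simulated panels of varying size,
and test cut-score stability — from Python or from the `ezset` command line.

## The method

Each judge gives, per station, the highest mark that certainly indicates an
incompetent examinee (*L*) and the lowest mark that certainly indicates a
competent one (*H*). With panel means X̄<sub>L</sub>, X̄<sub>H</sub> and
standard errors SE<sub>L</sub>, SE<sub>H</sub> (sample SD / √n), the equal Z
solves

> Z·SE<sub>L</sub> + Z·SE<sub>H</sub> = X̄<sub>H</sub> − X̄<sub>L</sub>  ⟹  Z = (X̄<sub>H</sub> − X̄<sub>L</sub>) / (SE<sub>L</sub> + SE<sub>H</sub>)

and the cut score is placed at X̄<sub>L</sub> + Z·SE<sub>L</sub> =
X̄<sub>H</sub> − Z·SE<sub>H</sub>: the point equidistant from both means in
their own standard-error units. Φ(Z) (the standard normal CDF) expresses
the one-sided confidence that the cut score is neither a passing nor a
failing mark, so the z-score doubles as a built-in reliability measure:
wider borderline range and tighter panel agreement both raise it.

The panel-size question is studied by resampling: draw many simulated
panels of size 5–25 (panelists sampled with replacement, each carrying
their marks for every station), compute each panel's EZ output for every
station, then (a) track the mean z against panel size — it grows roughly as
√n — and (b) run a per-station one-way ANOVA of cut scores with panel size
as the factor to check that size does not shift the expected cut score.

## Worked example

```python
from ezset import JudgmentSummary, confidence_from_z, ez_from_summary

summary = JudgmentSummary(x_l=42.00, x_h=60.43, se_l=3.74, se_h=8.34, n=7)
result = ez_from_summary(summary)
print(f"{result.z:.2f}  {result.cut_score:.2f}  "
      f"{confidence_from_z(result.z, round_z=True):.2f}%")
```

prints `1.53  47.71  93.70%`: for this seven-judge panel the equal Z is
1.53, the cut score 47.71 sits between the mean highest-fail mark (42.00)
and the mean lowest-pass mark (60.43), and we are 93.70% confident it is
neither a pass nor a fail mark. (The conventional thresholds z ≥ 1.64 /
z ≥ 1.96 are not reached — a larger panel would tighten the SEs.)

The `examples/` scripts show the other capabilities end to end. Running
`examples/minimum_panel_size.py` (synthetic 12-station, 31-panelist data;
1,000 resampled panels) prints

```
critical z = 1.64:
  minimum panel size, across-station mean z : 8
  stations reaching it within size 25       : 12/12
critical z = 1.96:
  minimum panel size, across-station mean z : 12
  stations reaching it within size 25       : 11/12
```

i.e. from 8 panelists up, the across-station mean z stays above 1.64
(one-sided 90% confidence) for that dataset, and from 12 up above 1.96.
`examples/stability_anova.py` prints the size-by-station mean-cut-score
matrix with a final row of ANOVA p-values — the cut-score stability check.

The same flows are available from the shell:

```
ezset synth --preset table1-like --panelists 31 --seed 7 --out marks.csv
ezset compute  --input marks.csv --output report.csv
ezset simulate --input marks.csv --n 1000 --sizes 5:25 --seed 42 --out sim/
ezset anova    --sim sim/ --out table.csv
```

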