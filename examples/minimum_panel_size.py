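"""How many panelists does the equal-Z method need?

Generates a synthetic 12-station, 31-panelist judgment dataset, resamples
1,000 panels with sizes uniform on 5-25 (panelists drawn with replacement,
each carrying all stations' marks), and reports the smallest panel size
from which the across-station mean z stays above the one-sided 90% and 95%
critical values (1.64 and 1.96).
"""

from ezset import (
    ResampleConfig,
    SyntheticConfig,
    generate_dataset,
    min_panel_for_confidence,
    run_simulation,
    table1_like_preset,
)

dataset = generate_dataset(
    SyntheticConfig(station_models=table1_like_preset(), n_panelists=31, seed=7)
)
table = run_simulation(dataset, ResampleConfig(n_samples=1000, seed=42))

for critical in (1.64, 1.96):
    mins = min_panel_for_confidence(table, critical)
    overall = mins.pop("overall")
    reached = {s: m for s, m in mins.items() if m is not None}
    print(f"critical z = {critical}:")
    print(f"  minimum panel size, across-station mean z : {overall}")
    print(f"  stations reaching it within size 25       : {len(reached)}/12")
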