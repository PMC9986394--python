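"""Simulate the screen: 954 inhibitors x 3 cell lines x 3 replicates.

Plants 4 parental-only, 9 resistant-only and 13 pan-line hits over a 0.05
baseline apoptotic score with replicate noise sd 0.02, and writes the
per-well score table, the plate map and the planted-truth table under
results/.
"""

from pathlib import Path

import pandas as pd

from mirscreen.io import write_platemap
from mirscreen.synthetic_data import gen_screen_table, make_planted_scenario

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240901

scenario = make_planted_scenario(seed=SEED, noise_sd=0.02)
table, truth = gen_screen_table(scenario, seed=SEED)

OUT.mkdir(exist_ok=True)
table.to_csv(OUT / "screen_well_scores.csv", index=False)
write_platemap(table, OUT / "screen_platemap.csv")
pd.Series(truth, name="category").rename_axis("inhibitor_id").to_csv(
    OUT / "screen_truth.csv"
)

n_planted = sum(1 for c in truth.values() if c != "none")
print(f"wrote {len(table)} wells ({table.role.eq('sample').sum()} sample wells)")
print(f"planted {n_planted} category hits among {scenario.n_inhibitors} inhibitors")
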