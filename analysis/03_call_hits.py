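"""Hit calling on the simulated screen from 01_simulate_screen.py.

Computes per-inhibitor LFC (resistant-line mean vs parental), robust
Z-scores (0.6745 * (x - median)/MAD, significant at |RZ| >= 2.5) and the
three-way phenotype categories, then checks category calls against the
planted truth. Writes results/hit_results.csv.
"""

from pathlib import Path

import pandas as pd

from mirscreen.screen_stats import call_hits, significance_pvalue

OUT = Path(__file__).resolve().parent.parent / "results"

table = pd.read_csv(OUT / "screen_well_scores.csv")
truth = pd.read_csv(OUT / "screen_truth.csv", index_col="inhibitor_id")["category"]

hits = call_hits(table)
hits.to_csv(OUT / "hit_results.csv", index=False)

pred = hits.set_index("inhibitor_id")["category"]
planted = truth[truth != "none"]
sens = (pred.loc[planted.index] == planted).mean()
fp = ((pred != "none") & (truth.loc[pred.index] == "none")).sum()
print(f"|RZ| >= 2.5 one-sided tail P = {significance_pvalue(2.5):.5f}")
print(f"{int(hits.significant.sum())} inhibitors significant by |RZ| >= 2.5")
print("category counts:", hits.category.value_counts().to_dict())
print(f"planted-category sensitivity = {sens:.3f}, false positives = {fp}")
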