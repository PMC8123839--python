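"""Clarke Error Grid analysis of the days-2-7 analysis set.

Classifies every analysed pair into zones A-E, reports the clinical-accuracy
(zone A) and clinical-acceptability (zones A+B) percentages, and draws the
grid with the pairs scattered over it (figure under scratch/figures/, summary
under results/clarke_summary.json).
"""

import json
from pathlib import Path

import pandas as pd

from cgmagree.clarke import clarke_summary, plot_clarke
from cgmagree.pairing import MatchedPair

ROOT = Path(__file__).resolve().parents[1]
pairs_csv = ROOT / "scratch" / "run" / "pairs.csv"

df = pd.read_csv(pairs_csv, parse_dates=["serum_time", "cgm_time"])
df = df[df.postop_day >= 2]  # day 1 is the sensor warm-up period
pairs = [
    MatchedPair(
        r.patient_id,
        r.serum_time.to_pydatetime(),
        r.cgm_time.to_pydatetime(),
        r.serum_value_mg_dl,
        r.cgm_value_mg_dl,
        r.delta_seconds,
        r.postop_day,
    )
    for r in df.itertuples(index=False)
]

res = clarke_summary(pairs)
(ROOT / "results").mkdir(exist_ok=True)
(ROOT / "results" / "clarke_summary.json").write_text(json.dumps(res.to_dict(), indent=2) + "\n")

figdir = ROOT / "scratch" / "figures"
figdir.mkdir(parents=True, exist_ok=True)
plot_clarke(pairs, figdir / "clarke.png", title="Clarke Error Grid, days 2-7")

print(f"{res.n} pairs classified:")
for z in "ABCDE":
    print(f"  zone {z}: {res.counts[z]:5d} ({res.proportions[z]:.1f}%)")
print(f"clinically accurate (A)    : {res.pct_clinically_accurate:.1f}%")
print(f"clinically acceptable (A+B): {res.pct_clinically_acceptable:.1f}%")
print(f"figure: {figdir / 'clarke.png'}")
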