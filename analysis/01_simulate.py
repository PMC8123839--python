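"""Generate the default synthetic ICU cohort and write its CSVs.

25 patients over 7 post-operative days under tight glycemic control: hourly
serum draws, 5-minute CGM readings with proportional + additive + per-day-bias
sensor error, inflated noise on sensor day 1, and positive CGM interference
for 7.5 h after each dose of an interfering drug (12 of the 25 patients start
dosing on days 4-7).

Writes samples/patients/truth CSVs under scratch/data/ (bulky, regenerable)
and the cohort bookkeeping under results/cohort_counts.json.
"""

import json
from pathlib import Path

from cgmagree.io import write_samples
from cgmagree.model import Source
from cgmagree.simulate import SimulationConfig, simulate_cohort

SEED = 1
ROOT = Path(__file__).resolve().parents[1]

cfg = SimulationConfig(seed=SEED)
cohort, truth = simulate_cohort(cfg)

out = ROOT / "scratch" / "data"
out.mkdir(parents=True, exist_ok=True)
write_samples(cohort, out / "samples.csv", out / "patients.csv")
truth.to_csv(out / "truth.csv", index=False)

counts = {
    "seed": SEED,
    "n_patients": len(cohort.patients),
    "days": cfg.days,
    "serum_samples": sum(1 for s in cohort.samples if s.source == Source.SERUM),
    "cgm_samples": sum(1 for s in cohort.samples if s.source == Source.CGM),
    "patients_on_interfering_drug": sum(1 for p in cohort.patients if p.drug_dose_times),
}
(ROOT / "results").mkdir(exist_ok=True)
(ROOT / "results" / "cohort_counts.json").write_text(json.dumps(counts, indent=2) + "\n")

print(f"simulated {counts['n_patients']} patients x {cfg.days} days (seed {SEED})")
print(f"  serum draws : {counts['serum_samples']} (hourly)")
print(f"  CGM readings: {counts['cgm_samples']} (every {cfg.cgm_interval_min} min)")
print(f"  on drug     : {counts['patients_on_interfering_drug']} patients (first dose days 4-7)")
print(f"  wrote {out}/samples.csv, patients.csv, truth.csv")
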