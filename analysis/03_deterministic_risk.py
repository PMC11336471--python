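"""Deterministic hazard quotients and lifetime cancer risks.

From the section-mean concentrations: HQ per compound × section × gender
(gender-invariant by construction, since IR/BW cancel against the RfC dose
conversion) and LTCR for the carcinogen DEHP.  Also prints the pooled
min/max HQ range per compound, which is how the headline ranges
(e.g. DBP up to 89.9) arise.
"""

import argparse
from pathlib import Path

import pandas as pd

from paerisk.config import TOTAL_LABEL, default_config
from paerisk.exposure import (
    average_daily_dose,
    derive_rfc,
    hazard_quotient,
    risk_frame,
    risk_table,
)
from paerisk.stats import frame_to_samples, summarize

parser = argparse.ArgumentParser()
parser.add_argument("--input", type=Path, default=Path("results/samples_exact.csv"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

cfg = default_config()
samples = frame_to_samples(pd.read_csv(args.input))
summaries = [s for s in summarize(samples) if s.compound != TOTAL_LABEL]

means = {(s.compound, s.section): s.mean for s in summaries}
risk = risk_frame(risk_table(means, cfg.exposure_factors.values(), cfg.toxicity))
risk.to_csv(args.out / "risk.csv", index=False)

hq = risk.query("metric == 'HQ' and gender == 'male'").pivot(
    index="compound", columns="section", values="value"
)
print("HQ at section means (male ≡ female):")
print(hq.round(2).to_string())

print("\nPooled-range HQ endpoints (configured min/max envelope, male factors):")
male = cfg.factors("male")
for comp in ("DMP", "DEP", "DBP", "DEHP"):
    lo = min(t[comp].min for t in cfg.concentration_targets.values())
    hi = max(t[comp].max for t in cfg.concentration_targets.values())
    tox = cfg.toxicity[comp]
    rfc = derive_rfc(tox, male)
    hq_lo = hazard_quotient(average_daily_dose(lo, male, "noncancer"), rfc)
    hq_hi = hazard_quotient(average_daily_dose(hi, male, "noncancer"), rfc)
    print(f"  {comp}: {hq_lo:.2g} – {hq_hi:.3g}")

ltcr = risk.query("metric == 'LTCR'")
print("\nDeterministic LTCR (DEHP):")
for _, row in ltcr.iterrows():
    print(f"  {row['section']:>14} {row['gender']:>6}: {row['value']:.1e}  [{row['classification']}]")
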