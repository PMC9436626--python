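"""Fit per-analyte calibration lines from the simulated standard series,
derive LOD/LOQ from signal-to-noise, and compute validation statistics
(repeatability RSD, spike recovery) on simulated replicates.

Writes results/calibration_curves.csv and results/validation_stats.csv.

Run from the repository root:  python analysis/02_calibration_and_validation.py [seed]
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from qamsherb import reference_data as ref
from qamsherb import study
from qamsherb.calibration import fit_calibration, lod_loq
from qamsherb.qams import validation_stats

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
out = Path("results")
out.mkdir(exist_ok=True)

# calibration: true peak areas from the simulated injection series
series = study.standard_series(SEED)
rows = {}
for analyte in ref.ANALYTES:
    conc, area = [], []
    for chrom, truth in series:
        rec = truth[truth["analyte_id"] == analyte].iloc[0]
        conc.append(rec["conc"])
        area.append(rec["area"])
    curve = fit_calibration(conc, area, analyte_id=analyte)
    height_slope = curve.slope / (study.PEAK_SIGMA_MIN * np.sqrt(2 * np.pi))
    curve.lod, curve.loq = lod_loq(study.NOISE_SD, height_slope)
    rows[analyte] = {
        "slope": curve.slope,
        "intercept": curve.intercept,
        "r2": curve.r2,
        "lod_mg_ml": curve.lod,
        "loq_mg_ml": curve.loq,
        "loq_lod_ratio": curve.loq / curve.lod,
    }
table = pd.DataFrame(rows).T
table.to_csv(out / "calibration_curves.csv")
print(table.round(6).to_string())
print(f"LOQ/LOD = 10/3 for every analyte: {np.allclose(table['loq_lod_ratio'], 10 / 3)}")

# validation: six repeatability replicates with 1.8% area scatter and a
# six-replicate spike-recovery design
rng = np.random.default_rng(SEED)
w_true = 30.6
repeat = w_true * (1 + rng.normal(0, 0.018, 6))
base, spike = 6.1, 6.0
found = base + spike * (1 + rng.normal(0, 0.02, 6))
val = pd.DataFrame(
    [
        {"statistic": "repeatability_rsd_pct", "value": validation_stats(repeat, "repeatability")},
        {
            "statistic": "mean_recovery_pct",
            "value": validation_stats(found, "recovery", base=base, spiked=np.full(6, spike)),
        },
    ]
)
val.to_csv(out / "validation_stats.csv", index=False)
print(val.to_string(index=False))
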