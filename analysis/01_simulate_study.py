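"""Generate the synthetic study: a six-level mixed-standard injection
series and ten batch-extract chromatograms with a two-origin group
structure.

Chromatogram traces (large) go to scratch/simulated/; the ground-truth
composition table goes to results/.

Run from the repository root:  python analysis/01_simulate_study.py [seed]
"""

import sys
from pathlib import Path

from qamsherb import study
from qamsherb.chromatograms import write_chromatogram
from qamsherb.simulate import write_truth

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

out_traces = Path("scratch/simulated")
out_traces.mkdir(parents=True, exist_ok=True)
out_tables = Path("results")
out_tables.mkdir(exist_ok=True)

series = study.standard_series(SEED)
for chrom, truth in series:
    inj = chrom.metadata["injection_id"]
    write_chromatogram(chrom, out_traces / f"standard_{inj}.csv")
    write_truth(truth, out_traces / f"standard_{inj}_truth.csv")
print(f"standards: {len(series)} injections at levels {study.CALIBRATION_LEVELS}")

runs, compositions, labels = study.sample_chromatograms(SEED)
for sample_id, chrom, truth in runs:
    write_chromatogram(chrom, out_traces / f"sample_{sample_id}.csv")
    write_truth(truth, out_traces / f"sample_{sample_id}_truth.csv")
compositions.assign(group=labels).to_csv(out_tables / "true_batch_compositions.csv")

print(f"samples: {len(runs)} batches, groups of {labels.value_counts().sort_index().tolist()}")
print(f"traces -> {out_traces}/, truth table -> {out_tables}/true_batch_compositions.csv")
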