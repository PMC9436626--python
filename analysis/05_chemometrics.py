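"""Classify the ten simulated batches: Ward clustering on the
common-peak area matrix (cut on the 0-25 rescaled dendrogram axis at
15), correlation-matrix PCA, and the cluster-ordered heatmap matrix.

Writes results/cluster_labels.csv, results/pca_table.csv and
results/heatmap_matrix.csv; a dendrogram + heatmap figure goes to
scratch/.

Run from the repository root:  python analysis/05_chemometrics.py [seed]
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.cluster import hierarchy

from qamsherb import study
from qamsherb.chemometrics import heatmap_matrix, hierarchical_cluster, pca_correlation
from qamsherb.fingerprint import match_common_peaks
from qamsherb.pipeline import PipelineConfig, _detect, _pin_internal_standard

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
out = Path("results")
out.mkdir(exist_ok=True)
scratch = Path("scratch")
scratch.mkdir(exist_ok=True)
config = PipelineConfig(seed=SEED)

runs, _, labels = study.sample_chromatograms(SEED)
tables = {}
is_rt = {}
for sample_id, chrom, _truth in runs:
    peaks = _detect(chrom, config)
    tables[sample_id] = peaks
    is_rt[sample_id] = float(_pin_internal_standard(peaks, config.is_rt_window)["rt_min"])
areas = match_common_peaks(tables, is_rt, time_window=config.time_window_min).areas

clus = hierarchical_cluster(areas, cut_distance=15.0, rescale=True)
result = clus.labels.to_frame()
result["true_group"] = labels.reindex(result.index).to_numpy()
result.to_csv(out / "cluster_labels.csv")
print(result.to_string())
agree = result.groupby("true_group")["cluster"].nunique().eq(1).all()
print(f"clusters at rescaled cut 15: {clus.labels.nunique()}; match origin groups: {agree}")

pca = pca_correlation(areas)
pca.report().to_csv(out / "pca_table.csv", index=False)
print(pca.report().head(4).to_string(index=False))
top3 = pca.cumulative_percent[2]
print(f"top-3 components explain {top3:.2f}% of the variance")

hm = heatmap_matrix(areas)
hm.to_csv(out / "heatmap_matrix.csv")

fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
hierarchy.dendrogram(
    clus.linkage_matrix,
    labels=list(areas.index),
    color_threshold=15.0 * clus.heights.max() / 25.0,
    ax=axes[0],
)
axes[0].set_title("Ward clustering (Euclidean, z-scored peaks)")
im = axes[1].imshow(hm.to_numpy(), aspect="auto", cmap="RdBu_r")
axes[1].set_xticks(range(hm.shape[1]), hm.columns, rotation=90)
axes[1].set_yticks(range(hm.shape[0]), hm.index)
axes[1].set_title("cluster-ordered z-scored areas")
fig.colorbar(im, ax=axes[1])
fig.tight_layout()
fig.savefig(scratch / "chemometrics.png", dpi=120)
print(f"figure -> {scratch / 'chemometrics.png'}")
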