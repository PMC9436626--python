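"""End-to-end orchestration: simulate/ingest -> peaks -> calibration ->
QAMS/ESM -> fingerprint -> chemometrics, emitting the full report set.

``run_pipeline`` drives the whole analysis from a :class:`PipelineConfig`
(YAML-loadable) and writes CSV reports: calibration lines with LOD/LOQ,
multipoint relative correction factors, relative retention times,
ESM-vs-QAMS mass fractions with signed SMD, fingerprint similarity,
cluster labels and the PCA eigenvalue table.  ``verify_reference_tables``
recomputes every summary statistic of the shipped published tables and
compares it with the printed value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import reference_data as ref
from . import study
from .calibration import esm_quantify, fit_calibration, lod_loq
from .chemometrics import hierarchical_cluster, heatmap_matrix, pca_correlation
from .chromatograms import detect_peaks, estimate_noise
from .fingerprint import match_common_peaks, similarity_report
from .qams import (
    compute_rcf,
    compute_rrt,
    durability_summary,
    locate_peaks_by_rrt,
    qams_quantify,
    rcf_table,
    round_half_away,
    rsd_percent,
    smd,
)

logger = logging.getLogger("qamsherb")


@dataclass
class PipelineConfig:
    """Analysis settings; defaults encode the published study design."""

    out_dir: str = "reports"
    seed: int = 0
    analytes: list = field(default_factory=lambda: list(ref.ANALYTES))
    internal_standard: str = ref.INTERNAL_STANDARD
    expected_rrt: dict = field(
        default_factory=lambda: {a: study.ALKALOID_RT[a] / study.IS_RT for a in ref.ANALYTES}
    )
    extract_volume_ml: float = ref.EXTRACT_VOLUME_ML
    sample_mass_g: float = ref.SAMPLE_MASS_G
    rrt_tolerance: float = 0.03
    time_window_min: float = 0.1
    calibration_levels: list = field(default_factory=lambda: list(study.CALIBRATION_LEVELS))
    is_rt_window: tuple = (26.0, 28.0)  # internal-standard peak pinned here
    min_snr: float = 3.0
    min_peak_width_min: float = 0.05
    blank_window: tuple = (29.5, 34.5)
    linkage: str = "ward"
    cut_clusters_rescaled: float = 15.0
    purity_correction: bool = False

    def __post_init__(self) -> None:
        if self.internal_standard not in self.analytes:
            raise ValueError("internal standard must be in the analyte list")
        if self.rrt_tolerance <= 0 or self.time_window_min <= 0:
            raise ValueError("tolerances must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _stock_conc(config: PipelineConfig, analyte: str) -> float:
    """Nominal stock concentration, optionally corrected for the
    certified purity of the standard substance."""
    conc = ref.STOCK_CONC[analyte]
    if config.purity_correction:
        conc *= ref.STANDARD_PURITY[analyte]
    return conc


def _pin_internal_standard(peaks: pd.DataFrame, window: tuple[float, float]) -> pd.Series:
    """The internal-standard peak: the largest peak inside its expected
    retention-time window."""
    inside = peaks[(peaks["rt_min"] >= window[0]) & (peaks["rt_min"] <= window[1])]
    if inside.empty:
        raise ValueError(f"no internal-standard peak in rt window {window}")
    return inside.loc[inside["area"].idxmax()]


def _detect(chrom, config: PipelineConfig) -> pd.DataFrame:
    noise = estimate_noise(chrom, config.blank_window)
    if noise == 0:
        noise = 1e-9  # noiseless simulation: keep S/N finite
    return detect_peaks(chrom, noise, min_snr=config.min_snr, min_width=config.min_peak_width_min)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic study and write the report bundle.

    Returns the bundle as a dict of DataFrames keyed by report name;
    every report is also written to ``config.out_dir`` as CSV.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: seed=%d version=%s", config.seed, __version__)
    bundle: dict[str, pd.DataFrame] = {}

    # ---- standards: six-level mixed injection series -------------------
    series = study.standard_series(config.seed)
    logger.info("simulate: %d standard injections", len(series))
    std_peaks = []
    for chrom, truth in series:
        peaks = _detect(chrom, config)
        is_peak = _pin_internal_standard(peaks, config.is_rt_window)
        located = locate_peaks_by_rrt(
            peaks, float(is_peak["rt_min"]), config.expected_rrt, config.rrt_tolerance
        )
        std_peaks.append((float(truth["level"].iloc[0]), located))
    logger.info("peaks: located %d analytes per standard injection", len(config.analytes))

    # ---- calibration: fit each analyte's line, LOD/LOQ ------------------
    cal_rows = {}
    curves = {}
    noise_for_lod = study.NOISE_SD
    for analyte in config.analytes:
        conc = [lvl * _stock_conc(config, analyte) for lvl, loc in std_peaks]
        area = [float(loc[analyte]["area"]) for _, loc in std_peaks]
        curve = fit_calibration(conc, area, analyte_id=analyte)
        height_slope = curve.slope / (study.PEAK_SIGMA_MIN * np.sqrt(2 * np.pi))
        curve.lod, curve.loq = lod_loq(noise_for_lod, height_slope)
        curves[analyte] = curve
        cal_rows[analyte] = {
            "slope": curve.slope,
            "intercept": curve.intercept,
            "r2": curve.r2,
            "lod_mg_ml": curve.lod,
            "loq_mg_ml": curve.loq,
            "range_lo": curve.linear_range[0],
            "range_hi": curve.linear_range[1],
        }
    bundle["calibration"] = pd.DataFrame(cal_rows).T
    logger.info("calibration: %d curves fitted", len(curves))

    # ---- RCF by multipoint correction, RRT per injection -----------------
    targets = [a for a in config.analytes if a != config.internal_standard]
    entries = []
    rrt_rows = []
    for analyte in targets:
        levels = []
        for lvl, located in std_peaks:
            a_s = float(located[config.internal_standard]["area"])
            a_i = float(located[analyte]["area"])
            c_s = lvl * _stock_conc(config, config.internal_standard)
            c_i = lvl * _stock_conc(config, analyte)
            levels.append((a_s, c_s, a_i, c_i))
        entries.append(compute_rcf(levels, analyte_id=analyte,
                                   level_ids=[lvl for lvl, _ in std_peaks]))
    for lvl, located in std_peaks:
        t_rs = float(located[config.internal_standard]["rt_min"])
        rrt_rows.append(
            {a: compute_rrt(float(located[a]["rt_min"]), t_rs) for a in targets} | {"level": lvl}
        )
    bundle["rcf"] = rcf_table(entries, config.internal_standard)
    rrt_df = pd.DataFrame(rrt_rows).set_index("level")
    bundle["rrt"] = pd.concat(
        [
            rrt_df.map(lambda v: round_half_away(v, 4)),
            pd.DataFrame(
                {a: [round_half_away(rrt_df[a].mean(), 4), round_half_away(rsd_percent(rrt_df[a]), 2)] for a in targets},
                index=["Mean", "RSD (%)"],
            ),
        ]
    )
    mean_f = {e.analyte_id: e.mean_f for e in entries}
    logger.info("qams: f estimated for %d analytes", len(entries))

    # ---- durability: f across replicate simulated conditions -------------
    f_by_cond = []
    for c in range(4):
        cond_series = study.standard_series(config.seed + 7919 * (c + 1))
        f_cond = {}
        for analyte in targets:
            lvls = []
            for chrom, truth in cond_series:
                peaks = _detect(chrom, config)
                is_peak = _pin_internal_standard(peaks, config.is_rt_window)
                located = locate_peaks_by_rrt(
                    peaks, float(is_peak["rt_min"]), config.expected_rrt, config.rrt_tolerance
                )
                lvl = float(truth["level"].iloc[0])
                lvls.append(
                    (
                        float(located[config.internal_standard]["area"]),
                        lvl * _stock_conc(config, config.internal_standard),
                        float(located[analyte]["area"]),
                        lvl * _stock_conc(config, analyte),
                    )
                )
            f_cond[analyte] = compute_rcf(lvls, analyte_id=analyte).mean_f
        f_by_cond.append(f_cond)
    bundle["durability"] = durability_summary(pd.DataFrame(f_by_cond))
    logger.info("durability: %d conditions", len(f_by_cond))

    # ---- samples: ESM vs QAMS with SMD ----------------------------------
    runs, compositions, labels = study.sample_chromatograms(config.seed)
    quant_rows = []
    batch_tables = {}
    batch_is_rt = {}
    for sample_id, chrom, _truth in runs:
        peaks = _detect(chrom, config)
        batch_tables[sample_id] = peaks
        is_peak = _pin_internal_standard(peaks, config.is_rt_window)
        batch_is_rt[sample_id] = float(is_peak["rt_min"])
        located = locate_peaks_by_rrt(
            peaks, float(is_peak["rt_min"]), config.expected_rrt, config.rrt_tolerance
        )
        a_s = float(located[config.internal_standard]["area"])
        w_s = esm_quantify(
            curves[config.internal_standard], a_s, config.extract_volume_ml, config.sample_mass_g
        )
        for analyte in config.analytes:
            if located[analyte] is None:
                raise ValueError(f"sample {sample_id}: analyte {analyte} not located")
            a_i = float(located[analyte]["area"])
            w_es = esm_quantify(curves[analyte], a_i, config.extract_volume_ml, config.sample_mass_g)
            row = {"sample": sample_id, "analyte": analyte, "w_es": w_es}
            if analyte != config.internal_standard:
                w_q = qams_quantify(mean_f[analyte], a_i, a_s, w_s)
                row["w_qams"] = w_q
                row["smd_percent"] = smd(w_es, w_q)
            quant_rows.append(row)
    bundle["quantification"] = pd.DataFrame(quant_rows)
    logger.info("quantification: %d samples x %d analytes", len(runs), len(config.analytes))

    # ---- fingerprint ----------------------------------------------------
    fp = match_common_peaks(batch_tables, batch_is_rt, time_window=config.time_window_min)
    bundle["fingerprint"] = fp.areas
    bundle["similarity"] = similarity_report(fp)
    logger.info(
        "fingerprint: %d common peaks, %d non-common", fp.areas.shape[1], len(fp.non_common)
    )

    # ---- chemometrics ----------------------------------------------------
    clus = hierarchical_cluster(
        fp.areas,
        linkage=config.linkage,
        cut_distance=config.cut_clusters_rescaled,
        rescale=True,
    )
    cluster_df = clus.labels.to_frame()
    cluster_df["true_group"] = labels.reindex(cluster_df.index).to_numpy()
    bundle["clusters"] = cluster_df
    pca = pca_correlation(fp.areas)
    bundle["pca"] = pca.report()
    bundle["heatmap"] = heatmap_matrix(fp.areas, linkage=config.linkage)
    logger.info(
        "chemometrics: %d clusters at rescaled cut %.1f; top-3 PCs explain %.1f%%",
        cluster_df["cluster"].nunique(),
        config.cut_clusters_rescaled,
        pca.cumulative_percent[min(2, len(pca.cumulative_percent) - 1)],
    )

    for name, frame in bundle.items():
        frame.to_csv(out / f"{name}_report.csv")
    logger.info("pipeline done: %d reports written to %s", len(bundle), out)
    return bundle


def verify_reference_tables() -> pd.DataFrame:
    """Recompute every printed summary statistic from the shipped
    per-level published values and compare with the printed number.

    One row per check: computed, expected, tolerance (half a unit in
    the printed last digit), pass/fail.  The one published RSD that is
    not reproducible from its own per-level values is reported but
    marked non-binding.
    """
    checks = []

    def add(name, computed, expected, decimals, binding=True):
        tol = 0.5 * 10.0 ** (-decimals)
        checks.append(
            {
                "check": name,
                "computed": round_half_away(computed, decimals + 2),
                "expected": expected,
                "tolerance": tol,
                "binding": binding,
                "passed": abs(computed - expected) <= tol + 1e-12,
            }
        )

    rcf = ref.rcf_levels()
    for analyte in rcf.columns:
        printed = ref.RCF_PRINTED[analyte]
        add(f"rcf_mean_{analyte}", rcf[analyte].mean(), printed["mean"], 4)
        add(
            f"rcf_rsd_{analyte}",
            rsd_percent(rcf[analyte]),
            printed["rsd_percent"],
            2,
            binding=analyte not in ref.RCF_UNVERIFIABLE_RSD,
        )

    rrt = ref.rrt_conditions()
    for analyte in ref.RRT_PRINTED.columns:
        printed = ref.RRT_PRINTED[analyte]
        add(f"rrt_mean_{analyte}", rrt[analyte].mean(), printed["mean"], 4)
        decimals = 1 if printed["rsd_percent"] >= 1 else 2
        add(f"rrt_rsd_{analyte}", rsd_percent(rrt[analyte]), printed["rsd_percent"], decimals)

    dur_ci = ref.durability_column_instrument()
    dur_t = ref.durability_temperature()
    for block, frame in (("column_instrument", dur_ci), ("temperature", dur_t)):
        printed_block = ref.DURABILITY_PRINTED[block]
        for analyte in printed_block.columns:
            printed = printed_block[analyte]
            mean_decimals = 3 if (block, analyte) == ("temperature", "palmatine") else 4
            add(f"durability_{block}_mean_{analyte}", frame[analyte].mean(), printed["mean"], mean_decimals)
            decimals = 1 if printed["rsd_percent"] >= 1 else 2
            add(
                f"durability_{block}_rsd_{analyte}",
                rsd_percent(frame[analyte]),
                printed["rsd_percent"],
                decimals,
            )

    quant = ref.quantification_table()
    max_abs_smd = 0.0
    for analyte in ("magnoflorine", "jatrorrhizine", "palmatine"):
        for sample in quant.index:
            s = smd(quant.loc[sample, f"{analyte}_esm"], quant.loc[sample, f"{analyte}_qams"])
            max_abs_smd = max(max_abs_smd, abs(s))
    checks.append(
        {
            "check": "max_abs_smd_below_2pct",
            "computed": round_half_away(max_abs_smd, 4),
            "expected": 2.0,
            "tolerance": 0.0,
            "binding": True,
            "passed": max_abs_smd < 2.0,
        }
    )

    lod_lo, _ = ref.LOD_RANGE
    loq_lo, _ = ref.LOQ_RANGE
    add("loq_from_lod_low_endpoint", lod_lo * 10.0 / 3.0, loq_lo, 4)

    lam = ref.PCA_PRINTED["eigenvalue"]
    pct = ref.PCA_PRINTED["percent_variance"]
    for k in lam.index:
        add(f"pca_pct_variance_pc{k}", 100.0 * lam[k] / ref.PCA_N_VARIABLES, pct[k], 2)
    add("pca_cumulative_top3", float(pct.sum()), 91.890, 3)

    return pd.DataFrame(checks)
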