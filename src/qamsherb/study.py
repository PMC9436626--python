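"""Synthetic study conditions for the four-alkaloid assay.

Bundles the simulation defaults that emulate the published study
design: a mixed-standard injection-volume series at six levels (1, 2,
4, 6, 8, 10 uL of stock), ten batches of sample extracts (0.5 g powder
per 20.0 mL) with a 4-vs-6 two-group composition structure, and eleven
fingerprint peaks of which four are the known alkaloids (the 4th, 9th,
10th and 11th in elution order: magnoflorine, jatrorrhizine, palmatine
and the internal standard berberine).

The detector response used for the sample system is proportional
(area = slope * conc) with the published calibration slopes: a stable
relative correction factor — the premise of single-marker
quantification — requires near-proportional response in the working
range, and the published per-level f values (RSD < 1%) confirm that
regime.  The published calibration intercepts are kept for the
calibration-refit simulations only, where the full line is the stated
model.  Simulator intensity units are arbitrary; no real detector
scale (mAU) is emulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import reference_data as ref
from .simulate import PeakSpec, RunDesign, generate_calibration_series, generate_chromatogram

#: elution positions (min) on the reference 35-min gradient; the
#: internal standard elutes at 27.0 min and the alkaloid positions
#: reproduce the published mean relative retention times.
IS_RT = 27.0
ALKALOID_RT = {
    "magnoflorine": 0.4784 * IS_RT,
    "jatrorrhizine": 0.8494 * IS_RT,
    "palmatine": 0.9672 * IS_RT,
    "berberine": IS_RT,
}

#: seven unidentified matrix peaks completing the 11-peak fingerprint
UNKNOWN_RT = [3.5, 6.0, 9.0, 15.5, 18.0, 20.5, 24.5]

PEAK_SIGMA_MIN = 0.08
SAMPLING_RATE = 60.0  # points/min
NOISE_SD = 150.0  # detector units
RT_JITTER_SD = 0.02  # minutes

#: injection-volume series (uL) expressed as on-column fraction of stock
CALIBRATION_VOLUMES_UL = [1, 2, 4, 6, 8, 10]
CALIBRATION_LEVELS = [v / 10.0 for v in CALIBRATION_VOLUMES_UL]

#: proportional sample-system response: published calibration slopes
RESPONSE_SLOPE = {
    "magnoflorine": 15369.0,
    "jatrorrhizine": 38648.0,
    "palmatine": 37947.0,
    "berberine": 39003.0,
}

#: group mean mass fractions (mg/g): 6 batches resemble the
#: Xining/Huangnan/Zeku-type composition, 4 the Qilian/Tongren type
#: (lower magnoflorine and berberine, higher palmatine).
GROUP_MASS_FRACTIONS = {
    "groupII": {"magnoflorine": 63.0, "jatrorrhizine": 4.2, "palmatine": 3.2, "berberine": 30.5},
    "groupI": {"magnoflorine": 56.2, "jatrorrhizine": 4.0, "palmatine": 3.7, "berberine": 23.9},
}
#: unknown-peak group mean areas (arbitrary units); geographic origin
#: shifts the whole matrix profile by 15-60% per peak, producing the
#: block structure seen in two-origin batch heatmaps
GROUP_UNKNOWN_AREAS = {
    "groupII": [9000.0, 15000.0, 6000.0, 22000.0, 11000.0, 8000.0, 13000.0],
    "groupI": [10350.0, 12750.0, 7800.0, 19800.0, 13200.0, 6000.0, 20800.0],
}
N_BATCHES = 10
GROUP_SIZES = (6, 4)  # groupII then groupI
WITHIN_GROUP_CV = 0.05


def standard_specs(conc: dict[str, float] | None = None, proportional: bool = True) -> list[PeakSpec]:
    """Mixed-standard peak specs at stock (or given) concentrations."""
    conc = dict(ref.STOCK_CONC) if conc is None else conc
    cal = ref.calibration_table()
    specs = []
    for analyte in ref.ANALYTES:
        slope = RESPONSE_SLOPE[analyte] if proportional else float(cal.loc[analyte, "slope"])
        intercept = 0.0 if proportional else float(cal.loc[analyte, "intercept"])
        specs.append(
            PeakSpec(
                analyte_id=analyte,
                rt_center=ALKALOID_RT[analyte],
                rt_sigma=PEAK_SIGMA_MIN,
                true_conc=conc[analyte],
                response_slope=slope,
                response_intercept=intercept,
            )
        )
    return specs


def default_design(seed: int, noise_sd: float = NOISE_SD, rt_jitter_sd: float = RT_JITTER_SD) -> RunDesign:
    return RunDesign(
        duration=35.0,
        sampling_rate=SAMPLING_RATE,
        noise_sd=noise_sd,
        rt_jitter_sd=rt_jitter_sd,
        seed=seed,
    )


def standard_series(seed: int, noise_sd: float = NOISE_SD):
    """Six-level mixed-standard injection series (the multipoint design)."""
    return generate_calibration_series(
        standard_specs(), CALIBRATION_LEVELS, default_design(seed, noise_sd=noise_sd)
    )


def batch_mass_fractions(seed: int, within_cv: float = WITHIN_GROUP_CV) -> tuple[pd.DataFrame, pd.Series]:
    """Per-batch true compositions: alkaloid mass fractions (mg/g) and
    unknown-peak areas, drawn log-normally around the group means."""
    alk = ref.ANALYTES
    profiles = np.array(
        [
            [GROUP_MASS_FRACTIONS["groupII"][a] for a in alk] + GROUP_UNKNOWN_AREAS["groupII"],
            [GROUP_MASS_FRACTIONS["groupI"][a] for a in alk] + GROUP_UNKNOWN_AREAS["groupI"],
        ]
    )
    from .simulate import generate_batch_set

    table, labels = generate_batch_set(
        profiles,
        n_batches=N_BATCHES,
        effect=1.0,
        within_cv=within_cv,
        seed=seed,
        group_sizes=GROUP_SIZES,
    )
    table.columns = alk + [f"U{j + 1}" for j in range(len(UNKNOWN_RT))]
    table.index = [f"S{i + 1}" for i in range(N_BATCHES)]
    labels.index = table.index
    return table, labels


def sample_specs(composition: pd.Series) -> list[PeakSpec]:
    """Peak specs for one batch extract.

    Alkaloid entries of ``composition`` are mass fractions (mg/g) and
    are converted to solution concentrations through the extraction
    design (x mass / volume); unknown entries are raw peak areas
    modeled with unit response slope.
    """
    specs = []
    for analyte in ref.ANALYTES:
        conc = composition[analyte] * ref.SAMPLE_MASS_G / ref.EXTRACT_VOLUME_ML
        specs.append(
            PeakSpec(
                analyte_id=analyte,
                rt_center=ALKALOID_RT[analyte],
                rt_sigma=PEAK_SIGMA_MIN,
                true_conc=conc,
                response_slope=RESPONSE_SLOPE[analyte],
            )
        )
    for j, rt in enumerate(UNKNOWN_RT):
        specs.append(
            PeakSpec(
                analyte_id=f"U{j + 1}",
                rt_center=rt,
                rt_sigma=PEAK_SIGMA_MIN,
                true_conc=composition[f"U{j + 1}"],
                response_slope=1.0,
            )
        )
    return specs


def sample_chromatograms(seed: int, noise_sd: float = NOISE_SD):
    """Ten simulated batch-extract injections with ground truth.

    Returns (list of (sample_id, Chromatogram, truth), compositions,
    group labels)."""
    comp, labels = batch_mass_fractions(seed)
    runs = []
    for i, sample_id in enumerate(comp.index):
        design = default_design(seed + 1000 + i, noise_sd=noise_sd)
        chrom, truth = generate_chromatogram(
            sample_specs(comp.loc[sample_id]),
            design,
            injection_id=sample_id,
            metadata={"batch": sample_id},
        )
        runs.append((sample_id, chrom, truth))
    return runs, comp, labels


def true_rcf() -> dict[str, float]:
    """True relative correction factors of the proportional sample
    system: slope ratios f_{s/i} = k_s / k_i."""
    k_s = RESPONSE_SLOPE[ref.INTERNAL_STANDARD]
    return {
        a: k_s / RESPONSE_SLOPE[a] for a in ref.ANALYTES if a != ref.INTERNAL_STANDARD
    }
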