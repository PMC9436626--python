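"""Published reference values for a four-alkaloid HPLC assay of
Berberidis Cortex (berberine hydrochloride as internal standard).

These small tables — calibration lines, per-level relative correction
factors, relative retention times across six instrument x column
conditions, robustness blocks, ten-batch ESM/QAMS mass fractions and a
PCA eigenvalue summary — are the published golden values the package's
own computations are validated against: recomputing each table's
Mean/RSD/SMD rows from its per-level entries must reproduce the printed
summary rows.

Analyte keys: ``magnoflorine`` (A), ``jatrorrhizine`` (B, hydrochloride),
``palmatine`` (C, hydrochloride), ``berberine`` (internal standard s,
hydrochloride).  f_s/X denotes f_{berberine/X}.
"""

from __future__ import annotations

import pandas as pd

INTERNAL_STANDARD = "berberine"
ANALYTES = ["magnoflorine", "jatrorrhizine", "palmatine", "berberine"]

#: extraction design: 0.5 g powder into 20.0 mL of 80% methanol
EXTRACT_VOLUME_ML = 20.0
SAMPLE_MASS_G = 0.5

#: mixed-standard stock concentrations, mg/mL
STOCK_CONC = {
    "magnoflorine": 1.55,
    "jatrorrhizine": 0.87,
    "palmatine": 0.76,
    "berberine": 1.00,
}

#: certified purities of the standard substances (fraction)
STANDARD_PURITY = {
    "magnoflorine": 0.980,
    "jatrorrhizine": 0.895,
    "palmatine": 0.857,
    "berberine": 0.859,
}


def calibration_table() -> pd.DataFrame:
    """Calibration lines area = slope*conc + intercept with printed
    R^2, LOD/LOQ (mg/mL) and linear range (mg/mL)."""
    rows = [
        ("magnoflorine", 15369.0, 153559.0, 0.9999, 0.0113, 0.0377, 0.078, 1.550),
        ("jatrorrhizine", 38648.0, 192212.0, 0.9999, 0.0056, 0.0185, 0.044, 0.870),
        ("palmatine", 37947.0, 146764.0, 0.9999, 0.0055, 0.0182, 0.038, 0.760),
        ("berberine", 39003.0, 87162.0, 1.000, 0.0044, 0.0145, 0.050, 1.000),
    ]
    return pd.DataFrame(
        rows,
        columns=["analyte", "slope", "intercept", "r2", "lod", "loq", "range_lo", "range_hi"],
    ).set_index("analyte")


#: LOD/LOQ range endpoints quoted at full precision in the assay summary
LOD_RANGE = (0.00436, 0.0113)
LOQ_RANGE = (0.01454, 0.03768)


def rcf_levels() -> pd.DataFrame:
    """Per-injection-volume relative correction factors f_{s/i}
    (multipoint correction at 1-10 uL), one column per target analyte."""
    data = {
        "volume_uL": [10, 8, 6, 4, 2, 1],
        "magnoflorine": [2.4742, 2.4476, 2.4480, 2.4433, 2.4476, 2.4614],
        "jatrorrhizine": [0.9914, 0.9837, 0.9831, 0.9768, 0.9664, 0.9682],
        "palmatine": [1.0084, 1.0039, 0.9975, 0.9990, 1.0047, 1.0072],
    }
    return pd.DataFrame(data).set_index("volume_uL")


#: printed Mean / RSD(%) summary rows of the multipoint-correction table.
#: The printed palmatine RSD (0.38) is not reproducible from the six
#: per-level values above (sample SD gives 0.44); it is carried here for
#: completeness but excluded from golden-value verification.
RCF_PRINTED = pd.DataFrame(
    {
        "magnoflorine": [2.4537, 0.48],
        "jatrorrhizine": [0.9783, 0.99],
        "palmatine": [1.0035, 0.38],
    },
    index=["mean", "rsd_percent"],
)
RCF_UNVERIFIABLE_RSD = ("palmatine",)


def rrt_conditions() -> pd.DataFrame:
    """Relative retention times across 2 instruments x 3 columns."""
    data = {
        "instrument": ["Waters 2695"] * 3 + ["Waters ACQUITY"] * 3,
        "column": ["CAPCELL PAK C18", "Phenomenex Luna C18", "Venusil XBP C18"] * 2,
        "magnoflorine": [0.4970, 0.4802, 0.4910, 0.4694, 0.4693, 0.4638],
        "jatrorrhizine": [0.8434, 0.8497, 0.8530, 0.8463, 0.8463, 0.8576],
        "palmatine": [0.9621, 0.9655, 0.9664, 0.9675, 0.9675, 0.9741],
    }
    return pd.DataFrame(data)


RRT_PRINTED = pd.DataFrame(
    {
        "magnoflorine": [0.4784, 2.8],
        "jatrorrhizine": [0.8494, 0.61],
        "palmatine": [0.9672, 0.41],
    },
    index=["mean", "rsd_percent"],
)


def durability_column_instrument() -> pd.DataFrame:
    """f_{s/i} across 2 instruments x 3 columns (robustness block)."""
    data = {
        "instrument": ["Waters 2695"] * 3 + ["Waters ACQUITY"] * 3,
        "column": ["CAPCELL PAK C18", "Phenomenex Luna C18", "Venusil XBP C18"] * 2,
        "magnoflorine": [2.4867, 2.5126, 2.4742, 2.4459, 2.4908, 2.4175],
        "jatrorrhizine": [0.9971, 0.9975, 0.9914, 0.9849, 0.9825, 0.9762],
        "palmatine": [1.0096, 1.0179, 1.0077, 0.9938, 1.0169, 0.9867],
    }
    return pd.DataFrame(data)


def durability_temperature() -> pd.DataFrame:
    """f_{s/i} at four column temperatures (robustness block)."""
    data = {
        "temperature_C": [20, 25, 30, 35],
        "magnoflorine": [2.4394, 2.4489, 2.4447, 2.4315],
        "jatrorrhizine": [0.9840, 0.9962, 0.9876, 0.9683],
        "palmatine": [1.0026, 1.0028, 1.0037, 0.9978],
    }
    return pd.DataFrame(data).set_index("temperature_C")


DURABILITY_PRINTED = {
    "column_instrument": pd.DataFrame(
        {
            "magnoflorine": [2.4713, 1.4],
            "jatrorrhizine": [0.9883, 0.86],
            "palmatine": [1.0054, 1.3],
        },
        index=["mean", "rsd_percent"],
    ),
    "temperature": pd.DataFrame(
        {
            "magnoflorine": [2.4411, 0.31],
            "jatrorrhizine": [0.9840, 1.2],
            "palmatine": [1.002, 0.27],
        },
        index=["mean", "rsd_percent"],
    ),
}


def quantification_table() -> pd.DataFrame:
    """Ten-batch ESM vs QAMS mass fractions (mg/g); the internal
    standard (berberine) carries an ESM value only."""
    rows = [
        # sample, magno ESM, magno QAMS, jatro ESM, jatro QAMS, palm ESM, palm QAMS, berb ESM
        ("S1", 72.054, 72.997, 4.4788, 4.4383, 3.0232, 3.0468, 30.684),
        ("S2", 69.421, 70.329, 4.7649, 4.7155, 3.2925, 3.3037, 30.551),
        ("S3", 59.079, 59.852, 3.9308, 3.8901, 3.0882, 3.0987, 29.654),
        ("S4", 57.634, 58.390, 3.8432, 3.8034, 3.029, 3.0393, 28.76),
        ("S5", 55.062, 55.783, 2.5538, 2.5274, 4.0719, 4.0858, 25.312),
        ("S6", 55.69, 56.418, 2.6996, 2.6717, 4.0044, 4.018, 23.541),
        ("S7", 57.297, 58.046, 6.8179, 6.7473, 3.4486, 3.4603, 23.705),
        ("S8", 57.608, 58.362, 6.9338, 6.862, 3.3088, 3.3200, 23.197),
        ("S9", 60.988, 61.786, 4.0477, 4.0058, 3.2511, 3.2621, 31.403),
        ("S10", 62.747, 63.569, 4.0798, 4.0376, 3.3541, 3.3655, 32.401),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "magnoflorine_esm",
            "magnoflorine_qams",
            "jatrorrhizine_esm",
            "jatrorrhizine_qams",
            "palmatine_esm",
            "palmatine_qams",
            "berberine_esm",
        ],
    ).set_index("sample")


#: PCA eigenvalue summary over the 11 common peaks: eigenvalue,
#: % of variance, cumulative %, for the top three components.
PCA_PRINTED = pd.DataFrame(
    {
        "eigenvalue": [4.869, 2.906, 2.333],
        "percent_variance": [44.260, 26.420, 21.210],
        "cumulative_percent": [44.260, 70.679, 91.890],
    },
    index=[1, 2, 3],
)
PCA_N_VARIABLES = 11

#: repeatability means (mg/g) for the four analytes, used as realistic
#: sample composition anchors by the synthetic study
REPEATABILITY_MASS_FRACTIONS = {
    "magnoflorine": 65.7280,
    "jatrorrhizine": 4.1964,
    "palmatine": 2.7840,
    "berberine": 30.6083,
}
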