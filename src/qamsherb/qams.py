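"""Quantitative analysis of multicomponents by single marker (QAMS).

One internal reference standard (here, berberine hydrochloride in a
four-alkaloid assay) is quantified by its own calibration curve; every
other analyte is quantified through a fixed relative correction factor

    f_{s/i} = (A_s * C_i) / (A_i * C_s)

estimated by multipoint correction over an injection-volume series, and
located across instruments and columns by relative retention time

    RRT_i = t_R(i) / t_R(s).

The QAMS mass fraction is W_QAMS,i = f_{s/i} * (A_i / A_s) * W_s, and
agreement with the external standard method is scored by the signed
standard method difference SMD% = 100 * (W_ES - W_QAMS) / W_ES; |SMD|
below 2% is the conventional feasibility criterion.

All relative standard deviations use the sample SD (n-1 denominator).
Report tables round half-away-from-zero to 4 decimals for f and RRT and
2 for RSD%, matching common chromatography-report display precision;
internal arithmetic is full precision.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (5 always rounds up in magnitude),
    on the decimal representation so 1.0035 -> 1.004 despite binary
    floating point."""
    quantum = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(float(x))).quantize(quantum, rounding=decimal.ROUND_HALF_UP))


def rsd_percent(values) -> float:
    """Relative standard deviation, 100 * sample SD / mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


@dataclass
class RCFEntry:
    """Per-analyte relative correction factors over calibration levels."""

    analyte_id: str
    levels: list  # level ids (e.g. injection volume in uL)
    f_values: np.ndarray  # per-level f_{s/i}
    mean_f: float
    rsd: float  # percent

    def as_row(self) -> dict:
        return {
            "analyte": self.analyte_id,
            "mean_f": round_half_away(self.mean_f, 4),
            "rsd_percent": round_half_away(self.rsd, 2),
        }


def compute_rcf(levels, analyte_id: str = "", level_ids=None) -> RCFEntry:
    """Relative correction factor by multipoint correction.

    ``levels`` is a sequence of (A_s, C_s, A_i, C_i) tuples, one per
    injection level: areas and concentrations of the internal standard s
    and the target analyte i in the same injection.  Per level,
    f = (A_s * C_i) / (A_i * C_s); the entry carries the arithmetic mean
    and the sample-SD RSD over levels.
    """
    rows = list(levels)
    if len(rows) < 2:
        raise ValueError("multipoint correction needs at least 2 levels")
    f_values = []
    for k, (a_s, c_s, a_i, c_i) in enumerate(rows):
        if a_s <= 0 or a_i <= 0:
            raise ValueError(f"zero or negative peak area in injection {k}")
        if c_s <= 0 or c_i <= 0:
            raise ValueError(f"zero or negative concentration in injection {k}")
        f_values.append((a_s * c_i) / (a_i * c_s))
    f_values = np.asarray(f_values)
    ids = list(level_ids) if level_ids is not None else list(range(len(rows)))
    return RCFEntry(
        analyte_id=analyte_id,
        levels=ids,
        f_values=f_values,
        mean_f=float(f_values.mean()),
        rsd=rsd_percent(f_values),
    )


def rcf_table(entries: list[RCFEntry], internal_standard_id: str) -> pd.DataFrame:
    """Report table: one column per analyte, one row per level, plus
    Mean and RSD(%) rows, mirroring a multipoint-correction report."""
    data = {}
    for e in entries:
        col = [round_half_away(v, 4) for v in e.f_values]
        col += [round_half_away(e.mean_f, 4), round_half_away(e.rsd, 2)]
        data[e.analyte_id] = col
    index = [str(l) for l in entries[0].levels] + ["Mean", "RSD (%)"]
    table = pd.DataFrame(data, index=index)
    table.attrs["internal_standard"] = internal_standard_id
    return table


def compute_rrt(t_ri: float, t_rs: float) -> float:
    """Relative retention time t_R(i) / t_R(s)."""
    if t_rs <= 0:
        raise ValueError("internal-standard retention time must be positive")
    if t_ri <= 0:
        raise ValueError("analyte retention time must be positive")
    return t_ri / t_rs


def locate_peaks_by_rrt(
    peaks: pd.DataFrame,
    is_peak_rt: float,
    expected_rrt: dict[str, float],
    tolerance: float = 0.03,
) -> dict[str, pd.Series | None]:
    """Assign analytes to detected peaks by relative retention time.

    Each analyte maps to the peak minimizing |RRT - expected| when that
    distance is within ``tolerance``; unmatched analytes map to None.
    Two analytes claiming the same peak is an error (their expected RRTs
    are too close for this run).
    """
    if is_peak_rt <= 0:
        raise ValueError("internal-standard peak rt must be positive")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    rrt = peaks["rt_min"].to_numpy(float) / is_peak_rt
    assignment: dict[str, pd.Series | None] = {}
    claimed: dict[int, str] = {}
    for analyte, exp in expected_rrt.items():
        if rrt.size == 0:
            assignment[analyte] = None
            continue
        dist = np.abs(rrt - exp)
        j = int(np.argmin(dist))
        if dist[j] > tolerance:
            assignment[analyte] = None
            continue
        if j in claimed:
            raise ValueError(
                f"analytes {claimed[j]!r} and {analyte!r} both claim the peak "
                f"at {peaks['rt_min'].iloc[j]:.3f} min"
            )
        claimed[j] = analyte
        assignment[analyte] = peaks.iloc[j]
    return assignment


def qams_quantify(f: float, a_i: float, a_s: float, w_s: float) -> float:
    """W_QAMS,i = f * (A_i / A_s) * W_s (mg/g).

    ``w_s`` is the internal standard's mass fraction from its own
    calibration curve in the same run; the extraction factor V/m cancels
    between the two analytes.
    """
    if f <= 0 or a_i <= 0 or w_s <= 0:
        raise ValueError("f, A_i and W_s must be positive")
    if a_s <= 0:
        raise ValueError("internal-standard peak area missing or non-positive")
    return f * (a_i / a_s) * w_s


def smd(w_es: float, w_qams: float) -> float:
    """Signed standard method difference, 100 * (W_ES - W_QAMS) / W_ES."""
    if w_es <= 0:
        raise ValueError("SMD undefined for non-positive W_ES")
    return 100.0 * (w_es - w_qams) / w_es


@dataclass
class QuantRecord:
    sample_id: str
    analyte_id: str
    w_es: float  # mg/g
    w_qams: float  # mg/g
    smd_percent: float = field(init=False)

    def __post_init__(self) -> None:
        if self.w_es < 0 or self.w_qams < 0:
            raise ValueError("mass fractions must be non-negative")
        self.smd_percent = smd(self.w_es, self.w_qams) if self.w_es > 0 else float("nan")


def durability_summary(f_by_condition: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample-SD RSD of f per analyte across robustness conditions.

    ``f_by_condition`` has one row per condition (column x instrument,
    or temperature) and one column per analyte; at least 2 conditions.
    """
    if len(f_by_condition) < 2:
        raise ValueError("durability needs at least 2 conditions")
    out = {}
    for col in f_by_condition.columns:
        vals = f_by_condition[col].to_numpy(float)
        out[col] = {
            "mean_f": round_half_away(float(vals.mean()), 4),
            "rsd_percent": round_half_away(rsd_percent(vals), 2),
        }
    return pd.DataFrame(out).T


def validation_stats(values, kind: str, base=None, spiked=None) -> float:
    """Method-validation statistic for replicate measurements.

    precision / stability / repeatability: RSD% of >= 2 replicates.
    recovery: mean of 100 * (found - base) / spiked over >= 3 spiked
    replicates, where ``values`` are the found amounts.
    """
    values = np.asarray(values, dtype=float)
    if kind in ("precision", "stability", "repeatability"):
        return rsd_percent(values)
    if kind == "recovery":
        if base is None or spiked is None:
            raise ValueError("recovery needs base and spiked amounts")
        base = np.broadcast_to(np.asarray(base, dtype=float), values.shape)
        spiked = np.asarray(spiked, dtype=float)
        if spiked.shape != values.shape:
            raise ValueError("spike design does not match replicates")
        if values.size < 3:
            raise ValueError("recovery needs at least 3 replicates")
        if np.any(spiked <= 0):
            raise ValueError("spiked amounts must be positive")
        return float(np.mean(100.0 * (values - base) / spiked))
    raise ValueError(f"unknown validation kind {kind!r}")
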