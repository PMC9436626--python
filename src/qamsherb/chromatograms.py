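"""Chromatogram containers, CSV I/O, peak detection and integration.

A chromatogram is a uniformly sampled detector trace (time in minutes,
intensity in arbitrary detector units).  Peaks are local maxima whose
height above the local baseline exceeds a signal-to-noise threshold;
bounds are placed at flanking valleys (perpendicular drop between
co-eluting peaks) or at baseline return, and areas are trapezoidal
integrals above a straight line drawn between the two bound points.

S/N convention: peak height divided by the standard deviation of the
baseline noise (not peak-to-peak noise).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

PEAK_COLUMNS = ["rt_min", "area", "height", "left_min", "right_min", "snr"]


@dataclass
class Chromatogram:
    """Uniformly sampled time/intensity trace with acquisition metadata."""

    time: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if self.time.size < 10:
            raise ValueError("chromatogram needs at least 10 points")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"time axis not strictly increasing at row {row}")

    @property
    def sampling_interval(self) -> float:
        return float(np.median(np.diff(self.time)))

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask selecting samples with t0 <= time <= t1."""
        return (self.time >= t0) & (self.time <= t1)


@dataclass
class Peak:
    """A detected peak: apex time t_R, area A, height, bounds, S/N."""

    rt: float
    area: float
    height: float
    left: float
    right: float
    snr: float

    def __post_init__(self) -> None:
        if not (self.left < self.rt < self.right):
            raise ValueError("peak bounds must bracket the apex")


def write_chromatogram(chrom: Chromatogram, path) -> None:
    """Write a two-column CSV with ``# key: value`` metadata header lines."""
    with open(path, "w", newline="\n") as fh:
        for key, value in chrom.metadata.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("time_min,intensity\n")
        for t, y in zip(chrom.time, chrom.intensity):
            fh.write(f"{t:.10g},{y:.10g}\n")


def read_chromatogram(path) -> Chromatogram:
    """Read a chromatogram CSV written by :func:`write_chromatogram`.

    Tolerates CRLF line endings.  A non-monotone time axis raises a
    ``ValueError`` naming the offending row.
    """
    metadata: dict = {}
    with open(path, "r", newline="") as fh:
        text = fh.read()
    body_lines = []
    for line in io.StringIO(text):
        line = line.rstrip("\r\n")
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            metadata[key.strip()] = value.strip()
        elif line:
            body_lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body_lines)))
    if df.shape[1] != 2:
        raise ValueError("expected exactly two numeric columns")
    return Chromatogram(
        time=df.iloc[:, 0].to_numpy(float),
        intensity=df.iloc[:, 1].to_numpy(float),
        metadata=metadata,
    )


def estimate_noise(chrom: Chromatogram, blank_window: tuple[float, float]) -> float:
    """SD of linearly detrended intensity inside a peak-free window.

    Detrending removes baseline drift so the estimate tracks the white
    noise, not the slope of the baseline.
    """
    t0, t1 = blank_window
    if t0 < chrom.time[0] - 1e-9 or t1 > chrom.time[-1] + 1e-9:
        raise ValueError("blank window lies outside the run")
    mask = chrom.window(t0, t1)
    if mask.sum() < 20:
        raise ValueError("blank window must contain at least 20 points")
    t = chrom.time[mask]
    y = chrom.intensity[mask]
    coef = np.polyfit(t, y, 1)
    resid = y - np.polyval(coef, t)
    return float(np.std(resid, ddof=1))


def _parabolic_apex(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Apex (rt, height) by parabola through the 3 points around index i."""
    if i == 0 or i == len(y) - 1:
        return float(t[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not locally concave: fall back to the grid point
        return float(t[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    dt = t[i + 1] - t[i] if delta >= 0 else t[i] - t[i - 1]
    apex_t = float(t[i] + delta * dt)
    apex_y = float(y1 - 0.25 * (y0 - y2) * delta)
    return apex_t, apex_y


def _smooth(y: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return y
    kernel = np.ones(w) / w
    pad = w // 2
    padded = np.pad(y, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: y.size]


def _bound_index(ys: np.ndarray, lo: int, hi: int, noise_sd: float, toward_apex: bool) -> int:
    """Peak bound inside [lo, hi] on the smoothed trace ``ys``: the
    valley minimum (perpendicular drop; first occurrence wins ties),
    tightened toward the apex to where the smoothed signal has returned
    to the local baseline level — so flat stretches are excluded but
    peak tails are kept.  The baseline level is the region's median
    (robust on long flat stretches), capped at the valley floor when
    the region is dominated by overlapping peak flanks."""
    region = ys[lo : hi + 1]
    valley = int(np.argmin(region))
    floor = min(float(np.median(region)), float(region[valley]) + 2.0 * noise_sd)
    floor += 0.5 * noise_sd + 1e-12
    if toward_apex:
        below = np.nonzero(region[valley:] <= floor)[0]
        if below.size == 0:
            return lo + valley
        return lo + valley + int(below[-1])
    below = np.nonzero(region[: valley + 1] <= floor)[0]
    if below.size == 0:
        return lo + valley
    return lo + int(below[0])


def detect_peaks(
    chrom: Chromatogram,
    noise_sd: float,
    min_snr: float = 3.0,
    min_width: float = 0.0,
) -> pd.DataFrame:
    """Detect peaks and return an rt-sorted peak table.

    Local maxima whose height above the local straight baseline exceeds
    ``min_snr * noise_sd`` are kept; bounds at flanking valleys or
    baseline return; areas by trapezoidal integration above the bound-
    to-bound straight line.  Empty traces yield an empty table.
    """
    y = chrom.intensity
    t = chrom.time
    empty = pd.DataFrame(columns=PEAK_COLUMNS)
    if y.size == 0:
        return empty
    dt = chrom.sampling_interval
    # candidate apices on a lightly smoothed trace: thresholds stated in
    # raw-noise units stay, but smoothing suppresses single-sample noise
    # excursions (smoothed noise SD shrinks ~sqrt(window))
    ys = _smooth(y, 7 if noise_sd > 0 else 1)
    height_floor = min_snr * noise_sd if noise_sd > 0 else None
    prominence = max(min_snr * noise_sd, 1e-12)
    # width in samples (at half prominence) rejects narrow noise ripples
    width = min_width / dt if min_width > 0 else None
    apices, _ = find_peaks(ys, height=height_floor, prominence=prominence, width=width)
    if apices.size == 0:
        return empty
    rows = []
    for k, i in enumerate(apices):
        lo = apices[k - 1] if k > 0 else 0
        hi = apices[k + 1] if k + 1 < len(apices) else len(y) - 1
        left = _bound_index(ys, lo, i, noise_sd, toward_apex=True)
        right = _bound_index(ys, i, hi, noise_sd, toward_apex=False)
        if right <= left:
            continue
        # apex from the smoothed trace (parabola over its 3 top points)
        # so rt resolution does not degrade with raw noise; height from
        # the raw trace at that position
        apex_rt, _ = _parabolic_apex(t, ys, i)
        apex_y = float(y[max(0, i - 3) : i + 4].max())
        # height above the straight baseline joining the bound points
        base_at_apex = np.interp(apex_rt, [t[left], t[right]], [y[left], y[right]])
        height = apex_y - base_at_apex
        snr = height / noise_sd if noise_sd > 0 else np.inf
        if height <= 0 or (noise_sd > 0 and snr < min_snr):
            continue
        area = integrate_peak(
            chrom, (t[left], t[right]), anchor_halfwidth=7 if noise_sd > 0 else 0
        )
        if min_width > 0 and (t[right] - t[left]) < min_width:
            continue
        rows.append((apex_rt, area, height, float(t[left]), float(t[right]), float(snr)))

    if not rows:
        return empty
    table = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    return table.sort_values("rt_min", ignore_index=True)


def integrate_peak(
    chrom: Chromatogram,
    bounds: tuple[float, float],
    baseline: str = "linear",
    anchor_halfwidth: int = 0,
) -> float:
    """Trapezoidal area above a straight baseline between the bounds.

    ``baseline="linear"`` subtracts the straight line joining the two
    bound points; ``"none"`` integrates the raw signal (additive over
    adjacent bounds).  With noisy data, ``anchor_halfwidth`` > 0 anchors
    the line at the median intensity of ±that many samples around each
    bound instead of the single (noise-afflicted) bound samples.
    """
    t0, t1 = bounds
    if not (t1 > t0):
        raise ValueError("peak bounds must have positive width")
    if t0 < chrom.time[0] - 1e-9 or t1 > chrom.time[-1] + 1e-9:
        raise ValueError("integration bounds lie outside the run")
    mask = chrom.window(t0, t1)
    t = chrom.time[mask]
    y = chrom.intensity[mask]
    if t.size < 2:
        raise ValueError("fewer than 2 samples inside the integration bounds")
    if baseline == "none":
        return float(np.trapezoid(y, t))
    if baseline != "linear":
        raise ValueError(f"unknown baseline mode {baseline!r}")

    def anchor(time_pt: float, outward: int) -> float:
        # baseline level near a bound: median just outside the bound
        # (clear of the peak tail), capped by the at-bound level so a
        # valley between fused peaks keeps its perpendicular-drop height
        i = int(np.argmin(np.abs(chrom.time - time_pt)))
        lo, hi = max(0, i - anchor_halfwidth), min(chrom.time.size, i + anchor_halfwidth + 1)
        at_bound = float(np.median(chrom.intensity[lo:hi]))
        if anchor_halfwidth == 0:
            return at_bound
        o0, o1 = i + min(0, outward), i + max(0, outward) + 1
        o0, o1 = max(0, o0), min(chrom.time.size, o1)
        outside = float(np.median(chrom.intensity[o0:o1])) if o1 > o0 else at_bound
        return min(at_bound, outside)

    span = 3 * anchor_halfwidth
    line = np.interp(t, [t[0], t[-1]], [anchor(t[0], -span), anchor(t[-1], span)])
    return float(np.trapezoid(y - line, t))


def write_peak_table(table: pd.DataFrame, path, injection_id: str = "inj") -> None:
    out = table.copy()
    out.insert(0, "injection_id", injection_id)
    out.to_csv(path, index=False)


def read_peak_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df[["injection_id", *PEAK_COLUMNS]] if "injection_id" in df else df[PEAK_COLUMNS]
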