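"""Synthetic chromatogram generator with known ground truth.

Generates Gaussian-peak chromatograms whose integrated areas follow a
linear response model (area = slope * concentration + intercept), plus
calibration injection series and multi-batch peak-area matrices with a
two-group composition structure.  Every simulated peak is accompanied
by a truth record, so downstream detection, integration, calibration,
single-marker quantification and chemometrics can all be tested for
parameter recovery without any instrument data.

Units: time in minutes, concentration in mg/mL, intensity in arbitrary
detector units (no real-scale detector response is emulated).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chromatograms import Chromatogram

_SQRT2PI = float(np.sqrt(2.0 * np.pi))

TRUTH_COLUMNS = ["injection_id", "analyte_id", "rt", "area", "conc", "unresolved"]


@dataclass(frozen=True)
class PeakSpec:
    """One analyte's peak: position, width, concentration and response.

    The linear response ``area = response_slope * true_conc +
    response_intercept`` fixes the peak's integrated area; the Gaussian
    height is derived from it as ``area / (rt_sigma * sqrt(2*pi))``.
    """

    analyte_id: str
    rt_center: float  # minutes
    rt_sigma: float  # minutes
    true_conc: float  # mg/mL
    response_slope: float  # area units per (mg/mL)
    response_intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.rt_sigma <= 0:
            raise ValueError(f"{self.analyte_id}: rt_sigma must be positive")
        if self.true_conc < 0:
            raise ValueError(f"{self.analyte_id}: negative concentration rejected")
        if self.response_slope <= 0:
            raise ValueError(f"{self.analyte_id}: response_slope must be positive")

    @property
    def true_area(self) -> float:
        return self.response_slope * self.true_conc + self.response_intercept


@dataclass(frozen=True)
class RunDesign:
    """Acquisition settings for one simulated injection."""

    duration: float = 35.0  # minutes (gradient end)
    sampling_rate: float = 20.0  # points per minute
    noise_sd: float = 0.0  # intensity units
    baseline_drift: tuple = (0.0,)  # polynomial coefficients, highest first
    rt_jitter_sd: float = 0.0  # minutes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.rt_jitter_sd < 0:
            raise ValueError("rt_jitter_sd must be non-negative")

    def time_axis(self) -> np.ndarray:
        n = int(round(self.duration * self.sampling_rate)) + 1
        return np.linspace(0.0, self.duration, n)


def generate_chromatogram(
    specs: list[PeakSpec],
    design: RunDesign,
    injection_id: str = "inj",
    metadata: dict | None = None,
) -> tuple[Chromatogram, pd.DataFrame]:
    """Simulate one injection; returns the trace and its truth table.

    intensity = polynomial baseline + sum of Gaussians + white noise.
    Two specs sharing an identical rt_center are flagged ``unresolved``
    in the truth table (their peaks cannot be told apart downstream).
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    for spec in specs:
        if not (0.0 <= spec.rt_center <= design.duration):
            raise ValueError(f"{spec.analyte_id}: rt_center outside the run")

    rng = np.random.default_rng(design.seed)
    t = design.time_axis()
    y = np.polyval(list(design.baseline_drift), t)

    centers = [s.rt_center for s in specs]
    truth_rows = []
    for spec in specs:
        rt = spec.rt_center + (rng.normal(0.0, design.rt_jitter_sd) if design.rt_jitter_sd > 0 else 0.0)
        area = spec.true_area
        height = area / (spec.rt_sigma * _SQRT2PI)
        y = y + height * np.exp(-0.5 * ((t - rt) / spec.rt_sigma) ** 2)
        unresolved = centers.count(spec.rt_center) > 1
        truth_rows.append((injection_id, spec.analyte_id, rt, area, spec.true_conc, unresolved))

    if design.noise_sd > 0:
        y = y + rng.normal(0.0, design.noise_sd, size=t.size)

    meta = {"injection_id": injection_id, "seed": design.seed}
    if metadata:
        meta.update(metadata)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return Chromatogram(time=t, intensity=y, metadata=meta), truth


def generate_calibration_series(
    specs: list[PeakSpec],
    levels: list[float],
    design: RunDesign,
) -> list[tuple[Chromatogram, pd.DataFrame]]:
    """One injection per level; levels scale each spec's stock concentration.

    A level is the on-column dilution/volume factor (level 1.0 injects
    the stock concentration, level 0.1 one tenth of it), so a spec with
    ``true_conc=1.0`` turns the level list directly into mg/mL.  Each
    injection draws its own noise from a per-level seed.
    """
    if len(set(levels)) < 2:
        raise ValueError("need at least 2 distinct calibration levels")
    for lvl in levels:
        if lvl <= 0:
            raise ValueError(f"non-positive calibration level {lvl} rejected")

    series = []
    for k, lvl in enumerate(sorted(levels)):
        lvl_specs = [replace(s, true_conc=s.true_conc * lvl) for s in specs]
        lvl_design = replace(design, seed=design.seed + k)
        chrom, truth = generate_chromatogram(
            lvl_specs, lvl_design, injection_id=f"cal{k}", metadata={"level": lvl}
        )
        truth["level"] = lvl
        series.append((chrom, truth))
    return series


def generate_batch_set(
    group_profiles: np.ndarray,
    n_batches: int,
    effect: float = 1.0,
    within_cv: float = 0.05,
    seed: int = 0,
    group_sizes: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Peak-area matrix for a two-group multi-batch design.

    ``group_profiles`` is a (2, k) array of mean peak areas.  ``effect``
    interpolates the second group geometrically between the first
    profile (effect=0, identical groups) and its own profile (effect=1).
    Within-group variation is log-normal with the given coefficient of
    variation.  Returns (batches x peaks areas, group labels).
    """
    profiles = np.asarray(group_profiles, dtype=float)
    if profiles.shape[0] != 2 or profiles.shape[1] < 2:
        raise ValueError("group_profiles must be a (2, k>=2) array")
    if np.any(profiles <= 0):
        raise ValueError("profile means must be positive")
    if n_batches < 4:
        raise ValueError("need at least 4 batches")
    if within_cv < 0:
        raise ValueError("negative within-group CV rejected")

    if group_sizes is None:
        group_sizes = (n_batches // 2, n_batches - n_batches // 2)
    if sum(group_sizes) != n_batches:
        raise ValueError("group sizes must sum to n_batches")

    k = profiles.shape[1]
    base = profiles[0]
    other = base * (profiles[1] / base) ** effect
    means = [base, other]

    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(within_cv**2)) if within_cv > 0 else 0.0
    rows, labels = [], []
    for g, size in enumerate(group_sizes):
        for _ in range(size):
            noise = rng.normal(0.0, sigma, size=k) if sigma > 0 else np.zeros(k)
            rows.append(means[g] * np.exp(noise))
            labels.append(g)

    index = [f"B{i + 1:02d}" for i in range(n_batches)]
    areas = pd.DataFrame(rows, index=index, columns=[f"P{j + 1}" for j in range(k)])
    return areas, pd.Series(labels, index=index, name="group")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)
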