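"""Common-peak fingerprints and batch similarity.

Peak tables from multiple batches are aligned on the internal-standard
peak (multipoint RRT alignment onto a reference time axis), merged into
common peaks within a stated time window (default 0.1 min), and each
batch's common-peak area vector is scored against a reference
fingerprint (column-wise mean by default) by cosine or Pearson
similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _group_by_window(pooled, time_window):
    """Sort aligned peaks and chain them into groups: a peak joins the
    current group while it stays within the window of the group's
    running mean position."""
    groups: list[list[tuple[str, float, float]]] = []
    for rec in sorted(pooled, key=lambda r: r[1]):
        if groups:
            current = groups[-1]
            center = np.mean([r[1] for r in current])
            if abs(rec[1] - center) <= time_window:
                current.append(rec)
                continue
        groups.append([rec])
    return groups


def _fit_time_corrections(groups, batches):
    """Per-batch linear map aligned_rt -> group center, fitted on
    groups shared with at least half the batches; batches with fewer
    than 3 usable anchor peaks are left uncorrected."""
    half = max(2, len(batches) // 2)
    anchors: dict[str, list[tuple[float, float]]] = {b: [] for b in batches}
    for grp in groups:
        present = {b for b, _, _ in grp}
        if len(present) < half:
            continue
        center = float(np.mean([rt for _, rt, _ in grp]))
        for batch, rt, _ in grp:
            anchors[batch].append((rt, center))
    corrections = {}
    for batch, pairs in anchors.items():
        if len(pairs) >= 3:
            x, yv = np.array(pairs).T
            corrections[batch] = tuple(np.polyfit(x, yv, 1))
    return corrections


@dataclass
class FingerprintMatrix:
    """Batches x common peaks area matrix plus alignment bookkeeping."""

    areas: pd.DataFrame  # rows: batch ids; columns: common-peak ids, RRT-ordered
    peak_rt: pd.Series  # reference-axis rt of each common peak
    peak_rrt: pd.Series  # rt / internal-standard rt
    non_common: pd.DataFrame  # aligned peaks present in only some batches


def match_common_peaks(
    peak_tables: dict[str, pd.DataFrame],
    is_rt: dict[str, float],
    time_window: float = 0.1,
    reference_batch: str | None = None,
    min_presence: float = 1.0,
) -> FingerprintMatrix:
    """Merge per-batch peak tables into a common-peak matrix.

    Every batch's retention times are mapped onto the reference batch's
    time axis through its internal-standard peak (rt * t_ref(s) /
    t_batch(s)), then single-linkage grouped: a peak joins the current
    group while it stays within ``time_window`` minutes of the group's
    running mean position.  Groups containing a peak from every batch
    are the common peaks (``min_presence`` < 1 relaxes this to a
    presence fraction for exploration); the rest are reported as
    non-common.  Absent cells in lenient mode are zero-filled.
    """
    if len(peak_tables) < 2:
        raise ValueError("need at least 2 batches")
    for batch in peak_tables:
        if batch not in is_rt or not np.isfinite(is_rt[batch]) or is_rt[batch] <= 0:
            raise ValueError(f"batch {batch!r} has no internal-standard peak")
    if time_window <= 0:
        raise ValueError("time window must be positive")

    batches = list(peak_tables)
    ref = reference_batch if reference_batch is not None else batches[0]
    t_ref_s = is_rt[ref]

    pooled = []
    for batch in batches:
        table = peak_tables[batch]
        scale = t_ref_s / is_rt[batch]
        for _, row in table.iterrows():
            pooled.append((batch, row["rt_min"] * scale, row["area"]))

    groups = _group_by_window(pooled, time_window)
    # multipoint correction: refine each batch's time axis by a linear
    # fit of its aligned positions onto the first-pass group centers,
    # then regroup — residual misalignment drops to per-peak jitter
    corrections = _fit_time_corrections(groups, batches)
    if corrections:
        pooled = [
            (batch, np.polyval(corrections.get(batch, (1.0, 0.0)), rt), area)
            for batch, rt, area in pooled
        ]
        groups = _group_by_window(pooled, time_window)

    n = len(batches)
    common, non_common_rows = [], []
    for grp in groups:
        present = {}
        for batch, rt, area in grp:
            # if a batch contributes twice, keep its larger peak
            if batch not in present or area > present[batch][1]:
                present[batch] = (rt, area)
        frac = len(present) / n
        center = float(np.mean([v[0] for v in present.values()]))
        if frac >= min_presence:
            common.append((center, present))
        else:
            non_common_rows.append(
                {"rt": center, "n_batches": len(present), "batches": ",".join(sorted(present))}
            )

    if not common:
        raise ValueError("no common peaks found")
    common.sort(key=lambda c: c[0])

    ids = [f"C{i + 1}" for i in range(len(common))]
    data = np.zeros((n, len(common)))
    for j, (_, present) in enumerate(common):
        for i, batch in enumerate(batches):
            if batch in present:
                data[i, j] = present[batch][1]
    areas = pd.DataFrame(data, index=batches, columns=ids)
    rt = pd.Series([c[0] for c in common], index=ids, name="rt_min")
    return FingerprintMatrix(
        areas=areas,
        peak_rt=rt,
        peak_rrt=rt / t_ref_s,
        non_common=pd.DataFrame(non_common_rows, columns=["rt", "n_batches", "batches"]),
    )


def reference_fingerprint(matrix: FingerprintMatrix | pd.DataFrame, method: str = "mean") -> pd.Series:
    """Reference vector over batches: column-wise mean (or median)."""
    areas = matrix.areas if isinstance(matrix, FingerprintMatrix) else matrix
    if areas.empty:
        raise ValueError("empty fingerprint matrix")
    if method == "mean":
        return areas.mean(axis=0)
    if method == "median":
        return areas.median(axis=0)
    raise ValueError(f"unknown reference method {method!r}")


def similarity(batch_vector, reference_vector, method: str = "cosine") -> float:
    """Similarity of a batch fingerprint to the reference, in [-1, 1]."""
    v = np.asarray(batch_vector, dtype=float)
    r = np.asarray(reference_vector, dtype=float)
    if v.shape != r.shape or v.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    if np.linalg.norm(v) == 0 or np.linalg.norm(r) == 0:
        raise ValueError("zero vector has no direction")
    if method == "cosine":
        return float(np.dot(v, r) / (np.linalg.norm(v) * np.linalg.norm(r)))
    if method == "pearson":
        vc, rc = v - v.mean(), r - r.mean()
        if np.linalg.norm(vc) == 0 or np.linalg.norm(rc) == 0:
            raise ValueError("constant vector has undefined correlation")
        return float(np.dot(vc, rc) / (np.linalg.norm(vc) * np.linalg.norm(rc)))
    raise ValueError(f"unknown similarity method {method!r}")


def similarity_report(matrix: FingerprintMatrix | pd.DataFrame, method: str = "mean") -> pd.DataFrame:
    """Cosine and Pearson similarity of every batch vs the reference."""
    areas = matrix.areas if isinstance(matrix, FingerprintMatrix) else matrix
    ref = reference_fingerprint(areas, method=method)
    rows = {
        batch: {
            "cosine": similarity(areas.loc[batch], ref, "cosine"),
            "pearson": similarity(areas.loc[batch], ref, "pearson"),
        }
        for batch in areas.index
    }
    return pd.DataFrame(rows).T
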