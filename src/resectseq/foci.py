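"""Focus colocalization statistics for super-resolution spread images.

Recombinase foci (e.g. DMC1 and RAD51) decorate meiotic chromosome axes and
frequently occur in side-by-side pairs on the two sides of — or along the
single ssDNA tail of — a DSB.  Given axis polylines and two channels of
focus coordinates (nm, 2-D maximum-intensity projections), this module
computes:

* axis association: a focus is axis-associated when its minimum Euclidean
  distance to any axis segment is <= 450 nm (inclusive);
* co-focus detection at <= 320 nm, by two rules — a per-focus
  nearest-neighbor criterion (the fraction statistic: is the nearest focus
  of the other channel within threshold?) and exclusive greedy
  mutual-nearest pairing (the distance statistic: one distance per physical
  co-focus);
* interfocus distance mean/SD and Welch's two-sample t test for comparing
  conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ParseError
from .simulate import FocusField, ParameterError

__all__ = [
    "AXIS_THRESHOLD_NM",
    "PAIR_THRESHOLD_NM",
    "CoFocusSet",
    "FocusStats",
    "point_segment_distances",
    "axis_distances",
    "axis_association",
    "nearest_neighbor_cofocus",
    "cofocus_pairing",
    "interfocus_stats",
    "two_sample_t_test",
    "read_focus_table",
    "write_focus_table",
    "analyze_field",
]

AXIS_THRESHOLD_NM = 450.0
PAIR_THRESHOLD_NM = 320.0


def point_segment_distances(points: np.ndarray, a: np.ndarray,
                            b: np.ndarray) -> np.ndarray:
    """Distance from each point to each segment ``a[j] -> b[j]`` (n x m).

    Projects each point onto each segment's supporting line, clamps the
    projection parameter to [0, 1], and measures to the clamped foot.
    """
    points = np.asarray(points, float).reshape(-1, 2)
    a = np.asarray(a, float).reshape(-1, 2)
    b = np.asarray(b, float).reshape(-1, 2)
    ab = b - a                                     # (m, 2)
    ap = points[:, None, :] - a[None, :, :]        # (n, m, 2)
    denom = np.einsum("md,md->m", ab, ab)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.einsum("nmd,md->nm", ap, ab) / denom
    t = np.nan_to_num(t, nan=0.0)                  # zero-length segments
    t = np.clip(t, 0.0, 1.0)
    foot = a[None, :, :] + t[..., None] * ab[None, :, :]
    return np.linalg.norm(points[:, None, :] - foot, axis=2)


def _axis_segments(field_: FocusField) -> tuple[np.ndarray, np.ndarray]:
    return (np.concatenate([ax[:-1] for ax in field_.axes]),
            np.concatenate([ax[1:] for ax in field_.axes]))


def axis_distances(field_: FocusField, channel: str) -> np.ndarray:
    """Minimum point-to-axis distance (nm) per focus of ``channel`` (A or B)."""
    foci = field_.fociA if channel == "A" else field_.fociB
    if foci.shape[0] == 0:
        return np.zeros(0)
    if not field_.axes:
        raise ParameterError("focus field has no axes")
    a, b = _axis_segments(field_)
    return point_segment_distances(foci, a, b).min(axis=1)


def axis_association(field_: FocusField, threshold: float = AXIS_THRESHOLD_NM,
                     ) -> dict[str, dict]:
    """Per-focus axis-association labels and fractions for both channels.

    A focus exactly at the threshold counts as associated (inclusive rule).
    Empty channels report a NaN fraction.
    """
    out = {}
    for channel in ("A", "B"):
        d = axis_distances(field_, channel)
        labels = d <= threshold
        out[channel] = {
            "distances": d,
            "associated": labels,
            "fraction": float(labels.mean()) if d.size else math.nan,
        }
    return out


@dataclass
class CoFocusSet:
    """Exclusive A-B pairs plus leftover indices from greedy pairing."""

    pairs: list                      # (indexA, indexB, distance)
    unpairedA: np.ndarray
    unpairedB: np.ndarray
    threshold: float

    @property
    def distances(self) -> np.ndarray:
        return np.array([d for _, _, d in self.pairs])


def _mutual_distance_matrix(field_: FocusField,
                            restrict_to_axis: bool,
                            axis_threshold: float) -> tuple[np.ndarray,
                                                            np.ndarray,
                                                            np.ndarray]:
    idxA = np.arange(field_.fociA.shape[0])
    idxB = np.arange(field_.fociB.shape[0])
    if restrict_to_axis:
        assoc = axis_association(field_, axis_threshold)
        idxA = idxA[assoc["A"]["associated"]]
        idxB = idxB[assoc["B"]["associated"]]
    if idxA.size and idxB.size:
        diff = field_.fociA[idxA][:, None, :] - field_.fociB[idxB][None, :, :]
        dist = np.linalg.norm(diff, axis=2)
    else:
        dist = np.zeros((idxA.size, idxB.size))
    return dist, idxA, idxB


def nearest_neighbor_cofocus(field_: FocusField,
                             threshold: float = PAIR_THRESHOLD_NM,
                             restrict_to_axis: bool = False,
                             axis_threshold: float = AXIS_THRESHOLD_NM,
                             ) -> dict[str, float]:
    """Fraction of each channel's foci with an opposite-channel focus <= threshold.

    This per-focus criterion allows many-to-one matches and is the
    convention behind reported colocalization percentages.  With
    ``restrict_to_axis`` both the scored foci and the candidate partners are
    limited to axis-associated foci.
    """
    dist, idxA, idxB = _mutual_distance_matrix(field_, restrict_to_axis,
                                               axis_threshold)
    fracA = float((dist.min(axis=1) <= threshold).mean()) if dist.size else math.nan
    fracB = float((dist.min(axis=0) <= threshold).mean()) if dist.size else math.nan
    if idxA.size == 0:
        fracA = math.nan
    if idxB.size == 0:
        fracB = math.nan
    return {"A": fracA, "B": fracB}


def cofocus_pairing(field_: FocusField, threshold: float = PAIR_THRESHOLD_NM,
                    restrict_to_axis: bool = False,
                    axis_threshold: float = AXIS_THRESHOLD_NM) -> CoFocusSet:
    """Greedy exclusive pairing: repeatedly match the closest unpaired A-B couple.

    Couples farther apart than ``threshold`` are never paired.  Ties are
    broken deterministically by (distance, indexA, indexB).  Each focus
    joins at most one pair, giving one distance per physical co-focus.
    """
    dist, idxA, idxB = _mutual_distance_matrix(field_, restrict_to_axis,
                                               axis_threshold)
    within = np.argwhere(dist <= threshold) if dist.size else np.zeros((0, 2), int)
    candidates = sorted((float(dist[i, j]), int(idxA[i]), int(idxB[j]))
                        for i, j in within)
    usedA: set[int] = set()
    usedB: set[int] = set()
    pairs = []
    for d, ia, ib in candidates:
        if ia in usedA or ib in usedB:
            continue
        pairs.append((ia, ib, d))
        usedA.add(ia)
        usedB.add(ib)
    return CoFocusSet(
        pairs=pairs,
        unpairedA=np.array([i for i in idxA if i not in usedA], dtype=np.int64),
        unpairedB=np.array([i for i in idxB if i not in usedB], dtype=np.int64),
        threshold=threshold,
    )


@dataclass
class FocusStats:
    """Summary of one field/condition: fractions and pair-distance moments."""

    axis_fraction_A: float
    axis_fraction_B: float
    cofocus_fraction_A: float
    cofocus_fraction_B: float
    distances: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mean: float = math.nan
    sd: float = math.nan
    n: int = 0


def interfocus_stats(pairs: CoFocusSet) -> FocusStats:
    """Sample mean and SD (n-1 denominator) of greedy-pair distances.

    One pair gives a mean but no SD; an empty set gives NaN for both.
    """
    d = pairs.distances
    mean = float(d.mean()) if d.size >= 1 else math.nan
    sd = float(d.std(ddof=1)) if d.size >= 2 else math.nan
    return FocusStats(axis_fraction_A=math.nan, axis_fraction_B=math.nan,
                      cofocus_fraction_A=math.nan, cofocus_fraction_B=math.nan,
                      distances=d, mean=mean, sd=sd, n=int(d.size))


def two_sample_t_test(distancesA: np.ndarray,
                      distancesB: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sided t test: (t, df, p).

    Requires n >= 2 per sample.  When both samples have zero variance and
    equal means the statistic is undefined: returns (nan, nan, nan).
    """
    a = np.asarray(distancesA, float)
    b = np.asarray(distancesB, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return math.nan, math.nan, math.nan
        return math.inf, float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    se2a, se2b = va / a.size, vb / b.size
    df = (se2a + se2b) ** 2 / (se2a ** 2 / (a.size - 1) + se2b ** 2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


# ---------------------------------------------------------------------------
# CSV I/O

_FOCI_COLS = ["cell", "x_nm", "y_nm"]
_AXIS_COLS = ["cell", "axis_id", "vertex", "x_nm", "y_nm"]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in required:
        if col in ("x_nm", "y_nm", "vertex"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = np.flatnonzero(vals.isna() & df[col].notna())
            if bad.size:
                raise ParseError(f"{path}: non-numeric {col} at data row(s) "
                                 f"{(bad + 2).tolist()}")
            df[col] = vals
    return df


def read_focus_table(axes_csv, fociA_csv, fociB_csv) -> list[FocusField]:
    """Read axis/focus CSVs into one :class:`FocusField` per cell.

    Schemas: foci files have ``cell,x_nm,y_nm``; the axis file has
    ``cell,axis_id,vertex,x_nm,y_nm`` with vertices ordered by ``vertex``.
    """
    axes_df = _read_csv(axes_csv, _AXIS_COLS)
    a_df = _read_csv(fociA_csv, _FOCI_COLS)
    b_df = _read_csv(fociB_csv, _FOCI_COLS)
    fields = []
    for cell in sorted(set(axes_df["cell"].astype(str))):
        cell_axes = []
        sub = axes_df[axes_df["cell"].astype(str) == cell]
        for _, ax in sub.groupby("axis_id"):
            ax = ax.sort_values("vertex")
            verts = ax[["x_nm", "y_nm"]].to_numpy(float)
            if verts.shape[0] < 2:
                raise ParseError(f"{axes_csv}: axis {ax['axis_id'].iloc[0]!r} in "
                                 f"cell {cell!r} has fewer than 2 vertices")
            cell_axes.append(verts)
        fa = a_df[a_df["cell"].astype(str) == cell][["x_nm", "y_nm"]].to_numpy(float)
        fb = b_df[b_df["cell"].astype(str) == cell][["x_nm", "y_nm"]].to_numpy(float)
        fields.append(FocusField(axes=cell_axes, fociA=fa, fociB=fb, cell=cell))
    if not fields:
        raise ParseError(f"{axes_csv}: no cells found")
    return fields


def write_focus_table(fields: list[FocusField], axes_csv, fociA_csv,
                      fociB_csv) -> None:
    """Write fields back to the three-CSV schema of :func:`read_focus_table`."""
    axis_rows, a_rows, b_rows = [], [], []
    for f in fields:
        for k, ax in enumerate(f.axes):
            for v, (x, y) in enumerate(ax):
                axis_rows.append((f.cell, k, v, x, y))
        a_rows += [(f.cell, x, y) for x, y in f.fociA]
        b_rows += [(f.cell, x, y) for x, y in f.fociB]
    pd.DataFrame(axis_rows, columns=_AXIS_COLS).to_csv(axes_csv, index=False)
    pd.DataFrame(a_rows, columns=_FOCI_COLS).to_csv(fociA_csv, index=False)
    pd.DataFrame(b_rows, columns=_FOCI_COLS).to_csv(fociB_csv, index=False)


def analyze_field(field_: FocusField, axis_threshold: float = AXIS_THRESHOLD_NM,
                  pair_threshold: float = PAIR_THRESHOLD_NM,
                  restrict_to_axis: bool = True) -> FocusStats:
    """Full focus analysis of one field.

    Axis-association fractions per channel; co-focus fractions by the
    per-focus nearest-neighbor rule (among axis-associated foci by
    default); interfocus mean/SD from exclusive greedy pairs.
    """
    assoc = axis_association(field_, axis_threshold)
    nn = nearest_neighbor_cofocus(field_, pair_threshold, restrict_to_axis,
                                  axis_threshold)
    pairs = cofocus_pairing(field_, pair_threshold, restrict_to_axis,
                            axis_threshold)
    dist_stats = interfocus_stats(pairs)
    return FocusStats(
        axis_fraction_A=assoc["A"]["fraction"],
        axis_fraction_B=assoc["B"]["fraction"],
        cofocus_fraction_A=nn["A"],
        cofocus_fraction_B=nn["B"],
        distances=dist_stats.distances,
        mean=dist_stats.mean,
        sd=dist_stats.sd,
        n=dist_stats.n,
    )
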