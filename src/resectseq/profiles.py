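"""Metaplot construction around DSB hotspot centers.

The central object is the genome-average, co-oriented profile: per-hotspot
windows of strand-specific endpoint counts are extracted, bottom-strand
windows are mirrored onto the top-strand frame (so leftward- and
rightward-moving resection tracts average together), and the stack is
averaged into one signal-versus-distance curve.  On that curve the pipeline
applies, in a fixed order, the standard transformations used for resection
maps: background subtraction (signal level 2.5 kb from the center), Hann
smoothing, peak or area normalization, and clamping of negative values for
plotting.  Per-hotspot heatmaps are row-normalized over a 4001-bp window and
color-coded by pooled deciles so spatial patterns can be compared across
hotspots of very different strengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .io import DataError, HotspotSet, StrandedEndpointTrack

__all__ = [
    "Profile",
    "StrandMatrices",
    "HeatmapMatrix",
    "extract_oriented_matrix",
    "average_profile",
    "strand_average_profiles",
    "subtract_background",
    "hann_smooth",
    "normalize_profile",
    "clamp_negatives",
    "heatmap_normalize",
    "read_profile",
    "write_profile",
]

log = logging.getLogger(__name__)


@dataclass
class Profile:
    """A signal-versus-position curve relative to hotspot centers.

    ``positions`` run from -W to +W in 1-bp steps.  Metadata fields record
    the transformation history so downstream metrics can check their
    preconditions (e.g. the mean-length estimator requires an unsmoothed,
    background-subtracted curve).
    """

    positions: np.ndarray
    values: np.ndarray
    n_hotspots: int = 0
    smoothing: int = 0
    background: float | None = None
    normalization: str = "none"
    negatives_clamped: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.positions.shape != self.values.shape:
            raise DataError("profile positions and values differ in length")
        if self.positions.size and np.any(np.diff(self.positions) != 1):
            raise DataError("profile positions must increase strictly by 1")

    def index(self, pos: int) -> int:
        i = int(pos - self.positions[0])
        if i < 0 or i >= self.positions.size:
            raise DataError(f"position {pos} outside profile span "
                            f"[{self.positions[0]}, {self.positions[-1]}]")
        return i

    def slice(self, lo: int, hi: int, *, inclusive: bool = False) -> np.ndarray:
        """Values over ``[lo, hi)`` (or ``[lo, hi]`` when inclusive)."""
        return self.values[self.index(lo): self.index(hi) + (1 if inclusive else 0)]


@dataclass
class StrandMatrices:
    """Per-hotspot windows of top- and bottom-strand signal.

    Rows follow the input hotspot order; ``positions`` give the relative
    coordinate of each column.  ``skipped`` lists hotspot ids whose window
    crossed a chromosome edge (dropped, not padded).
    """

    top: np.ndarray
    bottom: np.ndarray
    positions: np.ndarray
    ids: np.ndarray
    strengths: np.ndarray
    skipped: list = field(default_factory=list)

    @property
    def n_hotspots(self) -> int:
        return self.top.shape[0]

    def oriented(self) -> np.ndarray:
        """Co-oriented observation stack: top rows plus mirrored bottom rows.

        Each hotspot contributes two observations — its top-strand window
        as-is and its bottom-strand window reflected about the center — so
        both DSB sides are expressed in the rightward-resection frame.
        """
        return np.vstack([self.top, self.bottom[:, ::-1]])


@dataclass
class HeatmapMatrix:
    """Row-normalized, decile-coded heatmap data for one strand.

    ``values[i, j]`` is the fraction of hotspot i's windowed signal that
    falls in bin j; populated rows sum to 1.  ``deciles`` holds codes 1-10
    from pooled nonzero bins (0 marks empty bins).  Rows are ordered by
    descending hotspot strength.
    """

    values: np.ndarray
    deciles: np.ndarray
    bin_edges: np.ndarray
    ids: np.ndarray
    empty_rows: np.ndarray


def extract_oriented_matrix(track: StrandedEndpointTrack, hotspots: HotspotSet,
                            half_window: int = 2500) -> StrandMatrices:
    """Extract per-hotspot strand-specific windows of width ``2*half_window+1``.

    Hotspots whose window crosses a chromosome edge are skipped and logged.
    Raises :class:`DataError` if the hotspot set is empty or all are skipped.
    """
    if len(hotspots) == 0:
        raise DataError("empty hotspot set")
    width = 2 * half_window + 1
    keep_rows_top, keep_rows_bottom, keep_idx, skipped = [], [], [], []
    # Work chromosome by chromosome on dense arrays: one allocation per
    # chromosome instead of one binary search per hotspot.
    for chrom in track.chrom_sizes:
        on_c = np.flatnonzero(hotspots.chrom == chrom)
        if on_c.size == 0:
            continue
        size = track.chrom_sizes[chrom]
        dense_top = track.dense(chrom, "top")
        dense_bottom = track.dense(chrom, "bottom")
        for i in on_c:
            c = int(hotspots.center[i])
            if c - half_window < 0 or c + half_window + 1 > size:
                skipped.append(hotspots.ids[i])
                continue
            keep_rows_top.append(dense_top[c - half_window: c + half_window + 1])
            keep_rows_bottom.append(dense_bottom[c - half_window: c + half_window + 1])
            keep_idx.append(i)
    if skipped:
        log.info("skipped %d hotspot(s) whose window crossed a chromosome edge",
                 len(skipped))
    if not keep_idx:
        raise DataError("all hotspot windows crossed chromosome edges")
    order = np.argsort(keep_idx, kind="stable")  # preserve input hotspot order
    idx = np.asarray(keep_idx)[order]
    return StrandMatrices(
        top=np.vstack([keep_rows_top[i] for i in order]),
        bottom=np.vstack([keep_rows_bottom[i] for i in order]),
        positions=np.arange(-half_window, half_window + 1),
        ids=hotspots.ids[idx],
        strengths=hotspots.strength[idx],
        skipped=skipped,
    )


def average_profile(matrices: StrandMatrices, weighting: str = "uniform") -> Profile:
    """Average the co-oriented observation stack into a genome-average profile.

    ``weighting='strength'`` weights each hotspot's two observations by its
    strength; the default is the plain arithmetic mean.
    """
    obs = matrices.oriented()
    if weighting == "uniform":
        values = obs.mean(axis=0)
    elif weighting == "strength":
        w = np.concatenate([matrices.strengths, matrices.strengths]).astype(float)
        if w.sum() <= 0:
            raise DataError("strength weighting requires positive total strength")
        values = (obs * w[:, None]).sum(axis=0) / w.sum()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return Profile(matrices.positions.copy(), values, n_hotspots=matrices.n_hotspots)


def strand_average_profiles(matrices: StrandMatrices) -> tuple[Profile, Profile]:
    """Genome-average top- and bottom-strand profiles without co-orientation.

    Used for the double-cut diagnostic, where the sign of the top-versus-
    bottom central peak offset is the observable.
    """
    top = Profile(matrices.positions.copy(), matrices.top.mean(axis=0),
                  n_hotspots=matrices.n_hotspots)
    bottom = Profile(matrices.positions.copy(), matrices.bottom.mean(axis=0),
                     n_hotspots=matrices.n_hotspots)
    return top, bottom


def subtract_background(profile: Profile, bg_at: int = 2500,
                        bg_halfwidth: int = 50) -> Profile:
    """Subtract the signal level ``bg_at`` bp from the hotspot center.

    The background is the mean over the ``2*bg_halfwidth + 1`` positions
    ending at ``bg_at`` (extending toward the interior of the profile, so a
    negative ``bg_at`` works for bottom-strand frames); ``bg_halfwidth=0``
    recovers the single-position estimate.  Negative results are kept —
    clamping is a separate, plotting-time step.
    """
    inner = bg_at - 2 * bg_halfwidth if bg_at >= 0 else bg_at + 2 * bg_halfwidth
    lo, hi = sorted((bg_at, inner))
    window = profile.slice(lo, hi, inclusive=True)
    bg = float(window.mean())
    return replace(profile, values=profile.values - bg, background=bg)


def hann_kernel(window: int) -> np.ndarray:
    """Hann taper of odd length ``window``, normalized to sum 1."""
    if window % 2 != 1 or window < 1:
        raise ValueError(f"Hann window must be odd and >= 1, got {window}")
    if window == 1:
        return np.ones(1)
    n = np.arange(window)
    w = 1.0 - np.cos(2.0 * np.pi * n / (window - 1))
    return w / w.sum()


def hann_smooth(data: Profile | np.ndarray, window: int) -> Profile | np.ndarray:
    """Convolve with a normalized Hann kernel; edges renormalize the kernel.

    Away from edges the convolution conserves total signal exactly (the
    kernel sums to 1); at the edges the truncated kernel is renormalized so
    the smoothed curve stays on the scale of the input.
    """
    kernel = hann_kernel(window)
    values = data.values if isinstance(data, Profile) else np.asarray(data, float)
    smoothed = np.convolve(values, kernel, mode="same")
    coverage = np.convolve(np.ones_like(values), kernel, mode="same")
    smoothed = smoothed / coverage
    if isinstance(data, Profile):
        return replace(data, values=smoothed, smoothing=window)
    return smoothed


def normalize_profile(profile: Profile, mode: str,
                      peak_range: tuple[int, int] = (100, 2500),
                      auc_range: tuple[int, int] = (-1000, 2500)) -> Profile:
    """Scale a profile by its resection peak height or by an area.

    ``mode='peak'`` divides by the maximum over ``peak_range`` (inclusive),
    the resection-endpoint peak; ``mode='auc'`` divides by the per-bp sum
    over ``auc_range`` (inclusive), the convention for coverage-style
    (SSDS) profiles.  A non-positive normalizer raises :class:`DataError`.
    """
    if mode == "peak":
        norm = float(profile.slice(*peak_range, inclusive=True).max())
        what = f"max over [{peak_range[0]}, {peak_range[1]}]"
    elif mode == "auc":
        norm = float(profile.slice(*auc_range, inclusive=True).sum())
        what = f"area over [{auc_range[0]}, {auc_range[1]}]"
    else:
        raise ValueError(f"normalization mode must be 'peak' or 'auc', not {mode!r}")
    if norm <= 0:
        raise DataError(f"cannot normalize: {what} is {norm:g}")
    return replace(profile, values=profile.values / norm, normalization=mode)


def clamp_negatives(profile: Profile) -> Profile:
    """Set negative values to zero (idempotent; for plotting and AUC ratios)."""
    return replace(profile, values=np.maximum(profile.values, 0.0),
                   negatives_clamped=True)


def pooled_decile_codes(values: np.ndarray) -> np.ndarray:
    """Decile codes 1-10 over the nonzero entries of ``values`` by pooled rank.

    Ranks (stable across ties) are split into ten classes whose sizes differ
    by at most one; zero entries get code 0.  Rank-based assignment keeps the
    classes balanced even when many bins share a value.
    """
    codes = np.zeros(values.shape, dtype=np.int64)
    flat = values.ravel()
    nz = np.flatnonzero(flat)
    if nz.size == 0:
        return codes
    order = np.argsort(flat[nz], kind="stable")
    ranks = np.empty(nz.size, dtype=np.int64)
    ranks[order] = np.arange(nz.size)
    # anchored at the top so the pooled maximum always lands in class 10
    codes.ravel()[nz] = 10 - (nz.size - 1 - ranks) * 10 // nz.size
    return codes


def heatmap_normalize(matrices: StrandMatrices, bin: int = 40,
                      window: int = 4001) -> dict[str, HeatmapMatrix]:
    """Row-normalize per-hotspot signal for heatmap display, per strand.

    Signal is summed in ``bin``-bp bins across a ``window``-bp span centered
    on each hotspot, each row is divided by its window total (rows with zero
    total are left zero and flagged), and decile codes are assigned from the
    pooled nonzero normalized values of that strand.  Rows are ordered by
    descending hotspot strength.
    """
    if bin > window:
        raise ValueError(f"bin ({bin}) exceeds window ({window})")
    span = matrices.positions.size
    if window > span:
        raise DataError(f"heatmap window {window} exceeds matrix span {span}")
    half = window // 2
    start = matrices.positions.searchsorted(-half)
    n_bins = int(np.ceil(window / bin))
    edges = np.minimum(-half + bin * np.arange(n_bins + 1), -half + window)
    order = np.argsort(-matrices.strengths, kind="stable")
    out: dict[str, HeatmapMatrix] = {}
    for name, mat in (("top", matrices.top), ("bottom", matrices.bottom)):
        windowed = mat[order][:, start: start + window]
        binned = np.add.reduceat(windowed, edges[:-1] + half, axis=1)
        totals = binned.sum(axis=1)
        empty = totals == 0
        norm = np.where(empty, 1.0, totals)
        values = binned / norm[:, None]
        out[name] = HeatmapMatrix(values=values,
                                  deciles=pooled_decile_codes(values),
                                  bin_edges=edges,
                                  ids=matrices.ids[order],
                                  empty_rows=empty)
    return out


# ---------------------------------------------------------------------------
# Profile TSV round trip

_META_FIELDS = ("n_hotspots", "smoothing", "background", "normalization",
                "negatives_clamped")


def write_profile(profile: Profile, path) -> None:
    """Write a profile as TSV with a ``#`` header block recording metadata."""
    with open(path, "w") as fh:
        for name in _META_FIELDS:
            fh.write(f"# {name}={getattr(profile, name)!r}\n")
        fh.write("rel_pos\tvalue\n")
        for p, v in zip(profile.positions.tolist(), profile.values.tolist()):
            fh.write(f"{p}\t{v!r}\n")


def read_profile(path) -> Profile:
    """Read a profile TSV written by :func:`write_profile`."""
    import ast

    meta: dict = {}
    positions, values = [], []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                if key in _META_FIELDS:
                    meta[key] = ast.literal_eval(val)
                continue
            if not line or line.startswith("rel_pos"):
                continue
            p, v = line.split("\t")
            positions.append(int(p))
            values.append(float(v))
    return Profile(np.array(positions), np.array(values), **meta)
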