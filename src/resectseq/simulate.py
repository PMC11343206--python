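"""Synthetic end-capture, SSDS-coverage, and SIM-focus data with ground truth.

The endpoint simulator emulates the statistical structure of strand-specific
resection maps around meiotic DSB hotspots:

* **resected** reads: endpoints one gamma-distributed distance from the
  hotspot center, top strand to the right (rightward tracts), bottom strand
  to the left — the signal the resection-length estimators target.  The
  default gamma(13.4, 82) has mode ~1017 nt and mean ~1099 nt, the regime of
  wild-type mouse spermatocytes.
* **unresected** reads: both DSB ends sit at the cut site, so top- and
  bottom-strand reads cluster tightly at the center (Gaussian dyad jitter).
  With probability ``doublecut_prob`` the event is a SPO11 double cut: two
  or more cuts on one molecule spaced ``base + 10-nt-periodic`` apart, of
  which end capture reports only the *outermost* ends — top strand at the
  rightmost cut, bottom at the leftmost — offsetting the strand peaks.
* **intermediate** reads: recombination-intermediate signal, symmetric about
  the center with the same dispersion (the generative strand pattern of this
  class is not established; symmetry is a stand-in).
* **background** reads: uniform genome-wide on both strands.

Every recoverable parameter is recorded in a :class:`TruthRecord` so tests
can score estimator recovery against the realized draws rather than the
nominal parameters.

A second generator produces SSDS-like *coverage* (occupancy segments along
resected tracts, end-proximal for DMC1-like, end-distal for RAD51-like
factors), and a third produces 2-D fields of recombination foci on
chromosome axes for the colocalization statistics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from .io import HotspotSet, StrandedEndpointTrack, write_hotspots, write_stranded_track

__all__ = [
    "ParameterError",
    "SimParams",
    "TruthRecord",
    "FociSimParams",
    "FocusField",
    "FociTruth",
    "simulate_endpoint_dataset",
    "simulate_ssds_coverage",
    "simulate_focus_field",
    "binned_conditional_mean",
    "expected_central_ratio",
    "write_dataset",
]


class ParameterError(ValueError):
    """Simulation parameters violating their invariants."""


FRACTION_TOL = 1e-12


@dataclass(frozen=True)
class SimParams:
    """Parameters of the endpoint simulator (lengths in nt = bp).

    The mixture fractions must sum to 1; ``resection_max`` truncates the
    tract-length law above the estimators' 2.5-kb support so truncation bias
    is measurable.  ``edge_margin`` keeps hotspot centers clear of
    chromosome ends by at least the analysis window plus the longest tract.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    n_hotspots: int = 2000
    hotspot_strength_dispersion: float = 1.0
    total_reads: int = 2_000_000
    frac_resected: float = 0.65
    frac_unresected: float = 0.0
    frac_intermediate: float = 0.27
    frac_background: float = 0.08
    resection_shape: float = 13.4
    resection_scale: float = 82.0
    resection_min: float = 0.0
    resection_max: float = 3000.0
    central_sd: float = 50.0
    doublecut_prob: float = 0.0
    doublecut_spacing_base: float = 30.0
    doublecut_period: float = 10.0
    doublecut_n_periods_mean: float = 1.5
    ssds_segment_length: int = 300
    ssds_end_offset: int = 0
    edge_margin: int = 6000
    hotspot_min_spacing: int = 0

    def fractions(self) -> np.ndarray:
        return np.array([self.frac_resected, self.frac_unresected,
                         self.frac_intermediate, self.frac_background])

    def validate(self) -> None:
        f = self.fractions()
        if np.any(f < 0) or abs(f.sum() - 1.0) > FRACTION_TOL:
            raise ParameterError(f"mixture fractions {f.tolist()} must be "
                                 f"nonnegative and sum to 1")
        if self.total_reads < 0:
            raise ParameterError("total_reads must be >= 0")
        for name in ("n_chromosomes", "chrom_length", "n_hotspots"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("hotspot_strength_dispersion", "resection_shape",
                     "resection_scale", "resection_min", "resection_max",
                     "central_sd", "doublecut_spacing_base", "doublecut_period"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.doublecut_prob <= 1.0:
            raise ParameterError("doublecut_prob must be in [0, 1]")
        if self.doublecut_n_periods_mean < 1.0:
            raise ParameterError("doublecut_n_periods_mean must be >= 1")
        if 2 * self.edge_margin >= self.chrom_length:
            raise ParameterError("hotspot window (edge_margin) exceeds chromosome")
        if self.hotspot_min_spacing < 0:
            raise ParameterError("hotspot_min_spacing must be >= 0")
        usable = self.n_chromosomes * (self.chrom_length - 2 * self.edge_margin)
        if self.hotspot_min_spacing * self.n_hotspots > 0.5 * usable:
            raise ParameterError("hotspot_min_spacing too large for this "
                                 "hotspot count and genome size")

    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chromosomes)}


@dataclass
class TruthRecord:
    """Realized ground truth of one simulated endpoint dataset.

    ``resection_distances`` holds the sampled tract lengths (float nt,
    before rounding to integer coordinates) and ``doublecut_spacings`` the
    sampled cut-to-cut spacings; summary statistics are derived from these
    realized draws.  ``true_central_ratio`` is the noiseless expectation of
    the central/resection AUC statistic under the mixture, computed from the
    placement distributions.
    """

    seed: int
    class_counts: dict[str, int]
    realized_fractions: dict[str, float]
    hotspot_expected_share: np.ndarray
    resection_distances: np.ndarray
    true_conditional_mean: float
    true_mode: float
    doublecut_spacings: np.ndarray
    doublecut_spacing_mean: float
    true_central_ratio: float

    def summary_dict(self) -> dict:
        """JSON-serializable summary (distance samples reduced to bins)."""
        counts, _ = np.histogram(self.resection_distances,
                                 bins=np.arange(100, 2501, 100))
        return {
            "seed": self.seed,
            "class_counts": self.class_counts,
            "realized_fractions": self.realized_fractions,
            "resection_distance_bin_counts": counts.tolist(),
            "true_conditional_mean": self.true_conditional_mean,
            "true_mode": self.true_mode,
            "n_doublecuts": int(self.doublecut_spacings.size),
            "doublecut_spacing_mean": self.doublecut_spacing_mean,
            "true_central_ratio": self.true_central_ratio,
        }


def binned_conditional_mean(distances: np.ndarray, lo: int = 100, hi: int = 2500,
                            width: int = 100) -> float:
    """Midpoint-weighted mean of distances binned on ``[lo, hi)``.

    This is the estimand of the profile-based mean-length estimator: sampled
    distances are dropped into ``width``-nt bins and the bin-count-weighted
    midpoint mean is returned (NaN when nothing falls in range).
    """
    counts, edges = np.histogram(distances, bins=np.arange(lo, hi + 1, width))
    total = counts.sum()
    if total == 0:
        return float("nan")
    midpoints = edges[:-1] + width / 2.0
    return float((counts * midpoints).sum() / total)


def _doublecut_pmf(params: SimParams, kmax: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of the double-cut spacing law.

    spacing = base + period * k with k geometric on {1, 2, ...} and
    E[k] = doublecut_n_periods_mean.
    """
    p = 1.0 / params.doublecut_n_periods_mean
    k = np.arange(1, kmax + 1)
    pmf = p * (1 - p) ** (k - 1)
    pmf /= pmf.sum()
    return params.doublecut_spacing_base + params.doublecut_period * k, pmf


def expected_central_ratio(params: SimParams) -> float:
    """Noiseless expectation of the central/resection AUC ratio.

    Integrates each signal class's placement density over the estimator's
    windows, [-300, 100) and [100, 2500), in the co-oriented frame.
    Background is excluded (it is removed by background subtraction), and
    resected mass is renormalized for the truncation at ``resection_max``.
    """
    params.validate()
    sd = params.central_sd
    norm = stats.norm(0.0, sd) if sd > 0 else None

    def central_mass(shift: float) -> tuple[float, float]:
        # mass of shift + N(0, sd) in the central and resection windows,
        # in the co-oriented frame
        if norm is None:
            return (float(-300 <= shift < 100), float(100 <= shift < 2500))
        c = stats.norm.cdf(100, shift, sd) - stats.norm.cdf(-300, shift, sd)
        r = stats.norm.cdf(2500, shift, sd) - stats.norm.cdf(100, shift, sd)
        return c, r

    f_res, f_unres, f_inter, _ = params.fractions()
    central = resection = 0.0
    # intermediate + single-cut unresected: centered on the cut site
    c0, r0 = central_mass(0.0)
    central += (f_inter + f_unres * (1 - params.doublecut_prob)) * c0
    resection += (f_inter + f_unres * (1 - params.doublecut_prob)) * r0
    # double cuts: outermost ends at +/- spacing/2 -> co-oriented +spacing/2
    if f_unres > 0 and params.doublecut_prob > 0:
        spacings, pmf = _doublecut_pmf(params)
        for s, p in zip(spacings, pmf):
            c, r = central_mass(s / 2.0)
            central += f_unres * params.doublecut_prob * p * c
            resection += f_unres * params.doublecut_prob * p * r
    # resected: truncated shifted gamma
    if f_res > 0:
        if params.resection_scale > 0:
            g = stats.gamma(params.resection_shape, loc=params.resection_min,
                            scale=params.resection_scale)
            trunc = g.cdf(params.resection_max)
            if trunc <= 0:
                raise ParameterError("resection law has no mass below resection_max")
            central += f_res * (g.cdf(100) - g.cdf(-300)) / trunc
            resection += f_res * (g.cdf(2500) - g.cdf(100)) / trunc
        else:
            d = params.resection_min
            central += f_res * float(-300 <= d < 100)
            resection += f_res * float(100 <= d < 2500)
    if resection <= 0:
        return float("inf") if central > 0 else float("nan")
    return central / resection


def _sample_hotspots(params: SimParams, rng: np.random.Generator) -> HotspotSet:
    sizes = params.chrom_sizes()
    chroms = list(sizes)
    assignment = rng.integers(0, len(chroms), size=params.n_hotspots)
    lo, hi = params.edge_margin, params.chrom_length - params.edge_margin
    centers = rng.integers(lo, hi, size=params.n_hotspots)
    if params.hotspot_min_spacing > 0:
        # redraw centers that sit closer than the minimum spacing to an
        # already-valid neighbor on the same chromosome
        for _ in range(1000):
            order = np.lexsort((centers, assignment))
            same = assignment[order][1:] == assignment[order][:-1]
            close = np.diff(centers[order]) < params.hotspot_min_spacing
            bad = order[1:][same & close]
            if bad.size == 0:
                break
            centers[bad] = rng.integers(lo, hi, size=bad.size)
        else:
            raise ParameterError("could not place hotspots with the requested "
                                 "minimum spacing")
    strengths = rng.lognormal(mean=0.0, sigma=params.hotspot_strength_dispersion,
                              size=params.n_hotspots)
    order = np.lexsort((centers, assignment))
    return HotspotSet(
        chrom=np.array([chroms[i] for i in assignment[order]], dtype=object),
        center=centers[order],
        strength=strengths[order],
        ids=np.array([f"hs{i:05d}" for i in range(params.n_hotspots)], dtype=object),
    )


def _sample_truncated_distances(params: SimParams, n: int,
                                rng: np.random.Generator) -> np.ndarray:
    """Tract lengths ~ resection_min + gamma, resampled above resection_max."""
    if n == 0:
        return np.zeros(0)
    d = params.resection_min + rng.gamma(params.resection_shape,
                                         params.resection_scale, size=n)
    bad = np.flatnonzero(d > params.resection_max)
    while bad.size:
        d[bad] = params.resection_min + rng.gamma(params.resection_shape,
                                                  params.resection_scale,
                                                  size=bad.size)
        bad = bad[d[bad] > params.resection_max]
    return d


def simulate_endpoint_dataset(
        params: SimParams,
        rng: np.random.Generator | None = None,
) -> tuple[HotspotSet, StrandedEndpointTrack, TruthRecord]:
    """Draw one strand-specific endpoint dataset plus its ground truth.

    Reads are allocated to hotspots in proportion to strength; each read's
    class comes from the mixture and its position from the class's placement
    law (see module docstring).  Identical parameters and seed give
    byte-identical output.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    hotspots = _sample_hotspots(params, rng)
    sizes = params.chrom_sizes()
    chrom_names = np.array(list(sizes), dtype=object)

    share = hotspots.strength / hotspots.strength.sum()
    class_names = ("resected", "unresected", "intermediate", "background")
    counts = rng.multinomial(params.total_reads, params.fractions())
    class_counts = dict(zip(class_names, counts.tolist()))

    chrom_parts: list[np.ndarray] = []
    pos_parts: list[np.ndarray] = []
    strand_parts: list[np.ndarray] = []

    def emit(hot_idx: np.ndarray, offsets: np.ndarray, strands: np.ndarray) -> None:
        pos = hotspots.center[hot_idx] + np.rint(offsets).astype(np.int64)
        chrom_parts.append(hotspots.chrom[hot_idx])
        pos_parts.append(pos)
        strand_parts.append(strands)

    coin = lambda n: np.where(rng.integers(0, 2, size=n) == 1, "+", "-").astype(object)

    # resected: top at center+d, bottom at center-d, side by fair coin
    n_res = counts[0]
    distances = _sample_truncated_distances(params, n_res, rng)
    if n_res:
        h = rng.choice(len(hotspots), size=n_res, p=share)
        strands = coin(n_res)
        emit(h, np.where(strands == "+", distances, -distances), strands)

    # unresected: dyad-jittered central reads; double cuts report outermost ends
    n_unres = counts[1]
    spacings = np.zeros(0)
    if n_unres:
        h = rng.choice(len(hotspots), size=n_unres, p=share)
        strands = coin(n_unres)
        jitter = rng.normal(0.0, params.central_sd, size=n_unres)
        is_dc = rng.random(n_unres) < params.doublecut_prob
        shifts = np.zeros(n_unres)
        if is_dc.any():
            k = rng.geometric(1.0 / params.doublecut_n_periods_mean,
                              size=int(is_dc.sum()))
            spacings = params.doublecut_spacing_base + params.doublecut_period * k
            shifts[is_dc] = spacings / 2.0
        offsets = jitter + np.where(strands == "+", shifts, -shifts)
        emit(h, offsets, strands)

    # intermediate: symmetric central signal
    n_inter = counts[2]
    if n_inter:
        h = rng.choice(len(hotspots), size=n_inter, p=share)
        emit(h, rng.normal(0.0, params.central_sd, size=n_inter), coin(n_inter))

    # background: uniform genome-wide, both strands
    n_bg = counts[3]
    if n_bg:
        c = rng.integers(0, params.n_chromosomes, size=n_bg)
        chrom_parts.append(chrom_names[c])
        pos_parts.append(rng.integers(0, params.chrom_length, size=n_bg))
        strand_parts.append(coin(n_bg))

    if pos_parts:
        chrom = np.concatenate(chrom_parts)
        pos = np.clip(np.concatenate(pos_parts), 0, params.chrom_length - 1)
        strand = np.concatenate(strand_parts)
    else:
        chrom = np.zeros(0, dtype=object)
        pos = np.zeros(0, dtype=np.int64)
        strand = np.zeros(0, dtype=object)
    track = StrandedEndpointTrack.from_positions(
        sizes, chrom, pos, strand, total_reads=float(params.total_reads))

    total = max(params.total_reads, 1)
    truth = TruthRecord(
        seed=params.seed,
        class_counts=class_counts,
        realized_fractions={k: v / total for k, v in class_counts.items()},
        hotspot_expected_share=share,
        resection_distances=distances,
        true_conditional_mean=binned_conditional_mean(distances),
        true_mode=(params.resection_min
                   + max(params.resection_shape - 1.0, 0.0) * params.resection_scale),
        doublecut_spacings=spacings,
        doublecut_spacing_mean=float(spacings.mean()) if spacings.size else float("nan"),
        true_central_ratio=expected_central_ratio(params),
    )
    return hotspots, track, truth


# ---------------------------------------------------------------------------
# SSDS-like coverage

SSDS_MODES = ("end-proximal", "end-distal", "uniform")


def simulate_ssds_coverage(
        hotspots: HotspotSet, params: SimParams, mode: str,
        rng: np.random.Generator | None = None,
) -> tuple[StrandedEndpointTrack, dict]:
    """Per-base occupancy coverage of fixed-length segments on resected tracts.

    Each of ``total_reads`` tracts gets one ``ssds_segment_length``-nt
    occupancy segment: near the DSB end (``end-proximal``, DMC1-like), near
    the ssDNA/dsDNA boundary (``end-distal``, RAD51-like), or anywhere on
    the tract (``uniform``, RPA-like).  Segments longer than their tract are
    clipped to it (counted in the truth record).  Coverage keeps endpoint
    strand polarity: top-strand tracts extend rightward from the center.
    """
    params.validate()
    if mode not in SSDS_MODES:
        raise ParameterError(f"mode must be one of {SSDS_MODES}, got {mode!r}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.total_reads
    share = hotspots.strength / hotspots.strength.sum()
    d = np.rint(_sample_truncated_distances(params, n, rng)).astype(np.int64)
    d = np.maximum(d, 1)
    seg = np.minimum(params.ssds_segment_length, d)
    offset = params.ssds_end_offset
    if mode == "end-proximal":
        start = np.minimum(np.full(n, offset, dtype=np.int64), d - seg)
    elif mode == "end-distal":
        start = np.maximum(d - seg - offset, 0)
    else:
        start = rng.integers(0, np.maximum(d - seg, 0) + 1)
    start = np.maximum(start, 0)
    end = np.minimum(start + seg, d)
    n_clipped = int((seg < params.ssds_segment_length).sum())

    h = rng.choice(len(hotspots), size=n, p=share) if n else np.zeros(0, np.int64)
    top_side = rng.integers(0, 2, size=n) == 1
    sizes = params.chrom_sizes()
    chrom_names = list(sizes)
    L = params.chrom_length
    top: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    bottom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    centers = hotspots.center[h] if n else np.zeros(0, np.int64)
    for chrom in chrom_names:
        on_c = np.asarray(hotspots.chrom == chrom)
        for is_top, out in ((True, top), (False, bottom)):
            sel = np.flatnonzero(on_c[h] & (top_side == is_top)) if n \
                else np.zeros(0, np.int64)
            delta = np.zeros(L + 1)
            if sel.size:
                c = centers[sel]
                if is_top:
                    a, b = c + start[sel], c + end[sel]
                else:
                    a, b = c - end[sel] + 1, c - start[sel] + 1
                np.add.at(delta, np.clip(a, 0, L), 1.0)
                np.add.at(delta, np.clip(b, 0, L), -1.0)
            cov = np.cumsum(delta[:-1])
            nz = np.flatnonzero(cov)
            if nz.size:
                out[chrom] = (nz.astype(np.int64), cov[nz])
    track = StrandedEndpointTrack(dict(sizes), top, bottom,
                                  total_reads=float(n), units="raw")
    midpoints = (start + end) / 2.0
    truth = {
        "mode": mode,
        "n_tracts": n,
        "n_clipped": n_clipped,
        "true_mean_midpoint": float(midpoints.mean()) if n else float("nan"),
        "tract_length_mean": float(d.mean()) if n else float("nan"),
        "segment_length": params.ssds_segment_length,
    }
    return track, truth


# ---------------------------------------------------------------------------
# 2-D focus fields


@dataclass(frozen=True)
class FociSimParams:
    """Parameters of the SIM focus-field generator (all distances in nm).

    Defaults emulate the control regime: DMC1/RAD51 co-foci offset by
    ~103 nm on average (SD ~68 nm), 90% of pairs seeded on chromosome axes.
    """

    seed: int = 0
    n_axes: int = 4
    axis_waviness: float = 0.3
    axis_n_segments: int = 60
    axis_segment_length: float = 350.0
    n_cofoci: int = 1500
    interfocus_mean: float = 103.3
    interfocus_sd: float = 67.5
    frac_axis_associated: float = 0.9
    axis_jitter_sd: float = 50.0
    n_lone_fociA: int = 30
    n_lone_fociB: int = 60
    field_size: tuple[float, float] = (30000.0, 30000.0)

    def validate(self) -> None:
        if not 0.0 <= self.frac_axis_associated <= 1.0:
            raise ParameterError("frac_axis_associated must be in [0, 1]")
        for name in ("interfocus_mean", "interfocus_sd", "axis_jitter_sd",
                     "axis_segment_length"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.field_size[0] <= 0 or self.field_size[1] <= 0:
            raise ParameterError("field_size must be positive")
        for name in ("n_axes", "axis_n_segments", "n_cofoci",
                     "n_lone_fociA", "n_lone_fociB"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.n_axes == 0:
            raise ParameterError("need at least one axis")


@dataclass
class FocusField:
    """Axis polylines plus two channels of focus coordinates (nm)."""

    axes: list
    fociA: np.ndarray
    fociB: np.ndarray
    cell: str = "cell0"

    def __post_init__(self) -> None:
        self.axes = [np.asarray(a, dtype=np.float64) for a in self.axes]
        for a in self.axes:
            if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 2:
                raise ParameterError("axis polylines need >= 2 (x, y) vertices")
        self.fociA = np.asarray(self.fociA, dtype=np.float64).reshape(-1, 2)
        self.fociB = np.asarray(self.fociB, dtype=np.float64).reshape(-1, 2)
        for arr in (self.fociA, self.fociB, *self.axes):
            if not np.all(np.isfinite(arr)):
                raise ParameterError("focus/axis coordinates must be finite")


@dataclass
class FociTruth:
    """Ground truth of one simulated focus field."""

    seed: int
    pairA_index: np.ndarray       # index into fociA of each co-focus pair
    pairB_index: np.ndarray
    pair_distances: np.ndarray    # true A-B displacement length per pair, nm
    axis_seeded_A: np.ndarray     # bool per A focus: placed on an axis?
    axis_seeded_B: np.ndarray
    adjusted_interfocus_mu: float


def folded_normal_location(target_mean: float, sd: float) -> float:
    """Location mu >= 0 such that E|N(mu, sd)| equals ``target_mean``.

    Folding inflates the mean of a normal with positive location, so drawing
    pair offsets as |N(target, sd)| would overshoot; this solves for the
    corrected location (mu = target when sd = 0).  The folded mean is even
    in mu with minimum sd * sqrt(2/pi) at mu = 0, so targets below that
    floor are unattainable and mu = 0 (the closest achievable mean) is
    returned.
    """
    if sd == 0:
        return target_mean
    if target_mean <= sd * np.sqrt(2 / np.pi):
        return 0.0

    def f(mu: float) -> float:
        return (sd * np.sqrt(2 / np.pi) * np.exp(-mu ** 2 / (2 * sd ** 2))
                + mu * (1 - 2 * stats.norm.cdf(-mu / sd))) - target_mean

    return float(optimize.brentq(f, 0.0, target_mean + 10 * sd, xtol=1e-9))


def _make_axis(params: FociSimParams, rng: np.random.Generator) -> np.ndarray:
    """A smooth random polyline: a direction random walk, reflected at walls."""
    w, hgt = params.field_size
    point = rng.uniform([0.1 * w, 0.1 * hgt], [0.9 * w, 0.9 * hgt])
    theta = rng.uniform(0, 2 * np.pi)
    vertices = [point.copy()]
    for _ in range(params.axis_n_segments):
        theta += params.axis_waviness * rng.normal()
        step = params.axis_segment_length * np.array([np.cos(theta), np.sin(theta)])
        nxt = vertices[-1] + step
        # reflect at the field boundary
        for dim, limit in ((0, w), (1, hgt)):
            if nxt[dim] < 0 or nxt[dim] > limit:
                nxt[dim] = np.clip(2 * np.clip(nxt[dim], 0, limit) - nxt[dim],
                                   0, limit)
                theta = np.pi - theta if dim == 0 else -theta
        vertices.append(nxt)
    return np.array(vertices)


def _point_on_axes(axes: list, rng: np.random.Generator, n: int) -> np.ndarray:
    """n points drawn arc-length-uniformly over all axis segments."""
    starts, ends = [], []
    for ax in axes:
        starts.append(ax[:-1])
        ends.append(ax[1:])
    a = np.concatenate(starts)
    b = np.concatenate(ends)
    lengths = np.linalg.norm(b - a, axis=1)
    probs = lengths / lengths.sum()
    seg = rng.choice(len(lengths), size=n, p=probs)
    t = rng.random(n)[:, None]
    return a[seg] + t * (b[seg] - a[seg])


def simulate_focus_field(
        params: FociSimParams,
        rng: np.random.Generator | None = None,
) -> tuple[FocusField, FociTruth]:
    """Generate one 2-D focus field with axes, co-foci, and lone foci.

    Co-focus pairs place an A focus at an axis point (probability
    ``frac_axis_associated``, with Gaussian placement jitter) or uniformly
    in the field, then a B focus one folded-normal distance away in a
    uniform direction.  Lone foci in either channel are uniform in the
    field.  The truth records per-focus axis-seeding labels and the true
    pair displacement lengths.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    axes = [_make_axis(params, rng) for _ in range(params.n_axes)]
    w, hgt = params.field_size

    n = params.n_cofoci
    on_axis = rng.random(n) < params.frac_axis_associated
    a_points = np.empty((n, 2))
    if on_axis.any():
        pts = _point_on_axes(axes, rng, int(on_axis.sum()))
        if params.axis_jitter_sd > 0:
            pts = pts + rng.normal(0, params.axis_jitter_sd, size=pts.shape)
        a_points[on_axis] = pts
    if (~on_axis).any():
        a_points[~on_axis] = rng.uniform([0, 0], [w, hgt],
                                         size=(int((~on_axis).sum()), 2))
    mu = folded_normal_location(params.interfocus_mean, params.interfocus_sd)
    r = np.abs(rng.normal(mu, params.interfocus_sd, size=n)) \
        if params.interfocus_sd > 0 else np.full(n, abs(mu))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    b_points = a_points + r[:, None] * np.column_stack([np.cos(theta),
                                                        np.sin(theta)])

    loneA = rng.uniform([0, 0], [w, hgt], size=(params.n_lone_fociA, 2))
    loneB = rng.uniform([0, 0], [w, hgt], size=(params.n_lone_fociB, 2))
    fociA = np.vstack([a_points, loneA])
    fociB = np.vstack([b_points, loneB])
    field = FocusField(axes=axes, fociA=fociA, fociB=fociB)
    truth = FociTruth(
        seed=params.seed,
        pairA_index=np.arange(n),
        pairB_index=np.arange(n),
        pair_distances=r,
        axis_seeded_A=np.concatenate([on_axis,
                                      np.zeros(params.n_lone_fociA, bool)]),
        axis_seeded_B=np.concatenate([on_axis,
                                      np.zeros(params.n_lone_fociB, bool)]),
        adjusted_interfocus_mu=mu,
    )
    return field, truth


# ---------------------------------------------------------------------------
# Dataset export


def write_dataset(outdir: str | Path, hotspots: HotspotSet,
                  track: StrandedEndpointTrack, truth: TruthRecord) -> dict:
    """Write bedGraphs, hotspot BED, chrom.sizes, truth JSON, and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "top": outdir / "endpoints_top.bedgraph",
        "bottom": outdir / "endpoints_bottom.bedgraph",
        "hotspots": outdir / "hotspots.bed",
        "chrom_sizes": outdir / "chrom.sizes",
        "truth": outdir / "truth.json",
    }
    write_stranded_track(track, paths["top"], paths["bottom"])
    write_hotspots(hotspots, paths["hotspots"])
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in track.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(truth.summary_dict(), fh, indent=2)
        fh.write("\n")
    manifest = {"files": {}}
    for key, path in paths.items():
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["files"][key] = {"path": path.name, "sha256": digest}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest
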