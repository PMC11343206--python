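"""Scalar resection statistics computed from genome-average profiles.

Four quantities summarize a resection map:

* **mean resection length** — the background-subtracted, co-oriented signal
  between 100 bp and 2.5 kb is split into 24 contiguous 100-nt bins; the
  fraction of total signal per bin, times the bin midpoint, gives the mean
  tract length in nucleotides.
* **modal resection length** — the argmax of the Hann-smoothed profile over
  the same 100-2500 bp range.
* **central-to-resection AUC ratio** — signal from recombination
  intermediates / unresected breaks (area from -300 to +100 bp) relative to
  signal from resection endpoints (area from +100 to +2500 bp).
* **strand center offset** — the signed distance between the top- and
  bottom-strand central peaks; a positive offset (top right of bottom) is the
  signature of SPO11 double cutting, where only the outermost DSB ends are
  captured.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import DataError
from .profiles import Profile, clamp_negatives, hann_smooth

__all__ = [
    "ResectionSummary",
    "RESECTION_RANGE",
    "CENTRAL_RANGE",
    "BIN_WIDTH",
    "mean_resection_length",
    "modal_resection_length",
    "central_to_resection_ratio",
    "profile_auc",
    "strand_center_offset",
    "summarize_profiles",
    "compare_summaries",
]

RESECTION_RANGE = (100, 2500)   # half-open, nt from hotspot center
CENTRAL_RANGE = (-300, 100)     # half-open
BIN_WIDTH = 100                 # nt
NO_RESECTION_FLAG = "no-resection-signal"
NO_CENTRAL_FLAG = "no-central-peak"
NO_OFFSET_FLAG = "no-central-signal"

# Fraction of total signal below which the resection window is treated as
# empty (NA + flag).  The detection test uses raw background-subtracted
# sums, where sampling noise is mean-zero; clamping first would rectify
# noise into apparent window signal and make detection depth-dependent.
# Genuine resection puts a majority of signal in [100, 2500) while pure
# central (unresected) signal leaks only a few percent past +100 bp.
MIN_RESECTION_SIGNAL_FRACTION = 0.05


def _require_span(profile: Profile, lo: int, hi: int) -> None:
    if profile.positions[0] > lo or profile.positions[-1] < hi:
        raise DataError(f"profile span [{profile.positions[0]}, "
                        f"{profile.positions[-1]}] does not cover [{lo}, {hi}]")


def _check_subtracted(profile: Profile) -> None:
    if profile.background is None:
        raise DataError("profile must be background-subtracted first")


def mean_resection_length(profile: Profile) -> tuple[float, np.ndarray, list[str]]:
    """Mean resection tract length from 100-nt signal fractions.

    Expects a background-subtracted, co-oriented, *unsmoothed* profile.
    Negatives are clamped before summation (negative weights would make the
    weighted mean ill-defined).  Signal outside [100, 2500) is zeroed; the
    24 bin fractions and the midpoint-weighted mean are returned, with NaN
    and the ``no-resection-signal`` flag when the resection window holds no
    appreciable signal.  The no-signal test uses raw (unclamped) sums so
    that mean-zero sampling noise cannot masquerade as resection signal.
    """
    _check_subtracted(profile)
    if profile.smoothing:
        raise DataError("mean resection length is computed on unsmoothed profiles")
    _require_span(profile, 0, RESECTION_RANGE[1])
    clamped = clamp_negatives(profile)
    window = clamped.slice(*RESECTION_RANGE)
    n_bins = (RESECTION_RANGE[1] - RESECTION_RANGE[0]) // BIN_WIDTH
    bin_sums = window.reshape(n_bins, BIN_WIDTH).sum(axis=1)
    total = bin_sums.sum()
    raw_window = float(profile.slice(*RESECTION_RANGE).sum())
    raw_total = float(profile.values.sum())
    if total <= 0 or raw_window <= 0 or (
            raw_total > 0
            and raw_window < MIN_RESECTION_SIGNAL_FRACTION * raw_total):
        return math.nan, np.full(n_bins, np.nan), [NO_RESECTION_FLAG]
    fractions = bin_sums / total
    midpoints = RESECTION_RANGE[0] + BIN_WIDTH // 2 + BIN_WIDTH * np.arange(n_bins)
    return float(fractions @ midpoints), fractions, []


def modal_resection_length(profile: Profile, smooth: int = 151) -> tuple[float, list[str]]:
    """Peak position of the smoothed genome-average profile on [100, 2500].

    The profile is background-subtracted; Hann smoothing with ``smooth`` bp
    is applied here (pass ``smooth=1`` for none).  Ties break toward the
    smallest position.  NaN + flag when the range holds no positive signal.
    """
    _check_subtracted(profile)
    _require_span(profile, *RESECTION_RANGE)
    smoothed = hann_smooth(profile, smooth) if smooth > 1 else profile
    lo, hi = RESECTION_RANGE
    window = smoothed.slice(lo, hi, inclusive=True)
    if window.max() <= 0:
        return math.nan, [NO_RESECTION_FLAG]
    return float(lo + int(np.argmax(window))), []


def central_to_resection_ratio(profile: Profile) -> tuple[float, list[str]]:
    """AUC of the central peak (-300..+100) over the resection peak (+100..+2500).

    Windows are half-open so +100 belongs to the resection side exactly
    once.  Negatives are clamped; the ratio is NaN + flag when the resection
    AUC is zero.
    """
    _check_subtracted(profile)
    _require_span(profile, CENTRAL_RANGE[0], RESECTION_RANGE[1])
    clamped = clamp_negatives(profile)
    central = float(clamped.slice(*CENTRAL_RANGE).sum())
    resection = float(clamped.slice(*RESECTION_RANGE).sum())
    if resection <= 0:
        return math.nan, [NO_RESECTION_FLAG]
    return central / resection, []


def profile_auc(profile: Profile, lo: int = -1500, hi: int = 2500) -> float:
    """Per-bp sum over ``[lo, hi]`` inclusive (signal-level comparisons)."""
    if lo >= hi:
        raise ValueError(f"lo ({lo}) must be < hi ({hi})")
    _require_span(profile, lo, hi)
    return float(profile.slice(lo, hi, inclusive=True).sum())


def _argmax_smallest_magnitude(values: np.ndarray, positions: np.ndarray) -> int:
    """Peak position; among ties, the one closest to zero (then leftmost)."""
    peak = values.max()
    candidates = positions[np.isclose(values, peak, rtol=0, atol=0)]
    order = np.lexsort((candidates, np.abs(candidates)))
    return int(candidates[order[0]])


def strand_center_offset(top: Profile, bottom: Profile, search: int = 400,
                         smooth: int = 51,
                         method: str = "peak") -> tuple[float, list[str]]:
    """Signed top-minus-bottom central peak offset, in bp.

    Operates on genome-average *strand-specific* (not co-oriented),
    background-subtracted profiles.  Both are Hann-smoothed with ``smooth``
    bp, then the argmax of each within ``[-search, +search]`` is located
    (ties resolve toward the smallest magnitude).  A positive offset — the
    top-strand peak right of the bottom-strand peak — is the double-cut
    signature.  ``method='xcorr'`` instead reports the cross-correlation lag
    maximizing the alignment of the two strand profiles.
    """
    for p in (top, bottom):
        _check_subtracted(p)
        _require_span(p, -search, search)
    top_s = hann_smooth(top, smooth) if smooth > 1 else top
    bottom_s = hann_smooth(bottom, smooth) if smooth > 1 else bottom
    t = top_s.slice(-search, search, inclusive=True)
    b = bottom_s.slice(-search, search, inclusive=True)
    if t.max() <= 0 or b.max() <= 0:
        return math.nan, [NO_OFFSET_FLAG]
    if method == "peak":
        pos = np.arange(-search, search + 1)
        return float(_argmax_smallest_magnitude(t, pos)
                     - _argmax_smallest_magnitude(b, pos)), []
    if method == "xcorr":
        t0, b0 = t - t.mean(), b - b.mean()
        corr = np.correlate(t0, b0, mode="full")
        lags = np.arange(-(len(b0) - 1), len(t0))
        peak = corr.max()
        ties = lags[np.isclose(corr, peak, rtol=0, atol=0)]
        order = np.lexsort((ties, np.abs(ties)))
        return float(ties[order[0]]), []
    raise ValueError(f"method must be 'peak' or 'xcorr', not {method!r}")


@dataclass
class ResectionSummary:
    """All scalar statistics for one genotype/condition."""

    mean_length: float
    modal_length: float
    central_ratio: float
    auc: float
    strand_offset: float
    bin_fractions: list
    n_hotspots: int
    flags: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @staticmethod
    def from_json(path) -> "ResectionSummary":
        with open(path) as fh:
            return ResectionSummary(**json.load(fh))


def summarize_profiles(oriented: Profile, top: Profile | None = None,
                       bottom: Profile | None = None,
                       modal_smooth: int = 151,
                       offset_smooth: int = 51) -> ResectionSummary:
    """Compute every summary statistic from background-subtracted profiles.

    ``oriented`` must be the unsmoothed co-oriented average; ``top`` and
    ``bottom`` (optional) are the strand-specific averages for the
    double-cut offset.
    """
    mean_len, fractions, flags = mean_resection_length(oriented)
    modal_len, f2 = modal_resection_length(oriented, smooth=modal_smooth)
    ratio, f3 = central_to_resection_ratio(oriented)
    auc = profile_auc(oriented)
    if top is not None and bottom is not None:
        offset, f4 = strand_center_offset(top, bottom, smooth=offset_smooth)
    else:
        offset, f4 = math.nan, []
    all_flags = sorted(set(flags) | set(f2) | set(f3) | set(f4))
    return ResectionSummary(mean_length=mean_len, modal_length=modal_len,
                            central_ratio=ratio, auc=auc, strand_offset=offset,
                            bin_fractions=[float(x) for x in np.atleast_1d(fractions)],
                            n_hotspots=oriented.n_hotspots, flags=all_flags)


def compare_summaries(summaries: list[tuple[str, ResectionSummary]]) -> pd.DataFrame:
    """Pairwise differences of the scalar metrics across conditions.

    Returns one row per ordered pair with the difference and the
    percent-of-reference for each metric; NaN metrics propagate.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two summaries to compare")
    rows = []
    for i, (ref_label, ref) in enumerate(summaries):
        for label, s in summaries[i + 1:]:
            row: dict = {"reference": ref_label, "condition": label}
            for metric in ("mean_length", "modal_length", "central_ratio"):
                a, b = getattr(ref, metric), getattr(s, metric)
                row[f"{metric}_diff"] = b - a
                row[f"{metric}_pct_of_ref"] = (100.0 * b / a) if a else math.nan
            rows.append(row)
    return pd.DataFrame(rows)
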