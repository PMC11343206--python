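"""Readers and writers for hotspot sets and strand-specific endpoint tracks.

End-capture resection sequencing (S1-seq, Exo7/T-seq) reports, for every
sequenced molecule, the single nucleotide adjacent to the ligated adaptor:
a per-base count track on each strand of the reference.  This module holds
the two container types the rest of the pipeline consumes —
:class:`HotspotSet` (DSB hotspot centers with strengths, the coordinate
frame for all metaplots) and :class:`StrandedEndpointTrack` (sparse
per-base, per-strand endpoint counts) — plus parsers for the plain-text
formats they travel in (5-column BED, per-strand bedGraph, two-column
chrom.sizes, and a tab-delimited alignment-endpoint table).

Coordinates are 0-based half-open throughout, matching BED/bedGraph.
"Top strand" is the reference forward strand; a top-strand endpoint to the
right of a hotspot center marks a rightward-moving resection tract.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "DataError",
    "HotspotSet",
    "StrandedEndpointTrack",
    "read_chrom_sizes",
    "read_hotspots",
    "write_hotspots",
    "read_stranded_track",
    "write_stranded_track",
    "endpoints_from_alignments",
]


class ParseError(ValueError):
    """A malformed line in an input file (message names the file and line)."""


class DataError(ValueError):
    """Input values that parse but violate the data contract."""


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file into an ordered dict."""
    sizes: dict[str, int] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'chrom length', got {raw!r}")
        try:
            length = int(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer length {parts[1]!r}") from exc
        if length <= 0:
            raise ParseError(f"{path}:{lineno}: non-positive chromosome length")
        sizes[parts[0]] = length
    if not sizes:
        raise ParseError(f"{path}: no chromosome records")
    return sizes


# ---------------------------------------------------------------------------
# Hotspots


@dataclass
class HotspotSet:
    """DSB hotspot centers with strengths.

    Parameters
    ----------
    chrom, center, strength, ids
        Parallel arrays; ``center`` is the 0-based midpoint of the hotspot
        interval and ``strength`` an arbitrary-unit activity score (for the
        mouse B6 map, SPO11-oligo counts).
    """

    chrom: np.ndarray
    center: np.ndarray
    strength: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.center = np.asarray(self.center, dtype=np.int64)
        self.strength = np.asarray(self.strength, dtype=np.float64)
        self.ids = np.asarray(self.ids, dtype=object)
        n = len(self.chrom)
        if not (len(self.center) == len(self.strength) == len(self.ids) == n):
            raise DataError("hotspot fields have mismatched lengths")
        if np.any(self.strength < 0):
            raise DataError("hotspot strengths must be >= 0")
        if len(set(self.ids.tolist())) != n:
            raise DataError("hotspot ids must be unique")

    def __len__(self) -> int:
        return len(self.center)

    @property
    def strength_order(self) -> np.ndarray:
        """Indices sorting hotspots by descending strength (stable)."""
        return np.argsort(-self.strength, kind="stable")

    def subset(self, idx: np.ndarray) -> "HotspotSet":
        return HotspotSet(self.chrom[idx], self.center[idx],
                          self.strength[idx], self.ids[idx])


def read_hotspots(path: str | Path) -> HotspotSet:
    """Parse a 5-column BED (chrom, start, end, name, score) into a HotspotSet.

    The hotspot center is ``floor((start + end) / 2)`` and the strength is
    the BED score.  Malformed lines raise :class:`ParseError` naming the line.
    """
    chroms, centers, strengths, names = [], [], [], []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise ParseError(f"{path}:{lineno}: expected 5 BED columns, got {len(parts)}")
        try:
            start, end = int(parts[1]), int(parts[2])
            score = float(parts[4])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric coordinate or score") from exc
        if start < 0 or start >= end:
            raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        if score < 0:
            raise ParseError(f"{path}:{lineno}: negative score")
        chroms.append(parts[0])
        centers.append((start + end) // 2)
        strengths.append(score)
        names.append(parts[3])
    if not chroms:
        raise ParseError(f"{path}: no hotspot records")
    return HotspotSet(np.array(chroms, dtype=object), np.array(centers),
                      np.array(strengths), np.array(names, dtype=object))


def write_hotspots(hotspots: HotspotSet, path: str | Path, half_width: int = 500) -> None:
    """Write hotspots as 5-column BED with symmetric ``half_width`` intervals."""
    with open(path, "w") as fh:
        for c, p, s, name in zip(hotspots.chrom, hotspots.center,
                                 hotspots.strength, hotspots.ids):
            start = max(0, int(p) - half_width)
            fh.write(f"{c}\t{start}\t{int(p) + half_width}\t{name}\t{s:g}\n")


# ---------------------------------------------------------------------------
# Stranded endpoint tracks


@dataclass
class StrandedEndpointTrack:
    """Sparse per-base read-endpoint counts on each strand.

    ``top`` and ``bottom`` map chromosome name to ``(positions, counts)``
    pairs of aligned arrays with positions sorted and unique.  ``total_reads``
    is the library's mapped-read total used for RPM scaling (defaults to the
    in-track sum), and ``units`` records whether values are raw counts or RPM.
    """

    chrom_sizes: dict[str, int]
    top: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    bottom: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    total_reads: float | None = None
    units: str = "raw"

    def __post_init__(self) -> None:
        for strand in (self.top, self.bottom):
            for chrom, (pos, cnt) in strand.items():
                if chrom not in self.chrom_sizes:
                    raise DataError(f"unknown chromosome {chrom!r} in track")
                pos = np.asarray(pos, dtype=np.int64)
                cnt = np.asarray(cnt, dtype=np.float64)
                if pos.size and (pos.min() < 0 or pos.max() >= self.chrom_sizes[chrom]):
                    raise DataError(f"positions outside {chrom} bounds")
                if np.any(cnt < 0):
                    raise DataError(f"negative counts on {chrom}")
                strand[chrom] = (pos, cnt)
        if self.total_reads is None:
            self.total_reads = self.sum()

    def strand(self, name: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if name not in ("top", "bottom"):
            raise ValueError(f"strand must be 'top' or 'bottom', not {name!r}")
        return self.top if name == "top" else self.bottom

    def sum(self) -> float:
        return float(sum(cnt.sum() for strand in (self.top, self.bottom)
                         for _, cnt in strand.values()))

    def window(self, chrom: str, start: int, end: int, strand: str) -> np.ndarray:
        """Dense per-base values over ``[start, end)`` (zero-padded at edges)."""
        out = np.zeros(end - start, dtype=np.float64)
        data = self.strand(strand).get(chrom)
        if data is None:
            return out
        pos, cnt = data
        lo, hi = np.searchsorted(pos, [start, end])
        out[pos[lo:hi] - start] = cnt[lo:hi]
        return out

    def dense(self, chrom: str, strand: str) -> np.ndarray:
        """Whole-chromosome dense per-base array (use per chromosome only)."""
        return self.window(chrom, 0, self.chrom_sizes[chrom], strand)

    def to_rpm(self) -> "StrandedEndpointTrack":
        """Scale counts to reads per million mapped reads.

        Scaling by ``1e6 / total_reads`` preserves per-strand proportions and
        makes the in-track sum equal ``1e6 * in_track / total_reads``.
        """
        if self.units == "rpm":
            return self
        if not self.total_reads or self.total_reads <= 0:
            raise DataError("cannot convert to RPM: total_reads is zero or unset")
        f = 1e6 / self.total_reads
        scale = lambda d: {c: (p.copy(), v * f) for c, (p, v) in d.items()}
        return StrandedEndpointTrack(dict(self.chrom_sizes), scale(self.top),
                                     scale(self.bottom), self.total_reads, "rpm")

    @staticmethod
    def from_positions(chrom_sizes: Mapping[str, int],
                       chrom: np.ndarray, pos: np.ndarray, strand: np.ndarray,
                       total_reads: float | None = None) -> "StrandedEndpointTrack":
        """Accumulate per-read endpoint records into a sparse track."""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        strand = np.asarray(strand)
        top: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        bottom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for c in chrom_sizes:
            on_c = chrom == c
            for is_top, target in ((True, top), (False, bottom)):
                sel = on_c & (strand == ("+" if is_top else "-"))
                if not np.any(sel):
                    continue
                upos, cnt = np.unique(pos[sel], return_counts=True)
                target[c] = (upos, cnt.astype(np.float64))
        return StrandedEndpointTrack(dict(chrom_sizes), top, bottom, total_reads)


def _read_bedgraph(path: str | Path, chrom_sizes: Mapping[str, int],
                   integer_counts: bool) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    per_chrom: dict[str, tuple[list, list]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
        chrom = parts[0]
        try:
            start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric field") from exc
        if chrom not in chrom_sizes:
            raise DataError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if start < 0 or start >= end or end > chrom_sizes[chrom]:
            raise DataError(f"{path}:{lineno}: interval [{start}, {end}) outside "
                            f"{chrom} (length {chrom_sizes[chrom]})")
        if value < 0:
            raise DataError(f"{path}:{lineno}: negative value {value}")
        if integer_counts and value != int(value):
            raise DataError(f"{path}:{lineno}: non-integer raw count {value}")
        acc = per_chrom.setdefault(chrom, ([], []))
        # Expand interval to per-base records; bedGraph is half-open.
        acc[0].append(np.arange(start, end, dtype=np.int64))
        acc[1].append(np.full(end - start, value))
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, (plist, vlist) in per_chrom.items():
        pos = np.concatenate(plist)
        val = np.concatenate(vlist)
        upos, inverse = np.unique(pos, return_inverse=True)
        acc_val = np.zeros(upos.size)
        np.add.at(acc_val, inverse, val)
        keep = acc_val != 0
        out[chrom] = (upos[keep], acc_val[keep])
    return out


def read_stranded_track(top_path: str | Path, bottom_path: str | Path,
                        chrom_sizes: Mapping[str, int], *,
                        units: str = "raw",
                        total_reads: float | None = None) -> StrandedEndpointTrack:
    """Read a per-strand bedGraph pair into a :class:`StrandedEndpointTrack`.

    Multi-base intervals are expanded to per-base counts.  Raw tracks are
    validated as integers; set ``units='rpm'`` to accept float values.
    """
    integer = units == "raw"
    top = _read_bedgraph(top_path, chrom_sizes, integer)
    bottom = _read_bedgraph(bottom_path, chrom_sizes, integer)
    return StrandedEndpointTrack(dict(chrom_sizes), top, bottom, total_reads, units)


def write_stranded_track(track: StrandedEndpointTrack,
                         top_path: str | Path, bottom_path: str | Path) -> None:
    """Write single-base bedGraph lines per strand (bit-exact round trip)."""
    for strand, path in (("top", top_path), ("bottom", bottom_path)):
        with open(path, "w") as fh:
            data = track.strand(strand)
            for chrom in track.chrom_sizes:
                if chrom not in data:
                    continue
                pos, cnt = data[chrom]
                buf = _stdio.StringIO()
                for p, v in zip(pos.tolist(), cnt.tolist()):
                    buf.write(f"{chrom}\t{p}\t{p + 1}\t{v:g}\n")
                fh.write(buf.getvalue())


def endpoints_from_alignments(table: str | Path | pd.DataFrame,
                              chrom_sizes: Mapping[str, int],
                              mapq_min: int = 20) -> StrandedEndpointTrack:
    """Build a track from an alignment-endpoint table, dropping MAPQ < ``mapq_min``.

    The table (path to a tab-delimited file with header
    ``chrom  pos  strand  mapq``, or an equivalent DataFrame) carries the
    already-computed biotin-adjacent endpoint of each deduplicated read,
    0-based, with strand ``+`` (top) or ``-`` (bottom).  The retained row
    count becomes the track's ``total_reads``.
    """
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table, sep="\t")
    else:
        df = table.copy()
    required = {"chrom", "pos", "strand", "mapq"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"alignment table missing columns: {sorted(missing)}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ParseError(f"alignment table has invalid strand values: "
                         f"{sorted(df.loc[bad_strand, 'strand'].unique())}")
    unknown = sorted(set(df["chrom"]) - set(chrom_sizes))
    if unknown:
        raise DataError(f"alignment table references unknown chromosomes: {unknown}")
    kept = df[df["mapq"] >= mapq_min]
    pos = kept["pos"].to_numpy(dtype=np.int64)
    if pos.size:
        lengths = kept["chrom"].map(dict(chrom_sizes)).to_numpy()
        if (pos < 0).any() or (pos >= lengths).any():
            raise DataError("alignment endpoints outside chromosome bounds")
    return StrandedEndpointTrack.from_positions(
        chrom_sizes, kept["chrom"].to_numpy(dtype=object), pos,
        kept["strand"].to_numpy(), total_reads=float(len(kept)))
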