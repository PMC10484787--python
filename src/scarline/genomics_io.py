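"""Interval and track data model shared by every stage of the pipeline.

Coordinates are 0-based half-open everywhere internally (BED-native);
1-based closed GTF-like input is converted at the format boundary.
Missing track values are NaN and are distinct from zero: zero coverage
and "no data" mean different things in partition arithmetic.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "WindowGrid",
    "Track",
    "ParseError",
    "LayoutError",
    "EmptyStratumError",
    "intervals",
    "validate_intervals",
    "make_windows",
    "read_bed",
    "write_bed",
    "read_gtf_like",
    "read_intervals",
    "read_bedgraph",
    "track_from_bedgraph",
    "write_bedgraph",
    "overlap_windows",
    "window_overlap_bp",
    "stratify_by_timing",
]


class ParseError(ValueError):
    """A file did not parse under the declared dialect."""


class LayoutError(ValueError):
    """Chromosome names or coordinates disagree with the genome layout."""


class EmptyStratumError(ValueError):
    """A stratification produced no usable windows."""


INTERVAL_COLUMNS = ("chrom", "start", "end", "name", "strand")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered (chromosome, length-in-bp) pairs defining the toy genome."""

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise LayoutError("chromosome names must be unique")
        for name, length in self.chroms:
            if int(length) <= 0:
                raise LayoutError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GenomeLayout":
        return cls(tuple((str(k), int(v)) for k, v in d.items()))

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chroms]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: int(n) for c, n in self.chroms}

    @property
    def total_bp(self) -> int:
        return sum(n for _, n in self.chroms)


def intervals(chrom, start, end, name=None, strand=None) -> pd.DataFrame:
    """Build a validated interval table from columnar inputs."""
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
        }
    )
    df["name"] = "." if name is None else np.asarray(name, dtype=object)
    df["strand"] = "." if strand is None else np.asarray(strand, dtype=object)
    return validate_intervals(df)


def validate_intervals(df: pd.DataFrame, layout: GenomeLayout | None = None) -> pd.DataFrame:
    df = df.copy()
    for col, default in (("name", "."), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    if (df["end"] <= df["start"]).any():
        bad = df.index[(df["end"] <= df["start"])][0]
        raise ParseError(f"interval at row {bad}: end <= start")
    if (df["start"] < 0).any():
        raise ParseError("negative start coordinate")
    if not df["strand"].isin(["+", "-", "."]).all():
        raise ParseError("strand must be one of '+', '-', '.'")
    if layout is not None:
        lengths = layout.lengths
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in lengths:
                raise LayoutError(f"chromosome {chrom!r} not in layout")
            if (sub["end"] > lengths[chrom]).any():
                raise LayoutError(f"interval beyond end of {chrom}")
    return df


@dataclass
class WindowGrid:
    """Ordered, per-chromosome tiling windows (trailing remainders kept, flagged)."""

    layout: GenomeLayout
    size: int
    step: int
    windows: pd.DataFrame = field(repr=False)

    _ranges: dict[str, tuple[int, int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._ranges:
            chroms = self.windows["chrom"].to_numpy()
            for chrom in self.layout.names:
                idx = np.flatnonzero(chroms == chrom)
                if idx.size:
                    self._ranges[chrom] = (int(idx[0]), int(idx[-1]) + 1)

    @property
    def n(self) -> int:
        return len(self.windows)

    def index_range(self, chrom: str) -> tuple[int, int]:
        return self._ranges.get(chrom, (0, 0))

    def centers(self) -> np.ndarray:
        w = self.windows
        return (w["start"].to_numpy() + w["end"].to_numpy()) / 2.0

    @property
    def truncated(self) -> np.ndarray:
        return self.windows["truncated"].to_numpy()


@dataclass
class Track:
    """Per-window numeric values aligned to a grid; NaN marks missing."""

    grid: WindowGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n,):
            raise LayoutError(
                f"track has {self.values.shape[0]} values for a grid of {self.grid.n} windows"
            )


def make_windows(layout: GenomeLayout, size: int, step: int | None = None) -> WindowGrid:
    """Tile every chromosome left-to-right with fixed-size windows.

    A trailing remainder shorter than ``size`` is emitted as a final truncated
    window (flagged in the ``truncated`` column) rather than dropped, so the
    grid covers every base exactly once when ``step == size``.
    """
    step = size if step is None else step
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    chroms, starts, ends = [], [], []
    for chrom, length in layout.chroms:
        s = np.arange(0, length, step, dtype=np.int64)
        e = np.minimum(s + size, length)
        keep = e > s
        chroms.extend([chrom] * int(keep.sum()))
        starts.append(s[keep])
        ends.append(e[keep])
    starts = np.concatenate(starts) if starts else np.array([], dtype=np.int64)
    ends = np.concatenate(ends) if ends else np.array([], dtype=np.int64)
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chroms, dtype=object),
            "start": starts,
            "end": ends,
            "truncated": (ends - starts) < size,
        }
    )
    return WindowGrid(layout=layout, size=size, step=step, windows=df)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_bed(path) -> pd.DataFrame:
    """Read a 3-6 column BED file (0-based half-open, strand '.' = unstranded)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ParseError(f"{path}: line {lineno}: end <= start")
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ParseError(f"{path}: line {lineno}: bad strand {strand!r}")
            rows.append((parts[0], start, end, name, strand))
    return pd.DataFrame(rows, columns=list(INTERVAL_COLUMNS))


def write_bed(df: pd.DataFrame, path) -> None:
    df = validate_intervals(df)
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t0\t{row.strand}\n")


def read_gtf_like(path, attributes: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Read a tab-separated GTF-like annotation (1-based closed -> 0-based half-open).

    The 9th column is parsed for ``key "value"`` attributes; requested keys (or
    all found keys, by default) become columns.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ParseError(f"{path}: line {lineno}: fewer than 8 GTF columns")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if end < start:
                raise ParseError(f"{path}: line {lineno}: end < start")
            attrs = dict(_GTF_ATTR_RE.findall(parts[8])) if len(parts) > 8 else {}
            strand = parts[6] if parts[6] in ("+", "-") else "."
            rows.append((parts[0], start - 1, end, parts[2], strand, attrs))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "feature", "strand", "_attrs"])
    keys: list[str]
    if attributes is None:
        keys = sorted({k for a in df["_attrs"] for k in a})
    else:
        keys = list(attributes)
    for key in keys:
        df[key] = [a.get(key) for a in df["_attrs"]]
    return df.drop(columns="_attrs")


def read_intervals(path, format: str = "bed") -> pd.DataFrame:
    if format == "bed":
        return read_bed(path)
    if format in ("gtf", "gtf-like"):
        return read_gtf_like(path)
    raise ValueError(f"unknown interval format {format!r}")


def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}: line {lineno}: fewer than 4 bedGraph columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: malformed record") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def track_from_bedgraph(source, grid: WindowGrid) -> Track:
    """Project bedGraph records onto a grid by coverage-weighted averaging.

    Windows not covered by any record get NaN (missing), never zero.
    """
    df = read_bedgraph(source) if not isinstance(source, pd.DataFrame) else source
    cov = np.zeros(grid.n)
    wsum = np.zeros(grid.n)
    _project(grid, df, cov, wsum)
    with np.errstate(invalid="ignore"):
        values = np.where(cov > 0, wsum / np.where(cov > 0, cov, 1.0), np.nan)
    return Track(grid=grid, values=values)


def write_bedgraph(track: Track, path) -> None:
    w = track.grid.windows
    with open(path, "w") as fh:
        for chrom, start, end, value in zip(
            w["chrom"], w["start"], w["end"], track.values
        ):
            if np.isnan(value):
                continue
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# window arithmetic
# ---------------------------------------------------------------------------


def _project(grid: WindowGrid, feats: pd.DataFrame, cov: np.ndarray, wsum: np.ndarray | None) -> None:
    """Accumulate per-window overlap bp (and value-weighted sums) for features."""
    values = feats["value"].to_numpy() if (wsum is not None and "value" in feats) else None
    for chrom, sub in feats.groupby("chrom", sort=False):
        lo, hi = grid.index_range(chrom)
        if hi <= lo:
            if chrom not in grid.layout.lengths:
                raise LayoutError(f"feature chromosome {chrom!r} not on grid layout")
            continue
        starts = grid.windows["start"].to_numpy()[lo:hi]
        ends = grid.windows["end"].to_numpy()[lo:hi]
        for pos, (s, e) in zip(sub.index, zip(sub["start"], sub["end"])):
            i0 = int(np.searchsorted(ends, s, side="right"))
            i1 = int(np.searchsorted(starts, e, side="left"))
            if i1 <= i0:
                continue
            ov = np.minimum(ends[i0:i1], e) - np.maximum(starts[i0:i1], s)
            ov = np.clip(ov, 0, None)
            cov[lo + i0 : lo + i1] += ov
            if values is not None:
                wsum[lo + i0 : lo + i1] += ov * feats.at[pos, "value"]


def _merge(feats: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals per chromosome (so overlapping features do not double count)."""
    out = []
    for chrom, sub in feats.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def window_overlap_bp(grid: WindowGrid, features: pd.DataFrame) -> np.ndarray:
    """Per-window bp overlapped by the union of ``features``."""
    cov = np.zeros(grid.n)
    if len(features):
        _project(grid, _merge(validate_intervals(features)), cov, None)
    return cov


def overlap_windows(grid: WindowGrid, features: pd.DataFrame, min_overlap: int = 1) -> np.ndarray:
    """Boolean mask: window overlaps features by at least ``min_overlap`` bp."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1 bp")
    return window_overlap_bp(grid, features) >= min_overlap


def stratify_by_timing(grid: WindowGrid, rt: Track, mode: str) -> np.ndarray:
    """Early/late replication strata as top/bottom quartile of the timing track.

    The quartile cut is scale-free: "early" is the top quartile of non-missing
    replication-timing values (higher = earlier by convention of the track),
    "late" the bottom quartile. A constant track has no strict quartile and
    yields an empty mask with a warning.
    """
    if rt.grid is not grid and rt.grid.n != grid.n:
        raise LayoutError("timing track not aligned to grid")
    vals = rt.values
    finite = np.isfinite(vals)
    if not finite.any():
        raise EmptyStratumError("all replication-timing values are missing")
    lo_q, hi_q = np.quantile(vals[finite], [0.25, 0.75])
    if lo_q == hi_q:
        warnings.warn("constant replication-timing track: no strict quartile exists")
        return np.zeros(grid.n, dtype=bool)
    if mode == "early":
        return finite & (vals > hi_q)
    if mode == "late":
        return finite & (vals < lo_q)
    raise ValueError(f"mode must be 'early' or 'late', got {mode!r}")
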