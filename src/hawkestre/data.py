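"""Genomic interval input and marked-point-process dataset assembly.

ChIP-chip / ChIP-seq experiments report *enriched regions* -- intervals of
DNA bound by a factor.  For point-process modelling each enriched region is
reduced to a single point, its midpoint, taken as the proxy for the binding
site.  Histone-modification tracks, which are not point-like, are kept as
whole intervals and enter the model as {0,1} indicator covariates.

Coordinates: input files use the BED dialect (0-based, half-open).  The
midpoint rule reasons in 1-based inclusive coordinates: for a 1-based span
[s, e] the midpoint is floor((s + e) / 2), i.e. when the midpoint falls
between two base pairs the lesser of the two central bases is taken.

A :class:`MarkedPointDataset` holds M observation windows (chromosomes or
analysis regions), K marks of strictly increasing point positions per
window (a *simple* process -- duplicate positions within a mark are
merged), and piecewise-constant covariate indicator tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "Window",
    "MarkedPointDataset",
    "read_intervals",
    "read_windows",
    "interval_midpoint",
    "build_covariate_track",
    "assemble_dataset",
    "reverse_dataset",
    "write_intervals",
]


@dataclass(frozen=True)
class GenomicInterval:
    """An enriched region: BED 0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end {self.end} must exceed start {self.start}"
            )


@dataclass(frozen=True)
class Window:
    """A bounded observation interval [a, b] on one chromosome."""

    chrom: str
    a: float
    b: float
    id: int = 0

    def __post_init__(self) -> None:
        if self.b <= self.a:
            raise ValueError(f"window end {self.b} must exceed start {self.a}")

    @property
    def length(self) -> float:
        return self.b - self.a


def read_intervals(path, label: str = "") -> list[GenomicInterval]:
    """Read a whitespace/tab-delimited BED3(+) file into intervals.

    Lines starting with '#', 'track' or 'browser' are skipped.  Malformed
    lines raise a ``ValueError`` naming the line number.
    """
    out: list[GenomicInterval] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            try:
                out.append(GenomicInterval(parts[0], start, end, label))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_windows(path) -> list[Window]:
    """Read analysis windows from a BED3 file, one window per line."""
    ivs = read_intervals(path)
    return [
        Window(iv.chrom, float(iv.start), float(iv.end), id=i)
        for i, iv in enumerate(ivs)
    ]


def interval_midpoint(iv: GenomicInterval) -> int:
    """Midpoint of an enriched region, 1-based coordinate.

    The BED interval [start, end) covers the 1-based span
    [start + 1, end]; the midpoint is floor((s + e) / 2), the lesser of the
    two central base pairs when the span has even length.
    """
    s, e = iv.start + 1, iv.end
    return (s + e) // 2


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    """Union of [start, end) intervals; returns disjoint sorted arrays."""
    if starts.size == 0:
        return starts.astype(float), ends.astype(float)
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order].astype(float), ends[order].astype(float)
    m_starts, m_ends = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= m_ends[-1]:
            m_ends[-1] = max(m_ends[-1], e)
        else:
            m_starts.append(s)
            m_ends.append(e)
    return np.asarray(m_starts), np.asarray(m_ends)


def build_covariate_track(
    ivs: list[GenomicInterval], window: Window
) -> tuple[np.ndarray, np.ndarray]:
    """Indicator track for a covariate on one window.

    Returns disjoint sorted ``(starts, ends)`` arrays -- the union of the
    input intervals clipped to the window.  A 1-based position p is covered
    iff ``starts[j] < p <= ends[j]`` for some j (BED half-open convention).
    """
    sel = [iv for iv in ivs if iv.chrom == window.chrom and iv.end > window.a and iv.start < window.b]
    if not sel:
        return np.empty(0), np.empty(0)
    starts = np.array([max(iv.start, window.a) for iv in sel])
    ends = np.array([min(iv.end, window.b) for iv in sel])
    return _merge_intervals(starts, ends)


def _indicator(track: tuple[np.ndarray, np.ndarray], t: np.ndarray) -> np.ndarray:
    """Evaluate an indicator track at positions ``t`` (0/1 array)."""
    starts, ends = track
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if starts.size == 0:
        return np.zeros(t.shape)
    idx = np.searchsorted(starts, t, side="left") - 1
    ok = idx >= 0
    cov = np.zeros(t.shape)
    cov[ok] = (t[ok] <= ends[idx[ok]]).astype(float)
    cov[ok] *= (t[ok] > starts[idx[ok]]).astype(float)
    return cov


@dataclass
class MarkedPointDataset:
    """M windows x K marks of point positions plus covariate tracks.

    ``points[(i, mark)]`` is a strictly increasing float array of positions
    inside window i; ``covariates[(i, name)]`` is a ``(starts, ends)`` pair
    of disjoint sorted arrays defining a {0,1} indicator step function.
    """

    windows: list[Window]
    marks: tuple[str, ...]
    covariate_names: tuple[str, ...] = ()
    points: dict = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)
    n_dropped: int = 0

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def total_length(self) -> float:
        return float(sum(w.length for w in self.windows))

    def get_points(self, i: int, mark: str) -> np.ndarray:
        return self.points.get((i, mark), np.empty(0))

    def n_points(self, mark: str) -> int:
        return int(sum(self.get_points(i, mark).size for i in range(self.n_windows)))

    def covariate_indicator(self, i: int, name: str, t) -> np.ndarray:
        track = self.covariates.get((i, name), (np.empty(0), np.empty(0)))
        return _indicator(track, t)

    def validate(self) -> None:
        for (i, mark), pts in self.points.items():
            w = self.windows[i]
            if pts.size and (pts.min() < w.a or pts.max() > w.b):
                raise ValueError(f"points of {mark} outside window {i}")
            if pts.size > 1 and not np.all(np.diff(pts) > 0):
                raise ValueError(f"points of {mark} in window {i} not strictly increasing")

    def reverse(self) -> "MarkedPointDataset":
        return reverse_dataset(self)


def assemble_dataset(
    tre_intervals: dict[str, list[GenomicInterval]],
    windows: list[Window],
    cov_intervals: dict[str, list[GenomicInterval]] | None = None,
) -> MarkedPointDataset:
    """Reduce enriched regions to midpoints and build the dataset.

    Midpoints are assigned to the window containing them; midpoints outside
    every window are dropped and counted (logged).  Duplicate midpoints
    within a mark+window are merged (simple-process invariant).  A mark
    with zero points in all windows is retained in the mark set with a
    warning.
    """
    cov_intervals = cov_intervals or {}
    marks = tuple(tre_intervals)
    cov_names = tuple(cov_intervals)
    ds = MarkedPointDataset(windows=list(windows), marks=marks, covariate_names=cov_names)
    n_unique = 0
    for mark, ivs in tre_intervals.items():
        mids = {(iv.chrom, interval_midpoint(iv)) for iv in ivs}
        n_unique += len(mids)
        total = 0
        for i, w in enumerate(windows):
            pos = np.array(
                sorted(m for c, m in mids if c == w.chrom and w.a < m <= w.b),
                dtype=float,
            )
            ds.points[(i, mark)] = pos
            total += pos.size
        if total == 0:
            logger.warning("mark %s has zero points in all windows", mark)
    # midpoints outside every window, after merging duplicate midpoints
    ds.n_dropped = n_unique - sum(p.size for p in ds.points.values())
    if ds.n_dropped:
        logger.info("dropped %d midpoints falling outside every window", ds.n_dropped)
    for name, ivs in cov_intervals.items():
        for i, w in enumerate(windows):
            ds.covariates[(i, name)] = build_covariate_track(ivs, w)
    ds.validate()
    return ds


def reverse_dataset(d: MarkedPointDataset) -> MarkedPointDataset:
    """Mirror every window: position t -> (a + b) - t.

    Covariate change points are mirrored likewise.  Applying the operation
    twice restores the original dataset exactly.
    """
    out = MarkedPointDataset(
        windows=list(d.windows),
        marks=d.marks,
        covariate_names=d.covariate_names,
        n_dropped=d.n_dropped,
    )
    for (i, mark), pts in d.points.items():
        w = d.windows[i]
        out.points[(i, mark)] = np.sort((w.a + w.b) - pts)
    for (i, name), (starts, ends) in d.covariates.items():
        w = d.windows[i]
        new_starts = np.sort((w.a + w.b) - ends)
        new_ends = np.sort((w.a + w.b) - starts)
        out.covariates[(i, name)] = (new_starts, new_ends)
    return out


def write_intervals(path, intervals: list[GenomicInterval]) -> None:
    """Write intervals as BED3 (+label in column 4 when present)."""
    with Path(path).open("w") as fh:
        for iv in intervals:
            if iv.label:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
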