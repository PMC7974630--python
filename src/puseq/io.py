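"""Readers/writers for binned count tables, track tables and region files.

All on-disk coordinates are 0-based half-open (BED-compatible); bin ``i`` of a
chromosome spans ``[i * bin_width, min((i + 1) * bin_width, length))``.  The
last bin of a chromosome may be short.  All readers and writers are
gzip-transparent (paths ending in ``.gz`` are compressed).
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POLYMERASES = ("delta", "epsilon", "alpha")


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths plus the fixed bin width that defines the grid.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    bin_width
        Bin size in bp; 300 matches typical Pu-Seq processing.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_width: int = 300

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        if self.bin_width < 1:
            raise ValueError(f"bin_width must be >= 1, got {self.bin_width}")
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in chroms:
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.length(chrom) / self.bin_width)

    def bin_start(self, chrom: str, bin_index: int) -> int:
        return bin_index * self.bin_width

    def bin_end(self, chrom: str, bin_index: int) -> int:
        return min((bin_index + 1) * self.bin_width, self.length(chrom))

    def zeros(self, dtype=float) -> dict[str, np.ndarray]:
        """One zero-filled array per chromosome, on the bin grid."""
        return {c: np.zeros(self.n_bins(c), dtype=dtype) for c in self.names}


@dataclass
class BinnedStrandCounts:
    """Per-bin top/bottom strand rNMP counts for one strain/polymerase/replicate.

    ``top[chrom][i]`` is R_T, the number of rNMPs mapped to the top (Watson)
    strand in bin ``i``; ``bottom`` is R_B for the bottom strand.
    """

    layout: GenomeLayout
    strain: str
    polymerase: str
    replicate: int
    top: dict[str, np.ndarray]
    bottom: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.polymerase not in POLYMERASES:
            raise ValueError(
                f"polymerase must be one of {POLYMERASES}, got {self.polymerase!r}"
            )
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        for strand_name, strand in (("top", self.top), ("bottom", self.bottom)):
            for chrom in self.layout.names:
                arr = np.asarray(strand[chrom])
                if arr.shape != (self.layout.n_bins(chrom),):
                    raise ValueError(
                        f"{strand_name} counts for {chrom} have length {arr.shape}, "
                        f"expected {self.layout.n_bins(chrom)}"
                    )
                if np.any(arr < 0):
                    raise ValueError(f"negative count on {strand_name} strand of {chrom}")
                strand[chrom] = arr.astype(np.int64)


@dataclass(frozen=True)
class RegionRecord:
    """A BED5-style interval: 0-based half-open, with a name and a score."""

    chrom: str
    start: int
    end: int
    name: str
    score: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )


def read_layout(path: str | Path, bin_width: int = 300) -> GenomeLayout:
    """Read a 2-column chrom-sizes file (name, length) into a :class:`GenomeLayout`."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return GenomeLayout(tuple(zip(df["chrom"].astype(str), df["length"].astype(int))), bin_width)


def _validate_rows(
    df: pd.DataFrame, layout: GenomeLayout, path, count_cols: Sequence[str]
) -> None:
    for col in count_cols:
        bad = df[df[col] < 0]
        if len(bad):
            raise ValueError(f"{path}: negative count in row {bad.index[0]}: {bad.iloc[0].tolist()}")
    known = set(layout.names)
    unknown = set(df["chrom"].unique()) - known
    if unknown:
        raise ValueError(f"{path}: unknown chromosome(s) {sorted(unknown)!r}")
    bw = layout.bin_width
    for row in df.itertuples(index=False):
        if row.start % bw != 0:
            raise ValueError(
                f"{path}: interval {row.chrom}:{row.start}-{row.end} not aligned to {bw} bp bin grid"
            )
        length = layout.length(row.chrom)
        expected_end = min(row.start + bw, length)
        if row.end != expected_end:
            raise ValueError(
                f"{path}: interval {row.chrom}:{row.start}-{row.end} not aligned to "
                f"{bw} bp bin grid (expected end {expected_end})"
            )


def _fill_grid(df: pd.DataFrame, layout: GenomeLayout, col: str) -> dict[str, np.ndarray]:
    out = layout.zeros(dtype=np.int64)
    if len(df):
        bins = (df["start"] // layout.bin_width).to_numpy()
        for chrom, grp_idx in df.groupby("chrom", sort=False).indices.items():
            out[str(chrom)][bins[grp_idx]] = df[col].to_numpy()[grp_idx]
    return out


def read_counts(
    path: str | Path,
    layout: GenomeLayout,
    strain: str,
    polymerase: str,
    replicate: int,
    bottom_path: str | Path | None = None,
) -> BinnedStrandCounts:
    """Read a strand-count table onto the layout's bin grid.

    Two dialects are accepted:

    * a combined 5-column TSV with header ``chrom start end count_top count_bottom``
      (``path`` alone), or
    * a pair of headerless 4-column bedGraphs (``chrom start end count``), top
      strand in ``path`` and bottom strand in ``bottom_path``.

    Bins absent from the file are zero-filled.  Rows are validated against the
    bin grid; unknown chromosomes, misaligned intervals and negative counts
    raise ``ValueError``.
    """
    if bottom_path is None:
        df = pd.read_csv(path, sep="\t", comment="#")
        required = ["chrom", "start", "end", "count_top", "count_bottom"]
        if list(df.columns[:5]) != required:
            raise ValueError(
                f"{path}: expected header columns {required}, got {list(df.columns)}"
            )
        if df.empty:
            logger.warning("%s: empty counts table; using all-zero counts", path)
        _validate_rows(df, layout, path, ["count_top", "count_bottom"])
        top = _fill_grid(df, layout, "count_top")
        bottom = _fill_grid(df, layout, "count_bottom")
    else:
        frames = []
        for p in (path, bottom_path):
            df = pd.read_csv(
                p, sep="\t", header=None, names=["chrom", "start", "end", "count"],
                comment="#", skiprows=_n_track_lines(p),
            )
            if df.empty:
                logger.warning("%s: empty bedGraph; using all-zero counts", p)
            _validate_rows(df, layout, p, ["count"])
            frames.append(df)
        top = _fill_grid(frames[0], layout, "count")
        bottom = _fill_grid(frames[1], layout, "count")
    return BinnedStrandCounts(layout, strain, polymerase, replicate, top, bottom)


def _n_track_lines(path) -> int:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            if not line.startswith(("track", "browser")):
                return i
    return 0


def write_counts(counts: BinnedStrandCounts, path: str | Path) -> None:
    """Write counts in the combined 5-column dialect (zero rows included)."""
    rows = []
    lay = counts.layout
    for chrom in lay.names:
        for i in range(lay.n_bins(chrom)):
            rows.append(
                (chrom, lay.bin_start(chrom, i), lay.bin_end(chrom, i),
                 counts.top[chrom][i], counts.bottom[chrom][i])
            )
    pd.DataFrame(rows, columns=["chrom", "start", "end", "count_top", "count_bottom"]).to_csv(
        path, sep="\t", index=False
    )


def write_regions(records: Iterable[RegionRecord], path: str | Path) -> None:
    """Write BED5 (chrom, start, end, name, score), sorted by (chrom, start)."""
    recs = sorted(records, key=lambda r: (r.chrom, r.start))
    df = pd.DataFrame(
        [(r.chrom, r.start, r.end, r.name, r.score) for r in recs],
        columns=["chrom", "start", "end", "name", "score"],
    )
    df.to_csv(path, sep="\t", index=False, header=False)


def read_regions(path: str | Path) -> list[RegionRecord]:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name", "score"]
    )
    return [
        RegionRecord(str(r.chrom), int(r.start), int(r.end), str(r.name), float(r.score))
        for r in df.itertuples(index=False)
    ]


def write_track(track, path: str | Path) -> None:
    """Write a per-bin track as TSV (chrom, start, end, value, low_coverage).

    Low-coverage bins (no reads on either strand in some replicate) carry
    value 0 and ``low_coverage=1`` so they can be audited downstream.
    """
    lay = track.layout
    rows = []
    for chrom in lay.names:
        vals = track.values[chrom]
        flags = track.low_coverage[chrom]
        for i in range(lay.n_bins(chrom)):
            rows.append(
                (chrom, lay.bin_start(chrom, i), lay.bin_end(chrom, i),
                 float(vals[i]), int(flags[i]))
            )
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "value", "low_coverage"]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_track(path: str | Path, layout: GenomeLayout, polymerase: str):
    """Read a track TSV written by :func:`write_track`."""
    from .tracks import PolymeraseTrack  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t")
    values = layout.zeros()
    flags = layout.zeros(dtype=bool)
    bins = (df["start"] // layout.bin_width).to_numpy()
    for chrom, idx in df.groupby("chrom", sort=False).indices.items():
        values[str(chrom)][bins[idx]] = df["value"].to_numpy()[idx]
        flags[str(chrom)][bins[idx]] = df["low_coverage"].to_numpy()[idx].astype(bool)
    return PolymeraseTrack(layout, polymerase, values, flags)


def write_origins_table(origins, path: str | Path) -> None:
    """Write origin calls as a TSV with peak spans and raw/normalised efficiencies."""
    rows = [
        (o.chrom, o.origin_bin, o.peak.start_bin, o.peak.end_bin,
         o.peak.max_value, o.efficiency_raw,
         "" if o.efficiency_norm is None else o.efficiency_norm)
        for o in origins
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "origin_bin", "peak_start_bin", "peak_end_bin",
                 "peak_max", "efficiency_raw", "efficiency_norm"],
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_origins_table(path: str | Path):
    from .origins import OriginCall, Peak

    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        peak = Peak(
            chrom=str(r.chrom), start_bin=int(r.peak_start_bin),
            end_bin=int(r.peak_end_bin), max_value=float(r.peak_max),
            max_bin=int(r.origin_bin), sum_values=2.0 * float(r.efficiency_raw),
        )
        norm = None if pd.isna(r.efficiency_norm) else float(r.efficiency_norm)
        out.append(
            OriginCall(str(r.chrom), int(r.origin_bin), peak,
                       float(r.efficiency_raw), norm)
        )
    return out
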