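"""Polymerase tracks: the per-bin strand-bias statistic PT = (R_T − R_B)/(R_T + R_B).

A positive PT means the polymerase predominantly synthesised the top strand in
that bin, a negative PT the bottom strand.  Tracks are computed per biological
replicate and then averaged; the simple moving average used throughout the
pipeline (window 3, truncated at chromosome ends) also lives here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import POLYMERASES, BinnedStrandCounts, GenomeLayout


@dataclass
class PolymeraseTrack:
    """Replicate-level or replicate-averaged PT values on the bin grid.

    ``low_coverage[chrom][i]`` is True where R_T + R_B = 0 in any contributing
    replicate; such bins carry PT = 0 so downstream differentials stay defined.
    """

    layout: GenomeLayout
    polymerase: str
    values: dict[str, np.ndarray]
    low_coverage: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.polymerase not in POLYMERASES:
            raise ValueError(f"polymerase must be one of {POLYMERASES}")
        for chrom in self.layout.names:
            v = np.asarray(self.values[chrom], dtype=float)
            if v.shape != (self.layout.n_bins(chrom),):
                raise ValueError(f"track for {chrom} has wrong length")
            if np.any(np.abs(v) > 1 + 1e-12):
                raise ValueError(f"track for {chrom} has values outside [-1, 1]")
            self.values[chrom] = v
            self.low_coverage[chrom] = np.asarray(self.low_coverage[chrom], dtype=bool)


def compute_track(counts: BinnedStrandCounts) -> PolymeraseTrack:
    """PT = (R_T − R_B)/(R_T + R_B) per bin; zero-coverage bins get 0 and a flag."""
    values = {}
    flags = {}
    for chrom in counts.layout.names:
        top = counts.top[chrom].astype(float)
        bottom = counts.bottom[chrom].astype(float)
        total = top + bottom
        flag = total == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            pt = np.where(flag, 0.0, (top - bottom) / np.where(flag, 1.0, total))
        values[chrom] = pt
        flags[chrom] = flag
    return PolymeraseTrack(counts.layout, counts.polymerase, values, flags)


def average_replicates(tracks: list[PolymeraseTrack]) -> PolymeraseTrack:
    """Arithmetic per-bin mean of replicate tracks; low-coverage flags are OR-ed."""
    if not tracks:
        raise ValueError("need at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if t.layout != first.layout:
            raise ValueError("replicate tracks have mismatched layouts")
        if t.polymerase != first.polymerase:
            raise ValueError(
                f"cannot average {t.polymerase} with {first.polymerase} tracks"
            )
    values = {
        c: np.mean([t.values[c] for t in tracks], axis=0) for c in first.layout.names
    }
    flags = {
        c: np.any([t.low_coverage[c] for t in tracks], axis=0)
        for c in first.layout.names
    }
    for c in first.layout.names:  # flagged bins carry 0 by convention
        values[c][flags[c]] = 0.0
    return PolymeraseTrack(first.layout, first.polymerase, values, flags)


def sma(values, window: int = 3) -> np.ndarray:
    """Centred simple moving average with truncated windows at the ends.

    The window must be odd.  At a sequence edge the window shrinks to the
    available points (e.g. the first bin of a window-3 average is the mean of
    bins 0 and 1), so output length equals input length and no artificial
    zeros leak in from beyond the chromosome.  Apply per chromosome — never
    across chromosome boundaries.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    v = np.asarray(values, dtype=float)
    if v.size == 0 or window == 1:
        return v.copy()
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(v.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, v.size)
    return (csum[hi] - csum[lo]) / (hi - lo)
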