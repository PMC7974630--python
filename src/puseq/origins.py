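"""Origin calling from polymerase-track differentials.

The procedure: smooth each polymerase track (SMA window 3), take neighbouring
differences ``Diff_i = PT_i − PT_{i−1}`` with the first bin of each chromosome
set to 0, average the Polε differential with the negated Polδ and Polα
differentials, smooth again, and scan the combined signal for positive peaks.
A sharp rise in the Polε track (mirrored by a fall in Polδ/Polα) marks a
replication origin; half the summed differential over a peak estimates the
origin's firing efficiency, since the PT step across an origin is twice the
fraction of cells in which it fires actively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .io import GenomeLayout
from .tracks import PolymeraseTrack, sma

logger = logging.getLogger(__name__)


@dataclass
class DifferentialSignal:
    """Combined, smoothed per-bin differential of the three polymerase tracks."""

    layout: GenomeLayout
    values: dict[str, np.ndarray]
    provenance: tuple[str, ...] = ("epsilon", "delta", "alpha")

    def __post_init__(self) -> None:
        for chrom in self.layout.names:
            v = np.asarray(self.values[chrom], dtype=float)
            if v.shape != (self.layout.n_bins(chrom),):
                raise ValueError(f"signal for {chrom} has wrong length")
            self.values[chrom] = v


@dataclass(frozen=True)
class Peak:
    """A maximal run of positive differential values (possibly split)."""

    chrom: str
    start_bin: int  # inclusive
    end_bin: int  # inclusive
    max_value: float
    max_bin: int
    sum_values: float

    def __post_init__(self) -> None:
        if not (self.start_bin <= self.max_bin <= self.end_bin):
            raise ValueError("peak maximum outside its span")
        if not (self.sum_values >= self.max_value > 0):
            raise ValueError("peak must have sum >= max > 0")


@dataclass(frozen=True)
class OriginCall:
    """A called replication origin with raw and normalised firing efficiency.

    ``efficiency_raw`` is on the fraction scale (0.5 × the peak's summed
    differential); ``efficiency_norm`` is percent of the most efficient origin
    and is ``None`` until :func:`normalise_efficiencies` has run.
    """

    chrom: str
    origin_bin: int
    peak: Peak
    efficiency_raw: float
    efficiency_norm: float | None = None


def differentiate(track: PolymeraseTrack, window: int = 3) -> dict[str, np.ndarray]:
    """Per-chromosome ``Diff_i = PT_i − PT_{i−1}`` of the SMA-smoothed track.

    The first bin of each chromosome is assigned differential 0; differences
    never cross chromosome boundaries.
    """
    out = {}
    for chrom in track.layout.names:
        smoothed = sma(track.values[chrom], window)
        diff = np.empty_like(smoothed)
        diff[0] = 0.0
        diff[1:] = smoothed[1:] - smoothed[:-1]
        out[chrom] = diff
    return out


def combine_differentials(
    diff_epsilon: Mapping[str, np.ndarray],
    diff_delta: Mapping[str, np.ndarray],
    diff_alpha: Mapping[str, np.ndarray],
    layout: GenomeLayout,
    window: int = 3,
) -> DifferentialSignal:
    """Average the Polε differential with the opposites of Polδ and Polα, then smooth.

    Fork direction flips the sign of lagging-strand (δ, α) differentials
    relative to leading-strand (ε); negating them aligns all three so an
    origin appears as a single positive peak.
    """
    values = {}
    for chrom in layout.names:
        e, d, a = diff_epsilon[chrom], diff_delta[chrom], diff_alpha[chrom]
        if not (len(e) == len(d) == len(a) == layout.n_bins(chrom)):
            raise ValueError(f"differential length mismatch on {chrom}")
        values[chrom] = sma((e - d - a) / 3.0, window)
    return DifferentialSignal(layout, values)


def _local_maxima(v: np.ndarray) -> list[int]:
    """Leftmost bins of plateaus that are strict local maxima within ``v``.

    A plateau (maximal block of equal values) is a maximum when its value
    exceeds both flanking values; run boundaries count as lower.
    """
    maxima = []
    i = 0
    n = len(v)
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == n - 1 or v[j + 1] < v[i]
        if left_ok and right_ok:
            maxima.append(i)
        i = j + 1
    return maxima


def detect_peaks(
    signal: DifferentialSignal,
    min_sep_bins: int = 4,
    positive_tol: float = 1e-12,
) -> list[Peak]:
    """Find positive differential peaks, splitting multi-maxima runs.

    Candidate peaks are maximal runs of strictly positive values (values must
    exceed ``positive_tol``, which guards against floating-point dust left by
    the moving-average arithmetic on exactly-flat tracks).  When a run
    contains two or more distinct local maxima whose consecutive index
    distance is at least ``min_sep_bins``, it is split into independent peaks
    at the minimum-value bin between the pair (leftmost minimum on ties,
    assigned to the left peak).
    """
    peaks: list[Peak] = []
    for chrom in signal.layout.names:
        v = signal.values[chrom]
        positive = v > positive_tol
        # run boundaries of consecutive positive bins
        edges = np.flatnonzero(np.diff(np.concatenate([[0], positive.view(np.int8), [0]])))
        for start, stop in zip(edges[::2], edges[1::2]):
            run = v[start:stop]
            maxima = _local_maxima(run)
            cuts = []
            for m1, m2 in zip(maxima, maxima[1:]):
                if m2 - m1 >= min_sep_bins:
                    between = run[m1 + 1 : m2]
                    cuts.append(m1 + 1 + int(np.argmin(between)))
            bounds = [0, *[c + 1 for c in cuts], len(run)]
            for lo, hi in zip(bounds, bounds[1:]):
                seg = run[lo:hi]
                mx = int(np.argmax(seg))
                peaks.append(
                    Peak(
                        chrom=chrom,
                        start_bin=start + lo,
                        end_bin=start + hi - 1,
                        max_value=float(seg[mx]),
                        max_bin=start + lo + mx,
                        sum_values=float(seg.sum()),
                    )
                )
    return peaks


def filter_peaks(peaks: Sequence[Peak], percentile: float = 30.0) -> list[Peak]:
    """Drop peaks whose maximum falls below the given percentile of all peak maxima.

    The percentile (linear interpolation between order statistics) is taken
    over the genome-wide distribution of candidate-peak maxima; retention uses
    ``>=`` so an all-equal population survives intact.
    """
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    if not peaks:
        logger.warning("no candidate peaks to filter")
        return []
    threshold = float(np.percentile([p.max_value for p in peaks], percentile))
    return [p for p in peaks if p.max_value >= threshold]


def call_origins(
    signal: DifferentialSignal,
    percentile: float = 30.0,
    min_sep_bins: int = 4,
) -> list[OriginCall]:
    """Detect, filter and convert differential peaks to origin calls.

    Each surviving peak yields one origin at the peak-maximum bin, with raw
    efficiency 0.5 × the peak's summed values.  Output is sorted by
    (chromosome, origin bin); efficiencies are not yet normalised.
    """
    peaks = filter_peaks(detect_peaks(signal, min_sep_bins), percentile)
    calls = [
        OriginCall(
            chrom=p.chrom,
            origin_bin=p.max_bin,
            peak=p,
            efficiency_raw=0.5 * p.sum_values,
        )
        for p in peaks
    ]
    order = {c: i for i, c in enumerate(signal.layout.names)}
    calls.sort(key=lambda o: (order[o.chrom], o.origin_bin))
    return calls


def normalise_efficiencies(origins: Sequence[OriginCall]) -> list[OriginCall]:
    """Scale efficiencies so the most efficient origin is 100 (percent)."""
    if not origins:
        raise ValueError("cannot normalise an empty origin list")
    top = max(o.efficiency_raw for o in origins)
    return [
        replace(o, efficiency_norm=100.0 * o.efficiency_raw / top) for o in origins
    ]


def origins_from_tracks(
    tracks: Mapping[str, PolymeraseTrack],
    percentile: float = 30.0,
    min_sep_bins: int = 4,
) -> list[OriginCall]:
    """Full calling pipeline from replicate-averaged tracks keyed by polymerase."""
    layout = tracks["epsilon"].layout
    signal = combine_differentials(
        differentiate(tracks["epsilon"]),
        differentiate(tracks["delta"]),
        differentiate(tracks["alpha"]),
        layout,
    )
    calls = call_origins(signal, percentile, min_sep_bins)
    return normalise_efficiencies(calls) if calls else []
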