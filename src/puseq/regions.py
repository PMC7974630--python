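"""Efficient-origin and termination-zone selection, and meta-profiles.

A termination zone is the interval between two adjacent efficient origins
(normalised efficiency > 40% by default) that contains no
intermediary-efficiency origin (20% < efficiency < 40%); converging forks
from the flanking origins meet somewhere inside it.  Meta-profiles average
polymerase tracks either around origin centres (fixed flank) or across
termination zones rescaled to a common number of bins and centred on the
zone midpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .origins import OriginCall
from .tracks import PolymeraseTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TerminationZone:
    """Span strictly between two flanking efficient origins."""

    chrom: str
    left_origin: OriginCall
    right_origin: OriginCall
    start_bin: int  # inclusive, first bin after the left origin
    end_bin: int  # inclusive, last bin before the right origin
    midpoint_bin: int

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1


@dataclass
class MetaProfile:
    """Mean track values at relative offsets, per polymerase.

    ``offsets`` are bin offsets from the centre (origin bin or zone midpoint,
    in rescaled units for termination profiles).  ``matrices[pol]`` holds the
    per-region aligned values (n_regions × n_offsets) behind each mean.
    """

    offsets: np.ndarray
    values: dict[str, np.ndarray]
    matrices: dict[str, np.ndarray]
    n_regions: int


def select_efficient_origins(
    origins: Sequence[OriginCall], threshold_pct: float = 40.0
) -> list[OriginCall]:
    """Origins with normalised efficiency >= ``threshold_pct``, order preserved."""
    _require_normalised(origins)
    return [o for o in origins if o.efficiency_norm >= threshold_pct]


def select_termination_zones(
    origins: Sequence[OriginCall],
    eff_hi: float = 40.0,
    eff_lo: float = 20.0,
) -> list[TerminationZone]:
    """Zones between adjacent efficient origins free of intermediary origins.

    Flanking origins need normalised efficiency strictly above ``eff_hi``; a
    zone is rejected if any origin with efficiency in the open interval
    (``eff_lo``, ``eff_hi``) lies strictly between the pair.  Origins at or
    below ``eff_lo`` never disqualify a zone.  Input must be sorted by
    (chromosome, bin), as produced by the origin caller.
    """
    _require_normalised(origins)
    by_chrom: dict[str, list[OriginCall]] = {}
    for o in origins:
        group = by_chrom.setdefault(o.chrom, [])
        if group and o.origin_bin <= group[-1].origin_bin:
            raise ValueError("origins must be sorted by position within chromosomes")
        group.append(o)

    zones = []
    for chrom, group in by_chrom.items():
        efficient = [o for o in group if o.efficiency_norm > eff_hi]
        for left, right in zip(efficient, efficient[1:]):
            if right.origin_bin - left.origin_bin < 2:
                continue  # no interior bins
            between = [
                o for o in group
                if left.origin_bin < o.origin_bin < right.origin_bin
            ]
            if any(eff_lo < o.efficiency_norm < eff_hi for o in between):
                continue
            zones.append(
                TerminationZone(
                    chrom=chrom,
                    left_origin=left,
                    right_origin=right,
                    start_bin=left.origin_bin + 1,
                    end_bin=right.origin_bin - 1,
                    midpoint_bin=(left.origin_bin + right.origin_bin) // 2,
                )
            )
    return zones


def origin_metaprofile(
    tracks: Mapping[str, PolymeraseTrack],
    origins: Sequence[OriginCall],
    flank_bins: int = 50,
) -> MetaProfile:
    """Mean track values at offsets −flank..+flank around each origin bin.

    Origins whose flank would run past a chromosome end are dropped (count
    logged).
    """
    if flank_bins < 1:
        raise ValueError("flank_bins must be >= 1")
    layout = next(iter(tracks.values())).layout
    kept = [
        o for o in origins
        if o.origin_bin - flank_bins >= 0
        and o.origin_bin + flank_bins < layout.n_bins(o.chrom)
    ]
    if len(kept) < len(origins):
        logger.info("dropped %d origin(s) too close to a chromosome end",
                    len(origins) - len(kept))
    if not kept:
        raise ValueError("no origin with a full flank inside its chromosome")
    offsets = np.arange(-flank_bins, flank_bins + 1)
    values, matrices = {}, {}
    for pol, track in tracks.items():
        mat = np.stack([
            track.values[o.chrom][o.origin_bin - flank_bins : o.origin_bin + flank_bins + 1]
            for o in kept
        ])
        matrices[pol] = mat
        values[pol] = mat.mean(axis=0)
    return MetaProfile(offsets, values, matrices, n_regions=len(kept))


def rescale_to_bins(values: np.ndarray, n_out: int) -> np.ndarray:
    """Rescale a zone's values to ``n_out`` equal-width bins.

    Each output bin averages the input bins whose centres fall inside it;
    output bins that capture no input centre (possible when upsampling up to
    2×) are filled by linear interpolation of the input at the output-bin
    centre.
    """
    v = np.asarray(values, dtype=float)
    n_in = v.size
    if n_in == 0:
        raise ValueError("cannot rescale an empty zone")
    centres_in = (np.arange(n_in) + 0.5) / n_in
    idx = np.minimum((centres_in * n_out).astype(int), n_out - 1)
    out = np.full(n_out, np.nan)
    for j in range(n_out):
        sel = idx == j
        if sel.any():
            out[j] = v[sel].mean()
    empty = np.isnan(out)
    if empty.any():
        centres_out = (np.arange(n_out) + 0.5) / n_out
        out[empty] = np.interp(centres_out[empty], centres_in, v)
    return out


def termination_metaprofile(
    tracks: Mapping[str, PolymeraseTrack],
    zones: Sequence[TerminationZone],
    n_rescaled_bins: int = 20,
) -> MetaProfile:
    """Mean track values across zones rescaled to a common bin count.

    Each zone's span is rescaled to ``n_rescaled_bins`` equal-width bins and
    centred on the zone midpoint (offsets −n/2 .. n/2 − 1).  Zones shorter
    than ``n_rescaled_bins / 2`` original bins are dropped (count logged).
    """
    if n_rescaled_bins < 2 or n_rescaled_bins % 2:
        raise ValueError("n_rescaled_bins must be a positive even integer")
    kept = [z for z in zones if z.n_bins >= n_rescaled_bins // 2]
    if len(kept) < len(zones):
        logger.info("dropped %d zone(s) shorter than %d bins",
                    len(zones) - len(kept), n_rescaled_bins // 2)
    if not kept:
        raise ValueError("no termination zone long enough to rescale")
    offsets = np.arange(-n_rescaled_bins // 2, n_rescaled_bins // 2)
    values, matrices = {}, {}
    for pol, track in tracks.items():
        mat = np.stack([
            rescale_to_bins(
                track.values[z.chrom][z.start_bin : z.end_bin + 1], n_rescaled_bins
            )
            for z in kept
        ])
        matrices[pol] = mat
        values[pol] = mat.mean(axis=0)
    return MetaProfile(offsets, values, matrices, n_regions=len(kept))


def efficiency_distribution(
    origins: Sequence[OriginCall], bin_edges: Sequence[float]
) -> pd.DataFrame:
    """Histogram of normalised efficiencies over half-open bins [e_i, e_{i+1}).

    Returns a DataFrame with columns ``left``, ``right``, ``count``; origins
    outside the edge range are excluded.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 values")
    _require_normalised(origins)
    effs = np.array([o.efficiency_norm for o in origins])
    counts = np.zeros(len(edges) - 1, dtype=int)
    if effs.size:
        idx = np.searchsorted(edges, effs, side="right") - 1
        in_range = (idx >= 0) & (effs < edges[-1])
        for i in idx[in_range]:
            counts[i] += 1
    return pd.DataFrame({"left": edges[:-1], "right": edges[1:], "count": counts})


def _require_normalised(origins: Sequence[OriginCall]) -> None:
    for o in origins:
        if o.efficiency_norm is None:
            raise ValueError(
                "origin efficiencies must be normalised first "
                "(run normalise_efficiencies)"
            )
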