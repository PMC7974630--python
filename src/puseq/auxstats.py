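"""Auxiliary lab-measurement formulas: qPCR relative levels and doubling time."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class QpcrMeasurement:
    """Quantification cycles of a target and a reference gene for one sample."""

    sample: str
    cq_target: float
    cq_reference: float

    def __post_init__(self) -> None:
        for name, cq in (("cq_target", self.cq_target), ("cq_reference", self.cq_reference)):
            if not math.isfinite(cq) or cq <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {cq}")


@dataclass(frozen=True)
class GrowthSeries:
    """Time series of optical-density measurements in exponential growth.

    Times in hours, OD > 0.  Any culture dilutions must already be corrected
    for (multiply post-dilution ODs back up) before fitting.
    """

    times: tuple[float, ...]
    od: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.od, dtype=float)
        if t.size < 3 or t.size != d.size:
            raise ValueError("need >= 3 matched (time, OD) points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(d <= 0):
            raise ValueError("OD values must be positive")


def relative_transcript_level(m: QpcrMeasurement) -> float:
    """Relative transcript level 2^−Cq(target) / 2^−Cq(reference)."""
    return float(2.0 ** (m.cq_reference - m.cq_target))


def doubling_time(g: GrowthSeries) -> tuple[float, float]:
    """OLS slope k of log2(OD) versus time, and doubling time DT = 1/k hours."""
    fit = stats.linregress(np.asarray(g.times), np.log2(np.asarray(g.od)))
    k = float(fit.slope)
    if k <= 0:
        raise ValueError(f"non-growing culture: log2-OD slope k = {k:.4g} <= 0")
    return k, 1.0 / k
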