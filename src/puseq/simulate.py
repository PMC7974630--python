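"""Stochastic replication-program simulator producing Pu-Seq-like count data.

The model: each origin in a population of cells fires with probability ``p``
at an exponentially distributed time with mean ``τ`` (or never, with
probability 1 − p).  Fired origins launch two forks that move outward at a
constant speed; a bin is replicated by whichever fork reaches it first, and
an origin reached by a fork before its own firing time is passively
replicated.  From the resulting per-bin fork-direction fractions, leading- and
lagging-strand logic converts fork direction into strand-specific rNMP
signal: Polε synthesises the leading strand (top strand under rightward
forks), Polδ and Polα the lagging strand.  Poisson sampling with an optional
uniform background yields the final per-strand counts.

Fork-direction bookkeeping: in a cell where a bin is never replicated
(no origin fired on that chromosome), the bin contributes 0.5 to each
direction — no net strand bias.  A fired origin's own bin likewise counts 0.5
to each direction.  With this convention the sum rule f_right + f_left = 1
holds for every bin, and the PT step across an origin equals twice its
realized efficiency, which is exactly what the differential peak sum
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from .io import GenomeLayout

_POL_CODE = {"delta": 0, "epsilon": 1, "alpha": 2}

# chunk of cells processed at once in the vectorized population sweep;
# bounds memory at ~n_chunk * n_bins * 16 bytes per chromosome
_CELL_CHUNK = 2048


@dataclass(frozen=True)
class Origin:
    """One replication origin: grid position, firing probability and timing."""

    chrom: str
    position_bin: int
    firing_probability: float
    mean_firing_time: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.firing_probability <= 1.0:
            raise ValueError("firing_probability must be in [0, 1]")
        if self.mean_firing_time < 0:
            raise ValueError("mean_firing_time must be >= 0")


@dataclass(frozen=True)
class ReplicationProgram:
    """A set of origins plus a common constant fork speed (bins per time unit).

    ``firing_time_model`` selects exponential firing times (mean τ, the
    default) or deterministic times (exactly τ, zero variance) — the latter is
    useful for constructing exact fork-collision geometries.
    """

    layout: GenomeLayout
    origins: tuple[Origin, ...]
    fork_speed: float
    firing_time_model: Literal["exponential", "deterministic"] = "exponential"

    def __post_init__(self) -> None:
        if self.fork_speed <= 0:
            raise ValueError("fork_speed must be > 0")
        if self.firing_time_model not in ("exponential", "deterministic"):
            raise ValueError("firing_time_model must be 'exponential' or 'deterministic'")
        by_chrom: dict[str, int] = {}
        for o in self.origins:
            n = self.layout.n_bins(o.chrom)
            if not 0 <= o.position_bin < n:
                raise ValueError(f"origin bin {o.position_bin} outside {o.chrom}")
            if o.chrom in by_chrom and o.position_bin <= by_chrom[o.chrom]:
                raise ValueError("origin bins must be strictly increasing per chromosome")
            by_chrom[o.chrom] = o.position_bin


@dataclass
class ForkDirectionProfile:
    """Ground truth from a simulated population.

    ``f_right[chrom][i]`` is the fraction of cells in which bin ``i`` was
    replicated by a rightward-moving fork (0.5-weighted for origin-own bins
    and unreplicated cells); ``realized_efficiency[k]`` is the fraction of
    cells in which origin ``k`` fired actively rather than being passively
    replicated.
    """

    layout: GenomeLayout
    f_right: dict[str, np.ndarray]
    realized_efficiency: np.ndarray
    n_cells: int


@dataclass(frozen=True)
class NoiseModel:
    """Counting-noise model for Pu-Seq sampling.

    ``mean_depth`` λ is the expected total rNMP count per bin (top + bottom
    strands together).  ``background_fraction`` b assigns that portion of the
    signal uniformly to both strands, emulating residual ribonucleotide
    excision repair and mapping noise that carries no fork-direction
    information.
    """

    mean_depth: float
    background_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must be in [0, 1)")


def draw_firing_times(
    program: ReplicationProgram, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """Firing-time matrix (n_cells × n_origins); +inf marks a never-firing origin.

    Draw order is fixed (per origin: fire/no-fire Bernoulli, then times) so an
    independent per-cell simulator can consume the identical stream.
    """
    times = np.full((n_cells, len(program.origins)), np.inf)
    for k, o in enumerate(program.origins):
        fired = rng.random(n_cells) < o.firing_probability
        if program.firing_time_model == "exponential":
            t = rng.exponential(o.mean_firing_time, n_cells)
        else:
            t = np.full(n_cells, float(o.mean_firing_time))
        times[fired, k] = t[fired]
    return times


def profile_from_times(
    program: ReplicationProgram, times: np.ndarray
) -> ForkDirectionProfile:
    """Resolve fork directions and realized efficiencies from a firing-time matrix.

    A bin's replicator is the origin minimising ``t_k + |bin − x_k| / v``
    (passive replication never changes arrival times, since any fork path
    through an unfired origin is dominated by the direct one).  Arrival-time
    ties resolve by priority leftward fork > in-place firing > rightward fork,
    i.e. the leftward fork wins.
    """
    n_cells = times.shape[0]
    v = program.fork_speed
    f_right = program.layout.zeros()
    origin_idx = {c: [] for c in program.layout.names}
    for k, o in enumerate(program.origins):
        origin_idx[o.chrom].append(k)

    for chrom in program.layout.names:
        ks = origin_idx[chrom]
        n_bins = program.layout.n_bins(chrom)
        acc = np.zeros(n_bins)
        if not ks:
            f_right[chrom] = np.full(n_bins, 0.5)
            continue
        pos = np.array([program.origins[k].position_bin for k in ks])
        bins = np.arange(n_bins)
        # distance (origins × bins) and signed direction of the covering fork
        dist = np.abs(bins[None, :] - pos[:, None]) / v
        dir_code = np.sign(bins[None, :] - pos[:, None]).astype(np.int8)
        for lo in range(0, n_cells, _CELL_CHUNK):
            t = times[lo : lo + _CELL_CHUNK, ks]
            best_time = np.full((t.shape[0], n_bins), np.inf)
            best_dir = np.zeros((t.shape[0], n_bins), dtype=np.int8)
            # origins in increasing position; `<=` makes the rightmost
            # competitor win ties, which is the leftward fork for any bin
            # between two tied origins
            for j in range(len(ks)):
                arrival = t[:, j, None] + dist[None, j, :]
                take = arrival <= best_time
                best_time = np.where(take, arrival, best_time)
                best_dir = np.where(take, dir_code[j], best_dir)
            replicated = np.isfinite(best_time)
            contrib = np.where(
                replicated, (best_dir > 0) + 0.5 * (best_dir == 0), 0.5
            )
            acc += contrib.sum(axis=0)
        f_right[chrom] = acc / n_cells

    efficiency = np.zeros(len(program.origins))
    for chrom in program.layout.names:
        ks = origin_idx[chrom]
        if not ks:
            continue
        pos = np.array([program.origins[k].position_bin for k in ks])
        t = times[:, ks]
        for j, k in enumerate(ks):
            own = t[:, j]
            active = np.isfinite(own)
            for m in range(len(ks)):
                if m == j:
                    continue
                arrival = t[:, m] + abs(pos[m] - pos[j]) / v
                if pos[m] < pos[j]:  # rightward fork: firing wins ties
                    active &= own <= arrival
                else:  # leftward fork wins ties
                    active &= own < arrival
            efficiency[k] = active.mean()
    return ForkDirectionProfile(program.layout, f_right, efficiency, n_cells)


def simulate_population(
    program: ReplicationProgram, n_cells: int, seed: int
) -> ForkDirectionProfile:
    """Simulate ``n_cells`` independent replication programs; see module docstring."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if all(o.firing_probability == 0 for o in program.origins) or not program.origins:
        raise ValueError("unreplicable genome: no origin can ever fire")
    rng = np.random.default_rng(seed)
    times = draw_firing_times(program, n_cells, rng)
    return profile_from_times(program, times)


def expected_track(f_right, polymerase: str):
    """Noise-free expected PT from fork-direction fractions.

    Polε (leading strand) tracks fork direction directly: PT_ε = 2·f_right − 1.
    Polδ and Polα (lagging strand) are its mirror: PT = 1 − 2·f_right.
    Accepts a single array or a per-chromosome dict.
    """
    if polymerase not in _POL_CODE:
        raise ValueError(f"unknown polymerase {polymerase!r}")
    sign = 1.0 if polymerase == "epsilon" else -1.0

    def _one(arr):
        arr = np.asarray(arr, dtype=float)
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("f_right values must lie in [0, 1]")
        return sign * (2.0 * arr - 1.0)

    if isinstance(f_right, Mapping):
        return {c: _one(a) for c, a in f_right.items()}
    return _one(f_right)


def sample_counts(
    profile: ForkDirectionProfile,
    polymerase: str,
    noise: NoiseModel,
    replicate: int,
    seed: int,
    strain: str = "sim",
):
    """Draw Poisson strand counts for one polymerase dataset and replicate.

    Per bin, the signal strand fraction is ``s = f_right`` for Polε and
    ``1 − f_right`` for Polδ/Polα; expected counts are
    ``λ·[(1−b)·s + b/2]`` (top) and ``λ·[(1−b)·(1−s) + b/2]`` (bottom).
    Replicate ``r`` uses seed ``seed + r`` (mixed with a polymerase code so
    the lagging-strand datasets are not count-for-count identical).
    """
    from .io import BinnedStrandCounts

    rng = np.random.default_rng([seed + replicate, _POL_CODE[polymerase]])
    lam, b = noise.mean_depth, noise.background_fraction
    top = {}
    bottom = {}
    for chrom in profile.layout.names:
        f = profile.f_right[chrom]
        s = f if polymerase == "epsilon" else 1.0 - f
        top[chrom] = rng.poisson(lam * ((1 - b) * s + b / 2))
        bottom[chrom] = rng.poisson(lam * ((1 - b) * (1 - s) + b / 2))
    return BinnedStrandCounts(profile.layout, strain, polymerase, replicate, top, bottom)


def simulate_dataset(
    program: ReplicationProgram,
    noise: NoiseModel,
    n_cells: int,
    replicates: int,
    seed: int,
    strain: str = "sim",
):
    """Simulate one full Pu-Seq study: population sweep plus counts for all
    three polymerase datasets × replicates.

    Returns ``(profile, counts)`` with ``counts[(polymerase, replicate)]`` a
    :class:`~puseq.io.BinnedStrandCounts`.
    """
    profile = simulate_population(program, n_cells, seed)
    counts = {
        (pol, rep): sample_counts(profile, pol, noise, rep, seed, strain)
        for pol in _POL_CODE
        for rep in range(1, replicates + 1)
    }
    return profile, counts


def isolated_origin_profile(
    layout: GenomeLayout, chrom: str, origin_bin: int, efficiency: float
) -> ForkDirectionProfile:
    """Analytic (no-sampling) fork profile of a single origin firing in a
    fraction ``efficiency`` of cells.

    Bins right of the origin see a rightward fork in the firing cells and no
    fork otherwise, so f_right = 0.5 + e/2 there, 0.5 − e/2 to the left and
    exactly 0.5 at the origin bin.  Useful as an exact fixture for the
    efficiency-estimation identity.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must be in [0, 1]")
    f_right = {c: np.full(layout.n_bins(c), 0.5) for c in layout.names}
    bins = np.arange(layout.n_bins(chrom))
    f_right[chrom] = 0.5 + 0.5 * efficiency * np.sign(bins - origin_bin)
    eff = np.array([efficiency])
    return ForkDirectionProfile(layout, f_right, eff, n_cells=0)
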