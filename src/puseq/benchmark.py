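"""A reference simulated study used by the test suite, the acceptance script
and the README worked example.

The benchmark chromosome is 3,000 bins of 300 bp (900 kb) with ten origins
whose firing probabilities span 0.2–1.0.  Origin positions are irregularly
spaced (fixed jitter around a 300-bin pitch, minimum spacing 165 bins):
perfectly uniform spacing is a degenerate geometry in which fork-collision
midpoints from two strong neighbours coincide exactly with an intervening
weak origin and cancel part of its differential step, which real genomes do
not exhibit.  Sequencing conditions: mean depth 50 rNMPs per bin, 5%
direction-free background, two replicates, 10,000 simulated cells.
"""

from __future__ import annotations

import numpy as np

from .io import GenomeLayout
from .origins import origins_from_tracks
from .regions import select_efficient_origins, select_termination_zones
from .simulate import NoiseModel, Origin, ReplicationProgram, simulate_dataset
from .tracks import average_replicates, compute_track

_PITCH = 300
_JITTER = (0, 37, -52, 81, -23, 64, -71, 18, -45, 55)
_P_ORDER = (0, 5, 2, 7, 4, 9, 1, 6, 3, 8)

N_BINS = 3000
N_CELLS = 10_000
REPLICATES = 2
MEAN_DEPTH = 50.0
BACKGROUND = 0.05
MEAN_FIRING_TIME = 1.5  # time units
FORK_SPEED = 10.0  # bins per time unit (~3 kb/min at 300 bp bins)
MATCH_WINDOW = 5  # bins; calling can shift a maximum by the smoothing width


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation via the exact rank-difference formula.

    Valid for distinct values (no ties occur in the benchmark); exact 1.0
    when the rank orders agree, unlike rank-Pearson in floating point.
    """
    n = len(x)
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    d2 = int(((rx - ry) ** 2).sum())
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def benchmark_program() -> ReplicationProgram:
    """The ten-origin benchmark replication program."""
    layout = GenomeLayout((("chrI", N_BINS * _PITCH),), _PITCH)
    probs = np.linspace(0.2, 1.0, 10)[list(_P_ORDER)]
    origins = tuple(
        Origin("chrI", 150 + _PITCH * i + _JITTER[i], float(probs[i]), MEAN_FIRING_TIME)
        for i in range(10)
    )
    return ReplicationProgram(layout, origins, FORK_SPEED)


def run_recovery(seed: int) -> dict:
    """Simulate the benchmark study and score origin-efficiency recovery.

    Returns a dict with the called-origin list, per-origin matched estimates,
    RMSE against realized efficiencies, Spearman rank correlation, and the
    efficient-origin / termination-zone counts from the same calls.
    """
    program = benchmark_program()
    noise = NoiseModel(MEAN_DEPTH, BACKGROUND)
    profile, counts = simulate_dataset(program, noise, N_CELLS, REPLICATES, seed)
    tracks = {
        pol: average_replicates(
            [compute_track(counts[(pol, r)]) for r in range(1, REPLICATES + 1)]
        )
        for pol in ("delta", "epsilon", "alpha")
    }
    calls = origins_from_tracks(tracks)
    estimated = []
    for origin in program.origins:
        near = [c for c in calls if abs(c.origin_bin - origin.position_bin) <= MATCH_WINDOW]
        estimated.append(max((c.efficiency_raw for c in near), default=np.nan))
    estimated = np.asarray(estimated)
    realized = profile.realized_efficiency
    rmse = float(np.sqrt(np.nanmean((estimated - realized) ** 2)))
    rho = _spearman(estimated, realized)
    efficient = select_efficient_origins(calls)
    zones = select_termination_zones(calls)
    return {
        "program": program,
        "profile": profile,
        "tracks": tracks,
        "calls": calls,
        "realized_efficiency": realized,
        "estimated_efficiency": estimated,
        "rmse": rmse,
        "spearman": rho,
        "n_called": len(calls),
        "n_efficient": len(efficient),
        "n_zones": len(zones),
        "zones": zones,
    }
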