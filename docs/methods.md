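# Methods

## Background and scope

Polymerase usage sequencing (Pu-Seq) maps which replicative DNA polymerase
synthesised each strand of a genome. Strains carry a mutant polymerase
(Polδ `cdc6-L591G`, Polε `cdc20-M630F` or Polα `pol1-L850F`) that
misincorporates ribonucleotides (rNMPs) at an elevated rate, combined with
`rnh201Δ` so ribonucleotide excision repair cannot remove them. Sequencing
the rNMP positions strand-specifically yields, for each polymerase, binned
counts of nascent-strand synthesis on the top (Watson) and bottom (Crick)
strands. Because Polε synthesises the leading strand and Polδ/Polα the
lagging strand, the strand bias of each dataset reports local replication
fork direction, and changes in fork direction mark replication origins and
termination zones.

This package implements the downstream analysis (from binned per-strand
counts onward; read mapping is upstream and out of scope) and a stochastic
replication-program simulator that generates statistically realistic input
data with known ground truth, so that every stage is testable at desk scale.

## Polymerase tracks

For each {strain, polymerase, replicate} and each fixed-width bin
(300 bp default) the polymerase track is

    PT = (R_T − R_B) / (R_T + R_B)

where `R_T` and `R_B` are rNMP counts on the top and bottom strands.
PT ∈ [−1, 1]; positive values mean predominant synthesis of the top strand.
Tracks are computed per biological replicate and then averaged per bin.
Bins with `R_T + R_B = 0` get PT = 0 and a `low_coverage` flag (kept, not
interpolated, so downstream differentials stay defined and users can audit
them); replicate averaging propagates the flag by OR and zeroes flagged bins.

## Origin calling

1. Smooth each replicate-averaged track with a centred simple moving
   average, window 3. At chromosome ends the window truncates to the
   available bins (never padded with zeros, which would fabricate
   differential peaks at the ends); smoothing never crosses chromosome
   boundaries.
2. Differentiate: `Diff_i = PT_i − PT_{i−1}` per chromosome, with the first
   bin of each chromosome assigned 0.
3. Combine: average the Polε differential with the **negated** Polδ and Polα
   differentials (lagging-strand bias is the mirror image of leading-strand
   bias), then smooth again with the window-3 moving average.
4. Peak detection: candidate peaks are maximal runs of strictly positive
   combined differential. "Positive" means greater than 1e-12 — a numerical
   guard, since exact-arithmetic flat tracks leave ±1e-16 rounding dust
   after the cumulative-sum moving average. A run containing two or more
   distinct local maxima at consecutive index distance ≥ 4 bins is split
   into independent peaks at the minimum-value bin strictly between the
   pair; ties pick the leftmost minimum, and the minimum bin is assigned to
   the left peak (the split conserves the parent's sum). Plateaus of equal
   values count as one maximum at their leftmost bin; a plateau is a maximum
   only if strictly higher than both flanking values.
5. Filtering: the 30th percentile (linear interpolation between order
   statistics) of the genome-wide distribution of candidate-peak maxima is
   the threshold; peaks with maxima ≥ threshold are retained. The
   percentile population is peak maxima, not all differential values —
   filtering on all bin values would discard nearly every peak. Retention
   uses ≥ so an all-equal population survives.
6. Each surviving peak is an origin at its maximum bin, with raw firing
   efficiency = 0.5 × the peak's summed values. The rationale: summed
   differentials telescope to the PT step across the origin, and that step
   equals twice the fraction of cells in which the origin fires actively.
   Efficiencies are then normalised so the most efficient origin is 100%.

Degenerate geometry worth knowing about: when a weak origin sits exactly
midway between two stronger neighbours, the neighbours' fork-collision
midpoint coincides with the weak origin, and the collision's negative
differential cancels part of the origin's positive step, biasing its
efficiency downward. This is a property of the differential method itself;
real genomes, with irregular origin spacing, rarely produce the exact
coincidence.

## Region selection and meta-profiles

* Efficient origins: normalised efficiency ≥ 40% (threshold configurable).
* Termination zones: the interval strictly between two **adjacent**
  efficient origins (both strictly above 40%), rejected if any
  intermediary-efficiency origin (open interval 20–40%) lies strictly
  between them; origins at or below 20% never disqualify. The two slightly
  different flank criteria (≥ 40 for the efficient-origin list, > 40 for
  zone flanks) are deliberate and independently configurable. Zone midpoint
  is the floor of the flanking bins' mean. Thresholds apply to normalised
  efficiencies (they are quoted as percentages of the maximum); raw-scale
  thresholds can be passed instead.
* Origin meta-profile: mean track value at offsets −flank..+flank around
  each origin bin (default flank 50 bins = 15 kb); origins whose flank
  leaves the chromosome are dropped and counted.
* Termination meta-profile: each zone's values are rescaled to a common
  even number of bins (default 20) by averaging the original bins whose
  centres fall in each rescaled bin, and centred on the zone midpoint.
  When a zone is upsampled (allowed down to n/2 original bins; shorter
  zones are dropped and counted), rescaled bins that capture no original
  bin centre are filled by linear interpolation at the rescaled-bin centre.
  Rescaling conserves the zone mean to within (max−min)/n_original.
* Efficiency histograms use half-open bins [e_i, e_{i+1}).

Regions are intended to be selected once from a reference (wild-type)
strain's calls and then applied to every strain's tracks; the CLI takes the
origin table and the track directory independently for this reason.

## The replication simulator

Each simulated cell replicates the genome from a set of origins. Origin
`k` fires with probability `p_k`; if it fires, the firing time is
exponential with mean `τ_k` (a `deterministic` mode uses exactly `τ_k`,
handy for constructing exact fork-collision geometries). Fired origins
launch two forks moving outward at a constant speed `v` (bins per time
unit). A bin is replicated by whichever fork reaches it first; an origin
reached by a fork before its own firing time is passively replicated and
never fires. Because any fork path through an unfired origin is dominated
by the direct path, the replicator of bin `x` is simply the origin
minimising `t_k + |x − x_k|/v`, which is how the vectorized implementation
computes it; the test suite checks it bin-for-bin against an event-driven
single-cell simulator that moves forks explicitly, over a shared
firing-time stream.

Conventions, chosen for exactness of downstream identities:

* Arrival ties resolve by priority leftward fork > in-place firing >
  rightward fork ("the leftward fork wins"); with two equally-timed
  converging forks the meeting bin counts as leftward-replicated.
* A fired origin's own bin contributes 0.5 to each direction, so PT crosses
  zero at the origin.
* A bin never replicated in a cell (no origin fired on that chromosome)
  contributes 0.5 to each direction — no net strand bias. This keeps
  f_right + f_left = 1 for every bin and makes the PT step across an
  isolated origin exactly twice its realized efficiency, the identity the
  efficiency estimator relies on.

Realized efficiency of an origin is the fraction of cells in which it fired
actively; it never exceeds `p_k` and approaches it for isolated origins.

Counts are sampled per polymerase dataset and replicate: with signal strand
fraction `s = f_right` (Polε) or `1 − f_right` (Polδ/Polα), mean depth λ
per bin (top + bottom together) and background fraction `b` spread evenly
over both strands,

    top ~ Poisson(λ[(1−b)s + b/2]),   bottom ~ Poisson(λ[(1−b)(1−s) + b/2]).

The background emulates direction-free signal (residual repair, mapping
noise). Replicate `r` of a run seeded `S` draws from seed `S + r`, mixed
with a polymerase code so the two lagging-strand datasets are not
count-for-count identical. What the simulator does **not** model: per-mutant
rNMP incorporation-rate differences (all three datasets get equal depth, as
no quantitative rates are established), replication-timing chromatin
structure, fork stalling, or library-preparation biases beyond Poisson
counting. Passing tests therefore demonstrate correctness of the analysis
given fork-direction-driven strand bias with Poisson noise, not robustness
to every artefact of real libraries.

## Benchmark study

`puseq.benchmark` fixes one reference study used by the test suite and the
acceptance script: a 3,000-bin (900 kb) chromosome, ten origins with firing
probabilities spanning 0.2–1.0 (fixed shuffled order), mean firing time 1.5
time units, fork speed 10 bins per time unit (≈3 kb/min at 300 bp bins, the
fission-yeast range), depth λ = 50, background 5%, two replicates, 10,000
cells. Origin positions sit on a 300-bin pitch with fixed jitter (minimum
spacing 165 bins) to avoid the equal-spacing degeneracy described above.
Recovery is scored by matching each true origin to the strongest call
within ±5 bins (the smoothing width), then RMSE and Spearman rank
correlation (computed by the exact rank-difference formula, so perfect rank
agreement is exactly 1.0) against realized efficiencies. Typical results:
RMSE ≈ 0.03 — dominated by the (1−b) compression of PT that the estimator,
faithfully to the published procedure, does not correct — and ρ = 1.0.

## Auxiliary formulas

* Relative transcript level from qPCR: `2^−Cq(target) / 2^−Cq(reference)`
  = `2^(Cq_ref − Cq_target)`; invariant to a common Cq shift.
* Doubling time: ordinary least-squares slope `k` of log2(OD) against time
  (hours), `DT = 1/k`; invariant to OD rescaling, so dilution-corrected
  series can be fitted directly. No amplification-efficiency correction or
  ΔΔCq designs.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open (BED) on disk; bin `i` spans
  `[i·w, min((i+1)·w, length))` and the last bin may be short.
* Missing bins in count tables are zero-filled (sparse bedGraph is normal);
  misaligned intervals, unknown chromosomes and negative counts are errors.
* An all-probability-zero origin set is an error ("unreplicable genome").
* Empty peak lists filter to empty with a warning; normalising an empty
  origin list is an error.
* All randomness flows through `numpy.random.default_rng` from named seeds;
  every simulation is reproducible from its seed.

## Known limitations

* Origin efficiencies are compressed by the background fraction (factor
  1−b) and slightly truncated by converging-fork gradients; both are
  properties of the published estimator, reproduced deliberately.
* The percentile filter assumes many candidate peaks genome-wide; on tiny
  clean signals with a handful of peaks it can remove genuine weak origins
  (tests that probe estimator properties therefore disable it).
* Termination-zone rescaling assumes zones of at least half the rescaled
  bin count; very short zones are excluded rather than extrapolated.
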