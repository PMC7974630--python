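# puseq

Analysis of polymerase usage sequencing (Pu-Seq) data: per-bin polymerase
tracks, replication-origin calling with firing-efficiency estimation,
termination-zone selection, and origin/termination meta-profiles — together
with a stochastic replication-program simulator that generates
strand-specific rNMP count tables with known ground truth.

**Who it is for.** Pu-Seq maps which replicative polymerase (Polδ, Polε,
Polα) synthesised each genomic strand, by sequencing ribonucleotides
misincorporated by mutant polymerases in ribonucleotide-excision-repair
deficient (`rnh201Δ`) cells. Since Polε synthesises the leading strand and
Polδ/Polα the lagging strand, the strand bias of each dataset reports local
replication-fork direction. This package takes the binned per-strand rNMP
counts (e.g. the processed tables deposited with such experiments) and
produces origin positions, firing efficiencies, termination zones and
meta-profiles; the built-in simulator lets you validate the whole pipeline
against known truth before touching real data.

**The statistics at the core.** For rNMP counts R_T, R_B on the top and
bottom strands of a bin, the polymerase track is PT = (R_T − R_B)/(R_T + R_B),
computed per replicate and then averaged. Tracks are smoothed (simple moving
average, window 3) and differentiated per chromosome (Diff_i = PT_i − PT_{i−1},
first bin 0); the Polε differential is averaged with the negated Polδ and
Polα differentials and smoothed again. Positive peaks of this combined
differential mark origins (multi-maxima runs separated by ≥ 4 bins are split;
peaks below the 30th percentile of peak maxima are discarded), and an
origin's firing efficiency is half the summed differential over its peak —
the PT step across an origin is twice the fraction of cells in which it
fires actively. Efficiencies are normalised so the strongest origin is 100%.
Efficient origins (≥ 40%) and termination zones (between adjacent origins
> 40%, containing no origin in the open 20–40% band) feed centred and
length-rescaled meta-profiles. See `docs/methods.md` for the full model.

## Worked example

Simulate the built-in ten-origin benchmark chromosome (900 kb, 300 bp bins,
mean depth 50 rNMPs per bin, 5% direction-free background, two replicates,
10,000 cells) and recover origin efficiencies:

```python
from puseq.benchmark import run_recovery

r = run_recovery(seed=1)
print("origins called:", r["n_called"])
print("efficient origins (>=40%):", r["n_efficient"])
print("termination zones:", r["n_zones"])
for true, est in zip(r["realized_efficiency"], r["estimated_efficiency"]):
    print(f"  realized {true:.3f}  estimated {est:.3f}")
print(f"RMSE {r['rmse']:.4f}  Spearman rho {r['spearman']:.1f}")
```

prints

```
origins called: 311
efficient origins (>=40%): 7
termination zones: 4
  realized 0.200  estimated 0.211
  realized 0.646  estimated 0.606
  realized 0.373  estimated 0.366
  realized 0.819  estimated 0.784
  realized 0.558  estimated 0.529
  realized 1.000  estimated 0.961
  realized 0.282  estimated 0.284
  realized 0.735  estimated 0.729
  realized 0.464  estimated 0.484
  realized 0.913  estimated 0.869
RMSE 0.0279  Spearman rho 1.0
```

`realized` is the ground-truth fraction of simulated cells in which each
origin fired actively (rather than being passively replicated by a
neighbour's fork); `estimated` is what the differential-peak pipeline
recovers from the noisy counts. The 311 calls include many small noise
peaks that survive the percentile filter with tiny efficiencies; the
normalised ≥ 40% filter reduces them to the genuinely efficient origins.
The slight compression of high efficiencies (0.96 for a
fires-in-every-cell origin) is the expected effect of the 5% background,
which the published estimator does not correct for.

The same pipeline is available from the shell:

```sh
puseq simulate --config sim.yaml --out-dir counts/ --seed 1
puseq tracks --counts-dir counts/ --layout chrom.sizes --out-dir tracks/
puseq call-origins --tracks-dir tracks/ --layout chrom.sizes --out-prefix origins
puseq zones --origins origins.tsv --layout chrom.sizes --out zones.bed
puseq profile --tracks-dir tracks/ --layout chrom.sizes --origins origins.tsv \
      --mode termination --out tz_profile.tsv
```

Real data drop in at the `tracks` step: the reader accepts either a
combined 5-column TSV (`chrom start end count_top count_bottom`) or paired
4-column bedGraphs per strand, named `{strain}_{polymerase}_rep{N}.counts.tsv`
with polymerase in {delta, epsilon, alpha}. All readers and writers are
gzip-transparent, and all on-disk coordinates are 0-based half-open
(BED-compatible).

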