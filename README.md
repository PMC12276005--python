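# tagbench

Benchmarking pipeline for a specific confound in G-quadruplex (G4) mapping:
untargeted Tn5 tagmentation background at accessible chromatin in CUT&Tag
experiments.

## The problem

CUT&Tag maps chromatin features by directing a Protein A–Tn5 fusion to an
antibody-bound target, where the transposase fragments and tags nearby DNA.
Applied to G4 DNA structures (via the BG4/SG4 probes or G4-stabilizing
ligands), the method has a structural weakness: G4s form in nucleosome-free,
open chromatin, and Tn5 also tagments open chromatin *untargeted* — exactly
what ATAC-seq exploits deliberately. A "negative control" CUT&Tag library
without a targeting antibody is therefore not flat background: it is
enriched at the same accessible sites the G4-targeted library is, especially
when the control library has low complexity. Using such a control — either
inside a sparse-enrichment peak caller or in a differential read-count test —
subtracts real G4 signal along with the background, trading recall of true
G4 sites for precision.

`tagbench` implements the full evaluation stack for quantifying this
trade-off, exercised end-to-end on a synthetic tagmentation data generator
so that every claim can be tested against a known ground truth:

| module | what it does |
|---|---|
| `tagbench.simulate` | synthetic genomes, accessible/G4 site maps, fragment libraries (accessibility-driven background + targeted capture + Poisson PCR duplication) |
| `tagbench.complexity` | duplication histograms, zero-truncated Poisson unique-molecule estimation, ratio-based downsampling, deduplication |
| `tagbench.coverage` | binned coverage tracks, CPM, FRiP, peak count matrices, background (median-of-ratios) size factors, correlation matrices |
| `tagbench.peaks` | sparse-enrichment peak calling on signal-block AUCs, threshold mode and control mode |
| `tagbench.intervals` | interval sets, multi-library consensus, precision/recall/F1, Jaccard, width-preserving shuffled nulls, Fisher association |
| `tagbench.differential` | per-peak negative-binomial Wald test of targeted vs untargeted counts, BH-adjusted |
| `tagbench.workflow` / CLI | scenario orchestration and the `tagbench` command line |

## The statistics at the core

**Library complexity.** With N unique molecules each sequenced a
Poisson(λ) number of times and unobserved molecules truncated away, total
reads R and observed unique u satisfy R/u = λ/(1 − e^(−λ)). Solving for λ
gives N̂ = R/λ̂; libraries are equalized by Bernoulli read thinning at
p = target/N̂ followed by deduplication.

**Peak calling.** A signal block is a maximal run of nonzero coverage
bins; its AUC (Σ value·bin width) is thresholded. Threshold mode keeps the
top fraction f of blocks. Control mode scales an untargeted control to the
target's total AUC and picks the cutoff t\* maximizing
frac_target(AUC > t) − frac_control(AUC > t), searched over cutoffs where
that difference exceeds twice its binomial standard error.

**Benchmarking.** Peak-level precision (fraction of called peaks touching
a true site) and recall (fraction of true sites touched), Jaccard on base
pairs, and significance calibrated against width-preserving shuffled nulls.

**Differential enrichment.** Counts in peaks, normalized by
median-of-ratios size factors from 15 kb background bins, tested per peak
with an NB Wald statistic (method-of-moments dispersion shrunk halfway to
the across-peak median, Student-t reference with effective df
4·(n_T + n_U − 2)); peaks with BH FDR < 0.05 and log2FC > 0 count as
significantly target-enriched.

## Worked example

Run the default synthetic scenario (3 targeted + 3 matched untargeted
libraries sharing one genome with 75 true G4 sites among 300 accessible
sites):

```python
import json, tagbench as tb

summary = tb.run_scenario(tb.ScenarioConfig(seed=1))
print(json.dumps({k: summary[k] for k in
                  ("n_g4_true", "threshold_reference", "control_mode")},
                 indent=2))
```

prints

```json
{
  "n_g4_true": 75,
  "threshold_reference": {
    "f": 0.01,
    "n_peaks": 31,
    "precision": 1.0,
    "recall": 0.41333333333333333
  },
  "control_mode": {
    "n_peaks": 28,
    "precision": 1.0,
    "recall": 0.37333333333333335,
    "f1": 0.5436893203883496
  }
}
```

Both strategies call only true G4 sites (precision 1.0), but calling
against the matched untargeted control recovers fewer of them (recall 0.373
vs 0.413) — the control "explains away" G4 sites that sit in strongly
accessible chromatin. The depth-imbalance experiment shows the companion
effect on differential testing:

```python
from tagbench.workflow import depth_confound_experiment
print(depth_confound_experiment(seed=1))
```

```
{'n_regions': 2653, 'n_significant_up_dedup_only': 32,
 'n_significant_up_complexity_normalized': 4}
```

With targeted libraries 5× deeper than their controls and only modest
per-site enrichment, 32 peaks test significant after deduplication alone,
collapsing to 4 once library complexity is normalized first — the extra
sequencing depth, not G4 binding, carried most of the significance.

The same pipeline is scriptable from the shell:

```bash
tagbench fixtures --seed 0 --outdir fixtures
tagbench callpeaks fixtures/targeted_1.bed4 --genome fixtures/genome.tsv \
    -f 0.05 --out peaks.bed
tagbench bench peaks.bed fixtures/g4_true.bed --genome fixtures/genome.tsv
tagbench scenario --seed 1
```

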