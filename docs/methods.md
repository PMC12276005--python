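# Methods

This note documents the models and procedures implemented in `tagbench`,
the parameters that matter, the numerical choices, and the limits of what
the synthetic data can show.

## 1. The synthetic tagmentation model

### Genome and site map

The default genome is 3 chromosomes × 10 Mb with 1% of each chromosome
blacklisted in 10 kb blocks — large enough for sparse peaks, small enough
that every analysis runs in seconds. `simulate_genome` places
`n_accessible` (default 300) non-overlapping accessible-chromatin sites of
`accessible_width` (800 bp) uniformly on non-blacklist sequence. Each site
receives a relative accessibility weight drawn lognormal(0, `weight_sigma`)
and normalized to sum to 1.

`round(g4_fraction × n_accessible)` sites are flagged as true G4 sites,
sampled **without replacement with probability proportional to
accessibility weight**, and each G4 interval (150 bp) is centered inside
its accessible site. The weight-proportional selection is deliberate: G4s
form in nucleosome-free chromatin and are concentrated at strongly
accessible promoters, and the confound this package quantifies only exists
when G4 sites and untargeted Tn5 background share the same high-weight
sites. `weight_sigma = 1.5` is the default for the same reason: with a
flatter weight distribution (σ = 1.0) the untargeted control does not
colocalize with the targeted signal strongly enough for a control-based
caller to subtract real G4 peaks, which is not the regime of interest.

### Fragment libraries

`simulate_library` draws `n_unique_molecules` molecules from a three-way
placement mixture:

1. with probability `p_target` — centered on a true G4 site (site chosen by
   accessibility weight among G4 sites), Gaussian jitter `jitter_sd`
   (150 bp);
2. else with probability `p_accessible_bg` (0.7) — centered on an
   accessible site chosen by weight, same jitter;
3. else — uniform on non-blacklist sequence.

Fragment lengths are Normal(200, 60) rounded and truncated at 30 bp;
fragments are clipped into chromosome bounds preserving length. Each
molecule then receives Poisson(λ) sequencing draws
(`mean_depth_per_molecule`, default 2), molecules with zero draws are
dropped, and the draw count is stored as the record's copy count. This
makes the complexity estimator's sampling model *exactly* correct on
simulated data, which is what enables the parameter-recovery tests. An
optional per-molecule lognormal amplification bias (off by default)
violates that model on purpose; with it enabled the estimator is expected
to mis-estimate, which is documented rather than asserted.

`p_target = 0.6` is a free scenario knob, not an estimate — the real
targeted:background mixture of G4 CUT&Tag libraries is not known — and the
default scenario treats it as such.

Records with identical (chrom, start, end) are aggregated at construction
(copy counts summed). This keys everything — duplication histograms,
deduplication, file round trips — on fragment coordinates, matching
paired-end deduplication semantics. Distinct molecules that collide on
coordinates are therefore merged; collisions are negligible in every test
configuration (the calibration libraries place molecules uniformly over
~29.7 Mb), but at zero jitter all molecules of one site share coordinates,
so molecule-level statistics must then be read from copy counts.

### What the generator does *not* emulate

No sequence content, no alignment errors, no nucleosome positioning, no
fragment-length chromatin signature, no per-site saturation of insertable
positions, no optical duplicates, no cross-site correlation beyond the
shared weight vector. Consequences: passing tests show the *analysis
stack* behaves as specified under a known generative model; they do not
show that real G4 CUT&Tag libraries satisfy that model. In particular,
real duplication histograms mix PCR duplication with per-site insertion
saturation, so real-data complexity estimates inherit the biases of their
estimator in ways the simulation cannot reveal.

## 2. Library complexity

The estimator solves λ/(1 − e^(−λ)) = R/u for λ (Brent's method on
[10⁻¹², R/u + 1], relative tolerance 10⁻¹²) and reports N̂ = R/λ̂. This is
the exact maximum-likelihood estimator under the generator's zero-truncated
Poisson duplication model; it replaces the rational-function extrapolation
used by common QC tools with a closed, testable specification. When R = u
(no duplicates) the estimator is unbounded and the observed unique count is
returned with a `no_duplicates` status.

Downsampling thins each *read* independently (Bernoulli, fixed seed) at
p = target_unique / N̂, matching the contract of per-read random
subsampling in alignment tools; the limiting library is thinned at p = 1
(identity). Note a saturation caveat: ratio thinning equalizes *estimated*
complexity, but the *observed* unique counts after thinning,
N_a(1 − e^(−pλ)) vs N_b(1 − e^(−λ)), agree only in the unsaturated (small
λ) limit. At λ = 2 and a 3.3× complexity ratio they differ by ~40%. The
equalization property is therefore exercised at λ = 0.15 in the tests, and
consumers should expect only approximate equalization of observed counts
for heavily duplicated libraries.

## 3. Coverage and counting

Tracks are dense per-chromosome vectors at `bin_size` 50 bp. `span` mode
increments every bin a fragment overlaps (input to peak calling);
`midpoint` mode increments the single bin holding the fragment midpoint
(left-biased for even lengths), the analog of paired-end read centering —
under midpoint counting CPM sums to exactly 10⁶. CPM here always uses the
actual fragment total; the effective-genome-size constant used for real
human data applies only there. Zero bins are retained in memory; the
bedGraph writer collapses equal-value runs.

Count matrices count reads (copy-weighted; one per molecule after
deduplication) overlapping each merged region by ≥ 1 bp; a fragment
spanning two regions counts in both. Background size factors are
median-of-ratios over 15 kb bins (all libraries nonzero), i.e. a
DESeq-style size factor computed away from peaks, so that global depth is
normalized by background rather than by signal.

## 4. Peak calling

Signal blocks are maximal runs of positive bins; block AUC = Σ(value ×
bin width); edges stay bin-aligned (no sub-bin trimming).

**Threshold mode** retains blocks with AUC ≥ the empirical (1 − f)
quantile (type-1, inverse-ECDF — "top f fraction" is exact for distinct
values, m = ⌈fn⌉ blocks with an ε-guard against float fuzz in f·n); ties
at the cutoff are all retained.

**Control mode** scales control AUCs by the total-AUC ratio and searches
candidate cutoffs (the union of both AUC lists) for
t\* = argmax[frac_target(AUC > t) − frac_control(AUC > t)], ties toward
the largest candidate; `stringent` keeps target blocks above t\*,
`relaxed` backs off to the smallest candidate reaching 90% of the maximal
difference. This is a simplified, fully specified restatement of
sparse-enrichment control normalization, not a re-implementation of any
external caller: the conclusions it supports depend on the
threshold-vs-control contrast, not on tool internals.

Two numerical guards were found necessary for the rule to behave sanely at
its own boundary cases:

* *Lattice alignment.* Integer-count tracks put block AUCs on a bin-size
  lattice. Scaling the control by s ≈ 1 shifts its atoms fractionally off
  that lattice, and a strict `>` comparison then sees a spurious fraction
  difference as large as 0.29 between two statistically identical tracks.
  Scaled control AUCs are snapped to the target's AUC quantum (the minimal
  spacing of its distinct AUCs) before the search.
* *Significance guard.* The maximal fraction difference of two independent
  identically distributed tracks is always positive, so "max difference
  ≤ 0 → no peaks" alone never fires. The candidate search in
  `call_peaks_with_control` is restricted to cutoffs whose difference
  exceeds **2 pooled-binomial standard errors**; if no candidate qualifies
  the control explains the target and the call set is empty. With this
  guard an untargeted-vs-untargeted comparison returns no peaks across
  seeds, while the default scenario's genuine separation (a small but
  many-sigma excess of target blocks above every scaled control block)
  survives. `control_threshold(..., min_z=0)` exposes the unguarded rule.

## 5. Interval statistics

All overlap criteria are ≥ 1 bp; merging joins overlapping and book-ended
(gap 0) intervals. Consensus partitions the genome at all breakpoints,
keeps atoms covered by ≥ `min_count` merged input sets (default:
⌈n/2⌉ — "at least 50% of libraries"), and merges book-ended survivors.
Precision/recall count peaks, not base pairs (one query spanning two
reference peaks is one true-positive query but two recalled references),
consistent with their definitional reading. Empty query or reference
leaves precision or recall flagged undefined (NaN) rather than 0 — the
no-peaks case genuinely occurs (the default scenario returns an empty
control-mode consensus on some seeds) and silently reporting 0 would
invert its meaning for precision.

Shuffled nulls re-place each interval uniformly on the genome, preserving
width, rejecting placements that touch the exclusion set or a previously
placed interval (error after `max_tries`). The Fisher 2×2 table fills its
"neither" cell with a genome-segmentation heuristic (genome bp / mean
interval width over both sets); it is reported as a heuristic, and the
shuffled-null F1/Jaccard comparison is the primary significance device.

## 6. Differential enrichment

Per peak: normalized counts x = count/size-factor; group means μ_T, μ_U;
method-of-moments NB dispersion within each group, α = (s² − μ)/μ²
clipped at 0, pooled across groups with (n_g − 1) weights, shrunk halfway
to the across-peak median, floored at 10⁻⁸; log2FC with pseudo-count 0.5;
Wald statistic log2FC/SE under Var(x) = μ + αμ². The statistic is
referred two-sided to a **Student t with 4·(n_T + n_U − 2) degrees of
freedom**: halving the dispersion-estimate noise through the 0.5 shrinkage
quadruples the estimator's effective degrees of freedom
(Satterthwaite-style), and this reference reproduces the nominal 5% type-I
error in the package's own null calibration (a plain normal reference is
measurably anticonservative at 3 vs 3 — ~8% — while unshrunk-df t is
crushingly conservative). With a single library per group there are no
residual degrees of freedom and the statistic falls back to a normal
reference with the shrinkage target carrying the dispersion. All-zero
peaks report p = 1 and log2FC = 0 and are never dropped. BH adjustment is
applied across all peaks; "significantly enriched" means FDR < 0.05 *and*
log2FC > 0, and both the directional and total significant counts are
reported.

## 7. Scenario design

Two experiments are packaged, with conditions chosen once as study
conditions:

**Strategy contrast** (`run_scenario`): 3 targeted libraries (30 000
unique molecules, p_target 0.6) and 3 matched untargeted libraries (12 000
unique molecules, p_target 0) sharing one genome. The untargeted arm is
sequenced shallower, as matched negative-control libraries typically are;
12 000 is chosen so both arms carry comparable numbers of uniform-noise
blocks, which keeps the control-mode cutoff search focused on the
accessible/G4 signal rather than on noise-count imbalance. Threshold-mode
calls at f ∈ {0.001 … 0.1} and control-mode calls (replicate i vs matched
control i, all-replicate consensus) are benchmarked against the true G4
set. Under these conditions control-mode calling retains only the
strongest true G4 blocks: precision does not drop, recall does.

**Depth confound** (`depth_confound_experiment`): every accessible site
carries a target (g4_fraction 1) but capture is weak (p_target 0.25), so
per-site targeted excess is modest; targeted libraries have 5× the unique
molecules of their controls. Regions are the union of per-library
top-10% peaks. With deduplication only, the depth advantage carries many
marginal peaks over the significance line; after downsampling to the
limiting complexity the same test finds almost none. With equal-depth
arms the two branches are statistically indistinguishable. The marginal-
excess regime is the point: when targeted enrichment over background is
large, significance is insensitive to normalization, and no collapse can
be observed.

Determinism: one global seed spawns per-stage child seeds as
crc32(stage name) XOR (seed × 2654435761) mod 2³¹−1, so any stage can be
rerun in isolation; identical configuration and seed give identical
summaries and byte-identical files.

## 8. Problem sizes

Defaults are desk-scale by design: 30 Mb genome, 10⁴–10⁵ molecules per
library, 2 000 peaks in calibration simulations, 20 seeds for estimator
recovery and type-I measurement, 100 width-preserving shuffles for the
null F1 band. The full test suite runs in well under a minute on one CPU.

## 9. Known limitations

* The complexity estimator is exact only under Poisson duplication; PCR
  amplification bias (lognormal option) or per-site saturation bias it.
* Control-mode calling operates on block *fractions*; with very few
  blocks (tens) the 2-SE guard makes it conservative, returning no peaks
  on weak instances.
* The Fisher n22 heuristic makes absolute Fisher p-values
  interpretation-limited; use the shuffled nulls for calibrated
  significance.
* Peak-level precision/recall ignores partial-overlap geometry; Jaccard
  is the base-pair-level complement.
* No covariate modeling, LOESS MA-trend fitting, or independent filtering
  in the differential test.
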