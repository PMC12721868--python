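# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `ribopause`, and what the synthetic benchmarks do and do
not demonstrate about real data.

## Coordinates and footprint geometry

All coordinates are 0-based, half-open, transcript-relative. The CDS spans
`[cds_start, cds_end)`, includes the stop codon, and must carry ≥ 21-nt
flanks so that footprints of initiating and terminating ribosomes remain on
the transcript. The figure conventions (start A at 0; last stop nucleotide
at −1) are applied only when rendering metagene profiles.

A-site assignment adds a per-(length, frame) offset to the 5′ end and takes
the floor division by 3: offsets 16/16/17 for (28, frame 0), (29, frame 0)
and (29, frame 2). Because the offset may point at any nucleotide of the
A-site codon, the floor makes assignment robust to which nucleotide the
offset lands on. The offset table is fixed configuration, not re-inferred
from data; the empirical initiation peak (−12 nt for 28-nt frame-0 reads,
i.e. A site one codon downstream of the start) can be read off a
start-anchored metagene profile as a diagnostic but never overrides the
table. Disome footprints are assigned unconditionally with a 45-nt offset
to the lead ribosome's A site; with the 30-nt queue spacing this places
successive collided pairs exactly 10 codons apart.

The simulator emits footprints at the unique 5′ position that is congruent
to the read's frame (mod 3) and assigns back to the emitting codon:
`five_prime = cds_start + 3k − offset + ((offset + frame) mod 3)`. This
makes A-site assignment the exact inverse of emission — the round-trip
identity holds for 100% of elongating monosome and all disome footprints,
and is enforced by tests.

**Termination.** A terminating ribosome accommodates 4 nt in its A site
during stop-codon recognition. We place its 28-nt footprint at exactly
−18 nt in stop-anchored coordinates (the elongation-geometry position for a
ribosome decoding the stop codon), and its directly queued partner at −48 =
−(28 + 2 + 18). These positions are geometry inputs, not the output of a
nuclease-digestion model; in particular the ±1-nt apparent frame shift that
real terminating footprints display is *not* modelled, because under the
frame-0 emission convention a shifted terminating footprint would land off
the −18 position that defines the queue arithmetic. The −18/−48 peak pair
and the 2-nt inter-ribosome gap are what the termination model guarantees.

## The synthetic-data generator

The generator is first-class, tested code. It emulates:

* CDSs of 120–400 codons (yeast-scale), ATG-initiated, one stop codon,
  internal codons i.i.d. from a configurable usage (uniform over the 61
  sense codons by default), 21-nt random flanks;
* per-codon dwell weights times (P, A) codon-pair multipliers, per
  genotype — the stalling model in which the pair, not the single codon,
  sets the hazard;
* explicit stall sites with a queue-depth distribution; slot *m* behind the
  lead carries occupancy ∝ P(depth ≥ m+1), so decaying depth distributions
  give the lead peak dominance;
* monosome read classes (28 frame 0 : 29 frame 0 : 29 frame 2 at
  0.7 : 0.225 : 0.075 by default) and disome lengths uniform on 56–64 nt;
* initiation (weight 5 at codon 1) and termination (weight 5 at the stop,
  2 at the −48 queue slot) occupancy, all relative to a baseline elongating
  codon weight of 1;
* negative-binomial gene-level counts over a 2-genotype × 2-fraction design
  with lognormal baseline means, per-sample size-factor noise, a
  genotype-independent disome/monosome ratio, and planted per-gene
  interaction effects with truth labels.

Sampling is a single multinomial over (gene, codon, read-class) cells per
library, so counts are conserved exactly and a seed pins the byte-level
output. Random numbers are consumed in a fixed order: transcriptome first,
then genotypes in listed order, replicates in order, monosome before disome;
per-library generators are spawned from the seed with `SeedSequence`, so
adding a genotype does not perturb the libraries of another.

What it does **not** emulate: sequencing error, rRNA/ncRNA contamination,
nuclease-digestion length heterogeneity beyond the three read classes,
UTR-dependent initiation rates, or correlated biological replicate
variation (replicates differ only by counting noise). Passing tests
therefore demonstrate the correctness of the score algebra and geometry
handling, and the statistical calibration of the tests under the assumed
NB/multinomial noise — not robustness to the full messiness of real
libraries.

## Score definitions and numerical conventions

* **Pause score** (per gene, trim 15 codons per end): count divided by the
  mean count over included positions; the included range is 0-based
  positions `15 .. l−16` (`l − 30` positions). Genes below 0.1 reads/codon
  (over the whole CDS) are dropped; a retained gene with zero included
  reads is dropped with a warning. Scale invariance and the exact mean-1
  identity are property-tested.
* **Vulnerability**: pause scores recomputed on counts + 1 for both
  genotypes (the pseudocount exists only here, to keep ratios finite);
  per-instance score = median over all mutant × wild-type replicate-pair
  ratios (the pairing is deliberately exhaustive since no pairing of
  replicates is canonical); per-instance two-sample Student's t test
  across replicates. Only genes passing coverage in *every* replicate of
  both genotypes are scored, so instance sets align exactly.
* **Read-based speed**: codon frequencies pooled over the transcriptome
  (not per-gene), A-site versus the mean of +1/+2/+3 frequencies;
  downstream sites never read into the stop codon. The mutant/wild-type
  ratio uses replicate-mean rates, is log₂-transformed and median-centred
  over the 61 codons (exact-zero median by construction); significance is
  a one-sided Welch t test (mutant slower) at P < 0.05 with centred
  log₂FC > 0.1; no multiplicity correction is applied to the 61 tests.
* **Decile binning**: instances ranked ascending, remainder rows assigned
  to the lower bins; enrichment = within-bin codon frequency over overall
  frequency.
* **Residue enrichment** (positions −1..−30 upstream, amino-acid level):
  two-sided binomial test of top-set frequency against background
  frequency, Bonferroni over 30 × 20 cells at corrected P < 0.01. The
  binomial treats the background as fixed; with a background of similar
  size to the top set the family-wise guarantee is only approximate (the
  effective z is inflated by √2), so null calibration is tested with a
  background an order of magnitude larger. A continuity floor
  (`p₀ ≥ 1/(n_bg + 1)`) prevents residues absent from the finite
  background sample from forcing p = 0. Windows that would cross the start
  codon are skipped, not padded.
* **Di-codon matrix**: the pair's pause score is the A-site position's
  score (the P-site codon is context); contributing positions need the
  P-site codon inside the trim (positions ≥ 16). Cells average over
  instances (instance-weighted, not ORF-weighted), then over replicates;
  genes must pass coverage in all replicates so occurrence counts are
  well-defined. Ratio cells with an empty or zero wild-type cell are
  undefined; the display copy clamps at 2; cells under 5 contributing
  instances are flagged low-support (threshold configurable — no such
  threshold is inherent to the ratio).
* **Site-aligned profiles**: instance-averaged (not gene-averaged);
  instances within the window span of a CDS end are skipped so the window
  stays inside the ORF. The replicate band is min/max by default
  (± sd available); the experimental-variation band has no canonical
  numeric definition, so min/max was chosen as the most conservative
  visual envelope. Queue peaks are local maxima within ±1 codon of
  −10, −20, … codons exceeding 2× the profile median; the tolerance
  absorbs offset rounding, and the default fold threshold is a package
  choice (peaks in the source figures are read by eye, not thresholded).

## The disome-enrichment interaction test

Per gene, counts follow a negative-binomial GLM with log link and design
`~ fraction + genotype + fraction:genotype`; the interaction (does the
disome/monosome ratio change with genotype?) is tested by a likelihood-ratio
test against the reduced model, χ²(1). Library sizes enter as offsets from
median-of-ratios size factors (computed on genes positive in all samples).

Dispersion is estimated in the DESeq2 spirit but deliberately simplified:

1. per-gene Cox–Reid adjusted profile likelihood (the adjustment
   `−½ log det(XᵀWX)` compensates for fitting 4 mean parameters to 8
   observations — without it dispersions are biased low and the LRT is
   anticonservative);
2. a parametric mean–dispersion trend `α(μ) = a₀ + a₁/μ` fitted by
   gamma-weighted IRLS with coefficients clipped at 0; estimates stuck at
   the lower optimisation bound (α ≤ 10⁻⁶, i.e. genes that look
   sub-Poisson by chance) are excluded from the trend and prior fits and
   receive the trend value;
3. maximum-a-posteriori re-estimation under a log-normal prior centred on
   the trend, prior variance = robust (MAD-based) spread of the log
   residuals minus the expected sampling variance `trigamma((m−p)/2)`,
   floored at 0.25. The MAP is found by optimising the penalised Cox–Reid
   likelihood rather than blending point estimates, which matters because
   the likelihood is flat toward α → 0 and symmetric blending under-shrinks
   exactly the genes that inflate the type-I error.

On a 2000-gene null with two replicates per cell this pipeline's observed
type-I error at α = 0.05 is ≈ 0.05 (the test suite asserts the
[0.035, 0.065] band), and its fold changes and p-values agree with
Bioconductor DESeq2 run on the same counts (r > 0.95 on log₂FC; checked in
the test suite through Rscript). Known limitations relative to the full
empirical-Bayes machinery: no dispersion-outlier handling, no Cook's
distance filtering, no independent filtering of low-count genes.

Classification applies the two contrasts independently (mutant vs wild
type; triple vs double mutant), BH within each contrast, adjusted P < 0.05,
and the sign rule (up-then-down = RQC target, down-then-up = RRT, anything
else = neither). Labels are exclusive and exhaustive over the intersection
of tested genes.

With two replicates, strong planted effects (|log₂FC| 2.5 at mean 1000) are
recovered at ≥ 95% sensitivity with zero observed false discoveries; at
moderate effects (log₂FC 1, mean 200, dispersion 0.05) the asymptotic power
of *any* estimator of this design is ≈ 0.55 and the pipeline tracks a
known-dispersion oracle within 0.05, so requiring joint BH significance in
both contrasts roughly squares the per-contrast power — genome-wide target
lists at such effect sizes are necessarily incomplete, which is why the
benchmarks quantify the false-discovery proportion rather than demanding
full recall there.

## Gene-set statistics

Log-fold-change distributions between gene sets are compared with the
one-sided two-sample Kolmogorov–Smirnov test (direction chosen by the
caller). Aggregation propensity uses strict thresholds — linear fold
change > 2 (aggregation-prone) and < 0.5 (non-aggregating) — cross-tabulated
against labels and tested two-sided by Fisher's exact test (sidedness is not
dictated by the source convention; two-sided is the conservative choice).
Codon/codon-pair content is compared as per-gene density per CDS codon with
a two-sided Mann–Whitney U test.

## Problem sizes used by the benchmarks

The shipped benchmarks run at desk scale by design: 200 genes × 10⁵ reads
for the termination geometry; 40 genes × 4×10⁵ reads for collision
spacing; 2000 genes × 5×10⁶ reads × 3 replicates for codon-speed recovery;
400 genes × 2×10⁶ reads for di-codon recovery; 2000 genes × 2 replicates
for the null calibration and planted-target recovery. These sizes give the
geometric checks exact answers and the statistical checks comfortable
margins over their assertion thresholds.
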