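# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, the numerical choices, and the known limitations of
`epirepeat`. Nothing here states an empirical result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Coordinates and interval semantics

All coordinates are 0-based half-open (the BED convention); GTF input
(1-based closed) is converted on read. Touching intervals do not overlap.
Strand is carried through I/O but ignored by all overlap and coverage
computations — the island analyses are unstranded. Subject intervals are
merged (union) before coverage, so overlapping annotation entries are never
double-counted, and `overlap_fraction` is invariant under merging of the
subject set.

## Island calling

The caller emulates spatial clustering of enriched windows for broad marks;
it is a reimplementation of the published design, not a binary-compatible
SICER port.

1. Each chromosome is tiled into non-overlapping windows (default 200 bp).
2. A window is *eligible* when its ChIP read count has a Poisson upper-tail
   probability ≤ 0.2 under the genome-wide background rate
   λ = reads × window / genome length. A read belongs to the window
   containing its start.
3. Eligible windows separated by ≤ gap (default 400 bp) of ineligible
   windows merge into an island. The island score is Σ −ln p over its
   eligible windows' Poisson tail probabilities.
4. Island significance is a Poisson test of the island's ChIP count against
   the library-scaled Input count, floored at the background expectation
   λ × island length / window (so an empty Input region cannot make weak
   enrichment look infinitely significant).
5. Benjamini–Hochberg across islands; islands with q ≤ FDR (default 0.001)
   are reported.

Reads are single-end, fixed length (default 36 bp), counted as overlapping
an interval when `[pos, pos + read_length)` intersects it. There is no
duplicate filtering, fragment-shift model, or mappability correction.

## Differential islands

At fixed islands, condition A versus B is a two-sided doubled-tail binomial
test of `count_A` out of `count_A + count_B` against
`p = library_A / (library_A + library_B)`, BH-corrected across islands. The
underlying published analysis states only a fold-change threshold (1.5) and
an FDR (0.001) without naming the test; the binomial against the
library-ratio null is this package's choice and is exact under
Poisson-distributed counts, which holds for the synthetic tracks.
Fold-changes are computed on RPBM densities with a pseudocount of 0.5 reads
(converted to density per interval and library) so empty islands stay
finite; "decreased" means the A/B density fold-change exceeds the threshold
at q ≤ FDR.

## Repeat enrichment

Per-island percent coverage of a repeat label is compared between the
observed island set and a matched random-region null: for each island,
`n_draws` (default 10) regions of identical length placed uniformly at
random on the same chromosome, pooled across draws. "Comparable size and
frequency" is interpreted as equal count, identical lengths, same
chromosome, uniform placement; assembly gaps are not excluded (synthetic
genomes have none). The comparison is the two-sample Kolmogorov–Smirnov
statistic with the asymptotic two-sided p-value; direction is the sign of
the mean coverage shift. The subfamily enrichment matrix divides the
observed percent of islands overlapping each subfamily by the mean over the
matched random draws, floored at 0.5 percentage points to keep ratios
finite; hierarchical clustering of rows is presentation plumbing.

The asymptotic KS p-value assumes continuous data. Percent-coverage
distributions carry an atom at zero whose size depends on annotation
density; with sparse annotations the test is conservative. The calibration
test therefore uses a dense instance (80 five-kb islands versus 800
500-bp elements on 2 Mb, zero-coverage atom ≈ 0.1), where the measured
null fraction of p < 0.05 is ~0.05.

## Expression

RPKM is `count / (length/10³) / (library/10⁶)` with the library as the
sample's total assigned counts. Differential expression pools counts per
group and applies the same doubled-tail binomial against the library-size
ratio, after excluding genes with RPKM below 3 in both groups; a gene is DE
at q ≤ 0.001 and |fold-change| ≥ 2. This test deliberately replaces a
dispersion-modelling negative-binomial GLM: with a single library per
condition no within-group dispersion is estimable, and the package needs a
self-contained test. Consequence, measured on synthetic data: under
negative-binomial noise at dispersion 0.1 the binomial is anticonservative
(several hundred false DE calls among 5000 null genes); under near-Poisson
noise (dispersion ≤ ~0.01) it controls type I error. Interpret DE lists from
overdispersed data as enrichment-ranked, not FDR-calibrated. Planted 4-fold
effects at healthy expression are recovered with sensitivity ≥ 0.9 even at
dispersion 0.1 because the effect dwarfs the noise.

k-means and PCA operate on log2(RPKM + 1); k-means standardises each gene
to z-scores first (constant genes get z = 0) and fixes the seed; PCA
centres and fixes the sign so the earliest control sample has negative PC1.

Repeat expression assigns a read to every element it overlaps, once per
element (no fractional weighting of multireads — an approximation of
best-alignment mapping). Label aggregates are total reads in the label's
elements over total element bp, per million mapped reads. The expressed-
element filter keeps elements strictly above 0.003 RPBM. Subfamily
fold-changes use the aggregate densities with a half-read pseudocount over
the label's total bp; swapping the tracks inverts every fold-change.

## The ordering (accelerated-differentiation) statistic

Inputs are three aligned per-gene expression vectors: control ESC, control
EB at stage s, knockdown EB at stage s (replicates averaged; one value per
condition). Genes upregulated ≥ α-fold in the control (ratio with a 0.1
RPKM pseudocount; α = 1 is boundary-inclusive) form the selected set. The
observed statistic is the fraction of selected genes satisfying the strict
ordering `EB_ctrl > EB_kd > ESC`; ties fail. The bootstrap resamples genes
with replacement (default 1000) for the standard error. The shuffle null
permutes each of the three vectors independently over all genes, re-applies
the α selection to the shuffled control values, and recomputes the fraction
(default 1000 shuffles); replicates with empty selections are dropped, and
more than half dropped is an error. Re-selection inside each replicate is
the self-consistent reading of "all genes are shuffled"; the alternative —
permuting only within a fixed pre-selected set — is available via
`reselect=False`. The z-score is (observed − null mean)/null SD, the
empirical p is the two-sided exceedance fraction with +1 smoothing, and the
verdict triggers at |z| ≥ 2. A symmetric "down" variant selects
downregulated genes and reverses the ordering.

Sanity anchor: with the three vectors iid continuous and α = 1, exactly 2
of the 6 per-gene orderings satisfy the selection and 1 of those satisfies
the lag predicate, so the conditional expectation is 1/3; the shuffle null
reproduces this within ±0.02 at 5000 genes.

## Proximity

The TSS window is symmetric (±10 kb) since no direction is implied by
"within 10 kb". Distance is 0 for elements spanning the TSS, otherwise the
signed distance to the nearest element edge, oriented by the gene's strand
(negative upstream). Genic context has precedence exonic ≻ intronic ≻
intergenic across all overlapping genes, making labels deterministic for
elements inside overlapping gene models. The coupling report compares the
per-gene mean expression fold-change of TSS-proximal elements between
upregulated (DE with positive fold-change) and non-DE genes with the same
KS machinery; genes without nearby elements stay in the table with NaN
means and are excluded from the KS samples.

## Synthetic-data model

The generator's defaults define the conditions every test runs under:

* **Genome**: 3 chromosomes × 2 Mb.
* **Islands**: 60 non-overlapping 2 kb regions in evenly spaced slots; up
  to half are instead anchored within 6 kb of the TSS of a planted
  upregulated gene, which couples islands (and the elements on them) to
  genes for the proximity analysis.
* **Repeats**: 20 subfamilies — 14 heterochromatic LINE/L1 and LTR/ERVK
  subfamilies (80 elements each, 0.4–3 kb) placed with co-placement
  probability 0.8 on islands and carrying graded planted de-repression
  folds (2–60×), plus 6 neutral SINE/LINE/DNA subfamilies placed uniformly.
* **ChIP tracks**: Poisson reads at 0.02 reads/bp background (λ = 4 per
  200 bp window, ~140k reads per track), 10× enrichment inside islands; the
  knockdown track multiplies the island excess by 0.4 at the attenuated
  half of the islands (the gene-coupled islands first). Input is background
  only.
* **RNA tracks**: reads inside repeat elements at 0.01 reads/bp in the
  control, multiplied by the subfamily fold in the knockdown, plus sparse
  genome-wide background (0.0005 reads/bp). The library size adds a fixed
  padding of 10⁶ reads standing for the genic bulk of a real RNA library,
  which maps outside the repeat space but dominates library normalisation.
  Without that padding, de-repression would inflate the knockdown library
  several-fold and compress every fold-change estimate; with it, the
  remaining mild compression (top subfamilies estimated ~20× versus a
  planted 60×) is the realistic compositional effect, and rank order is
  preserved.
* **Time course**: 5000 genes, stages ESC → EB_d6 → EB_d10, one library per
  genotype × stage, negative-binomial counts at dispersion 0.1, baseline
  RPKM log-normal around 16. Planted DE genes (5%) change 4-fold in the
  knockdown at every stage, in random directions. Accelerated genes (30%)
  are drawn from the low-baseline half of genes — induced lineage genes are
  near-silent in ES cells — and follow a monotone control trajectory with a
  per-stage log2 step uniform in [1, 1.5]; knockdown values sit one stage
  ahead at post-ESC stages (the last stage extrapolates the trajectory; ES
  cells are identical across genotypes before differentiation begins). The
  low-baseline restriction and moderate steps keep the induced mass a minor
  fraction of the library: if the planted up-trajectories dominated the
  library sums, RPKM's compositional normalisation would deflate knockdown
  values across the board and distort the ordering statistic in the
  opposite direction — the same artefact that makes bulk-composition shifts
  treacherous in real differentiation data.
* With `de_fraction = accel_fraction = 0`, every gene is stage-stationary
  and the knockdown and control values are exchangeable, making the
  shuffle-null calibration checks exact by construction.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: read alignment and mappability artefacts,
duplicate reads, fragment-length effects, replicate-level batch effects,
sequence content of repeats, overdispersed ChIP backgrounds, isoform
structure, and genuinely compositional RNA libraries (the padding is a
fixed constant, not a modelled transcriptome).

## Numerical choices and scales

Random streams all derive from one master seed through named CRC32
substreams, so every pipeline stage and every written file is
bit-reproducible given the seed. Fold-change pseudocounts are half a read
(density units) for islands and repeat labels and 0.1 RPKM for gene ratio
selections. Poisson/binomial tails come from scipy; BH from statsmodels;
KS from scipy (asymptotic). Property-test problem sizes are chosen so the
whole suite and the acceptance script each run in well under their planning
budgets on one CPU: island and differential properties use 20 simulations
on 1–6 Mb genomes, the enrichment calibration 200 simulations, the
acceleration calibration 60–100 generator nulls at 2000–3000 genes (the
analytic anchor runs at the full 5000). The default `run-all` completes in
a few seconds and writes TSV/BED/PNG outputs plus a YAML manifest of all
parameters.

## Known limitations

* The DE binomial test is anticonservative under strong overdispersion
  (documented above); EdgeR/DESeq parity is out of scope.
* The island caller reproduces the published parameters, not SICER's exact
  internals; at very low coverage (λ ≈ 0.25 reads/window) short planted
  islands are recovered at ~77%, limited by 2-read eligibility windows and
  the BH cut, versus ≈ 99% at the default study depth.
* Aggregate repeat fold-changes are compositionally compressed when
  de-repression is massive; treat them as rank statistics.
* The matched random-region null does not exclude any regions (no gaps or
  blacklists exist in synthetic genomes) and is per-chromosome uniform.
* The verdict threshold |z| ≥ 2 makes single-dataset null misses a ~5%
  event by construction; calibration statements are proportions over many
  seeds, not guarantees per seed.
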