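# epirepeat

Analysis toolkit for heterochromatin ChIP-seq and retroelement expression in
knockdown studies, exercised end-to-end on synthetic genomes with known
planted ground truth.

## The scientific problem

Repressive histone marks such as H4K20me3 and H3K9me3 form broad
"islands" over repetitive DNA — LINE and LTR/ERV retroelements — and keep
those elements silent. Depleting a writer of such a mark (an shRNA
knockdown versus a control hairpin) is expected to (i) lower the mark's
density at thousands of islands, (ii) de-repress the retroelement
subfamilies those islands cover, (iii) perturb the differentiation
trajectory of embryonic stem (ES) cells into embryoid bodies (EBs), and
(iv) couple element de-repression to activation of neighbouring genes.
`epirepeat` implements the complete quantitative chain behind such a study
for users who need a tested, reusable, self-contained version of these
bespoke computations:

* **Island calling** (SICER-style spatial clustering): 200 bp windows with a
  permissive Poisson eligibility tail, merged across gaps ≤ 400 bp, scored
  against library-scaled Input with Benjamini–Hochberg control at FDR 0.001.
  Density is RPBM, reads·bp⁻¹ per million mapped reads:
  `RPBM = count / length / (library / 10⁶)`.
* **Differential islands** between conditions at fixed islands — a two-sided
  binomial test of `count_A` out of `count_A + count_B` against the
  library-size ratio, calls at fold-change > 1.5 and FDR < 0.001.
* **Repeat enrichment**: per-island percent coverage of a repeat class /
  family / subfamily, compared against matched random regions (equal count,
  identical lengths, same chromosome, uniform placement) by the two-sample
  Kolmogorov–Smirnov statistic `D = sup |ECDF_obs − ECDF_null|`.
* **Expression**: RPKM (`count / (length/10³) / (library/10⁶)`),
  differential genes (FC > 2, FDR < 0.001, genes with RPKM < 3 in both
  conditions excluded), k-means (k = 20) and PCA plumbing, per-element RPBM
  with the stringent `> 0.003` RPBM expressed-element filter, and repeat
  subfamily expression fold-changes.
* **Accelerated-differentiation ordering statistic**: for genes upregulated
  ≥ α-fold from ESC to an EB stage in the control, the fraction satisfying
  the strict lag ordering `EB(control) > EB(knockdown) > ESC`, with a gene
  bootstrap for the error bar and a per-vector shuffle null (each of the
  three expression vectors permuted independently over all genes, selection
  re-applied) for the expectation; verdicts at |z| ≥ 2.
* **Proximity**: LTR/ERV elements within ±10 kb of gene TSSs, genic context
  (exonic ≻ intronic ≻ intergenic), and a report coupling element
  de-repression to gene upregulation.
* **Synthetic data**: a 3 × 2 Mb genome, a RepeatMasker-style hierarchy of
  20 subfamilies, ChIP/Input/RNA read tracks, and a two-genotype
  ESC → EB_d6 → EB_d10 time course — all with planted, recoverable truth.

## Worked example

```python
import epirepeat as er

ds = er.generate_dataset(seed=42)
calls = er.call_islands(ds.chip_ctrl, ds.chip_input)   # window 200, gap 400, FDR 0.001
print(f"{len(calls)} islands called")

islands = er.IntervalSet([c.interval for c in calls], genome=ds.genome)
diffs = er.differential_islands(islands, ds.chip_ctrl, ds.chip_kd)
print(sum(d.call == "decreased" for d in diffs), "islands decreased in the knockdown")

fc = er.repeat_subfamily_fold_change(ds.rna_ctrl, ds.rna_kd, ds.repeats)
print(fc.head(3).round(3))

rpkm = er.compute_rpkm(ds.expression)
res = er.run_ordering_analysis(rpkm, ds.design, "EB_d6", alphas=[2.0],
                               n_boot=300, n_shuffles=500, seed=42)[0]
print(f"observed {res.observed_fraction:.3f}, expected {res.expected_mean:.3f}, "
      f"z={res.z_score:.1f} -> {res.verdict}")
```

prints

```
60 islands called
30 islands decreased in the knockdown
           density_a  density_b  fold_change
name
L1Md_T         0.054      1.069       19.667
MMETn-int      0.062      1.140       18.473
L1Md_Gf        0.060      1.006       16.893
observed 0.237, expected 0.471, z=-20.2 -> lagging_fewer_than_expected
```

All 60 planted islands are recovered; exactly the 30 knockdown-attenuated
islands are called "decreased"; the most de-repressed subfamilies rank at
the top of the fold-change table (the estimates sit below the planted 60×
and 50× because de-repression itself inflates the knockdown library — the
rank order is what the analysis recovers); and far fewer control-upregulated
genes lag behind in the knockdown than the shuffle null expects, the
signature of an altered differentiation trajectory.

The same analyses run from the shell:

```
epirepeat simulate --seed 42 --outdir sim/
epirepeat islands call --chip sim/reads_chip_ctrl.bed --input sim/reads_chip_input.bed \
    --chrom-sizes sim/genome.chrom.sizes --out islands.tsv
epirepeat run-all --seed 42 --outdir out/
```

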