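# Methods

This note records the statistical model, the synthetic-data design, the
numerical choices and the known limitations of `cellfate`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Pipeline model

The pipeline consumes a gene × sample count table, gene annotation
(biotype, length in bp), ordered stage labels per sample, gene-set catalogs
(GMT) and a cell-type signature matrix, and proceeds:

1. **Filtering.** Keep genes with count ≥ `min_count` (default 10) in ≥
   `min_samples` (default 2) samples and biotype outside `drop_biotypes`
   (default `lncRNA`). The low-quality cutoffs are deliberately
   configurable; there is no field consensus on a single value.
2. **TPM.** `TPM_gs = (count_gs / length_kb_g) / Σ_g(count_gs / length_kb_g)
   × 10⁶` — the standard length-normalized unit; columns sum to one million
   and the transform is library-size invariant. Everywhere downstream,
   "logTPM" means `log10(TPM + 1)`; the +1 pseudocount avoids log 0 and the
   base-10 convention matches how such data are usually displayed.
3. **Differential expression.** Per gene, `log2FC = log2((mean TPM_b + 1) /
   (mean TPM_a + 1))` (pseudocount 1 TPM guards against zero means) with a
   two-sided Mann–Whitney p and BH q over all tested genes. Direction
   (up/down/ns) uses |log2FC| ≥ 1 and raw p ≤ 0.05 by default; q is
   reported alongside. A negative-binomial count-model engine is *not*
   reimplemented — the thresholds, not the test engine, drive the
   downstream logic, and the test is injectable (`test=` argument) for
   anyone who wants a different engine.
4. **Ordination.** Classical PCoA (metric MDS, via scikit-bio) on Euclidean
   distances of logTPM profiles; on Euclidean distances this equals PCA
   scores up to axis sign, which the tests assert at 1e-8. Group separation
   uses a PERMANOVA pseudo-F with permutation p `(1 + #{F_perm ≥ F_obs}) /
   (n_perm + 1)`; the statistic is cross-checked against scikit-bio's
   PERMANOVA in the tests. 999–1,000 permutations by default.
5. **Over-representation.** Hypergeometric upper tail for overlap ≥ k, BH
   across sets; validated against exhaustive enumeration on small
   universes.
6. **Deconvolution.** Per sample, non-negative least squares of bulk TPM on
   the signature over shared genes (exact ID match), renormalized to the
   simplex. The estimator is deterministic, scale-invariant per sample, and
   exact on noiseless identifiable mixtures. The solver sits behind a
   stable contract so a learned deconvolver can replace it without touching
   any downstream stage.
7. **Interaction network.** The core. Per stage: gene-set distance
   `1 − Pearson` of logTPM profiles restricted to the set (the standard
   correlation-distance reading; a Euclidean alternative is one constructor
   away), scalar cell-type distance `|Δ proportion|`, Mantel statistic =
   Pearson of condensed distances, one-sided (greater) permutation p with
   the add-one rule, 1,000 permutations, ties counted inclusively
   (conservative). Each cell type is paired individually with each death
   mode — matching the pairwise readout the analysis is built for — rather
   than one test against the whole proportion matrix. BH family = all
   mode × type pairs within one stage (the per-stage network is the unit of
   interpretation). Flags: significant = adjusted p ≤ 0.05; strong =
   Mantel R > 0.5.
8. **Dynamics.** Counting uses the significance flag only (the Methods-level
   definition of significance); the strength flag rides along so a stricter
   rule is a one-line filter. Changes are computed between consecutive
   stages in declared order. "Correlation strength" per cell type is
   exported both as Mantel R trajectories and as the Spearman
   activity-vs-proportion heatmap (activity = mean logTPM over the set),
   since either reading is defensible.
9. **NOS association.** Pearson on logTPM per (NOS gene, necroptosis gene)
   pair within a stage, two-sided p from `t = r·sqrt((n−2)/(1−r²))`. Stars
   (*, **, ***) follow the raw-p figure-legend convention at
   0.05/0.01/0.001; BH q is exported alongside for stricter use. Signed
   significant counting splits p < 0.05 pairs by the sign of r.
10. **Biomarker.** Plain maximum-likelihood logistic regression via IRLS
    (Newton–Raphson; converged when max |score| < 1e-8 or 100 iterations;
    pinv-based solve so degenerate columns get minimum-norm updates;
    perfect separation detected and reported, optional ridge exposed). ROC
    by threshold sweep with ties grouped; trapezoid AUC is asserted
    internally to equal the tie-corrected Mann–Whitney AUC; the operating
    point maximizes Youden's J (the standard default when no criterion is
    specified).

### Seeds and determinism

A single global seed fans out to per-stage child seeds by a stable SHA-256
hash of the stage name, so adding a stage never perturbs earlier streams.
Within the interaction network, each record's permutation stream derives
from the seed plus the record's (stage, mode, type) position. Two runs of
`run_all` with the same config are byte-identical on every output table
(timestamps live only in the manifest).

## Synthetic cohort design

The generator emulates a staged bulk brain cohort: by default three stages
(BLB0/BLB5/BLB6) of 28 samples each (n = 84), ten neural cell types
(neurons, astrocytes, VLMCs, tanycytes, OPCs, oligodendrocytes, ependymal
cells, endothelial cells, microglia, NFOs), five 20-gene death programs
plus NOS (NOS1/2/3) and necroptosis markers (FAS, TLR2, TLR5, embedded in
the necroptosis set).

- **Composition.** Per sample, proportions are Dirichlet with concentration
  2.0 per type (exchangeable). A skewed "realistic brain" composition was
  considered and rejected: strongly unequal Dirichlet weights induce large
  negative proportion–proportion correlations on the simplex, which smear a
  planted coupling into off-target cell types and make the network readout
  ambiguous by construction. Exchangeable weights keep cross-type
  correlation at −1/(K−1) ≈ −0.11 while giving realistic inter-individual
  spread (sd ≈ 0.065 at mean 0.1).
- **Signature.** Background genes are log-normal with per-type variation;
  each type gets a disjoint marker block ≥ 5-fold its background mean,
  guaranteeing identifiability. Death/NOS program genes express uniformly
  across types, so their association with any cell type comes *only* from
  planted couplings.
- **Couplings.** A planted coupling (stage, set, cell type, β) multiplies
  the set's expression in that stage by
  `10^(β · l_g · (p_i − mean_stage p))`, with per-gene loadings
  `l_g ~ Normal(1, 0.75)` drawn once per coupling. Centring within the
  stage means couplings reshape covariance (what the Mantel layer detects)
  without shifting stage-mean expression — the interaction signal is
  deliberately orthogonal to the DEG signal. The loading spread is
  essential, not cosmetic: a uniform shift of all set genes cancels out of
  the correlation-based profile distance, so heterogeneous per-gene
  response is what makes the planted effect physically detectable; mean 1
  preserves the advertised shift of the set's mean log-expression. β is the
  per-unit-proportion shift of that mean, so β = 0.8 against a proportion
  sd of ≈ 0.065 is a large, clearly-detectable effect and β = 0.4 a
  moderate one.
- **Noise and counts.** Multiplicative log-normal noise with CV 0.1 by
  default (mean-one parameterization), then Poisson counts at an expected
  depth of 2×10⁷ reads. The depth scale is computed from gene lengths
  alone, not from realized expression, so couplings stay local to their
  set's rows (the locality invariant is tested). Because numpy's Poisson
  sampler consumes a data-dependent number of random draws, the
  count-noise layer can be switched off (`count_noise="none"`) — that
  setting is what the exactness invariant (TPM equals
  signature × proportions) is tested under. 5 % of background genes are
  labelled lncRNA to exercise the filter.

What the generator does **not** emulate: transcriptome-wide co-expression
structure, batch effects, GC/length biases beyond the TPM model,
single-cell dropout, or realistic gene-set sizes and overlaps (programs are
disjoint by construction). Passing recovery tests therefore demonstrates
that the machinery detects what it claims under its own generative model —
not that real cohorts are this clean. Real GMT catalogs and signature
matrices can be supplied in place of the synthetic ones throughout.

## Validation studies (benchmarks module)

`cellfate.benchmarks` runs seven self-contained studies, shared by the test
suite and the acceptance script; problem sizes were chosen to mirror the
emulated cohort design while completing in minutes on one CPU:

1. Mantel Monte-Carlo vs exhaustive enumeration (100 random 4–6-sample
   instances; exhaustive must equal an independent brute-force loop, MC
   within 3 MCSE plus the add-one offset).
2. Null calibration: 2,000 (mode, type) pairs from coupling-free cohorts;
   KS uniformity of raw p and BH flag rate at the nominal level.
3. Planted-coupling power: β = 0.8 necroptosis–neurons in the last stage,
   3 × 28 samples, CV 0.1; target flagged in ≥ 90 % of 100 cohorts, no
   off-target pair flagged in > 10 %.
4. Dynamics recovery: necroptosis β rising 0→0.4→0.8, ferroptosis falling
   0.8→0.4→0 (3 × 30 samples); net increase/decrease read out in ≥ 90 % of
   100 cohorts.
5. Deconvolution: noiseless max error < 1e-6; per-type r ≥ 0.95 at CV 0.1
   over 20 cohorts.
6. Primitive oracles: BH vs brute force, ORA vs exhaustive enumeration,
   trapezoid vs pair-count AUC (including the 6-sample worked example,
   AUC = 8/9), PCoA vs PCA at 1e-8.
7. Determinism: byte-identical tables across two runs of one manifest.

## Numerical choices

- Permutation ties count as exceedances, with an absolute tolerance of
  1e-12 on the Mantel statistic to keep the inclusive tie rule stable under
  floating-point jitter between the vectorized and scalar code paths.
- Mantel permutations are generated as argsorts of uniform draws and
  applied as a single vectorized gather over the condensed index, which is
  what makes 1,000-permutation tests across 150 records per cohort cheap.
- The permutation-p floor is 1/(n_perm+1); with BH over 50 pairs per stage
  this means n_perm ≥ 999 is required for *any* record to clear adjusted
  p ≤ 0.05 — a smaller permutation count silently caps the network's
  sensitivity, which is why 1,000 is the default and the tests use ≥ 999.
- Zero-variance distance vectors (constant profiles or proportions) are an
  error, not a NaN: the Mantel statistic is undefined there and silent NaNs
  would propagate into the BH family.
- TPM column sums are validated at relative 1e-6 on full matrices only; a
  gene subset keeps the TPM unit without the sum invariant.
- Gene matching is exact-identifier; no symbol aliasing is attempted.

## Limitations

- The deconvolution stage is a linear NNLS estimator, not a learned model;
  with strongly collinear real signatures it degrades (rank deficiency is
  detected and reported rather than silently absorbed).
- The DEG stand-in is rank-based and will disagree with count-model engines
  near the significance boundary; only the thresholded record table feeds
  the rest of the pipeline.
- Star annotations on NOS pairs follow raw p by convention; users who need
  family-wise control should filter on the exported q values.
- The biomarker ROC is in-sample; no cross-validation or external-cohort
  transfer is attempted.
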