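# Methods

## The model

A droplet dataset is a mixture of singlets and multiplets. The detector treats
multiplet identification as semi-supervised classification: a subset of
multiplets can be *identified* nearly directly from orthogonal modalities
(CITE-seq marker co-positivity; VDJ chain co-capture), and the profile of these
identified multiplets, contrasted with the remaining droplets (enriched for
true singlets), generalises to the whole dataset through a logistic GLM.

For droplet *i* with feature row x_i and identified-multiplet label y_i,

    logit P(y_i = 1) = beta_0 + beta' x_i ,

with x_i containing:

* `mito_ribo_ratio` = m/(m+r), m = % mitochondrial UMIs, r = % ribosomal-protein
  UMIs (prefix sets `MT-`/`mt-` and `RPS|RPL`/`Rps|Rpl`, configurable regexes).
  Defined as 0 when m = r = 0 (such droplets carry no apoptosis signal).
* per-sample CLR transforms of nUMI, nGenes and VDJ UMI counts:
  y_i = ln(x_i + 1) − mean_j ln(x_j + 1) across the droplets of the sample.
  The pseudocount 1 keeps zero counts finite; droplets with no VDJ capture
  enter with count 0, not missing.
* one module score per cluster: mean log-normalised expression of the cluster's
  top-5 marker genes minus the mean over control genes; for every set gene, 100
  controls are drawn (seeded) from the gene's average-expression bin, with 24
  equal-frequency bins over all genes. Scores are therefore only approximately
  centred (bin-width bias), which is inherent to the scheme; planted-marker
  effects are an order of magnitude larger than the null drift.

ADT counts are CLR-normalised per droplet across antibodies, computed within
each sample. The per-droplet margin is standard CITE-seq practice; because that
margin makes droplets independent, the sample-wise computation is explicit
rather than consequential. Scalar covariates (nUMI, nGenes, VDJ UMIs) are CLR
transformed across droplets within a sample, which is the margin that makes
"per-sample" meaningful for them.

### Identified multiplets

**CITE-seq.** For each antibody, a 1-D linear discriminant with pooled variance
is fitted between the CLR levels of a reference-positive population (cell types
expressing the corresponding gene, e.g. T cells for CD3) and a
reference-negative population. With equal priors the decision boundary is the
midpoint of the class means; the general form
t = (mu+ + mu−)/2 + sigma^2 ln(pi−/pi+)/(mu+ − mu−) is exposed via a `priors`
parameter (equal priors by default, because reference populations have
arbitrary relative sizes). Antibodies whose threshold recalls the
reference-positive population at sensitivity strictly above 0.70 are usable;
the rest are dropped together with any pair that references them. A droplet
positive (strict `>` threshold) for both members of at least one mutually
exclusive pair is flagged; all triggering pairs are recorded. The default human
pair list is CD19+CD3, CD19+CD4, CD19+CD8a, CD19+CD56, CD19+CD16, CD19+CD14,
CD19+CD127, CD4+CD16, CD127+CD16; pairs and antibody→population maps are plain
config so panels can be extended.

**VDJ-seq.** Contigs are kept if productive, with ≥ 6 UMIs, on a recognised
chain (IGH/IGK/IGL/TRA/TRB; e.g. "Multi" records are parsed but unusable).
Identical (chain, v_gene, cdr3) records on one barcode — a contig-caller
artifact — are collapsed to the highest-UMI record before counting. Rules:

| rule | fires when | subtype |
|------|------------|---------|
| a | ≥1 BCR chain and ≥1 TCR chain | heterotypic |
| b | ≥2 IGH, or ≥2 light chains (IGK and IGL pooled) | homotypic BCR if only b |
| c | ≥2 TRB (≥2 TRA only if `count_dual_tra`) | homotypic TCR if only c |
| d | BCR chain on a droplet not clustering with B cells | heterotypic |
| e | TCR chain on a droplet not clustering with T cells | heterotypic |

Dual-TRA droplets are not counted by default: 1–10% of genuine T cells express
two productive alpha chains, so dual TRA alone is weak evidence. `b_cell_types`
and `t_cell_types` accept either broad type names or fine cluster names —
whichever vocabulary the supplied labels use. Unlabelled barcodes skip rules
d/e.

### Training and prediction

Positives are the union of the flag columns of the configured sources (VDJ,
CITE, and/or an external call column); negatives are all remaining droplets.
Both groups are independently trimmed to within 2 SD of their own mean on each
of mito-ribo ratio, CLR nGenes, CLR nUMI and CLR VDJ UMIs. Trimming purges the
positive set of outliers and — more importantly — strips the unflagged
multiplets hiding in the negative tail, so the fitted boundary tightens around
the singlet envelope. Label noise remaining in the negatives is accepted, not
modelled.

The design matrix uses all four QC covariates plus the module scores
(`minimal_features` restricts it to mito-ribo ratio + CLR nUMI + scores). The
GLM is fitted by maximum likelihood on internally standardised columns
(coefficients and standard errors are reported back on the original scale; the
fit itself is affine-invariant). When the trimmed training set is separable —
common, since doubling of library size is a near-deterministic doublet
signature — the MLE diverges; the estimator then refits with an L2 penalty of
1e-4 on the standardised scale, which keeps the optimum finite while staying
close to the maximum-likelihood boundary. Standardisation matters here: the
features differ by two orders of magnitude in scale (CLR nGenes has sd ≈ 0.08),
and a raw-scale penalty would shrink exactly the covariates that carry the
homotypic signal. Collinear columns are dropped (with a warning) before
fitting.

Every droplet receives p_i = logit^{-1}(beta_0 + beta' x_i); the final call is
p_i > cutoff (default 0.5, config-exposed; the raw probabilities are always
exported) union the training positives. The estimated doublet proportion is
the fraction of final calls.

### Dying-cell threshold

A two-component 1-D Gaussian mixture (EM, 10 seeded restarts, tol 1e-6) is
fitted to the mito-ribo ratio; the threshold is the local minimum of the
mixture density strictly between the component means (grid argmin at step 1e-3,
refined to ~1e-6 by bounded scalar minimisation). A density monotone on the
interval raises an error — the data are effectively unimodal and thresholding
is not meaningful. The threshold is a dataset-specific output, not a constant.
The flag is exported as a diagnostic; the GLM consumes the ratio itself, not
the flag. The same machinery applies to any 1-D covariate (e.g. log nGenes for
a gene-count threshold).

## Plumbing choices

* QC: droplets retained iff nGenes > 500 AND nUMI > 1000 AND %mito < 25
  (strict inequalities, exactly as printed); no upper nUMI bound is applied
  before classification — high-nUMI droplets are what the classifier is for.
  The median+IQR cut appears only in simulation cleaning.
* Clustering is plumbing, not the method: PCA (30 PCs) + Leiden (resolution
  1.0) on log-normalised counts stands in for the original batch-corrected
  clustering, and external labels are accepted everywhere. Batch correction is
  out of scope.
* Marker genes per cluster: one-vs-rest Wilcoxon rank-sum with
  Benjamini–Hochberg correction; genes at adjusted p < 0.05 ranked by log
  fold-change, top 5 kept. Clusters under 3 cells are skipped.
* Module scores default to one score per supplied cluster (a per-broad-type
  map is just a coarser label vector away).

## The synthetic generator

The generator emulates a PBMC-like CITE+VDJ experiment at desk scale; all
values are fixed defaults of `SynthConfig`:

* **Cell types** B cell (1500), T cell (2000), myeloid (1500) — N = 5000.
* **RNA**: ~990 genes — 8 canonical markers per type (10x the 0.2 background
  mean in the owning type), 10 `MT-` genes, 16 `RPS/RPL` genes, 940
  housekeeping genes with lognormal base means (median 2.2, sigma 0.5).
  Counts are gamma–Poisson (NB) with dispersion 2 and a per-cell lognormal
  library factor (sigma 0.3). Healthy cells land at ~6% mito, ~18% ribo
  (mito-ribo ratio ≈ 0.23).
* **Apoptosis**: 5% of cells get 3x mito and 0.3x ribo means (ratio ≈ 0.73) —
  elevated but below the 25%-mito QC bound, so the signal survives filtering.
* **ADT**: a 14-antibody panel — CD19 (B), CD3/CD4/CD8a/CD127 (T; CD4 and CD8a
  positive on only 60%/40% of T cells, exercising the >70% sensitivity gate),
  CD14/CD16 (myeloid), CD56 plus six background/isotype antibodies that are
  never positive but stabilise the per-droplet CLR denominator, as they do in
  real panels. Positive/negative NB means 300/8 (shapes 8/10).
* **VDJ**: B cells carry IGH (p=0.85) and one light chain (p=0.85; IGK:IGL =
  60:40); T cells TRA (p=0.80, 3% dual-TRA) and TRB (p=0.85); contigs are
  productive with p=0.93 and have Poisson(12) UMIs, so a small tail fails the
  ≥6-UMI filter. Each contig gets a distinct CDR3 and a V gene from a small
  pool. Myeloid cells carry no chains.
* **Spiking**: after per-sample cleaning (drop nUMI > median + IQR, linear
  interpolation quartiles), D cell pairs are sampled without replacement
  (within sample) and their RNA/ADT counts summed and contigs pooled, with
  D solving D = round(p·(N − D)) so doublets are the fraction p of *output*
  droplets. Pairs only — no triplets.

What it does **not** model: ambient RNA/background contamination, batch
effects, cell-type-specific library sizes, empty droplets, doublet-biased
apoptosis (apoptosis and doublet formation are independent here), finer immune
subtypes. Passing tests therefore demonstrate the machinery and its
statistical behaviour under clean conditions, not performance on any real
dataset.

## Measurement designs in the test suite

* Proportion scaling uses N = 5000 data at spiking levels 1/2/5/10/15% with
  three replicate generator seeds; the estimate is compared with the realised
  doublet fraction of the analysed droplets.
* Per-pairing sensitivity at the 5% level is pooled over eight replicate runs:
  the rarest pairing (homotypic myeloid, ~20 planted doublets per run, and the
  hardest case — no VDJ or CITE evidence exists for it, so recovery rides
  entirely on the GLM's library-size covariates) cannot be measured to better
  than ±10 points in one run; pooling brings the standard error under 4
  points. Its pooled recovery sits just above the 68% mark that the easier
  pairings clear with a wide margin.
* Oracles are independent of the code paths they check: the VDJ rule engine is
  compared against an enumerated truth table over all chain-count × label
  combinations; the LDA threshold against a brute-force balanced-error grid
  search; the GMM threshold against the closed-form density-intersection root
  of an equal-variance mixture (which matches the density minimum to O(var/Δ));
  the GLM against simulations with known coefficients.

## Known limitations

* The standard-error columns are NaN when the ridge fallback engages (the
  penalised fit has no exact ML covariance); inference on coefficients is only
  available for identifiable fits.
* `clean_base` is not exactly idempotent (requantiling after removal can shift
  the cut); the pipeline applies it exactly once, before spiking.
* Reference populations for ADT thresholding come from the supplied labels; in
  datasets where a cluster is doublet-rich, thresholds inherit that noise.
* The CLR of ADT counts couples markers within a droplet: droplets positive
  for many markers shrink each marker's CLR value. Large panels mitigate this;
  very small panels (under ~8 antibodies) make LDA thresholds learned on
  singlets systematically high for multi-positive doublets.
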