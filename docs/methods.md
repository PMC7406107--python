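# Methods

This note records the modelling choices behind `ganprog`, the defaults and
why they are set where they are, what the synthetic data do and do not
emulate, and the known limitations. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The model

The pipeline treats disease progression as a path on the data manifold
learned by a generative model. A Wasserstein GAN with gradient penalty is
fit to (augmented, rescaled) expression profiles; the generator G maps an
i.i.d. latent vector z to a profile. Two condition states (say wild-type and
disease at the oldest age) are located in latent space by *resembling*: for
each sample, the top-k pool profiles by Pearson correlation are averaged in
latent space, giving per-sample latents whose condition centroids define the
difference vector Δ. Moving every start-condition latent along Δ,
z(t, i) = z_i + t·Δ, and decoding yields per-gene transition curves
T_g(t) = meanᵢ G(z(t, i))[g].

The scientific premise — inherited from latent-space arithmetic in image
GANs and from GAN work on single-cell RNA-seq — is that a well-trained
generator concentrates its output near the data manifold, so the decoded
path between two condition regions passes through *data-like* intermediate
profiles rather than naive linear blends. On synthetic data with planted
onset structure this is observable directly: decoded mid-path profiles sit
nearest (in Euclidean distance) to the intermediate-age disease groups, and
genes planted with early onset rise earlier along t than genes planted with
late onset. Passing tests therefore show that the *mechanism* works where a
disease-state continuum is encoded in the cross-condition correlation
structure; they cannot show that any particular real dataset encodes one.

### Assumptions

- Replicate-level expression within a condition is unimodal and roughly
  symmetric on the variance-stabilized log scale (linear interpolation of
  within-group pairs then produces plausible profiles).
- The gene set is small enough (hundreds to ~1–2k, pre-filtered to
  differentially expressed genes) that a 2-hidden-layer dense generator can
  model it from well under 10³ samples.
- Progression information is present as graded differences across the
  sampled condition groups; the interpolation cannot invent dynamics the
  cross-sectional design never expressed.

## Stage-by-stage choices

### Normalization (`normalize`)

- Counts are normalized by **median-of-ratios size factors** and transformed
  with log2(x + 1). This is a deliberately plain variance-stabilizing
  stand-in; the rest of the pipeline accepts any pre-normalized log-scale
  matrix (e.g. a regularized-log transform from a dedicated DE package), and
  matrices tagged `normalized` skip this stage entirely.
- Standard scaling divides by **max over conditions of the within-condition
  SD**, not the pooled SD: genes whose between-group differences dwarf their
  replicate noise would otherwise be compressed to near-binary signals.
- **Sample SD (ddof = 1)** is used for σ_{k,j} and σ_SS; the convention is
  recorded in the run manifest. σ_SS is the SD of the *entire*
  standard-scaled matrix, pooled over genes and samples, which makes the
  ≈95%-in-[0, 1] calibration hold globally: for Gaussian SS values the
  in-interval fraction is 2Φ(1.959) − 1 ≈ 0.9500 by construction
  (3.918 = 2 × 1.959). Strongly non-Gaussian data land lower (the planted
  synthetic design gives ~92–93%); that is a property of the data, not a
  failure of the transform.
- Genes with zero scale (constant within every group) abort the fit by
  default; the end-to-end pipeline instead drops them with a logged warning
  and records the count in the manifest.
- The DE gene filter is a Welch two-sample t-test at the last age with BH
  adjustment plus an expression floor — again a stand-in; an externally
  computed DEG list can be supplied and is simply intersected.

### Augmentation (`augment`)

- Interpolation weights x ∈ {0.1, …, 0.9}; the symmetric grid preserves each
  group's mean exactly (assertable to 1e-12), and every interpolant is
  convex in its two parents, so no out-of-range values can be created.
- Augmentation runs on the normalized scale *before* the scaling model is
  fitted, so the ScalingModel sees the augmented population it will actually
  rescale; the ordering is recorded in the manifest.
- The train/test split is stratified by condition group (proportional
  allocation, largest remainder). For 846 samples and the default test
  fraction 84/846 this gives exactly 14 test samples per group.
- A Gaussian alternative (per-group, per-gene normal fits) is available as
  `augment.mode: gaussian` for robustness comparisons.

### WGAN-GP (`gan`, `nn`)

- Networks are **hand-written NumPy dense nets**. The gradient penalty needs
  the derivative of the critic's input gradient with respect to the critic's
  weights; because leaky-ReLU masks have zero derivative almost everywhere,
  holding them fixed makes the input gradient multilinear in the weights and
  the penalty gradient has a closed form (computed in
  `DenseNet.gradient_penalty`, verified against central finite differences
  to 1e-4 in the tests). Bias parameters receive no penalty gradient for the
  same reason.
- Generator: leaky ReLU (slope 0.2) on **all** layers including the output —
  the rescaled data intentionally spill a little outside [0, 1], and a
  saturating output would fight the 95% calibration. Generator weights are
  initialized uniformly in [−0.3, 0.3]. Critic: leaky hidden layers, linear
  scalar output (a Wasserstein score has no natural squashing), Glorot
  uniform init (a ±0.3 uniform init on a genes-wide input layer would start
  the critic far out of scale).
- Unstated optimization hyperparameters use the standard WGAN-GP values:
  λ = 10, 5 critic steps per generator step, Adam(lr 1e-4, β₁ 0.5, β₂ 0.9),
  batch 32. All are config keys and all are logged in the manifest.
- **Epoch** means one pass over the training set in critic mini-batches; the
  generator steps once per 5 critic updates. The library default is 2,000
  epochs with checkpoints every 100 — a desk-scale schedule; the original
  full-scale schedule (200k epochs, checkpoints every 500) is available via
  `ganprog train --full-scale`.
- The latent sampler draws each coordinate i.i.d. from the empirical pooled
  distribution of rescaled training values (inverse-CDF on the sorted pool);
  generated latents therefore live on the same scale as the data the
  generator must output. A parametric fallback N(0.5, (1/3.918)²) exists.
- Training is deterministic given (data, config, seed) on a fixed
  BLAS/backend; checkpoints restore bit-exactly (tested). Non-finite losses
  abort training, retaining the checkpoints taken so far.
- The last generator layer's per-gene incoming weight vectors act as learned
  gene features; `gene_association` correlates them and reports connected
  components above a correlation cutoff (default 0.4) as gene clusters.

### Resembling and similarity (`resemble`)

- Defaults: pool of 10,000 generated profiles per epoch, top k = 10 by
  Pearson correlation, ties broken by pool index for bit-reproducibility.
  Cosine similarity is available by config.
- Averaging latents then decoding ≠ averaging decoded profiles for a
  nonlinear generator; both are stored (`profile`, `decoded_mean`) and they
  coincide exactly on an affine generator (tested with a slope-1 leaky net).
- The similarity report contains the standard diagnostics: pooled value
  histograms of real vs generated data (and their total-variation distance),
  the within-real and real-to-fake pairwise correlation distributions, and
  per-sample best-match correlations against a held-out test set.

### Transition curves (`progression`)

- t grid: 101 points by default (51 in the desk-scale test configuration).
- Curves are averaged over the **last 50% of checkpoints** by default —
  proportionally the same late-training window as averaging a 200k-epoch run
  over its 75k–125k checkpoints — with the per-t SD across checkpoints kept.
  Averaging over every start-condition latent (not one representative)
  damps the sensitivity of Δ and the irregular starting-point behavior that
  single latents exhibit.
- T(0) equals the decoded start-centroid by construction. T(1) equals the
  decoded *shifted* start centroid, which coincides with the decoded
  end-centroid only for an affine generator; the overlay diagnostic reports
  |T(0/1) − observed group mean| per gene rather than assuming the identity.
  Reversed curves satisfy T_fwd(t) = T_rev(1 − t) exactly only in the affine
  case (asserted on the affine double); the general deviation is visible in
  the diagnostics, never silently assumed away.

### Pattern templates (`patterns`)

The six archetypes cross timing (early/gradual/late) with direction
(up/down); down templates are exact vertical mirrors. The timing archetypes
are **logistic transitions centered at the terciles** of the progression
axis (centers t = 1/3 and 2/3, width 0.10) with a linear "gradual" template.
The logistic form is not cosmetic: latent interpolation produces curves with
flat shoulders at both ends (the decoded path lingers inside the start and
end condition regions before crossing between them), and against such
sigmoid curves any purely concave or convex archetype is dominated in
Pearson correlation by the straight line — a taxonomy built from saturating
exponentials classifies essentially *every* monotone curve as "gradual".
Sigmoid archetypes shifted to the early and late terciles discriminate the
three timings across a broad band of centers (0.30–0.40 × 0.60–0.75) and
widths (0.10–0.15); the tercile centers are the semantic anchor of
"early/middle/late", not a fitted constant. Membership thresholds are
r > 0.95 (strict, possibly multiple patterns) with a 0.90 floor for
best-match assignment. Curves genuinely intermediate between two archetypes
join both — the Venn-intersection phenomenon the classification is designed
to expose — and constant curves stay unassigned with a logged note.
Templates are read/written as TSV, so any alternative shapes can be
substituted without code changes.

### Enrichment (`enrichment`)

- One-sided hypergeometric ORA (P[X ≥ overlap]); depletion is out of scope.
- The universe defaults to the genes that entered the analysis (the DEG
  list), not the genome — enrichment is asked *relative to the analyzed
  genes*, matching how the pattern lists are formed. Configurable.
- BH FDR is computed within each query list's table (each list is its own
  testing family), recorded in the output metadata.
- Exactness is tested against exhaustive enumeration on all universe sizes
  up to 12.

## The synthetic-data generator

`synthetic.generate_dataset` emulates the target study design: 2 phenotypes
× 3 ages × n replicates (default 6), per-gene baselines uniform on [5, 12]
log₂ units (the well-expressed regime a mean-count filter would retain),
i.i.d. Gaussian replicate noise (default SD 0.1, a tight technical-replicate
regime), and planted trajectory blocks. A block's genes get a phenotype
effect (default 2 log₂ units) in the disease phenotype whose fraction at
(young, mid, old) ages is early (0.2, 0.9, 1.0), gradual (0.1, 0.5, 1.0) or
late (0.0, 0.1, 1.0), signed by direction; null genes get none. An optional
counts mode draws Poisson counts around the exponentiated means for
exercising the size-factor stage.

Deliberately **not** emulated: batch effects, library-size artifacts,
dropout/zero inflation, gene–gene correlation beyond the block structure,
outlier samples, and any aging drift in the healthy phenotype (healthy
groups are distributionally identical across ages). Consequently, passing
recovery tests demonstrates the machinery under clean, well-separated
conditions; real data add nuisance structure the tests do not probe, and the
absence of healthy-phenotype drift makes the early part of the virtual
progression axis traverse a wide healthy region — one reason transition
curves carry a flat initial shoulder.

## Desk-scale defaults

The test and acceptance configuration runs the full pipeline at: 350 genes
(six 50-gene planted blocks, effect 2, noise 0.1, plus 50 nulls), 846
augmented samples split 762/84, latent dimension 16, generator 16-128-128-350,
critic 350-96-96-1, batch 64, learning rate 2e-4, 3,000 epochs with
checkpoints every 150, resemble pool 2,000 with k = 10, 51 t-points, epoch
window = last half of checkpoints. This is the package's default study
scale for synthetic validation — chosen so a complete run finishes in a few
minutes on one CPU core while leaving every stage's behavior (convergence,
resembling quality, timing discrimination) measurable. The library defaults
(latent 100, 250/250 and 150/150 hidden layers, pool 10,000) reproduce the
original architecture for real-data use.

## Known limitations

- The progression axis is *virtual*: t is a latent-space coordinate, not
  time; its calibration against chronological or pathological age is
  unknown, and only the ordering of gene transitions carries meaning.
- Curve shapes inherit a systematic early shoulder (see above) and a
  run-to-run warp of the t-axis; classification is robust to the warp at the
  block level, but single-gene timing calls near a tercile boundary are
  fragile.
- The critic's linear output and the standard λ = 10 penalty are good
  defaults for profiles of a few hundred genes; very wide profiles (10k+)
  would need architecture and schedule changes the package does not attempt.
- Determinism holds per BLAS backend; bit-identical results across different
  numpy/BLAS builds are not guaranteed.
- ORA treats gene sets as flat lists (no topology, no redundancy reduction),
  and reproducing any particular external enrichment tool's printed FDRs is
  not claimed — backgrounds and families differ between tools.
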