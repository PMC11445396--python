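# Methods

This note documents the models implemented in `spatialcov`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate.

## Niche covariance (COVET)

A cell's niche is the set of its *k* spatially nearest cells (Euclidean
distance in coordinate space, the cell itself excluded; ties broken by
ascending cell index so results are platform-independent). The niche
matrix Eᵢ ∈ ℝ^{k×g} stacks those cells' expression vectors. The shifted
covariance

Σᵢ = (1/k) (Eᵢ − X̄)ᵀ (Eᵢ − X̄)

replaces the niche's own mean with the dataset-wide mean X̄, so that every
matrix is referenced to the same point; it coincides with the classical
(biased) covariance whenever X̄ happens to equal the niche mean, and it is
symmetric PSD by construction.

Parameters and defaults:

- **k = 8** niche neighbours. This captures the immediate
  microenvironment on roughly hexagonal tissue; larger k (20, 50) probes
  coarser spatial organisation. A radius mode replaces the fixed count
  with all cells inside a given radius; cells with an empty radius-niche
  are flagged and excluded from distance computations rather than
  zero-filled (a zero matrix would silently impersonate a real niche).
- **Expression scale.** COVET is computed on the matrix as provided; a
  `log1p` flag applies the log transform first. Count-scale covariances
  emphasise high-expression genes; log-scale ones are better conditioned
  and are what the integration model consumes by default.
- **PSD tolerance.** Eigenvalues in [−tol·max(1, λ_max), 0) are treated as
  numerical noise and clipped to zero before the square root
  (tol = 1e−8); anything more negative is rejected as genuinely non-PSD.
  The relative form matters for badly scaled counts, where eigensolver
  noise grows with the spectral radius.

## Distances between niches

The exact 2-Wasserstein distance between zero-mean Gaussians,
d = tr Σᵢ + tr Σⱼ − 2 tr (Σᵢ Σⱼ)^{1/2}, costs a matrix square root per
pair. The approximate-optimal-transport (AOT) form swaps root and product,
d_AOT = tr Σᵢ + tr Σⱼ − 2 tr (Σᵢ^{1/2} Σⱼ^{1/2}) = ‖Σᵢ^{1/2} − Σⱼ^{1/2}‖²_F,
which needs each matrix's root only once (O(n g³ + n² g²) for all pairs
instead of O(n² g³)) and is exact when the matrices commute. Matrix square
roots are the unique symmetric PSD roots from eigendecomposition. All
distances are kept **squared**; downstream k-NN ranking is invariant to
the monotone square root and the squared form is what the flatten-and-
Euclidean identity produces. The Bhattacharyya distance ships in its
zero-mean Gaussian form, ½ ln [det((Σ₁+Σ₂)/2) / √(det Σ₁ det Σ₂)], purely
as a benchmarking oracle, with a tol·I ridge for singular inputs. Sets of
niches are averaged in AOT geometry: the matrix square of the mean of the
square roots.

## MSSI

MSSI adapts multiscale SSIM from raster images to segmented cells. The
finest scale is the spatial k-NN graph (k = 8 by default, mirroring the
niche size; symmetrised, mutual edges carry weight 2). Four coarsening
steps each contract the graph to at most ⌈n/2⌉ supernodes by greedy
heavy-edge aggregation: a maximal matching over edges in decreasing weight
order (ties by node index), then further heaviest-edge contractions until
the factor-two target is met. Merges only follow edges, so disconnected
regions never mix. Pooling averages the merged nodes' signals — constant
signals are fixed points. Signals are min-max normalised to [0, 1] at the
finest scale only and never re-normalised after pooling.

At scales 1–4 the contrast and structure terms are evaluated; the
luminance term enters at the coarsest scale; the weighted geometric
product uses the standard five-level MS-SSIM weights. Negative structure
terms are clipped to zero, so anti-correlation at any scale sends the
score to its floor of 0. The stabilising constants are (0.01·M)² and
(0.03·M)² with M the joint maximum of the two signals, recomputed at each
scale; with these constants identical signals score exactly 1. An
alternative luminance denominator (0.01/M in place of (0.01·M)²) appears
in some descriptions of this index; it breaks the identity property
(identical signals score ≈ 0.995) and is available behind
`luminance_constant="asymmetric"` for cross-checking, but the standard
constant is the default. Degenerate cases: an all-zero signal pair is
defined as similarity 1 (the limit of identical signals); scales reduced
to a single node contribute neutral factors.

## The integration model (ENVI)

A conditional VAE embeds both modalities with one encoder. Inputs are
log1p counts over the shared ("imaged") panel plus one auxiliary neuron
(0 = spatial, 1 = dissociated); the encoder returns a diagonal-Gaussian
posterior (μ, σ), sampled with the reparameterisation trick. Two decoders
read the latent (the expression decoder also receives the auxiliary
neuron):

- **Expression decoder.** The output layer carries three blocks of g_sc
  neurons (rate parameter, second parameter, zero-inflation weight). Under
  the defaults the dissociated head is negative binomial — r = softplus,
  p = sigmoid, log-pmf ln Γ(k+r) − ln Γ(r) − ln Γ(k+1) + k ln(1−p) + r ln p —
  and the spatial head is Poisson on the first g_st rate neurons. Only
  those first g_st neurons are shared between modalities; the remaining
  genes train from dissociated data alone, which is what lets the model
  reconstruct (and impute) the full transcriptome from panel-only input.
  ZINB and normal heads are available per modality.
- **Environment decoder.** g_st(g_st+1)/2 outputs fill a lower-triangular
  Cholesky factor L; the Gramian L Lᵀ (PSD by construction) is the mean of
  an isotropic Gaussian over COVET square roots, whose log-density is
  −½‖Σ^{1/2} − L Lᵀ‖²_F — i.e. half the AOT distance, tying reconstruction
  geometry to the niche metric. COVET roots are precomputed once before
  training.

The loss is the negative evidence lower bound: dissociated likelihood over
the full gene scope + spatial likelihood + environment term − β·KL to a
standard-normal prior, averaged per cell. Training draws half of each
batch from each modality with replacement and runs Adam with the two-phase
learning rate (1e−3, dropping to 1e−4 for the final quarter of steps).

Reference defaults follow the full-scale configuration (latent 512, three
hidden ReLU layers of width 1024, 2^14 steps, batch 1024, 2048 highly
variable genes — selected by variance of log1p library-normalised
expression — β = 0.3 with an opt-in escalation to 1.0 for datasets under
10,000 cells). The test-bench and acceptance runs use a scaled-down
configuration chosen once for desk-scale data (512+512 cells, 30 genes:
latent 32, width 128, batch 256, 1000 steps, β = 0.3); at 30 genes the
β = 1.0 escalation over-regularises the posterior and remains opt-in.

Numerical and design choices that matter:

- **Output-bias initialisation.** The expression rate bias starts at the
  inverse softplus of the per-gene mean count and the environment bias at
  the Cholesky factor of the mean COVET root. Without this, short
  trainings spend most steps rebuilding the global mean through the
  softplus/Gramian nonlinearities and the environment decoder never leaves
  the mean.
- **Environment target scale.** The environment Gaussian has identity
  covariance, so the implicit weight of that term depends on the units of
  the COVET roots. Targets are standardised to unit entry s.d. at fit time
  (the factor is stored and inverted at inference), which weights the term
  on its natural scale; log1p-space roots otherwise sit near s.d. 0.3 and
  the term is effectively down-weighted ten-fold.
- **Inference latents are posterior means**, so imputation and niche
  inference are deterministic given a trained model; posterior sampling is
  available by flag. Imputation returns the head expectation
  (r(1−p)/p for NB, (1−π)·r(1−p)/p for ZINB, λ for Poisson).
- Gene alignment across modalities is an exact, case-sensitive name
  intersection in panel order, with dropped names reported — silent
  mismatches are the dominant real-world failure mode.
- The tensor backend is a small reverse-mode automatic-differentiation
  engine on numpy arrays written for this package and verified against
  central finite differences in the test suite.

## Downstream analyses

Because AOT distances are squared Euclidean distances between flattened
roots, every routine operates on those vectors directly. Diffusion
components use a k-NN graph (k = 30), an adaptive Gaussian kernel whose
per-point bandwidth is the distance to the 10th neighbour (scaled by a
global width parameter), symmetrisation by averaging, and row
normalisation by the inverse degree matrix; eigenvectors in order of
eigenvalue magnitude, skipping the trivial constant one, are the
components. Each component's sign is fixed to correlate positively with
the first input feature — the ordering and orientation of diffusion axes
is otherwise arbitrary. Disconnected graphs warn and fall back to the
largest component.

Label transfer is a majority-vote k-NN (k = 5) in AOT space with ties
broken by smallest summed distance, then lexicographically. Niche
composition counts cell types among the k = 8 niche neighbours (rows sum
to 8, or 1 when normalised) and regresses compositions onto query niches
by averaging the k = 5 AOT-nearest spatial cells' vectors.
Expression-vs-environment concordance clusters log expression and
flattened roots with k-means (10 restarts per side, seeds seed…seed+9) and
reports the mean adjusted Rand index over the 100 pairings. The
batch-mixing score projects the joint latent to its top 10 principal
components and averages, per cell type, 1 − |silhouette| of the modality
labels (1 = perfectly mixed, 0 = separated).

## Synthetic data: what it emulates, and what it does not

The generator plants exactly the statistical structures the methods
exploit, on a jittered unit grid (jitter ±0.3, which keeps k-NN ties
measure-zero while controlling density):

- **Zones** are vertical bands. Their identity is carried *only* by a
  ligand gene block with zone-specific log-mean shifts and by a receiver
  block that responds linearly (on log means) to the mean ligand level of
  the cell's 8 spatial neighbours — real cross-cell covariance. Both
  contrasts are gated by `coupling_strength`, so at zero coupling zones
  are statistically invisible; cell types are mixed uniformly everywhere.
  Zone and gradient gene programs come from a fixed dedicated RNG, so two
  tissues simulated with different seeds share the same archetypes and
  recovery can be tested across independent realisations. This matters:
  within one tissue, adjacent cells share niche members, so an AOT k-NN
  lookup reproduces any spatially contiguous labelling at ~0.95 accuracy
  with no signal at all; cross-realisation transfer closes that shortcut.
- **A gradient** runs along the orthogonal axis, as a monotone log-mean
  trend in a gradient block and, in the `gradient` preset, as a smooth
  cell-type composition drift (Gaussian-bump mixture along the axis).
  The composition drift is what makes the axis recoverable by the first
  diffusion component: covariance is quadratic in deviations from the
  mean, so a pure mean gradient folds back on itself (both tissue ends
  covary in the same matrix direction) and diffusion geometry sees
  distance-from-centre instead of the axis; a composition gradient rotates
  the niche covariance monotonically.
- **Counts** are Poisson for the spatial role (log-rates clipped at e⁹ as
  a safety guard); the dissociated sample re-draws all genes gamma-Poisson
  (negative binomial, shape = `dispersion`, Poisson in the large-shape
  limit), applies log-normal library-size factors and independent dropout
  thinning, and discards coordinates.

The generator does **not** emulate segmentation errors, spatial
domain boundaries with curvature, cell-type-specific dispersion, batch
effects within a modality, or ambient RNA. Passing tests therefore show
that each method recovers the structure it is designed for at realistic
noise levels — not that it is robust to every artifact of real tissue.

The gene-holdout harness partitions the imaged panel into five random
folds and scores per-gene Pearson on log(x + 0.1) alongside MSSI.

## Problem sizes

Unit and property tests run on 50–1,024 cells and 4–40 genes; the
integration smoke/recovery check uses 512 spatial + 512 dissociated cells
with 30 genes (20 imaged) and 1,000 training steps; metric-fidelity checks
use ensembles of 200–1,000 random 6×6 and 8×8 covariances. The full suite
completes in a few minutes on one CPU.

## Known limitations

- The AOT fidelity guarantee is empirical (rank correlation against the
  exact metric on random ensembles); adversarial far-from-commuting pairs
  can rank-invert individual distances.
- The autodiff engine is deliberately minimal (dense arrays, no
  broadcasting across matmul batch dimensions, no GPU); at full-scale
  settings (latent 512 / width 1024 / 2^14 steps) training is CPU-bound
  and slow — the architecture is faithful, the throughput is not.
- Radius-mode niches of very different sizes make COVET magnitudes
  hard to compare across cells; the fixed-k mode is the primary path.
- `expression_environment_concordance` uses k-means as the in-package
  clustering; graph-based clusterings of the same features may score
  differently.
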