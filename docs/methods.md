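# Methods

`colonscape` analyses spatially resolved surveys of the gut microbiota in
which small (~100 × 100 µm) biomass volumes are dissected along two axes of
the colon: longitudinal (blocks 1–7, proximal → distal, ~1 cm apart) and
lateral (mucus-adjacent vs. luminal). This note documents the models,
estimators, numerical choices, and the synthetic data that the test suite
uses as its ground truth.

## Community model and generator

Counts are generated from a log-normal–multinomial model. For taxon *t* in
sample *s* (mouse *m*, diet *d*, block *b*, compartment *c*):

    eta[t,s] = alpha[t] + beta[t] * g_d * (b - 4) + gamma[t] * 1[c = mucus]
               + delta[t,d] + u[t,m] + eps[t,s]

with `u ~ N(0, mouse_sd²)` a mouse random effect and
`eps ~ N(0, theta[d,c]²)` per-sample overdispersion noise. Expected
compositions are `softmax(eta)` per sample; counts are multinomial at a
log-normal library size. Overdispersion is modelled as Gaussian noise on
log abundances rather than as a Dirichlet–multinomial because the noise SD
`theta` then maps directly onto Taylor's power-law slope (variance of
counts ≈ m + m²(e^{theta²} − 1), pushing the log-variance/log-mean slope
from 1 toward 2), which gives the patchiness tests an interpretable dial.

Key defaults and what they represent:

| parameter | default | meaning |
|---|---|---|
| `n_blocks`, `n_replicates` | 7, 4 | blocks along the colon; dissections per block × compartment |
| `alpha_sd` | 1.5 | spread of baseline log abundances (≈ 2 decades of abundance) |
| `gradient_scale` | 0.5 (0.8 in the three-diet scenario) | log-abundance change per block for gradient taxa |
| `frac_gradient_up` | 0.3 | fraction of (rare) taxa rising distally — this is what makes distal richness higher |
| `mucus_effect`, `frac_mucus` | 1.2, 0.2 | log-offset and fraction of mucus-enriched taxa; concentrating the mucus community on fewer taxa lowers its richness |
| `theta` (per diet × compartment) | 0.5–1.65 | overdispersion; mucus > lumen, fibre-deprived > control |
| `depth_log_mean/sd` | ln 2000, 0.35 | library sizes around the 1000-read rarefaction depth (stool: ln 8000, rarefied at 4000) |
| `contaminant_scale` | 0.015–0.02 | reagent-contaminant share of a unit-biomass sample |
| `mouse_sd` | 0.3 | between-mouse variation |

Gradient slopes are assigned to the lowest-baseline taxa (rising) and the
highest-baseline taxa (declining): a richness gradient only emerges when
the rising taxa start below the detection limit proximally, so the
assignment is part of the model, not a convenience.

Stool is simulated per mouse as the uniform mixture of that mouse's
distal-lumen (blocks 6–7) expected compositions, reflecting the empirical
observation that stool resembles the distal lumen community.

Contaminants follow the reagent-contamination law: their expected relative
abundance is `q_j · contaminant_scale / biomass`, so low-biomass (mucus)
samples carry proportionally more contamination, and the log-share versus
log-biomass regression has slope −1 by construction. Negative controls
carry essentially no sample biomass: 97% of their reads come from the
contaminant profile, the rest from a small cross-contamination leak; with
no contaminants defined, control libraries collapse to the leak alone.

The three-diet scenario (`paper_like_params`) encodes the study contrast:
a fibre-rich control diet (intact gradient, moderate dispersion), a
fibre-deficient diet and a polysaccharide-and-fibre-deficient diet (diet
effect vectors plus a handful of strongly boosted taxa that concentrate
the community, gradient multiplier 0, and progressively larger theta).
Per-taxon diet effect sizes are free parameters of the generator, chosen
to reproduce the qualitative contrast — they are not calibrated to any
real dataset.

### Generator-side variance fractions

`SimTruth.variance_fractions` is the partition obtained by running the
package's own variation partitioning on the Bray–Curtis structure of the
*noise-free expected compositions* (which include the realised mouse and
overdispersion draws but no sequencing noise). It answers: what would an
exact analysis recover if sequencing were noiseless? Parameter-recovery
tests then quantify only the degradation caused by finite-depth
multinomial sampling and rarefaction. Because truth and estimate share
the partitioning code, these tests validate the *pipeline's robustness to
sequencing noise*; correctness of the partitioning itself is established
independently against vegan's `varpart` and closed-form cases.

The variance-recovery scenario (`variance_scenario_params`) sets effect
magnitudes so the noise-free partition attributes ≈25% of variation to
diet, ≈20% to the longitudinal axis and ≈2% to the lateral axis; 300 taxa
and a flatter baseline (`alpha_sd = 1`) keep the realised fractions stable
across seeds.

## Quality control

* **Contaminant test.** Per feature, presence (count > 0) is tabulated in
  negative controls versus true samples, and the score is the one-sided
  exact hypergeometric tail probability of at least the observed control
  prevalence. The exact test is used rather than a chi-squared
  approximation because dissection studies have few controls. Features
  with score < 0.1 are flagged. No minimum-abundance presence rule is
  applied.
* **Rarefaction** is a single seeded multivariate-hypergeometric draw
  (without replacement) per sample — not an average over repeated draws —
  so every downstream statistic is reproducible. Samples below the target
  depth (1000 reads for dissections, 4000 for stool) are dropped and
  reported.
* **Good's coverage** is 1 − f₁/N.

## Diversity and group comparisons

Richness is the number of detected features; Shannon entropy uses natural
logarithms. Bray–Curtis is Σ|x−y| / Σ(x+y) on counts; the
similarity-to-stool map uses relative abundances so libraries rarefied to
different depths (stool vs. dissections) remain comparable. Heatmap-style
summaries interpolate per-(block, compartment) means linearly along the
block axis only; the lateral axis is categorical and is never smoothed.

`group_compare(method="auto")` runs one-way ANOVA with Tukey HSD when all
groups pass Shapiro–Wilk at α = 0.05, otherwise Kruskal–Wallis with Dunn's
z-tests (tie-corrected); post-hoc p-values are Benjamini–Hochberg adjusted
within the pairwise family (the narrowest defensible reading of adjusting
"for multiple comparisons"). Degenerate all-equal inputs return statistic
0 and p = 1. A paired t-test handles matched two-group designs.

One caveat established during calibration: with mouse random effects, the
two Taylor slopes of the same mouse are positively correlated, making the
unpaired compartment comparison conservative; the type-I calibration uses
mouse-effect-free simulations, and a paired comparison by mouse
(`paired_key="mouse"`) is available when the clustering matters.

## Ordination and variation partitioning

PCoA eigendecomposes the Gower-centred −½D² matrix; when the smallest
eigenvalue is materially negative (Bray–Curtis is semimetric) the Lingoes
constant is added to the squared off-diagonal dissimilarities and the
decomposition redone, so all retained axes are non-negative.

perMANOVA uses SS_total = Σ_{i<j} d²ᵢⱼ/N and the within-group analogue,
pseudo-F = (SS_B/(a−1))/(SS_W/(N−a)), with unrestricted label permutation
and the (x+1)/(n+1) p-value convention (never zero). Permutations are not
restricted within mouse; a strata hook is left for future work.

db-RDA regresses the full set of corrected principal coordinates on the
predictors (McArdle–Anderson); R² is summed over all axes and adjusted
with the Ezekiel correction using the predictor rank. Variation
partitioning fits every non-empty subset of 2–3 predictor blocks and
combines the adjusted R² values by inclusion–exclusion; negative fractions
are reported as-is (clamping would hide misspecification). The
longitudinal axis is encoded as orthogonal polynomials of degree 2 in the
block index, the lateral axis as a mucus indicator, diet as treatment
dummies. The db-RDA response (rather than Hellinger-RDA) is the default
because Bray–Curtis is the dissimilarity used throughout.

## Directional modelling (AEM)

An asymmetric eigenvector map places an origin upstream of the
hypothesised flow, connects every site to it by a unique directed path
(sites form a tree; the colon is a 7-node chain per compartment, with
replicate dissections sharing their block's row; the lateral hypothesis
uses per-block origin → source-compartment → sink-compartment columns),
and decomposes the column-centred site-by-edge matrix by SVD. Two
properties discovered while building this module shape its design:

1. **Unweighted chains are direction-blind.** For a chain, the centred
   columns of the reversed incidence matrix are exactly the negatives of
   the forward ones, so both SVDs give the same eigenfunctions. Edge
   weights that decay with distance from the origin (default
   `exp(−(depth−1)/2)`) break the tie: the leading forward eigenfunctions
   then emphasise variation generated near the hypothesised source.
2. **Selected-model fits are capped at a common value.** Both direction
   hypotheses span the same centred site space, and the double stopping
   criterion caps any selected model at the (shared) global adjusted R²,
   so comparing *final* selected-model fits cannot separate directions.
   Direction comparison therefore scores hypotheses at **matched model
   size**: both selections are truncated to the smaller selected
   eigenfunction count, and the verdict goes to the hypothesis with the
   larger matched-size adjusted R², provided its permutation p ≤ α and its
   margin exceeds δ (default 0.02 adjusted-R² units); otherwise the
   comparison is ambiguous — consistent with bidirectional exchange. The
   directional signature is the *efficiency* of the leading
   eigenfunctions, not the endpoint fit.

Forward selection implements the double stopping criterion: a global
permutation test on the full candidate set gates entry (this is what keeps
the family-wise selection rate near α on pure noise); candidates are then
added greedily, each requiring a residual-permutation partial test at α
and a cumulative adjusted R² not exceeding the global model's (with a
10⁻³ tolerance, since a near-noise-free one-term model can exceed the full
model's adjusted R² by a sliver of the degrees-of-freedom correction).

The response is Hellinger-transformed relative abundance by default.
A genuinely directional test scenario must be non-stationary — a
stationary AR(1) is time-reversible, hence undetectable in principle — so
the directional simulation uses a strong source community at block 1
attenuating downstream (φ = 0.5) with small innovations. The pooled
three-diet community generator contains *no* directional process (its
block gradient is a deterministic trend, symmetric under reversal), so the
pipeline's AEM stage on that data correctly reports ambiguity.

## Taylor's power law

Per stratum (default mouse × compartment), each taxon present in ≥3 of the
stratum's sampling sites contributes its mean and variance of rarefied
counts across sites; OLS of log₁₀ v on log₁₀ m over taxa with positive
mean and variance gives the slope b (v = a·m^b). Counts, not relative
abundances, enter the fit — the law is defined on numbers of individuals
per unit area. Zero-variance taxa are excluded (log undefined) and
accounted in `n_taxa`. OLS is used rather than major-axis regression, the
convention for Taylor plots. Note that systematic spatial gradients within
a stratum also contribute cross-site variance, so a strong longitudinal
gradient raises b even without overdispersion.

## Image model and quantification

Scenes are single 2-D optical sections (area stands in for biovolume):
lumen at the top, a mucin band of known width above an undulating
epithelial surface, host tissue below, four channels (total bacteria,
target, host nuclei, mucin). Bacterial cells are disks of radius 1 µm
placed by a homogeneous Poisson background plus a Thomas-style cluster
process whose aggregate cells are *contact-packed* — offspring proposals
are Gaussian (scale σ_c) but snapped to cell–cell contact, touching and
never overlapping, as cells in a real clump are. This matters for the
estimator: the area-to-cell-number conversion is only meaningful when
aggregate area grows linearly in cell count; heavily overlapping disks
would make every cluster undercount.

Each cell joins the target population with probability
`p(d) = clip(p0 · (1 + A · max(0, 1 − d/L)), 0, 1)`, d the distance from
the mucus outer edge, so the target is enriched within L µm of the mucus.

Quantification:

* **Segmentation** is global Otsu thresholding (constant images are an
  error). Boundaries are explicit sidecar annotations, not auto-detected —
  mucus delineation is interactive in practice and is a separate research
  problem. The generator always emits them.
* **Biovolume profiles** bin luminal pixels by Euclidean-distance-
  transform distance from the mucus outer edge (2-µm bins, 0–150 µm) and
  take target∧total over total pixels per bin; bins with fewer than 50
  supporting pixels are NaN. Per mouse, profiles are normalised by the
  mean fraction beyond 75 µm (bulk lumen ↦ 1).
* **Enrichment extent** is the outer edge of the maximal contiguous run of
  bins, starting at the mucus edge, whose mean normalised fraction exceeds
  1 by a one-sided one-sample t-test at α = 0.05 across replicate
  profiles. The contiguous-run rule is an explicit substitution for an
  otherwise unspecified per-bin testing scheme. A power analysis done
  before freezing the recovery benchmark (per-bin fraction SE ≈
  `sqrt((1−p)/(p·n_cells_per_bin))/sqrt(n_images)`) fixed that scenario at
  amplitude 2, cell density 0.1 µm⁻², 20 images: the last detectable bin
  then sits within 2 bins of L for L ∈ {12, 20, 30} µm.
* **Cell and cluster statistics.** Mean single-cell area is the mean of
  connected components below 3× the modal component area (the modal bin of
  a 20-bin histogram); at high densities touching pairs inflate this by
  ~10%, so sparse acquisitions (density ≈ 0.015 µm⁻²) are used for
  single-cell statistics, as separate acquisitions would be in practice.
  Components holding ≥ `min_cells` = 5 estimated cells are clusters — the
  cutoff is a config key, as no standard definition exists. Pixel-based
  fractions also compress target/total ratios at high density (overlapping
  target and non-target cells share pixels), which is why profile scenes
  and statistics scenes use different densities.
* **Mucus thickness** measures distances from ≥10 evenly spaced points on
  the epithelial-surface polyline to the mucus outer edge, in µm; crossing
  boundaries are an error. **Goblet biovolume** is stain∧tissue over
  tissue pixels.

## Pipeline

`run_spatial_analysis` executes simulate → QC → diversity → ordination →
AEM → patchiness → images from one `RunConfig` (YAML-loadable;
`colonscape run --config …`). All randomness flows from one root seed
through named substreams (BLAKE2-hashed path → `SeedSequence` spawn key),
so re-running a config is byte-identical and adding a consumer never
perturbs existing streams. Each stage writes artifacts plus a marker
holding the config digest; deleting a stage's outputs and re-running
recomputes only that stage. The report contains no timestamps or absolute
paths.

Default problem sizes — 3 diets × 3 mice × 7 blocks × 2 compartments × 4
dissections (504 dissection libraries), 200 taxa, 199 permutations, 5
images per diet regime — complete the full run in well under a minute on
one CPU; they are chosen to match the study's design dimensions while
keeping simulation-based checks cheap to repeat.

## What the synthetic tests do and do not show

The generator reproduces the design's structure: compositional gradients
on both axes, diet effects, biomass-scaled contamination, library-size
variation, overdispersion, and mucus-adjacent aggregation in images. It
does **not** emulate sequencing error or chimeras, taxonomy, phylogenetic
correlation among taxa, temporal dynamics, 3-D image stacks, or realistic
point-spread functions. Passing parameter-recovery tests therefore shows
the estimators are correct and robust to sampling noise under the stated
model — not that the model captures every property of real amplicon or
microscopy data.

## Known limitations

* perMANOVA permutations ignore the repeated-measures structure (mouse);
  p-values for within-mouse factors are anti-conservative on real data.
* The AEM verdict depends on the chosen edge-weight decay; the default is
  justified by the separation analysis above, not by theory.
* Negative variation-partition fractions are reported unclamped and can
  confuse downstream consumers expecting proportions.
* The 2-D area proxy for biovolume ignores section thickness (10 µm
  sections treated as planar).
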