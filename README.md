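# colonscape

Spatial ecology of the gut microbiome at laser-capture-dissection scale.

Most microbiome surveys sample stool, which erases spatial information.
When the colon is instead sampled in small (~100 × 100 µm) dissected
volumes along two axes — longitudinal (proximal → distal blocks) and
lateral (mucus-adjacent vs. luminal) — a different set of questions opens
up: how is composition structured along the organ, how much variation does
each axis explain, in which direction do microbes flow, how patchy are
communities at sub-millimetre scale, and how does diet reshape all of
this. `colonscape` is a Python toolkit for exactly this kind of survey,
aimed at microbial ecologists working with low-biomass spatial amplicon
data and quantitative FISH imaging.

## What it computes

* **QC for low-biomass tables** — prevalence-based contaminant
  identification against negative controls (one-sided exact
  hypergeometric score, flagged below 0.1), contaminant removal, seeded
  rarefaction without replacement, Good's coverage `1 − f₁/N`.
* **Diversity gradients** — richness S, Shannon `H = −Σ pₜ ln pₜ`,
  Bray–Curtis `d = Σ|x−y| / Σ(x+y)`, per-mouse similarity-to-stool
  profiles, block-axis interpolation, and ANOVA/Kruskal–Wallis group
  comparisons with Tukey/Dunn post-hoc tests and Benjamini–Hochberg
  adjustment.
* **Ordination and variance decomposition** — PCoA with Lingoes
  correction; perMANOVA (pseudo-F on the Σd²-partition, permutation p);
  distance-based RDA with Ezekiel-adjusted `R²adj = 1 − (1−R²)(n−1)/(n−m−1)`;
  variation partitioning of community composition into diet /
  longitudinal / lateral fractions by inclusion–exclusion on the
  adjusted-R² scale (verified against vegan's `varpart`).
* **Directional modelling** — asymmetric eigenvector maps (AEM): spatial
  eigenfunctions from the SVD of the site-by-edge matrix of a directed
  site tree, forward selection with the double stopping criterion, and a
  direction comparison (proximal→distal vs. reverse; mucus→lumen vs.
  reverse) that scores opposing hypotheses at matched model size.
* **Patchiness** — Taylor's power law `v = a·mᵇ` fitted per mouse ×
  compartment across sampling sites; b = 1 is random (Poisson) placement,
  b → 2 is strongly aggregated.
* **Image quantification** — Otsu segmentation, biovolume fraction in
  2-µm distance bins from the annotated mucus edge (0–150 µm), per-mouse
  lumen normalisation, enrichment extent, single-cell area and
  cluster-size → cell-number statistics, mucus thickness, goblet
  biovolume fraction.
* **Synthetic data with ground truth** — a community generator over the
  full design (diets × mice × 7 blocks × {mucus, lumen} × replicates,
  stool proxies, biomass-inverse contaminants, negative controls) and a
  FISH-scene generator (mucin band, contact-packed cell aggregates,
  distance-dependent target enrichment), both recording every latent so
  each analysis has a parameter-recovery test.

## Worked example

Partition compositional variation into the three design axes and compare
against the generator's own noise-free partition
(`examples/variation_partitioning.py`):

```python
from colonscape.diversity import bray_curtis
from colonscape.ordination import design_matrices, variation_partition
from colonscape.sim import simulate_community, variance_scenario_params
from colonscape.tables import rarefy

params = variance_scenario_params(seed=0)
table, metadata, truth = simulate_community(params)
lcm_ids = metadata.index[metadata["sample_type"] == "lcm"]
lcm, _ = rarefy(table.select_samples(lcm_ids), depth=1000, seed=0)
part = variation_partition(
    bray_curtis(lcm), design_matrices(metadata.loc[list(lcm.sample_ids)])
)
```

Output:

```
unique adjusted-R2 fractions (% of compositional variation):
  diet          estimated  29.2%   generator truth  29.9%
  longitudinal  estimated  14.9%   generator truth  15.8%
  lateral       estimated   1.7%   generator truth   1.8%
  residual       55.0%

perMANOVA on diet: pseudo-F = 66.0, p = 0.005
```

Diet explains the largest unique share of Bray–Curtis variation, the
longitudinal axis an order of magnitude more than the lateral axis, and
the estimates recovered from noisy rarefied counts track the generator's
noise-free partition to within a point — the pattern this kind of survey
is designed to resolve. The other scripts in `examples/` walk through
contaminant screening, diversity gradients, the AEM direction test,
Taylor patchiness, and image quantification the same way.

The full study runs end to end from one config:

```sh
colonscape run --config config.yaml     # or: python examples/full_pipeline.py
```

producing per-stage artifacts and a consolidated `report.json` that is
byte-identical across re-runs of the same config and seed.

## Layout

```
src/colonscape/     library (tables, diversity, ordination, aem, taylor,
                    imaging, sim, pipeline, cli)
examples/           one narrative script per capability
tests/              pytest suite incl. end-to-end scientific checks
scripts/            acceptance.py
docs/methods.md     models, estimators, numerical choices, limitations
```
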