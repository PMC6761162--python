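"""Community-table generator emulating a spatial dissection survey.

The design is a crossed grid: for each diet group, ``n_mice`` mice are each
sampled in ``n_blocks`` longitudinal blocks (1 = proximal, increasing
distally) times two lateral compartments (mucus, lumen) times
``n_replicates`` dissections, plus one stool sample per mouse.  Log
abundances follow a linear model,

    eta[t, s] = alpha[t] + beta[t] * (block - mid) * g_diet
                + gamma[t] * 1[mucus] + delta[t, diet]
                + mouse effect + overdispersion noise,

compositions are softmax(eta) per sample, and counts are multinomial at a
lognormal library depth (a log-normal-multinomial model, whose noise SD
theta directly controls Taylor-slope behaviour).  Reagent contaminants are
mixed in with expected relative abundance proportional to
``contaminant_scale / biomass``, the inverse-biomass law characteristic of
reagent contamination, and dominate the separately generated negative
controls.  All latents are recorded in :class:`SimTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .._rng import substream
from ..tables import AsvTable

__all__ = [
    "DietSpec",
    "CommunitySimParams",
    "SimTruth",
    "simulate_community",
    "simulate_negative_controls",
    "simulate_directional_profile",
    "paper_like_params",
    "variance_scenario_params",
]


@dataclass(frozen=True)
class DietSpec:
    """Per-diet effect structure.

    ``effect_sd`` spreads per-taxon log offsets delta; ``dominance`` adds a
    large positive offset to ``n_dominant`` taxa, concentrating the
    community and lowering richness (the signature of fibre deprivation);
    ``gradient_multiplier`` scales the longitudinal slopes (0 flattens the
    gradient); ``theta_lumen``/``theta_mucus`` are per-compartment
    overdispersion noise SDs on the log scale.
    """

    name: str
    effect_sd: float = 0.0
    n_dominant: int = 0
    dominance: float = 0.0
    gradient_multiplier: float = 1.0
    theta_lumen: float = 0.5
    theta_mucus: float = 0.8

    def __post_init__(self) -> None:
        if self.theta_lumen <= 0 or self.theta_mucus <= 0:
            raise ValueError("dispersion theta must be positive")
        if self.n_dominant < 0:
            raise ValueError("n_dominant must be non-negative")


@dataclass(frozen=True)
class CommunitySimParams:
    """Parameters of the community generator.

    Per-taxon arrays (``alpha``, ``beta``, ``gamma``, per-diet ``delta``)
    may be supplied explicitly; when ``None`` they are drawn once from the
    rule parameters below using named substreams of ``seed``, so identical
    parameters and seed give bit-identical output.
    """

    n_taxa: int = 150
    n_mice: int = 3                       # per diet
    diets: tuple[DietSpec, ...] = (DietSpec("CON"),)
    n_blocks: int = 7
    n_replicates: int = 4
    seed: int = 0

    # baseline and effect-drawing rules
    alpha_sd: float = 1.5
    frac_gradient_up: float = 0.3         # rare taxa rising distally
    frac_gradient_down: float = 0.1       # abundant taxa declining distally
    gradient_scale: float = 0.5           # log-abundance change per block
    frac_mucus: float = 0.2               # mucus-enriched taxa
    mucus_effect: float = 1.2             # log offset of mucus taxa in mucus
    mucus_background: float = -0.4        # log offset of the remaining taxa
    mouse_sd: float = 0.3

    # library sizes
    depth_log_mean: float = float(np.log(2000.0))
    depth_log_sd: float = 0.35
    stool_depth_log_mean: float = float(np.log(8000.0))
    stool_depth_log_sd: float = 0.25

    # biomass and contamination
    biomass_log_mean_lumen: float = 0.0
    biomass_log_mean_mucus: float = -0.7
    biomass_log_mean_stool: float = 5.0
    biomass_log_sd: float = 0.6
    n_contaminants: int = 0
    contaminant_scale: float = 0.02
    n_controls: int = 0
    control_depth: float = 2000.0
    contaminant_purity: float = 0.97      # contaminant share of control reads

    # explicit per-taxon effects (override the rules above)
    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    gamma: np.ndarray | None = None
    delta: dict | None = None             # diet name -> per-taxon array

    # compute SimTruth.variance_fractions (costs one extra ordination)
    track_variance_fractions: bool = True

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError("n_blocks must be at least 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if min(self.n_taxa, self.n_mice) <= 0:
            raise ValueError("n_taxa and n_mice must be positive")
        if self.n_contaminants < 0 or self.n_controls < 0:
            raise ValueError("counts must be non-negative")
        names = [d.name for d in self.diets]
        if len(names) != len(set(names)):
            raise ValueError("duplicate diet labels")
        for arr, label in ((self.alpha, "alpha"), (self.beta, "beta"), (self.gamma, "gamma")):
            if arr is not None and len(arr) != self.n_taxa:
                raise ValueError(f"{label} must have length n_taxa")

    def diet(self, name: str) -> DietSpec:
        for d in self.diets:
            if d.name == name:
                return d
        raise KeyError(f"unknown diet label {name!r}")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth recorded by :func:`simulate_community`."""

    alpha: pd.Series
    beta: pd.Series
    gamma: pd.Series
    delta: dict                           # diet -> pd.Series per taxon
    contaminant_ids: tuple
    biomass: pd.Series                    # per sample
    expected_composition: pd.DataFrame    # features x samples, columns sum to 1
    variance_fractions: dict = field(default_factory=dict)
    host_feature_ids: tuple = ()


def _draw_effects(params: CommunitySimParams):
    n = params.n_taxa
    alpha = (
        np.asarray(params.alpha, float)
        if params.alpha is not None
        else substream(params.seed, "community", "alpha").normal(0.0, params.alpha_sd, n)
    )
    if params.beta is not None:
        beta = np.asarray(params.beta, float)
    else:
        rng = substream(params.seed, "community", "beta")
        beta = np.zeros(n)
        order = np.argsort(alpha)
        n_up = int(round(params.frac_gradient_up * n))
        n_down = int(round(params.frac_gradient_down * n))
        beta[order[:n_up]] = np.abs(rng.normal(params.gradient_scale, params.gradient_scale / 3, n_up))
        beta[order[n - n_down:]] = -np.abs(
            rng.normal(params.gradient_scale, params.gradient_scale / 3, n_down)
        )
    if params.gamma is not None:
        gamma = np.asarray(params.gamma, float)
    else:
        rng = substream(params.seed, "community", "gamma")
        gamma = np.full(n, params.mucus_background, float)
        n_muc = int(round(params.frac_mucus * n))
        idx = rng.choice(n, size=n_muc, replace=False)
        gamma[idx] = np.abs(rng.normal(params.mucus_effect, params.mucus_effect / 4, n_muc))
        if params.frac_mucus == 0 and params.mucus_background == 0:
            gamma[:] = 0.0
    delta = {}
    for spec in params.diets:
        if params.delta is not None and spec.name in params.delta:
            delta[spec.name] = np.asarray(params.delta[spec.name], float)
            continue
        rng = substream(params.seed, "community", "delta", spec.name)
        vec = rng.normal(0.0, spec.effect_sd, n) if spec.effect_sd > 0 else np.zeros(n)
        if spec.n_dominant > 0 and spec.dominance != 0:
            idx = rng.choice(n, size=min(spec.n_dominant, n), replace=False)
            vec[idx] += spec.dominance
        delta[spec.name] = vec
    return alpha, beta, gamma, delta


def _softmax(eta: np.ndarray) -> np.ndarray:
    z = eta - eta.max(axis=0, keepdims=True)
    w = np.exp(z)
    return w / w.sum(axis=0, keepdims=True)


def simulate_community(params: CommunitySimParams):
    """Generate (AsvTable, metadata, SimTruth) for the full sampling design.

    One sample per (mouse, block, compartment, replicate), plus one stool
    sample per mouse whose expected composition is the uniform mixture of
    that mouse's distal-lumen (last two blocks) expected compositions.
    """
    p = params
    n = p.n_taxa
    alpha, beta, gamma, delta = _draw_effects(p)
    feature_ids = [f"ASV{i + 1:04d}" for i in range(n)]
    cont_ids = [f"CONT{i + 1:03d}" for i in range(p.n_contaminants)]
    mid = (1 + p.n_blocks) / 2.0

    rng_mouse = substream(p.seed, "community", "mouse_effects")
    rng_eps = substream(p.seed, "community", "overdispersion")
    rng_bio = substream(p.seed, "community", "biomass")
    rng_depth = substream(p.seed, "community", "depths")
    rng_counts = substream(p.seed, "community", "counts")
    rng_cont = substream(p.seed, "community", "contaminants")

    cont_weights = (
        rng_cont.dirichlet(np.full(p.n_contaminants, 5.0))
        if p.n_contaminants
        else np.zeros(0)
    )

    sample_ids, meta_rows, host_cols, biomass_vals = [], [], {}, []
    mouse_effect: dict[str, np.ndarray] = {}
    mouse_lineup = []
    for spec in p.diets:
        g = spec.gradient_multiplier
        for im in range(p.n_mice):
            mouse = f"{spec.name}_m{im + 1}"
            mouse_lineup.append((spec, mouse))
            mouse_effect[mouse] = rng_mouse.normal(0.0, p.mouse_sd, n)
            for b in range(1, p.n_blocks + 1):
                for comp in ("mucus", "lumen"):
                    theta = spec.theta_mucus if comp == "mucus" else spec.theta_lumen
                    for r in range(1, p.n_replicates + 1):
                        sid = f"{mouse}_b{b}_{comp}_r{r}"
                        eta = (
                            alpha
                            + beta * g * (b - mid)
                            + (gamma if comp == "mucus" else 0.0)
                            + delta[spec.name]
                            + mouse_effect[mouse]
                            + rng_eps.normal(0.0, theta, n)
                        )
                        host_cols[sid] = _softmax(eta[:, None])[:, 0]
                        mu_b = (
                            p.biomass_log_mean_mucus
                            if comp == "mucus"
                            else p.biomass_log_mean_lumen
                        )
                        biomass_vals.append(np.exp(rng_bio.normal(mu_b, p.biomass_log_sd)))
                        sample_ids.append(sid)
                        meta_rows.append(
                            {"sample_id": sid, "mouse": mouse, "diet": spec.name,
                             "block": b, "compartment": comp, "replicate": r,
                             "sample_type": "lcm"}
                        )

    # stool: uniform mixture of the mouse's distal-lumen expected compositions
    distal_blocks = {p.n_blocks - 1, p.n_blocks} if p.n_blocks >= 2 else {p.n_blocks}
    for spec, mouse in mouse_lineup:
        members = [
            row["sample_id"]
            for row in meta_rows
            if row["mouse"] == mouse
            and row["sample_type"] == "lcm"
            and row["compartment"] == "lumen"
            and row["block"] in distal_blocks
        ]
        sid = f"{mouse}_stool"
        host_cols[sid] = np.mean([host_cols[m] for m in members], axis=0)
        biomass_vals.append(np.exp(rng_bio.normal(p.biomass_log_mean_stool, p.biomass_log_sd)))
        sample_ids.append(sid)
        meta_rows.append(
            {"sample_id": sid, "mouse": mouse, "diet": spec.name,
             "block": np.nan, "compartment": "stool", "replicate": 1,
             "sample_type": "stool"}
        )

    host = np.column_stack([host_cols[s] for s in sample_ids])
    biomass = np.asarray(biomass_vals)

    # contaminant mixing: expected share proportional to scale / biomass
    if p.n_contaminants:
        w = cont_weights[:, None] * (p.contaminant_scale / biomass)[None, :]
        total = w.sum(axis=0)
        scale_down = np.where(total > 0.9, 0.9 / total, 1.0)
        w = w * scale_down
        expected = np.vstack([host * (1.0 - w.sum(axis=0)), w])
        all_ids = feature_ids + cont_ids
    else:
        expected = host
        all_ids = list(feature_ids)

    depths = np.empty(len(sample_ids), dtype=np.int64)
    counts = np.empty((len(all_ids), len(sample_ids)), dtype=np.int64)
    for j, row in enumerate(meta_rows):
        if row["sample_type"] == "stool":
            d = rng_depth.lognormal(p.stool_depth_log_mean, p.stool_depth_log_sd)
        else:
            d = rng_depth.lognormal(p.depth_log_mean, p.depth_log_sd)
        depths[j] = max(1, int(round(d)))
        counts[:, j] = rng_counts.multinomial(depths[j], expected[:, j])

    table = AsvTable(pd.DataFrame(counts, index=all_ids, columns=sample_ids))
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = SimTruth(
        alpha=pd.Series(alpha, index=feature_ids),
        beta=pd.Series(beta, index=feature_ids),
        gamma=pd.Series(gamma, index=feature_ids),
        delta={k: pd.Series(v, index=feature_ids) for k, v in delta.items()},
        contaminant_ids=tuple(cont_ids),
        biomass=pd.Series(biomass, index=sample_ids),
        expected_composition=pd.DataFrame(expected, index=all_ids, columns=sample_ids),
        host_feature_ids=tuple(feature_ids),
    )
    if p.track_variance_fractions:
        truth = replace(truth, variance_fractions=_truth_variance_fractions(truth, metadata))
    return table, metadata, truth


def _truth_variance_fractions(truth: SimTruth, metadata: pd.DataFrame) -> dict:
    """Partition of the noise-free expected communities over the design axes.

    The generator's own linear predictor determines each sample's expected
    composition exactly; decomposing the Bray-Curtis structure of those
    expectations over the design encodings gives the variance fractions an
    exact analysis would recover in the absence of sequencing noise.
    """
    from ..ordination import design_matrices, variation_partition
    from scipy.spatial.distance import pdist, squareform

    lcm = metadata.index[metadata["sample_type"] == "lcm"]
    comp = truth.expected_composition[lcm].to_numpy().T
    d = pd.DataFrame(
        squareform(pdist(comp, metric="braycurtis")), index=lcm, columns=lcm
    )
    blocks = design_matrices(metadata.loc[lcm])
    if len(blocks) < 2:
        return {}
    part = variation_partition(d, blocks)
    return {
        "unique": dict(part.unique),
        "marginal": dict(part.marginal),
        "total_adj_r2": part.total_adj_r2,
    }


def simulate_negative_controls(params: CommunitySimParams, truth: SimTruth):
    """Negative-control libraries dominated by the contaminant features.

    Controls carry essentially no sample biomass, so their reads come almost
    entirely (``contaminant_purity``, default 97%) from the contaminant
    profile, with a small cross-contamination leak of the mean community;
    with no contaminants defined, only the leak remains and library sizes
    collapse.  Returns ``(AsvTable, metadata)`` with
    ``sample_type = "negative_control"``.
    """
    p = params
    if p.n_controls == 0:
        raise ValueError("n_controls is zero")
    rng = substream(p.seed, "controls")
    exp = truth.expected_composition
    all_ids = list(exp.index)
    host_mean = exp.to_numpy().mean(axis=1)
    host_mean = host_mean / host_mean.sum()
    purity = p.contaminant_purity
    if truth.contaminant_ids:
        profile = np.zeros(len(all_ids))
        cont_idx = [all_ids.index(c) for c in truth.contaminant_ids]
        q = rng.dirichlet(np.full(len(cont_idx), 5.0))
        profile[cont_idx] = q
        comp = purity * profile + (1.0 - purity) * host_mean
        depth_scale = 1.0
    else:
        comp = host_mean
        depth_scale = 1.0 - purity
    comp = comp / comp.sum()
    cols, meta_rows = {}, []
    for i in range(p.n_controls):
        depth = rng.poisson(p.control_depth * depth_scale)
        sid = f"NEGCTRL_{i + 1:02d}"
        cols[sid] = rng.multinomial(depth, comp) if depth > 0 else np.zeros(len(all_ids), int)
        meta_rows.append(
            {"sample_id": sid, "mouse": "", "diet": "", "block": np.nan,
             "compartment": "control", "replicate": i + 1,
             "sample_type": "negative_control"}
        )
    table = AsvTable(pd.DataFrame(cols, index=all_ids))
    return table, pd.DataFrame(meta_rows).set_index("sample_id")


def simulate_directional_profile(
    n_blocks: int = 7,
    n_replicates: int = 4,
    n_taxa: int = 60,
    mode: str = "downstream",
    phi: float = 0.5,
    source_sd: float = 2.0,
    innovation_sd: float = 0.15,
    replicate_sd: float = 0.5,
    alpha_sd: float = 1.0,
    depth: int = 1000,
    seed: int = 0,
):
    """Small single-transect community for direction-hypothesis testing.

    ``mode='downstream'``: block-level log abundances follow a directional
    autoregression eta_b = phi * eta_{b-1} + innovation, seeded by a strong
    source community at block 1, so upstream (proximal) structure propagates
    distally with attenuation.  ``mode='exchangeable'``: block effects are
    drawn independently, so the transect carries spatial structure with no
    direction.  Returns ``(AsvTable, metadata)`` where metadata has a
    ``block`` column and a ``site`` column (``"b<block>"``).
    """
    if mode not in ("downstream", "exchangeable"):
        raise ValueError("mode must be 'downstream' or 'exchangeable'")
    rng = substream(seed, "directional", mode)
    alpha = rng.normal(0.0, alpha_sd, n_taxa)
    block_eta = np.zeros((n_blocks, n_taxa))
    if mode == "downstream":
        block_eta[0] = rng.normal(0.0, source_sd, n_taxa)
        for b in range(1, n_blocks):
            block_eta[b] = phi * block_eta[b - 1] + rng.normal(0.0, innovation_sd, n_taxa)
    else:
        scale = np.sqrt(source_sd**2 + innovation_sd**2) / np.sqrt(2.0)
        for b in range(n_blocks):
            block_eta[b] = rng.normal(0.0, scale, n_taxa)
    cols, meta_rows = {}, []
    for b in range(1, n_blocks + 1):
        for r in range(1, n_replicates + 1):
            eta = alpha + block_eta[b - 1] + rng.normal(0.0, replicate_sd, n_taxa)
            comp = _softmax(eta[:, None])[:, 0]
            sid = f"b{b}_r{r}"
            cols[sid] = rng.multinomial(depth, comp)
            meta_rows.append({"sample_id": sid, "block": b, "site": f"b{b}"})
    table = AsvTable(
        pd.DataFrame(cols, index=[f"ASV{i + 1:04d}" for i in range(n_taxa)])
    )
    return table, pd.DataFrame(meta_rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# scenario factories
# ---------------------------------------------------------------------------

def paper_like_params(seed: int = 0, n_mice: int = 3, n_taxa: int = 200,
                      n_replicates: int = 4, **overrides) -> CommunitySimParams:
    """Three-diet scenario mirroring the study design.

    A control diet with intact longitudinal gradients and modest dispersion,
    a fibre-deficient diet with attenuated gradients, a concentrated
    community and patchier (higher-theta) spatial distributions, and a
    polysaccharide- and fibre-deficient diet in which those shifts are
    strongest.
    """
    diets = (
        DietSpec("CON", effect_sd=0.0, gradient_multiplier=1.0,
                 theta_lumen=0.5, theta_mucus=0.8),
        DietSpec("FD", effect_sd=0.8, n_dominant=10, dominance=2.5,
                 gradient_multiplier=0.0, theta_lumen=1.0, theta_mucus=1.35),
        DietSpec("PFD", effect_sd=1.0, n_dominant=8, dominance=3.5,
                 gradient_multiplier=0.0, theta_lumen=1.25, theta_mucus=1.65),
    )
    defaults = dict(
        n_taxa=n_taxa, n_mice=n_mice, diets=diets, n_replicates=n_replicates,
        seed=seed, frac_gradient_up=0.4, gradient_scale=0.8,
        n_contaminants=20, contaminant_scale=0.015, n_controls=8,
    )
    defaults.update(overrides)
    return CommunitySimParams(**defaults)


def variance_scenario_params(seed: int = 0, n_mice: int = 2, n_taxa: int = 300,
                             n_replicates: int = 2, **overrides) -> CommunitySimParams:
    """Scenario for variation-partitioning recovery.

    Effect magnitudes are set so that the generator's own noise-free
    partition attributes roughly 25% of compositional variation to diet,
    20% to the longitudinal axis and 2% to the lateral axis, echoing the
    relative importance of the three design axes in a diet-contrast survey.
    """
    diets = (
        DietSpec("CON", theta_lumen=0.35, theta_mucus=0.35),
        DietSpec("FD", effect_sd=1.7, theta_lumen=0.35, theta_mucus=0.35),
        DietSpec("PFD", effect_sd=1.7, theta_lumen=0.35, theta_mucus=0.35),
    )
    defaults = dict(
        n_taxa=n_taxa, n_mice=n_mice, diets=diets, n_replicates=n_replicates,
        seed=seed, alpha_sd=1.0, gradient_scale=0.65, frac_gradient_up=0.45,
        frac_gradient_down=0.25, frac_mucus=0.25, mucus_effect=1.1,
        mucus_background=-0.25, mouse_sd=0.15,
        depth_log_mean=float(np.log(2500.0)), depth_log_sd=0.2,
    )
    defaults.update(overrides)
    return CommunitySimParams(**defaults)
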