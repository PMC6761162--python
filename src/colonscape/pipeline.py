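"""End-to-end orchestration: simulate -> QC -> diversity -> ordination ->
AEM -> patchiness -> images, from one config.

Each stage writes its artifacts under ``out_dir/<stage>/`` together with a
completion marker holding a hash of the configuration; re-running with the
same config reuses completed stages and recomputes only those whose outputs
were removed, and the consolidated ``report.json`` is byte-identical across
re-runs because every stage draws from named substreams of the root seed
and no timestamps enter the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from ._rng import substream
from .aem import chain_edges, compare_directions, hellinger, lateral_edges
from .diversity import alpha_diversity_table, bray_curtis, group_compare, similarity_to_reference
from .ordination import design_matrices, permanova, variation_partition
from .sim import (
    ImageSimParams,
    paper_like_params,
    simulate_community,
    simulate_fish_image,
    simulate_negative_controls,
)
from .imaging import (
    biovolume_profile,
    cluster_stats,
    enrichment_extent,
    mean_cell_area,
    mucus_thickness,
    normalize_profiles,
    segment_channel,
)
from .tables import (
    AsvTable,
    goods_coverage,
    prevalence_contaminant_test,
    rarefy,
    read_table,
    remove_features,
    write_table,
)
from .taylor import taylor_by_stratum

__all__ = ["RunConfig", "StageError", "run_spatial_analysis"]

log = logging.getLogger("colonscape")

REPORT_SCHEMA_VERSION = 1

# per-diet image regimes of the demo: mucus band width (um), enrichment
# extent L (um) and aggregation intensity, fibre deprivation thinning the
# mucus, shortening the enrichment zone and increasing aggregation
IMAGE_REGIMES = {
    "CON": {"band_width_um": 58.5, "extent_um": 30.0, "kappa": 0.0002},
    "FD": {"band_width_um": 40.3, "extent_um": 20.0, "kappa": 0.0004},
    "PFD": {"band_width_um": 27.4, "extent_um": 12.0, "kappa": 0.0008},
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run."""

    out_dir: str
    seed: int = 0
    # inputs: either a simulation scenario or paths to existing tables
    scenario: str = "paper_like"          # "paper_like" or "input"
    n_mice: int = 3
    n_taxa: int = 200
    n_replicates: int = 4
    input_table: str | None = None
    input_metadata: str | None = None
    input_controls: str | None = None
    # QC
    lcm_depth: int = 1000
    stool_depth: int = 4000
    decontam_threshold: float = 0.1
    # statistics
    n_perm: int = 199
    alpha: float = 0.05
    aem_delta: float = 0.02
    taylor_min_prevalence: int = 3
    # imaging demo
    run_images: bool = True
    images_per_group: int = 5

    def __post_init__(self) -> None:
        if self.lcm_depth < 1 or self.stool_depth < 1:
            raise ValueError("rarefaction depths must be positive")
        if not 0.0 < self.decontam_threshold < 1.0:
            raise ValueError("decontam threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(
            {**dataclasses.asdict(self), "out_dir": None, "version": __version__},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


class _Runner:
    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.digest = config.digest()

    # -- stage plumbing ---------------------------------------------------
    def _stage_dir(self, name: str) -> Path:
        d = self.out / name
        d.mkdir(exist_ok=True)
        return d

    def _marker(self, name: str) -> Path:
        return self.out / name / "stage.json"

    def _complete(self, name: str, summary: dict) -> dict:
        marker = self._marker(name)
        payload = {"stage": name, "config_digest": self.digest,
                   "summary": _round_floats(summary)}
        marker.write_text(json.dumps(payload, sort_keys=True, indent=1))
        return payload["summary"]

    def _cached(self, name: str) -> dict | None:
        marker = self._marker(name)
        if not marker.exists():
            return None
        payload = json.loads(marker.read_text())
        if payload.get("config_digest") != self.digest:
            return None
        log.info("stage %s: reusing completed outputs", name)
        return payload["summary"]

    def _run_stage(self, name: str, fn) -> dict:
        cached = self._cached(name)
        if cached is not None:
            return cached
        log.info("stage %s: running", name)
        try:
            summary = fn()
        except Exception as exc:
            raise StageError(name, exc) from exc
        return self._complete(name, summary)

    # -- stages -----------------------------------------------------------
    def stage_simulate(self) -> dict:
        cfg, d = self.cfg, self._stage_dir("simulate")
        if cfg.scenario == "input":
            for key in ("input_table", "input_metadata"):
                path = getattr(cfg, key)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"{key} missing: {path}")
            table = read_table(cfg.input_table)
            metadata = pd.read_csv(cfg.input_metadata, sep="\t", index_col=0)
            controls = read_table(cfg.input_controls) if cfg.input_controls else None
            truth_summary: dict = {}
        elif cfg.scenario == "paper_like":
            params = paper_like_params(
                seed=cfg.seed, n_mice=cfg.n_mice, n_taxa=cfg.n_taxa,
                n_replicates=cfg.n_replicates,
            )
            table, metadata, truth = simulate_community(params)
            controls, control_meta = simulate_negative_controls(params, truth)
            metadata = pd.concat([metadata, control_meta])
            truth_summary = {
                "n_contaminants": len(truth.contaminant_ids),
                "variance_fractions": truth.variance_fractions,
            }
            (d / "truth.json").write_text(
                json.dumps(_round_floats({
                    "contaminant_ids": list(truth.contaminant_ids),
                    **truth_summary,
                }), sort_keys=True, indent=1)
            )
        else:
            raise ValueError(f"unknown scenario {cfg.scenario!r}")
        write_table(table, d / "table.tsv")
        metadata.to_csv(d / "metadata.tsv", sep="\t")
        if controls is not None:
            write_table(controls, d / "controls.tsv")
        return {
            "n_features": int(table.shape[0]),
            "n_samples": int(table.shape[1]),
            "n_controls": int(controls.shape[1]) if controls is not None else 0,
            **truth_summary,
        }

    def _load_simulated(self):
        d = self.out / "simulate"
        table = read_table(d / "table.tsv")
        metadata = pd.read_csv(d / "metadata.tsv", sep="\t", index_col=0)
        controls_path = d / "controls.tsv"
        controls = read_table(controls_path) if controls_path.exists() else None
        return table, metadata, controls

    def stage_qc(self) -> dict:
        cfg, d = self.cfg, self._stage_dir("qc")
        table, metadata, controls = self._load_simulated()
        summary: dict = {}
        if controls is not None:
            merged = AsvTable(
                pd.concat([table.counts, controls.counts], axis=1).fillna(0).astype(int)
            )
            is_control = np.array(
                [s in set(controls.sample_ids) for s in merged.sample_ids]
            )
            report = prevalence_contaminant_test(
                merged, is_control, threshold=cfg.decontam_threshold
            )
            report.to_csv(d / "contaminant_report.csv")
            table, removed_frac = remove_features(table, report.contaminant_ids)
            summary["n_flagged"] = int(len(report.contaminant_ids))
            summary["mean_removed_read_fraction"] = float(
                removed_frac.loc[list(table.sample_ids)].mean()
            )
        lcm_ids = metadata.index[metadata["sample_type"] == "lcm"]
        stool_ids = metadata.index[metadata["sample_type"] == "stool"]
        lcm, dropped = rarefy(
            table.select_samples([s for s in table.sample_ids if s in set(lcm_ids)]),
            cfg.lcm_depth, cfg.seed,
        )
        stool, stool_dropped = rarefy(
            table.select_samples([s for s in table.sample_ids if s in set(stool_ids)]),
            cfg.stool_depth, cfg.seed,
        )
        write_table(lcm, d / "lcm_rarefied.tsv")
        write_table(stool, d / "stool_rarefied.tsv")
        coverage = [goods_coverage(lcm.counts[s]) for s in lcm.sample_ids]
        summary.update(
            n_lcm_retained=int(lcm.shape[1]),
            n_lcm_dropped=len(dropped),
            n_stool_retained=int(stool.shape[1]),
            n_stool_dropped=len(stool_dropped),
            mean_goods_coverage=float(np.mean(coverage)),
        )
        return summary

    def _load_qc(self):
        d = self.out / "qc"
        lcm = read_table(d / "lcm_rarefied.tsv")
        stool = read_table(d / "stool_rarefied.tsv")
        metadata = pd.read_csv(
            self.out / "simulate" / "metadata.tsv", sep="\t", index_col=0
        )
        return lcm, stool, metadata

    def stage_diversity(self) -> dict:
        cfg, d = self.cfg, self._stage_dir("diversity")
        lcm, stool, metadata = self._load_qc()
        alpha = alpha_diversity_table(lcm, metadata)
        alpha.to_csv(d / "alpha_diversity.csv")
        summary: dict = {"mean_richness": float(alpha["richness"].mean())}

        # longitudinal richness trend per diet (lumen)
        trends = {}
        for diet, sub in alpha[alpha["compartment"] == "lumen"].groupby("diet"):
            rho, p = sps.spearmanr(sub["block"], sub["richness"])
            trends[str(diet)] = {"spearman_rho": float(rho), "pvalue": float(p)}
        summary["richness_block_trend_lumen"] = trends

        # mucus vs lumen richness
        res = group_compare(alpha["richness"], alpha["compartment"])
        summary["richness_mucus_vs_lumen"] = {
            "mean_mucus": float(alpha.loc[alpha["compartment"] == "mucus", "richness"].mean()),
            "mean_lumen": float(alpha.loc[alpha["compartment"] == "lumen", "richness"].mean()),
            "method": res.method,
            "pvalue": res.pvalue,
        }

        # similarity to stool along the colon, over mice whose stool library
        # survived rarefaction
        stool_mice = set(metadata.loc[list(stool.sample_ids), "mouse"])
        keep = [
            s for s in lcm.sample_ids if metadata.loc[s, "mouse"] in stool_mice
        ]
        merged = AsvTable(
            pd.concat([lcm.select_samples(keep).counts, stool.counts], axis=1)
            .fillna(0).astype(int)
        )
        sim = similarity_to_reference(merged, metadata.loc[list(merged.sample_ids)])
        sim.to_csv(d / "similarity_to_stool.csv")
        lumen = sim[sim["compartment"] == "lumen"]
        by_block = lumen.groupby("block")["distance"].mean()
        summary["stool_distance_lumen"] = {
            "proximal_block": float(by_block.iloc[0]),
            "distal_block": float(by_block.iloc[-1]),
        }
        return summary

    def stage_ordination(self) -> dict:
        cfg, d = self.cfg, self._stage_dir("ordination")
        lcm, _, metadata = self._load_qc()
        md = metadata.loc[list(lcm.sample_ids)]
        dmat = bray_curtis(lcm)
        blocks = design_matrices(md)
        summary: dict = {}
        if "diet" in blocks:
            res = permanova(dmat, md["diet"].to_numpy(), n_perm=cfg.n_perm, seed=cfg.seed)
            summary["permanova_diet"] = {
                "pseudo_f": res.statistic, "pvalue": res.pvalue,
                "n_samples": res.n_samples,
            }
        part = variation_partition(dmat, blocks)
        part.as_frame().to_csv(d / "variation_partition.csv", index=False)
        summary["variation_partition_unique_pct"] = {
            k: 100.0 * v for k, v in part.unique.items()
        }
        summary["variation_partition_total_adj_r2"] = part.total_adj_r2
        return summary

    def stage_aem(self) -> dict:
        cfg, d = self.cfg, self._stage_dir("aem")
        lcm, _, metadata = self._load_qc()
        md = metadata.loc[list(lcm.sample_ids)]
        reference_diet = sorted(md["diet"].unique())[0]
        summary: dict = {}
        sites = [f"b{b}" for b in sorted(md["block"].astype(int).unique())]
        for compartment in ("lumen", "mucus"):
            ids = md.index[(md["compartment"] == compartment) & (md["diet"] == reference_diet)]
            sub = lcm.select_samples(ids)
            y = hellinger(sub.counts)
            site_of_sample = ("b" + md.loc[ids, "block"].astype(int).astype(str)).tolist()
            res = compare_directions(
                y, site_of_sample,
                {"proximal_to_distal": (sites, chain_edges(sites)),
                 "distal_to_proximal": (sites, chain_edges(sites[::-1]))},
                alpha=cfg.alpha, n_perm=cfg.n_perm, delta=cfg.aem_delta, seed=cfg.seed,
            )
            summary[f"longitudinal_{compartment}"] = {
                "verdict": res.verdict,
                **{k: {"adj_r2": v["adj_r2"], "pvalue": v["pvalue"]}
                   for k, v in res.per_hypothesis.items()},
            }
        # lateral hypothesis on the mucus/lumen grid
        ids = md.index[md["diet"] == reference_diet]
        sub = lcm.select_samples(ids)
        y = hellinger(sub.counts)
        blocks_sorted = sorted(md["block"].astype(int).unique())
        site_of_sample = (
            md.loc[ids, "compartment"].astype(str)
            + ":" + md.loc[ids, "block"].astype(int).astype(str)
        ).tolist()
        m2l = lateral_edges(blocks_sorted, source="mucus")
        l2m = lateral_edges(blocks_sorted, source="lumen")
        res = compare_directions(
            y, site_of_sample,
            {"mucus_to_lumen": m2l, "lumen_to_mucus": l2m},
            alpha=cfg.alpha, n_perm=cfg.n_perm, delta=cfg.aem_delta, seed=cfg.seed,
        )
        summary["lateral"] = {
            "verdict": res.verdict,
            **{k: {"adj_r2": v["adj_r2"], "pvalue": v["pvalue"]}
               for k, v in res.per_hypothesis.items()},
        }
        (d / "comparison.json").write_text(
            json.dumps(_round_floats(summary), sort_keys=True, indent=1)
        )
        return summary

    def stage_patchiness(self) -> dict:
        cfg, d = self.cfg, self._stage_dir("patchiness")
        lcm, _, metadata = self._load_qc()
        fits = taylor_by_stratum(
            lcm, metadata, stratum_keys=("mouse", "compartment"),
            min_prevalence=cfg.taylor_min_prevalence,
        )
        diet = fits["mouse"].str.rsplit("_", n=1).str[0]
        fits = fits.assign(diet=diet)
        fits.to_csv(d / "taylor_fits.csv", index=False)
        res = group_compare(fits["slope"], fits["compartment"])
        summary = {
            "n_fits": int(len(fits)),
            "mean_slope_by_compartment": {
                str(k): float(v) for k, v in fits.groupby("compartment")["slope"].mean().items()
            },
            "mean_slope_by_diet": {
                str(k): float(v) for k, v in fits.groupby("diet")["slope"].mean().items()
            },
            "lumen_vs_mucus": {"method": res.method, "pvalue": res.pvalue},
        }
        return summary

    def stage_images(self) -> dict:
        cfg, d = self.cfg, self._stage_dir("images")
        summary: dict = {}
        for diet, regime in IMAGE_REGIMES.items():
            rng = substream(cfg.seed, "pipeline_images", diet)
            profiles, thickness, frac_est, frac_true = [], [], [], []
            # dense fields for the distance profiles, sparse fields for
            # single-cell/cluster statistics (separate acquisitions, as in
            # practice)
            for i in range(cfg.images_per_group):
                params = ImageSimParams(
                    seed=int(rng.integers(2**31)), amplitude=2.0,
                    cell_density=0.08, kappa=0.0, band_width_um=regime["band_width_um"],
                    extent_um=regime["extent_um"],
                )
                stack, truth = simulate_fish_image(params)
                total = segment_channel(stack, "total_bacteria")
                target = segment_channel(stack, "target")
                profiles.append(biovolume_profile(target, total, stack))
                _, mean, _ = mucus_thickness(stack)
                thickness.append(mean)
            for i in range(cfg.images_per_group):
                params = ImageSimParams(
                    seed=int(rng.integers(2**31)), cell_density=0.015, **regime
                )
                stack, truth = simulate_fish_image(params)
                total = segment_channel(stack, "total_bacteria")
                mca = mean_cell_area(total, stack.scale_um)
                frac_est.append(cluster_stats(total, stack.scale_um, mca).fraction_in_clusters)
                frac_true.append(truth.fraction_in_clusters)
            extent = enrichment_extent(normalize_profiles(profiles), alpha=cfg.alpha)
            summary[diet] = {
                "mucus_thickness_um": float(np.mean(thickness)),
                "true_band_width_um": regime["band_width_um"],
                "enrichment_extent_um": float(extent),
                "true_extent_um": regime["extent_um"],
                "fraction_cells_in_clusters": float(np.mean(frac_est)),
                "true_fraction_in_clusters": float(np.mean(frac_true)),
            }
        (d / "image_metrics.json").write_text(
            json.dumps(_round_floats(summary), sort_keys=True, indent=1)
        )
        return summary


def run_spatial_analysis(config: RunConfig) -> dict:
    """Run the full pipeline; returns the consolidated report dictionary.

    The report is also written to ``<out_dir>/report.json``.  Any stage
    failure raises :class:`StageError` naming the stage; artifacts of
    completed stages are retained.
    """
    runner = _Runner(config)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "config_digest": runner.digest,
        "stages": {},
    }
    stages = [
        ("simulate", runner.stage_simulate),
        ("qc", runner.stage_qc),
        ("diversity", runner.stage_diversity),
        ("ordination", runner.stage_ordination),
        ("aem", runner.stage_aem),
        ("patchiness", runner.stage_patchiness),
    ]
    if config.run_images:
        stages.append(("images", runner.stage_images))
    for name, fn in stages:
        report["stages"][name] = runner._run_stage(name, fn)
    out = Path(config.out_dir) / "report.json"
    out.write_text(json.dumps(_round_floats(report), sort_keys=True, indent=1))
    log.info("report written to %s", out)
    return report
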