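"""End-to-end orchestration: one config, deterministic seeds, a manifest.

A run either loads user data (trees, trait table, raster, range masks) or
generates a fully synthetic study from a :class:`SimulationConfig`, then
walks the stages: environmental metrics -> PGLS models -> phylogenetic PCA
-> regime classification -> stochastic character mapping -> multi-regime
OU model comparison -> migrant analysis.  The single mandatory seed fans
out to per-stage seeds keyed by stage name, so any stage can be re-run in
isolation and reproduce byte-identical numbers.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .trees import (
    Phylogeny, TreeEnsemble, simulate_yule_tree, read_newick,
    read_newick_ensemble, reconcile_tips, write_newick,
)
from .synthetic import (
    SimulationConfig, RasterSeries, RangeMask, er_rate_matrix, scale_tree,
    simulate_regime_history, simulate_trait, simulate_allometric_dataset,
    simulate_raster_series, simulate_species_ranges,
)
from .env import compute_env_metrics
from .comparative import pgls_fit, pgls_r2, phylo_pca, model_selection
from .regimes import (
    RegimeThresholds, classify_regimes, fit_mk, stochastic_map, ensemble_maps,
    summarize_transitions,
)
from .ou import ensemble_fit, relative_brain_residuals, FAMILIES

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "migrant_analysis", "stage_seed"]


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, keyed by stage name."""
    return (int(base_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything one run needs.  Exactly one of ``synthetic`` or the input
    paths (``trees_path`` + ``traits_path`` [+ raster/masks]) must be set."""

    seed: int
    synthetic: SimulationConfig | None = None
    trees_path: str | None = None
    traits_path: str | None = None
    raster_path: str | None = None
    masks_path: str | None = None
    thresholds: RegimeThresholds = field(default_factory=RegimeThresholds)
    ppca_mode: str = "correlation"
    families: tuple = FAMILIES
    n_trees: int = 1
    n_maps_per_tree: int = 10
    n_ou_maps: int = 20
    run_pgls: bool = True
    run_ppca: bool = True
    run_mapping: bool = True
    run_ou: bool = True

    def validate(self) -> None:
        has_paths = self.trees_path is not None and self.traits_path is not None
        if bool(self.synthetic) == has_paths:
            raise ValueError("set exactly one of: synthetic block, or trees+traits paths")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def config_hash(self) -> str:
        blob = yaml.safe_dump(_to_plain(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        syn = data.pop("synthetic", None)
        th = data.pop("thresholds", None)
        if "families" in data and isinstance(data["families"], list):
            data["families"] = tuple(data["families"])
        cfg = cls(
            synthetic=SimulationConfig.from_yaml(yaml.safe_dump(syn)) if syn else None,
            thresholds=RegimeThresholds(**th) if th else RegimeThresholds(),
            **data,
        )
        return cfg


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int, drops: list[str], **extra) -> None:
        self.stages.append(
            {"stage": stage, "n_in": n_in, "n_out": n_out,
             "n_dropped": len(drops), "dropped": drops, **extra}
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


# ---------------------------------------------------------------------------
# synthetic study assembly
# ---------------------------------------------------------------------------

def _synthesize(cfg: SimulationConfig, seed: int) -> dict:
    """Generate the full synthetic study bundle with ground truth attached."""
    rng_lat = np.random.default_rng(stage_seed(seed, "latitudes"))
    tree = scale_tree(
        simulate_yule_tree(cfg.n_species, cfg.birth_rate, seed=stage_seed(seed, "tree")),
        cfg.tree_depth,
    )
    Q = er_rate_matrix(len(cfg.regime_labels), cfg.regime_rate)
    history = simulate_regime_history(
        tree, Q, root_state=list(cfg.regime_labels).index(cfg.root_regime),
        state_labels=list(cfg.regime_labels), seed=stage_seed(seed, "regimes"),
    )
    tip_regimes = history.tip_states()
    theta = np.asarray(cfg.theta, dtype=float)
    alpha = cfg.alpha if cfg.trait_family.startswith("OU") else 0.0
    rel_brain = simulate_trait(
        history, theta, alpha, cfg.sigma2,
        root_value=theta[list(cfg.regime_labels).index(cfg.root_regime)],
        seed=stage_seed(seed, "trait"),
    )
    allo = simulate_allometric_dataset(
        tree, beta0=cfg.beta0, beta1=cfg.beta1, lambda_resid=cfg.lambda_resid,
        sigma2_resid=cfg.sigma2_resid, sigma2_body=cfg.sigma2_body,
        body_root=cfg.body_root, seed=stage_seed(seed, "allometry"),
    )
    # absolute brain carries both the allometric signal and the regime signal
    traits = allo.copy()
    traits["log_brain"] = traits["log_brain"] + rel_brain.loc[traits.index]

    lat_by_regime = dict(zip(cfg.regime_labels, cfg.regime_latitudes))
    lats, status, dist = [], [], []
    for sp in traits.index:
        reg = tip_regimes[sp]
        lats.append(lat_by_regime[reg] + rng_lat.normal(0.0, cfg.lat_jitter))
        if reg.startswith("migrant"):
            status.append("migrant")
            mean_d = cfg.migrant_distance_km[0] if reg == "migrant_short" else cfg.migrant_distance_km[1]
            dist.append(max(rng_lat.normal(mean_d, mean_d * 0.1), 50.0))
        else:
            status.append("resident")
            dist.append(0.0)
    traits["breeding_latitude"] = lats
    traits["migratory_status"] = status
    traits["migratory_distance_km"] = dist
    traits["log_migratory_distance"] = np.log(np.asarray(dist) + 1.0)

    raster = simulate_raster_series(cfg.raster, seed=stage_seed(seed, "raster"))
    masks = simulate_species_ranges(
        raster, list(traits.index), np.asarray(lats),
        np.asarray([s == "migrant" for s in status]),
    )
    return {
        "tree": tree, "history": history, "tip_regimes": tip_regimes,
        "traits": traits, "raster": raster, "masks": masks,
        "relative_brain_true": rel_brain, "Q_true": Q,
    }


def _load_inputs(config: RunConfig) -> dict:
    trees_text = Path(config.trees_path).read_text()
    ensemble = read_newick_ensemble(trees_text, source=config.trees_path)
    traits = pd.read_csv(config.traits_path, index_col=0)
    out = {"tree": ensemble.trees[0], "ensemble": ensemble, "traits": traits,
           "raster": None, "masks": None}
    if config.raster_path:
        out["raster"] = RasterSeries.from_frame(pd.read_csv(config.raster_path))
    if config.masks_path:
        mask_df = pd.read_csv(config.masks_path)
        masks = [
            RangeMask(sp, season, grp["cell"].to_numpy())
            for (sp, season), grp in mask_df.groupby(["species", "season"])
        ]
        out["masks"] = masks
    return out


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------

def migrant_analysis(traits: pd.DataFrame, tree: Phylogeny):
    """PGLS of log brain on log body + log migratory distance, migrants only.

    Raises if any resident species is present or the subset is too small."""
    if (traits["migratory_status"] != "migrant").any():
        raise ValueError("migrant_analysis expects a migrants-only trait table")
    X = traits[["log_body", "log_migratory_distance"]]
    if len(traits) <= X.shape[1] + 2:
        raise ValueError("too few migrants for the distance model")
    return pgls_fit(traits["log_brain"], X, tree)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and return the result bundle.

    The bundle maps stage names to in-memory results; with ``out_dir`` every
    table is also written as delimited text along with the manifest.
    """
    config.validate()
    seed = config.seed
    manifest = RunManifest(config.config_hash(), __version__, seed)
    bundle: dict = {"manifest": manifest}

    if config.synthetic is not None:
        data = _synthesize(config.synthetic, seed)
        ensemble = None
    else:
        data = _load_inputs(config)
        ensemble = data.get("ensemble")
    tree: Phylogeny = data["tree"]
    traits: pd.DataFrame = data["traits"]
    bundle["tree"] = tree
    bundle["traits"] = traits

    recon = reconcile_tips(tree, list(traits.index))
    manifest.record("reconcile", tree.n_tips, recon["n_shared"],
                    recon["dropped_from_tree"] + recon["dropped_from_table"],
                    n_near_zero_branches=recon["n_near_zero_branches"])

    if data.get("raster") is not None and data.get("masks"):
        env = compute_env_metrics(data["raster"], data["masks"])
        traits = traits.join(env, how="left", rsuffix="_env")
        # measured geography supersedes declared columns when both exist
        bundle["env_metrics"] = env
        manifest.record("env_metrics", len(env), len(env), [])
    env_cols = ["cv_within_year", "cv_among_years", "log_snow"]

    residents = traits[traits["migratory_status"] == "resident"]
    migrants = traits[traits["migratory_status"] == "migrant"]

    if config.run_pgls and set(env_cols) <= set(traits.columns):
        models = {}
        for name, cols in [
            ("seasonal", ["log_body", "cv_within_year"]),
            ("snow", ["log_body", "log_snow"]),
            ("among_years", ["log_body", "cv_among_years"]),
        ]:
            fit = pgls_fit(residents["log_brain"], residents[cols], tree)
            reduced = pgls_fit(residents["log_brain"], residents[["log_body"]], tree)
            r2, r2_partial = pgls_r2(fit, reduced)
            models[name] = {"fit": fit, "r2": r2, "r2_partial": r2_partial}
            manifest.record(f"pgls_{name}", len(residents), fit.n, fit.dropped)
        bundle["pgls"] = models

    if config.run_ppca and set(env_cols) <= set(traits.columns):
        ppca = phylo_pca(residents[env_cols].dropna(), tree, mode=config.ppca_mode)
        bundle["ppca"] = ppca
        scores = ppca.standardized_scores
        joined = residents.join(scores)
        fit = pgls_fit(joined["log_brain"], joined[["log_body", "PC1", "PC2"]], tree)
        reduced = pgls_fit(joined["log_brain"], joined[["log_body"]], tree)
        bundle["pgls_ppca"] = {"fit": fit, "r2_partial": pgls_r2(fit, reduced)[1]}
        manifest.record("ppca", len(residents), len(scores), [])

    if len(migrants) > 4:
        try:
            bundle["migrant_model"] = migrant_analysis(migrants, tree)
            manifest.record("migrant_analysis", len(migrants), bundle["migrant_model"].n,
                            bundle["migrant_model"].dropped)
        except ValueError as exc:
            manifest.record("migrant_analysis", len(migrants), 0, [], error=str(exc))

    classified = classify_regimes(traits, config.thresholds)
    bundle["classification"] = classified
    manifest.record("classify", len(traits), len(classified), [],
                    thresholds=asdict(config.thresholds))

    if config.run_mapping:
        tip_states = classified.loc[[lb for lb in tree.tip_labels if lb in classified.index], "regime"]
        labels = sorted(tip_states.unique())
        if ensemble is None:
            ensemble = TreeEnsemble([tree] + [
                scale_tree(simulate_yule_tree(
                    tree.n_tips, seed=stage_seed(seed, f"ensemble{i}"),
                ), tree.depth)
                for i in range(config.n_trees - 1)
            ])
        maps, mk_fits, failures = ensemble_maps(
            ensemble, tip_states, config.n_maps_per_tree,
            seed=stage_seed(seed, "mapping"), state_labels=labels,
        )
        bundle["maps"] = maps
        bundle["mk_fits"] = mk_fits
        bundle["transitions"] = summarize_transitions(maps)
        manifest.record("mapping", len(ensemble), len(maps),
                        [f"tree {i}: {msg}" for i, msg in failures])

        if config.run_ou:
            rel = relative_brain_residuals(traits["log_brain"], traits["log_body"], tree)
            bundle["relative_brain"] = rel
            ou_maps = maps[: config.n_ou_maps]
            bundle["ou_summary"] = ensemble_fit(ou_maps, rel, families=config.families)
            manifest.record("ou_fit", len(ou_maps), len(ou_maps), [],
                            best_family=bundle["ou_summary"].best_family)

    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(bundle["manifest"].to_json())
    (out / "tree.nwk").write_text(write_newick(bundle["tree"]))
    bundle["traits"].to_csv(out / "traits.csv")
    if "env_metrics" in bundle:
        bundle["env_metrics"].to_csv(out / "env_metrics.csv")
    if "pgls" in bundle:
        blocks = []
        for name, entry in bundle["pgls"].items():
            fit = entry["fit"]
            blocks.append(
                f"# model: {name} (n={fit.n}, lambda={fit.lambda_hat:.3f}, "
                f"R2={entry['r2']:.3f} ({entry['r2_partial']:.3f} body-removed))\n"
                + fit.params.to_csv()
            )
        (out / "pgls_models.csv").write_text("\n".join(blocks))
    if "ppca" in bundle:
        bundle["ppca"].loadings.to_csv(out / "ppca_loadings.csv")
        pd.Series(bundle["ppca"].variance_explained,
                  index=bundle["ppca"].loadings.columns,
                  name="variance_explained").to_csv(out / "ppca_variance.csv")
    if "classification" in bundle:
        bundle["classification"][["regime"]].to_csv(out / "regimes.csv")
    if "transitions" in bundle:
        bundle["transitions"].to_frame().to_csv(out / "transitions.csv", index=False)
    if "ou_summary" in bundle:
        summ = bundle["ou_summary"]
        summ.mean_weights.to_csv(out / "ou_weights.csv")
        summ.theta_summary.to_csv(out / "ou_theta.csv", index=False)
    if "migrant_model" in bundle:
        bundle["migrant_model"].params.to_csv(out / "migrant_model.csv")
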