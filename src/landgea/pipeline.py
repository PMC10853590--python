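"""End-to-end orchestration: simulate → filter → diversity → ordination → GEA →
adaptive index → gradient-forest offset, with a single seed and file-based
artifacts so every stage is independently inspectable and reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    adaptive_landscape,
    diversity,
    environment as env_mod,
    gea,
    gradient_forest as gf_mod,
    ordination,
    synthetic_data,
    variant_io,
)
from .environment import EnvTable
from .errors import ConfigurationError, NoSignalError

_FLOAT = "%.10g"

# Default landscape: temperature gradients run south-north (y), precipitation
# and water-chemistry gradients coast-inland (x); ranges are bioclim-plausible
# for interior British Columbia. Future bio5 warming fields span the
# best/worst-case 2041-2060 increases (3.7-8.9 and 5.1-11.2 degC) along x.
DEFAULT_GRADIENTS = {
    "bio5": ("y", (18.0, 33.0)),
    "bio6": ("y", (-20.0, -2.0)),
    "bio15": ("x", (30.0, 90.0)),
    "bio16": ("x", (150.0, 450.0)),
    "pH": ("x", (6.5, 8.5)),
    "surface_area": ("y", (10.0, 400.0)),
}
DEFAULT_BIO5_DELTA = {"rcp26": (3.7, 8.9), "rcp85": (5.1, 11.2)}
DEFAULT_KEEP_PRIORITY = ["surface_area", "pH", "bio5", "bio6", "bio15", "bio16"]
CLIMATE_VARIABLES = ["bio5", "bio6", "bio15", "bio16"]


@dataclass
class PipelineConfig:
    """All thresholds and fixture parameters for one pipeline run.

    Filter defaults follow the standard whole-genome GEA recipe: biallelic
    SNPs with < 30% site missingness, individuals with <= 30% missingness,
    LD pruning at r² > 0.5 in 200-kb sliding windows; SV genotypes with < 3
    supporting read pairs recoded missing and SV sites with > 20% missingness
    dropped; environmental variables pruned at r² > 0.7; outliers at 3 SD on
    3 axes with strong candidates at r² > 0.5; gradient forests with 500
    trees.
    """

    seed: int = 0
    # fixture scale
    grid_nx: int = 10
    grid_ny: int = 10
    n_pops: int = 20
    n_individuals: int = 10
    f_model: float = 0.05
    n_snp_neutral: int = 2000
    n_snp_adaptive: int = 50
    n_sv_loci: int = 500
    n_sv_adaptive: int = 25
    snp_missing_rate: float = 0.05
    sv_missing_rate: float = 0.10
    slope_range: tuple = (2.0, 3.0)
    landscape_noise_sd: float = 0.25
    scenarios: tuple = ("rcp26", "rcp85")
    # optional external inputs (skip simulation when snp_vcf given)
    snp_vcf: str | None = None
    sv_vcf: str | None = None
    env_recent_csv: str | None = None
    env_future_csvs: dict = field(default_factory=dict)
    grid_csv: str | None = None
    populations_csv: str | None = None
    repeats_bed: str | None = None
    genes_gff: str | None = None
    # thresholds
    max_site_missing: float = 0.30
    max_ind_missing: float = 0.30
    sv_max_missing: float = 0.20
    sv_min_support: int = 3
    ld_r2: float = 0.5
    ld_window_bp: int = 200_000
    env_prune_r2: float = 0.7
    keep_priority: list = field(default_factory=lambda: list(DEFAULT_KEEP_PRIORITY))
    n_pcs: int = 3
    n_axes: int = 3
    sd_cutoff: float = 3.0
    strong_r2: float = 0.5
    n_trees: int = 500
    gf_corr_threshold: float = 0.5
    offset_predictors: list = field(default_factory=lambda: ["bio5"])

    def validate(self) -> None:
        checks = [
            ("n_axes", self.n_axes >= 1),
            ("n_pcs", self.n_pcs >= 1),
            ("sd_cutoff", self.sd_cutoff > 0),
            ("n_trees", self.n_trees >= 1),
            ("max_site_missing", 0 <= self.max_site_missing <= 1),
            ("max_ind_missing", 0 <= self.max_ind_missing <= 1),
            ("sv_max_missing", 0 <= self.sv_max_missing <= 1),
            ("ld_r2", 0 <= self.ld_r2 <= 1),
            ("env_prune_r2", 0 <= self.env_prune_r2 <= 1),
            ("strong_r2", 0 <= self.strong_r2 <= 1),
            ("ld_window_bp", self.ld_window_bp >= 1),
            ("sv_min_support", self.sv_min_support >= 0),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ConfigurationError(f"config values outside domain: {bad}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["slope_range"] = list(self.slope_range)
        d["scenarios"] = list(self.scenarios)
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_fixture(config: PipelineConfig, out_dir) -> dict[str, str]:
    """Generate the default landscape + SNP/SV fixture and write its file set."""
    delta_spec = {
        "bio5": {
            scen: _linear_delta_grid(config, *DEFAULT_BIO5_DELTA[scen])
            for scen in config.scenarios
            if scen in DEFAULT_BIO5_DELTA
        }
    }
    grid = synthetic_data.make_landscape(
        config.grid_nx,
        config.grid_ny,
        DEFAULT_GRADIENTS,
        delta_spec=delta_spec,
        seed=config.seed,
        noise_sd=config.landscape_noise_sd,
    )
    design = synthetic_data.design_populations(
        grid,
        n_pops=config.n_pops,
        n_individuals=config.n_individuals,
        F=config.f_model,
        span_variable="bio5",
        seed=config.seed + 1,
    )
    snps, snp_truth = synthetic_data.simulate_genotypes(
        design,
        grid,
        n_neutral=config.n_snp_neutral,
        n_adaptive=config.n_snp_adaptive,
        slope_range=tuple(config.slope_range),
        missing_rate=config.snp_missing_rate,
        seed=config.seed + 2,
    )
    svs, sv_truth = synthetic_data.simulate_sv_panel(
        design,
        grid,
        n_loci=config.n_sv_loci,
        n_adaptive=config.n_sv_adaptive,
        missing_rate=config.sv_missing_rate,
        slope_range=tuple(config.slope_range),
        seed=config.seed + 3,
    )
    return synthetic_data.write_fixture(
        out_dir, grid, design, snps, snp_truth, svs, sv_truth, seed=config.seed
    )


def _linear_delta_grid(config: PipelineConfig, lo: float, hi: float) -> np.ndarray:
    xs, _ = np.meshgrid(
        np.arange(config.grid_nx), np.arange(config.grid_ny), indexing="ij"
    )
    x = xs.ravel().astype(float)
    span = x.max() or 1.0
    return lo + (hi - lo) * x / span


def _ecotype_dummies(individuals: pd.DataFrame) -> pd.DataFrame:
    eco = individuals["ecotype"].fillna("none").astype(str)
    dummies = pd.get_dummies(eco, prefix="eco", drop_first=False).astype(float)
    dummies = dummies[sorted(dummies.columns)]
    return dummies.iloc[:, 1:] if dummies.shape[1] > 1 else dummies


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage and write CSV artifacts plus a manifest.

    Returns a dict of in-memory results keyed by stage. Outputs under
    ``out_dir``: fixture files (when simulated), association tables,
    variance partitions, outlier and strong-candidate tables, adaptive index
    grids, gradient-forest importance tables, per-population offsets per
    scenario, ecotype offsets, and ``manifest.json``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": config.to_dict(),
                      "inputs": {}, "counts": {}}
    results: dict = {}

    # ---- stage: inputs -------------------------------------------------
    if config.snp_vcf is None:
        fixture = simulate_fixture(config, out / "fixture")
        snp_vcf = fixture["snps.vcf"]
        sv_vcf = fixture.get("svs.vcf")
        env_recent_csv = fixture["env_sites_recent.csv"]
        env_future_csvs = {
            s: fixture[f"env_sites_future_{s}.csv"] for s in config.scenarios
        }
        grid_csv = fixture["env_grid.csv"]
        populations_csv = fixture["populations.csv"]
    else:
        snp_vcf = config.snp_vcf
        sv_vcf = config.sv_vcf
        env_recent_csv = config.env_recent_csv
        env_future_csvs = dict(config.env_future_csvs)
        grid_csv = config.grid_csv
        populations_csv = config.populations_csv
    for p in [snp_vcf, sv_vcf, env_recent_csv, grid_csv, populations_csv, *env_future_csvs.values()]:
        if p:
            manifest["inputs"][Path(p).name] = _sha256(p)

    pops = pd.read_csv(populations_csv)
    env_recent = env_mod.load_env(env_recent_csv, layer="recent")
    env_futures = {
        s: env_mod.load_env(p, layer=f"future_{s}") for s, p in env_future_csvs.items()
    }
    cells, grid_layers = env_mod.load_grid_long(grid_csv)
    env_vars = [v for v in env_recent.variables if v not in ("x", "y")]

    panels: dict[str, dict] = {}
    snp_gm = variant_io.read_vcf(snp_vcf)
    panels["snp"] = {"raw": snp_gm}
    if sv_vcf:
        panels["sv"] = {"raw": variant_io.read_vcf(sv_vcf, support_field="SR")}

    # attach population / ecotype labels from the design table
    ind_pop = {}
    for _, row in pops.iterrows():
        ind_pop[row.pop_id] = row
    for panel in panels.values():
        gm = panel["raw"]
        pop_labels = [i.rsplit("_i", 1)[0] for i in gm.individuals.index]
        gm.individuals["population"] = pop_labels
        eco = []
        for ind, p in zip(gm.individuals.index, pop_labels):
            row = ind_pop.get(p)
            if row is None or row.ecotype == "none":
                eco.append(pd.NA)
            elif row.ecotype == "both":
                i = int(ind.rsplit("_i", 1)[1])
                eco.append("stream" if i % 2 == 0 else "shore")
            else:
                eco.append(row.ecotype)
        gm.individuals["ecotype"] = eco

    # ---- stage: filters ------------------------------------------------
    snp = variant_io.filter_sites(
        panels["snp"]["raw"], biallelic_only=True, max_site_missing=config.max_site_missing
    )
    snp = variant_io.filter_individuals(snp, config.max_ind_missing)
    if config.repeats_bed:
        snp = variant_io.exclude_regions(snp, config.repeats_bed)
    panels["snp"]["het_matrix"] = snp          # pre-pruning, pre-imputation
    panels["snp"]["filtered"] = variant_io.ld_prune(
        snp, config.ld_r2, config.ld_window_bp
    )
    if "sv" in panels:
        sv = variant_io.recode_low_support(
            panels["sv"]["raw"], config.sv_min_support
        )
        sv = variant_io.filter_sites(
            sv, biallelic_only=False, max_site_missing=config.sv_max_missing
        )
        sv = variant_io.filter_individuals(sv, config.max_ind_missing)
        panels["sv"]["het_matrix"] = sv
        panels["sv"]["filtered"] = sv

    # ---- stage: environment -------------------------------------------
    site_env_raw = env_recent.select(env_vars)
    site_env_std = env_mod.standardize(site_env_raw)
    pruned_env, drop_ledger = env_mod.prune_correlated(
        site_env_std, config.env_prune_r2, keep_priority=config.keep_priority
    )
    drop_ledger.to_csv(out / "env_drop_ledger.csv", index=False, float_format=_FLOAT)
    results["env"] = {"pruned": pruned_env, "drop_ledger": drop_ledger}

    for name, panel in panels.items():
        gm = panel["filtered"]
        pop_map = gm.individuals["population"]

        # ---- heterozygosity + mixed models ----------------------------
        het = diversity.heterozygosity(panel["het_matrix"])
        assoc = diversity.association_table(het, site_env_std, site_env_std.variables)
        het.to_csv(out / f"heterozygosity_{name}.csv", float_format=_FLOAT)
        assoc.to_csv(out / f"association_{name}.csv", index=False, float_format=_FLOAT)

        # ---- imputation, PCA, predictor tables ------------------------
        imputed = variant_io.impute_mode(gm)
        pc = ordination.pca(imputed.dosage, config.n_pcs)
        pcs = pc.scores_frame(gm.individuals.index)
        ind_env_std = pruned_env.broadcast(pop_map)
        ind_env_all = site_env_std.broadcast(pop_map)

        geo = env_recent.select(["x", "y"]).broadcast(pop_map).data
        eco_dummies = _ecotype_dummies(gm.individuals)
        sets = {
            "climate": ind_env_std.data,
            "structure": pcs,
            "geography": geo,
            "ecotype": eco_dummies,
        }
        Y = imputed.dosage_frame()
        partition = ordination.partial_rda_variance(Y, sets)
        partition.to_csv(out / f"partition_{name}.csv", index=False, float_format=_FLOAT)

        # ---- GEA: pRDA, outliers, assignment, strong -------------------
        model = ordination.rda(Y, ind_env_std.data, Z=pcs)
        outliers = gea.detect_outliers(model, config.n_axes, config.sd_cutoff)
        outliers = gea.assign_env(outliers, imputed, ind_env_std, ind_env_std.variables)
        strong = gea.strong_candidates(outliers, config.strong_r2)
        outliers.to_csv(out / f"outliers_{name}.csv", index=False, float_format=_FLOAT)
        strong.to_csv(out / f"strong_{name}.csv", index=False, float_format=_FLOAT)
        if config.genes_gff and len(strong):
            genes = gea.annotate_nearest_gene(strong, gm.loci, config.genes_gff)
            genes.to_csv(out / f"genes_{name}.csv", index=False, float_format=_FLOAT)

        # ---- adaptive index -------------------------------------------
        climate_vars = [v for v in CLIMATE_VARIABLES if v in pruned_env.variables]
        adaptive_loci = [
            l
            for l in adaptive_landscape.select_climate_candidates(strong)
            if l in Y.columns
        ]
        index_frames = []
        enriched = None
        if adaptive_loci and climate_vars:
            env4 = ind_env_std.select(climate_vars)
            enriched = adaptive_landscape.adaptive_enriched_rda(
                imputed, adaptive_loci, env4, pcs
            )
            grid_recent_std = env_mod.standardize(
                grid_layers["recent"].select(climate_vars),
                reference=site_env_std.select(climate_vars),
            )
            for axis in (1, 2):
                if axis <= enriched.variable_scores.shape[1]:
                    aig = adaptive_landscape.adaptive_index(
                        enriched, axis, grid_recent_std, cells
                    )
                    index_frames.append(aig.values)
        if index_frames:
            pd.concat(index_frames, ignore_index=True).to_csv(
                out / f"adaptive_index_{name}.csv", index=False, float_format=_FLOAT
            )

        # ---- gradient forest + offsets --------------------------------
        gf_loci = strong["locus_id"].tolist()
        if len(gf_loci) < 2:
            gf_loci = outliers["locus_id"].tolist()
        gf_model, offsets, eco_offsets, gf_note = None, {}, None, ""
        if len(gf_loci) >= 1:
            freqs = variant_io.allele_frequencies(gm.subset_loci(gf_loci), pop_map)
            site_ids = freqs.freq.index
            env_cur_raw = env_recent.select(env_vars)
            try:
                gf_model = gf_mod.fit_gradient_forest(
                    freqs,
                    env_cur_raw.data.loc[site_ids],
                    n_trees=config.n_trees,
                    corr_threshold=config.gf_corr_threshold,
                    seed=config.seed + 10,
                )
            except NoSignalError as exc:
                gf_note = str(exc)
        if gf_model is not None:
            gf_model.importance_table().to_csv(
                out / f"importance_{name}.csv", index=False, float_format=_FLOAT
            )
            gf_model.to_json(out / f"turnover_{name}.json")
            off_frames = []
            for scen, env_fut in env_futures.items():
                om = gf_mod.genomic_offset(
                    gf_model,
                    EnvTable(data=env_cur_raw.data.loc[site_ids], layer="recent"),
                    EnvTable(data=env_fut.select(env_vars).data.loc[site_ids],
                             layer=f"future_{scen}"),
                    predictors=config.offset_predictors,
                )
                offsets[scen] = om
                off_frames.append(
                    pd.DataFrame(
                        {"site": om.offsets.index, "scenario": scen,
                         "offset": om.offsets.to_numpy()}
                    )
                )
            pd.concat(off_frames, ignore_index=True).to_csv(
                out / f"offset_{name}.csv", index=False, float_format=_FLOAT
            )
            if name == "snp" and gm.individuals["ecotype"].notna().any():
                scen0 = list(env_futures)[0]
                eco_offsets = gf_mod.ecotype_offsets(
                    gm,
                    gf_loci,
                    env_mod.EnvTable(data=env_recent.select(env_vars).data, layer="recent"),
                    env_mod.EnvTable(
                        data=env_futures[scen0].select(env_vars).data,
                        layer=f"future_{scen0}",
                    ),
                    predictors=config.offset_predictors,
                    n_trees=config.n_trees,
                    seed=config.seed + 11,
                )
                eco_offsets.to_csv(
                    out / f"ecotype_offset_{name}.csv", index=False, float_format=_FLOAT
                )

        manifest["counts"][name] = {
            "loci_raw": int(panel["raw"].n_loci),
            "loci_filtered": int(gm.n_loci),
            "individuals": int(gm.n_individuals),
            "outliers": int(len(outliers)),
            "strong": int(len(strong)),
            "gf_loci": int(len(gf_loci)),
            "gf_note": gf_note,
            "filter_log": gm.filter_log,
        }
        results[name] = {
            "filtered": gm,
            "het": het,
            "assoc": assoc,
            "pcs": pcs,
            "partition": partition,
            "rda": model,
            "outliers": outliers,
            "strong": strong,
            "enriched": enriched,
            "gf": gf_model,
            "offsets": offsets,
            "ecotype_offsets": eco_offsets,
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    results["manifest"] = manifest
    return results
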