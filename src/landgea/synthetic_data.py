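"""Synthetic landscapes, population designs, and genotype panels with ground truth.

The generator mirrors the statistical structure the downstream analyses assume:

* an environmental grid with smooth gradients (recent layer) and additive
  change fields per emissions scenario (future layers);
* ~20 lake populations placed along the gradient with hierarchical structure
  under a nested Balding-Nichols F-model: ancestral allele frequencies drift
  first into regional lineages (differentiation F_region, emulating the strong
  colonization-history clades of post-glacial lake systems, which are largely
  uncoupled from geography) and then into populations within lineages
  (per-population F). With a single region this reduces to the plain
  Balding-Nichols law q ~ Beta(p(1-F)/F, (1-p)(1-F)/F);
* adaptive loci whose population frequencies follow a logistic function of a
  standardized causal environmental variable, q = logistic(a + b * z);
* biallelic dosage genotypes Binomial(2, q) with independent missingness, and
  an optional smaller, noisier SV-like panel (DEL/DUP/INS/INV classes with a
  per-genotype support-count field).

Every planted locus is recorded in a :class:`TruthTable` so recovery rates of
the association machinery can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import environment as env_mod
from . import variant_io
from .errors import ConfigurationError
from .variant_io import GenotypeMatrix

ECOTYPES = ("stream", "shore", "none", "both")


@dataclass
class EnvGrid:
    """Gridded environment: cell coordinates plus recent and future layers."""

    cells: pd.DataFrame                      # cell_id, x, y
    recent: pd.DataFrame                     # index cell_id x variables
    future: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def variables(self) -> list[str]:
        return list(self.recent.columns)

    @property
    def scenarios(self) -> list[str]:
        return list(self.future)


@dataclass
class PopulationDesign:
    """Populations placed on grid cells.

    ``populations`` columns: pop_id, cell_id, n_individuals, ecotype
    (stream/shore/none, or "both" for lakes where the two reproductive
    ecotypes co-occur and individuals are split evenly), F (Balding-Nichols
    differentiation parameter in (0, 1)), and optionally ``region`` (ancestral
    lineage label for the hierarchical F-model; omitted = one panmictic
    ancestry).
    """

    populations: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.populations
        if (p["n_individuals"] < 1).any():
            raise ConfigurationError("every population needs n_individuals >= 1")
        bad = ~p["ecotype"].isin(ECOTYPES)
        if bad.any():
            raise ConfigurationError(
                f"unknown ecotype labels: {p.loc[bad, 'ecotype'].unique().tolist()}"
            )
        if ((p["F"] <= 0) | (p["F"] >= 1)).any():
            raise ConfigurationError("F-model parameters must lie in (0, 1)")

    @property
    def n_populations(self) -> int:
        return len(self.populations)


@dataclass
class TruthTable:
    """Ledger of planted loci: class, causal variable, intercept and slope."""

    table: pd.DataFrame  # locus_id, cls, causal_variable, slope, intercept

    def adaptive_ids(self) -> list[str]:
        return self.table.loc[self.table["cls"] == "adaptive", "locus_id"].tolist()


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def make_landscape(
    n_x: int,
    n_y: int,
    gradient_spec: dict,
    delta_spec: dict | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    noise_smoothing: float = 1.5,
) -> EnvGrid:
    """Build an environmental grid with linear gradients plus smooth noise.

    ``gradient_spec`` maps variable -> (direction "x"|"y", (low, high));
    recent values run linearly from low to high along the stated axis.
    ``delta_spec`` maps variable -> {scenario: additive change}, where the
    change is a scalar or per-cell array; future layer = recent + delta.
    ``noise_sd`` adds a per-variable Gaussian random field (smoothed with a
    Gaussian filter of width ``noise_smoothing`` cells) to the recent layer,
    with standard deviation ``noise_sd * |high - low|`` — i.e. expressed as a
    fraction of each variable's gradient range, so one knob fits variables on
    very different scales.
    """
    if n_x * n_y < 4:
        raise ConfigurationError("grid needs at least 4 cells")
    delta_spec = delta_spec or {}
    unknown = set(delta_spec) - set(gradient_spec)
    if unknown:
        raise ConfigurationError(f"delta_spec variables not in gradient_spec: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    xs, ys = np.meshgrid(np.arange(n_x), np.arange(n_y), indexing="ij")
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{ix:03d}_{iy:03d}" for ix, iy in zip(xs.ravel(), ys.ravel())],
            "x": xs.ravel(),
            "y": ys.ravel(),
        }
    )

    recent = {}
    for var, (direction, (lo, hi)) in gradient_spec.items():
        if direction not in ("x", "y"):
            raise ConfigurationError(f"{var}: direction must be 'x' or 'y'")
        coord = cells["x"] if direction == "x" else cells["y"]
        span = max(coord.max(), 1)
        vals = lo + (hi - lo) * coord.to_numpy() / span
        if noise_sd > 0:
            from scipy.ndimage import gaussian_filter

            field2d = rng.normal(0.0, 1.0, size=(n_x, n_y))
            smooth = gaussian_filter(field2d, noise_smoothing, mode="nearest")
            sd = smooth.std() or 1.0
            vals = vals + noise_sd * abs(hi - lo) * (smooth / sd).ravel()
        recent[var] = vals
    recent_df = pd.DataFrame(recent, index=pd.Index(cells["cell_id"], name="cell_id"))

    scenarios = sorted({s for deltas in delta_spec.values() for s in deltas})
    future = {}
    for scen in scenarios:
        layer = recent_df.copy()
        for var, deltas in delta_spec.items():
            if scen in deltas:
                layer[var] = layer[var] + np.asarray(deltas[scen]).reshape(-1)
        future[scen] = layer
    return EnvGrid(cells=cells, recent=recent_df, future=future)


def design_populations(
    grid: EnvGrid,
    n_pops: int = 20,
    n_individuals: int = 10,
    F: float = 0.05,
    span_variable: str | None = None,
    n_both_ecotype: int = 3,
    n_regions: int = 4,
    seed: int = 0,
) -> PopulationDesign:
    """Place populations on distinct cells spanning the main gradient.

    Cells are ranked along ``span_variable`` (default: first grid variable)
    and populations placed at evenly spaced quantiles, so the design covers
    the environmental gradient. The first ``n_both_ecotype`` populations get
    ecotype "both" (co-occurring stream/shore spawners); the rest alternate
    stream/shore. Populations are assigned round-robin to ``n_regions``
    ancestral lineages, interleaved along the gradient so that lineage
    membership is decoupled from the environment — mirroring post-glacial
    colonization, where genetic similarity tracks history rather than
    geographic or climatic proximity.
    """
    rng = np.random.default_rng(seed)
    var = span_variable or grid.variables[0]
    order = grid.recent[var].sort_values().index.to_numpy()
    if n_pops > len(order):
        raise ConfigurationError("more populations than grid cells")
    picks = order[np.linspace(0, len(order) - 1, n_pops).round().astype(int)]
    # jitter duplicate picks onto unused neighbours
    picks = pd.unique(picks)
    while len(picks) < n_pops:
        extra = rng.choice([c for c in order if c not in set(picks)])
        picks = np.append(picks, extra)
    eco = []
    for k in range(n_pops):
        if k < n_both_ecotype:
            eco.append("both")
        else:
            eco.append("stream" if k % 2 == 0 else "shore")
    pops = pd.DataFrame(
        {
            "pop_id": [f"pop{k:02d}" for k in range(n_pops)],
            "cell_id": picks[:n_pops],
            "n_individuals": n_individuals,
            "ecotype": eco,
            "F": F,
            "region": [f"region{k % max(n_regions, 1)}" for k in range(n_pops)],
        }
    )
    return PopulationDesign(populations=pops)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _standardized_site_values(grid: EnvGrid, design: PopulationDesign, var: str) -> np.ndarray:
    vals = grid.recent.loc[design.populations["cell_id"], var].to_numpy(float)
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ConfigurationError(f"causal variable {var!r} constant across population cells")
    return (vals - vals.mean()) / sd


def _locus_coords(rng, n_loci: int, n_chrom: int = 5, chrom_len: int = 5_000_000):
    seen: set[tuple[int, int]] = set()
    chrom = np.empty(n_loci, int)
    pos = np.empty(n_loci, int)
    filled = 0
    while filled < n_loci:  # rejection-sample unique (chrom, pos) pairs
        c = int(rng.integers(0, n_chrom))
        p = int(rng.integers(1, chrom_len + 1))
        if (c, p) in seen:
            continue
        seen.add((c, p))
        chrom[filled], pos[filled] = c, p
        filled += 1
    order = np.lexsort((pos, chrom))
    return [f"chr{c + 1}" for c in chrom[order]], pos[order], order


def _individual_table(design: PopulationDesign) -> pd.DataFrame:
    rows = []
    for _, p in design.populations.iterrows():
        for i in range(int(p.n_individuals)):
            if p.ecotype == "both":
                eco = "stream" if i % 2 == 0 else "shore"
            elif p.ecotype == "none":
                eco = pd.NA
            else:
                eco = p.ecotype
            rows.append((f"{p.pop_id}_i{i:02d}", p.pop_id, eco))
    df = pd.DataFrame(rows, columns=["individual", "population", "ecotype"])
    return df.set_index("individual")


def simulate_genotypes(
    design: PopulationDesign,
    grid: EnvGrid,
    n_neutral: int = 2000,
    n_adaptive: int = 50,
    slope_range: tuple[float, float] = (2.0, 3.0),
    global_maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.05,
    seed: int = 0,
    causal_variables: list[str] | None = None,
    variant_classes: np.ndarray | None = None,
    region_F: float = 0.15,
    id_prefix: str = "snp",
) -> tuple[GenotypeMatrix, TruthTable]:
    """Simulate a dosage panel with neutral F-model loci and planted adaptive loci.

    Neutral locus: ancestral p ~ U(global_maf_range); when the design carries
    a ``region`` column, p first drifts into each regional lineage,
    p_r ~ Beta(p(1-F_r)/F_r, ...) with F_r = ``region_F``, and the population
    frequency is drawn around its lineage value,
    q_k ~ Beta(p_r(1-F_k)/F_k, (1-p_r)(1-F_k)/F_k); without regions q_k is
    drawn around p directly (plain Balding-Nichols). Adaptive locus:
    q_k = logistic(a + b z_k) with z_k the causal variable standardized over
    the population cells, a = logit(p), |b| ~ U(slope_range) with random sign.
    Dosages are Binomial(2, q_k) with independent missingness.
    """
    if not 0 <= missing_rate < 1:
        raise ConfigurationError("missing_rate must lie in [0, 1)")
    if n_neutral < 0 or n_adaptive < 0:
        raise ConfigurationError("locus counts must be non-negative")
    rng = np.random.default_rng(seed)
    pops = design.populations
    unknown_cells = set(pops["cell_id"]) - set(grid.cells["cell_id"])
    if unknown_cells:
        raise ConfigurationError(f"design cells absent from grid: {sorted(unknown_cells)}")
    causal_variables = list(causal_variables or grid.variables)
    unknown_vars = set(causal_variables) - set(grid.variables)
    if unknown_vars:
        raise ConfigurationError(f"causal variables absent from grid: {sorted(unknown_vars)}")

    n_loci = n_neutral + n_adaptive
    inds = _individual_table(design)
    n_ind = len(inds)
    F = pops["F"].to_numpy(float)
    n_pop = len(pops)

    z = {v: _standardized_site_values(grid, design, v) for v in causal_variables}

    is_adaptive = np.zeros(n_loci, bool)
    is_adaptive[rng.choice(n_loci, n_adaptive, replace=False)] = True

    if "region" in pops.columns and pops["region"].notna().all():
        region_labels = pops["region"].astype(str)
        if not 0 < region_F < 1:
            raise ConfigurationError("region_F must lie in (0, 1)")
    else:
        region_labels = pd.Series(["_all"] * n_pop)
    region_names = pd.unique(region_labels)
    region_of_pop = region_labels.map(
        {r: i for i, r in enumerate(region_names)}
    ).to_numpy()
    hierarchical = len(region_names) > 1

    p_anc = rng.uniform(*global_maf_range, n_loci)
    q = np.empty((n_pop, n_loci))
    causal_for = np.full(n_loci, None, dtype=object)
    slope = np.zeros(n_loci)
    intercept = np.zeros(n_loci)
    eps = 1e-6  # keep Beta parameters finite after regional drift
    for ell in range(n_loci):
        if is_adaptive[ell]:
            var = causal_variables[rng.integers(len(causal_variables))]
            b = rng.uniform(*slope_range) * rng.choice([-1.0, 1.0])
            a = float(logit(p_anc[ell]))
            q[:, ell] = expit(a + b * z[var])
            causal_for[ell], slope[ell], intercept[ell] = var, b, a
        else:
            p = p_anc[ell]
            if hierarchical:
                c = (1 - region_F) / region_F
                p_reg = rng.beta(p * c, (1 - p) * c, size=len(region_names))
                p_pop = np.clip(p_reg[region_of_pop], eps, 1 - eps)
            else:
                p_pop = np.full(n_pop, p)
            alpha = p_pop * (1 - F) / F
            beta = (1 - p_pop) * (1 - F) / F
            q[:, ell] = rng.beta(alpha, beta)

    pop_of_ind = inds["population"].map(
        {p: k for k, p in enumerate(pops["pop_id"])}
    ).to_numpy()
    dosage = rng.binomial(2, q[pop_of_ind, :]).astype(float)
    if missing_rate > 0:
        dosage[rng.random((n_ind, n_loci)) < missing_rate] = np.nan

    chroms, positions, order = _locus_coords(rng, n_loci)
    locus_ids = [f"{id_prefix}{j:05d}" for j in range(n_loci)]
    if variant_classes is None:
        classes = np.array([variant_io.SNP_CLASS] * n_loci)
    else:
        classes = np.asarray(variant_classes)
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, n_loci)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])

    loci = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "chrom": chroms,
            "pos": positions,
            "ref": ref[order] if variant_classes is None else "N",
            "alt": alt[order] if variant_classes is None else
            [f"<{c}>" for c in classes[order]],
            "variant_class": classes[order],
            "multiallelic": False,
        }
    )
    gm = GenotypeMatrix(
        dosage=dosage[:, order], individuals=inds, loci=loci,
    )
    gm._log("simulate", n_loci, n_loci, seed=int(seed))

    cls = np.where(is_adaptive, "adaptive", "neutral")
    truth = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "cls": cls[order],
            "causal_variable": causal_for[order],
            "slope": slope[order],
            "intercept": np.where(is_adaptive, intercept, logit(p_anc))[order],
        }
    )
    return gm, TruthTable(table=truth)


def simulate_sv_panel(
    design: PopulationDesign,
    grid: EnvGrid,
    n_loci: int = 500,
    n_adaptive: int | None = None,
    missing_rate: float = 0.15,
    seed: int = 0,
    slope_range: tuple[float, float] = (2.0, 3.0),
    causal_variables: list[str] | None = None,
    mean_support: float = 6.0,
) -> tuple[GenotypeMatrix, TruthTable]:
    """Simulate an SV-like panel: fewer loci, higher missingness, SV classes.

    Loci carry DEL/DUP/INS/INV classes and a per-genotype support-read count
    (Poisson with the given mean) exposed as ``GenotypeMatrix.support`` and
    written to the VCF FORMAT field ``SR``.
    """
    if n_adaptive is None:
        n_adaptive = max(1, n_loci // 20)
    rng = np.random.default_rng(seed)
    classes = rng.choice(["DEL", "DUP", "INS", "INV"], n_loci)
    gm, truth = simulate_genotypes(
        design,
        grid,
        n_neutral=n_loci - n_adaptive,
        n_adaptive=n_adaptive,
        slope_range=slope_range,
        missing_rate=missing_rate,
        seed=seed + 1,
        causal_variables=causal_variables,
        variant_classes=classes,
        id_prefix="sv",
    )
    support = rng.poisson(mean_support, gm.dosage.shape).astype(float)
    support[np.isnan(gm.dosage)] = np.nan
    gm.support = support
    return gm, truth


# ---------------------------------------------------------------------------
# Fixture files
# ---------------------------------------------------------------------------

def site_env_tables(grid: EnvGrid, design: PopulationDesign) -> dict[str, pd.DataFrame]:
    """Per-population environmental tables (recent + each scenario), indexed by pop_id."""
    cells = design.populations.set_index("pop_id")["cell_id"]
    coords = grid.cells.set_index("cell_id").loc[cells, ["x", "y"]]
    coords.index = cells.index
    out = {}
    for label, layer in [("recent", grid.recent)] + [
        (f"future_{s}", grid.future[s]) for s in grid.scenarios
    ]:
        t = layer.loc[cells].copy()
        t.index = cells.index
        out[label] = pd.concat([coords, t], axis=1)
    return out


def write_fixture(
    dir_path,
    grid: EnvGrid,
    design: PopulationDesign,
    snps: GenotypeMatrix,
    snp_truth: TruthTable,
    svs: GenotypeMatrix | None = None,
    sv_truth: TruthTable | None = None,
    seed: int | None = None,
) -> dict[str, str]:
    """Write the full fixture file set; returns a name -> path map.

    Files: SNP and SV VCFs, per-site env CSVs (recent and each scenario, with
    x/y coordinates), long-format grid CSV, population design CSV, truth
    CSVs, and a metadata JSON recording the seed. Everything round-trips
    losslessly through the variant_io / environment readers.
    """
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name):
        paths[name] = str(d / name)
        return d / name

    variant_io.write_vcf(snps, _p("snps.vcf"))
    if svs is not None:
        variant_io.write_vcf(svs, _p("svs.vcf"), support_field="SR")

    for label, table in site_env_tables(grid, design).items():
        table.to_csv(_p(f"env_sites_{label}.csv"), index_label="site", float_format="%.10g")

    layers = {"recent": env_mod.EnvTable(data=grid.recent, layer="recent")}
    for s in grid.scenarios:
        layers[f"future_{s}"] = env_mod.EnvTable(data=grid.future[s], layer=f"future_{s}")
    env_mod.write_grid_long(grid.cells, layers, _p("env_grid.csv"))

    design.populations.to_csv(_p("populations.csv"), index=False)
    snp_truth.table.to_csv(_p("truth_snps.csv"), index=False, float_format="%.10g")
    if sv_truth is not None:
        sv_truth.table.to_csv(_p("truth_svs.csv"), index=False, float_format="%.10g")

    meta = {
        "seed": seed,
        "n_populations": int(design.n_populations),
        "n_individuals": int(design.populations["n_individuals"].sum()),
        "n_snp_loci": int(snps.n_loci),
        "n_sv_loci": int(svs.n_loci) if svs is not None else 0,
        "scenarios": grid.scenarios,
    }
    with open(_p("metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return paths
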