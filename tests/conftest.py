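"""Shared fixtures: toy matrices plus session-scoped simulated study fixtures."""

import numpy as np
import pandas as pd
import pytest

from landgea import environment as em
from landgea import gea, ordination, pipeline as pl
from landgea import synthetic_data as sd
from landgea import variant_io as vio
from landgea.variant_io import GenotypeMatrix


def make_gm(dosage, positions=None, chrom="chr1", support=None,
            variant_class="SNP", populations=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw dosage array (NaN = missing)."""
    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    positions = positions if positions is not None else np.arange(1, m + 1) * 100
    inds = pd.DataFrame(
        {"population": populations if populations is not None else ["popA"] * n,
         "ecotype": pd.NA},
        index=pd.Index([f"ind{i:02d}" for i in range(n)], name="individual"),
    )
    loci = pd.DataFrame(
        {
            "locus_id": [f"L{j:03d}" for j in range(m)],
            "chrom": chrom,
            "pos": np.asarray(positions, int),
            "ref": "A",
            "alt": "T",
            "variant_class": variant_class,
            "multiallelic": False,
        }
    )
    return GenotypeMatrix(
        dosage=dosage, individuals=inds, loci=loci,
        support=None if support is None else np.asarray(support, float),
    )


@pytest.fixture(scope="session")
def small_landscape():
    grid = sd.make_landscape(
        8, 8,
        {"bio5": ("y", (20.0, 35.0)), "bio6": ("y", (-18.0, -4.0)),
         "bio15": ("x", (30.0, 90.0))},
        delta_spec={"bio5": {"rcp85": 5.0}},
        seed=101, noise_sd=0.25,
    )
    design = sd.design_populations(grid, n_pops=12, n_individuals=8, F=0.05,
                                   span_variable="bio5", seed=102)
    return grid, design


@pytest.fixture(scope="session")
def small_panel(small_landscape):
    grid, design = small_landscape
    gm, truth = sd.simulate_genotypes(
        design, grid, n_neutral=300, n_adaptive=15, slope_range=(2.0, 3.0),
        missing_rate=0.05, seed=103,
    )
    return gm, truth


@pytest.fixture(scope="session")
def gea_fixture():
    """Study-scale GEA fixture: 20 pops x 10 inds, 2000 neutral + 50 adaptive
    loci (|b| in [2, 3]), F = 0.05, causal variables across the landscape."""
    grid = sd.make_landscape(10, 10, pl.DEFAULT_GRADIENTS, seed=7, noise_sd=0.25)
    design = sd.design_populations(grid, n_pops=20, n_individuals=10, F=0.05,
                                   span_variable="bio5", seed=8)
    gm, truth = sd.simulate_genotypes(
        design, grid, n_neutral=2000, n_adaptive=50, slope_range=(2.0, 3.0),
        missing_rate=0.05, seed=9,
    )
    pop = gm.individuals["population"]
    imputed = vio.impute_mode(gm)
    pcs = ordination.pca(imputed.dosage, 3).scores_frame(gm.individuals.index)
    site_env = em.standardize(
        em.EnvTable(
            data=grid.recent.loc[design.populations.cell_id].set_axis(
                design.populations.pop_id
            )
        )
    )
    ind_env = site_env.broadcast(pop)
    model = ordination.rda(imputed.dosage_frame(), ind_env.data, Z=pcs)
    outliers = gea.detect_outliers(model, n_axes=3, sd_cutoff=3.0)
    outliers = gea.assign_env(outliers, imputed, ind_env, site_env.variables)
    strong = gea.strong_candidates(outliers, 0.5)
    return {
        "grid": grid, "design": design, "gm": gm, "truth": truth,
        "imputed": imputed, "pcs": pcs, "site_env": site_env,
        "ind_env": ind_env, "rda": model, "outliers": outliers, "strong": strong,
    }


@pytest.fixture(scope="session")
def gf_fixture():
    """Gradient-forest fixture: 40 loci tracking bio5 only, 20 population sites."""
    from landgea import gradient_forest as gfm

    grid = sd.make_landscape(10, 10, pl.DEFAULT_GRADIENTS, seed=11, noise_sd=0.25)
    design = sd.design_populations(grid, n_pops=20, n_individuals=10, F=0.05,
                                   span_variable="bio5", seed=12)
    gm, truth = sd.simulate_genotypes(
        design, grid, n_neutral=0, n_adaptive=40, slope_range=(2.5, 3.0),
        missing_rate=0.0, seed=13, causal_variables=["bio5"],
    )
    freqs = vio.allele_frequencies(gm, gm.individuals["population"])
    site_env = grid.recent.loc[design.populations.cell_id].set_axis(
        design.populations.pop_id
    )
    model = gfm.fit_gradient_forest(freqs, site_env, n_trees=300, seed=14)
    return {"grid": grid, "design": design, "gm": gm, "freqs": freqs,
            "site_env": site_env, "model": model}


SMALL_RUN_CONFIG = dict(
    seed=3, n_pops=12, n_individuals=6, n_snp_neutral=500, n_snp_adaptive=25,
    n_sv_loci=120, n_sv_adaptive=12, n_trees=80,
)


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Two full pipeline runs with one seed, for smoke + determinism checks."""
    d1 = tmp_path_factory.mktemp("run_a")
    d2 = tmp_path_factory.mktemp("run_b")
    res1 = pl.run_all(pl.PipelineConfig(**SMALL_RUN_CONFIG), d1)
    res2 = pl.run_all(pl.PipelineConfig(**SMALL_RUN_CONFIG), d2)
    return d1, d2, res1, res2
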