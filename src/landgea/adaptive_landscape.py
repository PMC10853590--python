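"""Adaptively enriched ordination and projection of the adaptive index.

The adaptive index maps adaptive genetic similarity across a landscape: for a
chosen constrained axis it is the dot product of the axis's predictor
("variable") scores with each grid cell's climate, standardized with the
*recent sampling-site* reference so that map values are on the same scale as
the sampled populations. It is linear in the standardized climate and zero at
the mean-climate cell; flipping the axis flips the whole map.

Lake-idiosyncratic variables (surface area, pH) have no projected future
change, so they — and the candidate loci most strongly associated with them —
are excluded before the enriched fit, leaving the temperature and
precipitation variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import EnvTable
from .errors import ConfigurationError, NoSignalError
from .ordination import RDAResult, rda

DEFAULT_EXCLUDED_VARIABLES = ("surface_area", "pH")


@dataclass
class AdaptiveIndexGrid:
    """Grid cells x axes adaptive-index values with axis metadata."""

    values: pd.DataFrame          # columns cell_id, x, y, axis, index
    variables: list[str]
    axis_proportions: np.ndarray


def select_climate_candidates(
    candidates: pd.DataFrame,
    exclude_variables=DEFAULT_EXCLUDED_VARIABLES,
) -> list[str]:
    """Candidate locus ids whose best variable is not in the excluded set."""
    keep = ~candidates["best_variable"].isin(set(exclude_variables))
    return candidates.loc[keep, "locus_id"].tolist()


def adaptive_enriched_rda(
    gm_imputed,
    candidate_loci: list[str],
    env_climate: EnvTable | pd.DataFrame,
    structure_pcs,
) -> RDAResult:
    """Partial RDA of the candidate-locus genotypes on climate, conditioned on
    population structure.

    ``env_climate`` is the individual-level table of the retained climate
    variables (e.g. bio5, bio6, bio15, bio16); ``structure_pcs`` the genotype
    PCA axes. Raises :class:`NoSignalError` when no candidate loci remain.
    """
    if len(candidate_loci) == 0:
        raise NoSignalError("no adaptive loci left after variable exclusion")
    dos = gm_imputed.dosage_frame() if hasattr(gm_imputed, "dosage_frame") else gm_imputed
    missing = [l for l in candidate_loci if l not in dos.columns]
    if missing:
        raise ConfigurationError(f"candidate loci absent from matrix: {missing[:5]}")
    Y = dos[list(candidate_loci)]
    X = env_climate.data if isinstance(env_climate, EnvTable) else env_climate
    return rda(Y, X, Z=structure_pcs)


def adaptive_index(
    result: RDAResult,
    axis: int,
    grid_env: EnvTable,
    cells: pd.DataFrame | None = None,
) -> AdaptiveIndexGrid:
    """Project an RDA axis across a standardized environmental grid.

    index(cell) = sum over predictors j of variable_score[j, axis] * z_j(cell).
    ``grid_env`` must be standardized with the recent site reference and
    contain every predictor of the fitted model; ``cells`` optionally supplies
    x/y coordinates per cell id.
    """
    if not 1 <= axis <= result.variable_scores.shape[1]:
        raise ConfigurationError(f"axis {axis} outside fitted axes")
    if not grid_env.is_standardized:
        raise ConfigurationError("grid environment must be standardized (recent reference)")
    missing = [v for v in result.predictor_names if v not in grid_env.data.columns]
    if missing:
        raise ConfigurationError(f"grid lacks model predictors: {missing}")
    Z = grid_env.data[result.predictor_names].to_numpy(float)
    scores = result.variable_scores[:, axis - 1]
    idx = Z @ scores
    values = pd.DataFrame({"cell_id": grid_env.data.index, "axis": axis, "index": idx})
    if cells is not None:
        values = cells[["cell_id", "x", "y"]].merge(values, on="cell_id", how="right")
    else:
        values.insert(1, "x", np.nan)
        values.insert(2, "y", np.nan)
    return AdaptiveIndexGrid(
        values=values,
        variables=list(result.predictor_names),
        axis_proportions=result.proportion_explained,
    )
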