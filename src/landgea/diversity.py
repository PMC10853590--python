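"""Standing genetic variation: per-individual heterozygosity and its
environmental correlates via random-intercept linear mixed models.

Heterozygosity is the proportion of heterozygous sites among the sites
actually genotyped in each individual — a measure that is insensitive to
per-population sample size. It is meant to be computed on the filtered but
*unimputed* (and unpruned) matrix: mode imputation would systematically
deflate heterozygote counts.

Each environmental variable is tested one at a time with
heterozygosity ~ variable + (1 | population), fit by REML. The slope p-value
reported as the headline is a likelihood-ratio test of nested models refit by
ML (a Wald p is also reported), and variance explained follows the
Nakagawa-Schielzeth decomposition: marginal R² = fixed-effect variance over
fixed + random-intercept + residual variance (conditional R² adds the random
intercept to the numerator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .environment import EnvTable
from .errors import ConfigurationError, DegenerateDataError
from .variant_io import GenotypeMatrix


def heterozygosity(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-individual proportion of heterozygous sites among genotyped sites.

    Returns a table with columns population, ecotype, n_genotyped and
    prop_het, indexed by individual id.
    """
    obs = ~np.isnan(gm.dosage)
    n_genotyped = obs.sum(axis=1)
    n_het = np.nansum(gm.dosage == 1.0, axis=1)
    with np.errstate(invalid="ignore"):
        prop = np.where(n_genotyped > 0, n_het / np.maximum(n_genotyped, 1), np.nan)
    out = gm.individuals.copy()
    out["n_genotyped"] = n_genotyped
    out["prop_het"] = prop
    return out


@dataclass
class LmmFit:
    variable: str
    slope: float
    intercept: float
    p_lrt: float
    p_wald: float
    r2_marginal: float
    r2_conditional: float
    var_random: float
    var_resid: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def _env_values_per_individual(het: pd.DataFrame, env: EnvTable, variable: str) -> pd.Series:
    if variable not in env.data.columns:
        raise ConfigurationError(f"variable {variable!r} not in environmental table")
    col = env.data[variable]
    if het.index.isin(col.index).all():          # individual-level table
        return col.reindex(het.index)
    pops = het["population"]
    if pops.isin(col.index).all():               # site-level table: broadcast
        vals = col.reindex(pops.to_numpy())
        vals.index = het.index
        return vals
    raise ConfigurationError(
        f"env table rows match neither individuals nor populations for {variable!r}"
    )


def fit_env_lmm(het: pd.DataFrame, env: EnvTable, variable: str) -> LmmFit:
    """Fit heterozygosity ~ variable with a population random intercept.

    ``env`` may be indexed by individual or by population (broadcast through
    the ``population`` column of ``het``). Raises for < 3 populations or a
    constant environmental column.
    """
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    y = het["prop_het"].to_numpy(float)
    x = _env_values_per_individual(het, env, variable).to_numpy(float)
    groups = het["population"].to_numpy()
    ok = np.isfinite(y) & np.isfinite(x)
    y, x, groups = y[ok], x[ok], groups[ok]
    if len(pd.unique(groups)) < 3:
        raise ConfigurationError("random intercept unidentifiable with < 3 populations")
    if np.ptp(x) == 0:
        raise DegenerateDataError(f"environmental variable {variable!r} is constant")

    def _fit(endog, exog, reml):
        # optimizers occasionally hit singular Hessians on near-zero random
        # effects; cascade through methods before giving up
        last = None
        for method in ("bfgs", "lbfgs", "powell", "nm"):
            try:
                return MixedLM(endog, exog, groups=groups).fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last = exc
        raise DegenerateDataError(f"mixed model failed to fit: {last}")

    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reml = _fit(y, X, reml=True)
        full_ml = _fit(y, X, reml=False)
        null_ml = _fit(y, X[:, :1], reml=False)

    slope = float(reml.fe_params[1])
    intercept = float(reml.fe_params[0])
    var_random = float(np.asarray(reml.cov_re)[0, 0])
    var_resid = float(reml.scale)
    var_fixed = float(np.var(slope * x))
    total = var_fixed + var_random + var_resid
    lr = max(0.0, 2.0 * (full_ml.llf - null_ml.llf))
    return LmmFit(
        variable=variable,
        slope=slope,
        intercept=intercept,
        p_lrt=float(stats.chi2.sf(lr, df=1)),
        p_wald=float(reml.pvalues[1]),
        r2_marginal=var_fixed / total if total > 0 else np.nan,
        r2_conditional=(var_fixed + var_random) / total if total > 0 else np.nan,
        var_random=var_random,
        var_resid=var_resid,
        n=int(len(y)),
    )


def association_table(
    het: pd.DataFrame, env: EnvTable, variables: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One mixed-model fit per variable; ``significant`` flags p_lrt < alpha.

    Degenerate variables (constant columns) yield a row of NaNs flagged in the
    ``note`` column rather than aborting the whole table.
    """
    variables = list(variables) if variables is not None else env.variables
    rows = []
    for v in variables:
        try:
            fit = fit_env_lmm(het, env, v)
            row = fit.as_dict()
            row["note"] = ""
        except DegenerateDataError as exc:
            row = {"variable": v, "slope": np.nan, "intercept": np.nan,
                   "p_lrt": np.nan, "p_wald": np.nan, "r2_marginal": np.nan,
                   "r2_conditional": np.nan, "var_random": np.nan,
                   "var_resid": np.nan, "n": 0, "note": str(exc)}
        rows.append(row)
    out = pd.DataFrame(rows)
    out["significant"] = out["p_lrt"] < alpha
    return out
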