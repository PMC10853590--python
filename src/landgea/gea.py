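"""Candidate-locus detection and characterization from constrained ordination.

A locus is a candidate when its loading on one of the leading constrained
axes lies more than ``sd_cutoff`` standard deviations from that axis's mean
loading (per-axis z-scores; the union over axes is reported, each locus once
with its max-|z| axis). At the default 3 SD cutoff the implied two-tailed
normal tail probability is 0.0027. Candidates are then assigned to the
environmental variable with which their (individual-level) dosages correlate
most strongly, and those with squared correlation above 0.5 form the "strong"
subset used for the adaptive landscape and offset analyses.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .environment import EnvTable
from .errors import ConfigurationError, DegenerateDataError, FormatError
from .ordination import RDAResult
from .variant_io import GenotypeMatrix


def detect_outliers(source, n_axes: int = 3, sd_cutoff: float = 3.0) -> pd.DataFrame:
    """Find loci with |per-axis loading z-score| > sd_cutoff on the first axes.

    ``source`` is an :class:`RDAResult` or a raw (m x k) loading matrix. Each
    detected locus appears once, attributed to its max-|z| axis. Scaling any
    axis's loadings by a nonzero constant leaves the result unchanged.
    """
    if isinstance(source, RDAResult):
        loadings = source.locus_loadings
        locus_ids = source.response_names
    else:
        loadings = np.asarray(source, float)
        locus_ids = None
    m, k = loadings.shape
    if n_axes > k:
        raise ConfigurationError(f"requested {n_axes} axes, result has {k}")
    if locus_ids is None:
        locus_ids = [f"locus{j}" for j in range(m)]

    L = loadings[:, :n_axes]
    mean = L.mean(axis=0)
    sd = L.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [f"axis {i + 1}" for i in np.where(sd == 0)[0]]
        raise DegenerateDataError(f"zero loading SD on {bad}")
    z = (L - mean) / sd
    hit = np.abs(z) > sd_cutoff
    detected = hit.any(axis=1)
    best_axis = np.abs(z).argmax(axis=1)
    rows = np.where(detected)[0]
    return pd.DataFrame(
        {
            "locus_id": [locus_ids[j] for j in rows],
            "axis": best_axis[rows] + 1,
            "loading": L[rows, best_axis[rows]],
            "z": z[rows, best_axis[rows]],
        }
    )


def assign_env(
    outliers: pd.DataFrame,
    gm_imputed,
    env_per_individual: EnvTable | pd.DataFrame,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Assign each candidate to its best-correlated environmental variable.

    Pearson correlations of individual dosages with each variable; best by
    |r| with ties broken by variable order. Constant loci are flagged
    ``degenerate`` and get NaN assignments.
    """
    dos = gm_imputed.dosage_frame() if isinstance(gm_imputed, GenotypeMatrix) else gm_imputed
    env = env_per_individual.data if isinstance(env_per_individual, EnvTable) else env_per_individual
    variables = list(variables) if variables is not None else list(env.columns)
    missing = [v for v in variables if v not in env.columns]
    if missing:
        raise ConfigurationError(f"variables not in env table: {missing}")
    env = env.reindex(dos.index)
    if env[variables].isna().any().any():
        raise ConfigurationError("environmental values missing for some individuals")

    E = env[variables].to_numpy(float)
    Ec = E - E.mean(axis=0)
    Esd = E.std(axis=0, ddof=1)
    if (Esd == 0).any():
        bad = [variables[i] for i in np.where(Esd == 0)[0]]
        raise DegenerateDataError(f"constant environmental variable(s): {bad}")

    out = outliers.copy()
    best_var, best_r, degenerate = [], [], []
    n = len(dos)
    for locus in out["locus_id"]:
        g = dos[locus].to_numpy(float)
        gsd = g.std(ddof=1)
        if gsd == 0:
            best_var.append(None)
            best_r.append(np.nan)
            degenerate.append(True)
            continue
        gc = g - g.mean()
        r = (gc @ Ec) / ((n - 1) * gsd * Esd)
        j = int(np.argmax(np.abs(r)))  # argmax keeps first on exact ties
        best_var.append(variables[j])
        best_r.append(float(r[j]))
        degenerate.append(False)
    out["best_variable"] = best_var
    out["best_r"] = best_r
    out["best_r2"] = np.asarray(best_r, float) ** 2
    out["degenerate"] = degenerate
    # degenerate (constant) loci are flagged and excluded from the result
    return out[~out["degenerate"]].reset_index(drop=True)


def strong_candidates(outliers: pd.DataFrame, r2_min: float = 0.5) -> pd.DataFrame:
    """Subset of candidates with best_r2 strictly greater than ``r2_min``."""
    if "best_r2" not in outliers.columns:
        raise ConfigurationError("run assign_env before strong_candidates")
    out = outliers.copy()
    out["strong"] = out["best_r2"] > r2_min
    return out[out["strong"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Nearest-gene annotation
# ---------------------------------------------------------------------------

_ATTR_ID = re.compile(r"(?:^|;)\s*(?:ID|gene_id)=([^;]+)")


def _read_genes(gff_path) -> pd.DataFrame:
    cols = ["chrom", "source", "type", "start", "end", "score", "strand", "frame", "attr"]
    df = pd.read_csv(
        gff_path, sep="\t", comment="#", header=None, names=cols,
        dtype={"chrom": str},
    )
    if df.empty:
        raise FormatError(f"{gff_path}: no feature rows")
    genes = df[df["type"] == "gene"].copy()
    ids = []
    for attr in genes["attr"]:
        m = _ATTR_ID.search(str(attr))
        ids.append(m.group(1) if m else str(attr))
    genes["gene_id"] = ids
    return genes[["chrom", "start", "end", "gene_id"]].reset_index(drop=True)


def annotate_nearest_gene(
    outliers: pd.DataFrame, loci: pd.DataFrame, gff_path
) -> pd.DataFrame:
    """Containing gene (distance 0, relation ``inside``) or nearest gene by edge
    distance on the same chromosome; ties go to the lower-coordinate gene.

    ``loci`` is a GenotypeMatrix ``loci`` table supplying chrom/pos per locus.
    Loci on chromosomes absent from the GFF get a ``no_gene`` row. Relation is
    the locus's position relative to the gene: ``upstream`` = locus before the
    gene start, ``downstream`` = locus after the gene end (GFF intervals are
    1-based inclusive; strand is ignored).
    """
    genes = _read_genes(gff_path)
    by_chrom = {c: g.sort_values(["start", "end"]).reset_index(drop=True)
                for c, g in genes.groupby("chrom")}
    pos_of = loci.set_index("locus_id")[["chrom", "pos"]]
    rows = []
    for locus in outliers["locus_id"]:
        if locus not in pos_of.index:
            raise ConfigurationError(f"locus {locus!r} absent from loci table")
        chrom, pos = pos_of.loc[locus]
        g = by_chrom.get(str(chrom))
        if g is None or g.empty:
            rows.append({"locus_id": locus, "gene_id": "no_gene",
                         "distance": np.nan, "relation": "no_gene"})
            continue
        start = g["start"].to_numpy()
        end = g["end"].to_numpy()
        inside = (start <= pos) & (pos <= end)
        if inside.any():
            j = int(np.where(inside)[0][0])  # lowest-coordinate containing gene
            rows.append({"locus_id": locus, "gene_id": g.loc[j, "gene_id"],
                         "distance": 0, "relation": "inside"})
            continue
        dist = np.where(pos < start, start - pos, pos - end)
        best = dist.min()
        cand = np.where(dist == best)[0]
        j = int(cand[np.argmin(start[cand])])  # tie-break: lower coordinate
        relation = "upstream" if pos < start[j] else "downstream"
        rows.append({"locus_id": locus, "gene_id": g.loc[j, "gene_id"],
                     "distance": int(best), "relation": relation})
    return pd.DataFrame(rows)
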