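"""Constrained ordination from first principles: PCA, RDA, partial RDA, partitioning.

RDA is multivariate least squares followed by an eigen-decomposition of the
fitted values: genotypes Y (individuals x loci, centered) are regressed on
standardized predictors X, and the constrained axes are the principal axes of
Ŷ = X (XᵀX)⁻ Xᵀ Y. Partial RDA residualizes both Y and X on conditioning
covariates Z (here, genotype-PCA axes summarizing neutral population
structure) before the fit, so that the constrained axes capture environmental
association beyond structure.

Projection uses an SVD pseudo-inverse throughout, so rank-deficient predictor
tables (e.g. a predictor fully absorbed by the conditioning set) degrade
gracefully instead of failing; :func:`check_collinearity` is available for a
strict pre-flight check that names collinear columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CollinearityError, ConfigurationError

_RCOND = 1e-10


@dataclass
class PCAResult:
    scores: np.ndarray          # n x k sample scores
    loadings: np.ndarray        # m x k locus loadings (unit eigenvectors)
    eigenvalues: np.ndarray     # descending, >= 0
    proportion: np.ndarray      # eigenvalue / total variance

    def scores_frame(self, index) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=index, columns=cols)


@dataclass
class RDAResult:
    eigenvalues: np.ndarray          # constrained eigenvalues, descending
    locus_loadings: np.ndarray       # m x k projections of responses on axes
    sample_scores: np.ndarray        # n x k
    variable_scores: np.ndarray      # p x k predictor-axis correlations
    r2: float                        # constrained / total variance at this stage
    adj_r2: float
    constrained_variance: float
    total_variance: float            # of the (possibly conditioned) response
    total_variance_original: float   # of the centered response before conditioning
    predictor_names: list[str]
    conditioning_names: list[str] = field(default_factory=list)
    response_names: list[str] | None = None
    sample_names: list | None = None
    effective_rank: int = 0

    @property
    def proportion_explained(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues * 0.0

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"RDA{i + 1}" for i in range(self.locus_loadings.shape[1])]
        idx = self.response_names
        return pd.DataFrame(self.locus_loadings, index=idx, columns=cols)

    def variable_scores_frame(self) -> pd.DataFrame:
        cols = [f"RDA{i + 1}" for i in range(self.variable_scores.shape[1])]
        return pd.DataFrame(self.variable_scores, index=self.predictor_names, columns=cols)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _as_matrix(t) -> tuple[np.ndarray, list[str], list | None]:
    if isinstance(t, pd.DataFrame):
        return t.to_numpy(float), [str(c) for c in t.columns], list(t.index)
    a = np.asarray(t, float)
    if a.ndim == 1:
        a = a[:, None]
    return a, [f"v{i}" for i in range(a.shape[1])], None


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0)


def _standardize_cols(a: np.ndarray, names: list[str]) -> np.ndarray:
    a = _center(a)
    sd = a.std(axis=0, ddof=1)
    bad = np.where(sd == 0)[0]
    if len(bad):
        raise ConfigurationError(
            f"constant predictor column(s): {[names[i] for i in bad]}"
        )
    return a / sd


def _sign_fix(V: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    flips = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
    flips[flips == 0] = 1.0
    return flips


def _project_out(A: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of (centered) A after least squares on (centered) Z."""
    B, *_ = np.linalg.lstsq(Z, A, rcond=_RCOND)
    return A - Z @ B


def _hat_matrix_apply(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """Return (projection of Y onto col-space of X, effective rank of X).

    Directions with singular value below both a relative cutoff and an
    absolute one (standardized predictors have singular values O(sqrt(n)))
    are treated as zero, so predictors fully absorbed by a conditioning set
    contribute nothing instead of projecting onto numerical noise.
    """
    n = X.shape[0]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    atol = 1e-8 * np.sqrt(max(n, 1))
    keep = s > max(_RCOND * (s[0] if len(s) else 1.0), atol)
    rank = int(keep.sum())
    Uk = U[:, keep]
    return Uk @ (Uk.T @ Y), rank


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel correction: 1 - (1 - R²)(n - 1)/(n - p - 1)."""
    if n - p - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def check_collinearity(X: pd.DataFrame, tol: float = 1e-8) -> None:
    """Raise :class:`CollinearityError` naming columns that are linearly dependent."""
    a, names, _ = _as_matrix(X)
    a = _center(a)
    rank = np.linalg.matrix_rank(a, tol=tol * max(1.0, np.abs(a).max()))
    if rank < a.shape[1]:
        # greedy: find the first column in the span of its predecessors
        for j in range(1, a.shape[1]):
            sub = a[:, : j + 1]
            if np.linalg.matrix_rank(sub, tol=tol * max(1.0, np.abs(sub).max())) <= j:
                raise CollinearityError(
                    f"column {names[j]!r} is collinear with {names[:j]}"
                )
        raise CollinearityError(f"predictor table {names} is rank deficient")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(X, k: int) -> PCAResult:
    """PCA via SVD of the centered matrix; deterministic sign convention.

    Eigenvalues are those of the sample covariance (ddof = 1). Each loading
    vector is flipped so its largest-magnitude entry is positive.
    """
    a, _, _ = _as_matrix(X)
    n, m = a.shape
    kmax = min(n - 1, m)
    if k > kmax:
        raise ConfigurationError(f"k={k} exceeds min(n-1, m)={kmax}")
    a = _center(a)
    U, s, Vt = np.linalg.svd(a, full_matrices=False)
    U, s, V = U[:, :k], s[:k], Vt[:k].T
    flips = _sign_fix(V)
    V = V * flips
    scores = (U * s) * flips
    eig = s**2 / (n - 1)
    total = a.var(axis=0, ddof=1).sum()
    prop = eig / total if total > 0 else eig * 0.0
    return PCAResult(scores=scores, loadings=V, eigenvalues=eig, proportion=prop)


# ---------------------------------------------------------------------------
# RDA / pRDA
# ---------------------------------------------------------------------------

def rda(Y, X, Z=None, scale_loci: bool = False, standardize_predictors: bool = True) -> RDAResult:
    """(Partial) redundancy analysis.

    Y: n x m response matrix (genotypes); centered internally, optionally
    scaled to unit locus variance. X: n x p predictors (standardized
    internally by default). Z: optional conditioning table; both Y and X are
    replaced by their residuals on [1, Z] first. The number of constrained
    axes is min(p, n - 1, m).
    """
    Ya, ynames, snames = _as_matrix(Y)
    Xa, xnames, _ = _as_matrix(X)
    n, m = Ya.shape
    if Xa.shape[0] != n:
        raise ConfigurationError("Y and X row counts differ")

    Ya = _center(Ya)
    if scale_loci:
        sd = Ya.std(axis=0, ddof=1)
        Ya = Ya / np.where(sd == 0, 1.0, sd)
    total_original = float((Ya**2).sum() / (n - 1))

    Xa = _standardize_cols(Xa, xnames) if standardize_predictors else _center(Xa)

    znames: list[str] = []
    if Z is not None:
        Za, znames, _ = _as_matrix(Z)
        if Za.shape[0] != n:
            raise ConfigurationError("Y and Z row counts differ")
        Za = _center(Za)
        Ya = _project_out(Ya, Za)
        Xa = _project_out(Xa, Za)

    total = float((Ya**2).sum() / (n - 1))
    Yhat, rank = _hat_matrix_apply(Xa, Ya)

    p = Xa.shape[1]
    k = min(p, n - 1, m)
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    U, s, V = U[:, :k], s[:k], Vt[:k].T
    flips = _sign_fix(V)
    V = V * flips
    U = U * flips

    eig = s**2 / (n - 1)
    constrained = float(eig.sum())
    r2 = constrained / total if total > 0 else 0.0
    sample_scores = U * s
    locus_loadings = Ya.T @ U
    # predictor-axis correlations ("biplot" scores)
    var_scores = np.zeros((p, k))
    ss = sample_scores.std(axis=0, ddof=1)
    xs = Xa.std(axis=0, ddof=1)
    for j in range(p):
        for ax in range(k):
            if ss[ax] > 0 and xs[j] > 0:
                var_scores[j, ax] = np.corrcoef(Xa[:, j], sample_scores[:, ax])[0, 1]

    return RDAResult(
        eigenvalues=eig,
        locus_loadings=locus_loadings,
        sample_scores=sample_scores,
        variable_scores=var_scores,
        r2=float(r2),
        adj_r2=adjusted_r2(r2, n, p),
        constrained_variance=constrained,
        total_variance=total,
        total_variance_original=total_original,
        predictor_names=xnames,
        conditioning_names=znames,
        response_names=ynames,
        sample_names=snames,
        effective_rank=rank,
    )


def partial_rda_variance(Y, sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Variance partitioning over named predictor sets (climate, structure, ...).

    For each set S the table reports the unconditioned R² of S alone and the
    marginal R² of S conditioned on the union of all other sets, both
    expressed against the total variance of the original centered response,
    plus Ezekiel-adjusted versions and a ``full`` row for the joint model.
    With mutually orthogonal sets the marginal R²s sum to the full-model R².
    """
    if len(sets) < 2:
        raise ConfigurationError("variance partitioning needs at least two predictor sets")
    names = list(sets)
    frames = {k: pd.DataFrame(v) for k, v in sets.items()}
    n = len(next(iter(frames.values())))

    full_X = pd.concat(frames.values(), axis=1)
    full = rda(Y, full_X)
    tot = full.total_variance_original
    rows = [
        {
            "set": "full",
            "n_predictors": full_X.shape[1],
            "r2": full.constrained_variance / tot,
            "adj_r2": adjusted_r2(full.constrained_variance / tot, n, full_X.shape[1]),
            "r2_marginal": np.nan,
            "adj_r2_marginal": np.nan,
        }
    ]
    for name in names:
        S = frames[name]
        others = pd.concat([frames[o] for o in names if o != name], axis=1)
        alone = rda(Y, S)
        marg = rda(Y, S, Z=others)
        r2_alone = alone.constrained_variance / tot
        r2_marg = marg.constrained_variance / tot
        rows.append(
            {
                "set": name,
                "n_predictors": S.shape[1],
                "r2": r2_alone,
                "adj_r2": adjusted_r2(r2_alone, n, S.shape[1]),
                "r2_marginal": r2_marg,
                "adj_r2_marginal": adjusted_r2(r2_marg, n, S.shape[1]),
            }
        )
    return pd.DataFrame(rows)
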