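"""Gradient forest: turnover functions and genomic offset from per-locus forests.

Each response locus (population-level allele frequency by default) is fitted
with a random forest of regression trees — bootstrap resampling of sites,
a random predictor subset at each split (mtry = max(1, p // 3)), variance-
reduction splitting, minimum terminal node size 2. Per-locus goodness of fit
is the out-of-bag R²; loci with R² <= 0 carry no signal and are dropped.

Every split contributes its impurity decrease at its split value to the
splitting predictor's mass list. Per locus, masses are rescaled to sum to
that locus's R² and then averaged over retained loci, which makes each
predictor's cumulative mass function F_p — the *turnover function* — a
non-decreasing step function rising from 0 to the predictor's R²-weighted
importance. Turnover functions translate raw climate values into "genetic
importance"; the genomic offset of a site is the Euclidean distance between
its turnover-transformed current and future climates, a relative measure of
climate vulnerability.

Split values live on the raw predictor scale, so inputs to the turnover
transform and offset must be unstandardized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import EnvTable
from .errors import ConfigurationError, NoSignalError
from .variant_io import FreqMatrix, GenotypeMatrix, allele_frequencies


@dataclass
class TurnoverModel:
    predictors: list[str]
    split_values: dict[str, np.ndarray]      # per predictor, sorted ascending
    split_masses: dict[str, np.ndarray]      # matching non-negative masses
    locus_r2: pd.Series                      # OOB R² per fitted locus
    retained: list[str]                      # loci with R² > 0
    importance: dict[str, float]             # R²-weighted predictor importance
    n_trees: int
    seed: int
    response_level: str = "population_freq"
    predictor_groups: list[list[str]] = field(default_factory=list)

    def turnover(self, predictor: str, value) -> np.ndarray | float:
        """Cumulative importance F_p(value): right-continuous step function."""
        if predictor not in self.split_values:
            raise ConfigurationError(f"predictor {predictor!r} not in model")
        sv = self.split_values[predictor]
        cum = np.concatenate([[0.0], np.cumsum(self.split_masses[predictor])])
        pos = np.searchsorted(sv, np.atleast_1d(np.asarray(value, float)), side="right")
        out = cum[pos]
        return float(out[0]) if np.isscalar(value) or np.asarray(value).ndim == 0 else out

    def importance_table(self) -> pd.DataFrame:
        return (
            pd.DataFrame(
                {"predictor": list(self.importance), "importance": list(self.importance.values())}
            )
            .sort_values("importance", ascending=False, kind="stable")
            .reset_index(drop=True)
        )

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        obj = {
            "predictors": self.predictors,
            "splits": {
                p: {"values": self.split_values[p].tolist(),
                    "masses": self.split_masses[p].tolist()}
                for p in self.predictors
            },
            "locus_r2": {str(k): float(v) for k, v in self.locus_r2.items()},
            "retained": list(self.retained),
            "importance": {k: float(v) for k, v in self.importance.items()},
            "n_trees": self.n_trees,
            "seed": self.seed,
            "response_level": self.response_level,
            "predictor_groups": self.predictor_groups,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TurnoverModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            predictors=obj["predictors"],
            split_values={p: np.asarray(d["values"]) for p, d in obj["splits"].items()},
            split_masses={p: np.asarray(d["masses"]) for p, d in obj["splits"].items()},
            locus_r2=pd.Series(obj["locus_r2"]),
            retained=obj["retained"],
            importance=obj["importance"],
            n_trees=obj["n_trees"],
            seed=obj["seed"],
            response_level=obj["response_level"],
            predictor_groups=obj.get("predictor_groups", []),
        )


@dataclass
class OffsetMap:
    """Per-site genomic offset for one scenario."""

    offsets: pd.Series       # index site/cell id, values >= 0
    scenario: str
    predictors: list[str]


# ---------------------------------------------------------------------------
# Forest fitting
# ---------------------------------------------------------------------------

def _tree_splits(tree, scale: float):
    """Yield (feature, threshold, impurity_decrease/scale) for each internal node."""
    t = tree.tree_
    left, right = t.children_left, t.children_right
    w = t.weighted_n_node_samples
    imp = t.impurity
    for node in range(t.node_count):
        if left[node] == -1:
            continue
        dec = (
            w[node] * imp[node]
            - w[left[node]] * imp[left[node]]
            - w[right[node]] * imp[right[node]]
        ) / scale
        yield int(t.feature[node]), float(t.threshold[node]), max(float(dec), 0.0)


def _fit_locus_forest(X, y, n_trees, mtry, rng):
    """Bootstrap forest with explicit OOB bookkeeping.

    Returns (oob_r2, raw per-predictor split records). OOB R² compares the
    mean OOB prediction per site with the observed value, over sites that
    were out of bag at least once.
    """
    from sklearn.tree import DecisionTreeRegressor

    n = len(y)
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n)
    records: list[tuple[int, float, float]] = []
    for _ in range(n_trees):
        idx = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=2,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        if len(oob):
            oob_sum[oob] += tree.predict(X[oob])
            oob_cnt[oob] += 1
        records.extend(_tree_splits(tree, scale=float(n)))
    covered = oob_cnt > 0
    if covered.sum() < 2:
        return -np.inf, records
    pred = oob_sum[covered] / oob_cnt[covered]
    resid = y[covered] - pred
    sst = float(((y[covered] - y[covered].mean()) ** 2).sum())
    if sst == 0:
        return -np.inf, records
    return 1.0 - float((resid**2).sum()) / sst, records


def correlated_groups(env: pd.DataFrame, threshold: float = 0.5) -> list[list[str]]:
    """Connected components of |r| > sqrt(threshold) among predictors (reporting aid)."""
    cols = list(env.columns)
    r2 = env.corr().to_numpy() ** 2
    groups, seen = [], set()
    for i, c in enumerate(cols):
        if c in seen:
            continue
        stack, comp = [i], []
        while stack:
            j = stack.pop()
            if cols[j] in seen:
                continue
            seen.add(cols[j])
            comp.append(cols[j])
            stack.extend(k for k in range(len(cols))
                         if k != j and r2[j, k] > threshold and cols[k] not in seen)
        groups.append(sorted(comp))
    return groups


def fit_gradient_forest(
    freqs: FreqMatrix | pd.DataFrame,
    env: EnvTable | pd.DataFrame,
    n_trees: int = 500,
    corr_threshold: float = 0.5,
    mtry: int | None = None,
    seed: int = 0,
    response_level: str = "population_freq",
) -> TurnoverModel:
    """Fit per-locus regression forests and aggregate split-importance masses.

    ``freqs``: sites x loci responses (allele frequencies, or dosages when
    ``response_level='individual_dosage'``); NaN cells are dropped pairwise.
    ``env``: sites x predictors on the raw scale, no missing values.
    ``corr_threshold`` only controls the correlated-predictor grouping stored
    for reporting; turnover masses come from impurity decreases.
    """
    F = freqs.freq if isinstance(freqs, FreqMatrix) else pd.DataFrame(freqs)
    E = env.data if isinstance(env, EnvTable) else pd.DataFrame(env)
    E = E.reindex(F.index)
    if E.isna().any().any():
        raise ConfigurationError("environmental table has missing values or sites")
    if len(F) < 5:
        raise ConfigurationError(f"need >= 5 sites, got {len(F)}")
    predictors = list(E.columns)
    p = len(predictors)
    mtry = mtry if mtry is not None else max(1, p // 3)
    Xfull = E.to_numpy(float)
    rng = np.random.default_rng(seed)

    locus_r2: dict[str, float] = {}
    raw: dict[str, list[tuple[int, float, float]]] = {}
    for locus in F.columns:
        y = F[locus].to_numpy(float)
        ok = np.isfinite(y)
        if ok.sum() < 5 or np.ptp(y[ok]) == 0:
            locus_r2[locus] = -np.inf
            continue
        r2, records = _fit_locus_forest(Xfull[ok], y[ok], n_trees, mtry, rng)
        locus_r2[locus] = r2
        raw[locus] = records

    retained = [l for l, r in locus_r2.items() if r > 0]
    if not retained:
        best = max(locus_r2.values()) if locus_r2 else float("nan")
        raise NoSignalError(
            f"no locus with positive OOB R² (best = {best:.4f}) — "
            "responses look unrelated to the predictors"
        )

    # per-locus masses rescaled to sum to its R², then averaged over retained loci
    agg: dict[int, list[tuple[float, float]]] = {j: [] for j in range(p)}
    for locus in retained:
        records = raw[locus]
        tot = sum(d for _, _, d in records)
        if tot <= 0:
            continue
        w = locus_r2[locus] / tot / len(retained)
        for feat, thr, dec in records:
            agg[feat].append((thr, dec * w))

    split_values, split_masses, importance = {}, {}, {}
    for j, name in enumerate(predictors):
        if agg[j]:
            arr = np.asarray(agg[j])
            order = np.argsort(arr[:, 0], kind="stable")
            split_values[name] = arr[order, 0]
            split_masses[name] = arr[order, 1]
        else:
            split_values[name] = np.empty(0)
            split_masses[name] = np.empty(0)
        importance[name] = float(split_masses[name].sum())

    return TurnoverModel(
        predictors=predictors,
        split_values=split_values,
        split_masses=split_masses,
        locus_r2=pd.Series({k: v for k, v in locus_r2.items() if np.isfinite(v)}),
        retained=retained,
        importance=importance,
        n_trees=n_trees,
        seed=seed,
        response_level=response_level,
        predictor_groups=correlated_groups(E, corr_threshold),
    )


# ---------------------------------------------------------------------------
# Offsets
# ---------------------------------------------------------------------------

def genomic_offset(
    model: TurnoverModel,
    env_current: EnvTable | pd.DataFrame,
    env_future: EnvTable | pd.DataFrame,
    predictors: list[str] | None = None,
) -> OffsetMap:
    """Euclidean distance between turnover-transformed current and future climate.

    offset(site) = sqrt(sum_p (F_p(future_p) - F_p(current_p))²). Both tables
    must share site ids and contain every named predictor on the raw scale.
    """
    cur = env_current.data if isinstance(env_current, EnvTable) else pd.DataFrame(env_current)
    fut = env_future.data if isinstance(env_future, EnvTable) else pd.DataFrame(env_future)
    scenario = env_future.layer if isinstance(env_future, EnvTable) else "future"
    predictors = list(predictors) if predictors is not None else model.predictors
    for name, table in (("current", cur), ("future", fut)):
        missing = [p for p in predictors if p not in table.columns]
        if missing:
            raise ConfigurationError(f"{name} layer lacks predictor(s) {missing}")
    if not cur.index.equals(fut.index):
        fut = fut.reindex(cur.index)
        if fut.isna().any().any():
            raise ConfigurationError("current and future layers do not share site ids")
    sq = np.zeros(len(cur))
    for pname in predictors:
        fc = model.turnover(pname, cur[pname].to_numpy(float))
        ff = model.turnover(pname, fut[pname].to_numpy(float))
        sq += (ff - fc) ** 2
    return OffsetMap(
        offsets=pd.Series(np.sqrt(sq), index=cur.index, name="offset"),
        scenario=str(scenario),
        predictors=predictors,
    )


def ecotype_offsets(
    gm: GenotypeMatrix,
    strong_loci: list[str],
    env_current: EnvTable,
    env_future: EnvTable,
    predictors: list[str] | None = None,
    n_trees: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Genomic offsets per population x ecotype group.

    Allele frequencies at the strong candidate loci are recomputed for each
    (population, ecotype) group (individuals without an ecotype label form a
    ``none`` group), a gradient forest is refit at group level with each
    group's site climate, and offsets are reported per group. Populations
    with a single ecotype emit one row.
    """
    if not strong_loci:
        raise NoSignalError("no strong candidate loci supplied")
    inds = gm.individuals
    eco = inds["ecotype"].fillna("none")
    labels = inds["population"].astype(str) + "|" + eco.astype(str)
    sub = gm.subset_loci(strong_loci)
    freqs = allele_frequencies(sub, labels)

    pop_of_group = pd.Series(
        {g: g.split("|")[0] for g in freqs.freq.index}, name="population"
    )
    cur = env_current.data.loc[pop_of_group.to_numpy()].set_axis(freqs.freq.index)
    fut = env_future.data.loc[pop_of_group.to_numpy()].set_axis(freqs.freq.index)

    model = fit_gradient_forest(
        freqs, cur, n_trees=n_trees, seed=seed, response_level="population_freq"
    )
    off = genomic_offset(
        model,
        EnvTable(data=cur, layer=env_current.layer),
        EnvTable(data=fut, layer=env_future.layer),
        predictors=predictors,
    )
    out = pd.DataFrame(
        {
            "group": off.offsets.index,
            "population": [g.split("|")[0] for g in off.offsets.index],
            "ecotype": [g.split("|")[1] for g in off.offsets.index],
            "offset": off.offsets.to_numpy(),
            "scenario": off.scenario,
        }
    )
    return out.reset_index(drop=True)
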