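"""Environmental tables: loading, standardization, and correlation pruning.

Recent-period tables define the standardization record (per-variable mean and
SD); projected future layers are always standardized with the *recent* record,
never their own, so that climate change is expressed on the scale the
genotype-environment models were fitted on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError, FormatError


@dataclass
class EnvTable:
    """Sites (or individuals) x environmental variables.

    ``standardization`` is a DataFrame indexed by variable with columns
    ``mean`` and ``sd`` — the recent-layer statistics used to z-score this
    table (None for raw tables). ``incomplete`` lists variables with any
    missing cell.
    """

    data: pd.DataFrame
    layer: str = "recent"
    standardization: pd.DataFrame | None = None
    incomplete: list[str] = field(default_factory=list)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def is_standardized(self) -> bool:
        return self.standardization is not None

    def select(self, variables) -> "EnvTable":
        missing = [v for v in variables if v not in self.data.columns]
        if missing:
            raise ConfigurationError(f"variables not in table: {missing}")
        std = None
        if self.standardization is not None:
            std = self.standardization.loc[list(variables)]
        return replace(
            self,
            data=self.data[list(variables)].copy(),
            standardization=std,
            incomplete=[v for v in self.incomplete if v in variables],
        )

    def broadcast(self, mapping: pd.Series) -> "EnvTable":
        """Expand a site-level table to individual level via individual -> site."""
        mapping = pd.Series(mapping)
        unknown = set(mapping) - set(self.data.index)
        if unknown:
            raise ConfigurationError(f"sites absent from env table: {sorted(unknown)[:5]}")
        data = self.data.loc[mapping.to_numpy()]
        data.index = mapping.index
        return replace(self, data=data)


def load_env(csv_path, layer: str = "recent") -> EnvTable:
    """Load a wide CSV (first column = site/individual id) as an EnvTable.

    Variables containing any missing cell are flagged ``incomplete`` (they stay
    in the table; :func:`prune_correlated` drops them by default).
    """
    df = pd.read_csv(csv_path, index_col=0)
    for c in df.columns:
        if pd.api.types.is_numeric_dtype(df[c]):
            df[c] = df[c].astype(float)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{csv_path}: duplicated site ids {dups[:5]}")
    incomplete = [c for c in df.columns if df[c].isna().any()]
    return EnvTable(data=df, layer=layer, incomplete=incomplete)


def write_env(env: EnvTable, csv_path) -> None:
    env.data.to_csv(csv_path, float_format="%.10g")


def standardize(env: EnvTable, reference: EnvTable | None = None) -> EnvTable:
    """Z-score variables using the reference table's statistics (or own).

    A table already standardized with the same record passes through
    unchanged, so the operation is idempotent for a fixed reference. Constant
    variables raise :class:`DegenerateDataError` naming the column.
    """
    if reference is not None and reference.is_standardized:
        record = reference.standardization
    elif reference is not None:
        record = _stats(reference.data)
    elif env.is_standardized:
        return env
    else:
        record = _stats(env.data)

    if env.is_standardized:
        if env.standardization.equals(record.loc[env.standardization.index]):
            return env
        raise ConfigurationError(
            "table already standardized with a different record; start from raw values"
        )
    record = record.loc[[v for v in env.variables if v in record.index]]
    missing = set(env.variables) - set(record.index)
    if missing:
        raise ConfigurationError(f"reference lacks variables {sorted(missing)}")
    zero = record.index[record["sd"] == 0].tolist()
    if zero:
        raise DegenerateDataError(f"zero-variance variable(s): {zero}")
    z = (env.data - record["mean"]) / record["sd"]
    return replace(env, data=z, standardization=record)


def _stats(df: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})


def prune_correlated(
    env: EnvTable,
    r2_threshold: float = 0.7,
    keep_priority: list[str] | None = None,
    drop_incomplete: bool = True,
) -> tuple[EnvTable, pd.DataFrame]:
    """Greedily drop variables whose squared Pearson correlation with a retained
    variable exceeds the threshold (strict >).

    Candidates are visited in ``keep_priority`` order first, then remaining
    column order; a visited variable is retained iff its r² with every
    already-retained variable is <= threshold. Returns the pruned table and a
    drop ledger (dropped variable, the retained variable that triggered it,
    their r², and a reason column — incomplete variables are dropped first
    with reason ``missing_data``).
    """
    if not 0 <= r2_threshold <= 1:
        raise ConfigurationError(f"r2_threshold {r2_threshold} not in [0, 1]")
    order = list(dict.fromkeys((keep_priority or []) + env.variables))
    unknown = [v for v in order if v not in env.variables]
    if unknown:
        raise ConfigurationError(f"keep_priority names unknown variables {unknown}")

    ledger_rows = []
    candidates = []
    for v in order:
        if drop_incomplete and v in env.incomplete:
            ledger_rows.append(
                {"dropped": v, "because_of": None, "r2": np.nan, "reason": "missing_data"}
            )
        else:
            candidates.append(v)

    corr = env.data[candidates].corr()
    retained: list[str] = []
    for v in candidates:
        trigger, worst = None, -1.0
        for kept in retained:
            r2 = corr.loc[v, kept] ** 2
            if r2 > r2_threshold and r2 > worst:
                trigger, worst = kept, r2
        if trigger is None:
            retained.append(v)
        else:
            ledger_rows.append(
                {"dropped": v, "because_of": trigger, "r2": worst, "reason": "correlated"}
            )
    # restore original column order among retained
    retained = [v for v in env.variables if v in retained]
    ledger = pd.DataFrame(ledger_rows, columns=["dropped", "because_of", "r2", "reason"])
    return env.select(retained), ledger


# ---------------------------------------------------------------------------
# Long-format grid CSVs (cell, x, y, variable, layer, value)
# ---------------------------------------------------------------------------

def load_grid_long(csv_path) -> tuple[pd.DataFrame, dict[str, EnvTable]]:
    """Read a long-format environmental grid export.

    Returns (cells, layers): ``cells`` has columns cell_id, x, y; ``layers``
    maps each layer label to an EnvTable indexed by cell_id.
    """
    df = pd.read_csv(csv_path)
    required = {"cell_id", "x", "y", "variable", "layer", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"{csv_path}: long grid CSV needs columns {sorted(required)}")
    df["value"] = df["value"].astype(float)
    cells = df[["cell_id", "x", "y"]].drop_duplicates("cell_id").reset_index(drop=True)
    var_order = list(pd.unique(df["variable"]))
    layers = {}
    for layer, grp in df.groupby("layer"):
        wide = grp.pivot(index="cell_id", columns="variable", values="value")
        wide = wide.loc[cells["cell_id"], var_order]
        wide.columns.name = None
        layers[str(layer)] = EnvTable(data=wide, layer=str(layer))
    return cells, layers


def write_grid_long(cells: pd.DataFrame, layers: dict[str, EnvTable], csv_path) -> None:
    parts = []
    for label, env in layers.items():
        long = env.data.reset_index(names="cell_id").melt(
            id_vars="cell_id", var_name="variable", value_name="value"
        )
        long["layer"] = label
        parts.append(long.merge(cells, on="cell_id"))
    out = pd.concat(parts, ignore_index=True)
    out[["cell_id", "x", "y", "variable", "layer", "value"]].to_csv(
        csv_path, index=False, float_format="%.10g"
    )
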