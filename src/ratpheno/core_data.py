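"""Data model and I/O for behavioral test-battery datasets.

A dataset is a rats × variables numeric table together with a per-rat stress
group label (``NS`` = no shock, ``IS`` = inescapable shock) and per-variable
metadata: which behavioral test the variable comes from and whether higher
values indicate resilience or susceptibility to stress.

The module also provides column-wise Z-scoring (pooled over both groups) and
the derived behavioral indices computed from raw test quantities (sucrose
preference, object discrimination, social preference, startle habituation,
prepulse inhibition).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TESTS",
    "VALENCES",
    "GROUPS",
    "SchemaError",
    "DegenerateDataError",
    "VariableMeta",
    "BehavioralDataset",
    "RawTestIndices",
    "ZScoredMatrix",
    "read_dataset",
    "write_dataset",
    "zscore",
    "sucrose_preference",
    "discrimination_index",
    "social_preference_ratio",
    "habituation_pct",
    "ppi_pct",
    "derive_test_indices",
]

#: Behavioral tests of the battery, in administration order:
#: open field, forced swim, social interaction, elevated plus maze, novel
#: object recognition, prepulse inhibition/startle, sucrose preference,
#: shuttle box.
TESTS = ("OF", "FST", "SIT", "EPM", "NOR", "PPI", "SPT", "SB")

VALENCES = ("resilience", "susceptibility")

GROUPS = ("NS", "IS")


class SchemaError(ValueError):
    """Input files or tables do not match the expected dataset schema."""


class DegenerateDataError(ValueError):
    """Data are degenerate for the requested operation (e.g. constant columns)."""


@dataclass(frozen=True)
class VariableMeta:
    """Metadata for one behavioral variable.

    Parameters
    ----------
    name
        Unique variable name (e.g. ``"SB_escape_failures"``).
    test
        Behavioral test the variable belongs to; one of :data:`TESTS`.
    valence
        ``"resilience"`` if higher values indicate adaptive coping,
        ``"susceptibility"`` if higher values indicate stress-induced
        maladaptation.
    units
        Free-text measurement units.
    """

    name: str
    test: str
    valence: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise SchemaError(
                f"variable {self.name!r}: unknown test {self.test!r}; expected one of {TESTS}"
            )
        if self.valence not in VALENCES:
            raise SchemaError(
                f"variable {self.name!r}: unknown valence {self.valence!r}; "
                f"expected one of {VALENCES}"
            )


@dataclass
class BehavioralDataset:
    """Rats × variables behavioral matrix with group labels and metadata.

    Attributes
    ----------
    values
        ``(n_rats, n_variables)`` float array; no missing values.
    rat_ids
        Per-rat identifiers, unique.
    group
        Per-rat stress group, ``"NS"`` or ``"IS"``.
    meta
        Per-variable :class:`VariableMeta`, in column order.
    hn_label
        Optional per-rat helplessness class, ``"H"`` or ``"NH"``.
    """

    values: np.ndarray
    rat_ids: list[str]
    group: np.ndarray
    meta: list[VariableMeta]
    hn_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        self.rat_ids = [str(r) for r in self.rat_ids]
        if self.values.ndim != 2:
            raise SchemaError("values must be a 2-D rats × variables matrix")
        n, p = self.values.shape
        if len(self.rat_ids) != n or len(self.group) != n:
            raise SchemaError(
                f"row mismatch: {n} value rows, {len(self.rat_ids)} rat_ids, "
                f"{len(self.group)} group labels"
            )
        if len(self.meta) != p:
            raise SchemaError(f"column mismatch: {p} value columns, {len(self.meta)} meta rows")
        names = [m.name for m in self.meta]
        if len(set(names)) != len(names):
            dupes = sorted({x for x in names if names.count(x) > 1})
            raise SchemaError(f"duplicate variable names: {dupes}")
        if len(set(self.rat_ids)) != len(self.rat_ids):
            raise SchemaError("rat_ids must be unique")
        bad = sorted(set(self.group) - set(GROUPS))
        if bad:
            raise SchemaError(f"unknown group labels {bad}; expected {GROUPS}")
        if np.isnan(self.values).any():
            rows = [self.rat_ids[i] for i in np.unique(np.where(np.isnan(self.values))[0])]
            raise SchemaError(f"missing values in rows {rows}; drop them or fix the input")
        if self.hn_label is not None:
            self.hn_label = np.asarray(self.hn_label, dtype=object)
            if len(self.hn_label) != n:
                raise SchemaError("hn_label length must match the number of rats")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_rats(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def variable_names(self) -> list[str]:
        return [m.name for m in self.meta]

    @property
    def valences(self) -> np.ndarray:
        """Per-variable valence labels as an object array."""
        return np.asarray([m.valence for m in self.meta], dtype=object)

    @property
    def tests(self) -> np.ndarray:
        """Per-variable test membership as an object array."""
        return np.asarray([m.test for m in self.meta], dtype=object)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.variable_names.index(name)
        except ValueError:
            raise KeyError(f"no variable named {name!r}") from None
        return self.values[:, j]

    def subset(self, names: Sequence[str]) -> "BehavioralDataset":
        """Dataset restricted to the given variables, in the given order."""
        idx = [self.variable_names.index(n) for n in names]
        return BehavioralDataset(
            values=self.values[:, idx],
            rat_ids=list(self.rat_ids),
            group=self.group.copy(),
            meta=[self.meta[j] for j in idx],
            hn_label=None if self.hn_label is None else self.hn_label.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Values as a DataFrame indexed by rat id, with a leading group column."""
        df = pd.DataFrame(self.values, index=self.rat_ids, columns=self.variable_names)
        df.insert(0, "group", self.group)
        df.index.name = "rat_id"
        return df

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.name, m.test, m.valence, m.units) for m in self.meta],
            columns=["name", "test", "valence", "units"],
        )


@dataclass(frozen=True)
class RawTestIndices:
    """Raw quantities from which the derived behavioral indices are computed.

    SI/WI: sucrose and water intake (ml); TN/TF: new and familiar object
    exploration time (s); OC/EC: interaction time with the occupied and empty
    cage (s); HAB0/HAB1: startle amplitude in the first and last habituation
    blocks (a.u.); PPplusP/P: startle amplitude on prepulse+pulse and
    pulse-only trials (a.u.).
    """

    SI: float | None = None
    WI: float | None = None
    TN: float | None = None
    TF: float | None = None
    OC: float | None = None
    EC: float | None = None
    HAB0: float | None = None
    HAB1: float | None = None
    PPplusP: float | None = None
    P: float | None = None


@dataclass
class ZScoredMatrix:
    """Column-standardized matrix with the standardization provenance.

    Each column of ``values`` has mean 0 and sample standard deviation 1
    (n−1 denominator). ``mean`` and ``sd`` record the per-column statistics
    that were subtracted and divided out.
    """

    values: np.ndarray
    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)


# -- I/O ----------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def read_dataset(
    values_path: str | Path,
    meta_path: str | Path,
    *,
    drop_missing: bool = False,
) -> BehavioralDataset:
    """Read a behavioral dataset from a values table and a metadata table.

    The values file is CSV/TSV with first column ``rat_id``, second column
    ``group`` (NS/IS), optional column ``hn_label`` (H/NH), and remaining
    columns numeric behavioral variables. The metadata file has columns
    ``name,test,valence,units`` and must cover every variable column; file
    column order is authoritative.

    Parameters
    ----------
    drop_missing
        If True, rows containing missing values are dropped (the study
        excluded animals rather than imputing); if False such rows raise
        :class:`SchemaError`.
    """
    values_path, meta_path = Path(values_path), Path(meta_path)
    df = pd.read_csv(values_path, sep=_sep_for(values_path), dtype={0: str})
    if df.columns[0] != "rat_id" or df.columns[1] != "group":
        raise SchemaError(
            f"{values_path}: first two columns must be 'rat_id','group', "
            f"got {list(df.columns[:2])}"
        )
    hn = None
    if "hn_label" in df.columns:
        hn = df.pop("hn_label").to_numpy(dtype=object)
    var_cols = list(df.columns[2:])
    for c in var_cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            i = int(np.where(bad)[0][0])
            raise SchemaError(
                f"{values_path}: non-numeric value {df[c].iloc[i]!r} "
                f"in column {c!r}, row {df.iloc[i, 0]!r}"
            )
        df[c] = coerced

    mdf = pd.read_csv(meta_path, sep=_sep_for(meta_path))
    required = {"name", "test", "valence"}
    if not required.issubset(mdf.columns):
        raise SchemaError(f"{meta_path}: metadata must have columns {sorted(required)}")
    meta_by_name = {
        str(r["name"]): VariableMeta(
            name=str(r["name"]),
            test=str(r["test"]),
            valence=str(r["valence"]),
            units="" if "units" not in mdf.columns or pd.isna(r.get("units")) else str(r["units"]),
        )
        for _, r in mdf.iterrows()
    }
    missing = [c for c in var_cols if c not in meta_by_name]
    if missing:
        raise SchemaError(f"{meta_path}: no metadata for variables {missing}")

    values = df[var_cols].to_numpy(dtype=float)
    keep = ~np.isnan(values).any(axis=1)
    if drop_missing and not keep.all():
        df = df.loc[keep]
        values = values[keep]
        hn = None if hn is None else hn[keep.to_numpy() if hasattr(keep, "to_numpy") else keep]
    return BehavioralDataset(
        values=values,
        rat_ids=df.iloc[:, 0].astype(str).tolist(),
        group=df.iloc[:, 1].to_numpy(dtype=object),
        meta=[meta_by_name[c] for c in var_cols],
        hn_label=hn,
    )


def write_dataset(
    dataset: BehavioralDataset,
    values_path: str | Path,
    meta_path: str | Path,
) -> None:
    """Write the dataset as a values table and a metadata table (CSV/TSV)."""
    values_path, meta_path = Path(values_path), Path(meta_path)
    df = dataset.to_frame().reset_index()
    if dataset.hn_label is not None:
        df.insert(2, "hn_label", dataset.hn_label)
    df.to_csv(values_path, sep=_sep_for(values_path), index=False)
    dataset.meta_frame().to_csv(meta_path, sep=_sep_for(meta_path), index=False)


# -- Z-scoring ----------------------------------------------------------------


def zscore(data: "BehavioralDataset | ZScoredMatrix | np.ndarray | pd.DataFrame") -> ZScoredMatrix:
    """Column-wise Z-score a rats × variables matrix, pooled over both groups.

    Each variable is standardized by subtracting its mean across all rats and
    dividing by the sample standard deviation (n−1 denominator). Constant
    columns make standardization undefined and raise
    :class:`DegenerateDataError` naming the offenders.
    """
    if isinstance(data, BehavioralDataset):
        X, cols = data.values, data.variable_names
    elif isinstance(data, ZScoredMatrix):
        X, cols = data.values, data.columns
    elif isinstance(data, pd.DataFrame):
        X, cols = data.to_numpy(dtype=float), [str(c) for c in data.columns]
    else:
        X = np.asarray(data, dtype=float)
        cols = [f"var{j}" for j in range(X.shape[1])]
    if X.shape[0] < 2:
        raise DegenerateDataError("need at least 2 rows to standardize")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = np.where(sd == 0)[0]
    if constant.size:
        raise DegenerateDataError(
            f"constant columns cannot be Z-scored: {[cols[j] for j in constant]}"
        )
    return ZScoredMatrix(values=(X - mean) / sd, columns=list(cols), mean=mean, sd=sd)


# -- derived behavioral indices ----------------------------------------------


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"denominator {name} must be > 0, got {value}")


def sucrose_preference(si: float, wi: float) -> float:
    """Daily sucrose preference %, (SI/(SI+WI))·100."""
    _require_positive("SI+WI", si + wi)
    return si / (si + wi) * 100.0


def discrimination_index(tn: float, tf: float) -> float:
    """New-object discrimination index, TN/(TF+TN)."""
    _require_positive("TF+TN", tf + tn)
    return tn / (tf + tn)


def social_preference_ratio(oc: float, ec: float) -> float:
    """Social preference ratio, OC/EC (occupied over empty cage time)."""
    _require_positive("EC", ec)
    return oc / ec


def habituation_pct(hab0: float, hab1: float) -> float:
    """Startle habituation %, 100 − 100·(HAB1/HAB0)."""
    _require_positive("HAB0", hab0)
    return 100.0 - 100.0 * (hab1 / hab0)


def ppi_pct(pp_plus_p: float, p: float) -> float:
    """Prepulse inhibition %, 100 − ((PP+P)/P)·100.

    ``pp_plus_p`` is the startle amplitude on prepulse+pulse trials and ``p``
    the amplitude on pulse-only trials; equal amplitudes give 0% inhibition.
    """
    _require_positive("P", p)
    return 100.0 - (pp_plus_p / p) * 100.0


_INDEX_RECIPES: Mapping[str, tuple[str, ...]] = {
    "sucrose_preference_pct": ("SI", "WI"),
    "discrimination_index": ("TN", "TF"),
    "social_preference_ratio": ("OC", "EC"),
    "habituation_pct": ("HAB0", "HAB1"),
    "ppi_pct": ("PPplusP", "P"),
}

_INDEX_FUNCS = {
    "sucrose_preference_pct": sucrose_preference,
    "discrimination_index": discrimination_index,
    "social_preference_ratio": social_preference_ratio,
    "habituation_pct": lambda hab0, hab1: habituation_pct(hab0, hab1),
    "ppi_pct": lambda pp, p: ppi_pct(pp, p),
}


def derive_test_indices(raw: RawTestIndices) -> dict[str, float]:
    """Compute every derived index whose raw inputs are present.

    Returns a dict with any of: ``sucrose_preference_pct``,
    ``discrimination_index``, ``social_preference_ratio``,
    ``habituation_pct``, ``ppi_pct``. Negative raw quantities and zero
    denominators raise :class:`ValueError`.
    """
    for f in raw.__dataclass_fields__:
        v = getattr(raw, f)
        if v is not None and v < 0:
            raise ValueError(f"raw quantity {f} must be non-negative, got {v}")
    out: dict[str, float] = {}
    for index_name, fields in _INDEX_RECIPES.items():
        args = [getattr(raw, f) for f in fields]
        if all(a is not None for a in args):
            out[index_name] = _INDEX_FUNCS[index_name](*args)
    return out
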