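"""Trait table loading, cleaning, and quantile discretization into items.

Continuous traits are cut into ordered levels (quintiles by default) and each
individual becomes a transaction of items like ``TG5`` (highest fifth of TG)
or ``LDL1`` (lowest fifth of LDL).  Nominal traits contribute one item per
observed category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TraitTable",
    "DiscretizationScheme",
    "ItemizedDataset",
    "load_trait_table",
    "filter_individuals_missing",
    "drop_traits",
    "fit_quantile_scheme",
    "itemize",
    "write_transactions",
    "read_transactions",
    "write_trait_table",
]


@dataclass
class TraitTable:
    """Individual-by-trait table with optional covariate columns.

    ``values`` holds the trait matrix (individuals on the index, one column
    per trait); continuous traits are float columns with NaN marking missing
    cells, nominal traits are object/string columns with None for missing.
    ``covariates`` carries columns such as cohort/area/sex that are kept for
    stratification but never discretized.
    """

    values: pd.DataFrame
    nominal: frozenset[str] = frozenset()
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate individual id {dup!r}")
        if self.values.shape[1] < 1:
            raise ValueError("trait table needs at least one trait")
        unknown = set(self.nominal) - set(self.values.columns)
        if unknown:
            raise ValueError(f"nominal traits not in table: {sorted(unknown)}")

    @property
    def individual_ids(self) -> pd.Index:
        return self.values.index

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_individuals(self) -> int:
        return len(self.values)

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def continuous_traits(self) -> list[str]:
        return [t for t in self.values.columns if t not in self.nominal]

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()


@dataclass
class DiscretizationScheme:
    """Per-trait cut points mapping continuous values to ordered levels.

    A trait with cuts ``c1 < ... < c(k-1)`` maps value ``v`` to level
    ``1 + #(cuts strictly below v)``; a value equal to a cut goes to the
    lower level.  Nominal traits are listed in ``nominal_levels`` with their
    category vocabulary instead of cuts.
    """

    n_levels: int
    cuts: dict[str, np.ndarray]
    method: str = "quantile"
    nominal_levels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for trait, c in self.cuts.items():
            c = np.asarray(c, dtype=float)
            if len(c) != self.n_levels - 1:
                raise ValueError(f"{trait}: expected {self.n_levels - 1} cuts, got {len(c)}")
            if not np.all(np.diff(c) > 0):
                raise ValueError(f"{trait}: cut points must be strictly increasing")
            self.cuts[trait] = c

    def level_of(self, trait: str, value: float) -> int:
        """1-based level for a continuous value (ties go to the lower level)."""
        return 1 + int(np.searchsorted(self.cuts[trait], value, side="left"))

    def to_yaml(self, path) -> None:
        doc = {
            "n_levels": self.n_levels,
            "method": self.method,
            "cuts": {t: [float(x) for x in c] for t, c in self.cuts.items()},
            "nominal_levels": {t: list(v) for t, v in self.nominal_levels.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "DiscretizationScheme":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            n_levels=int(doc["n_levels"]),
            cuts={t: np.asarray(c, dtype=float) for t, c in doc["cuts"].items()},
            method=doc.get("method", "quantile"),
            nominal_levels={t: list(v) for t, v in doc.get("nominal_levels", {}).items()},
        )


@dataclass
class ItemizedDataset:
    """Individuals encoded as transactions of trait-level items."""

    items: list[str]
    transactions: list[frozenset[str]]
    ids: list[str]

    def __post_init__(self) -> None:
        vocab = set(self.items)
        for i, t in enumerate(self.transactions):
            extra = t - vocab
            if extra:
                raise ValueError(f"transaction {i} has items outside vocabulary: {sorted(extra)}")

    @property
    def n_transactions(self) -> int:
        return len(self.transactions)


def load_trait_table(
    path,
    missing_marker: str = "NA",
    nominal: Iterable[str] = (),
    covariate_columns: Iterable[str] = (),
) -> TraitTable:
    """Read a tab-delimited trait table (header row, first column = individual id).

    Columns named in ``nominal`` keep their string categories; columns named
    in ``covariate_columns`` are split off as covariates.  Every other column
    must parse as a float or equal ``missing_marker``.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if raw.shape[1] < 2:
        raise ValueError("expected an id column plus at least one trait column")
    id_col = raw.columns[0]
    ids = raw[id_col]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate individual id {dup!r}")
    body = raw.drop(columns=[id_col])
    body.index = pd.Index(ids, name=id_col)

    nominal = frozenset(nominal)
    covariate_columns = list(covariate_columns)
    missing = set(covariate_columns) - set(body.columns)
    if missing:
        raise ValueError(f"covariate columns not found: {sorted(missing)}")
    cov = body[covariate_columns] if covariate_columns else None
    body = body.drop(columns=covariate_columns)

    parsed: dict[str, pd.Series] = {}
    for col in body.columns:
        s = body[col]
        s = s.where(s != missing_marker, other=pd.NA)
        if col in nominal:
            parsed[col] = s.astype(object)
        else:
            try:
                parsed[col] = pd.to_numeric(s, errors="raise").astype(float)
            except (ValueError, TypeError):
                bad = s[pd.to_numeric(s, errors="coerce").isna() & s.notna()]
                row = bad.index[0]
                raise ValueError(
                    f"non-numeric value {bad.iloc[0]!r} in continuous trait "
                    f"{col!r} for individual {row!r}"
                ) from None
    values = pd.DataFrame(parsed, index=body.index)
    return TraitTable(values=values, nominal=nominal & set(values.columns), covariates=cov)


def filter_individuals_missing(table: TraitTable) -> TraitTable:
    """Keep only individuals with no missing trait value."""
    keep = ~table.missing_mask().any(axis=1)
    if not keep.any():
        raise ValueError("all individuals have at least one missing trait value")
    values = table.values.loc[keep]
    cov = table.covariates.loc[keep] if table.covariates is not None else None
    return TraitTable(values=values, nominal=table.nominal, covariates=cov)


def drop_traits(table: TraitTable, names: Sequence[str]) -> TraitTable:
    """Remove the named traits, preserving the order of the rest."""
    names = list(names)
    unknown = [n for n in names if n not in table.values.columns]
    if unknown:
        raise KeyError(f"unknown trait name(s): {unknown}")
    if not names:
        return table
    values = table.values.drop(columns=names)
    return TraitTable(
        values=values,
        nominal=table.nominal & set(values.columns),
        covariates=table.covariates,
    )


def fit_quantile_scheme(table: TraitTable, n_levels: int = 5) -> DiscretizationScheme:
    """Fit per-trait cut points at empirical quantiles k/n_levels.

    Raises for constant traits or traits with fewer distinct values than
    levels — such traits cannot support the requested resolution.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    qs = np.arange(1, n_levels) / n_levels
    cuts: dict[str, np.ndarray] = {}
    for trait in table.continuous_traits():
        v = table.values[trait].dropna().to_numpy(dtype=float)
        distinct = np.unique(v)
        if distinct.size <= 1:
            raise ValueError(f"trait {trait!r} is constant; cannot discretize")
        if distinct.size < n_levels:
            raise ValueError(
                f"trait {trait!r} has {distinct.size} distinct values; need >= {n_levels}"
            )
        c = np.quantile(v, qs)
        if not np.all(np.diff(c) > 0):
            # heavy ties: nudge duplicated cuts apart is wrong; refuse instead
            raise ValueError(f"trait {trait!r}: quantile cuts not strictly increasing (heavy ties)")
        cuts[trait] = c
    nominal_levels = {
        t: sorted(str(x) for x in table.values[t].dropna().unique()) for t in table.nominal
    }
    return DiscretizationScheme(n_levels=n_levels, cuts=cuts, nominal_levels=nominal_levels)


def item_name(trait: str, level) -> str:
    return f"{trait}{level}"


def itemize(table: TraitTable, scheme: DiscretizationScheme) -> ItemizedDataset:
    """Turn each individual into a transaction of trait-level items.

    A missing cell contributes no item, so transactions may be shorter than
    the trait count.  Continuous traits use the scheme's cuts (value equal to
    a cut goes to the lower level); nominal traits use their category as the
    level suffix.
    """
    missing_cont = [t for t in table.continuous_traits() if t not in scheme.cuts]
    if missing_cont:
        raise KeyError(f"scheme has no cuts for trait(s): {missing_cont}")

    n = table.n_individuals
    txn_items: list[list[str]] = [[] for _ in range(n)]
    for trait in table.trait_names:
        col = table.values[trait]
        if trait in table.nominal:
            for i, v in enumerate(col):
                if pd.notna(v):
                    txn_items[i].append(item_name(trait, v))
        else:
            vals = col.to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            levels = 1 + np.searchsorted(scheme.cuts[trait], vals[ok], side="left")
            for i, lev in zip(np.flatnonzero(ok), levels):
                txn_items[i].append(item_name(trait, lev))

    vocab: set[str] = set()
    transactions = []
    for items in txn_items:
        s = frozenset(items)
        vocab |= s
        transactions.append(s)
    return ItemizedDataset(
        items=sorted(vocab),
        transactions=transactions,
        ids=[str(i) for i in table.individual_ids],
    )


def write_transactions(data: ItemizedDataset, path, header: str | None = None) -> None:
    """One line per individual: space-separated item tokens, sorted."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for txn in data.transactions:
            fh.write(" ".join(sorted(txn)) + "\n")


def write_trait_table(table: TraitTable, path, missing_marker: str = "NA") -> None:
    """TSV inverse of load_trait_table: id column, traits, then covariates."""
    out = table.values.copy()
    if table.covariates is not None:
        for col in table.covariates.columns:
            out[col] = table.covariates[col]
    out.index.name = out.index.name or "IID"
    out.to_csv(path, sep="\t", na_rep=missing_marker)


def read_transactions(path) -> ItemizedDataset:
    transactions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            transactions.append(frozenset(line.split()))
    vocab = sorted(set().union(*transactions)) if transactions else []
    return ItemizedDataset(
        items=vocab, transactions=transactions, ids=[str(i) for i in range(len(transactions))]
    )
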