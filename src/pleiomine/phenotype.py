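"""Case/control phenotype construction from rule-derived trait patterns.

A multivariate phenotype is a conjunction of predicates over single traits
(e.g. case: LDL >= 130 AND TG >= 180; control: LDL <= 100 AND TG <= 100).
Individuals failing both predicate sets are excluded rather than treated as
controls, so assigned samples are well-separated on every constituent trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .arm import AssociationRule
from .traits import TraitTable

__all__ = [
    "PhenotypePredicate",
    "PhenotypeDefinition",
    "CaseControlAssignment",
    "derive_definition",
    "assign",
    "summarize",
    "sex_by_status_test",
    "write_plink_phenotype",
]

_OPS = {"ge", "le", "in"}


@dataclass(frozen=True)
class PhenotypePredicate:
    """Single-trait predicate: trait >= v, trait <= v, or level-set membership."""

    trait: str
    op: str
    value: float | frozenset[int]

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"op must be one of {sorted(_OPS)}, got {self.op!r}")
        if self.op == "in":
            levels = frozenset(self.value)
            if not levels:
                raise ValueError("level set must be non-empty")
            object.__setattr__(self, "value", levels)
        else:
            v = float(self.value)
            if not np.isfinite(v):
                raise ValueError("threshold must be finite")
            object.__setattr__(self, "value", v)

    def evaluate(self, values: pd.Series, levels: pd.Series | None = None) -> pd.Series:
        """Boolean mask over individuals; missing values evaluate False."""
        if self.op == "ge":
            return values >= self.value
        if self.op == "le":
            return values <= self.value
        if levels is None:
            raise ValueError(f"level-set predicate on {self.trait!r} needs discretized levels")
        return levels.isin(self.value)

    def describe(self) -> str:
        if self.op == "in":
            return f"{self.trait} in {{{','.join(map(str, sorted(self.value)))}}}"
        sym = ">=" if self.op == "ge" else "<="
        return f"{self.trait} {sym} {self.value:g}"


@dataclass
class PhenotypeDefinition:
    """Named case/control design: conjunctions of predicates on single traits."""

    name: str
    case: tuple[PhenotypePredicate, ...]
    control: tuple[PhenotypePredicate, ...]

    def __post_init__(self) -> None:
        self.case = tuple(self.case)
        self.control = tuple(self.control)
        if not self.case or not self.control:
            raise ValueError("both case and control predicate sets must be non-empty")

    @property
    def traits(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.case + self.control:
            seen.setdefault(p.trait, None)
        return list(seen)

    def project(self, trait: str) -> "PhenotypeDefinition":
        """Single-trait design keeping only this trait's predicates."""
        case = tuple(p for p in self.case if p.trait == trait)
        control = tuple(p for p in self.control if p.trait == trait)
        if not case or not control:
            raise KeyError(f"trait {trait!r} absent from case or control predicates")
        return PhenotypeDefinition(name=f"high{trait}", case=case, control=control)

    def to_yaml(self, path) -> None:
        def enc(p: PhenotypePredicate):
            value = sorted(p.value) if p.op == "in" else p.value
            return {"trait": p.trait, "op": p.op, "value": value}

        doc = {
            "name": self.name,
            "case": [enc(p) for p in self.case],
            "control": [enc(p) for p in self.control],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhenotypeDefinition":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "PhenotypeDefinition":
        def dec(d) -> PhenotypePredicate:
            return PhenotypePredicate(trait=d["trait"], op=d["op"], value=d["value"])

        return cls(
            name=doc["name"],
            case=tuple(dec(d) for d in doc["case"]),
            control=tuple(dec(d) for d in doc["control"]),
        )


@dataclass
class CaseControlAssignment:
    """Per-individual status plus retained covariates for stratification."""

    name: str
    status: pd.Series  # values: 'case' | 'control' | 'excluded'
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        bad = set(self.status.unique()) - {"case", "control", "excluded"}
        if bad:
            raise ValueError(f"illegal status values: {sorted(bad)}")

    @property
    def n_cases(self) -> int:
        return int((self.status == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == "control").sum())

    @property
    def n_excluded(self) -> int:
        return int((self.status == "excluded").sum())

    def ids(self, which: str) -> pd.Index:
        return self.status.index[self.status == which]


def _item_level(item: str, trait: str) -> int | None:
    """Level of ``item`` if it encodes ``trait`` (prefix + integer level)."""
    if item.startswith(trait) and item[len(trait) :].isdigit():
        return int(item[len(trait) :])
    return None


def derive_definition(
    rules: Iterable[AssociationRule],
    traits: tuple[str, str],
    overrides: Mapping[str, Mapping[str, tuple[str, float]]] | None = None,
    n_levels: int = 5,
    name: str | None = None,
) -> PhenotypeDefinition:
    """Build a two-trait case/control design from mined rules.

    For each trait the highest level appearing in any rule becomes the case
    level; the control level is its mirror image (level ``n_levels + 1 - k``).
    Clinical ``overrides`` replace level membership with explicit thresholds,
    e.g. ``{"LDL": {"case": (">=", 130), "control": ("<=", 100)}}``.
    """
    rules = list(rules)
    level_seen: dict[str, set[int]] = {t: set() for t in traits}
    for rule in rules:
        for item in rule.items:
            for trait in traits:
                lev = _item_level(item, trait)
                if lev is not None:
                    level_seen[trait].add(lev)
    missing = [t for t in traits if not level_seen[t]]
    if missing:
        raise KeyError(f"trait(s) {missing} never appear in the rule set")

    op_map = {">=": "ge", "<=": "le", "ge": "ge", "le": "le"}
    overrides = overrides or {}
    case_preds, control_preds = [], []
    for trait in traits:
        if trait in overrides:
            ov = overrides[trait]
            cop, cval = ov["case"]
            kop, kval = ov["control"]
            case_preds.append(PhenotypePredicate(trait, op_map[cop], cval))
            control_preds.append(PhenotypePredicate(trait, op_map[kop], kval))
        else:
            case_level = max(level_seen[trait])
            control_level = n_levels + 1 - case_level
            case_preds.append(PhenotypePredicate(trait, "in", frozenset({case_level})))
            control_preds.append(PhenotypePredicate(trait, "in", frozenset({control_level})))
    return PhenotypeDefinition(
        name=name or "high" + "high".join(traits),
        case=tuple(case_preds),
        control=tuple(control_preds),
    )


def assign(
    table: TraitTable,
    defn: PhenotypeDefinition,
    levels: pd.DataFrame | None = None,
) -> CaseControlAssignment:
    """Label each individual case/control/excluded under the definition.

    ``levels`` (individuals x traits, integer level codes) is only needed
    when the definition uses level-set predicates.
    """
    missing = [t for t in defn.traits if t not in table.values.columns]
    if missing:
        raise KeyError(f"definition traits absent from table: {missing}")

    def conj(preds: Sequence[PhenotypePredicate]) -> pd.Series:
        mask = pd.Series(True, index=table.individual_ids)
        for p in preds:
            lev = levels[p.trait] if (levels is not None and p.trait in levels) else None
            mask &= p.evaluate(table.values[p.trait], lev).fillna(False)
        return mask

    is_case = conj(defn.case)
    is_control = conj(defn.control)
    both = is_case & is_control
    if both.any():
        first = both.index[both][0]
        raise ValueError(
            f"case and control predicates overlap: individual {first!r} satisfies both"
        )
    status = pd.Series("excluded", index=table.individual_ids, name=defn.name)
    status[is_case] = "case"
    status[is_control] = "control"
    assignment = CaseControlAssignment(name=defn.name, status=status, covariates=table.covariates)
    if assignment.n_cases == 0:
        raise ValueError("phenotype definition yields zero cases")
    if assignment.n_controls == 0:
        raise ValueError("phenotype definition yields zero controls")
    return assignment


def summarize(
    assignment: CaseControlAssignment,
    table: TraitTable,
    covariates: Sequence[str],
    traits: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-stratum descriptive table: n, mean, SD for each trait.

    Strata are (status, covariate value) cells for each requested covariate
    column.  A single-individual stratum reports SD 0 with ``degenerate``
    flagged; an empty stratum reports n=0 and no statistics.
    """
    if assignment.covariates is None:
        raise ValueError("assignment carries no covariates")
    unknown = [c for c in covariates if c not in assignment.covariates.columns]
    if unknown:
        raise KeyError(f"covariates not retained in assignment: {unknown}")
    traits = list(traits) if traits is not None else table.continuous_traits()

    rows = []
    for status in ("control", "case"):
        in_status = assignment.status == status
        for cov in covariates:
            col = assignment.covariates[cov]
            for value in sorted(col.dropna().unique(), key=str):
                sel = in_status & (col == value)
                sub = table.values.loc[sel.index[sel]]
                for trait in traits:
                    v = sub[trait].dropna() if len(sub) else pd.Series(dtype=float)
                    n = len(v)
                    rows.append(
                        {
                            "status": status,
                            "covariate": cov,
                            "stratum": value,
                            "trait": trait,
                            "n": n,
                            "mean": float(v.mean()) if n else np.nan,
                            "sd": (float(v.std(ddof=1)) if n > 1 else (0.0 if n == 1 else np.nan)),
                            "degenerate": n == 1,
                        }
                    )
    return pd.DataFrame(rows)


def sex_by_status_test(
    assignment: CaseControlAssignment, sex_column: str = "SEX"
) -> dict[str, float]:
    """2x2 chi-square of sex x case/control status.

    Returns both the continuity-corrected statistic (``chi2``) and the
    uncorrected one (``chi2_uncorrected``), each with its p-value; df is 1.
    """
    if assignment.covariates is None or sex_column not in assignment.covariates.columns:
        raise KeyError(f"covariate {sex_column!r} not available")
    keep = assignment.status != "excluded"
    tab = pd.crosstab(
        assignment.status[keep], assignment.covariates.loc[keep.index[keep], sex_column]
    )
    if tab.shape != (2, 2):
        raise ValueError(f"need a 2x2 sex-by-status table, got shape {tab.shape}")
    counts = tab.to_numpy()
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in sex-by-status table")
    corr = stats.chi2_contingency(counts, correction=True)
    unc = stats.chi2_contingency(counts, correction=False)
    return {
        "chi2": float(corr.statistic),
        "p": float(corr.pvalue),
        "chi2_uncorrected": float(unc.statistic),
        "p_uncorrected": float(unc.pvalue),
        "df": 1,
    }


def write_plink_phenotype(assignment: CaseControlAssignment, path) -> None:
    """FID IID PHENO rows: 2=case, 1=control, -9=excluded."""
    code = {"case": 2, "control": 1, "excluded": -9}
    with open(path, "w") as fh:
        for iid, status in assignment.status.items():
            fh.write(f"{iid}\t{iid}\t{code[status]}\n")
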