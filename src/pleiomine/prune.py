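"""Pleiotropy-oriented SNP pruning: mOR statistic, LD clumping, filters.

A SNP associated with a two-trait composite phenotype survives only if

(1) its composite-phenotype p-value is small enough (default <= 5e-4),
(2) the composite signal is at least 10x stronger than each single-trait
    signal (mOR >= 1 against both traits), and
(3) it sits in a linkage-disequilibrium clump anchored by a strong index
    SNP (index p <= 1e-5, member p <= 1e-4).

mOR(p_multi, p_single) = log10(p_single) - log10(p_multi): a value of 1
means the SNP is ten times as likely under the composite phenotype as under
the single trait.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import MISSING, GenotypeMatrix, _chrom_key

__all__ = [
    "ClumpSpec",
    "PrunedSet",
    "compute_mor",
    "mor_table",
    "pairwise_r2",
    "greedy_clump",
    "prune",
]

P_FLOOR = 1e-300  # guards log10 against numerical underflow to 0


@dataclass
class ClumpSpec:
    """Greedy LD-clumping parameters (PLINK-style defaults)."""

    p_index: float = 1e-5
    p_clumped: float = 1e-4
    r2_threshold: float = 0.5
    window_kb: int = 250

    def __post_init__(self) -> None:
        if not 0 < self.p_index <= self.p_clumped <= 1:
            raise ValueError("need 0 < p_index <= p_clumped <= 1")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


@dataclass
class PrunedSet:
    """Survivors plus a per-SNP audit of which filter removed what.

    ``audit`` has one row per input SNP with ``filter_status`` in
    {pass, fail_p_multi, fail_mor, fail_clump} naming the first failing
    condition.  ``clumps`` maps each index SNP to its member list.
    """

    survivors: list[str]
    audit: pd.DataFrame
    clumps: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.survivors) - set(self.audit["snp"]):
            raise ValueError("survivors must be a subset of audited SNPs")
        if self.audit["snp"].duplicated().any():
            raise ValueError("audit must cover every SNP exactly once")


def compute_mor(p_multi: float, p_single: float) -> float:
    """log10(p_single / p_multi); >= 1 iff p_single >= 10 * p_multi."""
    if not (0 < p_multi <= 1) or not (0 < p_single <= 1):
        raise ValueError(f"p-values must be in (0, 1], got ({p_multi}, {p_single})")
    p_multi = max(p_multi, P_FLOOR)
    p_single = max(p_single, P_FLOOR)
    return math.log10(p_single) - math.log10(p_multi)


def mor_table(
    multi: pd.DataFrame, single_i: pd.DataFrame, single_j: pd.DataFrame
) -> pd.DataFrame:
    """Join three scans on SNP id and compute both mOR columns.

    SNPs absent from any scan are dropped with a warning.  Output columns:
    snp, chrom, pos, p_multi, p_single_i, p_single_j, mor_i, mor_j.
    """
    frames = {"multi": multi, "single_i": single_i, "single_j": single_j}
    sets = {k: set(f["SNP"]) for k, f in frames.items()}
    common = sets["multi"] & sets["single_i"] & sets["single_j"]
    if not common:
        raise ValueError("no SNPs shared by all three scans")
    dropped = set().union(*sets.values()) - common
    if dropped:
        warnings.warn(f"{len(dropped)} SNP(s) missing from at least one scan; dropped", stacklevel=2)

    m = multi[multi["SNP"].isin(common)][["SNP", "CHR", "BP", "P", "OR"]].rename(
        columns={"SNP": "snp", "CHR": "chrom", "BP": "pos", "P": "p_multi", "OR": "or_multi"}
    )
    si = single_i[single_i["SNP"].isin(common)][["SNP", "P"]].rename(
        columns={"SNP": "snp", "P": "p_single_i"}
    )
    sj = single_j[single_j["SNP"].isin(common)][["SNP", "P"]].rename(
        columns={"SNP": "snp", "P": "p_single_j"}
    )
    out = m.merge(si, on="snp").merge(sj, on="snp")
    out["mor_i"] = [compute_mor(pm, ps) for pm, ps in zip(out["p_multi"], out["p_single_i"])]
    out["mor_j"] = [compute_mor(pm, ps) for pm, ps in zip(out["p_multi"], out["p_single_j"])]
    return out.reset_index(drop=True)


def pairwise_r2(gm: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of allele dosages (pairwise-complete).

    Returns nan when either SNP is monomorphic in the pairwise-complete
    subset; clumping treats that as 0.
    """
    da = gm.dosages(snp_a).astype(float)
    db = gm.dosages(snp_b).astype(float)
    ok = (da != MISSING) & (db != MISSING)
    if ok.sum() < 2:
        raise ValueError("need >= 2 individuals non-missing at both SNPs")
    da, db = da[ok], db[ok]
    va, vb = da.var(), db.var()
    if va == 0 or vb == 0:
        return float("nan")
    r = np.corrcoef(da, db)[0, 1]
    return float(r * r)


def _r2_matrix(gm: GenotypeMatrix, cols: list[int]) -> np.ndarray:
    """Pairwise dosage r² among the given variant columns (missing -> nan)."""
    g = gm.genotypes[:, cols].astype(float)
    g[g == MISSING] = np.nan
    k = len(cols)
    out = np.full((k, k), np.nan)
    for i in range(k):
        out[i, i] = 1.0
        for j in range(i + 1, k):
            ok = ~np.isnan(g[:, i]) & ~np.isnan(g[:, j])
            if ok.sum() < 2:
                continue
            a, b = g[ok, i], g[ok, j]
            if a.var() == 0 or b.var() == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            r = np.corrcoef(a, b)[0, 1]
            out[i, j] = out[j, i] = r * r
    return out


def greedy_clump(
    results: pd.DataFrame, gm: GenotypeMatrix, spec: ClumpSpec | None = None
) -> pd.DataFrame:
    """PLINK-style greedy clumping of an association scan.

    SNPs with p <= p_index are visited in ascending p (ties broken by
    chromosome then position); each still-unclaimed one founds a clump and
    claims every unclaimed SNP with p <= p_clumped on the same chromosome
    within window_kb and with dosage r² >= r2_threshold.

    Returns a frame with columns snp, clump_index (the founding SNP, or ''
    for SNPs in no clump), r2_to_index, is_index.
    """
    spec = spec or ClumpSpec()
    df = results.reset_index(drop=True)
    col_of = {s: j for j, s in enumerate(gm.variants["snp"])}
    try:
        snp_col = {s: col_of[s] for s in df["SNP"]}
    except KeyError as e:
        raise KeyError(f"variant {e.args[0]!r} not found") from None

    order = sorted(
        df.index[df["P"] <= spec.p_index],
        key=lambda i: (df["P"].iloc[i], _chrom_key(df["CHR"].iloc[i]), df["BP"].iloc[i]),
    )
    claimed: dict[int, tuple[str, float]] = {}  # row -> (index snp, r2)
    clump_index: dict[int, str] = {}
    window = spec.window_kb * 1000

    eligible = df.index[df["P"] <= spec.p_clumped]
    for i in order:
        if i in claimed:
            continue
        index_snp = df["SNP"].iloc[i]
        claimed[i] = (index_snp, 1.0)
        clump_index[i] = index_snp
        chrom, pos = df["CHR"].iloc[i], df["BP"].iloc[i]
        near = [
            j
            for j in eligible
            if j != i
            and j not in claimed
            and df["CHR"].iloc[j] == chrom
            and abs(int(df["BP"].iloc[j]) - int(pos)) <= window
        ]
        if not near:
            continue
        cols = [snp_col[index_snp]] + [snp_col[df["SNP"].iloc[j]] for j in near]
        r2 = _r2_matrix(gm, cols)[0, 1:]
        for j, r in zip(near, r2):
            if not np.isnan(r) and r >= spec.r2_threshold:
                claimed[j] = (index_snp, float(r))

    rows = []
    for i in df.index:
        if i in claimed:
            idx_snp, r2 = claimed[i]
            rows.append(
                {
                    "snp": df["SNP"].iloc[i],
                    "clump_index": idx_snp,
                    "r2_to_index": r2,
                    "is_index": i in clump_index,
                }
            )
        else:
            rows.append(
                {"snp": df["SNP"].iloc[i], "clump_index": "", "r2_to_index": np.nan, "is_index": False}
            )
    return pd.DataFrame(rows)


def prune(
    mor: pd.DataFrame,
    clumps: pd.DataFrame,
    p_multi_max: float = 5e-4,
    mor_min: float = 1.0,
    clump_rule: str = "member",
    clump_spec: ClumpSpec | None = None,
) -> PrunedSet:
    """Apply the three pruning conditions and intersect the mOR filters.

    Condition order for the audit: composite-p threshold, then both mOR
    thresholds simultaneously (the intersection of the two single-trait
    filtered sets), then the LD-clump condition.  ``clump_rule`` selects how
    the clump condition is read: "member" keeps any SNP belonging to a clump
    whose index meets p_index (the SNP itself must meet p_clumped, which
    greedy_clump already enforces); "index" keeps only index SNPs.
    """
    if clump_rule not in ("member", "index"):
        raise ValueError("clump_rule must be 'member' or 'index'")
    spec = clump_spec or ClumpSpec()
    joined = mor.merge(clumps, on="snp", how="left")
    ci = joined["clump_index"]
    joined["clump_index"] = ci.where(ci.notna(), "").astype(str)
    ii = joined["is_index"]
    joined["is_index"] = ii.where(ii.notna(), False).astype(bool)

    statuses = []
    for _, r in joined.iterrows():
        if r["p_multi"] > p_multi_max:
            statuses.append("fail_p_multi")
        elif not (r["mor_i"] >= mor_min and r["mor_j"] >= mor_min):
            statuses.append("fail_mor")
        else:
            in_clump = bool(r["clump_index"])
            ok = bool(r["is_index"]) if clump_rule == "index" else in_clump
            statuses.append("pass" if ok else "fail_clump")
    joined["filter_status"] = statuses
    survivors = list(joined.loc[joined["filter_status"] == "pass", "snp"])

    membership: dict[str, list[str]] = {}
    for _, r in clumps.iterrows():
        if r["clump_index"]:
            membership.setdefault(r["clump_index"], []).append(r["snp"])
    return PrunedSet(survivors=survivors, audit=joined, clumps=membership)


def write_pruned(pruned: PrunedSet, path, header: str | None = None) -> None:
    """Audit TSV: one row per SNP with p, OR, mOR columns and filter status."""
    cols = [
        "snp",
        "chrom",
        "pos",
        "p_multi",
        "or_multi",
        "mor_i",
        "mor_j",
        "r2_to_index",
        "clump_index",
        "filter_status",
    ]
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("\t".join(cols) + "\n")
        for _, r in pruned.audit.iterrows():
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")
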