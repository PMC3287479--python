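"""Genotype I/O (PLINK text .ped/.map) and case-control allelic association.

The scan is the basic 1-df allelic chi-square on the 2x2 table of allele
counts in cases versus controls, reported with an odds ratio oriented to
allele1 (the data-determined minor allele).  No covariate adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phenotype import CaseControlAssignment

__all__ = [
    "GenotypeMatrix",
    "read_ped_map",
    "write_ped_map",
    "allelic_test",
    "genome_scan",
    "replicate_stratified",
    "export_manhattan",
]

MISSING = -1  # genotype code for missing


@dataclass
class GenotypeMatrix:
    """N samples x M variants of allele1-dosage codes {0, 1, 2, -1=missing}.

    ``variants`` columns: snp, chrom, pos (1-based), allele1, allele2 —
    allele1 is the minor allele as determined from the loaded data.
    """

    variants: pd.DataFrame
    genotypes: np.ndarray  # int8, shape (N, M)
    sample_ids: list[str]

    def __post_init__(self) -> None:
        need = {"snp", "chrom", "pos", "allele1", "allele2"}
        if not need <= set(self.variants.columns):
            raise ValueError(f"variants frame missing columns: {need - set(self.variants.columns)}")
        n, m = self.genotypes.shape
        if n != len(self.sample_ids):
            raise ValueError("genotype rows != sample ids")
        if m != len(self.variants):
            raise ValueError("genotype columns != variant rows")
        legal = (self.genotypes >= MISSING) & (self.genotypes <= 2)
        if not legal.all():
            bad = np.argwhere(~legal)[0]
            raise ValueError(f"illegal genotype code at sample {bad[0]}, variant {bad[1]}")
        same = self.variants["allele1"] == self.variants["allele2"]
        if same.any():
            raise ValueError(
                f"allele1 == allele2 for variant {self.variants.loc[same, 'snp'].iloc[0]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def variant_index(self, snp: str) -> int:
        idx = self.variants.index[self.variants["snp"] == snp]
        if len(idx) == 0:
            raise KeyError(f"variant {snp!r} not found")
        return int(idx[0])

    def dosages(self, snp: str) -> np.ndarray:
        return self.genotypes[:, self.variant_index(snp)]

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"sample ids not in genotype matrix: {missing[:5]}")
        rows = [pos[s] for s in ids]
        return GenotypeMatrix(
            variants=self.variants.copy(),
            genotypes=self.genotypes[rows, :],
            sample_ids=list(ids),
        )


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Load PLINK text pedigree + map files.

    Allele1 is set to the minor allele observed in the data (ties broken
    toward the alphabetically first allele); a "0 0" token pair is missing.
    """
    variants = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{map_path}: line {lineno}: expected 4 fields, got {len(parts)}")
            chrom, snp, _cm, pos = parts
            variants.append((snp, chrom, int(pos)))
    m = len(variants)

    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])
    n = len(sample_ids)

    alleles = np.array(allele_rows, dtype="U8").reshape(n, m, 2) if n else np.empty((0, m, 2), "U8")
    genotypes = np.empty((n, m), dtype=np.int8)
    var_records = []
    for j, (snp, chrom, pos) in enumerate(variants):
        a = alleles[:, j, :]
        observed = sorted(set(a.ravel()) - {"0"})
        if len(observed) > 2:
            raise ValueError(f"variant {snp!r} has more than two alleles: {observed}")
        if len(observed) == 0:
            raise ValueError(f"variant {snp!r} has no called genotypes")
        if len(observed) == 1:
            # monomorphic: invent a placeholder second allele so a1 != a2
            observed = observed + ["?"] if observed[0] != "?" else observed + ["!"]
        counts = {al: int((a == al).sum()) for al in observed}
        # minor allele first; ties toward the alphabetically first
        a1, a2 = sorted(observed, key=lambda al: (counts.get(al, 0), al))
        miss = (a[:, 0] == "0") | (a[:, 1] == "0")
        dos = (a == a1).sum(axis=1).astype(np.int8)
        dos[miss] = MISSING
        half = ((a[:, 0] == "0") != (a[:, 1] == "0"))
        if half.any():
            raise ValueError(f"variant {snp!r}: half-missing genotype (single '0' token)")
        genotypes[:, j] = dos
        var_records.append({"snp": snp, "chrom": chrom, "pos": pos, "allele1": a1, "allele2": a2})
    # keep positions non-decreasing within chromosome
    order = sorted(range(m), key=lambda j: (_chrom_key(var_records[j]["chrom"]), var_records[j]["pos"]))
    var_records = [var_records[j] for j in order]
    genotypes = genotypes[:, order]
    vf = pd.DataFrame(var_records, columns=["snp", "chrom", "pos", "allele1", "allele2"])
    return GenotypeMatrix(variants=vf, genotypes=genotypes, sample_ids=sample_ids)


def write_ped_map(gm: GenotypeMatrix, ped_path, map_path) -> None:
    with open(map_path, "w") as fh:
        for _, v in gm.variants.iterrows():
            fh.write(f"{v['chrom']}\t{v['snp']}\t0\t{v['pos']}\n")
    a1 = gm.variants["allele1"].to_numpy()
    a2 = gm.variants["allele2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            tokens = [sid, sid, "0", "0", "0", "-9"]
            row = gm.genotypes[i]
            for j, d in enumerate(row):
                if d == MISSING:
                    tokens += ["0", "0"]
                elif d == 0:
                    tokens += [a2[j], a2[j]]
                elif d == 1:
                    tokens += [a1[j], a2[j]]
                else:
                    tokens += [a1[j], a1[j]]
            fh.write(" ".join(tokens) + "\n")


def allelic_test(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """1-df allelic chi-square on the table [[a, b], [c, d]].

    Rows are cases/controls, columns allele1/allele2 counts.  No continuity
    correction.  The odds ratio is (a*d)/(b*c) with 0.5 added to every cell
    iff any cell is zero (Haldane-Anscombe); the correction never touches
    the chi-square.  A zero marginal yields (0.0, 1.0, nan).
    """
    tab = np.array([[a, b], [c, d]], dtype=float)
    total = tab.sum()
    if total <= 0:
        raise ValueError("allele table is empty")
    rows = tab.sum(axis=1)
    cols = tab.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return 0.0, 1.0, float("nan")
    expected = np.outer(rows, cols) / total
    chi2 = float(((tab - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    if (tab == 0).any():
        tab = tab + 0.5
    odds = float((tab[0, 0] * tab[1, 1]) / (tab[0, 1] * tab[1, 0]))
    return chi2, p, odds


def _allele_counts(
    gm: GenotypeMatrix, case_ids: Sequence[str], control_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-variant allele1/allele2 counts in cases and controls."""
    pos = {s: i for i, s in enumerate(gm.sample_ids)}
    case_rows = [pos[s] for s in case_ids if s in pos]
    control_rows = [pos[s] for s in control_ids if s in pos]
    if not case_rows and not control_rows:
        raise ValueError("no overlap between assignment and genotype samples")

    def counts(rows: list[int]) -> tuple[np.ndarray, np.ndarray]:
        g = gm.genotypes[rows, :].astype(np.int64)
        called = g != MISSING
        a1 = np.where(called, g, 0).sum(axis=0)
        a2 = 2 * called.sum(axis=0) - a1
        return a1, a2

    ca1, ca2 = counts(case_rows)
    ka1, ka2 = counts(control_rows)
    return ca1, ca2, ka1, ka2


def genome_scan(gm: GenotypeMatrix, assignment: CaseControlAssignment) -> pd.DataFrame:
    """Allelic association scan over every variant.

    Excluded individuals contribute nothing.  Returns one row per variant
    sorted by (chrom, pos) with PLINK-style columns: CHR SNP BP A1 F_A F_U
    A2 CHISQ P OR plus the raw 2x2 allele counts.
    """
    case_ids = [s for s in assignment.ids("case")]
    control_ids = [s for s in assignment.ids("control")]
    known = set(gm.sample_ids)
    if not (set(case_ids) | set(control_ids)) & known:
        raise ValueError("no overlap between assignment and genotype samples")
    ca1, ca2, ka1, ka2 = (
        x.astype(float) for x in _allele_counts(gm, case_ids, control_ids)
    )

    # vectorized 1-df chi-square mirroring allelic_test exactly
    tab = np.stack([ca1, ca2, ka1, ka2], axis=1)
    total = tab.sum(axis=1)
    row_case = ca1 + ca2
    row_control = ka1 + ka2
    col_a1 = ca1 + ka1
    col_a2 = ca2 + ka2
    degenerate = (row_case == 0) | (row_control == 0) | (col_a1 == 0) | (col_a2 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = (
            np.stack(
                [row_case * col_a1, row_case * col_a2, row_control * col_a1, row_control * col_a2],
                axis=1,
            )
            / total[:, None]
        )
        chi2 = ((tab - exp) ** 2 / exp).sum(axis=1)
    chi2 = np.where(degenerate, 0.0, chi2)
    p = np.where(degenerate, 1.0, stats.chi2.sf(chi2, df=1))
    haldane = tab + np.where((tab == 0).any(axis=1)[:, None], 0.5, 0.0)
    odds = (haldane[:, 0] * haldane[:, 3]) / (haldane[:, 1] * haldane[:, 2])
    odds = np.where(degenerate, np.nan, odds)

    with np.errstate(divide="ignore", invalid="ignore"):
        f_a = np.where(row_case > 0, ca1 / row_case, np.nan)
        f_u = np.where(row_control > 0, ka1 / row_control, np.nan)
    out = pd.DataFrame(
        {
            "CHR": gm.variants["chrom"].to_numpy(),
            "SNP": gm.variants["snp"].to_numpy(),
            "BP": gm.variants["pos"].astype(int).to_numpy(),
            "A1": gm.variants["allele1"].to_numpy(),
            "F_A": f_a,
            "F_U": f_u,
            "A2": gm.variants["allele2"].to_numpy(),
            "CHISQ": chi2,
            "P": p,
            "OR": odds,
            "C_A1": ca1.astype(int),
            "C_A2": ca2.astype(int),
            "K_A1": ka1.astype(int),
            "K_A2": ka2.astype(int),
        }
    )
    return _sort_by_position(out).reset_index(drop=True)


def _chrom_key(chrom: str):
    try:
        return (0, int(chrom), "")
    except (TypeError, ValueError):
        return (1, 0, str(chrom))


def _sort_by_position(df: pd.DataFrame) -> pd.DataFrame:
    key = df["CHR"].map(_chrom_key)
    order = sorted(range(len(df)), key=lambda i: (key.iloc[i], df["BP"].iloc[i]))
    return df.iloc[order]


def replicate_stratified(
    gm: GenotypeMatrix,
    assignment: CaseControlAssignment,
    stratum_column: str,
    snps: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Independent scans within each covariate stratum plus the combined set.

    Strata with fewer than 2 cases or 2 controls are skipped with a warning.
    ``snps`` optionally restricts the scan to a survivor list.
    """
    if assignment.covariates is None or stratum_column not in assignment.covariates.columns:
        raise KeyError(f"stratum covariate {stratum_column!r} not available")
    sub_gm = gm
    if snps is not None:
        snps = list(snps)
        idx = [gm.variant_index(s) for s in snps]
        sub_gm = GenotypeMatrix(
            variants=gm.variants.iloc[idx].reset_index(drop=True),
            genotypes=gm.genotypes[:, idx],
            sample_ids=gm.sample_ids,
        )
    col = assignment.covariates[stratum_column]
    results: dict[str, pd.DataFrame] = {}
    for value in sorted(col.dropna().unique(), key=str):
        in_stratum = col == value
        status = assignment.status.where(in_stratum, other="excluded")
        n_cases = int((status == "case").sum())
        n_controls = int((status == "control").sum())
        if n_cases < 2 or n_controls < 2:
            warnings.warn(
                f"stratum {value!r} skipped: {n_cases} cases / {n_controls} controls",
                stacklevel=2,
            )
            continue
        strat_assign = CaseControlAssignment(
            name=f"{assignment.name}[{stratum_column}={value}]",
            status=status,
            covariates=assignment.covariates,
        )
        results[str(value)] = genome_scan(sub_gm, strat_assign)
    results["combined"] = genome_scan(sub_gm, assignment)
    return results


def export_manhattan(results: pd.DataFrame, path, header: str | None = None) -> None:
    """TSV of chr, pos, snp, p, -log10 p for plotting, sorted by (chr, pos)."""
    cols = ["chr", "pos", "snp", "p", "neg_log10_p"]
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("\t".join(cols) + "\n")
        if len(results) == 0:
            return
        out = _sort_by_position(results)
        for _, r in out.iterrows():
            p_val = float(r["P"])
            nlp = float(-np.log10(max(p_val, 1e-300)))
            fh.write(f"{r['CHR']}\t{r['BP']}\t{r['SNP']}\t{p_val!r}\t{nlp!r}\n")
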