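"""Synthetic genotype/trait/transaction generators with planted structure.

Everything is deterministic given the spec's seed.  Genotypes are drawn
under Hardy-Weinberg equilibrium; LD blocks share a founder haplotype that
each member site copies with a probability tuned to the target pairwise r²;
traits are additive in planted SNP dosages plus correlated Gaussian noise,
rescaled to clinically plausible means/SDs so threshold-based case/control
designs are exercised realistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .assoc import MISSING, GenotypeMatrix
from .traits import ItemizedDataset, TraitTable

__all__ = [
    "PlantedEffect",
    "LDBlock",
    "SimSpec",
    "SimTruth",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_transactions",
    "simulate_two_locus",
]


@dataclass(frozen=True)
class PlantedEffect:
    """Additive per-allele effect of one SNP on one or both focal traits."""

    snp: int  # variant column index
    target: str  # trait_i | trait_j | both
    beta: float  # per-allele effect in trait SD units

    def __post_init__(self) -> None:
        if self.target not in ("trait_i", "trait_j", "both"):
            raise ValueError(f"target must be trait_i|trait_j|both, got {self.target!r}")


@dataclass(frozen=True)
class LDBlock:
    """Half-open SNP index range [start, end) sharing a founder haplotype."""

    start: int
    end: int
    r2: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("block end must exceed start")
        if not 0 < self.r2 <= 1:
            raise ValueError(f"infeasible within-block r2 target {self.r2}")


@dataclass
class SimSpec:
    n_individuals: int = 1000
    n_traits: int = 2
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.1, 0.5)
    effects: tuple[PlantedEffect, ...] = ()
    noise_corr: float = 0.0  # correlation between trait_i and trait_j noise
    trait_corr: np.ndarray | None = None  # full matrix overrides noise_corr
    missing_rate: float = 0.0
    ld_blocks: tuple[LDBlock, ...] = ()
    seed: int = 0
    trait_names: tuple[str, ...] | None = None
    trait_means: tuple[float, ...] | None = None
    trait_sds: tuple[float, ...] | None = None
    snp_spacing: int = 2000  # base pairs between consecutive variants

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.maf_range
        if not 0 < lo <= hi < 0.5 + 1e-12:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_traits < 2:
            raise ValueError("need at least the two focal traits")
        self.effects = tuple(self.effects)
        self.ld_blocks = tuple(self.ld_blocks)
        for e in self.effects:
            if not 0 <= e.snp < self.n_snps:
                raise ValueError(f"effect references SNP {e.snp} outside [0, {self.n_snps})")
        for b in self.ld_blocks:
            if b.end > self.n_snps:
                raise ValueError(f"block {b} exceeds n_snps")
        if self.trait_corr is not None:
            c = np.asarray(self.trait_corr, dtype=float)
            if c.shape != (self.n_traits, self.n_traits):
                raise ValueError("trait_corr must be n_traits x n_traits")
            if np.linalg.eigvalsh(c).min() < -1e-9:
                raise ValueError("trait_corr must be positive semi-definite")
            self.trait_corr = c

    def resolved_trait_names(self) -> list[str]:
        if self.trait_names is not None:
            names = list(self.trait_names)
            if len(names) != self.n_traits:
                raise ValueError("trait_names length must equal n_traits")
            return names
        base = ["LDL", "TG"]
        return base + [f"T{k}" for k in range(3, self.n_traits + 1)]

    def resolved_scales(self) -> tuple[np.ndarray, np.ndarray]:
        means = self.trait_means
        sds = self.trait_sds
        if means is None:
            means = (115.0, 160.0) + (100.0,) * (self.n_traits - 2)
        if sds is None:
            sds = (30.0, 70.0) + (15.0,) * (self.n_traits - 2)
        means = np.asarray(means, dtype=float)
        sds = np.asarray(sds, dtype=float)
        if len(means) != self.n_traits or len(sds) != self.n_traits:
            raise ValueError("trait_means/trait_sds length must equal n_traits")
        return means, sds

    def noise_covariance(self) -> np.ndarray:
        if self.trait_corr is not None:
            return self.trait_corr
        c = np.eye(self.n_traits)
        c[0, 1] = c[1, 0] = self.noise_corr
        return c


@dataclass
class SimTruth:
    """Ground-truth SNP labels and realized summary statistics."""

    labels: pd.DataFrame  # snp, label in {pleiotropic, single_i, single_j, null}, maf
    trait_summary: pd.DataFrame | None = None  # trait, mean, sd (realized)

    def snps_with_label(self, label: str) -> list[str]:
        return list(self.labels.loc[self.labels["label"] == label, "snp"])


_LABEL = {"both": "pleiotropic", "trait_i": "single_i", "trait_j": "single_j"}


def simulate_genotypes(spec: SimSpec) -> tuple[GenotypeMatrix, SimTruth]:
    """Hardy-Weinberg genotypes with optional founder-copied LD blocks.

    Within a block every site shares one allele frequency and copies the
    block founder haplotype with probability r2**0.25, which makes the
    expected pairwise dosage correlation equal the target r² exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_individuals, spec.n_snps
    lo, hi = spec.maf_range
    mafs = rng.uniform(lo, hi, size=m)

    in_block = np.zeros(m, dtype=bool)
    for b in spec.ld_blocks:
        if in_block[b.start : b.end].any():
            raise ValueError("overlapping LD blocks")
        in_block[b.start : b.end] = True

    genotypes = np.empty((n, m), dtype=np.int8)
    free = ~in_block
    genotypes[:, free] = rng.binomial(2, mafs[free], size=(n, free.sum())).astype(np.int8)

    for b in spec.ld_blocks:
        p = float(mafs[b.start])  # one frequency per block keeps the copy model exact
        mafs[b.start : b.end] = p
        copy_p = b.r2**0.25
        width = b.end - b.start
        for hap in range(2):
            founder = rng.random(n) < p
            copies = rng.random((n, width)) < copy_p
            fresh = rng.random((n, width)) < p
            hap_alleles = np.where(copies, founder[:, None], fresh)
            if hap == 0:
                block_dos = hap_alleles.astype(np.int8)
            else:
                block_dos += hap_alleles.astype(np.int8)
        genotypes[:, b.start : b.end] = block_dos

    width = len(str(m))
    variants = pd.DataFrame(
        {
            "snp": [f"snp{j:0{width}d}" for j in range(m)],
            "chrom": "1",
            "pos": [(j + 1) * spec.snp_spacing for j in range(m)],
            "allele1": "A",
            "allele2": "G",
        }
    )
    sample_ids = [f"I{i:06d}" for i in range(n)]
    gm = GenotypeMatrix(variants=variants, genotypes=genotypes, sample_ids=sample_ids)

    label = np.array(["null"] * m, dtype=object)
    for e in spec.effects:
        label[e.snp] = _LABEL[e.target]
    realized = genotypes.astype(float).mean(axis=0) / 2.0
    truth = SimTruth(
        labels=pd.DataFrame({"snp": variants["snp"], "label": label, "maf": realized})
    )
    return gm, truth


def simulate_traits(gm: GenotypeMatrix, spec: SimSpec) -> TraitTable:
    """Additive-genetic traits on clinically plausible scales.

    trait_k = mean_k + sd_k * (sum of beta * centered dosage over planted
    SNPs targeting k + unit-variance noise); the noise of the two focal
    traits is correlated (noise_corr / trait_corr).  Trait missingness is
    applied uniformly at random at ``missing_rate``.
    """
    rng = np.random.default_rng(spec.seed + 1)  # independent of the genotype stream
    n = gm.n_samples
    t = spec.n_traits
    names = spec.resolved_trait_names()
    means, sds = spec.resolved_scales()

    cov = spec.noise_covariance()
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(t))
    noise = rng.standard_normal((n, t)) @ chol.T

    genetic = np.zeros((n, t))
    for e in spec.effects:
        d = gm.genotypes[:, e.snp].astype(float)
        d[d == MISSING] = np.nan
        centered = d - np.nanmean(d)
        centered = np.nan_to_num(centered)
        targets = (0, 1) if e.target == "both" else ((0,) if e.target == "trait_i" else (1,))
        for k in targets:
            genetic[:, k] += e.beta * centered

    raw = genetic + noise
    values = means[None, :] + sds[None, :] * raw

    if spec.missing_rate > 0:
        mask = rng.random((n, t)) < spec.missing_rate
        values = np.where(mask, np.nan, values)

    df = pd.DataFrame(values, columns=names, index=pd.Index(gm.sample_ids, name="IID"))
    covariates = pd.DataFrame(
        {
            "SEX": rng.integers(1, 3, size=n).astype(str),
            "AREA": rng.choice(["Ansung", "Ansan"], size=n),
        },
        index=df.index,
    )
    return TraitTable(values=df, covariates=covariates)


def simulate_two_locus(
    p1: float, p2: float, dprime: float, n: int, seed: int = 0
) -> tuple[GenotypeMatrix, float]:
    """Two linked loci drawn from haplotype frequencies set by D' and MAFs.

    Returns the genotype matrix (2n haplotypes paired at random) and the
    analytic r² = D² / (p1 q1 p2 q2) implied by the haplotype distribution.
    """
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0 < p < 1:
            raise ValueError(f"{name} must be in (0, 1)")
    if not 0 <= dprime <= 1:
        raise ValueError("dprime must be in [0, 1]")
    q1, q2 = 1 - p1, 1 - p2
    d_max = min(p1 * q2, q1 * p2)
    d = dprime * d_max
    hap_freqs = np.array(
        [p1 * p2 + d, p1 * q2 - d, q1 * p2 - d, q1 * q2 + d]
    )  # AB, Ab, aB, ab
    if (hap_freqs < -1e-12).any():
        raise ValueError("infeasible D' for the given allele frequencies")
    hap_freqs = np.clip(hap_freqs, 0, None)
    hap_freqs /= hap_freqs.sum()
    rng = np.random.default_rng(seed)
    haps = rng.choice(4, size=2 * n, p=hap_freqs)
    carries_a = (haps <= 1).astype(np.int8)  # allele A at locus 1
    carries_b = ((haps == 0) | (haps == 2)).astype(np.int8)  # allele B at locus 2
    genotypes = np.stack(
        [carries_a[:n] + carries_a[n:], carries_b[:n] + carries_b[n:]], axis=1
    )
    variants = pd.DataFrame(
        {
            "snp": ["locusA", "locusB"],
            "chrom": "1",
            "pos": [1000, 2000],
            "allele1": "A",
            "allele2": "G",
        }
    )
    gm = GenotypeMatrix(
        variants=variants,
        genotypes=genotypes,
        sample_ids=[f"I{i:06d}" for i in range(n)],
    )
    r2_analytic = d * d / (p1 * q1 * p2 * q2)
    return gm, float(r2_analytic)


def simulate_transactions(
    n: int,
    vocabulary: Sequence[str],
    planted: Sequence[tuple[frozenset[str], float]] = (),
    background_p: float = 0.05,
    seed: int = 0,
) -> ItemizedDataset:
    """Transactions with planted co-occurring itemsets at target supports.

    Each planted itemset is included as a whole with its target probability;
    all vocabulary items additionally fire independently at ``background_p``.
    Planted supports are therefore lower bounds hit within sampling noise.
    """
    vocab = list(vocabulary)
    vocab_set = set(vocab)
    for items, support in planted:
        if not items <= vocab_set:
            raise ValueError(f"planted items outside vocabulary: {sorted(items - vocab_set)}")
        if not 0 < support < 1:
            raise ValueError(f"infeasible target support {support}")
    if not 0 <= background_p < 1:
        raise ValueError("background_p must be in [0, 1)")

    rng = np.random.default_rng(seed)
    bg = rng.random((n, len(vocab))) < background_p
    plant_hits = [rng.random(n) < support for _, support in planted]

    transactions = []
    for i in range(n):
        items = {vocab[j] for j in np.flatnonzero(bg[i])}
        for (planted_items, _), hits in zip(planted, plant_hits):
            if hits[i]:
                items |= planted_items
        transactions.append(frozenset(items))
    return ItemizedDataset(
        items=vocab, transactions=transactions, ids=[f"I{i:06d}" for i in range(n)]
    )
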