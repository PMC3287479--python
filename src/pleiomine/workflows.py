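"""End-to-end workflow helpers built from the pipeline stages.

These wire simulation, phenotype assignment, the three association scans,
and pruning together so the whole pipeline can be scored against planted
ground truth in one call.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import assoc, phenotype, prune, sim

__all__ = ["RecoveryResult", "default_lipid_design", "score_recovery"]


@dataclass
class RecoveryResult:
    """Pipeline recovery score against planted SNP labels for one seed."""

    sensitivity: float  # surviving pleiotropic / planted pleiotropic
    precision: float  # truly pleiotropic / all survivors (1.0 when none survive)
    n_survivors: int
    n_cases: int
    n_controls: int
    survivors: list[str]


def default_lipid_design() -> phenotype.PhenotypeDefinition:
    """Composite lipid design: case LDL>=130 & TG>=180, control LDL<=100 & TG<=100."""
    P = phenotype.PhenotypePredicate
    return phenotype.PhenotypeDefinition(
        name="highLDLhighTG",
        case=(P("LDL", "ge", 130.0), P("TG", "ge", 180.0)),
        control=(P("LDL", "le", 100.0), P("TG", "le", 100.0)),
    )


def score_recovery(
    seed: int,
    n_individuals: int = 8000,
    n_snps: int = 5000,
    n_pleiotropic: int = 20,
    n_single_each: int = 20,
    beta: float = 0.25,
    noise_corr: float = 0.3,
    maf_range: tuple[float, float] = (0.15, 0.45),
    p_multi_max: float = 5e-4,
    mor_min: float = 1.0,
    clump_spec: prune.ClumpSpec | None = None,
) -> RecoveryResult:
    """Simulate, scan, prune, and score against the planted truth.

    Planted pleiotropic SNPs affect both focal traits; single-trait SNPs
    affect exactly one; everything else is null.  Pruning thresholds default
    to the pipeline's standard settings.
    """
    # spread planted SNPs out so they never share an LD window
    step = n_snps // (n_pleiotropic + 2 * n_single_each + 1)
    if step < 1:
        raise ValueError("n_snps too small for the planted effect count")
    slots = [step * (k + 1) for k in range(n_pleiotropic + 2 * n_single_each)]
    effects = (
        tuple(sim.PlantedEffect(snp=s, target="both", beta=beta) for s in slots[:n_pleiotropic])
        + tuple(
            sim.PlantedEffect(snp=s, target="trait_i", beta=beta)
            for s in slots[n_pleiotropic : n_pleiotropic + n_single_each]
        )
        + tuple(
            sim.PlantedEffect(snp=s, target="trait_j", beta=beta)
            for s in slots[n_pleiotropic + n_single_each :]
        )
    )
    spec = sim.SimSpec(
        n_individuals=n_individuals,
        n_snps=n_snps,
        effects=effects,
        noise_corr=noise_corr,
        maf_range=maf_range,
        seed=seed,
    )
    gm, truth = sim.simulate_genotypes(spec)
    table = sim.simulate_traits(gm, spec)

    defn = default_lipid_design()
    multi = phenotype.assign(table, defn)
    single_i = phenotype.assign(table, defn.project("LDL"))
    single_j = phenotype.assign(table, defn.project("TG"))

    scan_multi = assoc.genome_scan(gm, multi)
    scan_i = assoc.genome_scan(gm, single_i)
    scan_j = assoc.genome_scan(gm, single_j)

    mor = prune.mor_table(scan_multi, scan_i, scan_j)
    clumps = prune.greedy_clump(scan_multi, gm, clump_spec)
    pruned = prune.prune(
        mor, clumps, p_multi_max=p_multi_max, mor_min=mor_min, clump_spec=clump_spec
    )

    survivors = set(pruned.survivors)
    pleio = set(truth.snps_with_label("pleiotropic"))
    hit = len(survivors & pleio)
    return RecoveryResult(
        sensitivity=hit / len(pleio) if pleio else float("nan"),
        precision=hit / len(survivors) if survivors else 1.0,
        n_survivors=len(survivors),
        n_cases=multi.n_cases,
        n_controls=multi.n_controls,
        survivors=sorted(survivors),
    )
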