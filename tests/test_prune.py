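import numpy as np
import pandas as pd
import pytest

from pleiomine.assoc import GenotypeMatrix, genome_scan
from pleiomine.prune import (
    ClumpSpec,
    compute_mor,
    greedy_clump,
    mor_table,
    pairwise_r2,
    prune,
)
from pleiomine.sim import LDBlock, SimSpec, simulate_genotypes, simulate_two_locus


def scan_frame(records):
    df = pd.DataFrame(records)
    for col, default in [("CHR", "1"), ("BP", 0), ("OR", 1.0)]:
        if col not in df:
            df[col] = default
    return df


class TestComputeMor:
    def test_boundary_is_exactly_one(self):
        assert compute_mor(1e-4, 1e-3) == pytest.approx(1.0, abs=1e-12)

    def test_equal_ps_give_zero(self):
        assert compute_mor(0.01, 0.01) == 0.0

    def test_log_arithmetic(self):
        assert compute_mor(1e-6, 1e-2) == pytest.approx(4.0, abs=1e-12)

    def test_nonpositive_p_errors(self):
        with pytest.raises(ValueError):
            compute_mor(0.0, 0.5)
        with pytest.raises(ValueError):
            compute_mor(0.5, -1.0)
        with pytest.raises(ValueError):
            compute_mor(0.5, 1.5)

    def test_additive_in_log_ratio(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p1, p2, p3 = rng.uniform(1e-10, 1, size=3)
            assert compute_mor(p1, p3) == pytest.approx(
                compute_mor(p1, p2) + compute_mor(p2, p3), abs=1e-9
            )


class TestMorTable:
    def test_join_semantics_with_warning(self):
        multi = scan_frame({"SNP": ["a", "b", "c"], "P": [1e-4, 1e-3, 1e-2]})
        si = scan_frame({"SNP": ["a", "b"], "P": [1e-3, 1e-3]})
        sj = scan_frame({"SNP": ["a", "b"], "P": [1e-2, 1e-3]})
        with pytest.warns(UserWarning, match="missing"):
            out = mor_table(multi, si, sj)
        assert sorted(out["snp"]) == ["a", "b"]

    def test_identical_scans_zero_mor(self):
        s = scan_frame({"SNP": ["a", "b"], "P": [1e-4, 1e-3]})
        out = mor_table(s, s.copy(), s.copy())
        assert (out["mor_i"] == 0).all() and (out["mor_j"] == 0).all()

    def test_empty_intersection_errors(self):
        s1 = scan_frame({"SNP": ["a"], "P": [0.5]})
        s2 = scan_frame({"SNP": ["b"], "P": [0.5]})
        with pytest.raises(ValueError):
            mor_table(s1, s2, s2.copy())

    def test_matches_rowwise_recomputation(self):
        rng = np.random.default_rng(3)
        snps = [f"rs{i}" for i in range(50)]
        multi = scan_frame({"SNP": snps, "P": rng.uniform(1e-8, 1, 50)})
        si = scan_frame({"SNP": snps, "P": rng.uniform(1e-8, 1, 50)})
        sj = scan_frame({"SNP": snps, "P": rng.uniform(1e-8, 1, 50)})
        out = mor_table(multi, si, sj).set_index("snp")
        for k, s in enumerate(snps):
            pm = multi["P"].iloc[k]
            assert out.loc[s, "mor_i"] == pytest.approx(
                np.log10(si["P"].iloc[k]) - np.log10(pm), abs=1e-12
            )
            assert out.loc[s, "mor_j"] == pytest.approx(
                np.log10(sj["P"].iloc[k]) - np.log10(pm), abs=1e-12
            )


def tiny_gm(dosages: dict[str, list[int]]):
    snps = list(dosages)
    n = len(next(iter(dosages.values())))
    variants = pd.DataFrame(
        {
            "snp": snps,
            "chrom": "1",
            "pos": [1000 * (j + 1) for j in range(len(snps))],
            "allele1": "A",
            "allele2": "G",
        }
    )
    genotypes = np.array([dosages[s] for s in snps], dtype=np.int8).T
    return GenotypeMatrix(
        variants=variants, genotypes=genotypes, sample_ids=[f"s{i}" for i in range(n)]
    )


class TestPairwiseR2:
    def test_identical_vectors(self):
        gm = tiny_gm({"a": [0, 1, 2, 0], "b": [0, 1, 2, 0]})
        assert pairwise_r2(gm, "a", "b") == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        gm = tiny_gm({"a": [0, 1, 2, 0], "b": [2, 1, 0, 2]})
        assert pairwise_r2(gm, "a", "b") == pytest.approx(1.0)

    def test_monomorphic_is_nan(self):
        gm = tiny_gm({"a": [1, 1, 1, 1], "b": [0, 1, 2, 0]})
        assert np.isnan(pairwise_r2(gm, "a", "b"))

    def test_too_few_complete_pairs_errors(self):
        gm = tiny_gm({"a": [0, -1, -1, -1], "b": [2, 1, 0, 2]})
        with pytest.raises(ValueError):
            pairwise_r2(gm, "a", "b")

    @pytest.mark.parametrize(
        "p1,p2,dprime", [(0.3, 0.3, 1.0), (0.2, 0.4, 0.8), (0.5, 0.5, 0.5)]
    )
    def test_matches_closed_form(self, p1, p2, dprime):
        gm, r2_true = simulate_two_locus(p1, p2, dprime, n=2000, seed=15)
        r2_hat = pairwise_r2(gm, "locusA", "locusB")
        assert r2_hat == pytest.approx(r2_true, abs=0.02)


def reference_clump(df, r2_fn, spec):
    """Independent re-statement of the greedy rule for the oracle."""
    idx_order = sorted(
        [i for i in df.index if df.loc[i, "P"] <= spec.p_index],
        key=lambda i: (df.loc[i, "P"], int(df.loc[i, "CHR"]), df.loc[i, "BP"]),
    )
    assigned = {}
    for i in idx_order:
        if i in assigned:
            continue
        assigned[i] = df.loc[i, "SNP"]
        for j in df.index:
            if j in assigned or df.loc[j, "P"] > spec.p_clumped:
                continue
            if df.loc[j, "CHR"] != df.loc[i, "CHR"]:
                continue
            if abs(int(df.loc[j, "BP"]) - int(df.loc[i, "BP"])) > spec.window_kb * 1000:
                continue
            r2 = r2_fn(df.loc[i, "SNP"], df.loc[j, "SNP"])
            if not np.isnan(r2) and r2 >= spec.r2_threshold:
                assigned[j] = df.loc[i, "SNP"]
    return {df.loc[i, "SNP"]: v for i, v in assigned.items()}


class TestGreedyClump:
    def test_pair_in_ld_forms_one_clump(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=100).astype(np.int8)
        noisy = base.copy()
        flip = rng.random(100) < 0.05
        noisy[flip] = rng.integers(0, 3, size=int(flip.sum()))
        gm = tiny_gm({"rs1": base.tolist(), "rs2": noisy.tolist()})
        res = scan_frame({"SNP": ["rs1", "rs2"], "P": [1e-6, 1e-5],
                          "BP": [1000, 11000]})
        out = greedy_clump(res, gm).set_index("snp")
        assert out.loc["rs1", "is_index"]
        assert out.loc["rs2", "clump_index"] == "rs1"
        assert not out.loc["rs2", "is_index"]

    def test_low_r2_gives_singletons(self):
        rng = np.random.default_rng(1)
        gm = tiny_gm(
            {"rs1": rng.integers(0, 3, 200).tolist(), "rs2": rng.integers(0, 3, 200).tolist()}
        )
        res = scan_frame({"SNP": ["rs1", "rs2"], "P": [1e-6, 1e-5], "BP": [1000, 11000]})
        out = greedy_clump(res, gm).set_index("snp")
        assert out.loc["rs1", "is_index"] and out.loc["rs2", "is_index"]

    def test_window_excludes_distant_snps(self):
        gm = tiny_gm({"rs1": [0, 1, 2, 0, 1], "rs2": [0, 1, 2, 0, 1]})
        res = scan_frame(
            {"SNP": ["rs1", "rs2"], "P": [1e-6, 1e-5], "BP": [1000, 300_000_0]}
        )
        out = greedy_clump(res, gm).set_index("snp")
        assert out.loc["rs2", "clump_index"] == "rs2"  # too far despite r2=1

    def test_matches_brute_force_oracle(self):
        for trial in range(20):
            spec = SimSpec(
                n_individuals=150,
                n_snps=30,
                seed=100 + trial,
                ld_blocks=(LDBlock(0, 6, 0.8), LDBlock(10, 16, 0.9), LDBlock(20, 25, 0.7)),
            )
            gm, _ = simulate_genotypes(spec)
            rng = np.random.default_rng(200 + trial)
            pvals = 10 ** rng.uniform(-8, 0, size=30)
            res = scan_frame(
                {
                    "SNP": gm.variants["snp"],
                    "P": pvals,
                    "CHR": gm.variants["chrom"],
                    "BP": gm.variants["pos"],
                }
            )
            cspec = ClumpSpec(p_index=1e-4, p_clumped=1e-2, r2_threshold=0.5, window_kb=20)
            got = greedy_clump(res, gm, cspec)
            got_map = {
                r["snp"]: r["clump_index"] for _, r in got.iterrows() if r["clump_index"]
            }
            expected = reference_clump(res, lambda a, b: 1.0 if a == b else pairwise_r2(gm, a, b), cspec)
            assert got_map == expected

    def test_input_order_invariance(self):
        spec = SimSpec(n_individuals=150, n_snps=20, seed=7, ld_blocks=(LDBlock(0, 8, 0.9),))
        gm, _ = simulate_genotypes(spec)
        rng = np.random.default_rng(8)
        res = scan_frame(
            {
                "SNP": gm.variants["snp"],
                "P": 10 ** rng.uniform(-7, 0, size=20),
                "CHR": gm.variants["chrom"],
                "BP": gm.variants["pos"],
            }
        )
        cspec = ClumpSpec(p_index=1e-3, p_clumped=1e-1, r2_threshold=0.5, window_kb=20)
        a = greedy_clump(res, gm, cspec).sort_values("snp").reset_index(drop=True)
        shuffled = res.sample(frac=1, random_state=3).reset_index(drop=True)
        b = greedy_clump(shuffled, gm, cspec).sort_values("snp").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            ClumpSpec(p_index=1e-3, p_clumped=1e-5)
        with pytest.raises(ValueError):
            ClumpSpec(r2_threshold=0.0)


def mor_frame(records):
    df = pd.DataFrame(records)
    for col, default in [("chrom", "1"), ("pos", 0), ("or_multi", 1.0),
                         ("p_single_i", 1.0), ("p_single_j", 1.0)]:
        if col not in df:
            df[col] = default
    return df


def clump_frame(records):
    return pd.DataFrame(records, columns=["snp", "clump_index", "r2_to_index", "is_index"])


class TestPrune:
    def test_strong_snp_survives(self):
        mor = mor_frame(
            [{"snp": "rs11700112", "p_multi": 6.2e-5, "mor_i": 3.25, "mor_j": 1.58}]
        )
        clumps = clump_frame([{"snp": "rs11700112", "clump_index": "rs11700112",
                               "r2_to_index": 1.0, "is_index": True}])
        out = prune(mor, clumps)
        assert out.survivors == ["rs11700112"]
        assert out.audit["filter_status"].tolist() == ["pass"]

    def test_weak_multi_p_removed_first(self):
        mor = mor_frame([{"snp": "rs693", "p_multi": 7.3e-4, "mor_i": 0.04, "mor_j": 2.21}])
        clumps = clump_frame([])
        out = prune(mor, clumps)
        assert out.survivors == []
        assert out.audit["filter_status"].tolist() == ["fail_p_multi"]

    def test_one_sided_mor_removed(self):
        mor = mor_frame([{"snp": "a", "p_multi": 1e-5, "mor_i": 2.0, "mor_j": 0.5}])
        clumps = clump_frame([{"snp": "a", "clump_index": "a", "r2_to_index": 1.0,
                               "is_index": True}])
        out = prune(mor, clumps)
        assert out.audit["filter_status"].tolist() == ["fail_mor"]

    def test_clump_rule_member_vs_index(self):
        mor = mor_frame(
            [
                {"snp": "idx", "p_multi": 1e-6, "mor_i": 2.0, "mor_j": 2.0},
                {"snp": "mem", "p_multi": 5e-5, "mor_i": 2.0, "mor_j": 2.0},
            ]
        )
        clumps = clump_frame(
            [
                {"snp": "idx", "clump_index": "idx", "r2_to_index": 1.0, "is_index": True},
                {"snp": "mem", "clump_index": "idx", "r2_to_index": 0.8, "is_index": False},
            ]
        )
        member = prune(mor, clumps, clump_rule="member")
        assert member.survivors == ["idx", "mem"]
        index_only = prune(mor, clumps, clump_rule="index")
        assert index_only.survivors == ["idx"]

    def test_unclumped_snp_fails_condition_three(self):
        mor = mor_frame([{"snp": "a", "p_multi": 5e-5, "mor_i": 2.0, "mor_j": 2.0}])
        clumps = clump_frame([{"snp": "a", "clump_index": "", "r2_to_index": np.nan,
                               "is_index": False}])
        out = prune(mor, clumps)
        assert out.audit["filter_status"].tolist() == ["fail_clump"]

    def test_audit_covers_every_snp_once(self):
        rng = np.random.default_rng(5)
        snps = [f"rs{i}" for i in range(40)]
        mor = mor_frame(
            [
                {"snp": s, "p_multi": 10 ** rng.uniform(-8, 0),
                 "mor_i": rng.uniform(-2, 4), "mor_j": rng.uniform(-2, 4)}
                for s in snps
            ]
        )
        clumps = clump_frame(
            [{"snp": s, "clump_index": s, "r2_to_index": 1.0, "is_index": True} for s in snps]
        )
        out = prune(mor, clumps)
        assert sorted(out.audit["snp"]) == sorted(snps)
        assert set(out.survivors) <= set(snps)

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(9)
        snps = [f"rs{i}" for i in range(60)]
        mor = mor_frame(
            [
                {"snp": s, "p_multi": 10 ** rng.uniform(-8, 0),
                 "mor_i": rng.uniform(-2, 4), "mor_j": rng.uniform(-2, 4)}
                for s in snps
            ]
        )
        clumps = clump_frame(
            [{"snp": s, "clump_index": s, "r2_to_index": 1.0, "is_index": True} for s in snps]
        )
        strict = set(prune(mor, clumps, p_multi_max=5e-4, mor_min=1.0).survivors)
        relaxed = set(prune(mor, clumps, p_multi_max=5e-3, mor_min=0.5).survivors)
        assert strict <= relaxed
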