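"""Genotype simulation, association scan, min-P combination and clumping."""

import numpy as np
import pandas as pd
import pytest

from fundusvae import genetics as gen


def _latents(values: np.ndarray, names=None) -> pd.DataFrame:
    names = names or [f"s_z{i}" for i in range(values.shape[1])]
    idx = pd.MultiIndex.from_tuples(
        [(f"S{i}", "left") for i in range(len(values))], names=["subject_id", "eye"]
    )
    return pd.DataFrame(values, index=idx, columns=names)


class TestSimulateGenotypes:
    def test_binomial_mean(self):
        g = gen.simulate_genotypes(10_000, 5, maf_range=(0.5, 0.5), seed=0)
        assert g.genotypes.mean() == pytest.approx(1.0, abs=0.05)

    def test_low_maf_rarely_monomorphic(self):
        g = gen.simulate_genotypes(10_000, 50, maf_range=(0.05, 0.05), seed=1)
        assert not g.monomorphic().any()
        assert np.all(np.abs(g.empirical_maf() - 0.05) < 0.02)

    def test_seeded_determinism(self):
        a = gen.simulate_genotypes(100, 20, seed=3)
        b = gen.simulate_genotypes(100, 20, seed=3)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)

    def test_positions_spaced_beyond_clump_window(self):
        g = gen.simulate_genotypes(10, 10, seed=0)
        gaps = np.diff(g.snp_map["bp"].to_numpy())
        assert (gaps >= 500_000).all()

    def test_invalid_maf_range_rejected(self):
        with pytest.raises(ValueError):
            gen.simulate_genotypes(10, 5, maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            gen.simulate_genotypes(10, 5, maf_range=(0.1, 0.6))

    def test_text_round_trip(self, tmp_path):
        g = gen.simulate_genotypes(30, 8, seed=5)
        g.write(tmp_path / "geno")
        back = gen.GenotypeMatrix.read(tmp_path / "geno")
        np.testing.assert_array_equal(back.genotypes, g.genotypes)
        pd.testing.assert_frame_equal(back.snp_map, g.snp_map)


class TestAssociationScan:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        geno = gen.simulate_genotypes(2000, 3, maf_range=(0.3, 0.5), seed=1)
        g0 = geno.genotypes[:, 0].astype(float)
        y = 0.5 * g0 + rng.normal(0, 0.1, size=2000)
        scan = gen.association_scan(_latents(y[:, None]), geno)
        assert scan.effect.iloc[0, 0] == pytest.approx(0.5, abs=0.05)
        assert scan.pvalues.iloc[0, 0] < 1e-10

    def test_null_type_i_error(self):
        rng = np.random.default_rng(2)
        geno = gen.simulate_genotypes(500, 1000, seed=3)
        y = rng.normal(size=(500, 1))
        scan = gen.association_scan(_latents(y), geno)
        rate = float((scan.pvalues.to_numpy() < 0.05).mean())
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_consistent_permutation_invariance(self):
        rng = np.random.default_rng(4)
        geno = gen.simulate_genotypes(200, 5, seed=5)
        y = rng.normal(size=(200, 3))
        base = gen.association_scan(_latents(y), geno)
        perm = rng.permutation(200)
        geno_p = gen.GenotypeMatrix(
            genotypes=geno.genotypes[perm], maf=geno.maf, snp_map=geno.snp_map
        )
        scan_p = gen.association_scan(_latents(y[perm]), geno_p)
        np.testing.assert_allclose(
            scan_p.pvalues.to_numpy(), base.pvalues.to_numpy(), rtol=1e-9
        )

    def test_monomorphic_snp_excluded(self):
        rng = np.random.default_rng(6)
        geno = gen.simulate_genotypes(100, 4, seed=7)
        geno.genotypes[:, 2] = 1  # constant
        scan = gen.association_scan(_latents(rng.normal(size=(100, 2))), geno)
        assert scan.excluded == ["snp0002"]
        assert np.isnan(scan.pvalues.iloc[2]).all()

    def test_pvalues_match_permutation_test(self):
        """OLS t-test p-values agree with an empirical permutation null."""
        rng = np.random.default_rng(8)
        geno = gen.simulate_genotypes(150, 20, seed=9)
        y = rng.normal(size=(150, 4))
        scan = gen.association_scan(_latents(y), geno)
        checks = [(rng.integers(0, 20), rng.integers(0, 4)) for _ in range(20)]
        n_perm = 600
        for si, li in checks:
            g = geno.genotypes[:, si].astype(float)
            yv = y[:, li]
            obs = abs(np.corrcoef(g, yv)[0, 1])
            count = 0
            for _ in range(n_perm):
                count += abs(np.corrcoef(g, rng.permutation(yv))[0, 1]) >= obs
            perm_p = (count + 1) / (n_perm + 1)
            p = scan.pvalues.iloc[si, li]
            mc_sd = np.sqrt(p * (1 - p) / n_perm)
            assert perm_p == pytest.approx(p, abs=max(4 * mc_sd, 0.02))

    def test_covariate_adjustment_removes_confounding(self):
        rng = np.random.default_rng(10)
        geno = gen.simulate_genotypes(1000, 1, maf_range=(0.3, 0.5), seed=11)
        g = geno.genotypes[:, 0].astype(float)
        confounder = g + rng.normal(size=1000)
        y = 2.0 * confounder + rng.normal(size=1000)
        raw = gen.association_scan(_latents(y[:, None]), geno)
        adj = gen.association_scan(
            _latents(y[:, None]), geno, covariates=pd.DataFrame({"c": confounder})
        )
        assert raw.pvalues.iloc[0, 0] < 1e-6  # confounded signal
        assert adj.pvalues.iloc[0, 0] > 1e-3  # mostly absorbed by the covariate


class TestMinPCombine:
    def test_bonferroni_arithmetic(self):
        p = pd.DataFrame([[0.01] * 9 + [0.001]])
        assert gen.min_p_combine(p).iloc[0] == pytest.approx(0.01)

    def test_capped_at_one(self):
        p = pd.DataFrame([[1.0, 1.0, 1.0]])
        assert gen.min_p_combine(p).iloc[0] == 1.0


def _toy_result(pvals, positions, genotypes):
    n_snps = len(positions)
    snp_map = pd.DataFrame(
        {"snp": [f"snp{i}" for i in range(n_snps)], "chrom": 1, "bp": positions,
         "maf": [0.3] * n_snps}
    )
    geno = gen.GenotypeMatrix(
        genotypes=genotypes, maf=snp_map["maf"].to_numpy(), snp_map=snp_map
    )
    frame = pd.DataFrame(
        np.asarray(pvals)[:, None], index=snp_map["snp"], columns=["z0"]
    )
    res = gen.AssociationResult(
        effect=frame * 0, se=frame * 0, pvalues=frame, n=len(genotypes),
        dof=len(genotypes) - 2, excluded=[], snp_map=snp_map,
    )
    return res, geno


class TestClumping:
    def test_no_significant_snps_zero_loci(self):
        rng = np.random.default_rng(0)
        res, geno = _toy_result(
            [0.5, 0.2], [1_000_000, 2_000_000], rng.integers(0, 3, (50, 2)).astype(np.int8)
        )
        assert gen.count_significant_loci(res, geno, threshold=5e-8).n_loci == 0

    def test_correlated_nearby_snps_merge(self):
        rng = np.random.default_rng(1)
        g0 = rng.integers(0, 3, 200).astype(np.int8)
        flip = rng.random(200) < 0.05
        g1 = np.where(flip, rng.integers(0, 3, 200), g0).astype(np.int8)  # r^2 >> 0.1
        res, geno = _toy_result(
            [1e-10, 1e-9], [1_000_000, 1_100_000], np.column_stack([g0, g1])
        )
        loci = gen.count_significant_loci(res, geno, threshold=1e-3)
        assert loci.n_loci == 1
        assert loci.assignments["locus"].nunique() == 1
        assert loci.assignments.loc[loci.assignments["is_index"], "snp"].iloc[0] == "snp0"

    def test_distant_or_uncorrelated_snps_stay_separate(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, (500, 3)).astype(np.int8)  # independent draws
        res, geno = _toy_result(
            [1e-10, 1e-9, 1e-8], [1_000_000, 1_100_000, 9_000_000], g
        )
        assert gen.count_significant_loci(res, geno, threshold=1e-3).n_loci == 3

    def test_construction_guarantees_independence(self):
        rng = np.random.default_rng(3)
        geno = gen.simulate_genotypes(300, 6, seed=4)
        pv = pd.DataFrame(
            np.full((6, 2), 1e-12), index=geno.snp_map["snp"], columns=["a", "b"]
        )
        res = gen.AssociationResult(
            effect=pv * 0, se=pv * 0, pvalues=pv, n=300, dof=298, excluded=[],
            snp_map=geno.snp_map,
        )
        assert gen.count_significant_loci(res, geno, threshold=5e-8).n_loci == 6


class TestRecoveryComparison:
    def _result(self, pvals_by_latent, snp_map):
        frame = pd.DataFrame(pvals_by_latent, index=snp_map["snp"])
        return gen.AssociationResult(
            effect=frame * 0, se=frame * 0, pvalues=frame, n=100, dof=98,
            excluded=[], snp_map=snp_map,
        )

    def test_bookkeeping_rates(self):
        snp_map = pd.DataFrame(
            {"snp": [f"snp{i}" for i in range(6)], "chrom": 1,
             "bp": np.arange(6) * 600_000, "maf": 0.3}
        )
        causal = [(i, "vessel_tortuosity", "vessel") for i in range(6)]
        sa = self._result({"vessel_z0": [1e-12] * 6, "background_z0": [0.5] * 6}, snp_map)
        mono = self._result({"monolithic_z0": [0.9] * 6}, snp_map)
        out = gen.recovery_comparison(sa, mono, causal, threshold=1e-3)
        assert out["savae_recovery_rate"] == 1.0
        assert out["monolithic_recovery_rate"] == 0.0
        assert out["attribution_accuracy"] == 1.0

    def test_attribution_counts_best_latent_stream(self):
        snp_map = pd.DataFrame(
            {"snp": ["snp0"], "chrom": 1, "bp": [0], "maf": 0.3}
        )
        causal = [(0, "vessel_tortuosity", "vessel")]
        sa_wrong = self._result(
            {"vessel_z0": [1e-6], "background_z0": [1e-12]}, snp_map
        )
        mono = self._result({"monolithic_z0": [0.9]}, snp_map)
        out = gen.recovery_comparison(sa_wrong, mono, causal, threshold=1e-3)
        assert out["savae_recovery_rate"] == 1.0
        assert out["attribution_accuracy"] == 0.0
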