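import numpy as np
import pandas as pd
import pytest

from crossmeta import simulate as sim
from crossmeta.errors import ConfigError


def _cfg(**kw):
    base = dict(n_variants=100, n_blocks=10, block_rho=0.5, n_traits=2,
                cohort_sizes=(500, 500), study_traits=(0, 1),
                n_shared_causal=4, n_discordant_causal=2,
                n_specific_causal=2, seed=1)
    base.update(kw)
    return sim.SimConfig(**base)


class TestConfigValidation:
    def test_bad_frequency_range(self):
        with pytest.raises(ConfigError, match="frequency"):
            _cfg(allele_freq_range=(0.5, 0.2))

    def test_asymmetric_overlap(self):
        with pytest.raises(ConfigError, match="symmetric"):
            _cfg(overlap_matrix=np.array([[0, 10], [20, 0]]))

    def test_overlap_exceeding_cohort(self):
        with pytest.raises(ConfigError, match="exceed"):
            _cfg(overlap_matrix=np.array([[0, 600], [600, 0]]))

    def test_causal_counts_exceed_variants(self):
        with pytest.raises(ConfigError, match="causal"):
            _cfg(n_shared_causal=99)

    def test_bad_prevalence(self):
        with pytest.raises(ConfigError, match="prevalence"):
            _cfg(prevalence=1.5)


class TestGenotypes:
    def test_same_seed_identical(self):
        cfg = _cfg()
        g1 = sim.simulate_genotypes(cfg, 200, np.random.default_rng(3))
        g2 = sim.simulate_genotypes(cfg, 200, np.random.default_rng(3))
        np.testing.assert_array_equal(g1.dosages, g2.dosages)

    def test_dosages_in_range(self):
        g = sim.simulate_genotypes(_cfg(), 200)
        assert set(np.unique(g.dosages)) <= {0, 1, 2}

    def test_empirical_frequency_matches_configured(self):
        g = sim.simulate_genotypes(_cfg(), 3000)
        emp = g.dosages.mean(axis=0) / 2.0
        np.testing.assert_allclose(emp, g.variants["FRQ"], atol=0.04)

    def test_independence_when_rho_zero(self):
        cfg = _cfg(block_rho=0.0)
        g = sim.simulate_genotypes(cfg, 2000, np.random.default_rng(0))
        d = g.dosages.astype(float)
        r = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] for j in range(20)]
        assert np.max(np.abs(r)) < 0.08
        assert abs(np.mean(r)) < 0.02

    def test_adjacent_correlation_matches_rho(self):
        cfg = _cfg(n_variants=200, n_blocks=20, block_rho=0.9)
        g = sim.simulate_genotypes(cfg, 2000, np.random.default_rng(1))
        d = g.dosages.astype(float)
        rs = []
        for b in range(20):
            for j in range(b * 10, b * 10 + 9):
                rs.append(np.corrcoef(d[:, j], d[:, j + 1])[0, 1])
        assert np.mean(rs) == pytest.approx(0.9, abs=0.05)

    def test_cross_block_independence(self):
        cfg = _cfg(n_variants=200, n_blocks=20, block_rho=0.9)
        g = sim.simulate_genotypes(cfg, 2000, np.random.default_rng(2))
        d = g.dosages.astype(float)
        # last variant of one block vs first of the next
        rs = [np.corrcoef(d[:, b * 10 + 9], d[:, b * 10 + 10])[0, 1]
              for b in range(19)]
        assert abs(np.mean(rs)) < 0.03


class TestTruthTable:
    def test_role_counts_and_sign_structure(self):
        cfg = _cfg(n_traits=3, cohort_sizes=(300,) * 3,
                   study_traits=(0, 1, 2))
        truth = sim.simulate_truth(cfg)
        assert len(truth.indices("shared")) == cfg.n_shared_causal
        assert len(truth.indices("discordant")) == cfg.n_discordant_causal
        for j in truth.indices("shared"):
            signs = np.sign(truth.beta[j])
            assert len(set(signs)) == 1 and signs[0] != 0
        for j in truth.indices("discordant"):
            signs = set(np.sign(truth.beta[j]))
            assert {1.0, -1.0} <= signs or {-1.0, 1.0} <= signs
        null = truth.indices("null")
        assert np.all(truth.beta[null] == 0.0)


class TestPhenotypes:
    def test_null_case_fraction_matches_prevalence(self):
        cfg = _cfg(n_shared_causal=0, n_discordant_causal=0,
                   n_specific_causal=0, prevalence=0.1)
        rng = np.random.default_rng(9)
        geno = sim.simulate_genotypes(cfg, 4000, rng)
        truth = sim.simulate_truth(cfg, geno.variants, rng)
        labels, _ = sim.simulate_phenotypes(geno, truth, cfg, rng)
        frac = labels.mean(axis=0)
        # binomial 3-sigma at n = 4000
        assert np.all(np.abs(frac - 0.1) < 3 * np.sqrt(0.09 / 4000))

    def test_case_rate_monotone_in_genotype(self):
        cfg = _cfg(n_shared_causal=1, n_discordant_causal=0,
                   n_specific_causal=0, allele_freq_range=(0.4, 0.6))
        rng = np.random.default_rng(4)
        geno = sim.simulate_genotypes(cfg, 20_000, rng)
        truth = sim.simulate_truth(cfg, geno.variants, rng)
        j = truth.indices("shared")[0]
        truth.beta[j, :] = 0.8  # large positive liability effect
        labels, _ = sim.simulate_phenotypes(geno, truth, cfg, rng)
        rates = [labels[geno.dosages[:, j] == d, 0].mean() for d in (0, 1, 2)]
        assert rates[0] < rates[1] < rates[2]

    def test_same_seed_identical_labels(self):
        cfg = _cfg()
        geno = sim.simulate_genotypes(cfg, 500, np.random.default_rng(1))
        truth = sim.simulate_truth(cfg, geno.variants,
                                   np.random.default_rng(2))
        l1, _ = sim.simulate_phenotypes(geno, truth, cfg,
                                        np.random.default_rng(3))
        l2, _ = sim.simulate_phenotypes(geno, truth, cfg,
                                        np.random.default_rng(3))
        np.testing.assert_array_equal(l1, l2)


class TestSumstats:
    def test_null_mean_chi2_is_one(self, null_collection):
        study = next(iter(null_collection.studies.values()))
        chi2 = study["Z"].to_numpy() ** 2
        assert chi2.mean() == pytest.approx(1.0, abs=0.05)

    def test_null_z_mean_and_variance(self, null_collection):
        z = next(iter(null_collection.studies.values()))["Z"].to_numpy()
        m = z.size
        assert abs(z.mean()) < 3 / np.sqrt(m)
        assert z.var() == pytest.approx(1.0, abs=0.1)

    def test_duplicate_cohorts_identical_z(self):
        cfg = _cfg(n_traits=1, cohort_sizes=(400, 400), study_traits=(0, 0),
                   overlap_matrix=np.array([[0, 400], [400, 0]]))
        coll = sim.simulate_collection(cfg, quantitative=True)
        a, b = list(coll.studies.values())
        np.testing.assert_allclose(a["Z"], b["Z"])

    def test_planted_effect_reaches_gws(self):
        cfg = _cfg(n_shared_causal=1, n_discordant_causal=0,
                   n_specific_causal=0, cohort_sizes=(6000, 6000),
                   allele_freq_range=(0.3, 0.7))
        rng = np.random.default_rng(8)
        geno = sim.simulate_genotypes(cfg, 6000, rng)
        truth = sim.simulate_truth(cfg, geno.variants, rng)
        j = truth.indices("shared")[0]
        # noncentrality ~ sqrt(n) * beta * sd(g) ~ 7.7 at n=6000
        truth.beta[j, :] = 0.1
        _, liab = sim.simulate_phenotypes(geno, truth, cfg, rng)
        ss = sim.compute_sumstats(geno, liab[:, 0], np.arange(6000))
        assert ss.loc[j, "P"] < 5e-8

    def test_monomorphic_variant_flagged(self):
        cfg = _cfg(n_shared_causal=0, n_discordant_causal=0,
                   n_specific_causal=0)
        geno = sim.simulate_genotypes(cfg, 300, np.random.default_rng(6))
        geno.dosages[:, 3] = 2
        y = np.random.default_rng(0).normal(size=300)
        ss = sim.compute_sumstats(geno, y, np.arange(300))
        assert bool(ss.loc[3, "MONOMORPHIC"])
        assert np.isnan(ss.loc[3, "Z"])

    def test_one_class_cohort_rejected(self):
        cfg = _cfg()
        geno = sim.simulate_genotypes(cfg, 50, np.random.default_rng(6))
        with pytest.raises(ConfigError, match="constant"):
            sim.compute_sumstats(geno, np.zeros(50), np.arange(50))


class TestOverlap:
    def test_pairwise_overlap_realized_exactly(self):
        cfg = _cfg(cohort_sizes=(500, 600), study_traits=(0, 1),
                   overlap_matrix=np.array([[0, 150], [150, 0]]))
        cohorts, total = sim.build_cohorts(cfg)
        assert len(np.intersect1d(cohorts[0], cohorts[1])) == 150
        assert len(cohorts[0]) == 500 and len(cohorts[1]) == 600
        assert total == 500 + 600 - 150

    def test_z_correlation_matches_overlap_fraction(self):
        """Shared participants induce corr(Z) ~ n_s / sqrt(n1 n2)."""
        cfg = sim.SimConfig(
            n_variants=8000, n_blocks=8000, block_rho=0.0, n_traits=1,
            cohort_sizes=(2000, 2000), study_traits=(0, 0),
            overlap_matrix=np.array([[0, 1000], [1000, 0]]),
            n_shared_causal=0, n_discordant_causal=0, n_specific_causal=0,
            seed=12)
        coll = sim.simulate_collection(cfg, quantitative=True)
        a, b = list(coll.studies.values())
        r = float(np.corrcoef(a["Z"], b["Z"])[0, 1])
        assert r == pytest.approx(0.5, abs=0.05)


class TestExpressionAndAnnotations:
    def test_expression_dimensions_and_determinism(self):
        m1 = sim.generate_expression(50, 8, [1, 2], 5.0, seed=3)
        m2 = sim.generate_expression(50, 8, [1, 2], 5.0, seed=3)
        assert m1.shape == (50, 8)
        pd.testing.assert_frame_equal(m1, m2)

    def test_zero_shift_leaves_planted_genes_typical(self):
        m = sim.generate_expression(500, 6, np.arange(50), 0.0, seed=4)
        from crossmeta.enrichment import label_high
        labels = label_high(m)
        planted_rate = labels.iloc[:50].to_numpy().mean()
        other_rate = labels.iloc[50:].to_numpy().mean()
        assert abs(planted_rate - other_rate) < 0.05

    def test_annotations_internally_consistent(self):
        cfg = _cfg(n_shared_causal=6)
        rng = np.random.default_rng(2)
        geno = sim.simulate_genotypes(cfg, 100, rng)
        truth = sim.simulate_truth(cfg, geno.variants, rng)
        ann = sim.generate_annotations(cfg, truth, geno.variants, n_genes=10)
        genes = ann["genes"].set_index("GENE")
        for row in ann["eqtls"].itertuples(index=False):
            assert genes.loc[row.GENE, "CHR"] == "1"
        for row in ann["loops"].itertuples(index=False):
            assert row.END2 - row.START1 < 2_000_000
            assert row.START1 <= row.START2
        # known loci cover exactly half of the planted shared variants
        shared_bp = geno.variants["BP"].to_numpy()[truth.indices("shared")]
        covered = sum(
            ((ann["known_loci"]["START"] <= bp)
             & (ann["known_loci"]["END"] >= bp)).any()
            for bp in shared_bp)
        assert covered == len(shared_bp) // 2

    def test_truth_links_point_at_real_genes(self):
        cfg = _cfg()
        rng = np.random.default_rng(2)
        geno = sim.simulate_genotypes(cfg, 50, rng)
        truth = sim.simulate_truth(cfg, geno.variants, rng)
        ann = sim.generate_annotations(cfg, truth, geno.variants, n_genes=8)
        assert set(ann["truth_links"]["GENE"]) <= set(ann["genes"]["GENE"])
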