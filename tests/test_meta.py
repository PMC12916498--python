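
import numpy as np
import pandas as pd
import pytest

from crossmeta import meta
from crossmeta.errors import ConfigError, UsageError
from tests.conftest import toy_sumstats


def identity_model(labels, ns=None):
    k = len(labels)
    w = None if ns is None else np.sqrt(np.asarray(ns, dtype=float))
    return meta.OverlapModel(labels=list(labels), C=np.eye(k), w=w)


class TestWeightedZ:
    def test_two_independent_equal_n_studies(self):
        studies = {"a": toy_sumstats([2.0]), "b": toy_sumstats([2.0])}
        res = meta.meta_weighted_z(studies, identity_model(["a", "b"]))
        assert res.loc[0, "Z"] == pytest.approx(4 / np.sqrt(2), abs=1e-9)

    def test_fully_duplicated_studies_no_double_counting(self):
        studies = {"a": toy_sumstats([2.0]), "b": toy_sumstats([2.0])}
        model = meta.OverlapModel(labels=["a", "b"],
                                  C=np.array([[1.0, 1.0], [1.0, 1.0]]))
        res = meta.meta_weighted_z(studies, model)
        assert res.loc[0, "Z"] == pytest.approx(2.0, abs=1e-9)

    def test_single_study_variant_passthrough(self):
        a = toy_sumstats([1.5, 2.5], snps=["rs1", "rs2"])
        b = toy_sumstats([1.0], snps=["rs1"])
        res = meta.meta_weighted_z({"a": a, "b": b},
                                   identity_model(["a", "b"]))
        z_rs2 = res.set_index("SNP").loc["rs2", "Z"]
        assert z_rs2 == pytest.approx(2.5, abs=1e-9)

    def test_study_order_invariance(self, null_collection):
        studies = dict(list(null_collection.studies.items())[:3])
        labels = list(studies)
        model = meta.estimate_z_correlation(studies)
        res = meta.meta_weighted_z(studies, model)
        rev = {k: studies[k] for k in reversed(labels)}
        res2 = meta.meta_weighted_z(rev, model.submodel(list(rev)))
        merged = res.merge(res2, on="SNP", suffixes=("", "_rev"))
        np.testing.assert_allclose(merged["Z"], merged["Z_rev"], atol=1e-10)
        np.testing.assert_allclose(merged["N"], merged["N_rev"], atol=1e-8)

    def test_neff_bounded_by_sum(self, null_collection):
        studies = dict(list(null_collection.studies.items())[:2])
        res = meta.meta_weighted_z(studies,
                                   meta.estimate_z_correlation(studies))
        total = sum(float(s["N"].iloc[0]) for s in studies.values())
        assert np.all(res["N"] <= total + 1e-6)


class TestEffectiveSampleSize:
    def test_no_overlap_reduces_to_sum(self):
        assert meta.effective_sample_size(
            [100, 200], identity_model(["a", "b"])) == pytest.approx(300)

    def test_full_duplication_collapses(self):
        model = meta.OverlapModel(labels=["a", "b"],
                                  C=np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert meta.effective_sample_size([100, 100], model) == \
            pytest.approx(100)

    def test_partial_overlap_closed_form(self):
        model = meta.OverlapModel(labels=["a", "b"],
                                  C=np.array([[1.0, 0.5], [0.5, 1.0]]))
        # (100+300)^2 / (100 + 300 + 2*0.5*sqrt(100*300))
        expected = 160000 / (400 + np.sqrt(30000))
        got = meta.effective_sample_size([100, 300], model)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(279.1, abs=0.05)

    def test_nonpositive_denominator_rejected(self):
        model = meta.OverlapModel(labels=["a", "b"],
                                  C=np.array([[1.0, -2.0], [-2.0, 1.0]]))
        with pytest.raises(ConfigError):
            meta.effective_sample_size([100, 100], model)


class TestOverlapEstimation:
    def test_self_pair_correlation_is_one(self, null_collection):
        name, df = next(iter(null_collection.studies.items()))
        model = meta.estimate_z_correlation({"a": df, "b": df.copy()},
                                            min_shared=100)
        assert model.C[0, 1] == pytest.approx(1.0, abs=0.02)

    def test_independent_cohorts_near_zero(self, null_collection):
        studies = dict(list(null_collection.studies.items())[:2])
        model = meta.estimate_z_correlation(studies, min_shared=100)
        assert abs(model.C[0, 1]) < 0.05

    def test_fewer_than_two_studies_rejected(self, null_collection):
        one = dict(list(null_collection.studies.items())[:1])
        with pytest.raises(UsageError):
            meta.estimate_z_correlation(one)

    def test_pair_below_variant_floor_gets_zero(self, null_collection):
        a, b = list(null_collection.studies.values())[:2]
        model = meta.estimate_z_correlation({"a": a, "b": b.iloc[:50]},
                                            min_shared=1000)
        assert model.C[0, 1] == 0.0

    def test_truncation_deattenuation_round_trip(self):
        rng = np.random.default_rng(0)
        for rho in (0.2, 0.5, 0.8):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]],
                                        size=400_000)
            ok = (np.abs(z[:, 0]) < 1.96) & (np.abs(z[:, 1]) < 1.96)
            c_obs = np.corrcoef(z[ok, 0], z[ok, 1])[0, 1]
            assert meta._deattenuate(c_obs, 1.96) == pytest.approx(
                rho, abs=0.02)

    def test_psd_repair(self):
        C = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.9], [0.0, 0.9, 1.0]])
        repaired = meta.repair_psd(C)
        assert np.linalg.eigvalsh(repaired).min() >= 0
        np.testing.assert_allclose(np.diag(repaired), 1.0)


class TestConcordance:
    @pytest.mark.parametrize("signs,kept", [
        ((1, 1, 1, 1), True),
        ((1, 1, -1, 1), False),
        ((-1, -1, -1, -1), True),
        ((1, np.nan, 1, 1), True),        # absent study does not disqualify
        ((1, np.nan, np.nan, np.nan), False),  # below the presence floor
        ((1, 0, 1, 1), True),             # Z = 0 neither confirms nor breaks
        ((0, 0, np.nan, 0), False),       # no direction at all
    ])
    def test_sign_policy(self, signs, kept):
        df = pd.DataFrame({"SNP": ["rs1"], "Z": [1.0]})
        for i, s in enumerate(signs):
            df[f"SIGN_s{i}"] = [s]
        out = meta.concordance_filter(df)
        assert (len(out) == 1) is kept

    def test_null_four_trait_rate_is_one_eighth(self, null_collection):
        studies = null_collection.studies
        res = meta.meta_weighted_z(studies,
                                   meta.estimate_z_correlation(studies))
        kept = meta.concordance_filter(res)
        rate = len(kept) / len(res)
        m = len(res)
        assert rate == pytest.approx(0.125, abs=3 * np.sqrt(0.125 * 0.875 / m))

    def test_concordant_set_order_invariant(self, null_collection):
        studies = null_collection.studies
        model = meta.estimate_z_correlation(studies)
        res = meta.meta_weighted_z(studies, model)
        rev = {k: studies[k] for k in reversed(list(studies))}
        res2 = meta.meta_weighted_z(rev, model.submodel(list(rev)))
        assert set(meta.concordance_filter(res)["SNP"]) == \
            set(meta.concordance_filter(res2)["SNP"])


class TestNestedMeta:
    def test_single_leaf_identity(self, null_collection):
        name, df = next(iter(null_collection.studies.items()))
        out = meta.nested_meta({"node": [name]}, {name: df})
        np.testing.assert_allclose(out["node"]["Z"], df["Z"])

    def test_two_level_equals_flat_when_independent(self):
        rng = np.random.default_rng(3)
        studies = {f"s{i}": toy_sumstats(rng.normal(size=500), n=1000 * (i + 1))
                   for i in range(4)}
        ident4 = identity_model(list(studies))
        flat = meta.meta_weighted_z(studies, ident4)
        plan = {"ab": ["s0", "s1"], "cd": ["s2", "s3"],
                "root": ["ab", "cd"]}
        models = {"ab": identity_model(["s0", "s1"]),
                  "cd": identity_model(["s2", "s3"]),
                  "root": identity_model(["ab", "cd"])}
        nested = meta.nested_meta(plan, studies, models=models)
        merged = flat.merge(nested["root"], on="SNP", suffixes=("_f", "_n"))
        np.testing.assert_allclose(merged["Z_f"], merged["Z_n"], atol=1e-6)

    def test_cyclic_plan_rejected(self, null_collection):
        studies = dict(list(null_collection.studies.items())[:2])
        plan = {"a": ["b"], "b": ["a"]}
        with pytest.raises(ConfigError, match="cyclic"):
            meta.nested_meta(plan, studies)

    def test_table1_style_plan_smoke(self, null_collection):
        names = list(null_collection.studies)
        plan = {"oud": names[:2], "cross": ["oud"] + names[2:]}
        out = meta.nested_meta(plan, null_collection.studies, min_shared=100)
        assert set(out) == {"oud", "cross"}
        assert len(out["cross"]) == 4000


class TestCalibration:
    def test_overlap_correction_restores_type_i(self):
        """Half-shared cohorts: naive meta inflated, corrected nominal."""
        from crossmeta import simulate as sim
        cfg = sim.SimConfig(
            n_variants=20_000, n_blocks=20_000, block_rho=0.0, n_traits=1,
            cohort_sizes=(2000, 2000), study_traits=(0, 0),
            overlap_matrix=np.array([[0, 1000], [1000, 0]]),
            n_shared_causal=0, n_discordant_causal=0, n_specific_causal=0,
            seed=3)
        coll = sim.simulate_collection(cfg, quantitative=True)
        model = meta.estimate_z_correlation(coll.studies)
        corrected = meta.meta_weighted_z(coll.studies, model)
        naive = meta.meta_weighted_z(
            coll.studies, identity_model(list(coll.studies)))
        rate_naive = float((naive["P"] < 0.05).mean())
        rate_corr = float((corrected["P"] < 0.05).mean())
        assert rate_naive > 0.09          # materially inflated (~0.11)
        assert rate_corr == pytest.approx(0.05, abs=0.005)


class TestRecovery:
    def test_planted_shared_variants_recovered(self):
        """Shared causals of liability effect 0.05 end up concordant and
        GWS at a cohort size powered for them; discordant variants with
        correctly estimated signs never survive."""
        from crossmeta import simulate as sim
        cfg = sim.SimConfig(
            n_variants=1500, n_blocks=150, block_rho=0.6,
            allele_freq_range=(0.3, 0.7),
            n_traits=4, cohort_sizes=(40_000,) * 4, study_traits=(0, 1, 2, 3),
            n_shared_causal=10, n_discordant_causal=5, n_specific_causal=0,
            effect_size_sd=0.05, prevalence=0.1, seed=7)
        rng = np.random.default_rng(7)
        cohorts, total = sim.build_cohorts(cfg)
        geno = sim.simulate_genotypes(cfg, total, rng)
        truth = sim.simulate_truth(cfg, geno.variants, rng)
        causal = truth.beta != 0
        truth.beta[causal] = 0.05 * np.sign(truth.beta[causal])
        labels, _ = sim.simulate_phenotypes(geno, truth, cfg, rng)
        studies = {f"t{t}": sim.compute_sumstats(geno, labels[:, t],
                                                 cohorts[t])
                   for t in range(4)}

        class Coll:
            pass

        coll = Coll()
        coll.genotypes, coll.truth, coll.studies = geno, truth, studies
        model = meta.estimate_z_correlation(studies)
        res = meta.meta_weighted_z(studies, model)
        conc = meta.concordance_filter(res)
        snp = coll.genotypes.variants["SNP"]
        shared = set(snp[coll.truth.indices("shared")])
        conc_gws = set(conc.loc[conc["P"] < 5e-8, "SNP"])
        assert len(shared & conc_gws) >= 0.9 * len(shared)
        # discordant variants whose per-study signs match the planted
        # (discordant) truth cannot pass the filter
        disc_idx = coll.truth.indices("discordant")
        sign_cols = meta.sign_columns(res)
        res_idx = res.set_index("SNP")
        truth_signs = np.sign(coll.truth.beta[disc_idx])
        leaked = 0
        for row, j in enumerate(disc_idx):
            s = snp.iloc[j]
            if s not in res_idx.index or s not in set(conc["SNP"]):
                continue
            est = res_idx.loc[s, sign_cols].to_numpy(dtype=float)
            if np.array_equal(np.sign(est), truth_signs[row]):
                leaked += 1
        assert leaked == 0
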