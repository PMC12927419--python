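"""Pipeline stages 2-4: genetic values, noise, assembly, normalization,
binarization, multi-graph combination, and the end-to-end wrapper."""

import numpy as np
import pandas as pd
import pytest

import grgsim
from grgsim import (
    DistributionSpec,
    EffectTable,
    FixtureSpec,
    GenotypeMatrix,
    SimConfig,
    assemble_phenotypes,
    binarize,
    build_from_matrix,
    combine_genetic_values,
    draw_effects_standardized,
    environmental_noise,
    generate_matrix,
    genetic_values,
    genetic_values_standardized,
    load_custom_effects,
    normalize,
    sample_causal_mutations,
    sim_phenotypes,
    stage_rng,
)
from conftest import dense_X, dense_standardized_gv


def effect_table(ids, sizes, trait=0):
    return EffectTable(
        pd.DataFrame(
            {"mutation_id": ids, "causal_mutation_id": trait, "effect_size": sizes}
        )
    )


def random_effects(gm, m_causal, seed):
    rng = np.random.default_rng(seed)
    ids = np.sort(rng.choice(gm.num_mutations, size=m_causal, replace=False))
    return effect_table(ids, rng.normal(size=m_causal))


class TestGeneticValues:
    def test_zero_effects_zero_values(self, fig1):
        gv = genetic_values(fig1, effect_table([0, 1, 2], [0.0, 0.0, 0.0]))
        assert (gv.individuals["genetic_value"] == 0).all()

    def test_fig1_single_copy_individual(self, fig1):
        """m2 is carried by samples 1 and 2: the individual owning samples
        (0, 1) holds exactly one copy."""
        gv = genetic_values(fig1, effect_table([2], [1.0]))
        vals = gv.individual_values(0)
        assert vals.tolist() == [1.0, 1.0]  # (0,1) has one copy; (2,3) has one
        hap = gv.samples["genetic_value"].to_numpy()
        assert hap.tolist() == [0.0, 1.0, 1.0, 0.0]

    def test_individual_is_sum_of_its_two_samples(self, medium_gm, medium_grg):
        eff = random_effects(medium_gm, 12, seed=1)
        gv = genetic_values(medium_grg, eff)
        hap = gv.samples["genetic_value"].to_numpy()
        np.testing.assert_array_equal(
            gv.individuals["genetic_value"].to_numpy(), hap[0::2] + hap[1::2]
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_dense_oracle(self, seed):
        gm = generate_matrix(FixtureSpec(n_individuals=20, n_mutations=30, seed=seed))
        grg = build_from_matrix(gm, compress=seed % 2 == 0)
        eff = random_effects(gm, 10, seed=seed + 50)
        beta = eff.beta_vector(gm.num_mutations, 0)
        gv = genetic_values(grg, eff)
        np.testing.assert_allclose(
            gv.individual_values(0), dense_X(gm) @ beta, rtol=1e-10, atol=1e-12
        )

    def test_unknown_mutation_rejected(self, fig1):
        with pytest.raises(ValueError, match="mutation id 5"):
            genetic_values(fig1, effect_table([5], [1.0]))


class TestStandardizedGeneticValues:
    @pytest.mark.parametrize("seed", range(4))
    def test_dense_standardized_oracle(self, seed):
        gm = generate_matrix(FixtureSpec(n_individuals=25, n_mutations=30, seed=seed))
        grg = build_from_matrix(gm)
        eff = random_effects(gm, 8, seed=seed + 90)
        beta = eff.beta_vector(gm.num_mutations, 0)
        gv = genetic_values_standardized(grg, eff)
        np.testing.assert_allclose(
            gv.individual_values(0),
            dense_standardized_gv(gm, beta),
            rtol=1e-10,
            atol=1e-10,
        )

    def test_mean_zero_over_individuals(self, medium_gm, medium_grg):
        eff = random_effects(medium_gm, 15, seed=4)
        gv = genetic_values_standardized(medium_grg, eff)
        assert abs(gv.individual_values(0).mean()) < 1e-9

    def test_monomorphic_causal_site_rejected(self):
        values = np.ones((4, 2), dtype=np.int8)
        values[:, 1] = [0, 1, 0, 1]
        grg = build_from_matrix(GenotypeMatrix(values))
        with pytest.raises(ValueError, match="mutation 0 is monomorphic"):
            genetic_values_standardized(grg, effect_table([0], [1.0]))


class TestEnvironmentalNoise:
    def test_h2_one_gives_exact_zero(self, medium_gm, medium_grg):
        gv = genetic_values(medium_grg, random_effects(medium_gm, 10, seed=2))
        noise = environmental_noise(gv, h2=1.0, rng=np.random.default_rng(0))
        assert (noise["environmental_noise"] == 0).all()

    def test_degenerate_genetic_values_rejected(self, fig1):
        gv = genetic_values(fig1, effect_table([0, 1, 2], [0.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="degenerate"):
            environmental_noise(gv, h2=0.5, rng=np.random.default_rng(0))

    def test_exactly_one_of_h2_or_spec(self, fig1):
        gv = genetic_values(fig1, effect_table([2], [1.0]))
        with pytest.raises(ValueError, match="exactly one"):
            environmental_noise(gv)
        with pytest.raises(ValueError, match="exactly one"):
            environmental_noise(gv, h2=0.5, noise_spec=DistributionSpec())

    def test_monte_carlo_variance_ratio(self, medium_gm, medium_grg):
        """Empirical Var(eps)/V over 200 replicates matches 1/h2 - 1."""
        h2 = 0.5
        gv = genetic_values(medium_grg, random_effects(medium_gm, 10, seed=3))
        v = float(np.var(gv.individual_values(0), ddof=1))
        ratios = []
        for rep in range(200):
            noise = environmental_noise(gv, h2=h2, rng=np.random.default_rng(rep))
            ratios.append(np.var(noise["environmental_noise"], ddof=1) / v)
        target = 1.0 / h2 - 1.0
        mean = np.mean(ratios)
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(mean - target) < 3 * se

    def test_custom_noise_spec(self, medium_gm, medium_grg):
        gv = genetic_values(medium_grg, random_effects(medium_gm, 10, seed=3))
        noise = environmental_noise(
            gv, noise_spec=DistributionSpec(family="fixed", value=2.0),
            rng=np.random.default_rng(0),
        )
        assert (noise["environmental_noise"] == 2.0).all()


class TestAssembleAndNormalize:
    @pytest.fixture
    def pheno(self, medium_gm, medium_grg):
        gv = genetic_values(medium_grg, random_effects(medium_gm, 10, seed=6))
        noise = environmental_noise(gv, h2=0.5, rng=np.random.default_rng(1))
        return assemble_phenotypes(gv, noise)

    def test_additivity_exact(self, pheno):
        df = pheno.df
        np.testing.assert_array_equal(
            df["phenotype"].to_numpy(),
            df["genetic_value"].to_numpy() + df["environmental_noise"].to_numpy(),
        )

    def test_zero_noise_phenotype_equals_genetic_value(self, medium_gm, medium_grg):
        gv = genetic_values(medium_grg, random_effects(medium_gm, 10, seed=6))
        noise = environmental_noise(gv, h2=1.0, rng=np.random.default_rng(0))
        ph = assemble_phenotypes(gv, noise)
        np.testing.assert_array_equal(
            ph.df["phenotype"].to_numpy(), ph.df["genetic_value"].to_numpy()
        )

    def test_standard_normalization_moments(self, pheno):
        out = normalize(pheno, "standard")
        x = out.df["phenotype"].to_numpy()
        assert abs(x.mean()) < 1e-12
        assert abs(x.std(ddof=1) - 1.0) < 1e-12

    def test_quantile_closed_form(self):
        """Inverse-normal transform of (10, 20, 30) hits Phi^-1 of
        (1/6, 3/6, 5/6); constants frozen from the normal quantile function."""
        df = pd.DataFrame(
            {
                "individual_id": ["a", "b", "c"],
                "causal_mutation_id": 0,
                "genetic_value": [0.0, 0.0, 0.0],
                "environmental_noise": [10.0, 20.0, 30.0],
                "phenotype": [10.0, 20.0, 30.0],
            }
        )
        out = normalize(grgsim.PhenotypeTable(df), "quantile")
        np.testing.assert_allclose(
            out.df["normalized_phenotype"].to_numpy(),
            [-0.967421566101701, 0.0, 0.967421566101701],
            atol=1e-12,
        )
        # raw column preserved
        assert out.df["phenotype"].tolist() == [10.0, 20.0, 30.0]

    def test_both_modes_preserve_ranks(self, pheno):
        raw = pheno.df["phenotype"].to_numpy()
        std = normalize(pheno, "standard").df["phenotype"].to_numpy()
        qnt = normalize(pheno, "quantile").df["normalized_phenotype"].to_numpy()
        assert (np.argsort(std) == np.argsort(raw)).all()
        assert (np.argsort(qnt) == np.argsort(raw)).all()

    def test_target_both_touches_genetic_values(self, pheno):
        out = normalize(pheno, "standard", target="both")
        g = out.df["genetic_value"].to_numpy()
        assert abs(g.mean()) < 1e-12 and abs(g.std(ddof=1) - 1.0) < 1e-12
        qout = normalize(pheno, "quantile", target="both")
        assert "normalized_genetic_value" in qout.df.columns

    def test_zero_sd_rejected(self):
        df = pd.DataFrame(
            {
                "individual_id": ["a", "b"],
                "causal_mutation_id": 0,
                "genetic_value": [1.0, 1.0],
                "environmental_noise": [0.0, 0.0],
                "phenotype": [1.0, 1.0],
            }
        )
        with pytest.raises(ValueError, match="standard deviation is zero"):
            normalize(grgsim.PhenotypeTable(df), "standard")


class TestBinarize:
    @pytest.fixture
    def pheno(self, medium_gm, medium_grg):
        gv = genetic_values_standardized(medium_grg, random_effects(medium_gm, 10, seed=8))
        noise = environmental_noise(gv, h2=0.5, rng=np.random.default_rng(2))
        return assemble_phenotypes(gv, noise)

    def test_half_prevalence_threshold_is_zero(self, pheno):
        """K = 0.5 thresholds at Phi^-1(0.5) = 0: above-mean liability = case."""
        out = binarize(pheno, 0.5)
        liability = pheno.df["phenotype"].to_numpy()
        std = (liability - liability.mean()) / liability.std(ddof=1)
        np.testing.assert_array_equal(
            out.df["phenotype"].to_numpy(), (std > 0).astype(float)
        )

    def test_rejects_bad_prevalence(self, pheno):
        for k in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError, match="prevalence"):
                binarize(pheno, k)

    def test_rejects_already_binary(self, pheno):
        once = binarize(pheno, 0.3)
        with pytest.raises(ValueError, match="already binary"):
            binarize(once, 0.3)


class TestCombine:
    def test_single_input_identity(self, medium_gm, medium_grg):
        gv = genetic_values(medium_grg, random_effects(medium_gm, 5, seed=9))
        out = combine_genetic_values([gv])
        pd.testing.assert_frame_equal(out.individuals, gv.individuals)

    @pytest.mark.parametrize("n_parts", [2, 3, 5])
    def test_column_split_equals_single_graph_exactly(self, n_parts):
        """Splitting the mutation columns across graphs and combining
        reproduces the single-graph genetic values exactly (integer effects
        keep every intermediate value exact in float arithmetic)."""
        gm = generate_matrix(FixtureSpec(n_individuals=20, n_mutations=30, seed=13))
        rng = np.random.default_rng(77)
        beta = rng.integers(-3, 4, size=30).astype(float)
        full = genetic_values(
            build_from_matrix(gm), effect_table(np.arange(30), beta)
        )
        bounds = np.linspace(0, 30, n_parts + 1).astype(int)
        parts = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            sub = GenotypeMatrix(
                gm.values[:, lo:hi], individual_ids=list(gm.individual_ids)
            )
            eff = effect_table(np.arange(hi - lo), beta[lo:hi])
            parts.append(genetic_values(build_from_matrix(sub), eff))
        combined = combine_genetic_values(parts)
        np.testing.assert_array_equal(
            combined.individuals["genetic_value"].to_numpy(),
            full.individuals["genetic_value"].to_numpy(),
        )

    def test_zero_effect_second_graph_changes_nothing(self, medium_gm, medium_grg):
        gv = genetic_values(medium_grg, random_effects(medium_gm, 5, seed=9))
        zero = genetic_values(medium_grg, effect_table([0], [0.0]))
        out = combine_genetic_values([gv, zero])
        np.testing.assert_array_equal(
            out.individuals["genetic_value"].to_numpy(),
            gv.individuals["genetic_value"].to_numpy(),
        )

    def test_mismatched_individuals_named(self, medium_gm, medium_grg):
        gv = genetic_values(medium_grg, random_effects(medium_gm, 5, seed=9))
        other = generate_matrix(FixtureSpec(n_individuals=50, n_mutations=5, seed=1))
        other.individual_ids[3] = "stranger"
        gv2 = genetic_values(build_from_matrix(other), effect_table([0], [1.0]))
        with pytest.raises(ValueError, match="position 3.*stranger"):
            combine_genetic_values([gv, gv2])


class TestSimPhenotypes:
    def test_h2_one_fixed_effects_deterministic(self, medium_grg):
        config = SimConfig(
            m_causal=5,
            heritability=1.0,
            standardized=False,
            distribution=DistributionSpec(family="fixed", value=1.0),
            seed=3,
        )
        ph = sim_phenotypes(medium_grg, config)
        np.testing.assert_array_equal(
            ph.df["phenotype"].to_numpy(), ph.df["genetic_value"].to_numpy()
        )

    def test_same_seed_identical_runs(self, medium_grg):
        a = sim_phenotypes(medium_grg, heritability=0.4, m_causal=8, seed=5)
        b = sim_phenotypes(medium_grg, heritability=0.4, m_causal=8, seed=5)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_composition_identity(self, medium_grg):
        """The wrapper equals composing the stages by hand with the same
        per-stage substreams."""
        seed, m_causal, h2 = 17, 8, 0.6
        wrapped = sim_phenotypes(medium_grg, heritability=h2, m_causal=m_causal, seed=seed)

        causal = sample_causal_mutations(medium_grg, m_causal, stage_rng(seed, "causal"))
        pooled = draw_effects_standardized(h2, np.arange(m_causal), stage_rng(seed, "effects"))
        eff = EffectTable(
            pooled.df.assign(mutation_id=pooled.df["mutation_id"].map(dict(enumerate(causal))))
        )
        gv = genetic_values_standardized(medium_grg, eff)
        noise = environmental_noise(gv, h2=h2, rng={0: stage_rng(seed, "noise", 0)})
        manual = assemble_phenotypes(gv, noise)
        pd.testing.assert_frame_equal(wrapped.df, manual.df)

    def test_end_to_end_dense_pipeline_oracle(self):
        """Whole pipeline vs a dense-matrix re-implementation sharing the
        same effect and noise draws: identical genetic values and phenotypes."""
        gm = generate_matrix(FixtureSpec(n_individuals=40, n_mutations=60, seed=21))
        grg = build_from_matrix(gm)
        seed, m_causal, h2 = 31, 12, 0.5
        ph = sim_phenotypes(grg, heritability=h2, m_causal=m_causal, seed=seed)

        # dense route, graph-free, same substreams
        f = np.asarray(gm.values, dtype=float).mean(axis=0)
        eligible = np.flatnonzero((f > 0) & (f < 1))
        idx = np.sort(
            stage_rng(seed, "causal").choice(eligible.size, size=m_causal, replace=False)
        )
        causal = eligible[idx]
        beta_draws = stage_rng(seed, "effects").normal(
            0.0, np.sqrt(h2 / m_causal), size=m_causal
        )
        x = dense_X(gm)
        sigma = np.sqrt(2.0 * f * (1.0 - f))
        xs = (x[:, causal] - 2.0 * f[causal]) / sigma[causal]
        gvals = xs @ beta_draws
        v = np.var(gvals, ddof=1)
        eps = stage_rng(seed, "noise", 0).normal(
            0.0, np.sqrt(v * (1 / h2 - 1)), size=gvals.size
        )
        np.testing.assert_allclose(
            ph.df["genetic_value"].to_numpy(), gvals, rtol=1e-10, atol=1e-12
        )
        np.testing.assert_allclose(
            ph.df["phenotype"].to_numpy(), gvals + eps, rtol=1e-10, atol=1e-12
        )

    def test_multi_trait_run(self, medium_grg):
        config = SimConfig(
            m_causal=6,
            heritability=0.5,
            standardized=False,
            distribution=DistributionSpec(
                family="normal", num_traits=2, covariance=np.eye(2)
            ),
            seed=2,
        )
        ph = sim_phenotypes(medium_grg, config)
        assert ph.trait_ids == [0, 1]
        assert len(ph.df) == 2 * medium_grg.num_individuals

    def test_binary_run_prevalence(self, medium_grg):
        ph = sim_phenotypes(
            medium_grg, heritability=0.5, m_causal=8, prevalence=0.3, seed=4
        )
        assert set(np.unique(ph.df["phenotype"])) <= {0.0, 1.0}

    def test_stage_error_propagates_with_numbers(self, medium_grg):
        with pytest.raises(ValueError, match="m_causal=999 exceeds"):
            sim_phenotypes(medium_grg, heritability=0.5, m_causal=999, seed=0)

    def test_outputs_written(self, tmp_path, medium_grg):
        prefix = str(tmp_path / "run")
        sim_phenotypes(
            medium_grg, heritability=0.5, m_causal=4, seed=6, output_prefix=prefix
        )
        for suffix in (
            ".effects.tsv",
            ".genetic_values.samples.tsv",
            ".genetic_values.individuals.tsv",
            ".phenotypes.tsv",
            ".par",
            ".phen",
        ):
            assert (tmp_path / f"run{suffix}").exists()
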