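"""Forward simulator: architecture, DFE, life cycle, load bookkeeping, scenarios."""

import numpy as np
import pytest
from scipy import stats

from strigops import simulate as sim
from strigops.simulate import (DfeParams, LifeHistoryParams, LoadSummary,
                               Population, additive_load, build_architecture,
                               burn_in, compare_scenarios,
                               desk_scale_architecture, make_scenario,
                               mutation_class, mutation_rate_per_generation,
                               realized_generation_time, run_scenario,
                               sample_mutation, sample_selection_coefficients,
                               summarize_sample)


class TestArchitecture:
    def test_default_totals(self):
        arch = build_architecture()
        assert arch.n_genes == 3291 and arch.n_chromosomes == 23
        assert arch.total_bp == 4_936_500

    def test_small_layout(self):
        arch = build_architecture(n_genes=10, gene_length=100,
                                  n_chromosomes=2)
        assert arch.total_bp == 1000

    def test_proportional_allocation(self):
        arch = build_architecture(n_genes=40, n_chromosomes=3,
                                  weights=(2, 1, 1))
        assert arch.chrom_gene_counts().tolist() == [20, 10, 10]

    def test_desk_scale_preserves_genomic_mutation_input(self):
        arch = build_architecture()
        scaled = desk_scale_architecture(arch, 20)
        assert scaled.mu_per_gamete == pytest.approx(arch.mu_per_gamete)
        assert scaled.n_genes == pytest.approx(arch.n_genes / 20, rel=0.05)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            build_architecture(n_genes=0)
        with pytest.raises(ValueError):
            build_architecture(weights=(1, 2))  # wrong length

    def test_per_generation_rate_from_yearly_rate(self):
        assert mutation_rate_per_generation(0.89e-9, 15.0) == \
            pytest.approx(1.33e-8, abs=0.01e-8)


class TestDfe:
    def test_deleterious_fraction(self, rng):
        s = sample_selection_coefficients(rng, DfeParams(), 200_000)
        frac = (s < 0).mean()
        expected = 2.31 / 3.31
        sd = np.sqrt(expected * (1 - expected) / 200_000)
        assert abs(frac - expected) < 3 * sd

    def test_gamma_moments_uncapped(self, rng):
        s = sample_selection_coefficients(rng, DfeParams(), 10 ** 6,
                                          floor=False)
        s = s[s < 0]
        se = 0.14 / np.sqrt(len(s))
        assert abs(s.mean() + 0.024) < 3 * se
        assert s.std() == pytest.approx(0.14, rel=0.05)

    def test_floor_bounds_draws(self, rng):
        s = sample_selection_coefficients(rng, DfeParams(), 100_000)
        assert (s >= -1.0).all() and (s <= 0.0).all()

    def test_classes(self):
        assert mutation_class(0.0) == "neutral"
        assert mutation_class(-0.0005) == "weak"
        assert mutation_class(-0.001) == "weak"
        assert mutation_class(-0.005) == "mild"
        assert mutation_class(-0.01) == "mild"
        assert mutation_class(-0.5) == "strong"

    def test_sample_mutation_record(self, rng):
        arch = build_architecture(n_genes=10, n_chromosomes=2)
        rec = sample_mutation(rng, DfeParams(neutral_only=True), arch)
        assert rec.s == 0.0 and rec.mclass == "neutral"
        assert 0 <= rec.gene < 10 and 0 <= rec.offset < 1500


def small_arch(**kw):
    kw.setdefault("n_genes", 50)
    kw.setdefault("n_chromosomes", 5)
    kw.setdefault("genome_span", 5e7)
    return build_architecture(**kw)


def make_pop(n=60, dfe=None, life=None, seed=0, arch=None, **kw):
    return Population(arch or small_arch(), dfe or DfeParams(),
                      life or LifeHistoryParams(),
                      np.random.default_rng(seed), n_init=n, **kw)


class TestLifeCycle:
    def test_no_mature_females_no_offspring(self):
        pop = make_pop(20)
        pop.is_male[:] = True
        pop.step(100)
        assert pop.births_male + pop.births_female == 0

    def test_no_mature_males_no_offspring(self):
        pop = make_pop(20)
        pop.is_male[:] = False
        pop.step(100)
        assert pop.births_male + pop.births_female == 0

    def test_newborn_sex_ratio_two_to_one(self):
        pop = make_pop(400, seed=3)
        for _ in range(300):
            pop.step(400)
        births = pop.births_male + pop.births_female
        assert births > 10_000
        # binomial test against p = 2/3
        res = stats.binomtest(pop.births_male, births, p=2 / 3)
        assert res.pvalue > 1e-4

    def test_maturity_ranges(self):
        pop = make_pop(2000, seed=1)
        males = pop.maturity[pop.is_male]
        females = pop.maturity[~pop.is_male]
        assert males.min() >= 5 and males.max() <= 7
        assert females.min() >= 7 and females.max() <= 11

    def test_survival_expectation_when_overcrowded(self):
        """N >> K: expected survivors ~ K x base adult survival."""
        pop = make_pop(4000, dfe=DfeParams(neutral_only=True), seed=5)
        pop.age[:] = 20  # adults
        pop.is_male[:] = True  # no births
        K = 400
        pop._survive(K)
        expected = K * pop.life.adult_survival
        sd = np.sqrt(4000 * (expected / 4000) * (1 - expected / 4000))
        assert abs(pop.size - expected) < 4 * sd

    def test_max_age_is_lethal(self):
        pop = make_pop(50)
        pop.age[:] = pop.life.max_age + 1
        pop._survive(10 ** 9)
        assert pop.size == 0 and pop.extinct is False  # flag set by step()

    def test_all_neutral_fitness_is_one(self):
        pop = make_pop(100, dfe=DfeParams(neutral_only=True))
        for _ in range(50):
            pop.step(100)
        assert (pop.w == 1.0).all()

    def test_single_hom_mutation_fitness(self):
        pop = make_pop(10)
        pop.n_mut = 1
        pop.mut_s[0] = -0.5
        g = np.array([0], dtype=np.int64)
        assert pop._fitness(g, g) == pytest.approx(0.5)
        # heterozygous with h = 0 is neutral
        assert pop._fitness(g, np.empty(0, dtype=np.int64)) == 1.0

    def test_batch_fitness_matches_scalar(self):
        pop = make_pop(150, dfe=DfeParams(h=0.25), seed=7)
        for _ in range(150):
            pop.step(150)
        scalar = np.array([pop._fitness(pop.hap_a[i], pop.hap_b[i])
                           for i in range(pop.size)])
        batch = pop._fitness_batch(pop.hap_a, pop.hap_b)
        np.testing.assert_allclose(batch, scalar, rtol=1e-12)

    def test_no_recombination_single_parental_blocks(self):
        arch = small_arch(recombination_rate=0.0)
        pop = make_pop(10, arch=arch)
        # parent carries disjoint marker sets on its two haplotypes
        pop.n_mut = arch.n_genes * 2
        genes = np.concatenate([np.arange(arch.n_genes)] * 2)
        pop.mut_gene[:pop.n_mut] = genes
        pop.mut_chrom[:pop.n_mut] = arch.chrom_of_gene[genes]
        pop.hap_a[0] = np.arange(arch.n_genes, dtype=np.int64)
        pop.hap_b[0] = np.arange(arch.n_genes, 2 * arch.n_genes,
                                 dtype=np.int64)
        for _ in range(20):
            g = pop._gamete(0)
            source = np.where(g < arch.n_genes, 0, 1)
            chrom = pop.mut_chrom[g]
            for c in range(arch.n_chromosomes):
                assert len(set(source[chrom == c])) <= 1


class TestLoadAccounting:
    def test_additive_load_examples(self):
        s = np.array([-0.01, -0.02])
        h = np.array([0.25, 0.25])
        empty = np.empty(0, dtype=np.int64)
        assert additive_load(empty, empty, s, h) == 0.0
        # hom s=-0.01 plus het s=-0.02 with h=0.25: 0.01 + 0.005
        a = np.array([0, 1], dtype=np.int64)
        b = np.array([0], dtype=np.int64)
        assert additive_load(a, b, s, h) == pytest.approx(0.015)
        # fully recessive: heterozygotes contribute nothing
        h0 = np.zeros(2)
        assert additive_load(a, b, s, h0) == pytest.approx(0.01)
        assert additive_load(a, b, s, h, fixed_load=0.5) == pytest.approx(0.515)

    def test_mutation_count_conservation(self):
        """Per-mutation carrier counts equal a brute-force haplotype scan."""
        pop = make_pop(80, seed=2)
        for _ in range(120):
            pop.step(80)
        counts = pop.mutation_counts()
        brute = np.zeros(pop.n_mut, dtype=int)
        for hap in pop.hap_a + pop.hap_b:
            for m in hap:
                brute[m] += 1
        np.testing.assert_array_equal(counts, brute)

    def test_remove_fixed_preserves_individual_loads(self):
        pop = make_pop(40, seed=4)
        for _ in range(80):
            pop.step(40)
        # force one deleterious mutation to fixation
        pop.n_mut += 1
        fid = pop.n_mut - 1
        pop.mut_s[fid] = -0.123
        pop.mut_h[fid] = pop.dfe.h
        pop.hap_a = [np.sort(np.append(h, fid)) for h in pop.hap_a]
        pop.hap_b = [np.sort(np.append(h, fid)) for h in pop.hap_b]
        before = np.array([pop.load_of(i) for i in range(pop.size)])
        removed = pop.remove_fixed()
        assert removed >= 1
        after = np.array([pop.load_of(i) for i in range(pop.size)])
        np.testing.assert_allclose(after, before, rtol=1e-12)
        assert all(fid not in h for h in pop.hap_a + pop.hap_b)

    def test_neutral_population_has_zero_load(self):
        pop = make_pop(60, dfe=DfeParams(neutral_only=True), seed=6,
                       arch=small_arch(mu=1e-5))
        for _ in range(100):
            pop.step(60)
        summary = summarize_sample(pop, n=30)
        assert (summary.loads == 0).all()
        assert (summary.class_counts[["weak", "mild", "strong"]].to_numpy()
                == 0).all()
        assert summary.class_counts["neutral"].sum() > 0

    def test_zero_mutation_rate_keeps_pi_zero(self):
        arch = small_arch(mu=0.0)
        pop = make_pop(50, arch=arch, seed=1)
        for _ in range(60):
            pop.step(50)
        assert pop.pi() == 0.0 and pop.n_mut == 0

    def test_summarize_small_population_flagged(self):
        pop = make_pop(30, seed=9)
        summary = summarize_sample(pop, n=200)
        assert summary.whole_population and summary.sample_size == 30

    def test_hand_built_counts(self):
        pop = make_pop(10)
        pop.n_mut = 3
        pop.mut_s[:3] = [0.0, -0.0005, -0.5]
        pop.hap_a[0] = np.array([0, 1], dtype=np.int64)
        pop.hap_b[0] = np.array([1, 2], dtype=np.int64)
        counts = pop.class_allele_counts(0)
        assert counts == {"neutral": 1, "weak": 2, "mild": 0, "strong": 1}


class TestPedigreeAndNe:
    def test_generation_time_arithmetic(self):
        assert realized_generation_time([10, 10]) == (10.0, 0.0)
        mean, sd = realized_generation_time([10, 20])
        assert (mean, sd) == (15.0, 5.0)
        with pytest.raises(ValueError):
            realized_generation_time([])

    def test_ne_estimator_recovers_wright_fisher(self):
        rng = np.random.default_rng(0)
        N = 300
        f = np.full(512, 0.5)
        H = []
        for _ in range(1200):
            f = rng.binomial(2 * N, f) / (2 * N)
            H.append(np.mean(2 * f * (1 - f)))
        ne = sim.estimate_ne_from_het_decay(H, generation_time=1.0)
        assert ne == pytest.approx(N, rel=0.2)

    def test_marker_inheritance_keeps_frequency(self):
        pop = make_pop(200, dfe=DfeParams(neutral_only=True), seed=8,
                       n_markers=64)
        h0 = pop.marker_heterozygosity()
        for _ in range(30):
            pop.step(200)
        # 30 steps of drift at Ne ~ 50+ cannot erase heterozygosity
        assert 0.7 * h0 < pop.marker_heterozygosity() <= h0 * 1.05


class TestScenarios:
    def test_trajectories(self):
        s = make_scenario("stable", steps=100, scale=20)
        assert s.steps == 100
        assert (s.K == s.K[0]).all()
        assert s.K[0] == pytest.approx(2.8 * 10_000 / 20)
        d = make_scenario("stewart_island", steps=1000, scale=20)
        assert d.K[0] == pytest.approx(1400)
        assert d.K[-1] == pytest.approx(140)
        assert (np.diff(d.K[:200]) <= 0).all()

    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            make_scenario("atlantis", steps=10)

    def test_zero_capacity_extinction_flag(self):
        arch = small_arch()
        scen = sim.DemographicScenario("doom", np.zeros(50))
        pop = make_pop(50)
        res = run_scenario(scen, arch, pop.dfe, pop.life,
                           np.random.default_rng(0),
                           burnin=sim.BurnInResult(pop, np.array([]), True,
                                                   0, 0))
        assert res.extinct and res.summary is None
        assert res.trajectory["N"].iloc[-1] == 0

    def test_stable_regulation_cv(self):
        """Population fluctuates around K with a small CV."""
        pop = make_pop(300, dfe=DfeParams(neutral_only=True), seed=11)
        sizes = []
        for _ in range(400):
            pop.step(300)
            sizes.append(pop.size)
        sizes = np.array(sizes[100:])
        assert sizes.std() / sizes.mean() < 0.2
        assert abs(sizes.mean() - 300) / 300 < 0.3

    def test_burn_in_zero_mutation_rate(self):
        arch = small_arch(mu=0.0)
        res = burn_in(arch, DfeParams(neutral_only=True), LifeHistoryParams(),
                      K=60, rng=np.random.default_rng(0), scaled_steps=30,
                      equil_min=20, equil_max=40, trend_window=20)
        assert np.allclose(res.pi_series, 0.0)
        assert res.stationary  # constant series is trivially flat

    def test_truncated_burn_in_flagged(self):
        arch = small_arch()
        res = burn_in(arch, DfeParams(), LifeHistoryParams(), K=80,
                      rng=np.random.default_rng(1), scaled_steps=5,
                      equil_min=30, equil_max=30, trend_window=60)
        assert not res.stationary


class TestCompareScenarios:
    @staticmethod
    def _summary(loads, counts):
        import pandas as pd

        loads = np.asarray(loads, dtype=float)
        cc = pd.DataFrame({"neutral": counts, "weak": counts,
                           "mild": counts, "strong": counts})
        return LoadSummary(loads=loads, class_counts=cc,
                           sample_size=len(loads), whole_population=False,
                           mean_load=float(loads.mean()), ci_low=0, ci_high=0)

    def test_identical_replicates_give_p_one(self):
        reps = [self._summary([1.0, 1.1], [3, 4]) for _ in range(5)]
        table = compare_scenarios({"a": reps, "b": list(reps)})
        load_row = table[table["metric"] == "load"].iloc[0]
        assert load_row["p"] == pytest.approx(1.0)
        assert load_row["mean_a"] == load_row["mean_b"]

    def test_planted_shift_detected(self, rng):
        a = [self._summary(rng.normal(1.0, 0.1, 50), [5] * 50)
             for _ in range(10)]
        b = [self._summary(rng.normal(1.3, 0.1, 50), [5] * 50)
             for _ in range(10)]
        # replicate means shifted by ~3 replicate-level SDs
        table = compare_scenarios({"a": a, "b": b})
        assert table[table["metric"] == "load"]["p"].iloc[0] < 0.01

    def test_single_replicate_descriptive_only(self):
        table = compare_scenarios({"a": [self._summary([1.0], [1])],
                                   "b": [self._summary([2.0], [2])]})
        assert table["p"].isna().all()


def test_sample_export_round_trips_through_statistics():
    """Sampled simulated genomes export to a polarized matrix the empirical
    statistics accept, with dosages matching the haplotype contents."""
    from strigops import loadstats

    arch = small_arch(mu=1e-5)
    pop = make_pop(80, arch=arch, seed=12)
    for _ in range(150):
        pop.step(80)
    gm, ann = sim.sample_to_genotype_matrix(pop, n=40, population_label="sim")
    assert gm.is_complete
    assert gm.n_samples == min(40, pop.size)
    # positions strictly increasing per chromosome was enforced on build;
    # spot-check dosages against the haplotypes for one individual
    take_total = gm.dosage.sum()
    assert take_total > 0
    div = loadstats.diversity(gm, window=10 ** 7)
    assert (div.windows["pi"] >= 0).all()
    dm = loadstats.distance_matrix(gm)
    assert np.allclose(dm.D, dm.D.T)


def test_extreme_decline_increases_load_over_stable():
    """Strong drift raises additive genetic load relative to a stable
    population (run at divisor 10 so the Extreme deme does not vanish)."""
    arch = desk_scale_architecture(build_architecture(), 10)
    life = LifeHistoryParams()
    dfe = DfeParams(h=0.0)
    loads = {"extreme": [], "stable": []}
    for name in loads:
        for r in range(3):
            rng = np.random.default_rng(300 + r + (0 if name == "stable" else 50))
            scen = make_scenario(name, steps=1200, scale=10)
            res = run_scenario(scen, arch, dfe, life, rng, sample_n=200)
            if res.summary is not None:
                loads[name].append(res.summary.mean_load)
    assert len(loads["extreme"]) >= 2
    assert np.mean(loads["extreme"]) > np.mean(loads["stable"])


def test_neutral_equilibrium_diversity_matches_theta():
    """Neutral pi at drift-mutation equilibrium approaches 4 Ne mu.

    A small neutral population is run well past 2 Ne generations; Ne is
    measured from marker-heterozygosity decay and pi is averaged over the
    trailing half with a block-resampled standard error.
    """
    arch = desk_scale_architecture(build_architecture(), 20)
    pop = Population(arch, DfeParams(neutral_only=True), LifeHistoryParams(),
                     np.random.default_rng(42), n_init=140, n_markers=256)
    H, pis = [], []
    for t in range(2600):
        pop.step(140)
        if t % 25 == 0:
            pop.remove_fixed()
        H.append(pop.marker_heterozygosity())
        if t >= 1300 and t % 10 == 0:
            pis.append(pop.pi())
    gen, _ = realized_generation_time(pop.parent_ages)
    ne = sim.estimate_ne_from_het_decay(H, gen)
    theta = 4 * ne * arch.mu
    pis = np.array(pis)
    blocks = np.array_split(pis, 6)
    block_means = np.array([b.mean() for b in blocks])
    se = block_means.std(ddof=1) / np.sqrt(len(blocks))
    assert abs(pis.mean() - theta) < 2 * se + 0.3 * theta
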