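import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coopreset import fungi as f


class TestGrowColony:
    def test_monomorphic_spore_stays_fixed(self):
        spore = f.ColonyState(np.array([20, 0]))
        col = f.grow_colony(spore, 7, seed=0)
        assert col.genotype_counts.tolist() == [2560, 0]

    def test_total_multiplies_by_two_to_the_rounds(self):
        col = f.grow_colony(f.ColonyState(np.array([7, 13])), 7, seed=1)
        assert col.total == 20 * 2**7

    def test_frequency_is_a_martingale(self):
        """Urn growth keeps the expected genotype frequency at its spore
        value (checked over replicates within 3 SE)."""
        freqs = []
        for rep in range(4000):
            col = f.grow_colony(f.ColonyState(np.array([3, 7])), 3, seed=rep)
            freqs.append(col.fractions[0])
        freqs = np.asarray(freqs)
        se = freqs.std(ddof=1) / np.sqrt(freqs.size)
        assert abs(freqs.mean() - 0.3) < 3 * se

    def test_sequential_and_exact_growth_share_a_law(self):
        """The closed-form Dirichlet-multinomial draw and the literal
        birth-by-birth urn produce the same distribution (mean and variance
        of the added composition compared at 3 SE)."""
        n0_seq, n0_exact = [], []
        for rep in range(1500):
            seq = f.grow_colony(f.ColonyState(np.array([2, 3])), 2,
                                seed=rep, method="sequential")
            exa = f.grow_colony(f.ColonyState(np.array([2, 3])), 2,
                                seed=rep, method="exact")
            n0_seq.append(seq.genotype_counts[0])
            n0_exact.append(exa.genotype_counts[0])
        a, b = np.asarray(n0_seq, float), np.asarray(n0_exact, float)
        se_mean = np.hypot(a.std(ddof=1), b.std(ddof=1)) / np.sqrt(a.size)
        assert abs(a.mean() - b.mean()) < 3 * se_mean
        assert a.var(ddof=1) == pytest.approx(b.var(ddof=1), rel=0.15)


class TestSporulate:
    def test_fixed_colony_gives_fixed_spore(self):
        spore = f.sporulate(f.ColonyState(np.array([0, 2560])), 20, seed=0)
        assert spore.genotype_counts.tolist() == [0, 20]

    def test_oversized_spore_rejected(self):
        with pytest.raises(ValueError):
            f.sporulate(f.ColonyState(np.array([5, 5])), 11)

    def test_spore_frequency_unbiased(self):
        freqs = [
            f.sporulate(f.ColonyState(np.array([1280, 1280])), 20, seed=r)
            .fractions[0]
            for r in range(2000)
        ]
        freqs = np.asarray(freqs)
        se = freqs.std(ddof=1) / np.sqrt(freqs.size)
        assert abs(freqs.mean() - 0.5) < 3 * se


class TestAnastomose:
    def test_totals_conserved_exactly(self):
        a = f.ColonyState(np.array([100, 0]))
        b = f.ColonyState(np.array([0, 100]))
        na, nb = f.anastomose(a, b, seed=0)
        assert (na.genotype_counts + nb.genotype_counts).tolist() == [100, 100]

    def test_symmetric_expected_split(self):
        fracs = []
        for rep in range(2000):
            na, _ = f.anastomose(
                f.ColonyState(np.array([50, 0])),
                f.ColonyState(np.array([0, 50])),
                seed=rep,
            )
            fracs.append(na.fractions[0])
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / np.sqrt(fracs.size)
        assert abs(fracs.mean() - 0.5) < 3 * se

    def test_equal_colonies_keep_expected_composition(self):
        fracs = []
        for rep in range(2000):
            na, _ = f.anastomose(
                f.ColonyState(np.array([30, 70])),
                f.ColonyState(np.array([30, 70])),
                seed=rep,
            )
            fracs.append(na.fractions[0])
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / np.sqrt(fracs.size)
        assert abs(fracs.mean() - 0.3) < 3 * se

    def test_deterministic_mode_averages(self):
        na, nb = f.anastomose(
            f.ColonyState(np.array([100, 0])),
            f.ColonyState(np.array([0, 100])),
            averaging_mode="deterministic",
        )
        assert na.genotype_counts.tolist() == [50, 50]
        assert nb.genotype_counts.tolist() == [50, 50]

    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 500), st.integers(0, 500)).filter(
                lambda t: sum(t) > 0
            ),
            min_size=2,
            max_size=2,
        ),
        seed=st.integers(0, 1000),
    )
    def test_conservation_property(self, counts, seed):
        a = f.ColonyState(np.array(counts[0]))
        b = f.ColonyState(np.array(counts[1]))
        na, nb = f.anastomose(a, b, seed=seed)
        total = a.genotype_counts + b.genotype_counts
        assert np.array_equal(na.genotype_counts + nb.genotype_counts, total)
        assert na.total == a.total and nb.total == b.total


class TestGenerations:
    def test_single_isolated_colony_eventually_fixes(self):
        p = f.FungalParams(n_colonies=1, spore_size=5, division_rounds=4,
                           p_anastomosis=0.0, generations=120, seed=0)
        reports = f.run_generations(p)
        assert reports[-1].fraction_fixed == 1.0

    def test_fixation_decreases_with_anastomosis(self):
        """Matched seeds: more hyphal fusion, less fixation after 15
        generations; and the ordering holds across spore sizes."""
        for ns in (5, 10, 20):
            fixed = []
            for p_an in (0.0, 0.12, 0.25, 0.5):
                p = f.FungalParams(n_colonies=600, spore_size=ns,
                                   division_rounds=5, p_anastomosis=p_an,
                                   generations=15, seed=99)
                fixed.append(f.run_generations(p)[-1].fraction_fixed)
            assert fixed == sorted(fixed, reverse=True), (ns, fixed)

    def test_heterozygosity_decays_without_fusion(self):
        p = f.FungalParams(n_colonies=500, spore_size=10, division_rounds=5,
                           p_anastomosis=0.0, generations=10, seed=1)
        reports = f.run_generations(p)
        het = [r.heterozygosity for r in reports]
        assert het[-1] < het[0] * 0.7

    def test_report_schema(self):
        p = f.FungalParams(n_colonies=50, spore_size=10, division_rounds=3,
                           p_anastomosis=0.25, generations=4, seed=2)
        reports = f.run_generations(p)
        assert [r.generation for r in reports] == [1, 2, 3, 4]
        assert all(r.minor_fraction.shape == (50,) for r in reports)
        assert all(0 <= r.fraction_fixed <= 1 for r in reports)


class TestMutantFixation:
    def test_probability_is_reciprocal_spore_size(self):
        """Neutral martingale: a single mutant nucleus in a spore of N_s
        fixes with probability 1/N_s (colony level, no fusion)."""
        p = f.FungalParams(spore_size=5, division_rounds=7, p_anastomosis=0.0)
        est = f.mutant_fixation_probability(p, 2000, seed=3)
        assert est.n_censored == 0
        assert abs(est.probability - 0.2) < 3 * est.se

    def test_fusion_suppresses_colony_level_fixation(self):
        base = dict(spore_size=5, division_rounds=5, n_colonies=60,
                    generations=25)
        p_solo = f.FungalParams(p_anastomosis=0.0, **base)
        p_fuse = f.FungalParams(p_anastomosis=0.25, **base)
        solo = f.mutant_fixation_probability(p_solo, 400, seed=4,
                                             max_generations=60)
        fuse = f.mutant_fixation_probability(p_fuse, 400, seed=4,
                                             max_generations=60)
        assert fuse.probability < solo.probability

    def test_absent_mutant_never_appears(self):
        """A genotype with zero nuclei is an absorbing absence: it can never
        re-enter through growth, sporulation or fusion."""
        from coopreset.fungi import _grow_counts, _sporulate_counts

        rng = np.random.default_rng(5)
        spores = np.tile([0, 5], (200, 1)).astype(np.int64)
        for _ in range(5):
            grown = _grow_counts(spores, 4, rng)
            assert int(grown[:, 0].sum()) == 0
            spores = _sporulate_counts(grown, 5, rng)
        assert int(spores[:, 0].sum()) == 0

    def test_global_frequency_is_martingale_through_cycles(self):
        """Mean mutant frequency across replicate colonies stays at its
        initial value 1/N_s through growth+sporulation cycles (3 SE)."""
        ns, reps, gens = 10, 1500, 6
        rng = np.random.default_rng(6)
        from coopreset.fungi import _grow_counts, _sporulate_counts

        spores = np.tile([1, ns - 1], (reps, 1)).astype(np.int64)
        for _ in range(gens):
            grown = _grow_counts(spores, 4, rng)
            spores = _sporulate_counts(grown, ns, rng)
        freq = spores[:, 0] / ns
        se = freq.std(ddof=1) / np.sqrt(reps)
        assert abs(freq.mean() - 1 / ns) < 3 * se


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        f.FungalParams(spore_size=0)
    with pytest.raises(ValueError):
        f.FungalParams(p_anastomosis=1.5)
    with pytest.raises(ValueError):
        f.FungalParams(initial_fractions=(0.7, 0.7))
    with pytest.raises(ValueError):
        f.ColonyState(np.array([0, 0]))
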