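"""Coalescent simulator: priors, demography routing, reproducibility, and
distributional checks against closed-form expectations."""

import io

import numpy as np
import pytest
from scipy import stats as sps

from polyorigins import (
    LocusSpec,
    PolyploidScenario,
    PriorSet,
    ScenarioParameters,
    sample_prior,
    simulate_dataset,
    simulate_locus,
)
from polyorigins.coalsim import SIX_MODELS, write_ms_block


def degenerate_params(n_anc=2e4):
    """T_split = T_WGD ~ 0: every lineage coalesces in one panmictic deme."""
    return ScenarioParameters(
        N_dip=1e4, N_ext=1e4, N_tet=1e4, N_anc=n_anc,
        T_split=1e-6, T_WGD=1e-6, m_dip_to_A=0, m_dip_to_B=0,
        generation_time=2.0,
    )


class TestScenarioTypes:
    def test_six_model_set(self):
        assert len(SIX_MODELS) == 6
        assert all(m.inheritance == "tetrasomic" for m in SIX_MODELS)
        assert len({m.key for m in SIX_MODELS}) == 6

    def test_unknown_enum_rejected(self):
        with pytest.raises(ValueError):
            PolyploidScenario("hexaploid", "tetrasomic", "none")

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"T_WGD": 2e5, "T_split": 1e5},  # WGD after split
            {"N_tet": -1},
            {"m_dip_to_A": 0.7},
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            ScenarioParameters(**kwargs).validate()

    def test_tetrasomic_forbids_disomic_loci(self):
        params = ScenarioParameters(n_disomic_loci=3)
        with pytest.raises(ValueError):
            params.validate(PolyploidScenario(inheritance="tetrasomic"))


class TestSamplePrior:
    def test_reproducible(self):
        priors = PriorSet()
        assert sample_prior(priors, 42) == sample_prior(priors, 42)

    def test_joint_constraint_always_satisfied(self):
        priors = PriorSet()
        rng = np.random.default_rng(0)
        for _ in range(2000):
            p = sample_prior(priors, int(rng.integers(1, 2**31)))
            assert p.T_WGD <= p.T_split
            p.validate()

    def test_tsplit_marginal_is_uniform(self):
        priors = PriorSet()
        rng = np.random.default_rng(1)
        draws = [
            sample_prior(priors, int(rng.integers(1, 2**31))).T_split for _ in range(10_000)
        ]
        ks = sps.kstest(draws, sps.uniform(priors.T_split[0],
                                           priors.T_split[1] - priors.T_split[0]).cdf)
        assert ks.pvalue > 0.01

    def test_heterosomic_discrete_uniform(self):
        priors = PriorSet()
        rng = np.random.default_rng(2)
        draws = [
            sample_prior(priors, int(rng.integers(1, 2**31)), n_disomic_range=(0, 50)).n_disomic_loci
            for _ in range(4000)
        ]
        assert min(draws) == 0 and max(draws) == 50
        assert np.mean(draws) == pytest.approx(25, abs=1.0)


class TestSimulateLocus:
    def test_zero_rate_limit(self):
        locus = LocusSpec(length=1000, clock_rate=1e-16)
        sim = simulate_locus(
            PolyploidScenario(), ScenarioParameters(), locus, 4, 2, seed=1
        )
        assert sim.genotypes.shape[1] == 0

    def test_reproducible_by_seed(self):
        locus = LocusSpec(length=500)
        kwargs = dict(n_dip_lineages=4, n_tet_individuals=3, seed=99)
        a = simulate_locus(PolyploidScenario(), ScenarioParameters(), locus, **kwargs)
        b = simulate_locus(PolyploidScenario(), ScenarioParameters(), locus, **kwargs)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.positions, b.positions)

    def test_sample_layout(self):
        sim = simulate_locus(
            PolyploidScenario(), ScenarioParameters(), LocusSpec(300), 5, 3, seed=3,
            lineages_per_subgenome=2,
        )
        assert (sim.populations == "dip").sum() == 5
        assert (sim.populations == "A").sum() == 6
        assert (sim.populations == "B").sum() == 6
        for i in range(3):
            assert (sim.individuals == i).sum() == 4

    @pytest.mark.parametrize("formation", ["autopolyploid", "allopolyploid", "autopolyploid_extant"])
    @pytest.mark.parametrize("inheritance", ["tetrasomic", "disomic"])
    def test_all_formation_inheritance_routes_run(self, formation, inheritance):
        scen = PolyploidScenario(formation, inheritance, "bidirectional_AB")
        params = ScenarioParameters(m_A_to_dip=1e-5, m_B_to_dip=1e-5)
        sim = simulate_locus(scen, params, LocusSpec(400), 4, 2, seed=5, inheritance=inheritance)
        assert set(np.unique(sim.genotypes)) <= {0, 1}

    def test_mean_diversity_matches_theta_small(self):
        """Degenerate single-deme reduction: E[pi] = 2 N mu g per site."""
        params = degenerate_params(n_anc=2e4)
        mu_gen = 8.62e-10 * params.generation_time
        theta = 2 * params.N_anc * mu_gen
        locus = LocusSpec(length=2000)
        rng = np.random.default_rng(8)
        vals = []
        for _ in range(800):
            sim = simulate_locus(
                PolyploidScenario(), params, locus, 2, 0, seed=int(rng.integers(1, 2**31))
            )
            counts = sim.genotypes.sum(axis=0)
            pi = np.sum(2 * counts * (2 - counts) / 2) / locus.length
            vals.append(pi)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - theta) < 3 * se


class TestSimulateDataset:
    def test_counts_and_reproducibility(self):
        ds1 = simulate_dataset(PolyploidScenario(), ScenarioParameters(), n_loci=5,
                               n_dip_lineages=4, n_tet_individuals=2, seed=7)
        ds2 = simulate_dataset(PolyploidScenario(), ScenarioParameters(), n_loci=5,
                               n_dip_lineages=4, n_tet_individuals=2, seed=7)
        assert len(ds1.loci) == 5
        for a, b in zip(ds1.loci, ds2.loci):
            assert np.array_equal(a.genotypes, b.genotypes)

    def test_clock_rates_truncated_positive(self):
        ds = simulate_dataset(PolyploidScenario(), ScenarioParameters(), n_loci=40,
                              n_dip_lineages=2, n_tet_individuals=1, seed=3)
        rates = [l.clock_rate for l in ds.loci]
        assert all(r > 0 for r in rates)
        assert np.std(rates) > 0  # rates vary across loci

    def test_heterosomic_mixture_assignment(self):
        scen = PolyploidScenario("autopolyploid", "heterosomic", "none")
        params = ScenarioParameters(m_dip_to_A=0, m_dip_to_B=0, n_disomic_loci=4)
        ds = simulate_dataset(scen, params, n_loci=10, n_dip_lineages=2,
                              n_tet_individuals=2, seed=11)
        assert len(ds.disomic_loci) == 4
        modes = [l.inheritance for l in ds.loci]
        assert [i for i, m in enumerate(modes) if m == "disomic"] == ds.disomic_loci

    def test_high_divergence_fst_approaches_one(self):
        """No migration, T_split >> N: diploid and tetraploid near fixation."""
        from polyorigins.pipeline import simulated_stat_vector

        params = ScenarioParameters(
            N_dip=5e3, N_ext=5e3, N_tet=5e3, N_anc=5e3,
            T_split=5e8, T_WGD=2.5e8, m_dip_to_A=0, m_dip_to_B=0,
        )
        scen = PolyploidScenario("autopolyploid", "tetrasomic", "none")
        fst = []
        rng = np.random.default_rng(13)
        for _ in range(60):
            ds = simulate_dataset(scen, params, n_loci=4, locus=LocusSpec(200),
                                  n_dip_lineages=4, n_tet_individuals=4,
                                  seed=int(rng.integers(1, 2**31)))
            fst.append(simulated_stat_vector(ds).means["fst"])
        assert np.mean(fst) > 0.8

    def test_disomic_tetrasomic_agree_at_degenerate_wgd(self):
        """With T_WGD ~ 0 both inheritance modes collapse to the same
        single-deme history: between-subgenome Dxy means must overlap."""
        params = degenerate_params()
        rng = np.random.default_rng(5)
        means = {}
        for mode in ("tetrasomic", "disomic"):
            scen = PolyploidScenario("autopolyploid", mode, "none")
            vals = []
            for _ in range(500):
                sim = simulate_locus(scen, params, LocusSpec(1000), 0, 2,
                                     seed=int(rng.integers(1, 2**31)))
                a = sim.genotypes[sim.populations == "A"]
                b = sim.genotypes[sim.populations == "B"]
                pa, pb = a.mean(axis=0), b.mean(axis=0)
                vals.append(np.sum(pa * (1 - pb) + pb * (1 - pa)) / 1000)
            means[mode] = (np.mean(vals), np.std(vals) / np.sqrt(len(vals)))
        lo = {m: v - 3 * s for m, (v, s) in means.items()}
        hi = {m: v + 3 * s for m, (v, s) in means.items()}
        assert lo["tetrasomic"] <= hi["disomic"] and lo["disomic"] <= hi["tetrasomic"]

    def test_subgenome_exchange_knob_recovers_tetrasomic(self):
        """Disomic demes with strong inter-subgenome exchange behave like the
        pooled tetrasomic deme (overlapping between-subgenome Dxy)."""
        params = ScenarioParameters(
            N_dip=2e3, N_ext=2e3, N_tet=2e3, N_anc=2e3,
            T_split=4e5, T_WGD=2e5, m_dip_to_A=0, m_dip_to_B=0,
        )
        rng = np.random.default_rng(6)

        def mean_dxy(mode, exchange):
            scen = PolyploidScenario("autopolyploid", mode, "none")
            vals = []
            for _ in range(400):
                sim = simulate_locus(scen, params, LocusSpec(1000), 0, 2,
                                     seed=int(rng.integers(1, 2**31)),
                                     inheritance=mode, subgenome_exchange=exchange)
                a = sim.genotypes[sim.populations == "A"]
                b = sim.genotypes[sim.populations == "B"]
                pa, pb = a.mean(axis=0), b.mean(axis=0)
                vals.append(np.sum(pa * (1 - pb) + pb * (1 - pa)) / 1000)
            return np.mean(vals), np.std(vals) / np.sqrt(len(vals))

        tet = mean_dxy("tetrasomic", 0.0)
        dis = mean_dxy("disomic", 1.0)
        assert abs(tet[0] - dis[0]) < 3 * (tet[1] + dis[1])


class TestMsBlock:
    def test_round_trippable_text(self):
        sim = simulate_locus(PolyploidScenario(), ScenarioParameters(), LocusSpec(300),
                             3, 1, seed=21)
        buf = io.StringIO()
        write_ms_block(sim, buf)
        text = buf.getvalue().splitlines()
        assert text[0] == "//"
        assert text[1] == f"segsites: {sim.genotypes.shape[1]}"
        if sim.genotypes.shape[1]:
            assert len(text) == 3 + sim.genotypes.shape[0]
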