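"""Structured-coalescent simulation of polyploid speciation scenarios.

A tetraploid population (two homoeologous subgenomes A and B) forms at time
T_WGD either by whole-genome duplication of an extinct sister lineage of the
extant diploid (autopolyploidy), by hybridization between the diploid and the
extinct lineage (allopolyploidy), or by duplication of the extant diploid
itself; the extinct lineage split from the diploid at T_split >= T_WGD.
Chromosomal inheritance in the tetraploid is tetrasomic (all four copies
segregate freely: one panmictic deme of size N_tet), disomic (two isolated
demes of size N_tet/2), or heterosomic (a per-locus mixture).  Migration from
the diploid into the subgenomes (and optionally back) acts between the
present and T_WGD.

Coalescent machinery is msprime's; demography construction, parameter
semantics (gene-copy deme sizes, times in years, per-generation migrant
fractions) and the per-locus clock-rate model live here.  Output follows the
ms convention: binary infinite-sites haplotype matrices with positions in
[0, 1).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import msprime
import numpy as np

FORMATIONS = ("autopolyploid", "allopolyploid", "autopolyploid_extant")
INHERITANCES = ("tetrasomic", "disomic", "heterosomic")
MIGRATIONS = (
    "none",
    "unidirectional_dip_to_AB",
    "bidirectional_AB",
    "unidirectional_dip_to_A",
    "unidirectional_dip_to_B",
)

#: Mean and SD of the per-locus molecular clock rate (substitutions/site/year)
#: used when rates are drawn rather than fixed.
CLOCK_RATE_MEAN = 8.62e-10
CLOCK_RATE_SD = 1e-10

_EPS_GEN = 1e-9  # event-time floor; time-0 events would deactivate sampled demes
_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class PolyploidScenario:
    formation: str = "autopolyploid"
    inheritance: str = "tetrasomic"
    migration: str = "unidirectional_dip_to_AB"

    def __post_init__(self):
        if self.formation not in FORMATIONS:
            raise ValueError(f"unknown formation {self.formation!r}")
        if self.inheritance not in INHERITANCES:
            raise ValueError(f"unknown inheritance {self.inheritance!r}")
        if self.migration not in MIGRATIONS:
            raise ValueError(f"unknown migration {self.migration!r}")

    @property
    def key(self) -> str:
        return f"{self.formation}|{self.inheritance}|{self.migration}"


#: The six-model comparison set: {auto, allo} formation x {no migration,
#: diploid->AB unidirectional, AB bidirectional}, all tetrasomic.
SIX_MODELS = tuple(
    PolyploidScenario(f, "tetrasomic", m)
    for f in ("autopolyploid", "allopolyploid")
    for m in ("none", "unidirectional_dip_to_AB", "bidirectional_AB")
)


@dataclass
class ScenarioParameters:
    """Numeric parameters of a polyploid speciation scenario.

    Deme sizes are effective gene-copy counts; times are years; migration
    rates are per-generation migrant fractions (forward in time, from the
    diploid into subgenome A/B and back).
    """

    N_dip: float = 8e5
    N_ext: float = 8e5
    N_tet: float = 8e5
    N_anc: float = 8e5
    T_split: float = 2.88e5
    T_WGD: float = 1.0e5
    m_dip_to_A: float = 1e-4
    m_dip_to_B: float = 1e-4
    m_A_to_dip: float = 0.0
    m_B_to_dip: float = 0.0
    n_disomic_loci: int = 0
    generation_time: float = 2.0

    def validate(self, scenario: PolyploidScenario | None = None) -> None:
        for name in ("N_dip", "N_ext", "N_tet", "N_anc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.T_WGD <= self.T_split:
            raise ValueError("require 0 < T_WGD <= T_split")
        for name in ("m_dip_to_A", "m_dip_to_B", "m_A_to_dip", "m_B_to_dip"):
            rate = getattr(self, name)
            if not 0 <= rate < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5)")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be > 0")
        if self.n_disomic_loci < 0:
            raise ValueError("n_disomic_loci must be >= 0")
        if scenario is not None:
            if scenario.inheritance == "tetrasomic" and self.n_disomic_loci != 0:
                raise ValueError("tetrasomic inheritance requires n_disomic_loci = 0")

    def effective_migration(self, scenario: PolyploidScenario) -> tuple[float, float, float, float]:
        """(m_dip_to_A, m_dip_to_B, m_A_to_dip, m_B_to_dip) after masking
        by the scenario's migration structure."""
        m = scenario.migration
        da, db = self.m_dip_to_A, self.m_dip_to_B
        ad, bd = self.m_A_to_dip, self.m_B_to_dip
        if m == "none":
            return 0.0, 0.0, 0.0, 0.0
        if m == "unidirectional_dip_to_AB":
            return da, db, 0.0, 0.0
        if m == "unidirectional_dip_to_A":
            return da, 0.0, 0.0, 0.0
        if m == "unidirectional_dip_to_B":
            return 0.0, db, 0.0, 0.0
        return da, db, ad, bd  # bidirectional_AB


@dataclass(frozen=True)
class LocusSpec:
    length: int = 1381
    clock_rate: float = CLOCK_RATE_MEAN

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.clock_rate <= 0:
            raise ValueError("clock_rate must be > 0")


@dataclass(frozen=True)
class PriorSet:
    """Independent uniform priors; T_WGD is drawn conditional on T_split."""

    N_dip: tuple[float, float] = (1e3, 1e6)
    N_ext: tuple[float, float] = (1e3, 1e6)
    N_tet: tuple[float, float] = (1e3, 1e6)
    N_anc: tuple[float, float] = (1e3, 1e6)
    T_split: tuple[float, float] = (1e3, 1e7)
    T_WGD: tuple[float, float] = (1e2, 1e7)
    m_dip_to_A: tuple[float, float] = (0.0, 1e-3)
    m_dip_to_B: tuple[float, float] = (0.0, 1e-3)
    m_A_to_dip: tuple[float, float] = (0.0, 1e-3)
    m_B_to_dip: tuple[float, float] = (0.0, 1e-3)
    generation_time: float = 2.0

    def __post_init__(self):
        for name in (
            "N_dip", "N_ext", "N_tet", "N_anc", "T_split", "T_WGD",
            "m_dip_to_A", "m_dip_to_B", "m_A_to_dip", "m_B_to_dip",
        ):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"prior {name}: bad bounds ({lo}, {hi})")
        if self.T_WGD[0] > self.T_split[1]:
            raise ValueError("T_WGD lower bound exceeds T_split upper bound")

    def bounds(self) -> dict[str, tuple[float, float]]:
        return {
            name: getattr(self, name)
            for name in (
                "N_dip", "N_ext", "N_tet", "N_anc", "T_split", "T_WGD",
                "m_dip_to_A", "m_dip_to_B", "m_A_to_dip", "m_B_to_dip",
            )
        }


def sample_prior(
    priors: PriorSet,
    seed=None,
    n_disomic_range: tuple[int, int] | None = None,
) -> ScenarioParameters:
    """One independent joint draw, honouring T_WGD <= T_split.

    T_split is drawn first; T_WGD is then uniform on its prior interval
    truncated above at T_split.  ``n_disomic_range`` (inclusive) enables the
    heterosomic discrete-uniform draw of the number of disomic loci.
    """
    rng = np.random.default_rng(seed)
    draw = {name: rng.uniform(*bounds) for name, bounds in priors.bounds().items()}
    lo, hi = priors.T_WGD
    hi = min(hi, draw["T_split"])
    if lo > hi:
        lo = hi  # T_split fell below the T_WGD lower bound: pin at T_split
    draw["T_WGD"] = rng.uniform(lo, hi)
    n_disomic = 0
    if n_disomic_range is not None:
        n_disomic = int(rng.integers(n_disomic_range[0], n_disomic_range[1] + 1))
    return ScenarioParameters(
        generation_time=priors.generation_time, n_disomic_loci=n_disomic, **draw
    )


@dataclass
class SimulatedLocus:
    """Binary infinite-sites haplotypes at one locus (ms convention)."""

    genotypes: np.ndarray  # (n_haplotypes, n_segregating) in {0, 1}
    positions: np.ndarray  # fractions of locus length, in [0, 1)
    populations: np.ndarray  # 'dip', 'A' or 'B' per haplotype
    individuals: np.ndarray  # individual index per haplotype (-1 for unattached)
    length: int
    clock_rate: float
    inheritance: str


@dataclass
class SimulatedDataset:
    scenario: PolyploidScenario
    params: ScenarioParameters
    loci: list[SimulatedLocus]
    disomic_loci: list[int]
    seed: int | None = None


def _demography(
    scenario: PolyploidScenario,
    params: ScenarioParameters,
    inheritance: str,
    subgenome_exchange: float = 0.0,
) -> msprime.Demography:
    """Backward-time demography for one locus's inheritance mode."""
    d = msprime.Demography()
    d.add_population(name="dip", initial_size=params.N_dip)
    pooled = inheritance == "tetrasomic"
    if pooled:
        d.add_population(name="tet", initial_size=params.N_tet)
    else:
        d.add_population(name="subA", initial_size=params.N_tet / 2)
        d.add_population(name="subB", initial_size=params.N_tet / 2)
    d.add_population(name="ext", initial_size=params.N_ext)
    d.add_population(name="anc", initial_size=params.N_anc)

    m_da, m_db, m_ad, m_bd = params.effective_migration(scenario)
    # msprime migration rates are backward in time: a lineage now in the
    # subgenome deme traces back to the diploid at the forward migrant
    # fraction diploid -> subgenome.
    if pooled:
        d.set_migration_rate(source="tet", dest="dip", rate=(m_da + m_db) / 2)
        d.set_migration_rate(source="dip", dest="tet", rate=m_ad + m_bd)
    else:
        d.set_migration_rate(source="subA", dest="dip", rate=m_da)
        d.set_migration_rate(source="subB", dest="dip", rate=m_db)
        d.set_migration_rate(source="dip", dest="subA", rate=m_ad)
        d.set_migration_rate(source="dip", dest="subB", rate=m_bd)
        if subgenome_exchange > 0:
            d.set_migration_rate(source="subA", dest="subB", rate=subgenome_exchange)
            d.set_migration_rate(source="subB", dest="subA", rate=subgenome_exchange)

    g = params.generation_time
    t_wgd = max(params.T_WGD / g, _EPS_GEN)
    t_split = max(params.T_split / g, t_wgd + _EPS_GEN)

    d.add_migration_rate_change(time=t_wgd, rate=0)
    form = scenario.formation
    if pooled:
        if form == "autopolyploid":
            d.add_mass_migration(time=t_wgd, source="tet", dest="ext", proportion=1.0)
        elif form == "autopolyploid_extant":
            d.add_mass_migration(time=t_wgd, source="tet", dest="dip", proportion=1.0)
        else:  # allopolyploid, free segregation: fair coin per lineage
            d.add_mass_migration(time=t_wgd, source="tet", dest="dip", proportion=0.5)
            d.add_mass_migration(time=t_wgd, source="tet", dest="ext", proportion=1.0)
    else:
        dest_a = "dip" if form in ("allopolyploid", "autopolyploid_extant") else "ext"
        dest_b = "dip" if form == "autopolyploid_extant" else "ext"
        d.add_mass_migration(time=t_wgd, source="subA", dest=dest_a, proportion=1.0)
        d.add_mass_migration(time=t_wgd, source="subB", dest=dest_b, proportion=1.0)
    d.add_population_split(time=t_split, derived=["dip", "ext"], ancestral="anc")
    d.sort_events()
    return d


def _sample_layout(inheritance: str, n_dip_lineages: int, n_tet_individuals: int, k: int):
    """Sample sets plus per-haplotype population / individual labels."""
    pooled = inheritance == "tetrasomic"
    sets = []
    if n_dip_lineages:
        sets.append(msprime.SampleSet(n_dip_lineages, population="dip", ploidy=1))
    pops = ["dip"] * n_dip_lineages
    inds = [-1] * n_dip_lineages
    if n_tet_individuals:
        if pooled:
            sets.append(msprime.SampleSet(2 * k * n_tet_individuals, population="tet", ploidy=1))
            for i in range(n_tet_individuals):
                pops += ["A"] * k + ["B"] * k
                inds += [i] * (2 * k)
        else:
            sets.append(msprime.SampleSet(k * n_tet_individuals, population="subA", ploidy=1))
            sets.append(msprime.SampleSet(k * n_tet_individuals, population="subB", ploidy=1))
            for label in ("A", "B"):
                for i in range(n_tet_individuals):
                    pops += [label] * k
                    inds += [i] * k
    return sets, np.array(pops), np.array(inds)


def simulate_locus(
    scenario: PolyploidScenario,
    params: ScenarioParameters,
    locus: LocusSpec,
    n_dip_lineages: int,
    n_tet_individuals: int,
    seed: int | None = None,
    lineages_per_subgenome: int = 1,
    inheritance: str | None = None,
    subgenome_exchange: float = 0.0,
) -> SimulatedLocus:
    """Simulate one locus: binary haplotypes under the scenario's coalescent.

    ``inheritance`` overrides the scenario's mode for this locus (used by the
    heterosomic per-locus mixture).  ``subgenome_exchange`` is a backward
    migration rate between disomic subgenome demes, a consistency knob that
    recovers the tetrasomic model in the high-exchange limit.
    """
    params.validate(scenario)
    mode = inheritance or scenario.inheritance
    if mode == "heterosomic":
        raise ValueError("heterosomic is a per-dataset mixture; pass a per-locus override")
    rng = np.random.default_rng(seed)
    demog = _demography(scenario, params, mode, subgenome_exchange)
    sets, pops, inds = _sample_layout(
        mode, n_dip_lineages, n_tet_individuals, lineages_per_subgenome
    )
    if not sets:
        raise ValueError("no samples requested")
    ts = msprime.sim_ancestry(
        samples=sets,
        demography=demog,
        ploidy=1,
        sequence_length=locus.length,
        random_seed=int(rng.integers(1, _MAX_SEED)),
    )
    mts = msprime.sim_mutations(
        ts,
        rate=locus.clock_rate * params.generation_time,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=int(rng.integers(1, _MAX_SEED)),
    )
    genotypes = mts.genotype_matrix().T.astype(np.uint8)
    positions = mts.sites_position / locus.length
    return SimulatedLocus(genotypes, positions, pops, inds, locus.length, locus.clock_rate, mode)


def simulate_dataset(
    scenario: PolyploidScenario,
    params: ScenarioParameters,
    n_loci: int = 50,
    locus: LocusSpec | None = None,
    n_dip_lineages: int = 10,
    n_tet_individuals: int = 10,
    seed: int | None = None,
    lineages_per_subgenome: int = 1,
    draw_clock_rates: bool = True,
    lengths=None,
) -> SimulatedDataset:
    """Simulate ``n_loci`` independent loci under one parameter draw.

    Per-locus clock rates are Normal(8.62e-10, 1e-10) truncated at zero
    unless ``draw_clock_rates`` is off, in which case the template rate is
    used for every locus.  Heterosomic scenarios simulate exactly
    ``params.n_disomic_loci`` loci disomically (a seeded random subset) and
    the rest tetrasomically.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    params.validate(scenario)
    locus = locus or LocusSpec()
    if lengths is not None and len(lengths) != n_loci:
        raise ValueError("lengths must have one entry per locus")
    rng = np.random.default_rng(seed)
    if scenario.inheritance == "heterosomic":
        if params.n_disomic_loci > n_loci:
            raise ValueError("n_disomic_loci exceeds n_loci")
        disomic = sorted(rng.choice(n_loci, size=params.n_disomic_loci, replace=False).tolist())
    else:
        disomic = []
    disomic_set = set(disomic)
    loci = []
    for i in range(n_loci):
        rate = locus.clock_rate
        if draw_clock_rates:
            rate = 0.0
            while rate <= 0:
                rate = rng.normal(CLOCK_RATE_MEAN, CLOCK_RATE_SD)
        mode = None
        if scenario.inheritance == "heterosomic":
            mode = "disomic" if i in disomic_set else "tetrasomic"
        spec = replace(locus, clock_rate=rate)
        if lengths is not None:
            spec = replace(spec, length=int(lengths[i]))
        loci.append(
            simulate_locus(
                scenario,
                params,
                spec,
                n_dip_lineages,
                n_tet_individuals,
                seed=int(rng.integers(1, _MAX_SEED)),
                lineages_per_subgenome=lineages_per_subgenome,
                inheritance=mode,
            )
        )
    return SimulatedDataset(scenario, params, loci, disomic, seed)


def write_ms_block(locus: SimulatedLocus, fh: io.TextIOBase) -> None:
    """Write one locus as an ms-style segregating-sites block."""
    fh.write("//\n")
    fh.write(f"segsites: {locus.genotypes.shape[1]}\n")
    if locus.genotypes.shape[1]:
        fh.write("positions: " + " ".join(f"{p:.6f}" for p in locus.positions) + "\n")
        for row in locus.genotypes:
            fh.write("".join(map(str, row)) + "\n")
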