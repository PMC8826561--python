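"""Chromosomal-inheritance diagnosis from site-frequency spectra.

Disomic inheritance stops recombination between a tetraploid's subgenomes,
so alleles fixed differentially between subgenomes sit at exactly 50%
population frequency; tetrasomic inheritance (free segregation of all four
copies) produces no such excess.  A grid of speciation models — by default
3 inheritance modes x 3 formation modes x 5 migration patterns = 45
models — is simulated under shared priors, each model's tetraploid folded
SFS is pooled across simulations, and an observed spectrum is ranked
against the pool by total variation distance.  Heterosomic models draw the
number of disomic loci uniformly from {0..n_loci} per simulation, i.e. a
genome with ~50% disomic inheritance on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coalsim import (
    FORMATIONS,
    INHERITANCES,
    MIGRATIONS,
    LocusSpec,
    PolyploidScenario,
    PriorSet,
    sample_prior,
    simulate_dataset,
)
from .sumstats import FrequencySpectrum, folded_sfs, pooled_sfs

_MAX_SEED = 2**31 - 1


@dataclass
class ModelGridSpec:
    inheritances: tuple = INHERITANCES
    formations: tuple = FORMATIONS
    migrations: tuple = MIGRATIONS
    n_sims: int = 50
    n_loci: int = 50
    n_dip_lineages: int = 10
    n_tet_individuals: int = 10
    locus: LocusSpec = field(default_factory=LocusSpec)
    priors: PriorSet = field(default_factory=PriorSet)
    seed: int | None = None

    def scenarios(self) -> list[PolyploidScenario]:
        return [
            PolyploidScenario(f, i, m)
            for i in self.inheritances
            for f in self.formations
            for m in self.migrations
        ]


@dataclass
class GridSFSResult:
    spectra: dict[str, FrequencySpectrum]  # scenario key -> pooled spectrum
    n_sims: int
    seed: int | None


@dataclass
class SFSRanking:
    order: list[str]  # scenario keys, ascending distance
    distances: dict[str, float]
    excess_at_half: bool
    observed_mass_at_half: float
    tetrasomic_mean: float
    tetrasomic_sd: float


def total_variation(p: FrequencySpectrum, q: FrequencySpectrum) -> float:
    """Total variation distance between two folded spectra on common bins."""
    if p.n_haplotypes != q.n_haplotypes:
        raise ValueError(
            f"incompatible bins: sample sizes {p.n_haplotypes} vs {q.n_haplotypes}"
        )
    return float(0.5 * np.abs(p.mass - q.mass).sum())


def simulate_model_grid(spec: ModelGridSpec) -> GridSFSResult:
    """Pooled tetraploid folded SFS for every model of the grid."""
    if spec.n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(spec.seed)
    spectra: dict[str, FrequencySpectrum] = {}
    for scenario in spec.scenarios():
        per_sim = []
        for _ in range(spec.n_sims):
            n_range = (0, spec.n_loci) if scenario.inheritance == "heterosomic" else None
            params = sample_prior(spec.priors, int(rng.integers(1, _MAX_SEED)), n_range)
            ds = simulate_dataset(
                scenario,
                params,
                n_loci=spec.n_loci,
                locus=spec.locus,
                n_dip_lineages=spec.n_dip_lineages,
                n_tet_individuals=spec.n_tet_individuals,
                seed=int(rng.integers(1, _MAX_SEED)),
            )
            for locus in ds.loci:
                tet = locus.populations != "dip"
                per_sim.append(folded_sfs(locus.genotypes[tet]))
        spectra[scenario.key] = pooled_sfs(per_sim)
    return GridSFSResult(spectra, spec.n_sims, spec.seed)


def rank_models_by_sfs(observed: FrequencySpectrum, grid: GridSFSResult) -> SFSRanking:
    """Rank grid models by distance to an observed spectrum.

    ``excess_at_half`` flags an observed mass-at-50% more than 3 SDs above
    the mean of the tetrasomic models' pooled spectra — the signature that
    would rule tetrasomic inheritance out.
    """
    if observed.n_snps == 0:
        raise ValueError("observed spectrum is empty")
    distances = {key: total_variation(observed, sp) for key, sp in grid.spectra.items()}
    order = sorted(distances, key=lambda k: (distances[k], k))
    tet_mass = [
        sp.mass_at_half for key, sp in grid.spectra.items() if key.split("|")[1] == "tetrasomic"
    ]
    if not tet_mass:
        raise ValueError("grid contains no tetrasomic models")
    mean, sd = float(np.mean(tet_mass)), float(np.std(tet_mass))
    excess = observed.mass_at_half > mean + 3 * sd
    return SFSRanking(order, distances, bool(excess), observed.mass_at_half, mean, sd)


def write_grid_tsv(grid: GridSFSResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("model\tminor_count\tfrequency\tmass\n")
        for key, sp in grid.spectra.items():
            for i, (f, m) in enumerate(zip(sp.frequencies, sp.mass), start=1):
                fh.write(f"{key}\t{i}\t{f:.6g}\t{m:.6g}\n")
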