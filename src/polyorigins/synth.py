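"""Synthetic phased-alignment studies with known truth.

Generates complete truth-labeled studies — per-locus FASTA alignments of
phased haplotypes (2 per diploid, 4 per tetraploid), a sample metadata
table and a truth manifest — whose statistical structure matches the
anchored-hybrid-enrichment data the analysis expects: ~244 loci around
1,381 bp, 71 diploid and 35 tetraploid samples, ~2.7% missing cells.
Haplotypes come from the structured coalescent (:mod:`.coalsim`); binary
infinite-sites columns are mapped onto nucleotides (random ancestral base
per site, random distinct derived base per segregating site); missing data
and phase errors are injected afterwards.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .alignments import BASES, LocusAlignment, Sequence, write_locus_fasta
from .coalsim import (
    LocusSpec,
    PolyploidScenario,
    ScenarioParameters,
    SimulatedLocus,
    simulate_dataset,
)

_MAX_SEED = 2**31 - 1


@dataclass
class StudyConfig:
    """Conditions of a synthetic study.

    Defaults emulate the anchored-hybrid-enrichment study design: 244 loci,
    mean length 1,381 sites, 71 diploids, 35 tetraploids, 2.7% missing
    cells.  ``phase_error_rate`` is the per-polymorphic-site probability
    that two of a sample's haplotypes swap bases (computational phasing is
    imperfect; the true error rate is unknown, so this is a free fixture
    parameter).
    """

    n_loci: int = 244
    locus_length_mean: float = 1381.0
    locus_length_sd: float = 350.0
    locus_length_min: int = 300
    n_diploid: int = 71
    n_tetraploid: int = 35
    scenario: PolyploidScenario = field(default_factory=PolyploidScenario)
    params: ScenarioParameters = field(default_factory=ScenarioParameters)
    missing_rate: float = 0.027
    phase_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.phase_error_rate < 0.5:
            raise ValueError("phase_error_rate must be in [0, 0.5)")
        if self.locus_length_min < 12:
            raise ValueError("locus_length_min must be >= 12 (room for 5+1+5 windows)")
        self.params.validate(self.scenario)


@dataclass
class SyntheticStudy:
    config: StudyConfig
    sample_ploidy: dict[str, int]
    sample_population: dict[str, str]
    true_params: ScenarioParameters
    loci: list[LocusAlignment]
    disomic_loci: list[int]

    def diploids(self) -> list[str]:
        return [s for s, p in self.sample_ploidy.items() if p == 2]

    def tetraploids(self) -> list[str]:
        return [s for s, p in self.sample_ploidy.items() if p == 4]


def _binary_to_nucleotide(sim: SimulatedLocus, rng: np.random.Generator) -> np.ndarray:
    """Map binary infinite-sites haplotypes onto A/C/G/T sequences.

    Every site gets a uniform-random ancestral base; each segregating site
    additionally gets a derived base drawn uniformly from the remaining
    three.  Segregating sites occupy distinct uniform-random columns.
    """
    n_hap = sim.genotypes.shape[0]
    n_seg = sim.genotypes.shape[1]
    length = sim.length
    if n_seg > length:
        raise ValueError(f"{n_seg} segregating sites exceed locus length {length}")
    base_idx = rng.integers(0, 4, size=length)
    mat = np.tile(np.array([b.encode() for b in BASES])[base_idx], (n_hap, 1))
    if n_seg:
        cols = rng.choice(length, size=n_seg, replace=False)
        cols.sort()
        derived_idx = (base_idx[cols] + rng.integers(1, 4, size=n_seg)) % 4
        derived = np.array([b.encode() for b in BASES])[derived_idx]
        sub = mat[:, cols]
        sub[sim.genotypes.astype(bool)] = np.broadcast_to(derived, sub.shape)[
            sim.genotypes.astype(bool)
        ]
        mat[:, cols] = sub
    return mat


def _alignment_from_matrix(locus_id, mat, sample_ids, hap_indices) -> LocusAlignment:
    rows = [
        (sid, hap, Sequence(f"{sid}|hap{hap}", mat[i].tobytes().decode()))
        for i, (sid, hap) in enumerate(zip(sample_ids, hap_indices))
    ]
    return LocusAlignment(locus_id, rows)


def degrade_alignment(
    locus: LocusAlignment,
    missing_rate: float,
    phase_error_rate: float,
    seed: int | None = None,
) -> LocusAlignment:
    """Inject missing cells and phase errors into a phased alignment.

    A missing cell masks one (sample, site) — all of that sample's
    haplotypes get N there, emulating absent coverage.  A phase error at a
    site polymorphic within a sample swaps the bases of two of that
    sample's haplotypes; labels are untouched.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if not 0 <= phase_error_rate < 0.5:
        raise ValueError("phase_error_rate must be in [0, 0.5)")
    if missing_rate == 0 and phase_error_rate == 0:
        return locus
    rng = np.random.default_rng(seed)
    samples = locus.samples()
    mats = {sid: np.vstack([seq.array() for _, seq in locus.haplotypes(sid)]) for sid in samples}
    length = locus.length
    for sid in samples:
        mat = mats[sid].copy()
        if phase_error_rate > 0:
            within_poly = np.array(
                [len(set(mat[:, j].tolist())) > 1 for j in range(length)]
            )
            for j in np.nonzero(within_poly)[0]:
                if rng.random() < phase_error_rate:
                    i1, i2 = rng.choice(mat.shape[0], size=2, replace=False)
                    mat[[i1, i2], j] = mat[[i2, i1], j]
        if missing_rate > 0:
            mask = rng.random(length) < missing_rate
            mat[:, mask] = b"N"
        mats[sid] = mat
    rows = []
    for sid in samples:
        for k, (hap, _) in enumerate(locus.haplotypes(sid)):
            rows.append(
                (sid, hap, Sequence(f"{sid}|hap{hap}", mats[sid][k].tobytes().decode()))
            )
    return LocusAlignment(locus.locus_id, rows)


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate a complete truth-labeled study, deterministic given the seed.

    Diploids contribute 2 coalescent lineages each (from the diploid deme);
    tetraploids contribute 4 (2 per subgenome).  Locus lengths are
    Normal(mean, sd) truncated at the minimum and rounded.
    """
    rng = np.random.default_rng(config.seed)
    dip_ids = [f"dip{n:03d}" for n in range(config.n_diploid)]
    tet_ids = [f"tet{n:03d}" for n in range(config.n_tetraploid)]
    lengths = np.maximum(
        np.rint(rng.normal(config.locus_length_mean, config.locus_length_sd, config.n_loci)),
        config.locus_length_min,
    ).astype(int)

    sim = simulate_dataset(
        config.scenario,
        config.params,
        n_loci=config.n_loci,
        locus=LocusSpec(length=int(lengths[0])),
        n_dip_lineages=2 * config.n_diploid,
        n_tet_individuals=config.n_tetraploid,
        lineages_per_subgenome=2,
        seed=int(rng.integers(1, _MAX_SEED)),
        lengths=lengths,
    )
    loci = []
    for i, sim_locus in enumerate(sim.loci):
        sample_ids, hap_indices = [], []
        order = []
        for j, sid in enumerate(dip_ids):
            order += [2 * j, 2 * j + 1]
            sample_ids += [sid, sid]
            hap_indices += [0, 1]
        n_dip_rows = 2 * config.n_diploid
        for t in range(config.n_tetraploid):
            rows = [
                n_dip_rows + k
                for k in np.nonzero(sim_locus.individuals[n_dip_rows:] == t)[0]
            ]
            order += rows
            sample_ids += [tet_ids[t]] * 4
            hap_indices += [0, 1, 2, 3]
        if sim_locus.genotypes.shape[1] > sim_locus.length:
            raise ValueError(
                f"locus {i}: {sim_locus.genotypes.shape[1]} segregating sites exceed "
                f"length {sim_locus.length}; increase locus lengths or reduce diversity"
            )
        mat = _binary_to_nucleotide(sim_locus, rng)[order]
        clean = _alignment_from_matrix(f"locus_{i + 1:04d}", mat, sample_ids, hap_indices)
        loci.append(
            degrade_alignment(
                clean,
                config.missing_rate,
                config.phase_error_rate,
                seed=int(rng.integers(1, _MAX_SEED)),
            )
        )
    ploidy = {**{s: 2 for s in dip_ids}, **{s: 4 for s in tet_ids}}
    pop = {**{s: "diploid" for s in dip_ids}, **{s: "tetraploid" for s in tet_ids}}
    return SyntheticStudy(config, ploidy, pop, config.params, loci, sim.disomic_loci)


def expand_to_four_alleles(
    locus: LocusAlignment, phase_error_rate: float = 0.0, seed: int | None = None
) -> LocusAlignment:
    """Re-phase every diploid as four alleles by duplicating its haplotypes.

    Emulates what a 4-allele phaser produces when run on a diploid: each of
    the two true haplotypes appears twice (indices 0,1 copied to 2,3), then
    phase errors are applied.  Tetraploid samples pass through unchanged.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sid in locus.samples():
        haps = locus.haplotypes(sid)
        if len(haps) == 2:
            (h0, s0), (h1, s1) = haps
            rows += [
                (sid, 0, Sequence(f"{sid}|hap0", s0.residues)),
                (sid, 1, Sequence(f"{sid}|hap1", s1.residues)),
                (sid, 2, Sequence(f"{sid}|hap2", s0.residues)),
                (sid, 3, Sequence(f"{sid}|hap3", s1.residues)),
            ]
        else:
            rows += [(sid, h, s) for h, s in haps]
    expanded = LocusAlignment(locus.locus_id, rows)
    if phase_error_rate > 0:
        expanded = degrade_alignment(
            expanded, 0.0, phase_error_rate, seed=int(rng.integers(1, _MAX_SEED))
        )
    return expanded


# ---------------------------------------------------------------------------
# On-disk layout: locus_NNNN.fasta + samples.tsv + truth.json


def write_study(study: SyntheticStudy, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for locus in study.loci:
        write_locus_fasta(locus, outdir / f"{locus.locus_id}.fasta")
    with open(outdir / "samples.tsv", "w") as fh:
        fh.write("sample_id\tspecies_label\ttrue_ploidy\tpopulation\n")
        for sid, p in study.sample_ploidy.items():
            label = "H_chrysoscelis_like" if p == 2 else "H_versicolor_like"
            fh.write(f"{sid}\t{label}\t{p}\t{study.sample_population[sid]}\n")
    truth = {
        "scenario": asdict(study.config.scenario),
        "params": asdict(study.true_params),
        "seed": study.config.seed,
        "n_loci": study.config.n_loci,
        "disomic_loci": study.disomic_loci,
        "sample_ploidy": study.sample_ploidy,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return outdir


def read_truth(outdir) -> dict:
    with open(Path(outdir) / "truth.json") as fh:
        return json.load(fh)
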