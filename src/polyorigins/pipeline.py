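"""End-to-end orchestration: synthetic study -> observed statistics ->
reference table -> ABC model posterior and parameter posteriors.

The observed-data construction mirrors the study design: one random
haplotype per diploid sample plus the MIN and MAX haplotypes per tetraploid
(assigned by distance to the diploid consensus), columns with missing data
removed, statistics computed with the subgenomes pooled as one population.
Every stochastic stage receives a seed derived deterministically from the
master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .alignments import LocusAlignment, assign_subgenomes, consensus_sequence
from .coalsim import (
    SIX_MODELS,
    LocusSpec,
    PolyploidScenario,
    PriorSet,
    ScenarioParameters,
    simulate_dataset,
)
from .inference import (
    ReferenceTable,
    abc_model_choice,
    abc_parameter_posterior,
    build_reference_table,
)
from .sumstats import StatVector, dataset_stat_vector, locus_stats
from .synth import StudyConfig, SyntheticStudy, generate_study, write_study

logger = logging.getLogger(__name__)

_MAX_SEED = 2**31 - 1


@dataclass
class PipelineConfig:
    master_seed: int = 0
    study: StudyConfig = field(default_factory=StudyConfig)
    models: tuple = SIX_MODELS
    priors: PriorSet = field(default_factory=PriorSet)
    n_sims_per_model: int = 2000
    abc_n_loci: int = 50
    tolerance: float = 0.005
    n_nets: int = 35
    n_hidden: int = 10
    n_keep: int = 1000

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = [asdict(m) for m in self.models]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        study = d.pop("study", {})
        if isinstance(study, dict):
            scen = study.pop("scenario", {})
            params = study.pop("params", {})
            study = StudyConfig(
                scenario=PolyploidScenario(**scen),
                params=ScenarioParameters(**params),
                **study,
            )
        models = tuple(PolyploidScenario(**m) for m in d.pop("models", []))
        priors = d.pop("priors", {})
        if isinstance(priors, dict):
            priors = PriorSet(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in priors.items()})
        return cls(study=study, models=models or SIX_MODELS, priors=priors, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def observed_locus_matrix(
    locus: LocusAlignment,
    diploids: list[str],
    tetraploids: list[str],
    rng: np.random.Generator,
):
    """One random diploid haplotype each + MIN/MAX per tetraploid.

    Returns ``(byte matrix, diploid mask, tetraploid mask)``; the MIN/MAX
    reference is the consensus over all diploid haplotypes at this locus.
    """
    reference = consensus_sequence(locus, diploids)
    rows = []
    for sid in diploids:
        haps = locus.haplotypes(sid)
        rows.append(haps[rng.integers(0, len(haps))][1].array())
    n_dip = len(rows)
    for sid in tetraploids:
        a = assign_subgenomes(locus, sid, reference)
        haps = dict(locus.haplotypes(sid))
        rows.append(haps[a.min_hap_index].array())
        rows.append(haps[a.max_hap_index].array())
    mat = np.vstack(rows)
    mask_a = np.zeros(len(rows), dtype=bool)
    mask_a[:n_dip] = True
    return mat, mask_a, ~mask_a


def observed_stat_vector(study: SyntheticStudy, loci_indices=None, seed=None) -> StatVector:
    """Observed StatVector over a locus subset (default: all loci)."""
    rng = np.random.default_rng(seed)
    diploids, tetraploids = study.diploids(), study.tetraploids()
    indices = range(len(study.loci)) if loci_indices is None else loci_indices
    per_locus = []
    for i in indices:
        mat, mask_a, mask_b = observed_locus_matrix(study.loci[i], diploids, tetraploids, rng)
        per_locus.append(locus_stats(mat, mask_a, mask_b))
    return dataset_stat_vector(per_locus)


def simulated_stat_vector(dataset) -> StatVector:
    """StatVector of a simulated dataset (diploid vs pooled tetraploid)."""
    per_locus = []
    for locus in dataset.loci:
        mask_a = locus.populations == "dip"
        per_locus.append(locus_stats(locus.genotypes, mask_a, ~mask_a, length=locus.length))
    return dataset_stat_vector(per_locus)


def minmax_stat_vector(dataset) -> StatVector:
    """StatVector of a simulated dataset with MIN/MAX haplotype selection.

    Mirrors the observed-data construction exactly: each tetraploid
    individual carries four simulated haplotypes, of which the closest
    (MIN) and farthest (MAX) from the diploid majority consensus are kept
    (tie rules as in the sequence-space assignment: lowest row for MIN,
    highest for MAX).  Keeping the two constructions identical removes a
    systematic shift between observed and reference-table statistics that
    otherwise mimics an allopolyploid / migration signature.
    """
    per_locus = []
    for locus in dataset.loci:
        genotypes = locus.genotypes
        dip = locus.populations == "dip"
        consensus = (genotypes[dip].mean(axis=0) > 0.5).astype(np.uint8)
        keep = list(np.nonzero(dip)[0])
        n_dip = len(keep)
        for ind in sorted(set(locus.individuals[locus.individuals >= 0])):
            idx = np.nonzero(locus.individuals == ind)[0]
            dist = (genotypes[idx] != consensus).sum(axis=1)
            min_pos = int(np.argmin(dist))
            rest = np.delete(np.arange(len(idx)), min_pos)
            max_pos = rest[len(rest) - 1 - int(np.argmax(dist[rest][::-1]))]
            keep += [int(idx[min_pos]), int(idx[max_pos])]
        mask_a = np.zeros(len(keep), dtype=bool)
        mask_a[:n_dip] = True
        per_locus.append(
            locus_stats(genotypes[keep], mask_a, ~mask_a, length=locus.length)
        )
    return dataset_stat_vector(per_locus)


def make_simulate_stats(config: PipelineConfig, match_observed: bool = True):
    """The per-row simulator used to fill the reference table.

    With ``match_observed`` (the default), tetraploids are simulated with
    two lineages per subgenome and reduced to MIN/MAX haplotypes the same
    way the observed data are; otherwise one random lineage per subgenome
    is simulated directly.
    """

    def simulate_stats(scenario, params, seed) -> StatVector:
        ds = simulate_dataset(
            scenario,
            params,
            n_loci=config.abc_n_loci,
            locus=LocusSpec(length=int(config.study.locus_length_mean)),
            n_dip_lineages=config.study.n_diploid,
            n_tet_individuals=config.study.n_tetraploid,
            lineages_per_subgenome=2 if match_observed else 1,
            seed=seed,
        )
        return minmax_stat_vector(ds) if match_observed else simulated_stat_vector(ds)

    simulate_stats.n_loci = config.abc_n_loci
    return simulate_stats


def run_end_to_end(config: PipelineConfig, outdir=None) -> dict:
    """Execute the full pipeline and return (and optionally write) a report."""
    t0 = time.time()
    root = np.random.SeedSequence(config.master_seed)
    seeds = [int(s.generate_state(1)[0] % _MAX_SEED) for s in root.spawn(5)]
    log: list[str] = []

    def stage(msg):
        logger.info(msg)
        log.append(f"[{time.time() - t0:8.1f}s] {msg}")

    stage(f"config hash {config.config_hash()}; stage seeds {seeds}")
    study_config = dataclasses.replace(config.study, seed=seeds[0])
    study = generate_study(study_config)
    stage(f"synthetic study: {len(study.loci)} loci, "
          f"{len(study.diploids())} diploids, {len(study.tetraploids())} tetraploids")
    if outdir is not None:
        write_study(study, Path(outdir) / "study")

    rng = np.random.default_rng(seeds[1])
    n_loci = len(study.loci)
    k = min(config.abc_n_loci, n_loci)
    subset = sorted(rng.choice(n_loci, size=k, replace=False).tolist())
    observed = observed_stat_vector(study, subset, seed=seeds[1])
    stage(f"observed statistics from {k} loci")

    table = build_reference_table(
        config.models, config.priors, make_simulate_stats(config),
        config.n_sims_per_model, seed=seeds[2],
    )
    stage(f"reference table: {table.n_rows} rows, {len(config.models)} models")
    if outdir is not None:
        table.to_tsv(Path(outdir) / "reference_table.tsv")

    posterior = abc_model_choice(
        observed, table, config.tolerance, config.n_nets, config.n_hidden, seed=seeds[3]
    )
    best = max(posterior.probabilities, key=posterior.probabilities.get)
    stage(f"model posterior: best {best} "
          f"(p={posterior.probabilities[best]:.3f}, retained {posterior.n_retained})")

    model_table = table.restrict(best)
    n_keep = min(config.n_keep, model_table.n_rows)
    params_post = abc_parameter_posterior(
        observed, model_table, config.priors.bounds(),
        n_keep=n_keep, n_nets=config.n_nets, n_hidden=config.n_hidden, seed=seeds[4],
    )
    stage(f"parameter posterior for {best}: {len(params_post)} parameters, n_keep={n_keep}")

    report = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "stage_seeds": seeds,
        "true_model": study.config.scenario.key,
        "observed": {
            "means": observed.means,
            "sds": observed.sds,
            "n_loci": observed.n_loci,
        },
        "model_posterior": posterior.probabilities,
        "rejection_posterior": posterior.rejection_probabilities,
        "best_model": best,
        "parameter_posterior": {
            p: {"pdv": pp.pdv, "ci90": list(pp.ci90)} for p, pp in params_post.items()
        },
        "log": log,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
        with open(outdir / "pipeline.log", "w") as fh:
            fh.write("\n".join(log) + "\n")
    return report
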