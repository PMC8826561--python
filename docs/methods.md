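# Methods

This note documents the models, estimators, numerical choices and
limitations behind `polyorigins`.

## Demographic model of polyploid speciation

All scenarios share one backbone, parameterized in
`ScenarioParameters`:

| parameter | meaning | units | default |
|---|---|---|---|
| `N_dip`, `N_ext`, `N_tet`, `N_anc` | effective sizes of the extant diploid, the extinct progenitor, the tetraploid, and the common ancestor | gene copies | 8×10⁵ |
| `T_split` | divergence of the progenitor lineage from the extant diploid | years | 2.88×10⁵ |
| `T_WGD` | whole-genome duplication (tetraploid formation) | years | 1.0×10⁵ |
| `m_dip_to_A/B`, `m_A/B_to_dip` | per-generation migrant fractions, forward in time | — | 10⁻⁴ / 0 |
| `generation_time` | converts years to coalescent generations | years | 2 |
| `n_disomic_loci` | disomic loci per dataset (heterosomic only) | count | 0 |

Formation modes route subgenome lineages backwards in time at `T_WGD`:
**autopolyploid** sends both subgenomes into the extinct progenitor;
**allopolyploid** sends subgenome A to the diploid and B to the
progenitor (under tetrasomic inheritance, where subgenome identity is
not preserved, each lineage instead picks a parent with an independent
fair coin — the free-segregation limit); **autopolyploid-from-extant**
sends both into the diploid.  At `T_split` the progenitor and diploid
merge into the ancestor.  Inheritance modes set the tetraploid deme
structure: tetrasomic = one panmictic deme of `N_tet` gene copies;
disomic = two isolated demes of `N_tet/2`; heterosomic = a per-locus
mixture with exactly `n_disomic_loci` disomic loci (drawn as a seeded
random subset).  Migration acts only between the present and `T_WGD`.

The coalescent engine is msprime (haploid samples, so deme sizes are
gene-copy counts and the pairwise coalescence rate in a deme of size N
is 1/N per generation); mutations are infinite-sites binary
(`BinaryMutationModel`, continuous genome), giving ms-style 0/1
haplotype matrices with positions in [0, 1).  Two numerical guards:
event times are floored at 10⁻⁹ generations (msprime cannot sample from
a deme deactivated at time 0, and the degenerate `T_split = T_WGD = 0`
single-deme limit is exercised by tests), and `T_split` is kept at
least 10⁻⁹ generations above `T_WGD` so the formation event always
precedes the split event.  A `subgenome_exchange` knob adds symmetric
migration between disomic subgenome demes; in the strong-exchange limit
it recovers the tetrasomic model and is used only as a consistency
check in tests.

Defaults: the generation time of 2 years is a choice (treefrogs mature
in 1–3 years); deme sizes of 8×10⁵ gene copies were chosen so that
within-sample heterozygosity ≈ 2Nμg ≈ 0.003 per site, the median
per-sample SNP density the synthetic data are meant to emulate; the
default `T_split`/`T_WGD` are the posterior modes of the best-supported
history.  Per-locus clock rates are Normal(8.62×10⁻¹⁰, 10⁻¹⁰)
substitutions/site/year truncated at zero — the anchored-loci clock
distribution — redrawn per locus.

## Priors

`PriorSet` holds independent uniform priors; `T_WGD` is drawn uniform
on its interval truncated above at the drawn `T_split`, which enforces
the joint constraint without rejection loops (if `T_split` falls below
the `T_WGD` lower bound, `T_WGD` pins at `T_split`).  The default
bounds — sizes U(10³, 10⁶) gene copies, `T_split` U(10³, 10⁷) yr,
`T_WGD` U(10², `T_split`) yr, migrant fractions U(0, 10⁻³) — are wide
enough to contain the credible intervals the method is expected to
produce; all are configurable and none are hard-coded in the
simulator.  The heterosomic grid draws `n_disomic_loci` from
DiscreteUniform{0..n_loci} per simulation, i.e. a genome with ~50%
disomic inheritance on average.

## Synthetic studies

`generate_study` emulates the anchored-hybrid-enrichment design: 244
loci with lengths Normal(1381, 350) truncated at 300 and rounded; 71
diploids (2 coalescent lineages each) and 35 tetraploids (2 lineages
per subgenome); binary haplotypes mapped onto nucleotides with a
uniform-random ancestral base per site and a uniform-random distinct
derived base per segregating site (segregating sites at distinct
uniform-random columns).  Missing data are injected per (sample, site)
cell at rate 0.027, masking all of the sample's haplotypes at that site
(emulating absent coverage; no block structure).  Phase errors swap the
bases of two randomly chosen haplotypes of a sample at a
within-sample-polymorphic site with a configurable per-site probability;
the true phasing error rate of read-based phasing is unknown, so the
default is 0 and the parameter is a fixture knob, not an estimate.
`expand_to_four_alleles` builds the diploid-as-tetraploid fixtures that
a four-allele phaser would produce (each true haplotype duplicated,
then phase errors applied).

What the generator does **not** emulate: read coverage and assembly
artifacts, paralogy, block-wise missingness, within-locus recombination,
selection, gene conversion, and population structure within the diploid
or tetraploid.  Tests passing on these studies therefore demonstrate
the correctness and self-consistency of the computational pipeline
under its own model, not robustness to those real-data violations.

## Sequence processing

Missing symbols are `N` and `-`; distances use pairwise deletion and
return NaN when no column is comparable.  Consensus takes the
per-column majority base with alphabetical tie-break (keeping the
consensus inside the distance alphabet) and `N` for all-missing
columns.  MIN/MAX subgenome assignment takes the tetraploid haplotype
closest to (MIN) and farthest from (MAX) the diploid consensus, ties
broken to the lowest index for MIN and the highest for MAX; the two
intermediate haplotypes are discarded.  SNP extraction reports a column
iff exactly two bases segregate, the column and its `flank` (default 5)
neighbours on each side are missing-free, and the flanking columns are
monomorphic; columns with three or more alleles are dropped everywhere
(the downstream statistics are biallelic).  Coordinates are 0-based
internally, 1-based in written tables.  The phaseability constant is
2/300 rounded to 4 decimals: two SNPs within the 300 bp span bridged by
150 bp paired-end reads.

## Summary statistics

Per locus, for diploid population A and pooled tetraploid population B:
segregating sites, π (mean pairwise difference per site), Watterson's
θ = S/(a₁L), Tajima's D (standard variance normalization; NaN when
S = 0), raw divergence Dxy, net divergence Da = Dxy − (π_A+π_B)/2,
Hudson-type F_ST = 1 − π_within/π_total with equal population weighting
(NaN when π_total = 0), and the fixed/shared/exclusive biallelic-site
partition (sf + ss + sxA + sxB = biallelic sites).  A dataset is
summarized by mean and population SD of each statistic over loci, NaNs
skipped with counts recorded — the ABC reference-table row.  Nucleotide
input is first filtered to columns with no missing data (matching how
the observed alignments are prepared) and encoded 0/1 over biallelic
columns; per-site denominators count the retained columns.

Folded site-frequency spectra require an even sample size so the 50%
bin is exact; `mass_at_half` is the proportion of segregating sites at
exactly n/2 minor-allele count, with no frequency window — sample sizes
here are small and even by construction.  Disomic inheritance stops
recombination between subgenomes, so sites fixed differentially between
subgenomes sit at exactly 50% and inflate this mass; tetrasomic
segregation does not.  Pooling across simulations sums SNP counts
(a density histogram over all simulated SNPs), rather than averaging
per-simulation histograms.

## Observed-data construction and simulation parity

The observed vector for ABC is built from one random haplotype per
diploid plus the MIN and MAX haplotypes per tetraploid (selected by
p-distance to the diploid consensus), with missing columns removed and
the subgenomes pooled as one population.  The reference-table simulator
mirrors this construction exactly by default: each tetraploid
contributes four simulated haplotypes (two per subgenome), reduced to
MIN/MAX by Hamming distance to the diploid binary consensus with the
same tie rules.  Simulating one random lineage per subgenome instead
(available via `match_observed=False`) leaves a systematic shift
between observed and simulated statistics — selecting extremes of four
haplotypes lowers the MIN distance and raises within-individual
diversity, which imitates an allopolyploid or migration signature and
measurably degrades model recovery at desk scale.  Keeping both sides
of the comparison identically constructed removes that bias.

## ABC

Rejection: statistics are centred on the observed vector and scaled by
the reference table's per-statistic median absolute deviation (floored
at machine epsilon with a warning; SD scaling is available), distance
is Euclidean, the `tolerance` fraction of nearest rows is retained
(ties at the boundary resolve by row order), and retained rows get
Epanechnikov weights 1 − (d/d_max)².  Model choice regresses the
one-hot model indicator on the retained scaled statistics with an
ensemble of single-hidden-layer feed-forward networks — 35 nets of 10
hidden units by default, read as "35 networks, ten hidden units", the
standard ensemble meaning.  The regression backend takes no per-row
weights, so each ensemble member is fit on a weight-proportional
bootstrap resample of the retained rows (distinct seeded
initializations); predictions at the observed point are aggregated by
median, clipped to [0, 1] and renormalized.  The rejection-only
estimate (kernel-weighted model frequencies) is always reported
alongside; a model absent from the retained rows gets probability 0
with a warning.

Parameter posteriors logit-transform each parameter to its prior
bounds (guaranteeing adjusted samples stay inside), fit the same
ensemble regression of transformed parameters on scaled statistics
over the `n_keep` nearest rows, adjust each retained draw by
m(observed) + residual, and back-transform.  The PDV (peak distribution
value) is the mode of the weighted Gaussian kernel density (Silverman
bandwidth, 512-point grid); the 90% credible interval is the weighted
5%/95% quantile pair.  Parameters constant across retained rows return
point masses.  `n_keep` defaults to 1,000 — at the full scale of 10⁶
simulations per model that is the 1,000-closest-rows setting — and must
be scaled with the table (desk-scale tests use 400 of 1,500 rows;
keeping too large a fraction stops rejecting, keeping too few
destabilizes the regression).

Robustness of a model pair is the mean posterior probability matrix
over pseudo-observed datasets simulated under each model, summarized as
R = P(M1|M1)/(P(M1|M1)+P(M1|M2)).  Log-marginal likelihoods (e.g.
Bezier approximations from thermodynamic-integration MCMC runs) convert
to equal-prior model probabilities by max-shifted exponentiation and
normalization, which is numerically stable and shift-invariant.

Training hyperparameters of the networks (lbfgs, max 500 iterations,
L2 penalty 10⁻³) are defaults exposed in code; the ensemble median is
insensitive to moderate changes in them.

## Inheritance diagnosis

The model grid is 3 inheritance × 3 formation × 5 migration = 45
models (the full cross of the enumerations above), simulated under
shared priors; each model's tetraploid folded SFS is pooled across
simulations and an observed spectrum is ranked by total variation
distance.  `excess_at_half` flags an observed 50% mass more than 3 SDs
above the mean of the tetrasomic models' pooled masses — the signature
that would exclude tetrasomic inheritance.  The flag is meaningful only
when the grid contains several tetrasomic models (with one, the SD
degenerates to zero).

## Desk-scale experiment design

The full-scale study settings — 10⁶ simulations per model, 50 of 244
loci, 71 diploid + 35 tetraploid samples, 50,000 simulations per grid
model — are documented configuration; the test suite runs every
experiment at desk scale: reference tables of 180–2,400 rows, 6–15
loci, 8 diploid and 4–10 tetraploid samples, grids of tens of
simulations.  Two experiments
need care at this scale.  First, under the full-width migration prior
U(0, 10⁻³) most prior draws experience hundreds of migration events
per lineage before `T_WGD`, which erases the formation signal — the
same near-indistinguishability the full-scale analysis reports for
migration models.  The self-consistency experiments (model recovery;
credible-interval coverage) therefore use a narrower prior set
(N U(5×10⁴, 5×10⁵), `T_split` U(10⁶, 8×10⁶), `T_WGD` U(10⁴, 10⁶),
m U(0, 5×10⁻⁶)) and a generating point inside it where the six models
are mutually identifiable; they measure whether the machinery recovers
truth when truth is recoverable.  Second, the retained-row count must
scale with the table, as above.  Both choices are fixed in the test
module, not tuned per run.

## Known limitations

- No recombination within loci, no selection, no gene conversion, no
  triploid-bridge dynamics.
- The tetrasomic allopolyploid fair-coin parent assignment is the free-
  segregation limit; partial preferential pairing is not modelled
  except through the heterosomic per-locus mixture.
- The ploidy classifier is a transparent nearest-centroid
  reconstruction of the published distance-signal approach (pooled
  per-sample features, ambiguity threshold 0.1 standardized margin);
  it is not a port of the original package, whose exact algorithm and
  per-locus voting behaviour are not described in the primary text.
- MAD scaling degenerates for statistics that are constant over the
  table (scale floored, effectively an exact-match preference on that
  statistic); this occurs for the fixed-difference statistics at low
  divergence.
- The D3 statistic takes its two distances as explicit arguments; the
  package does not fix a taxon-triplet orientation.
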