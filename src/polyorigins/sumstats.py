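"""Per-locus and multilocus population-genetic summary statistics.

The statistic set follows the msnsam/mscalc lineage used for ABC on
two-population data: per-population segregating sites, nucleotide diversity,
Watterson's theta and Tajima's D, between-population Dxy, net divergence Da,
Hudson-type FST, and the fixed/shared/exclusive polymorphism counts.  A
dataset is summarised by the mean and SD of each statistic across loci
(the ABC reference-table row).  Also here: the folded site-frequency
spectrum with its mass-at-50% diagnostic of disomic inheritance, and the
k-locus subsampling randomization test.

Population "A" is the diploid; population "B" is the pooled tetraploid
(both subgenomes treated as one population, blind to any subgenome
demarcation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LOCUS_STAT_FIELDS = (
    "bialsites",
    "S_A",
    "S_B",
    "pi_A",
    "pi_B",
    "thetaW_A",
    "thetaW_B",
    "tajd_A",
    "tajd_B",
    "dxy",
    "da",
    "fst",
    "sf",
    "ss",
    "sxA",
    "sxB",
)


@dataclass(frozen=True)
class LocusStats:
    bialsites: int
    S_A: int
    S_B: int
    pi_A: float
    pi_B: float
    thetaW_A: float
    thetaW_B: float
    tajd_A: float
    tajd_B: float
    dxy: float
    da: float
    fst: float
    sf: int
    ss: int
    sxA: int
    sxB: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in LOCUS_STAT_FIELDS], dtype=float)


@dataclass
class StatVector:
    """Mean and population SD of each per-locus statistic across loci."""

    means: dict[str, float]
    sds: dict[str, float]
    n_loci: int
    n_undefined: dict[str, int]

    @staticmethod
    def manifest() -> list[str]:
        names = []
        for f in LOCUS_STAT_FIELDS:
            names.append(f"mean_{f}")
            names.append(f"sd_{f}")
        return names

    def as_array(self) -> np.ndarray:
        out = []
        for f in LOCUS_STAT_FIELDS:
            out.append(self.means[f])
            out.append(self.sds[f])
        return np.array(out, dtype=float)


@dataclass
class FrequencySpectrum:
    """Folded minor-allele-frequency histogram for an even sample size."""

    counts: np.ndarray  # length n//2; counts[i-1] = SNPs with minor count i
    n_haplotypes: int
    n_snps: int

    @property
    def mass(self) -> np.ndarray:
        if self.n_snps == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.n_snps

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(1, self.n_haplotypes // 2 + 1) / self.n_haplotypes

    @property
    def mass_at_half(self) -> float:
        """Proportion of SNPs at exactly 50% minor-allele frequency."""
        if self.n_snps == 0:
            return 0.0
        return float(self.counts[-1] / self.n_snps)


@dataclass
class RandomizationReport:
    statistics: list[str]
    observed: np.ndarray
    lower: np.ndarray  # 2.5% null quantile
    upper: np.ndarray  # 97.5% null quantile
    outside: np.ndarray  # bool per statistic
    n_replicates: int
    seed: int | None


def _tajima_d(n: int, S: int, pi_total: float) -> float:
    """Tajima's D from sample size, segregating sites and total pairwise
    diversity (not per site)."""
    if S == 0 or n < 3:
        return float("nan")
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((pi_total - S / a1) / np.sqrt(var))


def _pairwise_pi_total(counts: np.ndarray, n: int) -> float:
    """Sum over columns of expected heterozygosity (mean pairwise diffs)."""
    return float(np.sum(2.0 * counts * (n - counts) / (n * (n - 1))))


def encode_binary(matrix: np.ndarray, missing=(b"N", b"-")) -> tuple[np.ndarray, int]:
    """Nucleotide byte matrix -> (binary matrix over biallelic columns, L).

    Columns with any missing cell are removed first (observed alignments are
    filtered to complete columns before comparison with simulated data); the
    returned L is the number of retained columns, the denominator for
    per-site statistics.
    Among retained columns, biallelic ones are encoded 0/1 (minor allele 1,
    alphabetical tie-break); columns with 3+ alleles are dropped.
    """
    if matrix.dtype == np.uint8 or matrix.dtype == bool:
        return matrix.astype(np.uint8), matrix.shape[1]
    miss = np.zeros(matrix.shape, dtype=bool)
    for sym in missing:
        miss |= matrix == sym
    keep = ~miss.any(axis=0)
    mat = matrix[:, keep]
    length = mat.shape[1]
    cols = []
    for j in range(length):
        col = mat[:, j]
        alleles, counts = np.unique(col, return_counts=True)
        if len(alleles) != 2:
            continue
        minor = int(np.argmin(counts))  # ties: first (alphabetical) allele
        cols.append((col == alleles[minor]).astype(np.uint8))
    binary = np.array(cols, dtype=np.uint8).T if cols else np.zeros((matrix.shape[0], 0), np.uint8)
    return binary, length


def locus_stats(matrix: np.ndarray, pop_a_mask, pop_b_mask, length: int | None = None) -> LocusStats:
    """Two-population summary statistics at one locus.

    ``matrix`` is binary (haplotypes x segregating sites) or a nucleotide
    byte matrix (converted via :func:`encode_binary`).  ``length`` is the
    per-site denominator; for binary input it must be supplied (the locus
    length in the ms convention).
    """
    pop_a_mask = np.asarray(pop_a_mask, dtype=bool)
    pop_b_mask = np.asarray(pop_b_mask, dtype=bool)
    n_a, n_b = int(pop_a_mask.sum()), int(pop_b_mask.sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("each population needs >= 2 haplotypes")
    if matrix.dtype != np.uint8 and matrix.dtype != bool:
        matrix, enc_len = encode_binary(matrix)
        length = enc_len if length is None else length
    if length is None:
        raise ValueError("length is required for binary input")
    matrix = matrix.astype(np.uint8)

    a = matrix[pop_a_mask]
    b = matrix[pop_b_mask]
    ca = a.sum(axis=0)
    cb = b.sum(axis=0)
    c_tot = ca + cb
    n = n_a + n_b

    poly = (c_tot > 0) & (c_tot < n)
    bialsites = int(poly.sum())
    seg_a = (ca > 0) & (ca < n_a)
    seg_b = (cb > 0) & (cb < n_b)
    S_A, S_B = int(seg_a.sum()), int(seg_b.sum())

    pi_a_tot = _pairwise_pi_total(ca, n_a)
    pi_b_tot = _pairwise_pi_total(cb, n_b)
    pi_a, pi_b = pi_a_tot / length, pi_b_tot / length
    a1_a = np.sum(1.0 / np.arange(1, n_a))
    a1_b = np.sum(1.0 / np.arange(1, n_b))
    theta_a = S_A / (a1_a * length)
    theta_b = S_B / (a1_b * length)
    tajd_a = _tajima_d(n_a, S_A, pi_a_tot)
    tajd_b = _tajima_d(n_b, S_B, pi_b_tot)

    pa, pb = ca / n_a, cb / n_b
    dxy = float(np.sum(pa * (1 - pb) + pb * (1 - pa))) / length
    da = dxy - (pi_a + pi_b) / 2

    pi_total = _pairwise_pi_total(c_tot, n) / length
    pi_within = (pi_a + pi_b) / 2
    fst = float("nan") if pi_total == 0 else float(1 - pi_within / pi_total)

    fixed_a = (ca == 0) | (ca == n_a)
    fixed_b = (cb == 0) | (cb == n_b)
    sf = int((poly & fixed_a & fixed_b & (pa != pb)).sum())
    ss = int((poly & seg_a & seg_b).sum())
    sxA = int((poly & seg_a & fixed_b).sum())
    sxB = int((poly & seg_b & fixed_a).sum())

    return LocusStats(
        bialsites, S_A, S_B, pi_a, pi_b, theta_a, theta_b,
        tajd_a, tajd_b, dxy, da, fst, sf, ss, sxA, sxB,
    )


def dataset_stat_vector(per_locus: list[LocusStats]) -> StatVector:
    """Mean and population SD per statistic over loci, skipping NaNs."""
    if not per_locus:
        raise ValueError("no loci")
    table = np.vstack([s.as_array() for s in per_locus])
    means, sds, undef = {}, {}, {}
    for j, f in enumerate(LOCUS_STAT_FIELDS):
        col = table[:, j]
        ok = ~np.isnan(col)
        undef[f] = int((~ok).sum())
        if ok.any():
            means[f] = float(col[ok].mean())
            sds[f] = float(col[ok].std())
        else:
            means[f] = float("nan")
            sds[f] = float("nan")
    return StatVector(means, sds, len(per_locus), undef)


def folded_sfs(matrix: np.ndarray) -> FrequencySpectrum:
    """Folded SFS of one population's haplotypes (binary matrix).

    The sample size must be even so that the 50%-frequency bin (the
    disomic-inheritance diagnostic) is well defined.
    """
    matrix = np.asarray(matrix, dtype=np.uint8)
    n = matrix.shape[0]
    if n == 0:
        raise ValueError("no haplotypes")
    if n % 2:
        raise ValueError("folded SFS with a mass-at-half needs an even sample size")
    counts = matrix.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    minor = np.minimum(counts[seg], n - counts[seg]).astype(int)
    hist = np.bincount(minor, minlength=n // 2 + 1)[1:]
    return FrequencySpectrum(hist, n, int(seg.sum()))


def pooled_sfs(spectra: list[FrequencySpectrum]) -> FrequencySpectrum:
    """Pool SNP counts across replicate spectra with a common sample size."""
    if not spectra:
        raise ValueError("no spectra")
    n = {s.n_haplotypes for s in spectra}
    if len(n) != 1:
        raise ValueError(f"incompatible sample sizes {sorted(n)}")
    counts = np.sum([s.counts for s in spectra], axis=0)
    return FrequencySpectrum(counts, n.pop(), int(counts.sum()))


def write_stat_vector(sv: StatVector, path) -> None:
    """One flat TSV row in manifest order, with the manifest as header."""
    names = StatVector.manifest()
    values = sv.as_array()
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        fh.write("\t".join(f"{v:.10g}" for v in values) + "\n")


def randomization_test_loci(
    per_locus: list[LocusStats],
    observed_indices,
    n_reps: int = 1000,
    seed: int | None = None,
) -> RandomizationReport:
    """Test a designated k-locus subset against random k-subsets.

    The observed StatVector (means and SDs over the designated subset) is
    compared per statistic with the two-tailed 2.5/97.5 percentile envelope
    of ``n_reps`` random without-replacement k-subsets of all loci.
    """
    observed_indices = list(observed_indices)
    k = len(observed_indices)
    if k == 0 or k > len(per_locus):
        raise ValueError("need 0 < k <= number of loci")
    rng = np.random.default_rng(seed)
    names = StatVector.manifest()
    obs = dataset_stat_vector([per_locus[i] for i in observed_indices]).as_array()
    null = np.empty((n_reps, len(names)))
    for r in range(n_reps):
        idx = rng.choice(len(per_locus), size=k, replace=False)
        null[r] = dataset_stat_vector([per_locus[i] for i in idx]).as_array()
    lower = np.nanpercentile(null, 2.5, axis=0)
    upper = np.nanpercentile(null, 97.5, axis=0)
    with np.errstate(invalid="ignore"):
        outside = (obs < lower) | (obs > upper)
    return RandomizationReport(names, obs, lower, upper, outside, n_reps, seed)
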