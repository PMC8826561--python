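"""Polyploid-aware sequence data processing.

Phased per-locus alignments (2 haplotypes per diploid sample, 4 per
tetraploid), consensus sequences, pairwise p-distances, MIN/MAX subgenome
assignment of tetraploid haplotypes, flank-filtered SNP extraction and
fixed/shared/private classification, the D3 distance statistic, and
per-sample SNP-density (phaseability) profiling.

Coordinates are 0-based half-open internally and 1-based closed in
human-readable output.  ``N`` and ``-`` are both treated as missing;
distances use pairwise deletion of missing columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = ("A", "C", "G", "T")
MISSING = frozenset("N-")
_ALPHABET = frozenset("ACGTN-")

#: SNP density above which two adjacent SNPs fit within the 300 bp span
#: bridged by 150 bp paired-end reads, making a locus read-phaseable:
#: 2 SNPs / 300 bp, rounded to 4 decimals.
PHASEABILITY_THRESHOLD = round(2 / 300, 4)


@dataclass(frozen=True)
class Sequence:
    """A named nucleotide sequence over {A,C,G,T,N,-}."""

    id: str
    residues: str

    def __post_init__(self):
        res = self.residues.upper()
        if not res:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(res) - _ALPHABET
        if bad:
            raise ValueError(f"sequence {self.id!r} has invalid symbols {sorted(bad)}")
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def array(self) -> np.ndarray:
        return np.frombuffer(self.residues.encode(), dtype="S1")


@dataclass
class LocusAlignment:
    """Equal-length phased haplotypes at one locus.

    ``rows`` are ``(sample_id, haplotype_index, Sequence)`` with 2 rows per
    diploid sample and 4 per tetraploid; haplotype indices are unique within
    a sample.
    """

    locus_id: str
    rows: list[tuple[str, int, Sequence]] = field(default_factory=list)

    def __post_init__(self):
        if not self.rows:
            raise ValueError(f"locus {self.locus_id!r} has no rows")
        lengths = {len(seq) for _, _, seq in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"locus {self.locus_id!r}: unequal sequence lengths {lengths}")
        per_sample: dict[str, list[int]] = {}
        for sid, hap, _ in self.rows:
            per_sample.setdefault(sid, []).append(hap)
        for sid, haps in per_sample.items():
            if len(set(haps)) != len(haps):
                raise ValueError(f"sample {sid!r}: duplicate haplotype indices")
            if len(haps) not in (2, 4):
                raise ValueError(f"sample {sid!r}: {len(haps)} haplotypes (need 2 or 4)")

    @property
    def length(self) -> int:
        return len(self.rows[0][2])

    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid, _, _ in self.rows:
            seen.setdefault(sid)
        return list(seen)

    def haplotypes(self, sample_id: str) -> list[tuple[int, Sequence]]:
        out = sorted((hap, seq) for sid, hap, seq in self.rows if sid == sample_id)
        if not out:
            raise KeyError(f"sample {sample_id!r} not in locus {self.locus_id!r}")
        return out

    def matrix(self, sample_ids=None) -> np.ndarray:
        """Byte matrix (rows x sites), optionally restricted to samples."""
        rows = self.rows
        if sample_ids is not None:
            keep = set(sample_ids)
            rows = [r for r in rows if r[0] in keep]
            if not rows:
                raise ValueError("no rows left after sample restriction")
        return np.vstack([seq.array() for _, _, seq in rows])


@dataclass(frozen=True)
class SubgenomeAssignment:
    """MIN/MAX haplotype choice for one tetraploid sample at one locus."""

    locus_id: str
    sample_id: str
    min_hap_index: int
    max_hap_index: int
    d_min: float
    d_max: float
    discarded: tuple[int, int]


@dataclass(frozen=True)
class SNPRecord:
    locus_id: str
    column: int  # 0-based
    alleles: tuple[str, str]  # alphabetical
    counts: tuple[int, int]  # haplotype counts per allele
    calls: dict  # (sample_id, hap_index) -> base
    passes_flank: bool = True
    complete: bool = True

    @property
    def position_1based(self) -> int:
        return self.column + 1


@dataclass(frozen=True)
class PolymorphismCounts:
    fixed: int
    shared: int
    private_a: int
    private_b: int

    @property
    def total(self) -> int:
        return self.fixed + self.shared + self.private_a + self.private_b


def _missing_mask(mat: np.ndarray) -> np.ndarray:
    return (mat == b"N") | (mat == b"-")


def consensus_sequence(alignment: LocusAlignment, group, seq_id: str = "consensus") -> Sequence:
    """Per-column majority base over a sample group.

    Ties break to the alphabetically first base; all-missing columns yield N.
    """
    group = list(group)
    if not group:
        raise ValueError("empty group")
    mat = alignment.matrix(group)
    out = np.full(mat.shape[1], b"N", dtype="S1")
    counts = np.stack([(mat == base.encode()).sum(axis=0) for base in BASES])
    any_base = counts.sum(axis=0) > 0
    # argmax returns the first (= alphabetically smallest) index on ties
    out[any_base] = np.array([b.encode() for b in BASES])[np.argmax(counts, axis=0)][any_base]
    return Sequence(seq_id, out.tobytes().decode())


def p_distance(a: Sequence, b: Sequence) -> float:
    """Proportion of differing comparable sites (pairwise deletion).

    Returns NaN when no column is comparable.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    av, bv = a.array(), b.array()
    comparable = ~(_missing_mask(av.reshape(1, -1))[0] | _missing_mask(bv.reshape(1, -1))[0])
    n = int(comparable.sum())
    if n == 0:
        return float("nan")
    return float((av[comparable] != bv[comparable]).sum() / n)


def assign_subgenomes(
    locus: LocusAlignment, sample_id: str, reference: Sequence
) -> SubgenomeAssignment:
    """Assign a tetraploid's MIN/MAX haplotypes by distance to a reference.

    MIN is the haplotype closest to the (diploid consensus) reference, MAX
    the farthest; the two intermediate haplotypes are discarded.  Ties break
    to the lowest haplotype index for MIN and the highest for MAX.
    """
    haps = locus.haplotypes(sample_id)
    if len(haps) != 4:
        raise ValueError(f"sample {sample_id!r} is not phased as 4 haplotypes at {locus.locus_id!r}")
    dists = {hap: p_distance(seq, reference) for hap, seq in haps}
    if all(np.isnan(d) for d in dists.values()):
        raise ValueError(f"no comparable sites for {sample_id!r} at {locus.locus_id!r}")
    defined = {h: d for h, d in dists.items() if not np.isnan(d)}
    d_min = min(defined.values())
    min_hap = min(h for h, d in defined.items() if d == d_min)
    candidates = {h: d for h, d in defined.items() if h != min_hap}
    if not candidates:
        raise ValueError(f"only one comparable haplotype for {sample_id!r} at {locus.locus_id!r}")
    d_max = max(candidates.values())
    max_hap = max(h for h, d in candidates.items() if d == d_max)
    discarded = tuple(sorted(h for h, _ in haps if h not in (min_hap, max_hap)))
    return SubgenomeAssignment(
        locus.locus_id, sample_id, min_hap, max_hap, d_min, dists[max_hap], discarded
    )


def extract_snps(loci, samples, flank: int = 5) -> list[SNPRecord]:
    """Biallelic SNPs flanked by ``flank`` monomorphic, complete sites.

    A column is reported iff, among the included samples' haplotypes,
    exactly two bases segregate, the column and the ``flank`` columns on
    each side have no missing data, and those flanking columns are
    monomorphic.  Columns too close to a locus edge are excluded.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample subset")
    records: list[SNPRecord] = []
    for locus in loci:
        keep = [r for r in locus.rows if r[0] in set(samples)]
        if not keep:
            continue
        mat = np.vstack([seq.array() for _, _, seq in keep])
        miss = _missing_mask(mat)
        col_missing = miss.any(axis=0)
        n_alleles = np.zeros(mat.shape[1], dtype=int)
        for base in BASES:
            n_alleles += (mat == base.encode()).any(axis=0)
        biallelic = (n_alleles == 2) & ~col_missing
        clean_mono = (n_alleles == 1) & ~col_missing
        length = mat.shape[1]
        for col in np.nonzero(biallelic)[0]:
            lo, hi = col - flank, col + flank
            if lo < 0 or hi >= length:
                continue
            window = np.r_[lo:col, col + 1 : hi + 1]
            if not clean_mono[window].all():
                continue
            column = mat[:, col]
            alleles = tuple(sorted({c.decode() for c in column}))
            counts = tuple(int((column == a.encode()).sum()) for a in alleles)
            calls = {(sid, hap): column[i].decode() for i, (sid, hap, _) in enumerate(keep)}
            records.append(SNPRecord(locus.locus_id, int(col), alleles, counts, calls))
    return records


def classify_polymorphisms(snps, group_a, group_b) -> PolymorphismCounts:
    """Count fixed / shared / private-A / private-B SNPs between two groups.

    SNPs monomorphic for the same base in both groups (possible when the
    groups are a strict subset of the extraction samples) are not counted.
    """
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    if group_a & group_b:
        raise ValueError(f"groups overlap: {sorted(group_a & group_b)}")
    fixed = shared = priv_a = priv_b = 0
    for rec in snps:
        a_bases = {b for (sid, _), b in rec.calls.items() if sid in group_a}
        b_bases = {b for (sid, _), b in rec.calls.items() if sid in group_b}
        if not a_bases or not b_bases:
            continue
        a_poly, b_poly = len(a_bases) > 1, len(b_bases) > 1
        if a_poly and b_poly:
            shared += 1
        elif a_poly:
            priv_a += 1
        elif b_poly:
            priv_b += 1
        elif a_bases != b_bases:
            fixed += 1
    return PolymorphismCounts(fixed, shared, priv_a, priv_b)


def d3_statistic(d13: float, d23: float) -> float:
    """(d13 - d23) / (d13 + d23): distance-based introgression signal.

    Inputs are mean pairwise p-distances between the named populations;
    the statistic is antisymmetric in its arguments and lies in [-1, 1].
    """
    if d13 < 0 or d23 < 0:
        raise ValueError("distances must be non-negative")
    if d13 + d23 == 0:
        raise ValueError("both distances are zero")
    return (d13 - d23) / (d13 + d23)


def snp_density_profile(loci, sample_ids=None) -> dict[str, float]:
    """Per-sample heterozygous-site density (SNPs per comparable site).

    For each sample, a column counts toward the denominator when at least
    two of the sample's haplotype cells are non-missing there, and toward
    the numerator when those cells carry >= 2 distinct bases.  Compare with
    :data:`PHASEABILITY_THRESHOLD` to judge read-phaseability.
    """
    loci = list(loci)
    if sample_ids is None:
        sample_ids = sorted({sid for locus in loci for sid in locus.samples()})
    out: dict[str, float] = {}
    for sid in sample_ids:
        het = 0
        usable = 0
        for locus in loci:
            if sid not in locus.samples():
                continue
            mat = np.vstack([seq.array() for _, seq in locus.haplotypes(sid)])
            miss = _missing_mask(mat)
            n_ok = (~miss).sum(axis=0)
            cols = n_ok >= 2
            usable += int(cols.sum())
            n_distinct = np.zeros(mat.shape[1], dtype=int)
            for base in BASES:
                n_distinct += ((mat == base.encode()) & ~miss).any(axis=0)
            het += int((cols & (n_distinct >= 2)).sum())
        if usable == 0:
            raise ValueError(f"sample {sid!r}: no comparable columns")
        out[sid] = het / usable
    return out


def mean_group_distance(alignment: LocusAlignment, group_1, group_2) -> float:
    """Mean pairwise p-distance between two sample groups at one locus."""
    h1 = [seq for sid in group_1 for _, seq in alignment.haplotypes(sid)]
    h2 = [seq for sid in group_2 for _, seq in alignment.haplotypes(sid)]
    vals = [p_distance(a, b) for a, b in itertools.product(h1, h2)]
    vals = [v for v in vals if not np.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# FASTA / TSV interchange


def read_locus_fasta(path) -> LocusAlignment:
    """Read one locus from FASTA with ``sampleID|hapK`` headers."""
    path = Path(path)
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sid, _, hap = rec.id.rpartition("|")
        if not sid or not hap.startswith("hap"):
            raise ValueError(f"{path}: header {rec.id!r} is not 'sample|hapK'")
        rows.append((sid, int(hap[3:]), Sequence(rec.id, str(rec.seq))))
    return LocusAlignment(path.stem, rows)


def write_locus_fasta(alignment: LocusAlignment, path) -> None:
    records = [
        SeqRecord(Seq(seq.residues), id=f"{sid}|hap{hap}", description="")
        for sid, hap, seq in alignment.rows
    ]
    SeqIO.write(records, str(path), "fasta")


def write_snp_table(snps, path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tposition\tallele_1\tallele_2\tcount_1\tcount_2\n")
        for rec in snps:
            fh.write(
                f"{rec.locus_id}\t{rec.position_1based}\t{rec.alleles[0]}\t"
                f"{rec.alleles[1]}\t{rec.counts[0]}\t{rec.counts[1]}\n"
            )


def write_polymorphism_counts(counts: PolymorphismCounts, path, label="all") -> None:
    with open(path, "w") as fh:
        fh.write("comparison\tfixed\tshared\tprivate_a\tprivate_b\ttotal\n")
        fh.write(
            f"{label}\t{counts.fixed}\t{counts.shared}\t{counts.private_a}\t"
            f"{counts.private_b}\t{counts.total}\n"
        )


def write_subgenome_assignments(assignments, path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tsample\tmin_hap\tmax_hap\td_min\td_max\tdiscarded\n")
        for a in assignments:
            fh.write(
                f"{a.locus_id}\t{a.sample_id}\t{a.min_hap_index}\t{a.max_hap_index}\t"
                f"{a.d_min:.6g}\t{a.d_max:.6g}\t{a.discarded[0]},{a.discarded[1]}\n"
            )
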