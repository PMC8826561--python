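"""Sequence-processing operations: consensus, distances, subgenome
assignment, SNP extraction/classification, D3, SNP density."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyorigins import (
    PHASEABILITY_THRESHOLD,
    Sequence,
    assign_subgenomes,
    classify_polymorphisms,
    consensus_sequence,
    d3_statistic,
    extract_snps,
    p_distance,
    read_locus_fasta,
    snp_density_profile,
    write_locus_fasta,
)
from conftest import make_alignment, random_alignment


class TestConsensus:
    def test_identical_rows(self):
        aln = make_alignment("l", [("a", 0, "ACGT"), ("a", 1, "ACGT"), ("b", 0, "ACGT"), ("b", 1, "ACGT")])
        assert consensus_sequence(aln, ["a", "b"]).residues == "ACGT"

    def test_majority_and_alphabetical_tie(self):
        aln = make_alignment(
            "l",
            [("a", 0, "AG"), ("a", 1, "AG"), ("b", 0, "AA"), ("b", 1, "GA")],
        )
        # col0: {A:3, G:1} -> A;  col1: {G:2, A:2} -> A (alphabetical)
        assert consensus_sequence(aln, ["a", "b"]).residues == "AA"

    def test_all_missing_column_yields_n(self):
        aln = make_alignment("l", [("a", 0, "A-"), ("a", 1, "AN")])
        assert consensus_sequence(aln, ["a"]).residues == "AN"

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        aln = random_alignment(rng, n_samples=4, length=30)
        cons = consensus_sequence(aln, aln.samples())
        again = make_alignment("c", [("c", 0, cons.residues), ("c", 1, cons.residues)])
        assert consensus_sequence(again, ["c"]).residues == cons.residues

    def test_empty_group_rejected(self):
        aln = make_alignment("l", [("a", 0, "AC"), ("a", 1, "AC")])
        with pytest.raises(ValueError):
            consensus_sequence(aln, [])


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 0.0),
            ("ACGT", "ACGA", 0.25),
            ("ACNT", "ACGT", 0.0),  # 3 comparable, 0 diffs
            ("A-GT", "ACGA", 1 / 3),
        ],
    )
    def test_examples(self, a, b, expected):
        assert p_distance(Sequence("a", a), Sequence("b", b)) == pytest.approx(expected)

    def test_no_comparable_columns_is_nan(self):
        assert np.isnan(p_distance(Sequence("a", "NN"), Sequence("b", "AC")))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            p_distance(Sequence("a", "ACG"), Sequence("b", "AC"))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_metric_on_gap_free_triples(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array([b"A", b"C", b"G", b"T"])
        seqs = [
            Sequence(f"s{i}", rng.choice(bases, size=20).tobytes().decode()) for i in range(3)
        ]
        d = {(i, j): p_distance(seqs[i], seqs[j]) for i in range(3) for j in range(3)}
        for i in range(3):
            assert d[(i, i)] == 0
            for j in range(3):
                assert d[(i, j)] == d[(j, i)]
        assert d[(0, 2)] <= d[(0, 1)] + d[(1, 2)] + 1e-12


class TestSubgenomeAssignment:
    def _locus(self, hap_seqs):
        rows = [("tet", h, s) for h, s in enumerate(hap_seqs)]
        return make_alignment("l", rows)

    def test_ordered_distances(self):
        ref = Sequence("ref", "A" * 100)
        seqs = ["A" * 100, "T" + "A" * 99, "TT" + "A" * 98, "TTT" + "A" * 97]
        a = assign_subgenomes(self._locus(seqs), "tet", ref)
        assert (a.min_hap_index, a.max_hap_index) == (0, 3)
        assert a.discarded == (1, 2)
        assert a.d_min <= a.d_max

    def test_all_identical_tie_rule(self):
        ref = Sequence("ref", "ACGT" * 5)
        a = assign_subgenomes(self._locus(["AAGT" + "ACGT" * 4] * 4), "tet", ref)
        assert (a.min_hap_index, a.max_hap_index) == (0, 3)
        assert a.d_min == a.d_max

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_argmin_argmax(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array([b"A", b"C", b"G", b"T"])
        seqs = [rng.choice(bases, size=40).tobytes().decode() for _ in range(4)]
        ref = Sequence("ref", rng.choice(bases, size=40).tobytes().decode())
        a = assign_subgenomes(self._locus(seqs), "tet", ref)
        d = [p_distance(Sequence(str(i), s), ref) for i, s in enumerate(seqs)]
        assert d[a.min_hap_index] == min(d)
        assert d[a.max_hap_index] == max(x for i, x in enumerate(d) if i != a.min_hap_index)

    def test_storage_order_invariance(self):
        rng = np.random.default_rng(17)
        bases = np.array([b"A", b"C", b"G", b"T"])
        seqs = [rng.choice(bases, size=60).tobytes().decode() for _ in range(4)]
        ref = Sequence("ref", rng.choice(bases, size=60).tobytes().decode())
        base = assign_subgenomes(self._locus(seqs), "tet", ref)
        for perm in itertools.permutations(range(4)):
            rows = [("tet", h, Sequence(f"tet|hap{h}", seqs[h])) for h in perm]
            shuffled = type(self._locus(seqs))("l", rows)
            a = assign_subgenomes(shuffled, "tet", ref)
            assert (a.min_hap_index, a.max_hap_index) == (base.min_hap_index, base.max_hap_index)

    def test_diploid_rejected(self):
        aln = make_alignment("l", [("d", 0, "ACGT"), ("d", 1, "ACGT")])
        with pytest.raises(ValueError):
            assign_subgenomes(aln, "d", Sequence("r", "ACGT"))


def brute_force_snps(loci, samples, flank):
    """Independent per-column scanner implementing the flank filter."""
    out = []
    for locus in loci:
        rows = [seq.residues for sid, _, seq in locus.rows if sid in set(samples)]
        length = len(rows[0])
        for col in range(length):
            window = range(col - flank, col + flank + 1)
            if window[0] < 0 or window[-1] >= length:
                continue
            ok = True
            for w in window:
                column = [r[w] for r in rows]
                if any(c in "N-" for c in column):
                    ok = False
                    break
                if w != col and len(set(column)) != 1:
                    ok = False
                    break
            if ok and len({r[col] for r in rows}) == 2:
                out.append((locus.locus_id, col))
    return out


class TestExtractSnps:
    def test_single_clean_snp(self):
        base = "A" * 20
        alt = "A" * 10 + "G" + "A" * 9
        aln = make_alignment("l", [("a", 0, base), ("a", 1, base), ("b", 0, alt), ("b", 1, alt)])
        recs = extract_snps([aln], ["a", "b"], flank=5)
        assert len(recs) == 1 and recs[0].column == 10
        assert recs[0].alleles == ("A", "G") and recs[0].counts == (2, 2)

    def test_edge_snp_excluded(self):
        base = "A" * 20
        alt = "AAAG" + "A" * 16  # biallelic at column 3: left flank too short
        aln = make_alignment("l", [("a", 0, base), ("a", 1, alt)])
        assert extract_snps([aln], ["a"], flank=5) == []

    def test_monomorphic_alignment(self):
        aln = make_alignment("l", [("a", 0, "ACGT" * 5), ("a", 1, "ACGT" * 5)])
        assert extract_snps([aln], ["a"], flank=5) == []

    @pytest.mark.parametrize("flank", range(6))
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_scanner(self, flank, seed):
        rng = np.random.default_rng(seed)
        loci = [
            random_alignment(rng, n_samples=3, length=int(rng.integers(20, 60)), locus_id=f"l{i}")
            for i in range(5)
        ]
        samples = ["s0", "s1", "s2"]
        got = [(r.locus_id, r.column) for r in extract_snps(loci, samples, flank=flank)]
        assert got == brute_force_snps(loci, samples, flank)


class TestClassifyPolymorphisms:
    def test_fixed_and_shared(self):
        seqs = {
            # col 10 fixed A/T; col 30 shared
            ("a", 0): "A" * 30 + "A" + "A" * 9,
            ("a", 1): "A" * 30 + "C" + "A" * 9,
            ("b", 0): "A" * 10 + "A" * 20 + "A" + "A" * 9,
        }
        rows = [
            ("a", 0, "A" * 40),
            ("a", 1, "A" * 30 + "C" + "A" * 9),
            ("b", 0, "A" * 10 + "T" + "A" * 19 + "A" + "A" * 9),
            ("b", 1, "A" * 10 + "T" + "A" * 19 + "C" + "A" * 9),
        ]
        aln = make_alignment("l", rows)
        recs = extract_snps([aln], ["a", "b"], flank=5)
        counts = classify_polymorphisms(recs, ["a"], ["b"])
        assert counts.fixed == 1 and counts.shared == 1
        assert counts.total == len(recs)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_sets(self, seed):
        rng = np.random.default_rng(seed)
        loci = [random_alignment(rng, n_samples=4, length=50, locus_id=f"l{i}") for i in range(3)]
        samples = [f"s{i}" for i in range(4)]
        recs = extract_snps(loci, samples, flank=1)
        group_a, group_b = samples[:2], samples[2:]
        counts = classify_polymorphisms(recs, group_a, group_b)
        fixed = shared = pa = pb = 0
        for rec in recs:
            sa = {b for (sid, _), b in rec.calls.items() if sid in group_a}
            sb = {b for (sid, _), b in rec.calls.items() if sid in group_b}
            if len(sa) > 1 and len(sb) > 1:
                shared += 1
            elif len(sa) > 1:
                pa += 1
            elif len(sb) > 1:
                pb += 1
            elif sa and sb and sa != sb:
                fixed += 1
        assert (counts.fixed, counts.shared, counts.private_a, counts.private_b) == (
            fixed, shared, pa, pb,
        )

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            classify_polymorphisms([], ["a"], ["a"])


class TestD3:
    def test_symmetry_zero(self):
        assert d3_statistic(0.1, 0.1) == 0

    def test_arithmetic(self):
        assert d3_statistic(0.2, 0.1) == pytest.approx(1 / 3)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetric_and_bounded(self, d13, d23):
        if d13 + d23 == 0:
            with pytest.raises(ValueError):
                d3_statistic(d13, d23)
            return
        v = d3_statistic(d13, d23)
        assert -1 <= v <= 1
        assert v == pytest.approx(-d3_statistic(d23, d13))


class TestSnpDensity:
    def test_phaseability_constant(self):
        assert PHASEABILITY_THRESHOLD == 0.0067

    def test_simple_density(self):
        het = "A" * 500 + "C" * 500
        hom = "A" * 1000
        # 4 heterozygous sites over 1000 columns
        h1 = "A" * 1000
        h2 = "A" * 248 + "C" + "A" * 250 + "C" + "A" * 250 + "C" + "A" * 124 + "C" + "A" * 124
        aln = make_alignment("l", [("x", 0, h1), ("x", 1, h2), ("y", 0, hom), ("y", 1, hom)])
        dens = snp_density_profile([aln])
        assert dens["x"] == pytest.approx(0.004)
        assert dens["y"] == 0.0


class TestFastaRoundTrip:
    def test_round_trip(self, tmp_path, tiny_study):
        locus = tiny_study.loci[0]
        path = tmp_path / f"{locus.locus_id}.fasta"
        write_locus_fasta(locus, path)
        back = read_locus_fasta(path)
        assert back.locus_id == locus.locus_id
        assert [(s, h, q.residues) for s, h, q in back.rows] == [
            (s, h, q.residues) for s, h, q in locus.rows
        ]
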