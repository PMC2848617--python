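import itertools
import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from appia import synthetic
from appia.io_formats import GeneLocation, OrthologAlignment, OrthologTable, PairList
from appia.predictors import (
    DistanceMatrix,
    PhyloProfile,
    build_profile,
    distance_matrix,
    gc_score,
    gc_scores_bulk,
    i2h_score,
    ingest_gf,
    mclachlan_matrix,
    mclachlan_site_correlation,
    mt_score,
    neighborhood_distance,
    pp_score,
    pp_score_matrix,
)

bits = st.lists(st.integers(0, 1), min_size=1, max_size=30)


def _profile(vector):
    return PhyloProfile(protein="p", bits=np.asarray(vector, dtype=np.uint8))


def _table(genomes, assignments):
    """assignments: protein -> iterable of genome indices with orthologs."""
    entries = {
        (p, genomes[g]): f"{p}@{genomes[g]}"
        for p, present in assignments.items()
        for g in present
    }
    return OrthologTable(genomes=list(genomes), proteins=list(assignments), entries=entries)


# ---------------------------------------------------------------------------
# PP
# ---------------------------------------------------------------------------

class TestPhyloProfiles:
    def test_build_profile_bit_pattern(self):
        table = _table(["g0", "g1", "g2", "g3"], {"p": [0, 2]})
        assert build_profile("p", table).bits.tolist() == [1, 0, 1, 0]

    def test_absent_everywhere(self):
        table = _table(["g0", "g1"], {"p": []})
        assert build_profile("p", table).bits.tolist() == [0, 0]

    def test_present_everywhere(self):
        table = _table(["g0", "g1"], {"p": [0, 1]})
        assert build_profile("p", table).bits.tolist() == [1, 1]

    def test_identity_zero(self):
        assert pp_score(_profile([1, 0, 1]), _profile([1, 0, 1])) == 0

    def test_mismatch_count(self):
        assert pp_score(_profile([1, 0, 1, 1, 0]), _profile([1, 0, 0, 1, 1])) == 2

    def test_complementary_over_118_genomes(self):
        a = _profile([1] * 118)
        b = _profile([0] * 118)
        assert pp_score(a, b) == 118

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pp_score(_profile([1, 0]), _profile([1, 0, 1]))

    @given(bits, bits, bits)
    def test_metric_properties(self, u, v, w):
        n = max(len(u), len(v), len(w))
        u, v, w = (x + [0] * (n - len(x)) for x in (u, v, w))
        pu, pv, pw = _profile(u), _profile(v), _profile(w)
        assert pp_score(pu, pv) == pp_score(pv, pu)
        assert (pp_score(pu, pv) == 0) == (u == v)
        assert pp_score(pu, pw) <= pp_score(pu, pv) + pp_score(pv, pw)

    def test_matrix_agrees_with_scalar(self, rng):
        mat = (rng.random((8, 12)) < 0.5).astype(np.uint8)
        pairwise = pp_score_matrix(mat)
        for i, j in itertools.combinations(range(8), 2):
            assert pairwise[i, j] == pp_score(
                PhyloProfile("a", mat[i]), PhyloProfile("b", mat[j])
            )


# ---------------------------------------------------------------------------
# GC
# ---------------------------------------------------------------------------

def _loc(start, end, genome="g", contig="c"):
    return GeneLocation(genome=genome, contig=contig, start=start, end=end, strand="+")


class TestNeighborhoodDistance:
    def test_worked_example_gap_149(self):
        # oracle: integer positions strictly between [100,200] and [350,500]
        oracle = len([p for p in range(1, 1000) if 200 < p < 350])
        assert oracle == 149
        assert neighborhood_distance(_loc(100, 200), _loc(350, 500)) == 149

    def test_overlap_is_zero(self):
        assert neighborhood_distance(_loc(100, 400), _loc(300, 500)) == 0
        assert neighborhood_distance(_loc(100, 500), _loc(200, 300)) == 0  # containment

    def test_different_contigs_undefined(self):
        assert neighborhood_distance(_loc(1, 10), _loc(20, 30, contig="c2")) is None

    def test_different_genomes_undefined(self):
        assert neighborhood_distance(_loc(1, 10), _loc(20, 30, genome="g2")) is None

    def test_symmetric(self):
        assert neighborhood_distance(_loc(350, 500), _loc(100, 200)) == 149


class TestGcScore:
    def _world(self, gaps):
        """One genome per requested gap; genes for p1/p2 separated by it."""
        genomes = [f"g{i}" for i in range(len(gaps))]
        table = _table(genomes, {"p1": range(len(gaps)), "p2": range(len(gaps))})
        coords = {}
        for i, (genome, gap) in enumerate(zip(genomes, gaps)):
            coords[(genome, f"p1@{genome}")] = _loc(100, 200, genome=genome)
            coords[(genome, f"p2@{genome}")] = _loc(201 + gap, 400 + gap, genome=genome)
        return table, coords

    def test_both_gaps_below_300(self):
        table, coords = self._world([100, 250])
        assert gc_score("p1", "p2", table, coords) == 2

    def test_gap_exactly_300_not_counted(self):
        table, coords = self._world([100, 300])
        assert gc_score("p1", "p2", table, coords) == 1

    def test_never_cooccurring(self):
        table = _table(["g0", "g1"], {"p1": [0], "p2": [1]})
        assert gc_score("p1", "p2", table, {}) == 0

    def test_symmetric(self):
        table, coords = self._world([100])
        assert gc_score("p1", "p2", table, coords) == gc_score("p2", "p1", table, coords)

    def test_bounded_by_cooccurrence(self, small_world):
        table = small_world.table
        rng = np.random.default_rng(1)
        proteins = rng.choice(table.proteins, size=8, replace=False)
        for a, b in itertools.combinations(sorted(proteins), 2):
            cooccur = sum(
                1
                for g in table.genomes
                if (a, g) in table.entries and (b, g) in table.entries
            )
            assert gc_score(a, b, table, small_world.coordinates) <= cooccur

    def test_bulk_agrees_with_scalar(self, small_world):
        bulk = gc_scores_bulk(small_world.table, small_world.coordinates)
        rng = np.random.default_rng(2)
        some = rng.choice(small_world.table.proteins, size=10, replace=False)
        for a, b in itertools.combinations(sorted(some), 2):
            scalar = gc_score(a, b, small_world.table, small_world.coordinates)
            assert bulk.get((a, b), 0) == scalar
        # every bulk pair matches the scalar path too
        for (a, b), count in bulk.items():
            assert count >= 1


# ---------------------------------------------------------------------------
# MT
# ---------------------------------------------------------------------------

def _aln(rows, protein="p"):
    return OrthologAlignment(protein=protein, rows=rows)


class TestDistanceMatrix:
    def test_identical_rows(self):
        dm = distance_matrix(_aln({"s1": "ACDE", "s2": "ACDE"}))
        assert dm.d[0, 1] == 0.0

    def test_one_mismatch_of_four(self):
        dm = distance_matrix(_aln({"s1": "AAAA", "s2": "AAAT"}))
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_gap_column_excluded(self):
        dm = distance_matrix(_aln({"s1": "A-AA", "s2": "ATAA"}))
        assert dm.d[0, 1] == 0.0

    def test_zero_comparable_positions_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix(_aln({"s1": "A-", "s2": "-T"}))

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix(_aln({"s1": "ACDE"}))


class TestMtScore:
    def _matrix(self, n, rng, species=None):
        x = rng.random((n, n)) * 0.5
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0.0)
        species = species or [f"s{i}" for i in range(n)]
        return DistanceMatrix(species=species, d=d)

    def test_self_correlation(self, rng):
        m = self._matrix(12, rng)
        assert mt_score(m, m) == pytest.approx(1.0)

    def test_affine_negation(self, rng):
        m = self._matrix(12, rng)
        negated = DistanceMatrix(species=list(m.species), d=1.0 - m.d)
        assert mt_score(m, negated) == pytest.approx(-1.0)

    def test_too_few_common_species(self, rng):
        a = self._matrix(5, rng)
        b = self._matrix(5, rng)
        assert mt_score(a, b, min_common=11) is None

    def test_zero_variance_missing(self):
        d = np.full((12, 12), 0.3)
        np.fill_diagonal(d, 0.0)
        flat = DistanceMatrix(species=[f"s{i}" for i in range(12)], d=d)
        assert mt_score(flat, flat) is None

    def test_reorder_invariance(self, rng):
        a = self._matrix(12, rng)
        b = self._matrix(12, rng)
        baseline = mt_score(a, b)
        order = rng.permutation(12)
        shuffled = DistanceMatrix(
            species=[a.species[i] for i in order], d=a.d[np.ix_(order, order)]
        )
        assert mt_score(shuffled, b) == pytest.approx(baseline)

    def test_symmetric(self, rng):
        a = self._matrix(12, rng)
        b = self._matrix(12, rng)
        assert mt_score(a, b) == pytest.approx(mt_score(b, a))


# ---------------------------------------------------------------------------
# I2H
# ---------------------------------------------------------------------------

class TestSiteCorrelation:
    def test_invariant_column_undefined(self):
        assert mclachlan_site_correlation("AAAA", "ARND") is None

    def test_copied_column_perfect(self):
        assert mclachlan_site_correlation("ARNDC", "ARNDC") == pytest.approx(1.0)

    def test_too_few_rows(self):
        assert mclachlan_site_correlation("ARN", "ARN") is None

    def test_gapped_rows_excluded(self):
        # the gapped species drops out, leaving 3 rows -> undefined
        assert mclachlan_site_correlation("ARN-", "ARND") is None

    def test_four_species_toy_vs_brute_force(self):
        order, matrix = mclachlan_matrix()
        col_i, col_j = "ARIW", "NDCV"
        index = {aa: k for k, aa in enumerate(order)}
        si, sj = [], []
        for k, l in itertools.combinations(range(4), 2):
            si.append(matrix[index[col_i[k]], index[col_i[l]]])
            sj.append(matrix[index[col_j[k]], index[col_j[l]]])
        expected = statistics.correlation(si, sj)
        assert mclachlan_site_correlation(col_i, col_j) == pytest.approx(expected)


def _columns_to_alignment(columns, species, protein="p"):
    rows = {
        s: "".join(col[i] for col in columns) for i, s in enumerate(species)
    }
    return OrthologAlignment(protein=protein, rows=rows)


class TestI2hScore:
    species = [f"s{i:02d}" for i in range(12)]

    def test_perfectly_covarying_twin(self):
        column = "ARNDCQEGHILK"
        aln = _columns_to_alignment([column, column], self.species)
        assert i2h_score(aln, aln) == pytest.approx(1.0)

    def test_all_invariant_missing(self):
        aln = _columns_to_alignment(["A" * 12, "R" * 12], self.species)
        assert i2h_score(aln, aln) is None

    def test_too_few_common_species(self):
        aln = _columns_to_alignment(["ARNDC", "QEGHI"], [f"s{i}" for i in range(5)])
        assert i2h_score(aln, aln, min_common=11) is None

    def test_matches_scalar_brute_force(self, rng):
        aa = "ARNDCQEGHILKMFPSTWYV"
        n_species, n_cols = 10, 5
        def random_aln(protein):
            cols = [
                "".join(rng.choice(list(aa), size=n_species)) for _ in range(n_cols)
            ]
            return _columns_to_alignment(cols, self.species[:n_species], protein)
        aln_a, aln_b = random_aln("a"), random_aln("b")
        score = i2h_score(aln_a, aln_b, min_common=8)
        correlations = []
        for i in range(n_cols):
            for j in range(n_cols):
                col_a = "".join(aln_a.rows[s][i] for s in self.species[:n_species])
                col_b = "".join(aln_b.rows[s][j] for s in self.species[:n_species])
                r = mclachlan_site_correlation(col_a, col_b)
                if r is not None:
                    correlations.append(r)
        if not correlations:
            assert score is None
        else:
            expected = sum(1 for r in correlations if r >= 0.5) / len(correlations)
            assert score == pytest.approx(expected)

    def test_planted_covariation_recovered(self):
        hits = 0
        for seed in range(1, 11):
            rng = np.random.default_rng(seed)
            tree = synthetic.random_bifurcating_tree(self.species, rng)
            aln_a, aln_b = synthetic.generate_coupled_alignments(
                tree, coupling=0.0, length=12, rng=rng, rate=0.15
            )
            null = i2h_score(aln_a, aln_b, min_common=8)
            # plant: 4 columns of b deterministically mapped from a
            aa = np.array(list("ARNDCQEGHILKMFPSTWYV"))
            rows_b = {s: np.array(list(seq)) for s, seq in aln_b.rows.items()}
            for col_a, col_b in [(0, 1), (2, 3), (4, 5), (6, 7)]:
                mapping = dict(zip("ARNDCQEGHILKMFPSTWYV", aa[rng.permutation(20)]))
                for s in rows_b:
                    rows_b[s][col_b] = mapping[aln_a.rows[s][col_a]]
            planted_aln = OrthologAlignment(
                protein="b", rows={s: "".join(r) for s, r in rows_b.items()}
            )
            planted = i2h_score(aln_a, planted_aln, min_common=8)
            if planted is not None and (null is None or planted > null):
                hits += 1
        assert hits >= 9


# ---------------------------------------------------------------------------
# GF
# ---------------------------------------------------------------------------

class TestIngestGf:
    def test_passthrough(self):
        pairs = PairList()
        pairs.add("a", "b", score=3.1)
        assert ingest_gf(pairs) == {("a", "b"): 3.1}

    def test_duplicates_keep_maximum(self):
        pairs = PairList()
        pairs.add("a", "b", score=1.0)
        pairs.add("a", "b", score=2.0)
        assert ingest_gf(pairs) == {("a", "b"): 2.0}

    def test_empty(self):
        assert ingest_gf(PairList()) == {}

    def test_scoreless_pair_rejected(self):
        pairs = PairList()
        pairs.add("a", "b")
        with pytest.raises(ValueError):
            ingest_gf(pairs)
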