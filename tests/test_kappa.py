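from fractions import Fraction

import numpy as np
import pytest

from pathprocnet.annotation_io import TermRecord
from pathprocnet.enrichment import ContingencyCounts
from pathprocnet.kappa import KappaError, contingency, kappa_matrix, kappa_score


def kappa_bruteforce(a, b, c, d):
    """Direct rational arithmetic from the agreement definition."""
    n = a + b + c + d
    pr_agree = Fraction(a + d, n)
    pr_random = Fraction((a + b) * (a + c) + (b + d) * (c + d), n * n)
    if pr_random == 1:
        return 1.0 if b == c == 0 else 0.0
    return float((pr_agree - pr_random) / (1 - pr_random))


def classify_bruteforce(gi, gj, universe):
    """Per-element membership tally, the independent contingency oracle."""
    a = b = c = d = 0
    for gene in universe:
        in_i, in_j = gene in gi, gene in gj
        if in_i and in_j:
            a += 1
        elif in_i:
            b += 1
        elif in_j:
            c += 1
        else:
            d += 1
    return a, b, c, d


class TestContingency:
    def test_identical_sets(self):
        counts = contingency({"g1", "g2"}, {"g1", "g2"}, {"g1", "g2", "g3", "g4"})
        assert (counts.a, counts.b, counts.c, counts.d) == (2, 0, 0, 2)

    def test_disjoint_cover(self):
        counts = contingency({"g1"}, {"g2"}, {"g1", "g2"})
        assert (counts.a, counts.b, counts.c, counts.d) == (0, 1, 1, 0)

    def test_empty_universe_rejected(self):
        with pytest.raises(KappaError):
            contingency({"g1"}, {"g2"}, set())

    def test_random_sets_match_membership_tally(self):
        rng = np.random.default_rng(17)
        universe = [f"G{i}" for i in range(30)]
        for _ in range(50):
            gi = set(rng.choice(universe, size=int(rng.integers(0, 21)), replace=False))
            gj = set(rng.choice(universe, size=int(rng.integers(0, 21)), replace=False))
            counts = contingency(gi, gj, universe)
            assert (counts.a, counts.b, counts.c, counts.d) == classify_bruteforce(gi, gj, universe)


class TestKappaScore:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((2, 0, 0, 2), 1.0),       # perfect agreement
            ((0, 1, 1, 0), -1.0),      # total disagreement at chance 0.5
            ((2, 1, 1, 6), 11 / 21),   # worked value by direct arithmetic
        ],
    )
    def test_reference_values(self, table, expected):
        assert kappa_score(ContingencyCounts(*table)) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_rational_oracle_on_random_tables(self):
        rng = np.random.default_rng(23)
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if a + b + c + d == 0:
                continue
            assert kappa_score(ContingencyCounts(a, b, c, d)) == pytest.approx(
                kappa_bruteforce(a, b, c, d), abs=1e-12
            )

    def test_degenerate_chance_agreement(self):
        # both sets empty: agree exactly -> 1; universe split without overlap -> 0
        assert kappa_score(ContingencyCounts(0, 0, 0, 5)) == 1.0
        assert kappa_score(ContingencyCounts(5, 0, 0, 0)) == 1.0

    def test_symmetry_and_kappa_one_iff_equal_sets(self):
        rng = np.random.default_rng(31)
        universe = [f"G{i}" for i in range(25)]
        for _ in range(200):
            gi = set(rng.choice(universe, size=int(rng.integers(1, 15)), replace=False))
            gj = set(rng.choice(universe, size=int(rng.integers(1, 15)), replace=False))
            kij = kappa_score(contingency(gi, gj, universe))
            kji = kappa_score(contingency(gj, gi, universe))
            assert kij == pytest.approx(kji, abs=1e-15)
            assert (kij == pytest.approx(1.0)) == (gi == gj)


class TestKappaMatrix:
    def _terms(self, prefix, sets, source="GOBP"):
        return [
            TermRecord(f"{prefix}{i}", f"{prefix}{i}", source, frozenset(s))
            for i, s in enumerate(sets)
        ]

    def test_single_identical_pair(self):
        g = self._terms("GO:", [{"A", "B"}])
        p = self._terms("hsa", [{"A", "B"}], source="KEGG")
        m = kappa_matrix(g, p, universe={"A", "B", "C"})
        assert m.scores.shape == (1, 1) and m.scores[0, 0] == 1.0

    def test_duplicated_gene_set_is_row_maximum(self):
        rng = np.random.default_rng(3)
        universe = [f"G{i}" for i in range(40)]
        sets = [set(rng.choice(universe, size=10, replace=False)) for _ in range(4)]
        g = self._terms("GO:", sets)
        p = self._terms("hsa", [sets[2], set(universe[:5])], source="KEGG")
        m = kappa_matrix(g, p, universe=universe)
        assert m.scores[2, 0] == 1.0
        assert m.scores[2, 0] == m.scores[2].max() == m.scores[:, 0].max()

    def test_every_cell_matches_pairwise_recomputation(self):
        rng = np.random.default_rng(7)
        universe = [f"G{i}" for i in range(50)]
        g = self._terms("GO:", [set(rng.choice(universe, size=12, replace=False)) for _ in range(5)])
        p = self._terms(
            "hsa", [set(rng.choice(universe, size=9, replace=False)) for _ in range(4)], "KEGG"
        )
        m = kappa_matrix(g, p, universe=universe)
        for i, gt in enumerate(g):
            for j, pt in enumerate(p):
                expected = kappa_score(contingency(gt.genes, pt.genes, universe))
                assert m.scores[i, j] == pytest.approx(expected, abs=1e-12)

    def test_default_universe_is_union_of_all_terms(self):
        g = self._terms("GO:", [{"A", "B"}])
        p = self._terms("hsa", [{"B", "C"}], source="KEGG")
        expected = kappa_score(contingency({"A", "B"}, {"B", "C"}, {"A", "B", "C"}))
        assert kappa_matrix(g, p).scores[0, 0] == pytest.approx(expected)

    def test_duplicate_ids_rejected(self):
        g = self._terms("GO:", [{"A"}, {"B"}])
        g[1] = TermRecord("GO:0", "dup", "GOBP", frozenset({"B"}))
        with pytest.raises(KappaError, match="duplicate"):
            kappa_matrix(g, self._terms("hsa", [{"A"}], "KEGG"), universe={"A", "B"})

    def test_tsv_roundtrip(self, tmp_path):
        from pathprocnet.kappa import KappaMatrix

        g = self._terms("GO:", [{"A", "B"}, {"C"}])
        p = self._terms("hsa", [{"A"}, {"B", "C"}], source="KEGG")
        m = kappa_matrix(g, p, universe={"A", "B", "C", "D"})
        path = tmp_path / "kappa.tsv"
        m.write_tsv(path)
        back = KappaMatrix.read_tsv(path)
        assert back.gobp_ids == m.gobp_ids and back.pathway_ids == m.pathway_ids
        np.testing.assert_allclose(back.scores, m.scores, atol=1e-9)
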