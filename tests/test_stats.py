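"""Count tables, KLd/Z-score statistics, ordination and composition."""

import numpy as np
import pandas as pd
import pytest

from sashape.stats import (CountTable, aa_composition, bonferroni_threshold,
                           correspondence_analysis, count_letters, kld,
                           pca_descriptors, preferential_pct, zscore)


def table_from(rows: dict) -> CountTable:
    return CountTable.from_dict(
        {l: dict(zip(("interface", "surface", "core"), v)) for l, v in rows.items()})


class TestCountLetters:
    def test_hand_tally(self, model):
        from sashape.encoder import StructuralSequence
        from sashape.io import ResidueKey
        from sashape.sasa import AccessibilityRecord
        keys = [ResidueKey("A", i) for i in range(1, 7)]
        seq = StructuralSequence("t", None, [], residue_letter_map={
            keys[0]: "A", keys[1]: "A", keys[2]: "L",
            keys[3]: "D", keys[4]: "D", keys[5]: "D"})
        recs = [AccessibilityRecord(keys[0], "A", 0, 0, 0, compartment="core"),
                AccessibilityRecord(keys[1], "A", 0, 0, 0, compartment="surface"),
                AccessibilityRecord(keys[2], "A", 0, 0, 0, compartment="surface"),
                AccessibilityRecord(keys[3], "A", 0, 0, 0, compartment="interface"),
                AccessibilityRecord(keys[4], "A", 0, 0, 0, compartment="undefined"),
                AccessibilityRecord(keys[5], "A", 0, 0, 0, compartment="core")]
        table = count_letters([seq], recs)
        assert table.counts.loc["A", "core"] == 1
        assert table.counts.loc["A", "surface"] == 1
        assert table.counts.loc["L", "surface"] == 1
        assert table.counts.loc["D", "interface"] == 1
        assert table.counts.loc["D", "core"] == 1
        assert table.counts.to_numpy().sum() == 5   # undefined excluded

    def test_empty_intersection_raises(self):
        from sashape.encoder import StructuralSequence
        seq = StructuralSequence("t", None, [], residue_letter_map={})
        with pytest.raises(ValueError):
            count_letters([seq], [])


class TestKld:
    def test_zero_when_letter_matches_class(self):
        t = table_from({"D": (10, 20, 70), "E": (10, 20, 70)})
        entry = kld(t, "D")
        assert entry.kld == pytest.approx(0.0, abs=1e-12)
        assert not entry.significant

    def test_direct_evaluation_against_formula(self):
        # letter D: (10,20,70); letter E fills class totals to (100,100,100)
        t = table_from({"D": (10, 20, 70), "E": (90, 80, 30)})
        entry = kld(t, "D")
        expected = 0.1 * np.log(0.3) + 0.2 * np.log(0.6) + 0.7 * np.log(2.1)
        assert entry.kld == pytest.approx(expected, abs=1e-12)
        assert entry.kld == pytest.approx(0.2968, abs=5e-5)
        assert entry.quantity == pytest.approx(59.36, abs=0.01)
        assert entry.critical == pytest.approx(5.99, abs=0.005)
        assert entry.significant

    def test_zero_class_frequency_with_mass_raises(self):
        t = table_from({"D": (10, 0, 0), "E": (5, 0, 0)})
        entry = kld(t, "D")     # q zero only where p zero: fine
        assert np.isfinite(entry.kld)
        t2 = table_from({"D": (10, 5, 0), "E": (5, 0, 0)})
        # class surface frequency comes only from D itself -> still positive
        assert np.isfinite(kld(t2, "D").kld)


class TestZscore:
    def test_zero_when_observed_equals_expected(self):
        t = table_from({"L": (30, 30, 0), "M": (70, 70, 0)})
        entry = zscore(t, "L", "interface", "surface")
        assert entry.z == pytest.approx(0.0, abs=1e-12)

    def test_direct_evaluation(self):
        # class totals: interface 100, surface 100; f_surface(L) = 0.2
        t = table_from({"L": (30, 20, 0), "M": (70, 80, 0)})
        entry = zscore(t, "L", "interface", "surface")
        assert entry.n_exp == pytest.approx(20.0)
        assert entry.z == pytest.approx(10 / np.sqrt(20), abs=1e-9)
        assert entry.meaningful

    def test_small_expectation_not_meaningful(self):
        t = table_from({"L": (3, 2, 0), "M": (7, 8, 0)})
        entry = zscore(t, "L", "interface", "surface")
        assert entry.n_exp == pytest.approx(2.0)
        assert not entry.meaningful

    def test_sign_tracks_relative_frequency(self, rng):
        # Z > 0 iff the letter is relatively more frequent in cp1 than cp2
        for _ in range(50):
            counts = rng.integers(1, 200, size=(2, 3))
            t = table_from({"L": tuple(counts[0]), "M": tuple(counts[1])})
            e = zscore(t, "L", "surface", "core")
            f1 = counts[0, 1] / (counts[0, 1] + counts[1, 1])
            f2 = counts[0, 2] / (counts[0, 2] + counts[1, 2])
            if abs(f1 - f2) > 1e-12:
                assert (e.z > 0) == (f1 > f2)


class TestBonferroni:
    @pytest.mark.parametrize("m,expected", [(1, 1.960), (12, 2.865), (39, 3.220)])
    def test_two_sided_quantiles(self, m, expected):
        assert bonferroni_threshold(0.05, m, "two") == pytest.approx(expected, abs=5e-4)

    def test_one_sided_is_smaller(self):
        assert bonferroni_threshold(0.05, 10, "one") < bonferroni_threshold(0.05, 10, "two")


class TestCorrespondenceAnalysis:
    def test_independent_table_has_zero_inertia(self):
        r = np.array([5, 10, 25], float)
        c = np.array([2, 3, 5], float)
        table = pd.DataFrame(np.outer(r, c), index=list("XYZ"),
                             columns=["interface", "surface", "core"])
        res = correspondence_analysis(table)
        assert res.total == pytest.approx(0.0, abs=1e-12)

    def test_letters_by_three_table_has_two_axes(self):
        t = table_from({"D": (10, 20, 70), "E": (90, 80, 30), "F": (5, 8, 2),
                        "G": (40, 2, 9)})
        res = correspondence_analysis(t)
        assert res.row_coords.shape == (4, 2)
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_inertia_matches_eigendecomposition_oracle(self):
        n = np.array([[10.0, 20, 30], [5, 50, 10], [25, 5, 40]])
        table = pd.DataFrame(n, index=list("XYZ"),
                             columns=["interface", "surface", "core"])
        res = correspondence_analysis(table)
        # independent oracle: eigenvalues of SᵀS for the residual matrix
        p = n / n.sum()
        r, c = p.sum(1), p.sum(0)
        s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        eig = np.sort(np.linalg.eigvalsh(s.T @ s))[::-1][:2]
        np.testing.assert_allclose(np.sort(res.values)[::-1], eig, atol=1e-12)


class TestPca:
    def test_points_on_a_line_give_pc1_100(self):
        t = np.outer(np.arange(10.0), np.array([1.0, 2.0, -1.0, 0.5]))
        res = pca_descriptors(t + 1.0, standardize=False)
        assert res.explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_2d_eigenvalues(self, rng):
        x = rng.normal(size=(40, 2))
        res = pca_descriptors(x, standardize=False)
        cov = np.cov(x, rowvar=False)
        tr, det = cov[0, 0] + cov[1, 1], np.linalg.det(cov)
        lam = (tr + np.sqrt(tr ** 2 - 4 * det)) / 2      # quadratic-formula oracle
        assert res.values[0] == pytest.approx(lam, abs=1e-10)

    def test_matches_sklearn_on_random_table(self, rng):
        from sklearn.decomposition import PCA
        x = rng.normal(size=(27, 4)) * np.array([1.0, 3.0, 0.5, 2.0])
        res = pca_descriptors(x, standardize=True)
        xs = (x - x.mean(0)) / x.std(0, ddof=1)
        sk = PCA().fit(xs)
        np.testing.assert_allclose(res.explained, sk.explained_variance_ratio_,
                                   atol=1e-10)

    def test_zero_variance_column_raises(self):
        x = np.ones((10, 4))
        with pytest.raises(ValueError):
            pca_descriptors(x, standardize=True)


class TestPreferentialPct:
    def test_zero_when_observed_proportional_to_expected(self):
        t = table_from({"L": (10, 20, 30), "M": (20, 40, 60)})
        for cp in ("interface", "surface", "core"):
            assert preferential_pct(t, "strand", cp) == pytest.approx(0.0, abs=1e-9)

    def test_two_letter_hand_case(self):
        # X:(80,20), Y:(20,80) over two compartments -> 30% in each
        t = table_from({"L": (80, 20, 0), "M": (20, 80, 0)})
        assert preferential_pct(t, "strand", "interface") == pytest.approx(30.0)
        assert preferential_pct(t, "strand", "surface") == pytest.approx(30.0)

    def test_bounded_on_random_tables(self, rng):
        for _ in range(200):
            t = table_from({"L": tuple(rng.integers(1, 100, 3)),
                            "M": tuple(rng.integers(1, 100, 3)),
                            "N": tuple(rng.integers(1, 100, 3))})
            pct = preferential_pct(t, "strand", "core")
            assert 0.0 <= pct <= 100.0


class TestAaComposition:
    def test_single_residue_is_indicator(self):
        from sashape.encoder import StructuralSequence
        from sashape.io import CaChain, ResidueKey
        from sashape.sasa import AccessibilityRecord
        keys = [ResidueKey("A", i) for i in range(1, 5)]
        chain = CaChain("A", keys, list("GWGG"),
                        np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [9.0, 3, 0]]))
        seq = StructuralSequence("t", chain, [], residue_letter_map={keys[1]: "A"})
        recs = [AccessibilityRecord(keys[1], "W", 0, 0, 0, compartment="core")]
        comp = aa_composition([seq], recs)
        assert comp.loc[("A", "core"), "W"] == pytest.approx(1.0)
        assert comp.loc[("A", "core")].sum() == pytest.approx(1.0)
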