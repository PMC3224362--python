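"""Chain pairing, transition matrices, exposure differences and RMSD."""

import numpy as np
import pandas as pd
import pytest

from sashape.deformation import (PositionMap, changed_fraction, delta_p,
                                 deformation_proportions, exposure_difference,
                                 kabsch_rmsd, pair_chains, straight_letter_shift,
                                 transition_counts)
from sashape.io import CaChain, ResidueKey
from sashape.model import LETTERS
from sashape.synthetic import HelixSpec, make_helix


def chain_with_sequence(seq: str, chain_id="A", start=1) -> CaChain:
    helix = make_helix(HelixSpec(n_residues=max(len(seq), 4)))
    keys = [ResidueKey(chain_id, start + i) for i in range(len(seq))]
    return CaChain(chain_id, keys, list(seq), helix.coords[:len(seq)])


class TestPairChains:
    def test_identical_sequences_map_fully(self):
        u = chain_with_sequence("AVLIEKRDST")
        b = chain_with_sequence("AVLIEKRDST", chain_id="B")
        pmap = pair_chains(u, b)
        assert len(pmap) == 10
        assert pmap.identity == 100.0

    def test_missing_n_terminal_residues_excluded(self):
        u = chain_with_sequence("AVLIEKRDST")
        b = chain_with_sequence("LIEKRDST", chain_id="B")
        pmap = pair_chains(u, b)
        assert len(pmap) == 8
        assert [k.residue_number for k in pmap.unaligned_unbound] == [1, 2]

    def test_internal_gap_pairs_flanks_only(self):
        u = chain_with_sequence("AVLIEKRDST")
        b = chain_with_sequence("AVLRDST", chain_id="B")   # IEK missing
        pmap = pair_chains(u, b)
        paired_u = [k.residue_number for k, _ in pmap.pairs]
        assert paired_u == [1, 2, 3, 7, 8, 9, 10]

    def test_low_identity_raises(self):
        u = chain_with_sequence("AAAAAAAAAA")
        b = chain_with_sequence("WWWWWWWWWW", chain_id="B")
        with pytest.raises(ValueError, match="identity"):
            pair_chains(u, b)


def make_map(n, chain_u="U", chain_b="B"):
    pairs = [(ResidueKey(chain_u, i + 1), ResidueKey(chain_b, i + 1))
             for i in range(n)]
    return PositionMap(pairs=pairs)


class TestTransitionCounts:
    def test_identical_strings_are_diagonal(self):
        pmap = make_map(5)
        lu = {k: "A" for k, _ in pmap.pairs}
        lb = {k: "A" for _, k in pmap.pairs}
        cp = {k: "core" for _, k in pmap.pairs}
        c = transition_counts(pmap, lu, lb, cp)
        assert c["core"].loc["A", "A"] == 5
        assert changed_fraction(c["core"]) == 0.0

    def test_hand_counted_example(self):
        # unbound BAAaaC vs bound BAAAAC, all at the interface
        pmap = make_map(6)
        lu = dict(zip((k for k, _ in pmap.pairs), "BAAaaC"))
        lb = dict(zip((k for _, k in pmap.pairs), "BAAAAC"))
        cp = {k: "interface" for _, k in pmap.pairs}
        c = transition_counts(pmap, lu, lb, cp)
        ci = c["interface"]
        assert ci.loc["a", "A"] == 2
        assert np.trace(ci.to_numpy()) == 4
        assert changed_fraction(ci) == pytest.approx(2 / 6)

    def test_positions_without_letters_skipped(self):
        pmap = make_map(3)
        keys_u = [k for k, _ in pmap.pairs]
        keys_b = [k for _, k in pmap.pairs]
        lu = {keys_u[0]: "A", keys_u[2]: "V"}
        lb = {keys_b[0]: "A", keys_b[1]: "W"}
        cp = {k: "surface" for k in keys_b}
        c = transition_counts(pmap, lu, lb, cp)
        assert c["surface"].to_numpy().sum() == 1


class TestDeformationProportions:
    def test_single_deformation(self):
        c = pd.DataFrame(0, index=list(LETTERS), columns=list(LETTERS))
        c.loc["a", "A"] = 1
        p = deformation_proportions(c)
        assert p.loc["a", "A"] == pytest.approx(1.0)
        assert list(p.index) == ["a"]

    def test_three_to_one_ratio(self):
        c = pd.DataFrame(0, index=list(LETTERS), columns=list(LETTERS))
        c.loc["a", "A"] = 3
        c.loc["a", "V"] = 1
        c.loc["a", "a"] = 10          # diagonal never contributes
        p = deformation_proportions(c)
        assert p.loc["a", "A"] == pytest.approx(0.75)
        assert p.loc["a", "V"] == pytest.approx(0.25)

    def test_rows_sum_to_one(self, rng):
        c = pd.DataFrame(rng.integers(0, 20, size=(27, 27)),
                         index=list(LETTERS), columns=list(LETTERS))
        p = deformation_proportions(c)
        np.testing.assert_allclose(p.sum(axis=1, skipna=True), 1.0, atol=1e-12)


class TestDeltaP:
    def test_identical_matrices_give_zero(self):
        c = pd.DataFrame(0, index=list(LETTERS), columns=list(LETTERS))
        c.loc["a", "A"] = 2
        p = deformation_proportions(c)
        d, missing = delta_p(p, p)
        assert float(d.loc["a", "A"]) == pytest.approx(0.0)
        assert not missing["interface_only"] and not missing["surface_only"]

    def test_row_missing_on_one_side_uses_zero_and_flags(self):
        ci = pd.DataFrame(0, index=list(LETTERS), columns=list(LETTERS))
        ci.loc["a", "A"] = 4
        cs = pd.DataFrame(0, index=list(LETTERS), columns=list(LETTERS))
        cs.loc["L", "N"] = 2
        d, missing = delta_p(deformation_proportions(ci), deformation_proportions(cs))
        assert d.loc["a", "A"] == pytest.approx(1.0)
        assert d.loc["L", "N"] == pytest.approx(-1.0)
        assert missing == {"surface_only": ["L"], "interface_only": ["a"]}

    def test_entries_bounded(self, rng):
        ci = pd.DataFrame(rng.integers(0, 9, (27, 27)), index=list(LETTERS),
                          columns=list(LETTERS))
        cs = pd.DataFrame(rng.integers(0, 9, (27, 27)), index=list(LETTERS),
                          columns=list(LETTERS))
        d, _ = delta_p(deformation_proportions(ci), deformation_proportions(cs))
        v = d.to_numpy()
        assert np.nanmin(v) >= -1.0 and np.nanmax(v) <= 1.0


class TestExposureDifference:
    def setup_positions(self):
        pmap = make_map(4)
        keys_u = [k for k, _ in pmap.pairs]
        keys_b = [k for _, k in pmap.pairs]
        # loop-letter transitions: D->U (s/s), D->G (s/c), G->U (c/s), G->E (c/c)
        lu = dict(zip(keys_u, "DDGG"))
        lb = dict(zip(keys_b, "UGUE"))
        cp = {k: "interface" for k in keys_b}
        au = dict(zip(keys_u, [30.0, 30.0, 50.0, 10.0]))
        ab = dict(zip(keys_b, [40.0, 25.0, 50.0, 4.0]))
        return pmap, lu, lb, cp, au, ab

    def test_sign_convention_and_aggregates(self):
        pmap, lu, lb, cp, au, ab = self.setup_positions()
        positions, agg = exposure_difference(pmap, lu, lb, cp, au, ab)
        assert len(positions) == 4
        # unbound 30%, bound 40% -> D = -10 (more exposed upon binding)
        assert positions.loc[0, "D"] == pytest.approx(-10.0)
        assert set(positions["category"]) == {"s/s", "s/c", "c/s", "c/c"}
        assert agg.loc["s/s", "mean"] == pytest.approx(-10.0)
        assert agg.loc["s/c", "median"] == pytest.approx(5.0)
        assert agg.loc["c/c", "mean"] == pytest.approx(6.0)

    def test_unchanged_letters_and_non_interface_positions_excluded(self):
        pmap, lu, lb, cp, au, ab = self.setup_positions()
        keys_b = [k for _, k in pmap.pairs]
        lb2 = dict(lb)
        lb2[keys_b[0]] = "D"            # unchanged letter
        cp2 = dict(cp)
        cp2[keys_b[1]] = "surface"      # not at interface
        positions, _ = exposure_difference(pmap, lu, lb2, cp2, au, ab)
        assert len(positions) == 2


class TestStraightLetterShift:
    @pytest.mark.parametrize("u,b,expected", [
        ("AATM", "AATM", 0),
        ("aa", "AA", +2),
        ("ATMa", "aVWD", -3),
        ("LLNN", "TMLN", +2),
    ])
    def test_counts(self, u, b, expected):
        assert straight_letter_shift(list(u), list(b)) == expected


class TestKabschRmsd:
    def test_identical_sets_give_zero(self, rng):
        x = rng.normal(size=(10, 3))
        assert kabsch_rmsd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_gives_zero(self, rng):
        from scipy.spatial.transform import Rotation
        x = rng.normal(size=(12, 3))
        rot = Rotation.random(random_state=3).as_matrix()
        y = x @ rot.T + np.array([5.0, -3.0, 9.0])
        assert kabsch_rmsd(x, y) == pytest.approx(0.0, abs=1e-9)

    def test_collinear_scaling_closed_form(self):
        x = np.array([[-1.0, 0, 0], [0, 0, 0], [1.0, 0, 0]])
        assert kabsch_rmsd(x, 2 * x) == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)

    def test_symmetric_and_rotation_invariant(self, rng):
        from scipy.spatial.transform import Rotation
        x = rng.normal(size=(8, 3))
        y = x + rng.normal(scale=0.3, size=(8, 3))
        r = kabsch_rmsd(x, y)
        assert kabsch_rmsd(y, x) == pytest.approx(r, abs=1e-9)
        rot = Rotation.random(random_state=11).as_matrix()
        assert kabsch_rmsd(x @ rot.T, y) == pytest.approx(r, abs=1e-9)

    def test_agrees_with_scipy_align_vectors(self, rng):
        from scipy.spatial.transform import Rotation
        x = rng.normal(size=(15, 3))
        y = x + rng.normal(scale=0.5, size=(15, 3))
        xc, yc = x - x.mean(0), y - y.mean(0)
        rot, rssd = Rotation.align_vectors(yc, xc)
        assert kabsch_rmsd(x, y) == pytest.approx(rssd / np.sqrt(15), abs=1e-8)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))
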