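"""Dihedrals, Ramachandran-box classification and backbone H-bonds."""

import gemmi
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betalayer.geometry import (
    backbone_hbonds,
    classify_phi_psi,
    compute_torsions,
    dihedral,
    torsion_table,
)
from betalayer.synthetic import build_backbone_from_torsions
from tests.conftest import random_rigid_transform


class TestDihedral:
    def test_planar_anti(self):
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (-1, 1, 0)) == pytest.approx(180.0)

    def test_planar_syn(self):
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (1, 1, 0)) == pytest.approx(0.0)

    def test_perpendicular_sign_matches_independent_formula(self):
        """±90° case checked against gemmi's independent implementation."""
        pts = [(1, 0, 0), (0, 0, 0), (0, 1, 0), (0, 1, 1)]
        ours = dihedral(*pts)
        ref = np.degrees(
            gemmi.calculate_dihedral(*(gemmi.Position(*p) for p in pts))
        )
        assert abs(ours) == pytest.approx(90.0)
        assert ours == pytest.approx(ref)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_gemmi_on_random_points(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-5, 5, size=(4, 3))
        ours = dihedral(*pts)
        ref = np.degrees(gemmi.calculate_dihedral(*(gemmi.Position(*p) for p in pts)))
        if np.isfinite(ours):
            assert np.isclose(
                np.exp(1j * np.radians(ours)), np.exp(1j * np.radians(ref)), atol=1e-6
            )

    def test_degenerate_geometry_gives_nan(self):
        assert np.isnan(dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)))
        assert np.isnan(dihedral((2, 0, 0), (1, 0, 0), (0, 0, 0), (-1, 0, 0)))

    def test_rigid_invariance_and_mirror_flip(self, rng):
        pts = rng.uniform(-3, 3, size=(4, 3))
        base = dihedral(*pts)
        R, t = random_rigid_transform(rng)
        moved = pts @ R.T + t
        assert dihedral(*moved) == pytest.approx(base, abs=1e-6)
        mirrored = pts * np.array([1, 1, -1])
        assert dihedral(*mirrored) == pytest.approx(-base, abs=1e-6)


class TestClassification:
    @pytest.mark.parametrize(
        "phi, psi, expected",
        [
            (-65, -40, "alpha"),
            (-120, 130, "beta"),
            (-30, -40, "other"),      # phi outside -180..-40
            (-40, -10, "alpha"),      # boundaries inclusive
            (-40, 20, "beta"),
            (-40, -9.99, "other"),    # just outside alpha in psi
            (-120, 0, "other"),       # between the boxes in psi
            (60, 40, "other"),
            (float("nan"), -40, "undefined"),
        ],
    )
    def test_box_membership(self, phi, psi, expected):
        assert classify_phi_psi(phi, psi) == expected

    @given(
        st.floats(-180, 180, allow_nan=False),
        st.floats(-180, 180, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_boxes_are_disjoint(self, phi, psi):
        assert classify_phi_psi(phi, psi) in {"alpha", "beta", "other"}
        # alpha and beta are separated in psi, so no pair is ever both;
        # membership tested independently here:
        in_alpha = -180 <= phi <= -40 and -70 <= psi <= -10
        in_beta = -180 <= phi <= -40 and 20 <= psi <= 180
        assert not (in_alpha and in_beta)
        if in_alpha:
            assert classify_phi_psi(phi, psi) == "alpha"
        if in_beta:
            assert classify_phi_psi(phi, psi) == "beta"


class TestComputeTorsions:
    def test_round_trip_uniform_helix(self):
        chain = build_backbone_from_torsions([(-57, -47)] * 12)
        ts = compute_torsions(chain)
        assert np.allclose(ts.phi[1:], -57, atol=1e-3)
        assert np.allclose(ts.psi[:-1], -47, atol=1e-3)
        assert np.isnan(ts.phi[0]) and np.isnan(ts.psi[-1])
        assert ts.ss_class[0] == "undefined" and ts.ss_class[-1] == "undefined"
        assert all(c == "alpha" for c in ts.ss_class[1:-1])

    def test_round_trip_random_torsions(self, rng):
        tors = [
            (float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180)))
            for _ in range(15)
        ]
        chain = build_backbone_from_torsions(tors)
        ts = compute_torsions(chain)
        for i in range(1, 15):
            assert ts.phi[i] == pytest.approx(tors[i][0], abs=1e-3)
        for i in range(14):
            assert ts.psi[i] == pytest.approx(tors[i][1], abs=1e-3)

    def test_rigid_invariance(self, rng):
        chain = build_backbone_from_torsions([(-57, -47)] * 8 + [(-120, 130)] * 3)
        base = compute_torsions(chain)
        for _ in range(3):
            R, t = random_rigid_transform(rng)
            moved = chain.transformed(R, t)
            ts = compute_torsions(moved)
            assert np.allclose(ts.phi[1:], base.phi[1:], atol=1e-6)
            assert np.allclose(ts.psi[:-1], base.psi[:-1], atol=1e-6)

    def test_incomplete_residue_breaks_segment(self):
        chain = build_backbone_from_torsions([(-57, -47)] * 9)
        chain.coords["O"][4] = np.nan  # knock out one carbonyl
        ts = compute_torsions(chain)
        assert ts.ss_class[4] == "undefined"
        # neighbours lose the torsion crossing the incomplete residue
        assert np.isnan(ts.psi[3]) and np.isnan(ts.phi[5])

    def test_torsion_table_layout(self):
        chain = build_backbone_from_torsions([(-57, -47)] * 5, sequence="AAAAA")
        table = torsion_table(chain)
        assert list(table.columns) == [
            "chain", "resnum", "icode", "aa", "phi", "psi", "class",
        ]
        assert len(table) == 5


class TestHBonds:
    @staticmethod
    def _pair(distance_no, distance_on=10.0):
        """Two single-residue chains with controlled N-O distances."""
        a = build_backbone_from_torsions([(-57, -47)], chain_id="A")
        b = build_backbone_from_torsions([(-57, -47)], chain_id="B")
        # place B's O at the requested distance from A's N, and B's N far
        # from A's O unless asked otherwise
        shift = a.coords["N"][0] + np.array([distance_no, 0, 0]) - b.coords["O"][0]
        for name in b.coords:
            b.coords[name] = b.coords[name] + shift
        b.coords["N"][0] = a.coords["O"][0] + np.array([0, distance_on, 0])
        return a, b

    def test_single_direction_contact(self):
        a, b = self._pair(2.9)
        contacts = backbone_hbonds((a, 0), (b, 0))
        assert len(contacts) == 1
        assert contacts[0].n_o_distance == pytest.approx(2.9)
        assert contacts[0].direction == "N_i->O_j"

    def test_cutoff_is_inclusive(self):
        a, b = self._pair(3.5)
        assert len(backbone_hbonds((a, 0), (b, 0))) == 1
        a, b = self._pair(3.5000001)
        assert backbone_hbonds((a, 0), (b, 0)) == []

    def test_both_directions_counted(self):
        a, b = self._pair(2.9, distance_on=3.1)
        contacts = backbone_hbonds((a, 0), (b, 0))
        assert {c.direction for c in contacts} == {"N_i->O_j", "N_j->O_i"}

    def test_missing_atom_warns_and_skips(self):
        a, b = self._pair(2.9)
        b.coords["O"][0] = np.nan
        with pytest.warns(UserWarning):
            assert backbone_hbonds((a, 0), (b, 0)) == []
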