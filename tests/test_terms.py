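"""The five additive shift terms against independent oracles."""

import math
from pathlib import Path

import numpy as np
import pytest

from amideshift.fixtures import make_dimer
from amideshift.params import read_series_file, read_surface_file
from amideshift.structure import AcceptorClass, AmideGroup, AromaticRing, HydrogenBond, detect_hydrogen_bonds
from amideshift.terms import (BondNetwork, GridSurface, TermBreakdown, backbone_term,
                              primary_hb_term, ring_current_term, secondary_hb_term,
                              tertiary_term)

DATA = Path(__file__).resolve().parents[1] / "src" / "amideshift" / "data"


def _fake_bond(klass, r_ho, angle_hoc, angle_nho=165.0):
    donor = AmideGroup(chain="A", res_index=2, res_name="ALA",
                       h=np.array([1.01, 0.0, 0.0]), n=np.zeros(3),
                       c_carbonyl=np.array([0.0, 2.0, 0.0]),
                       o_carbonyl=np.array([0.0, 3.0, 0.0]))
    return HydrogenBond(donor=donor, acceptor_chain="A", acceptor_res_index=9,
                        acceptor_res_name="XXX", acceptor_atom="O",
                        acceptor_class=klass, r_ho=r_ho, angle_hoc=angle_hoc,
                        angle_nho=angle_nho, dihedral_rho=0.0)


class TestBackboneTerm:
    def test_series_matches_term_by_term_oracle(self, params):
        series = read_series_file(DATA / "backbone_series.txt")
        phi, psi = -57.0, -47.0
        basis = {"cc": lambda a, b: math.cos(a) * math.cos(b),
                 "cs": lambda a, b: math.cos(a) * math.sin(b),
                 "sc": lambda a, b: math.sin(a) * math.cos(b),
                 "ss": lambda a, b: math.sin(a) * math.sin(b)}
        expected = sum(c * basis[bs](m * math.radians(phi), n * math.radians(psi))
                       for m, n, bs, c in series)
        got = backbone_term(phi, psi, (1.0, 0.0), params.backbone_series)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_degenerate_scaling_is_constant(self, params):
        for angles in [(-57.0, -47.0), (100.0, -30.0)]:
            assert backbone_term(*angles, (0.0, 8.0), params.backbone_series) == 8.0

    def test_identity_scaling_at_symmetry_point(self, params):
        # at (0, 0) every sine basis vanishes; the value is the plain cosine sum
        raw = sum(c for m, n, bs, c in params.backbone_series if bs == "cc")
        assert backbone_term(0.0, 0.0, (1.0, 0.0), params.backbone_series) == pytest.approx(raw, abs=1e-12)


class TestRingCurrent:
    def _axis_ring(self, intensity=1.0):
        return AromaticRing(res_index=1, chain="A", kind="PHE6",
                            center=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]),
                            intensity=intensity)

    def test_magic_angle_zero(self):
        theta = np.arccos(1.0 / np.sqrt(3.0))
        h = 4.0 * np.array([np.sin(theta), 0.0, np.cos(theta)])
        assert abs(ring_current_term(h, [self._axis_ring()])) < 1e-9

    def test_axial_hand_value(self):
        # i * B * (1 - 3cos^2 0) / r^3 = 30.42 * (-2) / 27
        got = ring_current_term(np.array([0.0, 0.0, 3.0]), [self._axis_ring()], B=30.42)
        assert got == pytest.approx(30.42 * (1 - 3) / 27.0, abs=1e-9)

    def test_axial_equatorial_sign_flip(self):
        axial = ring_current_term(np.array([0.0, 0.0, 3.0]), [self._axis_ring()])
        equatorial = ring_current_term(np.array([3.0, 0.0, 0.0]), [self._axis_ring()])
        assert axial < 0 < equatorial

    def test_cubic_decay(self):
        near = ring_current_term(np.array([0.0, 0.0, 3.0]), [self._axis_ring()])
        far = ring_current_term(np.array([0.0, 0.0, 100.0]), [self._axis_ring()])
        assert abs(far) < 1e-4 * abs(near)

    def test_proton_at_center_is_an_error(self):
        with pytest.raises(ValueError, match="ring center"):
            ring_current_term(np.zeros(3), [self._axis_ring()])


class TestPrimaryBondTerm:
    def test_solvent_exposed_water_value(self, params):
        hb = _fake_bond(AcceptorClass.NONE, float("inf"), float("nan"))
        assert primary_hb_term(hb, params) == 2.07

    def test_amide_term_decays_monotonically(self, params):
        radii = np.arange(1.8, 3.01, 0.1)
        vals = [primary_hb_term(_fake_bond(AcceptorClass.BACKBONE_AMIDE, r, 155.0), params)
                for r in radii]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(v > 0 for v in vals)

    def test_real_dimer_path_decays(self, params):
        vals = []
        for r in (1.8, 2.1, 2.4):
            d = make_dimer(r, 150.0)
            hb = next(b for b in detect_hydrogen_bonds(d) if b.bonded)
            vals.append(primary_hb_term(hb, params))
        assert vals[0] > vals[1] > vals[2]

    def test_grid_nodes_reproduced_exactly(self, params):
        _, r_nodes, a_nodes, values = read_surface_file(DATA / "surface_carboxylate.txt")
        for i in (0, 3, len(r_nodes) - 1):
            for j in (0, 4, len(a_nodes) - 1):
                hb = _fake_bond(AcceptorClass.CARBOXYLATE, float(r_nodes[i]), float(a_nodes[j]))
                assert primary_hb_term(hb, params) == pytest.approx(values[i, j], abs=1e-12)

    def test_bilinear_between_node_bounds(self, params):
        _, r_nodes, a_nodes, values = read_surface_file(DATA / "surface_alcohol.txt")
        surface = GridSurface(AcceptorClass.ALCOHOL, r_nodes, a_nodes, values)
        r = 0.5 * (r_nodes[2] + r_nodes[3])
        a = 0.5 * (a_nodes[5] + a_nodes[6])
        corners = values[2:4, 5:7]
        v = surface(r, a)
        assert corners.min() - 1e-12 <= v <= corners.max() + 1e-12

    def test_out_of_range_clamps(self, params):
        inside = primary_hb_term(_fake_bond(AcceptorClass.CARBOXYLATE, 3.0, 175.0), params)
        beyond = primary_hb_term(_fake_bond(AcceptorClass.CARBOXYLATE, 4.5, 175.0), params)
        assert beyond == pytest.approx(inside, abs=1e-12)


class TestSecondaryAndTertiary:
    def test_no_secondary_bond_is_zero(self, params):
        assert secondary_hb_term(None, params) == 0.0

    def test_secondary_magnitude_decays(self, params):
        vals = [secondary_hb_term(_fake_bond(AcceptorClass.BACKBONE_AMIDE, r, 150.0), params)
                for r in (1.9, 2.2, 2.5)]
        assert abs(vals[0]) > abs(vals[1]) > abs(vals[2])

    def test_secondary_matches_coefficient_file(self, params):
        coeffs = {}
        for line in (DATA / "hbond_secondary.txt").read_text().splitlines():
            if line and not line.startswith("#"):
                k, v = line.split()
                coeffs[k] = float(v)
        r, ang = 1.95, 152.0
        expected = (coeffs["amplitude_ppm"] * math.exp(-coeffs["decay_inv_angstrom"] * r)
                    * math.cos(math.radians(ang)) ** 2)
        got = secondary_hb_term(_fake_bond(AcceptorClass.BACKBONE_AMIDE, r, ang), params)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_tertiary_unbonded_partner_zero(self, params):
        assert tertiary_term(BondNetwork(False, False), params) == 0.0

    def test_tertiary_reproduces_increment_table(self, params):
        incr = {}
        for line in (DATA / "tertiary_increments.txt").read_text().splitlines():
            if line and not line.startswith("#"):
                k, v = line.split()
                incr[k] = float(v)
        assert tertiary_term(BondNetwork(True, False), params) == incr["primary_partner_bonded"]
        assert tertiary_term(BondNetwork(True, True), params) == pytest.approx(
            incr["primary_partner_bonded"] + incr["secondary_partner_bonded"], abs=1e-15)

    def test_tertiary_smaller_than_primary(self, params):
        primary = primary_hb_term(_fake_bond(AcceptorClass.BACKBONE_AMIDE, 2.0, 155.0), params)
        assert abs(tertiary_term(BondNetwork(True, True), params)) < abs(primary)


def test_breakdown_total_is_exact_sum():
    bd = TermBreakdown(5.1, 1.8, 0.3, 0.1, -0.4)
    assert bd.total == pytest.approx(5.1 + 1.8 + 0.3 + 0.1 - 0.4, abs=1e-15)
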