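import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dynifp as d
from dynifp.contact_engine import _BASIC_RESNAMES  # noqa: F401 (sanity import)

from conftest import brute_force_hbond, brute_force_vdw


def make_sel(indices, label=""):
    return d.Selection(atom_indices=tuple(indices), label=label)


def carbon_pair_topology(distance):
    """Two lone carbon 'residues' at a given separation."""
    atoms = (
        d.AtomRecord(1, "CB", "C", "ALA", 1, "A", (0.0, 0.0, 0.0)),
        d.AtomRecord(2, "CB", "C", "ALA", 2, "A", (distance, 0.0, 0.0)),
    )
    return d.Topology(atoms=atoms, residues=(("A", 1, "ALA"), ("A", 2, "ALA")))


class TestVdwContact:
    radii = d.bondi_radii()

    @pytest.mark.parametrize("distance,expected", [
        (3.30, True),   # < 1.70 + 1.70
        (3.40, True),   # boundary is inclusive
        (3.50, False),
    ])
    def test_carbon_pair_boundary(self, distance, expected):
        top = carbon_pair_topology(distance)
        present, pairs = d.vdw_contact_present(
            top.coords(), make_sel([0]), make_sel([1]), self.radii,
            top.elements())
        assert present is expected
        assert pairs == ([(0, 1)] if expected else [])

    def test_missing_radius_names_element(self):
        atoms = (
            d.AtomRecord(1, "XX", "Xx", "UNK", 1, "A", (0.0, 0.0, 0.0)),
            d.AtomRecord(2, "CB", "C", "ALA", 2, "A", (1.0, 0.0, 0.0)),
        )
        top = d.Topology(atoms=atoms, residues=(("A", 1, "UNK"), ("A", 2, "ALA")))
        with pytest.raises(KeyError, match="Xx"):
            d.vdw_contact_present(top.coords(), make_sel([0]), make_sel([1]),
                                  self.radii, top.elements())

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.random((20, 3)) * 8
        elements = ["C", "N", "O", "H"] * 5
        a, b = make_sel(range(10)), make_sel(range(10, 20))
        p1, pairs1 = d.vdw_contact_present(coords, a, b, self.radii, elements)
        p2, pairs2 = d.vdw_contact_present(coords, b, a, self.radii, elements)
        assert p1 == p2
        assert {(i, j) for i, j in pairs1} == {(j, i) for i, j in pairs2}

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        coords = rng.random((n, 3)) * 12
        elements = list(rng.choice(["C", "N", "O", "H", "S"], size=n))
        split = n // 2
        a, b = make_sel(range(split)), make_sel(range(split, n))
        _, pairs = d.vdw_contact_present(coords, a, b, self.radii, elements)
        assert pairs == brute_force_vdw(coords, range(split), range(split, n),
                                        self.radii, elements)


def hbond_fixture(d_da, off_axis_deg):
    """Ser OG–HG donor and a carbonyl-O acceptor at controlled geometry."""
    theta = np.radians(off_axis_deg)
    acceptor = (d_da * np.cos(theta), d_da * np.sin(theta), 0.0)
    atoms = (
        d.AtomRecord(1, "OG", "O", "SER", 1, "A", (0.0, 0.0, 0.0)),
        d.AtomRecord(2, "HG", "H", "SER", 1, "A", (1.0, 0.0, 0.0)),
        d.AtomRecord(3, "O", "O", "GLY", 2, "A", acceptor),
    )
    top = d.Topology(atoms=atoms, residues=(("A", 1, "SER"), ("A", 2, "GLY")))
    donors = [d.DonorGroup(donor_heavy=0, hydrogen=1)]
    return top.coords(), donors, [2]


class TestHBond:
    @pytest.mark.parametrize("d_da,angle,expected", [
        (3.0, 0.0, True),    # collinear mid-range
        (2.5, 0.0, True),    # lower distance bound inclusive
        (3.5, 0.0, True),    # upper distance bound inclusive
        (3.6, 0.0, False),   # beyond distance
        (2.4, 0.0, False),   # below distance
        (3.0, 29.0, True),   # just inside angle
        (3.0, 31.0, False),  # beyond angle
        (3.0, 35.0, False),
    ])
    def test_boundary_contract(self, d_da, angle, expected):
        coords, donors, acceptors = hbond_fixture(d_da, angle)
        present, triples = d.hbond_present(coords, donors, acceptors)
        assert present is expected
        assert triples == ([(0, 1, 2)] if expected else [])

    def test_angle_bound_is_strict_distance_inclusive(self):
        # exactly 30 degrees off-axis fails; exactly 2.5 A passes
        coords, donors, acceptors = hbond_fixture(3.0, 30.0)
        assert d.hbond_present(coords, donors, acceptors)[0] is False
        coords, donors, acceptors = hbond_fixture(2.5, 0.0)
        assert d.hbond_present(coords, donors, acceptors)[0] is True

    def test_qualifying_triples_respect_bounds(self):
        rng = np.random.default_rng(4)
        coords = rng.random((30, 3)) * 10
        atoms = []
        for i in range(30):
            el = ["N", "O", "H", "C"][i % 4]
            atoms.append(d.AtomRecord(i + 1, f"{el}{i}", el, "UNK", i + 1, "A",
                                      tuple(coords[i])))
        top = d.Topology(atoms=tuple(atoms),
                         residues=tuple(("A", i + 1, "UNK") for i in range(30)))
        donors, acceptors = d.enumerate_donors_acceptors(top)
        crit = d.HBondCriteria()
        _, triples = d.hbond_present(coords, donors, acceptors, crit)
        for D, H, A in triples:
            assert crit.d_min <= np.linalg.norm(coords[D] - coords[A]) <= crit.d_max
        assert triples == brute_force_hbond(coords, donors, acceptors, crit)

    def test_hydrogen_vertex_convention(self):
        # collinear D-H-A: angle at H is 180 deg, deviation 0 -> present
        coords, donors, acceptors = hbond_fixture(3.0, 0.0)
        crit = d.HBondCriteria(vertex="hydrogen")
        assert d.hbond_present(coords, donors, acceptors, crit)[0] is True


class TestEnumerateDonorsAcceptors:
    def test_serine_donor_group(self, small_topology):
        donors, acceptors = d.enumerate_donors_acceptors(small_topology)
        ser_og = next(i for i, a in enumerate(small_topology.atoms)
                      if a.residue_seq == 1 and a.name == "OG")
        ser_hg = next(i for i, a in enumerate(small_topology.atoms)
                      if a.residue_seq == 1 and a.name == "HG")
        assert d.DonorGroup(ser_og, ser_hg) in donors
        assert ser_og in acceptors

    def test_acceptor_without_h_is_not_donor(self, small_topology):
        donors, acceptors = d.enumerate_donors_acceptors(small_topology)
        asp_od1 = next(i for i, a in enumerate(small_topology.atoms)
                       if a.residue_name == "ASP" and a.name == "OD1")
        assert asp_od1 in acceptors
        assert all(g.donor_heavy != asp_od1 for g in donors)

    def test_carbons_excluded(self, small_topology):
        donors, acceptors = d.enumerate_donors_acceptors(small_topology)
        carbons = {i for i, a in enumerate(small_topology.atoms)
                   if a.element == "C"}
        assert not carbons & set(acceptors)
        assert not carbons & {g.donor_heavy for g in donors}


class TestResidueContactSeries:
    def test_programmed_vdw_schedule_recovered(self):
        definition = d.ContactDefinition(kind="vdw", side_a=("A", 6, "ALA"),
                                         side_b="ligand")
        spec = d.SyntheticSpec(
            n_residues=6, ligand_atoms=3, n_frames=100,
            schedules=(d.ContactSchedule(definition, 0.63, "vdw-touch"),),
            seed=3)
        top = d.synth_topology(spec)
        tr = d.synth_trajectory(top, spec)
        series = d.residue_contact_series(tr, definition)
        assert sum(series.presence) == 63

    def test_apo_ligand_side_errors(self):
        spec = d.SyntheticSpec(n_residues=3, ligand_atoms=0, n_frames=5)
        top = d.synth_topology(spec)
        tr = d.synth_trajectory(top, spec)
        definition = d.ContactDefinition(kind="vdw", side_a=("A", 1, "SER"),
                                         side_b="ligand")
        with pytest.raises(ValueError, match="empty selection"):
            d.residue_contact_series(tr, definition)

    def test_distant_pair_all_false(self, small_topology, small_spec):
        tr = d.synth_trajectory(small_topology, small_spec)
        definition = d.ContactDefinition(kind="hbond", side_a=("A", 1, "SER"),
                                         side_b=("A", 2, "TYR"))
        series = d.residue_contact_series(tr, definition)
        assert not any(series.presence)


class TestSaltBridgeAnnotation:
    @pytest.mark.parametrize("res_a,res_b,flagged", [
        (("A", 185, "LYS"), ("A", 190, "ASP"), True),
        (("A", 182, "ASP"), ("A", 185, "LYS"), True),
        (("A", 107, "SER"), ("A", 251, "TYR"), False),
    ])
    def test_charged_pairs(self, res_a, res_b, flagged, small_topology):
        definition = d.ContactDefinition(kind="hbond", side_a=res_a, side_b=res_b)
        out = d.annotate_salt_bridge(definition, small_topology)
        assert out.charged_pair_flag is flagged
        assert out.kind == "hbond"  # geometry stays the H-bond criterion
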