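"""Solvent accessibility, contact detection, secondary structure, omega."""

import numpy as np
import pytest

from tmimpact.constants import vdw_radius
from tmimpact.features import (
    BondGraph, assign_secondary_structure, compute_sasa, find_disulphides,
    find_hbonds, find_salt_bridges, is_cis, omega_angle,
)
from tmimpact.fixtures import (
    FixtureSpec, build_contact_motif, build_fixture, build_gxg,
)
from tmimpact.structure import (
    Atom, Chain, Residue, ResidueSelector, Structure, StructureError,
)


def carbon_structure(coords):
    """HET residues of single carbon atoms at the given centres."""
    ch = Chain(chain_id="A")
    for i, c in enumerate(coords, start=1):
        r = Residue(chain_id="A", seq_id=i, aa_type="HET", het=True, name="C1")
        r.atoms.append(Atom(name="C", element="C", coord=np.asarray(c, float)))
        ch.residues.append(r)
    return Structure(chains=[ch], id="carbons")


class TestSasa:
    def test_isolated_atom_analytic_sphere(self):
        s = carbon_structure([[0, 0, 0]])
        res = compute_sasa(s, probe=1.4, points=960)
        expected = 4.0 * np.pi * (1.70 + 1.4) ** 2
        got = res.atom_sasa[(ResidueSelector("A", 1), "C")]
        assert got == pytest.approx(expected, rel=0.01)

    def test_fully_enclosed_atom_is_zero(self):
        # icosahedral-ish cage of carbons tight around a central atom
        from tmimpact.fixtures import _fibonacci_sphere
        shell = 2.6 * _fibonacci_sphere(60)
        s = carbon_structure([[0, 0, 0]] + list(shell))
        res = compute_sasa(s, probe=1.4, points=960)
        assert res.atom_sasa[(ResidueSelector("A", 1), "C")] == 0.0

    def test_two_sphere_closed_form(self):
        """Two overlapping equal spheres lose the analytic cap area."""
        d = 4.0
        s = carbon_structure([[0, 0, 0], [d, 0, 0]])
        res = compute_sasa(s, probe=1.4, points=960)
        r = 1.70 + 1.4
        cap = 2.0 * np.pi * r * (r - d / 2.0)  # spherical cap hidden per atom
        expected = 4.0 * np.pi * r * r - cap
        for i in (1, 2):
            got = res.atom_sasa[(ResidueSelector("A", i), "C")]
            assert got == pytest.approx(expected, rel=0.02)

    def test_residue_sum_equals_atom_sum(self, helix20):
        s, _ = helix20
        res = compute_sasa(s, points=240)
        assert sum(res.residue_sasa.values()) == pytest.approx(
            sum(res.atom_sasa.values()), abs=1e-6)

    @pytest.mark.parametrize("aa", ["A", "L", "R", "W", "G"])
    def test_rsa_of_reference_tripeptide_is_unity(self, aa):
        """RSA of X in the extended Gly-X-Gly reference is ~1 by
        construction of the packaged maxima."""
        s = build_gxg(aa)
        res = compute_sasa(s)
        rsa = res.rsa(ResidueSelector("A", 2))
        assert rsa == pytest.approx(1.0, abs=0.1)

    def test_cross_check_against_biotite(self, helix20):
        """Independent Shrake-Rupley implementation agrees on a helix."""
        biotite_struct = pytest.importorskip("biotite.structure")
        s, _ = helix20
        atoms = [(r, a) for r in s.residues() for a in r.heavy_atoms()]
        arr = biotite_struct.AtomArray(len(atoms))
        for i, (r, a) in enumerate(atoms):
            arr.coord[i] = a.coord
            arr.chain_id[i] = r.chain_id
            arr.res_id[i] = r.seq_id
            arr.res_name[i] = r.aa_type
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
        radii = np.array([a.vdw_radius for _, a in atoms], dtype=np.float32)
        ref = biotite_struct.sasa(arr, probe_radius=1.4, vdw_radii=radii,
                                  point_number=960)
        ours = compute_sasa(s, points=960)
        total_ref = float(np.nansum(ref))
        total_ours = sum(ours.atom_sasa.values())
        assert total_ours == pytest.approx(total_ref, rel=0.02)


def motif(kind, distance, seq_pair=None):
    spec = FixtureSpec(kind="contact_motif", length=1,
                       sequence=(seq_pair or "E")[0], motif=kind,
                       contact_distance=distance)
    return build_contact_motif(spec)


class TestContacts:
    @pytest.mark.parametrize("d,found", [(4.9, True), (5.1, False),
                                         (3.0, True)])
    def test_salt_bridge_cutoff_strict(self, d, found):
        s, _ = motif("salt_bridge", d)
        bridges = find_salt_bridges(s)
        assert bool(bridges) is found
        if found:
            assert len(bridges) == 1
            assert bridges[0].distance == pytest.approx(d, abs=1e-6)

    def test_like_charges_not_a_bridge(self):
        from tmimpact.fixtures import build_chain, _apply
        s1 = build_chain("E", phi=-57, psi=-47, chain_id="A")
        s2 = build_chain("D", phi=-57, psi=-47, chain_id="B")
        _apply(s2, shift=np.array([3.0, 0.0, 0.0]) +
               s1.chains[0].residues[0].atom("OE1").coord -
               s2.chains[0].residues[0].atom("OD1").coord)
        s = Structure(chains=[s1.chains[0], s2.chains[0]])
        assert find_salt_bridges(s) == []

    @pytest.mark.parametrize("d,found", [(2.05, True), (3.2, True),
                                         (3.5, False)])
    def test_disulphide_cutoff(self, d, found):
        s, _ = motif("disulphide", d)
        assert bool(find_disulphides(s)) is found

    def test_single_cysteine_no_disulphide(self):
        from tmimpact.fixtures import build_chain
        s = build_chain("C", phi=-57, psi=-47)
        assert find_disulphides(s) == []

    @pytest.mark.parametrize("d,found", [(2.9, True), (4.4, True),
                                         (4.6, False)])
    def test_hbond_cutoff(self, d, found):
        s, _ = motif("hbond", d)
        pairs = {frozenset((c.a[1], c.b[1])) for c in find_hbonds(s)
                 if c.a[0] != c.b[0]}
        assert (frozenset(("OG", "ND2")) in pairs) is found

    def test_helix_backbone_ladder_matches_brute_force(self, helix20):
        """All i -> i+4 backbone bonds are present and the full contact
        list equals an all-pairs distance scan under the same rules."""
        s, _ = helix20
        graph = BondGraph(s)
        contacts = find_hbonds(s, 3.5, 1.0, graph)
        got = {frozenset((c.a, c.b)) for c in contacts}
        residues = list(s.residues(amino_only=True))
        for i in range(len(residues) - 4):
            a = (residues[i + 4].selector, "N")
            b = (residues[i].selector, "O")
            assert frozenset((a, b)) in got

        # brute-force oracle: element rules + cutoff + bond-graph exclusion
        expected = set()
        atoms = [(r.selector, a) for r in residues for a in r.heavy_atoms()]
        for i in range(len(atoms)):
            for j in range(len(atoms)):
                (sa, aa), (sb, ab) = atoms[i], atoms[j]
                if sa == sb or i == j:
                    continue
                if aa.element not in ("N", "O", "S") or ab.element not in ("N", "O"):
                    continue
                d = np.linalg.norm(aa.coord - ab.coord)
                if d >= 4.5:
                    continue
                if graph.within_two_bonds((sa, aa.name), (sb, ab.name)):
                    continue
                expected.add(frozenset(((sa, aa.name), (sb, ab.name))))
        assert got == expected

    def test_slack_monotonicity(self, helix20):
        s, _ = helix20
        graph = BondGraph(s)
        counts = [len(find_hbonds(s, 3.5, sl, graph))
                  for sl in (0.0, 0.5, 1.0, 1.5, 2.0)]
        assert counts == sorted(counts)
        counts_sb = [len(find_salt_bridges(s, 4.0, sl))
                     for sl in (0.0, 1.0, 2.0)]
        assert counts_sb == sorted(counts_sb)


class TestSecondaryStructure:
    def test_ideal_helix_all_h(self, helix20):
        s, _ = helix20
        labels = assign_secondary_structure(s)
        assert all(v == "H" for v in labels.values())

    def test_extended_chain_has_no_helix(self):
        s, _ = build_fixture(FixtureSpec(kind="extended_chain", length=10,
                                         sequence="L" * 10))
        labels = assign_secondary_structure(s)
        assert "H" not in labels.values()

    def test_two_residue_chain_all_coil(self):
        from tmimpact.fixtures import build_chain
        s = build_chain("LL", phi=-57, psi=-47)
        labels = assign_secondary_structure(s)
        assert set(labels.values()) == {"C"}

    def test_invariant_under_rigid_motion(self, helix20):
        from tmimpact.geometry import rotation_x
        from tmimpact.structure import transform_structure
        s, _ = helix20
        moved = transform_structure(s, rotation_x(77.0),
                                    np.array([10.0, -3.0, 8.0]))
        assert assign_secondary_structure(s) == {
            k: v for k, v in assign_secondary_structure(moved).items()}

    def test_hairpin_turn_is_bend(self):
        from tmimpact.fixtures import build_buried_gly_bend
        s, truth = build_buried_gly_bend()
        labels = assign_secondary_structure(s)
        assert labels[ResidueSelector("A", 5)] == "B"


class TestOmega:
    def test_cis_and_trans_classification(self):
        s, truth = build_fixture(FixtureSpec(kind="cis_peptide", length=3,
                                             sequence="APA"))
        om = omega_angle(s, ResidueSelector("A", 2))
        assert om == pytest.approx(0.0, abs=1e-6)
        assert is_cis(om)
        om3 = omega_angle(s, ResidueSelector("A", 3))
        assert abs(om3) == pytest.approx(180.0, abs=1e-6)
        assert not is_cis(om3)

    def test_helix_omegas_all_trans(self, helix20):
        s, _ = helix20
        for res in list(s.residues(amino_only=True))[1:]:
            assert not is_cis(omega_angle(s, res.selector))

    def test_first_residue_has_no_omega(self, helix20):
        s, _ = helix20
        with pytest.raises(StructureError):
            omega_angle(s, ResidueSelector("A", 1))
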