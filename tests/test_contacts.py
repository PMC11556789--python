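import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_plant_spec
from oracles import (all_heavy_predicate, residue_contact_sets,
                     sidechain_heavy_predicate)
from saltcondense.contacts import (ContactParams, classify_pair,
                                   contact_residue_pairs,
                                   contacts_per_residue,
                                   residue_contact_partners,
                                   typed_interchain_contacts,
                                   typed_pairs_in_frame)
from saltcondense.model import Frame, Trajectory, build_topology
from saltcondense.synthetic import (ContactPlant, PlantSpec,
                                    make_planted_condensate)

RES_CODES = ["ARG", "LYS", "ASP", "GLU", "TYR", "PHE", "ASN", "GLN",
             "GLY", "SER", "ALA", "HIS", "TRP", "MET"]


class TestClassifyPair:
    @pytest.mark.parametrize("a,b,label", [
        ("ARG", "ASP", "salt_bridge"),
        ("LYS", "GLU", "salt_bridge"),
        ("ARG", "TYR", "cation_pi"),
        ("LYS", "PHE", "cation_pi"),
        ("ASN", "TYR", "amino_pi"),
        ("GLN", "PHE", "amino_pi"),
        ("TYR", "TYR", "pi_pi"),
        ("TYR", "PHE", "pi_pi"),
        ("GLY", "SER", "other"),
        ("ARG", "ASN", "other"),
    ])
    def test_rule_table(self, a, b, label):
        assert classify_pair(a, b) == label

    @given(a=st.sampled_from(RES_CODES), b=st.sampled_from(RES_CODES))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_total(self, a, b):
        assert classify_pair(a, b) == classify_pair(b, a)
        assert classify_pair(a, b) in ("salt_bridge", "cation_pi", "amino_pi",
                                       "pi_pi", "other")

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            classify_pair("ARG", "XYZ")


def _two_residue_frame(gap: float):
    """Two single-residue Gly chains whose nearest heavy atoms sit ``gap``
    apart along x (closest pair: C of chain 0, N of chain 1)."""
    top = build_topology([["GLY"], ["GLY"]])
    a = np.array([[-1.2, 0, 0], [0, 0, 0], [1.2, 0, 0], [1.2, 1.3, 0]])
    b = a + np.array([2.4 + gap, 0.0, 0.0])
    shift = np.array([40.0, 40.0, 40.0])
    return top, Frame(np.vstack([a, b]) + shift, (100.0, 100.0, 100.0))


class TestContactCutoff:
    def test_boundary_at_six_angstrom(self):
        params = ContactParams()
        top, frame = _two_residue_frame(5.9)
        assert contact_residue_pairs(frame, top, params) == {(0, 1)}
        top, frame = _two_residue_frame(6.1)
        assert contact_residue_pairs(frame, top, params) == set()

    def test_intra_neighbor_exclusion(self):
        """A residue whose only near partner is its sequence neighbor has an
        empty intra partner set."""
        top = build_topology(["GGG"])
        from saltcondense.synthetic import chain_template
        coords = chain_template(top.chain_sequence(0)) + 40.0
        frame = Frame(coords, (100.0, 100, 100))
        params = ContactParams()
        assert residue_contact_partners(frame, top, 1, params,
                                        scope="intra") == set()
        # with exclusion disabled the neighbours appear
        params0 = ContactParams(intra_neighbor_exclusion=0)
        assert residue_contact_partners(frame, top, 1, params0,
                                        scope="intra") == {0, 2}

    def test_monotone_in_cutoff(self, small_planted):
        traj, _ = small_planted
        frame = traj.frames[0]
        sizes = [len(contact_residue_pairs(frame, traj.topology,
                                           ContactParams(cutoff=c)))
                 for c in (4.0, 6.0, 8.0)]
        assert sizes == sorted(sizes)


class TestAgainstBruteForce:
    def test_planted_fixture_matches_ledger_and_oracle(self, small_planted):
        traj, truth = small_planted
        top = traj.topology
        frame = traj.frames[0]
        params = ContactParams()
        pairs = contact_residue_pairs(frame, top, params)
        inter = {p for p in pairs
                 if top.residues[p[0]].chain_id != top.residues[p[1]].chain_id}
        oracle_inter, oracle_intra = residue_contact_sets(
            frame, top, params.cutoff, all_heavy_predicate(top),
            params.intra_neighbor_exclusion)
        assert inter == oracle_inter == truth.contacts_inter
        intra = {p for p in pairs
                 if top.residues[p[0]].chain_id == top.residues[p[1]].chain_id
                 and abs(top.residues[p[0]].local_index
                         - top.residues[p[1]].local_index)
                 > params.intra_neighbor_exclusion}
        assert intra == oracle_intra == truth.contacts_intra

    @pytest.mark.parametrize("seed", range(6))
    def test_randomized_fixtures_match_oracle(self, seed):
        traj, truth = make_planted_condensate(random_plant_spec(300 + seed))
        top = traj.topology
        frame = traj.frames[0]
        params = ContactParams()
        oracle_inter, oracle_intra = residue_contact_sets(
            frame, top, params.cutoff, all_heavy_predicate(top),
            params.intra_neighbor_exclusion)
        assert oracle_inter == truth.contacts_inter
        assert oracle_intra == truth.contacts_intra
        pairs = contact_residue_pairs(frame, top, params)
        got_inter = {p for p in pairs if top.residues[p[0]].chain_id
                     != top.residues[p[1]].chain_id}
        assert got_inter == oracle_inter

    def test_symmetry_and_degree_sum(self, small_planted):
        """Sum over residues of inter partner counts is twice the number of
        inter-chain pairs."""
        traj, _ = small_planted
        top = traj.topology
        frame = traj.frames[0]
        params = ContactParams()
        pairs = contact_residue_pairs(frame, top, params)
        inter = {p for p in pairs if top.residues[p[0]].chain_id
                 != top.residues[p[1]].chain_id}
        degree = 0
        for r in range(top.n_residues):
            degree += len(residue_contact_partners(frame, top, r, params,
                                                   scope="inter"))
        assert degree == 2 * len(inter)


class TestTypedContacts:
    def test_planted_interaction_types_counted_exactly(self):
        # chains: Arg-bearing, Asp-bearing, Tyr/Phe, Gln -> plant one contact
        # of each type across distinct chain pairs
        seqs = ["GRGGG", "GDGGG", "GYGGG", "GQGGG"]
        spec = PlantSpec(n_chains=4, sequence=seqs, chain_length=5,
                         box=(140.0, 140.0, 140.0),
                         contact_plan=(ContactPlant(0, 1, 1, 1),
                                       ContactPlant(2, 1, 3, 1)),
                         seed=7)
        traj, truth = make_planted_condensate(spec)
        counts = typed_pairs_in_frame(traj.frames[0], traj.topology)
        expected = {label: len(pairs)
                    for label, pairs in truth.typed_inter.items()}
        assert dict(counts) == expected
        assert expected.get("salt_bridge", 0) >= 1   # planted Arg-Asp
        assert expected.get("amino_pi", 0) >= 1      # planted Tyr-Gln

    def test_per_chain_normalization(self, small_planted):
        traj, truth = small_planted
        summaries = typed_interchain_contacts(traj)
        for label, summary in summaries.items():
            expected = len(truth.typed_inter.get(label, ())) / \
                traj.topology.n_chains
            assert summary.mean == pytest.approx(expected, abs=1e-12)

    def test_backbone_only_proximity_not_typed(self):
        """Residues whose only close atoms are backbone atoms produce no
        typed (sidechain-scope) contact."""
        top = build_topology([["ARG"], ["ASP"]])
        from saltcondense.synthetic import chain_template
        a = chain_template(["ARG"])
        b = chain_template(["ASP"])
        # place chain 1 so backbones are 4 A apart but sidechain ladders
        # (which extend to +z) point away from each other
        b = b * np.array([1.0, 1.0, -1.0]) + np.array([0.0, 4.0, -4.0])
        coords = np.vstack([a, b]) + 50.0
        frame = Frame(coords, (120.0, 120, 120))
        all_scope = contact_residue_pairs(frame, top, ContactParams())
        side_scope = contact_residue_pairs(
            frame, top, ContactParams(atom_scope="sidechain_heavy"))
        assert all_scope == {(0, 1)}
        assert side_scope == set()


class TestContactsPerResidue:
    def test_isolated_chains_have_zero_inter(self):
        spec = PlantSpec(n_chains=3, chain_length=8, box=(120.0, 120, 120),
                         seed=5)
        traj, truth = make_planted_condensate(spec)
        assert truth.contacts_inter == set()
        s = contacts_per_residue(traj, "inter")
        assert s.mean == 0.0

    def test_mean_equals_ledger_arithmetic(self, small_planted):
        traj, truth = small_planted
        s = contacts_per_residue(traj, "inter")
        expected = 2.0 * len(truth.contacts_inter) / traj.topology.n_residues
        assert s.mean == pytest.approx(expected, abs=1e-12)

    def test_replicate_summary_spread(self, small_planted):
        traj, _ = small_planted
        s = contacts_per_residue([traj, traj], "inter")
        assert s.sd == 0.0
        assert len(s.per_replicate_values) == 2
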