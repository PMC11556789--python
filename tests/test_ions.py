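import numpy as np
import pytest

from conftest import random_plant_spec
from oracles import chains_contacted, image_min_distance, ion_shell
from saltcondense.ions import (assign_ion_shells, bridging_ions, compute_rdf,
                               count_bound_ions, net_charge_series,
                               protein_no_sites, rdf_points, select_sites,
                               suggest_shell_cutoffs)
from saltcondense.model import (DEFAULT_CUTOFFS, Frame, RDFResult,
                                ShellCutoffs, Trajectory, build_topology)
from saltcondense.synthetic import (IonPlant, PlantSpec, make_ideal_gas,
                                    make_planted_condensate)


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------


class TestRdf:
    def test_uniform_gas_is_flat(self):
        frame = make_ideal_gas(4000, (80.0, 80.0, 80.0), seed=2)
        rdf = rdf_points(frame.coords, None, frame.box, bin_width=0.25,
                         r_max=30.0)
        window = (rdf.bin_centers > 2.0) & (rdf.bin_centers < 30.0)
        g = rdf.g[window]
        assert abs(g.mean() - 1.0) < 0.01
        assert g.std() < 0.1

    def test_planted_thin_shell_recovers_pair_count(self):
        """All targets in a [3.0, 3.1] A shell around one center: g vanishes
        outside and the density integral returns the planted count."""
        box = np.array([60.0, 60.0, 60.0])
        rng = np.random.default_rng(5)
        n = 400
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        radii = rng.uniform(3.0, 3.1, size=n)
        center = box / 2
        targets = center + u * radii[:, None]
        rdf = rdf_points(np.array([center]), targets, box, bin_width=0.05,
                         r_max=10.0)
        r = rdf.bin_centers
        outside = (r < 2.95) | (r > 3.15)
        assert np.all(rdf.g[outside] == 0.0)
        rho = n / box.prod()
        shell = (4 / 3) * np.pi * np.diff(rdf.bin_edges ** 3)
        recovered = np.sum(rdf.g * rho * shell)
        assert recovered == pytest.approx(n, abs=1e-9)

    def test_first_shell_plant_peaks_near_contact_distance(self, small_planted):
        traj, _ = small_planted
        rdf = compute_rdf(traj, "ARG:sidechain_N", "CL", bin_width=0.05,
                          r_max=10.0)
        peak_r = rdf.bin_centers[np.argmax(rdf.g)]
        assert 3.0 < peak_r < 3.5      # planted first-shell distance 3.2 A

    def test_r_max_beyond_half_box_rejected(self, small_planted):
        traj, _ = small_planted
        with pytest.raises(ValueError, match="half"):
            compute_rdf(traj, "ARG:sidechain_N", "CL", r_max=100.0)

    def test_empty_target_selection_rejected(self, small_planted):
        traj, _ = small_planted
        with pytest.raises(ValueError):
            compute_rdf(traj, "ARG:sidechain_N", np.array([], dtype=int))


class TestSuggestShellCutoffs:
    @staticmethod
    def _profile(noise=0.0, seed=0):
        edges = np.arange(0.0, 8.0 + 0.025, 0.05)
        r = 0.5 * (edges[:-1] + edges[1:])
        g = np.interp(r, [0.0, 2.8, 3.2, 4.0, 5.2, 6.4, 7.5, 8.0],
                      [0.0, 0.0, 5.0, 0.5, 2.0, 0.9, 1.0, 1.0])
        if noise:
            g = g + np.random.default_rng(seed).normal(0, noise, size=g.size)
        return RDFResult(edges, g, 1.0, 1, 1)

    def test_planted_minima_recovered(self):
        cuts = suggest_shell_cutoffs(self._profile(), species="CL")
        assert cuts.first == pytest.approx(4.0, abs=0.1)
        assert cuts.second == pytest.approx(6.4, abs=0.1)

    def test_noisy_profile_within_bins(self):
        cuts = suggest_shell_cutoffs(self._profile(noise=0.02, seed=3))
        assert cuts.first == pytest.approx(4.0, abs=0.15)
        assert cuts.second == pytest.approx(6.4, abs=0.15)

    def test_featureless_profile_rejected(self):
        edges = np.arange(0.0, 8.0 + 0.025, 0.05)
        g = np.linspace(0.0, 1.0, edges.size - 1)
        with pytest.raises(ValueError, match="peak"):
            suggest_shell_cutoffs(RDFResult(edges, g, 1.0, 1, 1))


# ---------------------------------------------------------------------------
# shell assignment
# ---------------------------------------------------------------------------


def _ion_at_distance(d):
    """One Arg residue plus one Cl ion at distance d from NH2."""
    top = build_topology(["R"], ions={"CL": 1})
    from saltcondense.synthetic import chain_template
    coords = np.vstack([chain_template(["ARG"]),
                        np.zeros((1, 3))]) + np.array([40.0, 40.0, 40.0])
    nh2 = next(i for i in range(top.n_atoms) if top.atom_name[i] == "NH2")
    coords[-1] = coords[nh2] + np.array([0.0, 0.0, d])
    return top, Frame(coords, (100.0, 100.0, 100.0))


class TestShellAssignment:
    @pytest.mark.parametrize("d,shell", [
        (3.2, "first"), (4.0, "first"),          # boundary inclusive
        (5.0, "second"), (6.4, "second"),
        (7.0, None),
    ])
    def test_shell_bands_with_inclusive_boundaries(self, d, shell):
        top, frame = _ion_at_distance(d)
        sel = select_sites(top, "ARG:sidechain_N")
        recs = assign_ion_shells(frame, top, sel, DEFAULT_CUTOFFS["CL"], "CL")
        if shell is None:
            assert recs == []
        else:
            assert len(recs) == 1 and recs[0].shell == shell

    def test_partner_residues_within_second_cutoff(self):
        top, frame = _ion_at_distance(3.2)
        sel = select_sites(top, "ARG:sidechain_N")
        recs = assign_ion_shells(frame, top, sel, DEFAULT_CUTOFFS["CL"], "CL")
        assert recs[0].partner_residues == [(0, 0)]

    def test_species_absent_rejected(self):
        top, frame = _ion_at_distance(3.2)
        sel = select_sites(top, "ARG:sidechain_N")
        with pytest.raises(ValueError):
            assign_ion_shells(frame, top, sel, DEFAULT_CUTOFFS["NA"], "NA")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_randomized_plants(self, seed):
        traj, truth = make_planted_condensate(random_plant_spec(700 + seed))
        top = traj.topology
        frame = traj.frames[0]
        for rec in truth.ion_records:
            cuts = DEFAULT_CUTOFFS[rec.species]
            sel = select_sites(top, rec.site)
            oracle = ion_shell(frame, top, rec.atom_index,
                               sel.atom_indices, cuts)
            got = {r.ion_index: r.shell
                   for r in assign_ion_shells(frame, top, sel, cuts,
                                              rec.species)}
            if rec.shell == "unbound":
                assert oracle in (None, "second")   # unbound w.r.t. this site
                if rec.shell == "unbound":
                    all_no = protein_no_sites(top)
                    d = min(image_min_distance(frame.coords[rec.atom_index],
                                               frame.coords[a], frame.box)
                            for a in all_no.atom_indices)
                    assert d > cuts.second
            else:
                assert got[rec.atom_index] == rec.shell == oracle


# ---------------------------------------------------------------------------
# bound-ion counting (unique-ion rule)
# ---------------------------------------------------------------------------


class TestCountBoundIons:
    def test_bridging_ion_counted_once_per_selection(self):
        """A Cl in the first shell of Arg residues on two chains adds one,
        not two, to the Arg-sidechain total."""
        spec = PlantSpec(n_chains=2, chain_length=12,
                         box=(120.0, 120.0, 120.0),
                         ion_plan=(IonPlant("CL", "first", "ARG:sidechain_N",
                                            (0, 1)),),
                         seed=21)
        traj, truth = make_planted_condensate(spec)
        assert truth.ion_records[0].bridged_k == 2
        sel = {"arg_n": select_sites(traj.topology, "ARG:sidechain_N")}
        res = count_bound_ions(traj, sel, DEFAULT_CUTOFFS["CL"], "CL",
                               shell_mode="first_only")
        assert res["arg_n"].total.mean == 1.0
        # 2 chains x 1 Arg each -> 0.5 ions per Arg residue
        assert res["arg_n"].per_residue.mean == pytest.approx(0.5)

    def test_per_residue_normalization_from_ledger(self):
        plan = tuple(IonPlant("CL", "first", "ARG:sidechain_N", (c,))
                     for c in range(5))
        spec = PlantSpec(n_chains=8, chain_length=12,
                         box=(140.0, 140.0, 140.0), ion_plan=plan, seed=9)
        traj, truth = make_planted_condensate(spec)
        n_arg = sum(1 for r in traj.topology.residues if r.res_type == "ARG")
        assert n_arg == 8
        sel = {"arg_n": select_sites(traj.topology, "ARG:sidechain_N")}
        res = count_bound_ions(traj, sel, DEFAULT_CUTOFFS["CL"], "CL",
                               shell_mode="first_only")
        assert res["arg_n"].total.mean == 5.0
        assert res["arg_n"].per_residue.mean == pytest.approx(5.0 / 8.0)

    def test_first_leq_first_and_second(self, small_planted):
        traj, _ = small_planted
        sel = {"no": protein_no_sites(traj.topology)}
        for sp in ("CL", "NA"):
            first = count_bound_ions(traj, sel, DEFAULT_CUTOFFS[sp], sp,
                                     "first_only")["no"].total.mean
            both = count_bound_ions(traj, sel, DEFAULT_CUTOFFS[sp], sp,
                                    "first_and_second")["no"].total.mean
            assert first <= both

    def test_no_ions_means_zero(self):
        spec = PlantSpec(n_chains=2, chain_length=8, box=(100.0, 100, 100),
                         ion_plan=(IonPlant("CL", "unbound"),), seed=2)
        traj, _ = make_planted_condensate(spec)
        sel = {"no": protein_no_sites(traj.topology)}
        res = count_bound_ions(traj, sel, DEFAULT_CUTOFFS["CL"], "CL",
                               "first_and_second")
        assert res["no"].total.mean == 0.0


# ---------------------------------------------------------------------------
# net charge
# ---------------------------------------------------------------------------


class TestNetCharge:
    def test_no_bound_ions_gives_protein_charge(self):
        spec = PlantSpec(n_chains=4, chain_length=12, box=(120.0, 120, 120),
                         ion_plan=(IonPlant("CL", "unbound"),
                                   IonPlant("NA", "unbound")), seed=13)
        traj, _ = make_planted_condensate(spec)
        series = net_charge_series(traj)
        qp = traj.topology.total_protein_charge
        assert np.all(series.per_frame == qp)

    def test_planted_bound_counts_shift_charge(self):
        plan = (tuple(IonPlant("CL", "first", "backbone_O", (c % 3,))
                      for c in range(5))
                + tuple(IonPlant("NA", "first", "ASP:sidechain_O", (c,))
                        for c in range(2)))
        spec = PlantSpec(n_chains=3, chain_length=24,
                         box=(140.0, 140.0, 140.0), ion_plan=plan, seed=17)
        traj, truth = make_planted_condensate(spec)
        assert truth.bound_ions == {"CL": 5, "NA": 2}
        series = net_charge_series(traj)
        qp = traj.topology.total_protein_charge
        assert np.all(series.per_frame == qp + 2 - 5)

    @pytest.mark.parametrize("seed", range(5))
    def test_identity_holds_exactly_per_frame(self, seed):
        traj, _ = make_planted_condensate(random_plant_spec(900 + seed))
        series = net_charge_series(traj)
        np.testing.assert_array_equal(
            series.per_frame,
            series.protein_charge + series.na_bound - series.cl_bound)


# ---------------------------------------------------------------------------
# bridging
# ---------------------------------------------------------------------------


class TestBridging:
    def test_three_chain_bridge_multiplicity(self):
        spec = PlantSpec(n_chains=3, chain_length=12, box=(120.0, 120, 120),
                         ion_plan=(IonPlant("NA", "first", "backbone_O",
                                            (0, 1, 2), distance=2.5),),
                         seed=23)
        traj, truth = make_planted_condensate(spec)
        assert truth.bridge_k["NA"] == {3: 1}
        hist = bridging_ions(traj)
        assert hist.counts["NA"][3] == 1.0
        assert hist.bridging_total["NA"] == 1.0
        oracle = chains_contacted(traj.frames[0], traj.topology,
                                  traj.topology.ion_indices("NA")[0],
                                  DEFAULT_CUTOFFS["NA"].second)
        assert oracle == {0, 1, 2}

    def test_same_chain_multisite_is_not_bridging(self, small_planted):
        traj, truth = small_planted
        hist = bridging_ions(traj)
        # the two single-chain CL plants bind chain 0 only -> k = 1
        assert hist.counts["CL"][1] == 2.0
        assert hist.bridging_total["CL"] == 0.0
        assert hist.bridging_total["NA"] == 1.0    # the planted 2-chain bridge

    def test_fraction_bridging_fifth(self):
        """10 bound ions of which 2 bridge -> bridging fraction 0.2."""
        plan = (IonPlant("CL", "first", "backbone_O", (0, 1)),
                IonPlant("NA", "first", "backbone_O", (2, 3), distance=2.5))
        singles = tuple(IonPlant("CL", "first", "backbone_O", (c % 5,))
                        for c in range(8))
        spec = PlantSpec(n_chains=5, chain_length=24,
                         box=(160.0, 160.0, 160.0),
                         ion_plan=plan + singles, seed=29)
        traj, truth = make_planted_condensate(spec)
        hist = bridging_ions(traj)
        bound = sum(hist.bound_total.values())
        assert bound == 10.0
        assert hist.fraction_bridging() == pytest.approx(0.2)

    def test_single_chain_topology_rejected(self):
        spec = PlantSpec(n_chains=1, chain_length=8, box=(100.0, 100, 100),
                         ion_plan=(IonPlant("CL", "unbound"),), seed=1)
        traj, _ = make_planted_condensate(spec)
        with pytest.raises(ValueError, match="two chains"):
            bridging_ions(traj)

    @pytest.mark.parametrize("seed", range(5))
    def test_histogram_sums_match_bound_counts(self, seed):
        traj, truth = make_planted_condensate(random_plant_spec(1100 + seed))
        hist = bridging_ions(traj)
        for sp, counts in hist.counts.items():
            assert counts[1:].sum() == pytest.approx(truth.bound_ions[sp])
            assert hist.bridging_total[sp] == pytest.approx(
                truth.bridging_ions[sp])
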