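"""Model builder: structures, contact maps, AFF assembly, mutations, bias."""

import numpy as np
import pytest

from switchpath.errors import (CalibrationError, ConfigurationError,
                               ConstructionError, MissingChainError)
from switchpath.model import (BeadStructure, ContactMap, LigandBias,
                              MutationSpec, apply_ligand_bias, apply_mutation,
                              binding_loop_bias, build_aff_model,
                              build_two_state_model, compute_native_contacts,
                              load_structure, structure_to_pdb)
from switchpath.calibrate import calibrate_contact_strength
from switchpath.dynamics import potential_energy


def beads(coords):
    coords = np.asarray(coords, dtype=float)
    return BeadStructure(residue_index=np.arange(1, len(coords) + 1),
                         residue_name=tuple(["GLY"] * len(coords)),
                         coords=coords)


# ---------------------------------------------------------------------------
# PDB loading
# ---------------------------------------------------------------------------

class TestLoadStructure:
    def test_round_trips_fixture_coordinates(self, hairpin_structure):
        text = structure_to_pdb(hairpin_structure)
        loaded = load_structure(text, chain="A")
        assert loaded.chain_length == 16
        # coordinates are exact at PDB text precision (values are written
        # with three decimals and parsed back through float32)
        np.testing.assert_allclose(loaded.coords, hairpin_structure.coords,
                                   atol=1e-5)

    def test_missing_chain_names_available_chains(self, hairpin_structure):
        text = structure_to_pdb(hairpin_structure, chain="B")
        with pytest.raises(MissingChainError, match="'B'"):
            load_structure(text, chain="Z")

    def test_missing_calpha_reports_gap(self, hairpin_structure):
        text = structure_to_pdb(hairpin_structure)
        # residue 3 keeps an atom record but loses its Cα
        lines = [l.replace(" CA ", " CB ", 1)
                 if l.startswith("ATOM") and int(l[22:26]) == 3 else l
                 for l in text.splitlines(keepends=True)]
        from switchpath.errors import ChainGapError
        with pytest.raises(ChainGapError, match="3"):
            load_structure("".join(lines), chain="A")

    def test_four_residue_toy_is_identity(self):
        s = beads([[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 3.8, 0.5]])
        loaded = load_structure(structure_to_pdb(s), chain="A")
        np.testing.assert_allclose(loaded.coords, s.coords, atol=1e-3)


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------

class TestNativeContacts:
    def test_collinear_chain_has_no_eligible_pairs(self):
        # 4 collinear beads spaced 3.8 Å: the only pair with sequence
        # separation >= 3 is (1, 4) at 11.4 Å, beyond the 8 Å cutoff
        s = beads([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0]])
        assert len(compute_native_contacts(s, cutoff=8.0,
                                           min_separation=3)) == 0

    def test_square_keeps_only_the_far_corner_pair(self):
        s = beads([[0, 0, 0], [5, 0, 0], [5, 5, 0], [0, 5, 0]])
        cm = compute_native_contacts(s, cutoff=8.0, min_separation=3)
        assert [(i, j) for i, j in zip(cm.i, cm.j)] == [(1, 4)]
        np.testing.assert_allclose(cm.r0, [5.0])

    def test_tight_cutoff_empties_the_map(self):
        s = beads([[0, 0, 0], [5, 0, 0], [5, 5, 0], [0, 5, 0]])
        assert len(compute_native_contacts(s, cutoff=4.0,
                                           min_separation=3)) == 0

    def test_exhaustive_filters_match_brute_force(self, two_hand_structure):
        cm = compute_native_contacts(two_hand_structure, cutoff=8.0,
                                     min_separation=3)
        xyz = two_hand_structure.coords
        expected = {(i + 1, j + 1)
                    for i in range(len(xyz)) for j in range(len(xyz))
                    if j - i >= 3
                    and np.linalg.norm(xyz[i] - xyz[j]) <= 8.0}
        assert set(zip(cm.i, cm.j)) == expected


# ---------------------------------------------------------------------------
# AFF assembly
# ---------------------------------------------------------------------------

class TestAFFAssembly:
    def test_calbindin_sized_construct_arithmetic(self):
        # 75-residue chain, duplicated range 44-75, six-residue linker
        rng = np.random.default_rng(0)
        walk = np.cumsum(rng.normal(scale=1.0, size=(75, 3)), axis=0)
        walk += np.arange(75)[:, None] * [3.0, 0.5, 0.0]
        d = np.linalg.norm(np.diff(walk, axis=0), axis=1)
        walk = walk / d.mean() * 3.8  # bead spacing ~ Cα
        wt = beads(walk)
        cm = compute_native_contacts(wt)
        model = build_aff_model(wt, cm, (44, 75), 6)
        assert model.topology.total_length == 113

    def test_degenerate_construct_is_the_wild_type(self, hairpin_structure):
        cm = compute_native_contacts(hairpin_structure)
        model = build_aff_model(hairpin_structure, cm, None, 0)
        assert model.topology.total_length == 16
        assert len(model.topology.frame_Nprime_residues) == 0
        assert not model.has_nprime
        assert set(model.contacts.frame_tag) == {"N"}

    def test_toy_construct_remapping(self, toy_aff):
        topo = toy_aff.model.topology
        assert topo.total_length == 32
        cm = toy_aff.model.contacts
        nprime = cm.frame_tag == "Nprime"
        # every N'-only contact uses the N-terminal duplicate copy
        assert np.all(cm.i[nprime] <= topo.duplicate_length)

    def test_remapping_closure_and_single_counting(self, toy_aff):
        model = toy_aff.model
        topo = model.topology
        cm = model.contacts
        a, _ = topo.duplicated_range
        off = topo.offset

        def inverse(r):
            return r + a - 1 if r <= topo.duplicate_length else r - off

        n_pairs = {(i - off, j - off, round(r, 6), round(e, 6))
                   for i, j, r, e, t in zip(cm.i, cm.j, cm.r0, cm.eps,
                                            cm.frame_tag)
                   if t in ("N", "shared")}
        np_pairs = set()
        for i, j, r, e, t in zip(cm.i, cm.j, cm.r0, cm.eps, cm.frame_tag):
            if t in ("Nprime", "shared"):
                p, q = sorted((inverse(int(i)), inverse(int(j))))
                np_pairs.add((p, q, round(r, 6), round(e, 6)))
        assert n_pairs == np_pairs          # identical (r0, eps) multisets
        tags = cm.frame_tag
        assert (np.sum(tags == "N") + np.sum(tags == "Nprime")
                + np.sum(tags == "shared")) == len(cm)
        assert len({(i, j) for i, j in zip(cm.i, cm.j)}) == len(cm)

    def test_shared_contacts_sit_inside_the_shared_segment(self, toy_aff):
        model = toy_aff.model
        shared = set(model.topology.shared_residues.tolist())
        mask = model.contacts.frame_tag == "shared"
        assert mask.any()
        assert all(i in shared and j in shared
                   for i, j in zip(model.contacts.i[mask],
                                   model.contacts.j[mask]))

    def test_overlapping_duplicated_range_rejected(self, hairpin_structure):
        cm = compute_native_contacts(hairpin_structure)
        with pytest.raises(ConstructionError):
            build_aff_model(hairpin_structure, cm, (10, 20), 2)

    def test_twin_mapping_is_involutive(self, toy_aff):
        topo = toy_aff.model.topology
        a, b = topo.duplicated_range
        for wt_res in range(a, b + 1):
            c = topo.wt_to_construct(wt_res)
            tw = topo.twin(c)
            assert tw is not None and topo.twin(tw) == c
        assert topo.twin(topo.wt_to_construct(1)) is None


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

class TestMutations:
    def test_native_energy_rises_by_deleted_well_depths(self, toy_aff):
        model = toy_aff.model
        res = int(model.topology.wt_to_construct(13))
        deleted = model.contacts.eps[model.contacts.involving(res)].sum()
        assert deleted > 0
        mut = apply_mutation(model, MutationSpec(res))
        x = model.native_coords_N
        de = potential_energy(mut, x) - potential_energy(model, x)
        # the deleted 12-10 wells vanish and the pairs fall back to plain
        # excluded volume; both terms are recomputed independently here
        formed = model.contacts.involving(res)
        d = np.linalg.norm(x[model.contacts.i[formed] - 1]
                           - x[model.contacts.j[formed] - 1], axis=1)
        e0 = model.contacts.eps[formed]
        q = (model.contacts.r0[formed] / d) ** 2
        well = np.sum(e0 * (5 * q ** 6 - 6 * q ** 5))
        sig = model.ff.ev_sigma
        ev_eps = model.ff.ev_eps * model.eps
        close = d < 2 * sig
        ev = np.sum(ev_eps * ((sig / d[close]) ** 12 - 2.0 ** -12))
        np.testing.assert_allclose(de, -well + ev, rtol=1e-9)

    def test_exact_well_depth_sum_at_native_distances(self):
        # 4-bead square with a single contact at its native distance
        s = beads([[0, 0, 0], [5, 0, 0], [5, 5, 0], [0, 5, 0]])
        model = build_two_state_model(s, eps=1.2)
        assert len(model.contacts) == 1
        mut = apply_mutation(model, MutationSpec(1))
        de = potential_energy(mut, s.coords) - potential_energy(model,
                                                                s.coords)
        np.testing.assert_allclose(de, 1.2, rtol=1e-12)

    def test_mutating_contactless_residue_changes_nothing(self, rng,
                                                          toy_aff):
        model = toy_aff.model
        linker = int(model.topology.duplicate_length + 1)
        assert not model.contacts.involving(linker).any()
        mut = apply_mutation(model, MutationSpec(linker))
        for _ in range(5):
            x = model.native_coords_N + rng.normal(scale=0.2,
                                                   size=(model.n_beads, 3))
            assert potential_energy(mut, x) == potential_energy(model, x)

    def test_idempotence(self, toy_aff):
        model = toy_aff.model
        spec = MutationSpec(int(model.topology.wt_to_construct(13)))
        once = apply_mutation(model, spec)
        twice = apply_mutation(once, spec)
        np.testing.assert_array_equal(once.contacts.eps, twice.contacts.eps)
        assert once.mutations == twice.mutations

    def test_mutation_never_lowers_energy(self, rng, toy_aff):
        # deleting attractive wells cannot stabilize any configuration in
        # which the wells are in their attractive range (perturbations are
        # kept small enough not to drive pairs onto the repulsive core,
        # where the deleted term itself would have been positive)
        model = toy_aff.model
        mut = apply_mutation(
            model, MutationSpec(int(model.topology.wt_to_construct(13))))
        for _ in range(10):
            x = model.native_coords_N + rng.normal(scale=0.25,
                                                   size=(model.n_beads, 3))
            assert potential_energy(mut, x) >= potential_energy(model, x) \
                - 1e-9

    def test_unknown_residue_rejected(self, toy_aff):
        with pytest.raises(ConfigurationError):
            apply_mutation(toy_aff.model, MutationSpec(999))


# ---------------------------------------------------------------------------
# Ligand bias
# ---------------------------------------------------------------------------

class TestLigandBias:
    def test_unit_scale_reproduces_the_apo_model(self, rng, toy_aff):
        model = toy_aff.model
        bias = binding_loop_bias(model, "Nprime", loop_residues=[1, 2, 3],
                                 strength_scale=1.0)
        biased = apply_ligand_bias(model, bias)
        x = model.native_coords_Nprime + rng.normal(
            scale=0.1, size=(model.n_beads, 3))
        assert potential_energy(biased, x) == potential_energy(model, x)

    def test_scaling_deepens_only_the_stated_frame(self, toy_aff):
        model = toy_aff.model
        bias = binding_loop_bias(model, "Nprime", loop_residues=[1, 2, 3],
                                 strength_scale=1.5)
        biased = apply_ligand_bias(model, bias)
        eff = biased.packed()["con_eps"]
        base = model.packed()["con_eps"]
        changed = eff != base
        assert changed.any()
        assert np.all(biased.contacts.frame_tag[changed] == "Nprime")
        np.testing.assert_allclose(eff[changed], base[changed] * 1.5)

    def test_pair_outside_frame_rejected(self, toy_aff):
        model = toy_aff.model
        n_pair = next((int(i), int(j)) for i, j, t in
                      zip(model.contacts.i, model.contacts.j,
                          model.contacts.frame_tag) if t == "N")
        with pytest.raises(ConfigurationError):
            apply_ligand_bias(model, LigandBias(
                frame="Nprime", strength_scale=1.2,
                affected_pairs=(n_pair,)))


# ---------------------------------------------------------------------------
# Calibration search (bisection mechanics; WE-backed estimator is exercised
# in the acceptance suite)
# ---------------------------------------------------------------------------

class TestCalibrationSearch:
    @staticmethod
    def analytic(eps):
        # monotone ΔG(ε) with known inverse
        return 3.0 - 4.0 * eps

    def test_recovers_target_within_tolerance(self):
        res = calibrate_contact_strength(self.analytic, target_dG=-5.0,
                                         tolerance=0.1, eps_bounds=(0.4, 4.0))
        assert abs(res.dG_fold + 5.0) <= 0.1
        assert abs(res.eps - 2.0) < 0.1
        assert res.trace[0][0] == 0.4 and res.trace[1][0] == 4.0

    def test_midpoint_target_balances_the_populations(self):
        res = calibrate_contact_strength(self.analytic, target_dG=0.0,
                                         tolerance=0.05)
        assert abs(self.analytic(res.eps)) <= 0.05

    def test_unbracketable_target_fails_with_trace(self):
        with pytest.raises(CalibrationError, match="trace"):
            calibrate_contact_strength(self.analytic, target_dG=-100.0,
                                       tolerance=0.3)
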