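"""Surfaces, transition-path extraction, contact scores, design ranking."""

import numpy as np
import pandas as pd
import pytest

from switchpath.ensembles import (ContactScoreTable, contact_score,
                                  contact_score_table, extract_tpe,
                                  free_energy_surface, rank_candidates,
                                  tpe_probability_field)
from switchpath.errors import ConfigurationError
from switchpath.kinetics import StateDefinition
from switchpath.model import ContactMap
from switchpath.units import R_KCAL_PER_MOL_K
from switchpath.we import LABEL_I, WEArchive, WEIteration

state_i = StateDefinition("i", (-np.inf,), (-1.0,))
state_j = StateDefinition("j", (1.0,), (np.inf,))


def scripted_archive(paths, weights=None):
    """Archive with one single-sample segment per iteration per walker.

    ``paths`` is a list of per-walker coordinate sequences (all the same
    length); walker k in iteration t descends from walker k in t-1.  The
    final frame of a walker whose last position is inside the target state
    is marked recycled.
    """
    paths = [np.asarray(p, dtype=float) for p in paths]
    n_iter = len(paths[0])
    m = len(paths)
    weights = weights or [1.0 / m] * m
    arch = WEArchive(mode="steady-state", tau=1.0, sample_interval=1.0,
                     seed=0, walkers_per_bin=1, progress_dim=1,
                     initial_coords=np.array([[p[0]] for p in paths],
                                             dtype=np.float32),
                     initial_progress=np.array([[p[0]] for p in paths]),
                     state_i=state_i, state_j=state_j)
    for t in range(1, n_iter):
        recycled = np.array([state_j.contains([p[t]]) for p in paths])
        arch.iterations.append(WEIteration(
            index=t - 1,
            weights=np.asarray(weights, dtype=float),
            labels=np.full(m, LABEL_I, dtype=np.int8),
            parents=np.arange(m, dtype=np.int32),
            end_progress=np.array([[p[t]] for p in paths]),
            recycled=recycled,
            bin_index=np.zeros(m, dtype=np.int32),
            recycled_flux=float(sum(w for w, r in zip(weights, recycled)
                                    if r)),
            weight_error=0.0,
            samples=np.array([[[p[t]]] for p in paths], dtype=np.float32),
            sample_progress=np.array([[[p[t]]] for p in paths]),
            restart_coords={}))
    return arch


# ---------------------------------------------------------------------------
# Probability fields
# ---------------------------------------------------------------------------

class TestFreeEnergySurface:
    def test_uniform_weights_give_flat_surface(self):
        arch = scripted_archive([[-2.0, -1.5, -0.5, 0.5]] , weights=[1.0])
        edges = (np.array([-2.0, -1.0, 0.0, 1.0]),)
        field = free_energy_surface(arch, edges, units="reduced",
                                    temperature=1.0, burn_in_fraction=0.0)
        finite = field.G[np.isfinite(field.G)]
        np.testing.assert_allclose(finite - finite.min(), 0.0, atol=1e-9)

    def test_ninefold_ratio_in_kcal(self):
        # P = 0.9 / 0.1 between two cells: ΔG = RT ln 9 = 1.280 kcal/mol
        paths = [[-0.5] * 11, [0.5] * 11]
        arch = scripted_archive(paths, weights=[0.9, 0.1])
        edges = (np.array([-1.0, 0.0, 1.0]),)
        field = free_energy_surface(arch, edges, units="real",
                                    temperature=293.15,
                                    burn_in_fraction=0.0)
        dg = field.G[1] - field.G[0]
        assert dg == pytest.approx(R_KCAL_PER_MOL_K * 293.15 * np.log(9.0),
                                   abs=1e-9)
        assert dg == pytest.approx(1.280, abs=5e-4)

    def test_probability_normalized(self):
        arch = scripted_archive([[-1.5, 0.0, 1.5, -0.3]], weights=[1.0])
        field = free_energy_surface(arch, (np.array([-2.0, 0.0, 2.0]),),
                                    units="reduced", temperature=1.0,
                                    burn_in_fraction=0.0)
        assert field.P.sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Transition-path extraction (scripted lineages)
# ---------------------------------------------------------------------------

class TestExtractTPE:
    def test_last_exit_to_first_entry(self):
        # i, i, b, b, j -> path = frames 3..5
        arch = scripted_archive([[-1.5, -1.2, 0.0, 0.5, 1.5]])
        paths = extract_tpe(arch, state_i, state_j)
        assert len(paths) == 1
        np.testing.assert_allclose(paths[0].frames.ravel(), [0.0, 0.5, 1.5])

    def test_reentry_restarts_the_path(self):
        # i, b, i, b, j -> path starts after the second i visit
        arch = scripted_archive([[-1.5, 0.0, -1.1, 0.4, 1.2]])
        paths = extract_tpe(arch, state_i, state_j)
        assert len(paths) == 1
        np.testing.assert_allclose(paths[0].frames.ravel(), [0.4, 1.2])

    def test_unproductive_excursion_emits_nothing(self):
        # i, b, i: never reaches j
        arch = scripted_archive([[-1.5, 0.0, -1.1]])
        assert extract_tpe(arch, state_i, state_j) == []

    def test_path_weight_equals_recycled_weight(self):
        arch = scripted_archive([[-1.5, 0.2, 1.4]], weights=[0.37])
        paths = extract_tpe(arch, state_i, state_j)
        assert paths[0].weight == pytest.approx(0.37)
        total_flux = arch.flux_series().sum()
        assert sum(p.weight for p in paths) <= total_flux + 1e-12

    def test_no_intermediate_frame_is_in_either_state(self):
        arch = scripted_archive(
            [[-1.5, -1.2, 0.3, 0.9, -0.5, 0.2, 1.1]])
        paths = extract_tpe(arch, state_i, state_j)
        assert len(paths) == 1
        inner = paths[0].frames.ravel()[:-1]
        assert all(not state_i.contains([x]) and not state_j.contains([x])
                   for x in inner)


# ---------------------------------------------------------------------------
# Contact scores
# ---------------------------------------------------------------------------

def square_contacts():
    return ContactMap(i=np.array([1, 1, 2]), j=np.array([4, 3, 4]),
                      r0=np.array([5.0, 5.0, 5.0]),
                      eps=np.array([1.0, 1.0, 1.0]),
                      frame_tag=np.array(["N", "N", "N"], dtype="U6"))


class TestContactScore:
    native = np.array([[0, 0, 0], [5, 0, 0], [5, 5, 0], [0, 5, 0]],
                      dtype=float)

    def test_native_ensemble_scores_equal_degrees(self):
        cm = square_contacts()
        # the diagonal pairs sit at sqrt(50); give them their true native
        # distances so every listed contact is formed in the native frame
        cm.r0[1] = cm.r0[2] = np.sqrt(50.0)
        scores = contact_score(self.native[None], np.array([1.0]), cm, 4)
        np.testing.assert_allclose(scores, cm.degree(4))

    def test_extended_ensemble_scores_zero(self):
        ext = np.arange(4)[:, None] * np.array([30.0, 0.0, 0.0])
        scores = contact_score(ext[None], np.array([1.0]),
                               square_contacts(), 4)
        np.testing.assert_allclose(scores, 0.0)

    def test_weighted_two_frame_average(self):
        # residue forming 4 contacts in one frame (w = 0.75) and 0 in the
        # other (w = 0.25): score = 3.0
        cm = ContactMap(i=np.array([1, 1, 1, 1]), j=np.array([4, 5, 6, 7]),
                        r0=np.full(4, 5.0), eps=np.ones(4),
                        frame_tag=np.array(["N"] * 4, dtype="U6"))
        formed = np.zeros((7, 3))
        formed[3:] = [[5, 0, 0], [0, 5, 0], [-5, 0, 0], [0, -5, 0]]
        broken = formed.copy()
        broken[3:] *= 10
        frames = np.stack([formed, broken])
        scores = contact_score(frames, np.array([0.75, 0.25]), cm, 7)
        assert scores[0] == pytest.approx(3.0)

    def test_scores_bounded_by_degree(self, rng):
        cm = square_contacts()
        frames = self.native[None] + rng.normal(scale=1.0, size=(20, 4, 3))
        scores = contact_score(frames, np.ones(20), cm, 4)
        assert np.all(scores >= 0) and np.all(scores <= cm.degree(4))

    def test_table_collects_means_and_sems(self):
        cm = square_contacts()
        runs = [ (self.native[None], np.array([1.0])) for _ in range(3)]
        table = contact_score_table({"N": runs}, cm, 4)
        assert set(table.table.columns) == {"score_N", "sem_N"}
        np.testing.assert_allclose(table.table["sem_N"], 0.0)


# ---------------------------------------------------------------------------
# Candidate ranking
# ---------------------------------------------------------------------------

def score_frame(n, diff_fwd, diff_rev):
    df = pd.DataFrame({
        "residue": np.arange(1, n + 1),
        "score_N": 4.0 + np.asarray(diff_fwd, dtype=float),
        "score_TPE_fwd": 4.0,
        "score_Nprime": 4.0 + np.asarray(diff_rev, dtype=float),
        "score_TPE_rev": 4.0,
    }).set_index("residue")
    return ContactScoreTable(df)


class TestRankCandidates:
    def test_broken_interface_residue_ranks_first(self):
        diff = np.zeros(6)
        diff[2] = 3.0    # residue 3 loses three contacts in the TPE
        scores = score_frame(6, diff, diff)
        ranking = rank_candidates(scores, binding_site_residues=[],
                                  interface_residues=[1, 2, 3, 4, 5, 6])
        assert ranking.table.index[0] == 3
        assert ranking.negative_control != 3

    def test_binding_site_residue_flagged_not_ranked(self):
        diff = np.zeros(6)
        diff[2] = 3.0
        scores = score_frame(6, diff, diff)
        ranking = rank_candidates(scores, binding_site_residues=[2],
                                  interface_residues=[1, 2, 3, 4, 5, 6])
        # residue 3 is adjacent to binding-site residue 2: flagged
        row = ranking.table.loc[3]
        assert row["near_binding_site"] and row["excluded"]
        assert 3 not in ranking.candidates

    def test_ties_break_by_residue_index(self):
        scores = score_frame(5, np.ones(5), np.ones(5))
        ranking = rank_candidates(scores, binding_site_residues=[],
                                  interface_residues=[2, 3, 4])
        assert list(ranking.table.index)[:2] == [1, 2]
        assert ranking.negative_control == 2

    def test_stability_floor_excludes_fragile_mutants(self):
        diff = np.zeros(4)
        diff[0] = 2.0
        scores = score_frame(4, diff, diff)
        ranking = rank_candidates(scores, binding_site_residues=[],
                                  interface_residues=[1, 2, 3, 4],
                                  stabilities={1: -0.5}, stability_floor=-2.0)
        assert ranking.table.loc[1, "below_stability_floor"]
        assert 1 not in ranking.candidates

    def test_buried_filter_uses_contact_degree(self):
        scores = score_frame(4, [0.1, 0.1, 0.1, 2.0], [0.1, 0.1, 0.1, 2.0])
        cm = square_contacts()   # degrees 2, 1, 1, 2
        ranking = rank_candidates(scores, binding_site_residues=[],
                                  interface_residues=[1, 2, 3, 4],
                                  contacts=cm)
        # residues 1 and 4 are "buried" (degree >= median); 4 changes most,
        # so the control is residue 1
        assert ranking.negative_control == 1

    def test_empty_table_rejected(self):
        with pytest.raises((ConfigurationError, KeyError)):
            rank_candidates(ContactScoreTable(pd.DataFrame()),
                            binding_site_residues=[], interface_residues=[1])


# ---------------------------------------------------------------------------
# TPE probability field: intermediate detection
# ---------------------------------------------------------------------------

class TestIntermediateDetection:
    def test_scripted_intermediate_shows_interior_mode(self):
        # dwell at the midpoint mimics a metastable on-path intermediate
        arch = scripted_archive(
            [[-1.5, -0.1, 0.0, 0.05, -0.05, 0.0, 1.2]])
        paths = extract_tpe(arch, state_i, state_j)
        edges = (np.linspace(-1.5, 1.5, 13),)
        field = tpe_probability_field(paths, edges, units="reduced",
                                      temperature=1.0)
        interior = field.P[3:-3]
        assert interior.max() == field.P.max()
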