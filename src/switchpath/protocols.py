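"""Reference study protocols at fixture scale.

These functions bundle the package's end-to-end workflows — rate
validation against brute force, equilibrium unbiasedness, the efficiency
sweep, mutual exclusivity, the mutation design screen, and stability
calibration — at problem sizes chosen to run on a single CPU in minutes.
The test suite and the acceptance script both drive them, so the numbers
they produce are always recomputed from scratch.
"""

from __future__ import annotations

import warnings

import numpy as np

from .calibrate import calibrate_contact_strength
from .dynamics import GoPropagator
from .ensembles import (contact_score_table, ensemble_frames, extract_tpe,
                        rank_candidates)
from .fixtures import (REDUCED_CONFIG, DoubleWellSpec, ToyAFF,
                       brute_force_rate, build_hairpin_model, hairpin_states,
                       make_double_well)
from .kinetics import efficiency, estimate_rate, estimate_stability
from .model import MutationSpec, apply_mutation
from .we import BinMapper, WEConfig, run_we

__all__ = ["double_well_rate_check", "double_well_unbiasedness",
           "efficiency_sweep", "toy_mutual_exclusivity", "toy_switch_rate",
           "toy_design_screen", "mutate_site", "hairpin_fine_bins",
           "hairpin_directional_stability", "hairpin_calibration_check",
           "mutant_stability_shift"]


def _quiet_run(prop, cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_we(prop, cfg)


# ---------------------------------------------------------------------------
# Double-well protocols
# ---------------------------------------------------------------------------

def double_well_rate_check(barrier: float = 5.0, n_we_runs: int = 5,
                           n_iterations: int = 400, n_events: int = 200,
                           seed: int = 0) -> dict:
    """WE rate vs the brute-force waiting-time oracle on the double well."""
    prop = make_double_well(DoubleWellSpec(barrier_height=barrier))
    si, sj = prop.default_states()
    archives = []
    for r in range(n_we_runs):
        archives.append(_quiet_run(prop, WEConfig(
            mode="steady-state", n_iterations=n_iterations,
            bin_mapper=prop.default_mapper(),
            initial_sampler=lambda rng: np.array([-prop.spec.a]),
            state_i=si, state_j=sj, seed=seed * 1000 + r,
            store_samples=False, store_end=False)))
    est = estimate_rate(archives)
    bf = brute_force_rate(prop, si, sj, n_events=n_events, seed=seed + 17)
    sem_we = est.sem if np.isfinite(est.sem) else 0.0
    combined = float(np.hypot(sem_we, bf.sem_rate))
    return {
        "k_we": est.k, "sem_we": sem_we, "k_bf": bf.rate,
        "sem_bf": bf.sem_rate, "combined_sem": combined,
        "within_3sem": bool(abs(est.k - bf.rate) <= 3 * combined),
        "ratio": est.k / bf.rate,
        "max_weight_error": max(a.max_weight_error() for a in archives),
        "archives": archives,
    }


def double_well_unbiasedness(barrier: float = 4.0, n_iterations: int = 1500,
                             seed: int = 3) -> dict:
    """Total variation distance between the WE equilibrium histogram and
    the exact Boltzmann bin probabilities."""
    prop = make_double_well(DoubleWellSpec(barrier_height=barrier))
    si, sj = prop.default_states()
    mapper = prop.default_mapper()
    arch = _quiet_run(prop, WEConfig(
        mode="equilibrium", n_iterations=n_iterations, bin_mapper=mapper,
        initial_sampler=lambda rng: np.array([-prop.spec.a]),
        state_i=si, state_j=sj, seed=seed,
        store_samples=False, store_end=False))
    edges = np.concatenate([[-4.0 * prop.spec.a], mapper.edges[0],
                            [4.0 * prop.spec.a]])
    t0 = arch.burn_in_start(0.3)
    acc = np.zeros(len(edges) - 1)
    for it in arch.iterations[t0:]:
        h, _ = np.histogram(it.end_progress[:, 0], bins=edges,
                            weights=it.weights)
        acc += h
    we_hist = acc / acc.sum()
    exact = prop.equilibrium_histogram(edges)
    tv = 0.5 * float(np.abs(we_hist - exact).sum())
    return {"tv_distance": tv,
            "max_weight_error": arch.max_weight_error()}


def efficiency_sweep(barriers=(4.0, 6.0, 8.0), n_iterations: int = 800,
                     seed: int = 5) -> dict:
    """WE efficiency S versus barrier height (monotone growth expected)."""
    out = []
    for b in barriers:
        prop = make_double_well(DoubleWellSpec(barrier_height=b))
        si, sj = prop.default_states()
        arch = _quiet_run(prop, WEConfig(
            mode="steady-state", n_iterations=n_iterations,
            bin_mapper=prop.default_mapper(),
            initial_sampler=lambda rng: np.array([-prop.spec.a]),
            state_i=si, state_j=sj, seed=seed + int(b),
            store_samples=False, store_end=False))
        est = estimate_rate(arch)
        rep = efficiency(est, arch)
        out.append(rep.S)
    return {"barriers": list(barriers), "S": out,
            "monotone": bool(np.all(np.diff(out) > 0))}


# ---------------------------------------------------------------------------
# Toy-AFF protocols
# ---------------------------------------------------------------------------

def toy_mutual_exclusivity(toy: ToyAFF, n_iterations: int = 350,
                           seed: int = 11) -> dict:
    """Equilibrium weight of the both-frames-folded corner of the
    (rmsd_N, rmsd_N') plane (should be essentially empty)."""
    prop = toy.propagator()
    arch = _quiet_run(prop, WEConfig(
        mode="equilibrium", n_iterations=n_iterations,
        bin_mapper=toy.mapper, initial_sampler=toy.initial_sampler("N"),
        state_i=toy.state_N, state_j=toy.state_Nprime, seed=seed,
        store_samples=False, store_end=False))
    c = toy.spec.folded_rmsd
    t0 = arch.burn_in_start(0.3)
    both = total = 0.0
    for it in arch.iterations[t0:]:
        total += it.weights.sum()
        mask = (it.end_progress[:, 0] <= c) & (it.end_progress[:, 1] <= c)
        both += it.weights[mask].sum()
    return {"both_folded_fraction": both / total,
            "max_weight_error": arch.max_weight_error()}


def toy_switch_rate(toy: ToyAFF, model, direction: str, seeds,
                    n_iterations: int, store_samples: bool = False,
                    burn_in: float = 0.3):
    """Steady-state switching rate of a toy-AFF variant; returns
    (RateEstimate, archives)."""
    prop = toy.propagator(model)
    if direction == "fwd":
        si, sj, start = toy.state_N, toy.state_Nprime, "N"
    else:
        si, sj, start = toy.state_Nprime, toy.state_N, "Nprime"
    archives = [
        _quiet_run(prop, WEConfig(
            mode="steady-state", n_iterations=n_iterations,
            bin_mapper=toy.mapper,
            initial_sampler=toy.initial_sampler(start, model),
            state_i=si, state_j=sj, seed=int(s),
            store_samples=store_samples, store_end=False))
        for s in seeds]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = estimate_rate(archives, burn_in_fraction=burn_in)
    return est, archives


def mutate_site(toy: ToyAFF, wt_site: int, model=None):
    """Delete-attractive mutation of a wild-type site and its duplicate-copy
    twin (the two-copies-at-once convention of the design screen)."""
    m = model if model is not None else toy.model
    c = m.topology.wt_to_construct(wt_site)
    out = apply_mutation(m, MutationSpec(c, label=f"X{wt_site}A"))
    twin = m.topology.twin(c)
    if twin is not None:
        out = apply_mutation(out, MutationSpec(twin, label=f"X{wt_site}'A"))
    return out


def _tpe_frames(archive, state_i, state_j):
    paths = extract_tpe(archive, state_i, state_j)
    if not paths:
        return None
    frames = np.concatenate([p.frames for p in paths])
    weights = np.concatenate([
        np.full(len(p.frames), p.weight / len(p.frames)) for p in paths])
    return frames, weights


def toy_design_screen(toy: ToyAFF, fwd_archives, rev_archives,
                      burn_in: float = 0.3,
                      binding_site_residues=()) -> dict:
    """Contact-score screen from stored WT steady-state archives.

    Ground-state columns come from the archives' frames restricted to the
    ground states; TPE columns from lineage-extracted transition paths.
    The interface set supplied to the ranking covers the wild-type copy of
    both hands (the packing interface region).
    """
    m = toy.model
    ens = {"N": [], "Nprime": [], "TPE_fwd": [], "TPE_rev": []}
    for a in fwd_archives:
        ens["N"].append(ensemble_frames(a, toy.state_N, burn_in))
        tpe = _tpe_frames(a, toy.state_N, toy.state_Nprime)
        if tpe is not None:
            ens["TPE_fwd"].append(tpe)
    for a in rev_archives:
        ens["Nprime"].append(ensemble_frames(a, toy.state_Nprime, burn_in))
        tpe = _tpe_frames(a, toy.state_Nprime, toy.state_N)
        if tpe is not None:
            ens["TPE_rev"].append(tpe)
    table = contact_score_table(ens, m.contacts, m.n_beads)
    # the negative control is drawn from the shared hand (the analog of the
    # always-folded scaffold hand), where mutation affects both frames
    # symmetrically; candidates come from the duplicated hand, whose two
    # copies each destabilize one ground state
    a, _ = m.topology.duplicated_range
    shared_hand = [m.topology.wt_to_construct(r) for r in range(1, a)]
    ranking = rank_candidates(
        table, binding_site_residues=binding_site_residues,
        interface_residues=shared_hand, topology=m.topology,
        contacts=m.contacts)
    twin_sites = [s for s in ranking.table.index
                  if m.topology.twin(int(s)) is not None
                  and not ranking.table.loc[s, "excluded"]]
    top_site = int(twin_sites[0])
    return {"table": table, "ranking": ranking, "top_site": top_site,
            "negative_control": ranking.negative_control}


# ---------------------------------------------------------------------------
# Hairpin stability / calibration protocols
# ---------------------------------------------------------------------------

def hairpin_fine_bins() -> BinMapper:
    """Fine rungs near the folded basin, where the unfolding ladder is
    steepest; coarser beyond."""
    return BinMapper((np.concatenate([np.arange(0.75, 4.0, 0.25),
                                      np.arange(4.0, 14.0, 0.5)]),))


def hairpin_directional_stability(eps: float, seed: int,
                                  n_iterations: int = 450,
                                  n_runs: int = 2,
                                  walkers_per_bin: int = 8):
    """ΔG_fold of the hairpin from opposing steady-state runs (the mutant
    stability protocol), in k_BT units."""
    model = build_hairpin_model(eps=eps)
    return _directional_stability(model, seed, n_iterations, n_runs,
                                  walkers_per_bin)


def _directional_stability(model, seed, n_iterations, n_runs,
                           walkers_per_bin):
    folded, unfolded = hairpin_states()
    mapper = hairpin_fine_bins()
    prop = GoPropagator(model, REDUCED_CONFIG)
    native = model.native_coords_N
    n = model.n_beads
    stretched = np.zeros((n, 3))
    stretched[:, 1] = 3.8 * np.arange(n)
    stretched[:, 2] = 0.35 * (-1.0) ** np.arange(n)

    fold_archives, unfold_archives = [], []
    for r in range(n_runs):
        fold_archives.append(_quiet_run(prop, WEConfig(
            mode="steady-state", n_iterations=n_iterations,
            bin_mapper=mapper, initial_sampler=lambda rng: stretched.copy(),
            state_i=unfolded, state_j=folded,
            walkers_per_bin=walkers_per_bin, seed=seed + 1000 + r,
            store_samples=False, store_end=False)))
        unfold_archives.append(_quiet_run(prop, WEConfig(
            mode="steady-state", n_iterations=n_iterations,
            bin_mapper=mapper, initial_sampler=lambda rng: native.copy(),
            state_i=folded, state_j=unfolded,
            walkers_per_bin=walkers_per_bin, seed=seed + 2000 + r,
            store_samples=False, store_end=False)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return estimate_stability(folded, unfolded,
                                  folding_archives=fold_archives,
                                  unfolding_archives=unfold_archives,
                                  temperature=1.0, units="reduced",
                                  burn_in_fraction=0.3)


def hairpin_calibration_check(target_dg_kcal: float = -5.6,
                              tolerance_kcal: float = 0.3,
                              seed: int = 0, n_iterations: int = 450,
                              n_runs: int = 2,
                              walkers_per_bin: int = 8,
                              max_bisections: int = 8) -> dict:
    """Calibrate ε against a target stability, then re-estimate the
    stability of the calibrated model with a fresh seed."""
    from .units import R_KCAL_PER_MOL_K, DEFAULT_TEMPERATURE_K
    rt = R_KCAL_PER_MOL_K * DEFAULT_TEMPERATURE_K

    def estimator_factory(s):
        def estimator(eps):
            est = hairpin_directional_stability(
                eps, seed=s, n_iterations=n_iterations, n_runs=n_runs,
                walkers_per_bin=walkers_per_bin)
            return est.dG_fold * rt          # kT -> kcal/mol
        return estimator

    result = calibrate_contact_strength(
        estimator_factory(seed), target_dg_kcal, tolerance_kcal,
        eps_bounds=(1.2, 2.1), max_iterations=max_bisections)
    fresh = estimator_factory(seed + 5000)(result.eps)
    return {"eps": result.eps, "dG_claimed": result.dG_fold,
            "dG_fresh": fresh,
            "fresh_error": abs(fresh - target_dg_kcal),
            "n_evaluations": result.n_evaluations}


def mutant_stability_shift(site: int = 3, eps: float = 1.55,
                           seed: int = 9, n_iterations: int = 450,
                           walkers_per_bin: int = 8) -> dict:
    """ΔΔG_fold (mutant − wild type) of a delete-attractive hairpin mutant
    by the opposing-steady-state protocol, in k_BT units."""
    wt = hairpin_directional_stability(eps, seed=seed,
                                       n_iterations=n_iterations,
                                       walkers_per_bin=walkers_per_bin)
    model = apply_mutation(build_hairpin_model(eps=eps), MutationSpec(site))
    mut = _directional_stability(model, seed + 100, n_iterations, 2,
                                 walkers_per_bin)
    sems = [e.sem for e in (wt, mut) if np.isfinite(e.sem)]
    sem = float(np.sqrt(np.sum(np.square(sems)))) if sems else np.nan
    return {"ddG": mut.dG_fold - wt.dG_fold, "sem": sem,
            "dG_wt": wt.dG_fold, "dG_mut": mut.dG_fold}
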