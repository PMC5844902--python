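"""Calibration of the uniform contact strength against a target stability.

The parameterization step of the design workflow: find the single well depth ε at
which the two-state component reproduces a target folding free energy.
ΔG_fold(ε) is monotonically decreasing in ε, so a bracketing bisection over
ε suffices; every evaluation is recorded in the search trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import CalibrationError, ConfigurationError
from .units import DEFAULT_TEMPERATURE_K

__all__ = ["CalibrationResult", "calibrate_contact_strength",
           "hairpin_stability_estimator", "calibrate_hairpin_eps"]


@dataclass(frozen=True)
class CalibrationResult:
    eps: float
    dG_fold: float
    trace: tuple          # ((eps, dG), ...) in evaluation order
    n_evaluations: int


def calibrate_contact_strength(estimator: Callable, target_dG: float,
                               tolerance: float,
                               eps_bounds: tuple = (0.4, 4.0),
                               max_iterations: int = 24) -> CalibrationResult:
    """Bisection over ε until |ΔG_fold(ε) - target| <= tolerance.

    ``estimator`` maps ε to an estimated ΔG_fold (same units as the
    target).  The target must be bracketed by the bounds, i.e. ΔG at the
    lower bound above the target and ΔG at the upper bound below it;
    otherwise a calibration failure carrying the trace is raised.
    """
    if tolerance <= 0:
        raise ConfigurationError("tolerance must be positive")
    lo, hi = eps_bounds
    if not 0 < lo < hi:
        raise ConfigurationError("need 0 < eps_lo < eps_hi")
    trace = []

    def ev(eps: float) -> float:
        dg = float(estimator(eps))
        trace.append((eps, dg))
        return dg

    dg_lo = ev(lo)
    if abs(dg_lo - target_dG) <= tolerance:
        return CalibrationResult(lo, dg_lo, tuple(trace), len(trace))
    dg_hi = ev(hi)
    if abs(dg_hi - target_dG) <= tolerance:
        return CalibrationResult(hi, dg_hi, tuple(trace), len(trace))
    if not (dg_lo > target_dG > dg_hi):
        raise CalibrationError(
            f"target ΔG {target_dG} not bracketed on ε ∈ [{lo}, {hi}]: "
            f"ΔG({lo}) = {dg_lo:.3g}, ΔG({hi}) = {dg_hi:.3g}; "
            f"trace = {trace}")
    for _ in range(max_iterations):
        mid = 0.5 * (lo + hi)
        dg = ev(mid)
        if abs(dg - target_dG) <= tolerance:
            return CalibrationResult(mid, dg, tuple(trace), len(trace))
        if dg > target_dG:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"no ε within tolerance after {max_iterations} bisections; "
        f"trace = {trace}")


def hairpin_stability_estimator(n_beads: int = 16,
                                temperature: float = 1.0,
                                units: str = "reduced",
                                n_iterations: int = 250,
                                n_runs: int = 2,
                                seed: int = 0) -> Callable:
    """ΔG_fold(ε) estimator for the hairpin fixture.

    For each ε, opposing steady-state WE runs (folding and unfolding) are
    combined into an equilibrium estimate through their rate balance —
    the same protocol used for mutant stability tables.
    """
    from .dynamics import GoPropagator
    from .fixtures import (REDUCED_CONFIG, build_hairpin_model,
                           hairpin_bins, hairpin_states)
    from .kinetics import estimate_stability
    from .we import WEConfig, run_we

    folded, unfolded = hairpin_states()
    mapper = hairpin_bins()

    def estimator(eps: float) -> float:
        model = build_hairpin_model(eps=eps, n_beads=n_beads)
        prop = GoPropagator(model, REDUCED_CONFIG)
        native = model.native_coords_N

        def from_folded(rng):
            return native.copy()

        def from_unfolded(rng):
            # stretched chain: all native pair distances beyond the wells
            n = model.n_beads
            x = np.zeros((n, 3))
            x[:, 1] = 3.8 * np.arange(n)
            x[:, 2] = 0.35 * (-1.0) ** np.arange(n)
            return x

        fold_archives, unfold_archives = [], []
        for r in range(n_runs):
            fold_archives.append(run_we(prop, WEConfig(
                mode="steady-state", n_iterations=n_iterations,
                bin_mapper=mapper, initial_sampler=from_unfolded,
                state_i=unfolded, state_j=folded, seed=seed + 1000 + r,
                store_samples=False, store_end=False)))
            unfold_archives.append(run_we(prop, WEConfig(
                mode="steady-state", n_iterations=n_iterations,
                bin_mapper=mapper, initial_sampler=from_folded,
                state_i=folded, state_j=unfolded, seed=seed + 2000 + r,
                store_samples=False, store_end=False)))
        est = estimate_stability(folded, unfolded,
                                 folding_archives=fold_archives,
                                 unfolding_archives=unfold_archives,
                                 temperature=temperature, units=units)
        return est.dG_fold

    return estimator


def calibrate_hairpin_eps(target_dG: float, tolerance: float = 0.3,
                          n_beads: int = 16,
                          temperature: float = DEFAULT_TEMPERATURE_K,
                          units: str = "real",
                          seed: int = 0, **estimator_kw) -> CalibrationResult:
    """Convenience wrapper: calibrate the hairpin fixture's ε to a target
    ΔG_fold (kcal/mol in real units, k_BT in reduced units)."""
    est = hairpin_stability_estimator(n_beads=n_beads,
                                      temperature=temperature, units=units,
                                      seed=seed, **estimator_kw)
    return calibrate_contact_strength(est, target_dG, tolerance)
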