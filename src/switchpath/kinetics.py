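"""Rate constants, stabilities and WE efficiency from iteration archives.

The macroscopic rate constant between states i and j is

    k_ij = f_ij / p_i

where f_ij is the probability flux carried by trajectories arriving in j
(the recycled weight per unit time) and p_i is the time-averaged weight
fraction of trajectories more recently in i than in j.  Walkers that have
not yet visited either state are excluded from both numerator and
denominator of p_i; their fraction is reported so its decay can be checked.

Folding stabilities follow ΔG_fold = -RT ln(P_folded / P_unfolded), either
from an equilibrium archive directly or by combining steady-state archives
run in opposite directions: the two directional runs sample the unfolded-
and folded-labeled ensembles, which are weighted by the steady-state label
populations k_u/(k_f + k_u) and k_f/(k_f + k_u) — for a two-state system
this reduces to ΔG_fold = -RT ln(k_fold / k_unfold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, UndefinedStateError
from .units import DEFAULT_TEMPERATURE_K, thermal_energy

__all__ = ["StateDefinition", "RateEstimate", "StabilityEstimate",
           "BarrierReduction", "EfficiencyReport", "define_states",
           "estimate_rate", "estimate_stability", "barrier_reduction",
           "mfpt", "efficiency"]


# ---------------------------------------------------------------------------
# State definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateDefinition:
    """A closed rectangular region of the progress coordinate."""

    state_id: str
    lower: tuple        # per-dimension lower bounds (-inf allowed)
    upper: tuple        # per-dimension upper bounds (+inf allowed)

    def __post_init__(self):
        lo = tuple(float(v) for v in np.atleast_1d(self.lower))
        hi = tuple(float(v) for v in np.atleast_1d(self.upper))
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if len(lo) != len(hi) or any(l > u for l, u in zip(lo, hi)):
            raise ConfigurationError("state bounds must satisfy lower <= upper")

    @property
    def ndim(self) -> int:
        return len(self.lower)

    def contains(self, progress) -> bool:
        p = np.atleast_1d(np.asarray(progress, dtype=float))
        if len(p) != self.ndim:
            raise ConfigurationError(
                f"progress dimension {len(p)} != state dimension {self.ndim}")
        return bool(np.all(p >= self.lower) and np.all(p <= self.upper))

    def contains_many(self, progress: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(progress, dtype=float))
        return np.all((p >= self.lower) & (p <= self.upper), axis=1)

    def overlaps(self, other: "StateDefinition") -> bool:
        return all(l1 <= u2 and l2 <= u1
                   for l1, u1, l2, u2 in zip(self.lower, self.upper,
                                             other.lower, other.upper))


def define_states(hist: np.ndarray, edges: np.ndarray,
                  state_ids: tuple = ("i", "j"),
                  min_mass_fraction: float = 1e-4) -> tuple:
    """Place two state boundaries at the probability-distribution maxima.

    Given a 1-D histogram of the equilibrium distribution along the
    progress coordinate, each state boundary is the position of its basin's
    mode; the boundary bin belongs to the state (ties resolve toward the
    basin) and the barrier region is the open interval between the modes.
    """
    hist = np.asarray(hist, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if len(edges) != len(hist) + 1:
        raise ConfigurationError("edges must have len(hist) + 1 entries")
    if hist.sum() <= 0:
        raise UndefinedStateError("empty histogram")
    floor = hist.sum() * min_mass_fraction
    modes = []
    for k in range(len(hist)):
        left = hist[k - 1] if k > 0 else -np.inf
        right = hist[k + 1] if k < len(hist) - 1 else -np.inf
        if hist[k] > left and hist[k] >= right and hist[k] > floor:
            modes.append(k)
    # keep the two most probable modes separated by a strictly lower bin
    modes.sort(key=lambda k: -hist[k])
    for a in range(len(modes)):
        for b in range(a + 1, len(modes)):
            lo, hi = sorted((modes[a], modes[b]))
            if hi > lo and hist[lo + 1:hi].size \
                    and hist[lo + 1:hi].min() < min(hist[lo], hist[hi]):
                centers = 0.5 * (edges[:-1] + edges[1:])
                return (
                    StateDefinition(state_ids[0], (-np.inf,), (centers[lo],)),
                    StateDefinition(state_ids[1], (centers[hi],), (np.inf,)))
    raise UndefinedStateError(
        "histogram has no two separated modes; cannot define two states")


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateEstimate:
    """Eq.-1 rate estimate; invariant k = f / p holds exactly as stored."""

    k: float                  # per unit time
    f: float                  # probability flux per unit time
    p: float                  # labeled weight fraction of the initial state
    burn_in_fraction: float
    sem: float = np.nan       # s.e.m. of k over independent archives
    n_runs: int = 1
    unset_fraction: float = 0.0
    upper_bound: bool = False

    def __post_init__(self):
        if self.f < 0 or not (0.0 < self.p <= 1.0):
            raise ConfigurationError("require f >= 0 and p in (0, 1]")
        if abs(self.k - self.f / self.p) > 1e-12 * max(1.0, abs(self.k)):
            raise ConfigurationError("stored k must equal f / p")


def _rate_one(archive, burn_in_fraction: float) -> tuple:
    from .we import LABEL_I, LABEL_J, LABEL_UNSET

    t0 = archive.burn_in_start(burn_in_fraction)
    its = archive.iterations[t0:]
    if not its:
        raise ConfigurationError("no iterations after burn-in")
    flux = sum(it.recycled_flux for it in its)
    f = flux / (len(its) * archive.tau)
    wi = wj = wu = 0.0
    for it in its:
        wi += float(it.weights[it.labels == LABEL_I].sum())
        wj += float(it.weights[it.labels == LABEL_J].sum())
        wu += float(it.weights[it.labels == LABEL_UNSET].sum())
    if wi + wj <= 0:
        raise ConfigurationError("no labeled weight after burn-in")
    p = wi / (wi + wj)
    unset = wu / (wi + wj + wu)
    return f, p, unset, len(its)


def estimate_rate(archives, burn_in_fraction: float = 0.1) -> RateEstimate:
    """Rate constant k_ij = f_ij / p_i from steady-state archive(s).

    With two or more independent archives the s.e.m. of k across archives
    is reported.  Zero flux after burn-in triggers a warning and an
    upper-bound estimate of one event per run length.
    """
    if not isinstance(archives, (list, tuple)):
        archives = [archives]
    per_run = []
    for arch in archives:
        if arch.mode != "steady-state":
            raise ConfigurationError("rate estimation needs steady-state mode")
        f, p, unset, n_it = _rate_one(arch, burn_in_fraction)
        per_run.append((f, p, unset, n_it, arch.tau))
    fs = np.array([r[0] for r in per_run])
    ps = np.array([r[1] for r in per_run])
    ks = fs / ps
    f_bar, p_bar = float(fs.mean()), float(ps.mean())
    upper = False
    if np.all(fs == 0.0):
        n_it, tau = per_run[0][3], per_run[0][4]
        warnings.warn("zero recycled flux after burn-in; "
                      "reporting an upper bound of one event per run")
        f_bar = 1.0 / (n_it * tau * len(per_run))
        ks = np.array([f_bar / p_bar])
        upper = True
    k = float(f_bar / p_bar)
    sem = float(ks.std(ddof=1) / np.sqrt(len(ks))) if len(ks) > 1 else np.nan
    return RateEstimate(k=k, f=f_bar, p=p_bar,
                        burn_in_fraction=burn_in_fraction, sem=sem,
                        n_runs=len(per_run),
                        unset_fraction=float(np.mean([r[2] for r in per_run])),
                        upper_bound=upper)


# ---------------------------------------------------------------------------
# Stabilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StabilityEstimate:
    """Folding free energy; invariant dG = -kT ln(P_f/P_u) as stored."""

    dG_fold: float
    p_folded: float
    p_unfolded: float
    temperature: float
    units: str
    sem: float = np.nan
    ddG_mut_minus_wt: float = np.nan

    @property
    def kT(self) -> float:
        return thermal_energy(self.temperature, self.units)


def _occupancy(archive, state, burn_in_fraction: float) -> float:
    t0 = archive.burn_in_start(burn_in_fraction)
    its = archive.iterations[t0:]
    w = 0.0
    for it in its:
        w += float(it.weights[state.contains_many(it.end_progress)].sum())
    return w / len(its)


def estimate_stability(folded: StateDefinition, unfolded: StateDefinition,
                       equilibrium_archives=None,
                       folding_archives=None, unfolding_archives=None,
                       temperature: float = DEFAULT_TEMPERATURE_K,
                       units: str = "real",
                       burn_in_fraction: float = 0.1,
                       reference: "StabilityEstimate | None" = None
                       ) -> StabilityEstimate:
    """ΔG_fold from equilibrium archives, or from opposing steady-state
    archives combined through their labeled-ensemble rate balance.

    ``reference`` (a wild-type estimate at the same temperature and state
    definitions) yields ΔΔG_mut-WT as mutant ΔG minus reference ΔG.
    """
    kT = thermal_energy(temperature, units)
    if equilibrium_archives is not None:
        if not isinstance(equilibrium_archives, (list, tuple)):
            equilibrium_archives = [equilibrium_archives]
        dgs, pf_all, pu_all = [], [], []
        for arch in equilibrium_archives:
            pf = _occupancy(arch, folded, burn_in_fraction)
            pu = _occupancy(arch, unfolded, burn_in_fraction)
            if pf <= 0 or pu <= 0:
                raise UndefinedStateError(
                    "a state carries no weight; stability undefined")
            dgs.append(-kT * np.log(pf / pu))
            pf_all.append(pf)
            pu_all.append(pu)
        pf, pu = float(np.mean(pf_all)), float(np.mean(pu_all))
        dg = -kT * float(np.log(pf / pu))
        sem = (float(np.std(dgs, ddof=1) / np.sqrt(len(dgs)))
               if len(dgs) > 1 else np.nan)
    elif folding_archives is not None and unfolding_archives is not None:
        k_fold = estimate_rate(folding_archives, burn_in_fraction)
        k_unfold = estimate_rate(unfolding_archives, burn_in_fraction)
        if k_fold.k <= 0 or k_unfold.k <= 0:
            raise UndefinedStateError("zero rate; stability undefined")
        ratio = k_fold.k / k_unfold.k
        pf, pu = ratio / (1.0 + ratio), 1.0 / (1.0 + ratio)
        dg = -kT * float(np.log(pf / pu))
        rel = []
        for est in (k_fold, k_unfold):
            if np.isfinite(est.sem) and est.k > 0:
                rel.append((est.sem / est.k) ** 2)
        sem = kT * float(np.sqrt(sum(rel))) if rel else np.nan
    else:
        raise ConfigurationError(
            "provide equilibrium_archives or both directional archive sets")
    ddg = np.nan
    if reference is not None:
        if (reference.temperature, reference.units) != (temperature, units):
            raise ConfigurationError(
                "ΔΔG requires matching temperature and unit system")
        ddg = dg - reference.dG_fold
    return StabilityEstimate(dG_fold=dg, p_folded=pf, p_unfolded=pu,
                             temperature=temperature, units=units, sem=sem,
                             ddG_mut_minus_wt=ddg)


# ---------------------------------------------------------------------------
# Barrier conversions, MFPT, efficiency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BarrierReduction:
    """ΔΔG‡ implied by a fold-change in rate: ΔΔG‡ = RT ln(k_mut/k_WT)."""

    fold_change: float
    temperature: float
    ddG_barrier: float
    units: str = "real"

    def summary(self) -> str:
        return (f"{self.fold_change:g}-fold -> "
                f"{self.ddG_barrier:.1f} kcal mol^-1"
                if self.units == "real" else
                f"{self.fold_change:g}-fold -> {self.ddG_barrier:.1f} kT")


def barrier_reduction(fold_change: float,
                      temperature: float = DEFAULT_TEMPERATURE_K,
                      units: str = "real") -> BarrierReduction:
    """Free-energy-barrier reduction equivalent to a rate fold-change."""
    if fold_change <= 0:
        raise ConfigurationError("fold change must be positive")
    kT = thermal_energy(temperature, units)
    return BarrierReduction(fold_change=float(fold_change),
                            temperature=temperature,
                            ddG_barrier=kT * float(np.log(fold_change)),
                            units=units)


def mfpt(rate: RateEstimate) -> tuple:
    """Mean first passage time 1/k with propagated s.e.m., in the archive's
    time unit (τ-based rates give MFPTs in τ)."""
    if rate.k <= 0:
        raise ConfigurationError("zero rate has no finite MFPT")
    t = 1.0 / rate.k
    sem = rate.sem / rate.k ** 2 if np.isfinite(rate.sem) else np.nan
    return t, sem


@dataclass(frozen=True)
class EfficiencyReport:
    """WE-vs-brute-force efficiency S = brute-force cost / WE cost.

    The brute-force cost of harvesting the same number of independent
    switching events is MFPT × n_events; the WE cost is the aggregate
    simulated time of the run.
    """

    S: float
    brute_force_cost: float
    we_cost: float
    mfpt: float
    n_events: int

    def __post_init__(self):
        if self.brute_force_cost <= 0 or self.we_cost <= 0:
            raise ConfigurationError("costs must be positive")
        if abs(self.S - self.brute_force_cost / self.we_cost) > 1e-9 * self.S:
            raise ConfigurationError("S must equal cost ratio")


def efficiency(rate: RateEstimate, archives,
               burn_in_fraction: float = 0.1) -> EfficiencyReport:
    """Efficiency of the WE run(s) that produced ``rate``."""
    if not isinstance(archives, (list, tuple)):
        archives = [archives]
    n_events = sum(a.n_recycle_events(burn_in_fraction) for a in archives)
    if n_events == 0:
        raise ConfigurationError("no switching events; efficiency undefined")
    t, _ = mfpt(rate)
    bf_cost = t * n_events
    we_cost = float(sum(a.aggregate_time for a in archives))
    return EfficiencyReport(S=bf_cost / we_cost, brute_force_cost=bf_cost,
                            we_cost=we_cost, mfpt=t, n_events=n_events)
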