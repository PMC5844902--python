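"""Synthetic toy systems and brute-force oracles.

Everything the test and acceptance suites need is generated here at run
time: 1-D diffusive double/triple wells with numerically known rates, a
two-strand bead "hairpin" (a minimal two-state folder), and a miniature
alternate-frame-folding construct in which two copies of one strand
compete for a shared strand.  All fixtures are seed-deterministic, use
reduced units (k_BT = 1) unless noted, and the brute-force oracles share
no resampling logic with the WE engine, so oracle agreement is a genuine
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import cumulative_trapezoid

from . import _kernels
from .dynamics import GoPropagator, IntegratorConfig, TrajectorySegment
from .errors import ConfigurationError, NumericalError
from .kinetics import StateDefinition
from .model import (AFFModel, BeadStructure, ForceFieldParams,
                    build_aff_model, build_two_state_model,
                    compute_native_contacts, structure_to_pdb)
from .we import BinMapper

__all__ = ["DoubleWellSpec", "DoubleWellPropagator", "make_double_well",
           "brute_force_rate", "BruteForceRate", "make_hairpin",
           "build_hairpin_model", "hairpin_states", "hairpin_bins",
           "ToyAFFSpec", "ToyAFF", "make_toy_aff", "make_two_hand_fold"]


# ---------------------------------------------------------------------------
# 1-D double / triple wells
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoubleWellSpec:
    """Quartic double well V(x) = h ((x/a)^2 - 1)^2 with minima at ±a and a
    barrier of height h (k_BT units) at x = 0; an optional Gaussian dimple
    of depth ``third_well_depth`` at the origin creates a metastable
    intermediate (the triple-well fixture)."""

    barrier_height: float = 5.0      # k_BT
    well_separation: float = 2.0     # distance between minima (a = sep/2)
    diffusion: float = 1.0
    third_well_depth: float = 0.0    # k_BT
    third_well_width: float = 0.25
    timestep: float = 5.0e-3
    tau: float = 0.5
    sample_interval: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.barrier_height < 0 or self.well_separation <= 0:
            raise ConfigurationError("invalid well geometry")

    @property
    def a(self) -> float:
        return self.well_separation / 2.0


class DoubleWellPropagator:
    """1-D Brownian particle in the closed-form double/triple well.

    Satisfies the WE propagator contract; the progress coordinate is the
    position itself.  Coordinates are length-1 arrays.
    """

    def __init__(self, spec: DoubleWellSpec):
        self.spec = spec
        self.kT = 1.0
        n = spec.tau / spec.timestep
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("tau must be a multiple of timestep")
        self.n_steps = int(round(n))
        self.sample_stride = int(round(spec.sample_interval / spec.timestep))
        if self.n_steps % self.sample_stride:
            raise ConfigurationError(
                "tau must be a multiple of sample_interval")

    @property
    def tau(self) -> float:
        return self.spec.tau

    @property
    def sample_interval(self) -> float:
        return self.spec.sample_interval

    @property
    def ndim(self) -> int:
        return 1

    def potential(self, x):
        s = self.spec
        v = s.barrier_height * ((np.asarray(x) / s.a) ** 2 - 1.0) ** 2
        if s.third_well_depth:
            v = v - s.third_well_depth * np.exp(
                -np.asarray(x) ** 2 / (2.0 * s.third_well_width ** 2))
        return v

    def propagate(self, coords, rng: np.random.Generator) -> TrajectorySegment:
        s = self.spec
        x0 = float(np.atleast_1d(coords)[0])
        noise = np.sqrt(2.0 * s.diffusion * s.timestep) \
            * rng.standard_normal(self.n_steps)
        samples = np.empty(self.n_steps // self.sample_stride)
        end = _kernels.dw_segment(
            x0, self.n_steps, s.diffusion * s.timestep / self.kT, noise,
            self.sample_stride, s.barrier_height, s.a,
            s.third_well_depth, s.third_well_width, samples)
        times = s.sample_interval * np.arange(1, len(samples) + 1)
        return TrajectorySegment(frames=samples, times=times,
                                 end_coords=np.array([end]))

    def progress(self, coords) -> np.ndarray:
        return np.atleast_1d(np.asarray(coords, dtype=float))

    # ---- closed-form / brute-force oracles ------------------------------

    def mfpt_quadrature(self, x_start: float, x_target: float,
                        x_min: float = None, n_grid: int = 4001) -> float:
        """Mean first passage time by the double-integral formula

            MFPT = (1/D) ∫_{x0}^{b} dy e^{V(y)} ∫_{-inf}^{y} dz e^{-V(z)}

        (reflecting boundary far to the left, absorbing at the target).
        """
        s = self.spec
        if x_min is None:
            x_min = -abs(s.a) * 4.0
        y = np.linspace(x_min, x_target, n_grid)
        v = self.potential(y)
        inner = cumulative_trapezoid(np.exp(-(v - v.min())), y, initial=0.0)
        # evaluate exp(V) * inner in log space to avoid overflow far from
        # the wells, where exp(V) alone overflows but the product is tiny
        with np.errstate(divide="ignore"):
            log_term = (v - v.min()) + np.log(inner)
        integrand = np.where(inner > 0, np.exp(log_term), 0.0)
        outer = cumulative_trapezoid(integrand, y, initial=0.0)
        start_idx = int(np.searchsorted(y, x_start))
        return float((outer[-1] - outer[start_idx]) / s.diffusion)

    def brute_force_passage_times(self, state_i: StateDefinition,
                                  state_j: StateDefinition, n_events: int,
                                  seed: int,
                                  max_steps: int = 2_000_000_000) -> tuple:
        """History-labeled i->j waiting times from one long unbiased
        trajectory (independent of the WE machinery)."""
        s = self.spec
        i_is_low = np.isinf(state_i.lower[0])   # i = (-inf, b] ?
        if i_is_low:
            low_bound, high_bound = state_i.upper[0], state_j.lower[0]
            x0 = -s.a
        else:
            low_bound, high_bound = state_j.upper[0], state_i.lower[0]
            x0 = s.a
        times, count, steps = _kernels.dw_first_passage(
            x0, s.timestep, s.diffusion * s.timestep / self.kT,
            np.sqrt(2.0 * s.diffusion * s.timestep),
            s.barrier_height, s.a, s.third_well_depth, s.third_well_width,
            low_bound, high_bound, i_is_low, n_events, max_steps, seed)
        return times[:count], steps * s.timestep

    def default_states(self) -> tuple:
        a = self.spec.a
        return (StateDefinition("i", (-np.inf,), (-a,)),
                StateDefinition("j", (a,), (np.inf,)))

    def default_mapper(self, n_bins: int = 16) -> BinMapper:
        a = self.spec.a
        return BinMapper(edges=(np.linspace(-1.6 * a, 1.6 * a, n_bins + 1),))

    def equilibrium_histogram(self, edges: np.ndarray) -> np.ndarray:
        """Exact Boltzmann bin probabilities (quadrature oracle), normalized
        over the binned range; integrates each bin on its own subgrid."""
        probs = np.empty(len(edges) - 1)
        for k in range(len(probs)):
            xs = np.linspace(edges[k], edges[k + 1], 801)
            probs[k] = np.trapezoid(np.exp(-self.potential(xs)), xs)
        return probs / probs.sum()


def make_double_well(spec: DoubleWellSpec) -> DoubleWellPropagator:
    """Propagator for the closed-form 1-D well system."""
    return DoubleWellPropagator(spec)


# ---------------------------------------------------------------------------
# Brute-force rate oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BruteForceRate:
    """Label-based brute-force rate: k = 1 / mean waiting time."""

    rate: float
    mfpt: float
    sem_mfpt: float
    sem_rate: float
    n_events: int
    total_time: float
    partial: bool = False


def brute_force_rate(propagator, state_i: StateDefinition,
                     state_j: StateDefinition, n_events: int,
                     seed: int = 0, max_segments: int = 2_000_000
                     ) -> BruteForceRate:
    """Unbiased long-trajectory rate estimate.

    Uses the propagator's dedicated kernel when available (1-D wells);
    otherwise propagates τ-segments and tracks history labels at segment
    resolution.  Each completed i->j label switch contributes one waiting
    time; the rate is the reciprocal mean waiting time with the s.e.m.
    propagated from the event-time dispersion.
    """
    if n_events < 50:
        raise ConfigurationError("need n_events >= 50 for a stable oracle")
    if hasattr(propagator, "brute_force_passage_times"):
        times, total = propagator.brute_force_passage_times(
            state_i, state_j, n_events, seed)
    else:
        rng = np.random.default_rng(seed)
        x = propagator.initial_coords(rng) if hasattr(
            propagator, "initial_coords") else None
        if x is None:
            raise ConfigurationError(
                "generic brute force needs propagator.initial_coords")
        label, entered = None, 0.0
        t_now = 0.0
        waits = []
        for _ in range(max_segments):
            seg = propagator.propagate(x, rng)
            x = seg.end_coords
            t_now += propagator.tau
            p = propagator.progress(x)
            if state_i.contains(p):
                if label != "i":
                    label, entered = "i", t_now
            elif state_j.contains(p):
                if label == "i":
                    waits.append(t_now - entered)
                    if len(waits) >= n_events:
                        break
                label = "j"
        times, total = np.asarray(waits), t_now
    partial = len(times) < n_events
    if partial:
        import warnings
        warnings.warn(f"event budget exhausted: {len(times)}/{n_events} "
                      "events; estimate is partial")
    if len(times) == 0:
        raise NumericalError("no passage events observed")
    m = float(np.mean(times))
    sem_m = float(np.std(times, ddof=1) / np.sqrt(len(times))) \
        if len(times) > 1 else np.nan
    return BruteForceRate(rate=1.0 / m, mfpt=m, sem_mfpt=sem_m,
                          sem_rate=sem_m / m ** 2, n_events=len(times),
                          total_time=float(total), partial=partial)


# ---------------------------------------------------------------------------
# Toy hairpin (two-state folder)
# ---------------------------------------------------------------------------

def make_hairpin(n_beads: int = 16, strand_separation: float = 5.0,
                 bond_length: float = 3.8, wobble: float = 0.35
                 ) -> BeadStructure:
    """Two antiparallel zigzag strands: a minimal cooperative two-state
    folder.  Coordinates are rounded to PDB precision (10^-3 Å) so written
    files round-trip exactly."""
    if n_beads < 8 or n_beads % 2:
        raise ConfigurationError("hairpin needs an even bead count >= 8")
    half = n_beads // 2
    rise = np.sqrt(bond_length ** 2 - (2 * wobble) ** 2)
    coords = []
    for i in range(half):
        coords.append([0.0, i * rise, wobble * (-1) ** i])
    for i in range(half):
        coords.append([strand_separation, (half - 1 - i) * rise,
                       wobble * (-1) ** i])
    coords = np.round(np.asarray(coords), 3)
    return BeadStructure(residue_index=np.arange(1, n_beads + 1),
                         residue_name=tuple(["ALA"] * n_beads),
                         coords=coords)


#: Default contact depth for hairpin fixtures (k_BT units); gives a folded
#: two-state hairpin with ΔG_fold of a few k_BT at k_BT = 1.
HAIRPIN_EPS = 1.3

#: Reduced-unit integrator settings shared by the bead-model fixtures.
REDUCED_CONFIG = IntegratorConfig(timestep=1.25e-3, tau=0.2,
                                  sample_interval=0.1, diffusion=1.0,
                                  temperature=1.0, units="reduced",
                                  max_step=2.0)


def build_hairpin_model(eps: float = HAIRPIN_EPS, n_beads: int = 16,
                        ff: ForceFieldParams = ForceFieldParams()
                        ) -> AFFModel:
    """Two-state hairpin model in reduced units."""
    return build_two_state_model(make_hairpin(n_beads), eps=eps, ff=ff)


def hairpin_states(folded_rmsd: float = 2.0,
                   unfolded_rmsd: float = 6.5) -> tuple:
    """Fixture state definitions along the RMSD-to-native coordinate."""
    return (StateDefinition("folded", (-np.inf,), (folded_rmsd,)),
            StateDefinition("unfolded", (unfolded_rmsd,), (np.inf,)))


def hairpin_bins(max_rmsd: float = 14.0, width: float = 0.5) -> BinMapper:
    return BinMapper(edges=(np.arange(width, max_rmsd, width),))


# ---------------------------------------------------------------------------
# Toy AFF construct
# ---------------------------------------------------------------------------

def make_two_hand_fold(hand_gap: float = 7.8, strand_separation: float = 5.0,
                       bond_length: float = 3.8, wobble: float = 0.35
                       ) -> BeadStructure:
    """A 20-residue fold of two packed "hands" (mini-hairpins).

    Hand A (residues 1-10) and hand B (residues 11-20) are each a 5+5
    antiparallel hairpin; the hands stack at an interface of ~9 native
    contacts.  This miniaturizes a two-EF-hand architecture: duplicating
    hand B yields an AFF construct in which the two copies of B compete
    for the same docking site on the shared hand A, and the undocked
    ("orphan") copy retains its intra-hand structure.  Coordinates are
    rounded to PDB precision.
    """
    q = 5
    rise = np.sqrt(bond_length ** 2 - (2 * wobble) ** 2)
    coords = []
    for i in range(q):
        coords.append([0.0, i * rise, wobble * (-1) ** i])
    for i in range(q):
        coords.append([strand_separation, (q - 1 - i) * rise,
                       wobble * (-1) ** i])
    for i in range(q):
        coords.append([strand_separation, i * rise,
                       hand_gap + wobble * (-1) ** i])
    for i in range(q):
        coords.append([0.0, (q - 1 - i) * rise,
                       hand_gap + wobble * (-1) ** i])
    coords = np.round(np.asarray(coords), 3)
    return BeadStructure(residue_index=np.arange(1, 21),
                         residue_name=tuple(["ALA"] * 20), coords=coords)


@dataclass(frozen=True)
class ToyAFFSpec:
    """Miniature AFF construct built on the two-hand fold: hand B
    (residues 11-20) is duplicated and appended N-terminally through a
    2-residue linker, so the two copies of B compete for hand A."""

    wt_length: int = 20
    duplicated_range: tuple = (11, 20)
    linker_length: int = 2
    eps: float = 0.95           # interface contact depth (k_BT)
    hand_strength: float = 2.0  # intra-hand contacts scaled by this factor
    folded_rmsd: float = 2.5    # state boundary on each frame's RMSD
    other_rmsd: float = 4.0     # the competing frame must exceed this
    target_dG: float | None = None   # per-frame ΔG_fold (k_BT); None = eps


@dataclass
class ToyAFF:
    """Bundle of everything needed to simulate the toy switch."""

    model: AFFModel
    wt: BeadStructure
    pdb_text: str
    config: IntegratorConfig
    state_N: StateDefinition
    state_Nprime: StateDefinition
    mapper: BinMapper
    spec: ToyAFFSpec

    def propagator(self, model: AFFModel | None = None) -> GoPropagator:
        return GoPropagator(model if model is not None else self.model,
                            self.config)

    def initial_sampler(self, state: str, model: AFFModel | None = None,
                        n_relax: int = 2) -> Callable:
        """Sampler drawing relaxed configurations inside one folded state."""
        mdl = model if model is not None else self.model
        prop = GoPropagator(mdl, self.config)
        start = (mdl.native_coords_N if state == "N"
                 else mdl.native_coords_Nprime)
        target = self.state_N if state == "N" else self.state_Nprime

        def sampler(rng: np.random.Generator):
            x = start.copy()
            for _ in range(n_relax):
                seg = prop.propagate(x, rng)
                if target.contains(prop.progress(seg.end_coords)):
                    x = seg.end_coords
            return x
        return sampler


def make_toy_aff(spec: ToyAFFSpec = ToyAFFSpec()) -> ToyAFF:
    """Build the toy AFF switch (model, states, bins, PDB round-trip text).

    The construct is calibrated implicitly through ``spec.eps``; passing
    ``target_dG`` instead runs the hairpin calibration for the wild-type
    component and reuses the resulting ε.
    """
    if spec.wt_length != 20:
        raise ConfigurationError("the two-hand toy fold has 20 residues")
    wt = make_two_hand_fold()
    eps = spec.eps
    if spec.target_dG is not None:
        from .calibrate import calibrate_hairpin_eps
        eps = calibrate_hairpin_eps(spec.target_dG, n_beads=spec.wt_length,
                                    units="reduced").eps
    contacts = compute_native_contacts(wt, cutoff=8.0, min_separation=3,
                                       eps=eps)
    # hands are stiffer than the packing interface they exchange: intra-hand
    # contacts are deepened so the orphan copy stays internally folded while
    # docking/undocking crosses only the soft interface
    intra = ((contacts.i <= 10) & (contacts.j <= 10)) \
        | ((contacts.i >= 11) & (contacts.j >= 11))
    contacts.eps[intra] *= spec.hand_strength
    model = build_aff_model(wt, contacts, spec.duplicated_range,
                            spec.linker_length, eps=eps)
    c, u = spec.folded_rmsd, spec.other_rmsd
    state_N = StateDefinition("N", (0.0, u), (c, np.inf))
    state_Np = StateDefinition("Nprime", (u, 0.0), (np.inf, c))
    # 2-D bins over (rmsd_N, rmsd_N'), fine near the folded basins where
    # the dock/undock ladder needs resolution and coarse in the far field
    fine = np.array([1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.5, 6.0, 9.0])
    mapper = BinMapper(edges=(fine, fine))
    return ToyAFF(model=model, wt=wt, pdb_text=structure_to_pdb(wt),
                  config=REDUCED_CONFIG, state_N=state_N,
                  state_Nprime=state_Np, mapper=mapper, spec=spec)
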