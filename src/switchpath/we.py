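"""Weighted-ensemble orchestration.

Many weighted trajectory replicas ("walkers") are propagated in parallel
for fixed intervals τ, then split and merged per progress-coordinate bin so
that every occupied bin holds the same number of walkers.  Splitting and
merging conserve probability exactly and preserve the expectation of every
weight-linear observable, so the dynamics are never biased.

Two modes are supported:

* ``steady-state`` — walkers reaching the target state are "recycled":
  terminated and restarted from the initial-state distribution with the
  same weight.  The recycled weight per unit time is the probability flux
  entering the target.
* ``equilibrium`` — no recycling; the walker ensemble relaxes toward the
  Boltzmann distribution.

Each walker carries a history label: the state (initial or target) it
visited most recently.  Labels are inherited through splits and merges and
feed the rate estimator k_ij = f_ij / p_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, CorruptArchiveError
from .kinetics import StateDefinition

__all__ = ["Walker", "BinMapper", "WEConfig", "WEIteration", "WEArchive",
           "assign_bins", "resample_bin", "recycle", "update_history_labels",
           "run_we"]

LABEL_UNSET = -1
LABEL_I = 0
LABEL_J = 1

WEIGHT_TOLERANCE = 1e-12


@dataclass
class Walker:
    """One trajectory replica."""

    coords: np.ndarray
    weight: float
    history_label: int = LABEL_UNSET      # LABEL_I, LABEL_J or LABEL_UNSET
    parent_id: int = -1
    walker_id: int = -1
    progress: np.ndarray | None = None

    def __post_init__(self):
        if not (0.0 < self.weight <= 1.0 + WEIGHT_TOLERANCE):
            raise ConfigurationError(f"walker weight {self.weight} not in (0, 1]")


@dataclass(frozen=True)
class BinMapper:
    """Rectilinear binning of a progress coordinate.

    ``edges`` holds the interior edges per dimension; bins are half-open
    [low, high) and the outermost bins absorb under/overflow, so every
    finite coordinate maps to exactly one bin.  ``coordinate_fn`` optionally
    maps walker coordinates to the binning coordinate; when absent, the
    propagator's progress coordinate is binned directly.  (Binning only
    controls where computational effort is spent — any choice leaves the
    sampled dynamics unbiased.)
    """

    edges: tuple
    coordinate_fn: Callable | None = None

    def __post_init__(self):
        edges = tuple(np.asarray(e, dtype=float) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        for e in edges:
            if len(e) and np.any(np.diff(e) <= 0):
                raise ConfigurationError("bin edges must be strictly increasing")

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def shape(self) -> tuple:
        return tuple(len(e) + 1 for e in self.edges)

    def assign(self, progress: np.ndarray) -> int:
        """Flat bin index of one binning coordinate."""
        progress = np.atleast_1d(np.asarray(progress, dtype=float))
        if len(progress) != self.ndim or not np.all(np.isfinite(progress)):
            raise ConfigurationError(
                f"progress coordinate {progress} not finite {self.ndim}-D")
        idx = tuple(int(np.searchsorted(e, p, side="right"))
                    for e, p in zip(self.edges, progress))
        return int(np.ravel_multi_index(idx, self.shape))

    def binning_coordinate(self, coords, progress: np.ndarray) -> np.ndarray:
        """The coordinate this mapper bins: a function of the walker's
        configuration if one was supplied, else the progress coordinate."""
        if self.coordinate_fn is None:
            return progress
        return np.atleast_1d(self.coordinate_fn(coords))


def assign_bins(walkers: Sequence[Walker], mapper: BinMapper) -> dict:
    """Exhaustive, disjoint partition of walkers by bin index.

    Walkers with a non-finite progress coordinate are quarantined under the
    key ``"quarantined"`` together with an error record.
    """
    groups: dict = {}
    quarantined = []
    for k, w in enumerate(walkers):
        p = np.atleast_1d(w.progress)
        if not np.all(np.isfinite(p)):
            quarantined.append((k, w, f"non-finite progress {p}"))
            continue
        groups.setdefault(mapper.assign(p), []).append(w)
    if quarantined:
        groups["quarantined"] = quarantined
    return groups


def resample_bin(walkers: Sequence[Walker], target_count: int,
                 rng: np.random.Generator) -> list:
    """Split/merge one bin's walkers to exactly ``target_count``.

    Splitting divides a parent's weight equally among its clones; merging
    repeatedly combines the two lowest-weight walkers, keeping one of the
    two with probability proportional to weight (the survivor absorbs both
    weights).  Total weight is conserved and the expectation of any
    weight-linear observable is preserved.
    """
    if target_count < 1:
        raise ConfigurationError("target_count must be >= 1")
    if not walkers:
        raise ConfigurationError("cannot resample an empty bin")
    pool = [replace(w) for w in walkers]
    while len(pool) > target_count:
        pool.sort(key=lambda w: w.weight)
        a, b = pool[0], pool[1]
        total = a.weight + b.weight
        survivor = a if rng.random() < a.weight / total else b
        survivor = replace(survivor, weight=total)
        pool = [survivor] + pool[2:]
    while len(pool) < target_count:
        pool.sort(key=lambda w: -w.weight)
        parent = pool.pop(0)
        half = parent.weight / 2.0
        pool.extend([replace(parent, weight=half),
                     replace(parent, weight=half)])
    return pool


def update_history_labels(walkers: Sequence[Walker],
                          state_defs: Sequence[StateDefinition],
                          progress_fn: Callable | None = None) -> list:
    """Set each walker's label to the state containing it; otherwise the
    label is inherited unchanged.  State regions must be disjoint."""
    for a in range(len(state_defs)):
        for b in range(a + 1, len(state_defs)):
            if state_defs[a].overlaps(state_defs[b]):
                raise ConfigurationError(
                    f"state definitions {state_defs[a].state_id!r} and "
                    f"{state_defs[b].state_id!r} overlap")
    out = []
    for w in walkers:
        p = w.progress if progress_fn is None else progress_fn(w.coords)
        label = w.history_label
        for s_idx, state in enumerate(state_defs):
            if state.contains(p):
                label = s_idx
                break
        out.append(replace(w, history_label=label, progress=p))
    return out


def recycle(walkers: Sequence[Walker], target_state: StateDefinition,
            initial_sampler: Callable, rng: np.random.Generator,
            mode: str = "steady-state",
            initial_label: int = LABEL_I) -> tuple:
    """Replace every walker inside the target state by a fresh
    initial-state walker of identical weight; returns (walkers, flux).

    In equilibrium mode this is the identity with zero flux.
    """
    if mode == "equilibrium":
        return list(walkers), 0.0
    out = []
    flux = 0.0
    for w in walkers:
        if target_state.contains(w.progress):
            flux += w.weight
            out.append(replace(w, coords=initial_sampler(rng), progress=None,
                               history_label=initial_label))
        else:
            out.append(replace(w))
    return out, flux


@dataclass(frozen=True)
class WEConfig:
    """Run configuration for the WE engine."""

    mode: str                           # "steady-state" | "equilibrium"
    n_iterations: int
    bin_mapper: BinMapper
    initial_sampler: Callable           # rng -> coords
    walkers_per_bin: int = 4
    state_i: StateDefinition | None = None
    state_j: StateDefinition | None = None
    seed: int = 0
    store_samples: bool = True
    store_end: bool = True

    def __post_init__(self):
        if self.mode not in ("steady-state", "equilibrium"):
            raise ConfigurationError(f"unknown WE mode {self.mode!r}")
        if self.walkers_per_bin < 1:
            raise ConfigurationError("walkers_per_bin must be >= 1")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.mode == "steady-state" and (self.state_i is None
                                            or self.state_j is None):
            raise ConfigurationError(
                "steady-state mode requires initial and target states")

    @property
    def states(self) -> list:
        return [s for s in (self.state_i, self.state_j) if s is not None]


@dataclass
class WEIteration:
    """Per-iteration record of the propagated (pre-resampling) segments."""

    index: int
    weights: np.ndarray          # (m,)
    labels: np.ndarray           # (m,) int8, label after this segment
    parents: np.ndarray          # (m,) int32, record index in prev iteration
    end_progress: np.ndarray     # (m, d) progress at segment end
    recycled: np.ndarray         # (m,) bool, recycled at end of this segment
    bin_index: np.ndarray        # (m,) int32, bin after recycling
    recycled_flux: float
    weight_error: float          # |sum(weights) - 1|
    samples: np.ndarray | None = None          # (m, k, ...) float32
    sample_progress: np.ndarray | None = None  # (m, k, d)
    end_coords: np.ndarray | None = None       # (m, ...) float32
    restart_coords: dict = field(default_factory=dict)  # rec idx -> coords

    @property
    def n_walkers(self) -> int:
        return len(self.weights)


@dataclass
class WEArchive:
    """Iteration archive of one WE run."""

    mode: str
    tau: float
    sample_interval: float
    seed: int
    walkers_per_bin: int
    progress_dim: int
    initial_coords: np.ndarray        # (m0, ...) iteration-0 start points
    initial_progress: np.ndarray      # (m0, d)
    iterations: list = field(default_factory=list)
    state_i: StateDefinition | None = None
    state_j: StateDefinition | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def burn_in_start(self, burn_in_fraction: float = 0.1) -> int:
        return int(math.floor(self.n_iterations * burn_in_fraction))

    @property
    def aggregate_time(self) -> float:
        """Total simulated time across all segments."""
        return self.tau * sum(it.n_walkers for it in self.iterations)

    def flux_series(self) -> np.ndarray:
        return np.array([it.recycled_flux for it in self.iterations])

    def n_recycle_events(self, burn_in_fraction: float = 0.0) -> int:
        t0 = self.burn_in_start(burn_in_fraction)
        return int(sum(it.recycled.sum() for it in self.iterations[t0:]))

    def label_fractions(self, burn_in_fraction: float = 0.1) -> dict:
        """Time-averaged weight fractions by history label."""
        t0 = self.burn_in_start(burn_in_fraction)
        acc = {LABEL_I: 0.0, LABEL_J: 0.0, LABEL_UNSET: 0.0}
        n = 0
        for it in self.iterations[t0:]:
            for lab in acc:
                acc[lab] += float(it.weights[it.labels == lab].sum())
            n += 1
        if n == 0:
            raise CorruptArchiveError("archive has no post-burn-in iterations")
        return {k: v / n for k, v in acc.items()}

    def max_weight_error(self) -> float:
        return max((it.weight_error for it in self.iterations), default=0.0)

    def validate_lineage(self) -> None:
        """Every walker in iteration t > 0 must point to a valid parent."""
        for t, it in enumerate(self.iterations):
            n_prev = (len(self.initial_coords) if t == 0
                      else self.iterations[t - 1].n_walkers)
            bad = (it.parents < 0) | (it.parents >= n_prev)
            if np.any(bad):
                raise CorruptArchiveError(
                    f"iteration {t}: invalid parent indices "
                    f"{it.parents[bad].tolist()}")


def _label_of(progress, state_i, state_j, fallback: int) -> int:
    if state_i is not None and state_i.contains(progress):
        return LABEL_I
    if state_j is not None and state_j.contains(progress):
        return LABEL_J
    return fallback


def run_we(propagator, config: WEConfig) -> WEArchive:
    """Run a WE simulation; a fixed seed fully determines the archive."""
    rng = np.random.default_rng(config.seed)
    for a, sa in enumerate(config.states):
        for sb in config.states[a + 1:]:
            if sa.overlaps(sb):
                raise ConfigurationError("state definitions overlap")

    m0 = config.walkers_per_bin
    init_coords, init_progress = [], []
    walkers = []
    for k in range(m0):
        c = np.asarray(config.initial_sampler(rng))
        p = np.atleast_1d(propagator.progress(c))
        init_coords.append(c)
        init_progress.append(p)
        walkers.append(Walker(coords=c, weight=1.0 / m0,
                              history_label=_label_of(p, config.state_i,
                                                      config.state_j,
                                                      LABEL_UNSET),
                              parent_id=k, walker_id=k, progress=p))

    archive = WEArchive(
        mode=config.mode, tau=propagator.tau,
        sample_interval=getattr(propagator, "sample_interval",
                                getattr(getattr(propagator, "config", None),
                                        "sample_interval", propagator.tau)),
        seed=config.seed, walkers_per_bin=config.walkers_per_bin,
        progress_dim=len(init_progress[0]),
        initial_coords=np.asarray(init_coords, dtype=np.float32),
        initial_progress=np.asarray(init_progress),
        state_i=config.state_i, state_j=config.state_j)

    for t in range(config.n_iterations):
        m = len(walkers)
        weights = np.array([w.weight for w in walkers])
        parents = np.array([w.parent_id for w in walkers], dtype=np.int32)
        end_progress = np.empty((m, archive.progress_dim))
        labels = np.empty(m, dtype=np.int8)
        recycled = np.zeros(m, dtype=bool)
        samples_list, sample_prog_list, end_list = [], [], []
        restart = {}
        flux = 0.0
        next_states = []   # (coords, progress, label) after recycling

        batch = getattr(propagator, "propagate_many", None)
        if batch is not None:
            ends, batch_samples = batch([w.coords for w in walkers], rng,
                                        store_samples=config.store_samples)
        for k, w in enumerate(walkers):
            if batch is not None:
                end_coords = ends[k]
                frames = (batch_samples[k] if config.store_samples else None)
            else:
                seg = propagator.propagate(w.coords, rng)
                end_coords = seg.end_coords
                frames = seg.frames if config.store_samples else None
            endp = np.atleast_1d(propagator.progress(end_coords))
            end_progress[k] = endp
            lab = _label_of(endp, config.state_i, config.state_j,
                            w.history_label)
            if config.store_samples:
                samples_list.append(np.asarray(frames, dtype=np.float32))
                sample_prog_list.append(np.asarray(
                    [np.atleast_1d(propagator.progress(fr))
                     for fr in frames]))
            if config.store_end:
                end_list.append(np.asarray(end_coords, dtype=np.float32))
            if (config.mode == "steady-state"
                    and config.state_j.contains(endp)):
                recycled[k] = True
                flux += w.weight
                c = np.asarray(config.initial_sampler(rng))
                p = np.atleast_1d(propagator.progress(c))
                restart[k] = np.asarray(c, dtype=np.float32)
                next_states.append((c, p, LABEL_I))
                labels[k] = lab
            else:
                next_states.append((end_coords, endp, lab))
                labels[k] = lab

        post = [Walker(coords=c, weight=float(weights[k]), history_label=lab,
                       parent_id=k, walker_id=k, progress=p)
                for k, (c, p, lab) in enumerate(next_states)]

        groups: dict = {}
        bin_index = np.empty(m, dtype=np.int32)
        for w in post:
            bc = config.bin_mapper.binning_coordinate(w.coords, w.progress)
            if not np.all(np.isfinite(bc)):
                raise CorruptArchiveError(
                    f"iteration {t}: non-finite binning coordinate for "
                    f"walker {w.parent_id}")
            b = config.bin_mapper.assign(bc)
            groups.setdefault(b, []).append(w)
            bin_index[w.parent_id] = b

        new_walkers = []
        for b in sorted(groups):
            new_walkers.extend(
                resample_bin(groups[b], config.walkers_per_bin, rng))
        walkers = new_walkers

        weight_error = abs(math.fsum(w.weight for w in walkers) - 1.0)
        if weight_error > 1e-9:
            raise CorruptArchiveError(
                f"iteration {t}: weight drift {weight_error:.3e}")

        archive.iterations.append(WEIteration(
            index=t, weights=weights, labels=labels, parents=parents,
            end_progress=end_progress, recycled=recycled,
            bin_index=bin_index, recycled_flux=flux,
            weight_error=weight_error,
            samples=(np.asarray(samples_list, dtype=np.float32)
                     if config.store_samples else None),
            sample_progress=(np.asarray(sample_prog_list)
                             if config.store_samples else None),
            end_coords=(np.asarray(end_list, dtype=np.float32)
                        if config.store_end else None),
            restart_coords=restart))
    return archive
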