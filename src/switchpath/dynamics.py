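"""Overdamped Brownian dynamics of bead models and progress coordinates.

Trajectories are advanced in fixed-length segments of duration τ (the
weighted-ensemble resampling interval), with configurations stored every
``sample_interval``.  The propagator is the inertialess Euler–Maruyama
scheme

    x <- x + (D Δt / k_BT) F(x) + ξ,   ξ ~ N(0, 2 D Δt) per coordinate,

with identical per-bead diffusion coefficient D.  Stability is guarded by a
per-step displacement sanity bound rather than claimed a priori.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import _kernels
from .errors import (ConfigurationError, NonFiniteEnergyError, TimestepError,
                     UndefinedSuperpositionError)
from .model import AFFModel
from .superpose import superposed_rmsd
from .units import DEFAULT_TEMPERATURE_K, thermal_energy

__all__ = ["IntegratorConfig", "TrajectorySegment", "potential_energy",
           "forces", "brownian_step", "run_segment", "compute_progress",
           "GoPropagator"]


@dataclass(frozen=True)
class IntegratorConfig:
    """Brownian-dynamics settings.

    Defaults are the real-unit conventions (20 °C, τ = 100 ps, samples every
    50 ps); fixtures use ``units="reduced"`` with k_BT = 1.
    """

    timestep: float = 0.05            # ps (or reduced time)
    tau: float = 100.0                # segment length
    sample_interval: float = 50.0
    diffusion: float = 0.02           # Å^2 / time-unit, per bead
    temperature: float = DEFAULT_TEMPERATURE_K
    units: str = "real"
    store_initial: bool = False
    max_step: float = 2.0             # Å, per-bead per-step sanity bound
    rng_seed: int | None = None

    def __post_init__(self):
        if self.timestep <= 0:
            raise ConfigurationError("timestep must be positive")
        for name in ("tau", "sample_interval"):
            val = getattr(self, name)
            ratio = val / self.timestep
            if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
                raise ConfigurationError(
                    f"{name} must be a positive integer multiple of timestep")
        ratio = self.tau / self.sample_interval
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError(
                "tau must be an integer multiple of sample_interval")

    @property
    def kT(self) -> float:
        return thermal_energy(self.temperature, self.units)

    @property
    def n_steps(self) -> int:
        return int(round(self.tau / self.timestep))

    @property
    def sample_stride(self) -> int:
        return int(round(self.sample_interval / self.timestep))

    @property
    def n_samples(self) -> int:
        return int(round(self.tau / self.sample_interval))

    @property
    def drift_coefficient(self) -> float:
        return self.diffusion * self.timestep / self.kT

    @property
    def noise_scale(self) -> float:
        return float(np.sqrt(2.0 * self.diffusion * self.timestep))


@dataclass
class TrajectorySegment:
    """One propagated segment: stored frames, time offsets, end state."""

    frames: np.ndarray        # (k, n, 3) or (k,) for 1-D systems
    times: np.ndarray         # (k,) time offsets within the segment
    end_coords: np.ndarray
    rng_state_out: dict | None = None

    def __post_init__(self):
        if len(self.times) != len(self.frames):
            raise ConfigurationError("frames and times must align")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ConfigurationError("times must be strictly increasing")


def _kernel_args(model: AFFModel) -> tuple:
    p = model.packed()
    return (p["bond_idx"], p["bond_r0"], p["bond_k"],
            p["angle_idx"], p["angle_theta0"], p["angle_k"],
            p["dih_idx"], p["dih_phi0"], p["dih_k1"], p["dih_k3"],
            p["con_i"], p["con_j"], p["con_r0"], p["con_eps"],
            p["ev_idx"], p["ev_eps"], p["ev_sigma"], p["r_floor"])


def potential_energy(model: AFFModel, coords: np.ndarray) -> float:
    """Total potential energy (bonded + native contacts + excluded volume)."""
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    if coords.shape != (model.n_beads, 3) or not np.all(np.isfinite(coords)):
        raise ConfigurationError("coords must be finite (n_beads, 3)")
    f = np.empty_like(coords)
    e = _kernels.forces_energy(coords, *_kernel_args(model), f)
    if not np.isfinite(e):
        raise NonFiniteEnergyError("bead overlap below the hard floor")
    return float(e)


def forces(model: AFFModel, coords: np.ndarray) -> np.ndarray:
    """Forces, the exact negative gradient of ``potential_energy``."""
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    if coords.shape != (model.n_beads, 3) or not np.all(np.isfinite(coords)):
        raise ConfigurationError("coords must be finite (n_beads, 3)")
    f = np.empty_like(coords)
    e = _kernels.forces_energy(coords, *_kernel_args(model), f)
    if not np.isfinite(e):
        raise NonFiniteEnergyError("bead overlap below the hard floor")
    return f


def brownian_step(coords: np.ndarray, force: np.ndarray,
                  config: IntegratorConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """One overdamped Euler–Maruyama step (bitwise reproducible per rng)."""
    disp = config.drift_coefficient * np.asarray(force, dtype=float) \
        + config.noise_scale * rng.standard_normal(np.shape(coords))
    step_norm = np.linalg.norm(np.atleast_2d(disp), axis=-1)
    if np.any(step_norm > config.max_step):
        raise TimestepError(
            f"per-step displacement {step_norm.max():.3g} Å exceeds the "
            f"sanity bound {config.max_step} Å; reduce the timestep")
    return np.asarray(coords, dtype=float) + disp


def run_segment(model: AFFModel, start_coords: np.ndarray,
                config: IntegratorConfig,
                rng: np.random.Generator) -> TrajectorySegment:
    """Propagate exactly τ of dynamics, storing samples every
    ``sample_interval``; the final sample coincides with the end state."""
    x = np.ascontiguousarray(start_coords, dtype=np.float64).copy()
    if x.shape != (model.n_beads, 3) or not np.all(np.isfinite(x)):
        raise ConfigurationError("start coords must be finite (n_beads, 3)")
    n_steps = config.n_steps
    noise = config.noise_scale * rng.standard_normal((n_steps, model.n_beads, 3))
    samples = np.empty((config.n_samples, model.n_beads, 3))
    f = np.empty_like(x)
    status = _kernels.bd_segment(
        x, n_steps, config.drift_coefficient, noise, config.sample_stride,
        config.max_step, *_kernel_args(model), f, samples)
    if status == _kernels.STATUS_NONFINITE:
        raise NonFiniteEnergyError("bead overlap during propagation")
    if status == _kernels.STATUS_BLOWUP:
        raise TimestepError(
            f"per-step displacement exceeded {config.max_step} Å; "
            "reduce the timestep")
    times = config.sample_interval * np.arange(1, config.n_samples + 1)
    frames = samples
    if config.store_initial:
        frames = np.concatenate([start_coords[None], samples], axis=0)
        times = np.concatenate([[0.0], times])
    return TrajectorySegment(frames=frames, times=times, end_coords=x,
                             rng_state_out=rng.bit_generator.state)


def compute_progress(model: AFFModel, coords: np.ndarray) -> np.ndarray:
    """Progress coordinate: minimized Cα RMSD of each frame from its folded
    reference — (rmsd_N, rmsd_N') for dual-frame models, (rmsd_N,) else."""
    coords = np.asarray(coords, dtype=float)
    idx_n = model.frame_N_index0
    if len(idx_n) < 3:
        raise UndefinedSuperpositionError("N frame has fewer than 3 residues")
    out = [superposed_rmsd(coords[idx_n], model.ref_frame_N)]
    if model.has_nprime:
        idx_np = model.frame_Nprime_index0
        if len(idx_np) < 3:
            raise UndefinedSuperpositionError(
                "N' frame has fewer than 3 residues")
        out.append(superposed_rmsd(coords[idx_np], model.ref_frame_Nprime))
    return np.asarray(out)


def contact_fractions(model: AFFModel, coords: np.ndarray,
                      formation_factor: float = 1.2,
                      approach_factor: float | None = None) -> np.ndarray:
    """Fraction of each frame's native contacts formed (Q_N, Q_N').

    A smoother companion to the RMSD progress coordinate: each broken
    contact moves Q by one quantum, which makes it a natural ladder for
    WE binning of folding/docking transitions.  With ``approach_factor``
    set (> formation_factor), pairs within that looser radius earn half
    credit, so mere approach of an undocked segment already climbs the
    ladder — useful for binning diffusive docking searches.
    """
    coords = np.asarray(coords, dtype=float)
    cm = model.contacts
    d = np.linalg.norm(coords[cm.i - 1] - coords[cm.j - 1], axis=1)
    if approach_factor is None:
        formed = (d <= formation_factor * cm.r0).astype(float)
    else:
        formed = 0.5 * (d <= formation_factor * cm.r0) \
            + 0.5 * (d <= approach_factor * cm.r0)
    out = []
    for tags in (("N", "shared"), ("Nprime", "shared")):
        sel = np.isin(cm.frame_tag, tags)
        if sel.any():
            out.append(formed[sel].mean())
        elif tags[0] == "N":
            out.append(0.0)
    return np.asarray(out[:model.progress_dim])


class GoPropagator:
    """Propagator contract used by the WE engine for bead models."""

    def __init__(self, model: AFFModel, config: IntegratorConfig):
        self.model = model
        self.config = config

    @property
    def tau(self) -> float:
        return self.config.tau

    @property
    def ndim(self) -> int:
        return self.model.progress_dim

    def propagate(self, coords: np.ndarray,
                  rng: np.random.Generator) -> TrajectorySegment:
        return run_segment(self.model, coords, self.config, rng)

    def progress(self, coords: np.ndarray) -> np.ndarray:
        return compute_progress(self.model, coords)

    def contact_fractions(self, coords: np.ndarray) -> np.ndarray:
        return contact_fractions(self.model, coords)

    def propagate_many(self, coords_list, rng: np.random.Generator,
                       store_samples: bool = False):
        """Propagate a batch of walkers with one noise draw.

        Returns (ends, samples) where samples is None unless requested.
        Equivalent to calling :meth:`propagate` per walker; used by the WE
        engine to amortize per-segment overhead.
        """
        cfg = self.config
        m = len(coords_list)
        n = self.model.n_beads
        n_steps = cfg.n_steps
        noise = cfg.noise_scale * rng.standard_normal((m, n_steps, n, 3))
        args = _kernel_args(self.model)
        ends = np.empty((m, n, 3))
        samples = (np.empty((m, cfg.n_samples, n, 3))
                   if store_samples else None)
        buf = np.empty((cfg.n_samples, n, 3))
        f = np.empty((n, 3))
        for k in range(m):
            x = np.ascontiguousarray(coords_list[k], dtype=np.float64).copy()
            status = _kernels.bd_segment(
                x, n_steps, cfg.drift_coefficient, noise[k],
                cfg.sample_stride, cfg.max_step, *args, f,
                samples[k] if store_samples else buf)
            if status == _kernels.STATUS_NONFINITE:
                raise NonFiniteEnergyError("bead overlap during propagation")
            if status == _kernels.STATUS_BLOWUP:
                raise TimestepError(
                    f"per-step displacement exceeded {cfg.max_step} Å; "
                    "reduce the timestep")
            ends[k] = x
        return ends, samples
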