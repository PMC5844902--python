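"""Free-energy surfaces, transition-path ensembles and the design screen.

The design screen ranks candidate mutation sites by how much less a
residue packs in the transition path ensemble (TPE) than in the relevant
ground state.  Because the model is native-centric, a residue's
contribution to the stability of an ensemble is its *contact score*: the
ensemble-averaged number of native contacts it forms.  Sites whose contact
scores drop most between ground state and TPE preferentially destabilize
the ground states when mutated, lowering the switching barrier in both
directions; a buried interface site whose score barely changes is the
negative control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, CorruptArchiveError,
                     UndefinedStateError)
from .kinetics import StateDefinition
from .model import AFFModel, ContactMap
from .units import DEFAULT_TEMPERATURE_K, thermal_energy
from .we import WEArchive

__all__ = ["ProbabilityField", "TransitionPath", "ContactScoreTable",
           "CandidateRanking", "free_energy_surface", "extract_tpe",
           "ensemble_frames", "contact_score", "contact_score_table",
           "rank_candidates"]


# ---------------------------------------------------------------------------
# Probability fields / free-energy surfaces
# ---------------------------------------------------------------------------

@dataclass
class ProbabilityField:
    """Normalized probability mass on a progress-coordinate grid, with the
    free energy G = -kT ln P defined where P > 0."""

    edges: tuple              # per-dimension bin edges
    P: np.ndarray
    G: np.ndarray
    ensemble_tag: str
    temperature: float = DEFAULT_TEMPERATURE_K
    units: str = "real"

    def __post_init__(self):
        if abs(float(self.P.sum()) - 1.0) > 1e-9:
            raise ConfigurationError("probability field must sum to 1")

    def mode_cell(self) -> tuple:
        return np.unravel_index(int(np.argmax(self.P)), self.P.shape)

    def axis_histogram(self, axis: int = 0) -> tuple:
        """Marginal histogram along one axis: (values, edges)."""
        other = tuple(d for d in range(self.P.ndim) if d != axis)
        return self.P.sum(axis=other) if other else self.P, self.edges[axis]


def _progress_histogram(archive: WEArchive, edges, burn_in_fraction):
    t0 = archive.burn_in_start(burn_in_fraction)
    its = archive.iterations[t0:]
    shape = tuple(len(e) - 1 for e in edges)
    acc = np.zeros(shape)
    for it in its:
        if it.sample_progress is not None:
            m, k, d = it.sample_progress.shape
            pts = it.sample_progress.reshape(m * k, d)
            wts = np.repeat(it.weights / k, k)
        else:
            pts = it.end_progress
            wts = it.weights
        hist, _ = np.histogramdd(pts, bins=edges, weights=wts)
        acc += hist
    total = acc.sum()
    if total <= 0:
        raise UndefinedStateError("no probability mass inside the grid")
    return acc / total


def free_energy_surface(archives, edges, ensemble_tag: str = "equilibrium",
                        temperature: float = DEFAULT_TEMPERATURE_K,
                        units: str = "real",
                        burn_in_fraction: float = 0.1) -> ProbabilityField:
    """Accumulate walker weights into grid cells and convert to -kT ln P.

    Multiple archives are pooled by averaging their normalized fields.
    """
    if not isinstance(archives, (list, tuple)):
        archives = [archives]
    if not archives:
        raise ConfigurationError("no archives supplied")
    edges = tuple(np.asarray(e, dtype=float) for e in edges)
    fields = [_progress_histogram(a, edges, burn_in_fraction)
              for a in archives]
    P = np.mean(fields, axis=0)
    P = P / P.sum()
    kT = thermal_energy(temperature, units)
    with np.errstate(divide="ignore"):
        G = np.where(P > 0, -kT * np.log(np.where(P > 0, P, 1.0)), np.nan)
    return ProbabilityField(edges=edges, P=P, G=G, ensemble_tag=ensemble_tag,
                            temperature=temperature, units=units)


def tpe_probability_field(paths, edges,
                          temperature: float = DEFAULT_TEMPERATURE_K,
                          units: str = "real") -> ProbabilityField:
    """Probability field of a transition-path ensemble: each path's weight
    is spread uniformly over its frames."""
    if not paths:
        raise ConfigurationError("empty transition-path ensemble")
    edges = tuple(np.asarray(e, dtype=float) for e in edges)
    shape = tuple(len(e) - 1 for e in edges)
    acc = np.zeros(shape)
    for path in paths:
        w = path.weight / len(path.progress)
        hist, _ = np.histogramdd(path.progress, bins=edges,
                                 weights=np.full(len(path.progress), w))
        acc += hist
    total = acc.sum()
    if total <= 0:
        raise UndefinedStateError("no TPE mass inside the grid")
    P = acc / total
    kT = thermal_energy(temperature, units)
    with np.errstate(divide="ignore"):
        G = np.where(P > 0, -kT * np.log(np.where(P > 0, P, 1.0)), np.nan)
    return ProbabilityField(edges=edges, P=P, G=G,
                            ensemble_tag="TPE-steady-state",
                            temperature=temperature, units=units)


# ---------------------------------------------------------------------------
# Transition-path extraction
# ---------------------------------------------------------------------------

@dataclass
class TransitionPath:
    """One productive switching pathway.

    Frames run from the first configuration after the trajectory last
    exited the initial state through the first configuration inside the
    target state; no intermediate frame lies in either state.
    """

    frames: np.ndarray        # (F, ...) coordinates
    progress: np.ndarray      # (F, d)
    weight: float
    origin: str
    destination: str
    duration: float
    iteration_span: tuple
    event_id: int


def _segment_frames(archive: WEArchive, t: int, rec: int):
    """Sampled frames and progress of one segment, oldest first."""
    it = archive.iterations[t]
    if it.samples is None or it.sample_progress is None:
        raise CorruptArchiveError(
            "archive was run without sample storage; TPE unavailable")
    return it.samples[rec], it.sample_progress[rec]


def extract_tpe(archive: WEArchive, state_i: StateDefinition,
                state_j: StateDefinition) -> list:
    """Reconstruct the transition path ensemble through walker lineage.

    For every recycling event into the target state the lineage is walked
    backward to the last frame inside the initial state; the segment after
    that frame through the first entry into the target is emitted with the
    recycled walker's weight.  Unproductive excursions are excluded by
    construction.  Events whose lineage begins outside the initial state
    (e.g. the run's very first iterations) are skipped.
    """
    archive.validate_lineage()
    paths = []
    event_id = 0
    for t, it in enumerate(archive.iterations):
        for rec in np.where(it.recycled)[0]:
            chain = []      # list of (iteration, frames, progress)
            ti, ri = t, int(rec)
            resolved = True
            while True:
                frames, prog = _segment_frames(archive, ti, ri)
                chain.append((ti, frames, prog))
                if state_i.contains_many(prog).any():
                    break
                parent = int(archive.iterations[ti].parents[ri])
                if ti == 0:
                    # lineage root: initial walker
                    p0 = archive.initial_progress[parent]
                    chain.append((-1,
                                  archive.initial_coords[parent][None],
                                  p0[None]))
                    if not state_i.contains(p0):
                        resolved = False
                    break
                prev = archive.iterations[ti - 1]
                if prev.recycled[parent]:
                    # trajectory began fresh from the initial state here
                    c0 = prev.restart_coords[parent]
                    p0 = np.atleast_1d(prev.end_progress[parent]) * np.nan
                    # restart coordinates are in state i by construction;
                    # synthesize their progress from the stored next segment
                    chain.append((ti - 1, np.asarray(c0)[None],
                                  None))
                    break
                ti, ri = ti - 1, parent
                if len(chain) > archive.n_iterations + 2:
                    raise CorruptArchiveError(
                        f"lineage loop detected at iteration {t}")
            if not resolved:
                continue
            # assemble frames oldest-first
            chain.reverse()
            all_frames, all_prog, markers = [], [], []
            for _, frames, prog in chain:
                if prog is None:
                    # fresh restart point: inside state i by construction
                    all_frames.append(frames[0])
                    all_prog.append(None)
                    continue
                for f, p in zip(frames, prog):
                    all_frames.append(f)
                    all_prog.append(p)
            in_i = np.array([True if p is None else state_i.contains(p)
                             for p in all_prog])
            in_j = np.array([False if p is None else state_j.contains(p)
                             for p in all_prog])
            if not in_i.any():
                continue
            last_i = int(np.where(in_i)[0][-1])
            after_j = np.where(in_j[last_i + 1:])[0]
            if len(after_j) == 0:
                continue
            first_j = last_i + 1 + int(after_j[0])
            frames = np.asarray(all_frames[last_i + 1:first_j + 1])
            prog = np.asarray([np.atleast_1d(p)
                               for p in all_prog[last_i + 1:first_j + 1]])
            paths.append(TransitionPath(
                frames=frames, progress=prog,
                weight=float(it.weights[rec]),
                origin=state_i.state_id, destination=state_j.state_id,
                duration=len(frames) * archive.sample_interval,
                iteration_span=(chain[0][0], t), event_id=event_id))
            event_id += 1
    return paths


# ---------------------------------------------------------------------------
# Contact scores
# ---------------------------------------------------------------------------

def ensemble_frames(archive: WEArchive, state: StateDefinition | None = None,
                    burn_in_fraction: float = 0.1) -> tuple:
    """Pooled sampled frames (and weights) of an archive, optionally
    restricted to frames inside ``state``."""
    t0 = archive.burn_in_start(burn_in_fraction)
    frames, weights = [], []
    for it in archive.iterations[t0:]:
        if it.samples is None:
            raise CorruptArchiveError("archive stores no frames")
        m, k = it.samples.shape[:2]
        for rec in range(m):
            for s in range(k):
                p = it.sample_progress[rec, s]
                if state is None or state.contains(p):
                    frames.append(it.samples[rec, s])
                    weights.append(it.weights[rec] / k)
    if not frames:
        raise UndefinedStateError("no frames in the requested ensemble")
    return np.asarray(frames), np.asarray(weights)


def contact_score(frames: np.ndarray, weights: np.ndarray,
                  contacts: ContactMap, n_residues: int,
                  formation_factor: float = 1.2) -> np.ndarray:
    """Weighted mean number of native contacts formed per residue.

    A contact is formed when its pair distance is at most
    ``formation_factor`` times the native distance.
    """
    frames = np.asarray(frames, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if frames.ndim != 3 or len(frames) != len(weights):
        raise ConfigurationError("frames must be (F, n, 3) aligned to weights")
    if np.any(weights <= 0):
        raise ConfigurationError("frame weights must be positive")
    if len(contacts) and contacts.j.max() > frames.shape[1]:
        raise ConfigurationError(
            "contact references residues absent from the frames")
    if frames.shape[1] < n_residues:
        raise ConfigurationError("frames shorter than the residue count")
    wsum = weights.sum()
    scores = np.zeros(n_residues)
    if not len(contacts):
        return scores
    d = np.linalg.norm(frames[:, contacts.i - 1, :]
                       - frames[:, contacts.j - 1, :], axis=-1)
    formed = (d <= formation_factor * contacts.r0).astype(float)  # (F, C)
    mean_formed = weights @ formed / wsum                         # (C,)
    np.add.at(scores, contacts.i - 1, mean_formed)
    np.add.at(scores, contacts.j - 1, mean_formed)
    return scores


@dataclass
class ContactScoreTable:
    """Per-residue contact scores per ensemble with cross-run s.e.m."""

    table: pd.DataFrame       # residue-indexed; score_*/sem_* columns

    def column(self, name: str) -> np.ndarray:
        return self.table[f"score_{name}"].to_numpy()

    def difference(self, ground: str, tpe: str) -> np.ndarray:
        """Ground-state column minus TPE column."""
        return self.column(ground) - self.column(tpe)


def contact_score_table(ensembles: dict, contacts: ContactMap,
                        n_residues: int,
                        formation_factor: float = 1.2) -> ContactScoreTable:
    """Build the score table.

    ``ensembles`` maps a column name (e.g. "N", "Nprime", "TPE_fwd",
    "TPE_rev") to a list of (frames, weights) tuples, one per independent
    simulation; per-simulation means feed the cross-simulation s.e.m.
    """
    if not ensembles:
        raise ConfigurationError("no ensembles supplied")
    data = {"residue": np.arange(1, n_residues + 1)}
    for name, runs in ensembles.items():
        if not runs:
            raise ConfigurationError(f"ensemble {name!r} has no runs")
        per_run = np.stack([
            contact_score(fr, w, contacts, n_residues, formation_factor)
            for fr, w in runs])
        data[f"score_{name}"] = per_run.mean(axis=0)
        data[f"sem_{name}"] = (per_run.std(axis=0, ddof=1)
                               / np.sqrt(len(runs))
                               if len(runs) > 1 else np.zeros(n_residues))
    df = pd.DataFrame(data).set_index("residue")
    return ContactScoreTable(table=df)


# ---------------------------------------------------------------------------
# Candidate ranking (the design screen)
# ---------------------------------------------------------------------------

@dataclass
class CandidateRanking:
    """Ranked mutation sites with exclusion flags and the negative control.

    Sites are wild-type residue positions; in a dual-frame construct a
    site aggregates a residue and its duplicate-copy twin, mirroring the
    practice of mutating both copies at once.
    """

    table: pd.DataFrame
    negative_control: int

    @property
    def candidates(self) -> list:
        ok = self.table[~self.table["excluded"]]
        return ok.index.tolist()


def rank_candidates(scores: ContactScoreTable,
                    binding_site_residues: Iterable[int],
                    interface_residues: Iterable[int],
                    topology=None,
                    stabilities: dict | None = None,
                    stability_floor: float | None = None,
                    contacts: ContactMap | None = None,
                    ground_fwd: str = "N", tpe_fwd: str = "TPE_fwd",
                    ground_rev: str = "Nprime", tpe_rev: str = "TPE_rev",
                    ) -> CandidateRanking:
    """Rank mutation sites by ground-minus-TPE contact-score differences.

    Sites are ordered by the sum of the two direction-normalized score
    differences (largest first; ties broken by residue index).  Sites in or
    adjacent to the binding-site list, or whose mutant ΔG_fold exceeds the
    stability floor, are flagged and excluded from the candidate list.  The
    negative control is the buried interface site (contact degree at least
    the median over the interface set) with the smallest combined change.
    """
    df = scores.table
    if df.empty:
        raise ConfigurationError("empty score table")
    n = len(df)
    diff_fwd = scores.difference(ground_fwd, tpe_fwd)
    diff_rev = scores.difference(ground_rev, tpe_rev)

    # aggregate construct residues into mutation sites
    if topology is not None and topology.duplicated_range is not None:
        site_of = {}
        for res in df.index:
            twin = topology.twin(res)
            if res <= topology.duplicate_length and twin is not None:
                site_of[res] = twin          # duplicate copy -> WT position
            else:
                site_of[res] = res
    else:
        site_of = {res: res for res in df.index}
    sites = sorted(set(site_of.values()))
    s_index = {s: k for k, s in enumerate(sites)}
    agg_fwd = np.zeros(len(sites))
    agg_rev = np.zeros(len(sites))
    for res in df.index:
        k = s_index[site_of[res]]
        agg_fwd[k] += diff_fwd[res - 1]
        agg_rev[k] += diff_rev[res - 1]

    def _norm(v: np.ndarray) -> np.ndarray:
        top = v.max()
        return v / top if top > 0 else np.zeros_like(v)

    combined = _norm(agg_fwd) + _norm(agg_rev)

    binding = set(int(r) for r in binding_site_residues)
    adjacent = binding | {r + 1 for r in binding} | {r - 1 for r in binding}
    near_binding = np.array([s in adjacent for s in sites])
    unstable = np.zeros(len(sites), dtype=bool)
    if stabilities is not None and stability_floor is not None:
        for s, dg in stabilities.items():
            if s in s_index and dg > stability_floor:
                unstable[s_index[s]] = True
    excluded = near_binding | unstable

    out = pd.DataFrame({
        "site": sites,
        "diff_fwd": agg_fwd,
        "diff_rev": agg_rev,
        "combined": combined,
        "near_binding_site": near_binding,
        "below_stability_floor": unstable,
        "excluded": excluded,
    }).set_index("site")
    out = out.sort_values(["combined", "site"],
                          ascending=[False, True], kind="stable")

    interface = sorted(set(int(r) for r in interface_residues))
    if not interface:
        raise ConfigurationError("interface residue set is empty")
    iface_sites = sorted({site_of.get(r, r) for r in interface})
    if contacts is not None:
        deg = contacts.degree(n)
        site_deg = {}
        for res in df.index:
            site_deg[site_of[res]] = site_deg.get(site_of[res], 0) \
                + int(deg[res - 1])
        degrees = np.array([site_deg.get(s, 0) for s in iface_sites])
        buried = [s for s, d in zip(iface_sites, degrees)
                  if d >= np.median(degrees)]
    else:
        buried = iface_sites
    control = min(buried,
                  key=lambda s: (abs(combined[s_index[s]]), s))
    return CandidateRanking(table=out, negative_control=int(control))
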