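"""HDF5 persistence for models and WE archives; TSV exports.

Model archives hold /topology, /beads, /contacts, /bonded and /provenance
(with a config hash); iteration archives hold one group per WE iteration.
All datasets are written with ``track_times=False`` so identical runs
produce identical files.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .errors import CorruptArchiveError
from .kinetics import StateDefinition
from .model import (AFFModel, AFFTopology, BeadStructure, BondedTerms,
                    ContactMap, ForceFieldParams, LigandBias, MutationSpec)
from .we import WEArchive, WEIteration

__all__ = ["save_model", "load_model", "contacts_to_tsv", "save_archive",
           "load_archive", "scores_to_tsv", "ranking_to_tsv",
           "tpe_index_to_tsv", "config_hash"]


def config_hash(payload: dict) -> str:
    """Stable hash of a configuration mapping."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write(group, name, data):
    group.create_dataset(name, data=data, track_times=False)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def save_model(model: AFFModel, path: str) -> None:
    import h5py

    with h5py.File(path, "w", track_order=True) as f:
        topo = f.create_group("topology")
        t = model.topology
        topo.attrs["wt_length"] = t.wt_length
        topo.attrs["linker_length"] = t.linker_length
        topo.attrs["total_length"] = t.total_length
        topo.attrs["duplicated_range"] = (
            list(t.duplicated_range) if t.duplicated_range else [0, -1])
        _write(topo, "frame_N_residues", t.frame_N_residues)
        _write(topo, "frame_Nprime_residues", t.frame_Nprime_residues)
        _write(topo, "shared_residues", t.shared_residues)

        beads = f.create_group("beads")
        _write(beads, "residue_index", model.beads.residue_index)
        _write(beads, "residue_name",
               np.array(model.beads.residue_name, dtype="S4"))
        _write(beads, "coords", model.beads.coords)

        con = f.create_group("contacts")
        for name in ("i", "j", "r0", "eps"):
            _write(con, name, getattr(model.contacts, name))
        _write(con, "frame_tag",
               model.contacts.frame_tag.astype("S6"))

        bonded = f.create_group("bonded")
        for name in ("bond_idx", "bond_r0", "bond_k", "angle_idx",
                     "angle_theta0", "angle_k", "dih_idx", "dih_phi0",
                     "dih_k1", "dih_k3"):
            _write(bonded, name, getattr(model.bonded, name))

        refs = f.create_group("references")
        _write(refs, "ref_frame_N", model.ref_frame_N)
        _write(refs, "native_coords_N", model.native_coords_N)
        if model.ref_frame_Nprime is not None:
            _write(refs, "ref_frame_Nprime", model.ref_frame_Nprime)
            _write(refs, "native_coords_Nprime", model.native_coords_Nprime)

        prov = f.create_group("provenance")
        ff = {k: getattr(model.ff, k) for k in (
            "k_bond", "k_angle", "k_dihedral_1", "k_dihedral_3",
            "ev_eps", "ev_sigma", "r_floor")}
        prov.attrs["ff"] = json.dumps(ff)
        prov.attrs["eps"] = model.eps
        prov.attrs["mutations"] = json.dumps(
            [[m.residue_index, m.label, m.mode] for m in model.mutations])
        if model.ligand_bias is not None:
            prov.attrs["ligand_bias"] = json.dumps(
                [model.ligand_bias.frame, model.ligand_bias.strength_scale,
                 [list(p) for p in model.ligand_bias.affected_pairs]])
        prov.attrs["package_version"] = _pkg_version
        prov.attrs["config_hash"] = config_hash(
            {"ff": ff, "eps": model.eps,
             "n_contacts": len(model.contacts),
             "total_length": t.total_length})


def load_model(path: str) -> AFFModel:
    import h5py

    with h5py.File(path, "r") as f:
        topo = f["topology"]
        dr = list(topo.attrs["duplicated_range"])
        duplicated_range = None if dr[1] < dr[0] else (int(dr[0]), int(dr[1]))
        topology = AFFTopology(
            wt_length=int(topo.attrs["wt_length"]),
            duplicated_range=duplicated_range,
            linker_length=int(topo.attrs["linker_length"]),
            total_length=int(topo.attrs["total_length"]),
            frame_N_residues=topo["frame_N_residues"][()],
            frame_Nprime_residues=topo["frame_Nprime_residues"][()],
            shared_residues=topo["shared_residues"][()])
        beads = BeadStructure(
            residue_index=f["beads/residue_index"][()],
            residue_name=tuple(s.decode() for s in f["beads/residue_name"]),
            coords=f["beads/coords"][()])
        contacts = ContactMap(
            i=f["contacts/i"][()], j=f["contacts/j"][()],
            r0=f["contacts/r0"][()], eps=f["contacts/eps"][()],
            frame_tag=np.array([s.decode() for s in f["contacts/frame_tag"]],
                               dtype="U6"))
        bonded = BondedTerms(**{k: f[f"bonded/{k}"][()] for k in (
            "bond_idx", "bond_r0", "bond_k", "angle_idx", "angle_theta0",
            "angle_k", "dih_idx", "dih_phi0", "dih_k1", "dih_k3")})
        prov = f["provenance"]
        ff = ForceFieldParams(**json.loads(prov.attrs["ff"]))
        mutations = tuple(MutationSpec(int(r), label=l, mode=mo)
                          for r, l, mo in json.loads(prov.attrs["mutations"]))
        bias = None
        if "ligand_bias" in prov.attrs:
            frame, scale, pairs = json.loads(prov.attrs["ligand_bias"])
            bias = LigandBias(frame=frame, strength_scale=scale,
                              affected_pairs=tuple(tuple(p) for p in pairs))
        refs = f["references"]
        return AFFModel(
            topology=topology, beads=beads, contacts=contacts,
            bonded=bonded, ff=ff, eps=float(prov.attrs["eps"]),
            ref_frame_N=refs["ref_frame_N"][()],
            ref_frame_Nprime=(refs["ref_frame_Nprime"][()]
                              if "ref_frame_Nprime" in refs else None),
            native_coords_N=refs["native_coords_N"][()],
            native_coords_Nprime=(refs["native_coords_Nprime"][()]
                                  if "native_coords_Nprime" in refs else None),
            mutations=mutations, ligand_bias=bias)


def contacts_to_tsv(contacts: ContactMap, path: str) -> None:
    pd.DataFrame({"i": contacts.i, "j": contacts.j, "r0": contacts.r0,
                  "eps": contacts.eps, "frame_tag": contacts.frame_tag}
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# WE archives
# ---------------------------------------------------------------------------

def _state_to_attrs(group, name, state):
    if state is not None:
        group.attrs[f"{name}_id"] = state.state_id
        group.attrs[f"{name}_lower"] = list(state.lower)
        group.attrs[f"{name}_upper"] = list(state.upper)


def _state_from_attrs(group, name):
    if f"{name}_id" not in group.attrs:
        return None
    return StateDefinition(str(group.attrs[f"{name}_id"]),
                           tuple(group.attrs[f"{name}_lower"]),
                           tuple(group.attrs[f"{name}_upper"]))


def save_archive(archive: WEArchive, path: str) -> None:
    import h5py

    with h5py.File(path, "w", track_order=True) as f:
        meta = f.create_group("meta")
        for k in ("mode", "tau", "sample_interval", "seed",
                  "walkers_per_bin", "progress_dim"):
            meta.attrs[k] = getattr(archive, k)
        _state_to_attrs(meta, "state_i", archive.state_i)
        _state_to_attrs(meta, "state_j", archive.state_j)
        _write(f, "initial_coords", archive.initial_coords)
        _write(f, "initial_progress", archive.initial_progress)
        its = f.create_group("iterations")
        for it in archive.iterations:
            g = its.create_group(f"{it.index:06d}")
            g.attrs["recycled_flux"] = it.recycled_flux
            g.attrs["weight_error"] = it.weight_error
            for name in ("weights", "labels", "parents", "end_progress",
                         "recycled", "bin_index"):
                _write(g, name, getattr(it, name))
            for name in ("samples", "sample_progress", "end_coords"):
                val = getattr(it, name)
                if val is not None:
                    _write(g, name, val)
            if it.restart_coords:
                idx = sorted(it.restart_coords)
                _write(g, "restart_idx", np.array(idx, dtype=np.int32))
                _write(g, "restart_coords",
                       np.stack([it.restart_coords[k] for k in idx]))


def load_archive(path: str) -> WEArchive:
    import h5py

    with h5py.File(path, "r") as f:
        meta = f["meta"]
        archive = WEArchive(
            mode=str(meta.attrs["mode"]), tau=float(meta.attrs["tau"]),
            sample_interval=float(meta.attrs["sample_interval"]),
            seed=int(meta.attrs["seed"]),
            walkers_per_bin=int(meta.attrs["walkers_per_bin"]),
            progress_dim=int(meta.attrs["progress_dim"]),
            initial_coords=f["initial_coords"][()],
            initial_progress=f["initial_progress"][()],
            state_i=_state_from_attrs(meta, "state_i"),
            state_j=_state_from_attrs(meta, "state_j"))
        names = sorted(f["iterations"])
        for k, name in enumerate(names):
            if int(name) != k:
                raise CorruptArchiveError(f"missing iteration {k}")
            g = f["iterations"][name]
            restart = {}
            if "restart_idx" in g:
                for idx, c in zip(g["restart_idx"][()],
                                  g["restart_coords"][()]):
                    restart[int(idx)] = c
            archive.iterations.append(WEIteration(
                index=k, weights=g["weights"][()], labels=g["labels"][()],
                parents=g["parents"][()],
                end_progress=g["end_progress"][()],
                recycled=g["recycled"][()], bin_index=g["bin_index"][()],
                recycled_flux=float(g.attrs["recycled_flux"]),
                weight_error=float(g.attrs["weight_error"]),
                samples=g["samples"][()] if "samples" in g else None,
                sample_progress=(g["sample_progress"][()]
                                 if "sample_progress" in g else None),
                end_coords=g["end_coords"][()] if "end_coords" in g else None,
                restart_coords=restart))
    return archive


# ---------------------------------------------------------------------------
# Tabular exports
# ---------------------------------------------------------------------------

def scores_to_tsv(table, path: str) -> None:
    table.table.to_csv(path, sep="\t")


def ranking_to_tsv(ranking, path: str) -> None:
    df = ranking.table.copy()
    df["negative_control"] = df.index == ranking.negative_control
    df.to_csv(path, sep="\t")


def tpe_index_to_tsv(paths, path: str) -> None:
    pd.DataFrame({
        "event_id": [p.event_id for p in paths],
        "iteration_start": [p.iteration_span[0] for p in paths],
        "iteration_end": [p.iteration_span[1] for p in paths],
        "n_frames": [len(p.frames) for p in paths],
        "duration": [p.duration for p in paths],
        "weight": [p.weight for p in paths],
    }).to_csv(path, sep="\t", index=False)


def field_to_tsv(field, path: str) -> None:
    """Long-format TSV of a probability field (cell centers, P, G)."""
    centers = [0.5 * (e[:-1] + e[1:]) for e in field.edges]
    mesh = np.meshgrid(*centers, indexing="ij")
    data = {f"coord_{d}": m.ravel() for d, m in enumerate(mesh)}
    data["P"] = field.P.ravel()
    data["G"] = field.G.ravel()
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
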