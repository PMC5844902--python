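"""Cα bead models, native contact maps and dual-frame AFF topologies.

The force field is a standard Cα structure-based ("Gō-type") model: harmonic
bonds and angles, 1- and 3-fold periodic dihedrals, 12-10 Lennard-Jones-type
wells at the native pair distances for native contacts, and r^-12 excluded
volume between all other non-bonded pairs.  Only native contacts are
attractive, so removing a residue's attractive interactions is the idealized
maximum-underpacking model of a large-to-small substitution.

An alternate-frame-folding (AFF) construct fuses a protein with a circular
permutant of itself.  The construct sequence is

    duplicated C-terminal segment + linker + full wild-type sequence

so that two overlapping "frames" — N (the wild-type fold) and N' (the
circular-permutant fold) — compete for the shared segment and fold in a
mutually exclusive manner.  Mutual exclusivity needs no special term: the
two copies of the duplicated segment sterically exclude one another from
the shared-segment interface.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import (ChainGapError, ConfigurationError, ConstructionError,
                     MissingChainError)

__all__ = [
    "BeadStructure", "ContactMap", "AFFTopology", "AFFModel", "MutationSpec",
    "LigandBias", "ForceFieldParams", "BondedTerms", "load_structure",
    "structure_to_pdb", "compute_native_contacts", "build_aff_model",
    "build_two_state_model", "apply_mutation", "apply_ligand_bias",
    "binding_loop_bias",
]

#: Frame tags used in contact maps.
TAG_N = "N"
TAG_NPRIME = "Nprime"
TAG_SHARED = "shared"


# ---------------------------------------------------------------------------
# Bead structures and PDB I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadStructure:
    """One bead per residue at the Cα position.

    Residue indices are 1-based, strictly increasing and contiguous.
    """

    residue_index: np.ndarray          # (n,) int
    residue_name: tuple                # (n,) 3-letter codes
    coords: np.ndarray                 # (n, 3) float, Å

    def __post_init__(self):
        idx = np.asarray(self.residue_index, dtype=int)
        xyz = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "residue_index", idx)
        object.__setattr__(self, "coords", xyz)
        n = len(idx)
        if n < 4:
            raise ConfigurationError(f"chain has {n} residues; need >= 4")
        if xyz.shape != (n, 3) or not np.all(np.isfinite(xyz)):
            raise ConfigurationError("coordinates must be finite (n, 3)")
        if not np.array_equal(idx, np.arange(idx[0], idx[0] + n)):
            raise ConfigurationError(
                "residue indices must be strictly increasing and contiguous")

    @property
    def chain_length(self) -> int:
        return len(self.residue_index)


def load_structure(pdb_text: str, chain: str = "A") -> BeadStructure:
    """Extract one Cα bead per residue of ``chain`` from PDB-format text.

    Altlocs are resolved by highest occupancy then lexicographic label;
    residues are renumbered contiguously from 1 in file order.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(io.StringIO(pdb_text))
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    chains = sorted(set(atoms.chain_id))
    if chain not in chains:
        raise MissingChainError(
            f"chain {chain!r} not found; available chains: {chains}")
    sel = atoms[atoms.chain_id == chain]

    ca = sel[sel.atom_name == "CA"]
    ca_ids = set(zip(ca.res_id, ca.ins_code))
    # Residues (by id + insertion code, in file order) lacking a Cα atom.
    seen, order = set(), []
    for rid, icode in zip(sel.res_id, sel.ins_code):
        key = (int(rid), str(icode))
        if key not in seen:
            seen.add(key)
            order.append(key)
    missing = [key for key in order if key not in ca_ids]
    if missing:
        raise ChainGapError(
            "residues without a Cα atom in chain "
            f"{chain!r}: {[r for r, _ in missing]}")

    coords, names = [], []
    picked = set()
    for rid, icode in order:
        mask = (ca.res_id == rid) & (ca.ins_code == icode)
        idx = np.where(mask)[0][0]
        if (rid, icode) in picked:
            continue
        picked.add((rid, icode))
        coords.append(ca.coord[idx])
        names.append(str(ca.res_name[idx]))
    coords = np.asarray(coords, dtype=float)
    return BeadStructure(residue_index=np.arange(1, len(coords) + 1),
                         residue_name=tuple(names), coords=coords)


def structure_to_pdb(structure: BeadStructure, chain: str = "A") -> str:
    """Render a bead structure as PDB text (one Cα ATOM record per residue)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = structure.chain_length
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(structure.coords, dtype=np.float32)
    atoms.chain_id = np.full(n, chain)
    atoms.res_id = np.asarray(structure.residue_index)
    atoms.res_name = np.asarray(structure.residue_name)
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------

@dataclass
class ContactMap:
    """Native contact pairs (i < j, 1-based) with native distances and depths."""

    i: np.ndarray          # (m,) int
    j: np.ndarray          # (m,) int
    r0: np.ndarray         # (m,) float, Å
    eps: np.ndarray        # (m,) float, energy units
    frame_tag: np.ndarray  # (m,) str in {"N", "Nprime", "shared"}

    def __post_init__(self):
        self.i = np.asarray(self.i, dtype=int)
        self.j = np.asarray(self.j, dtype=int)
        self.r0 = np.asarray(self.r0, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        self.frame_tag = np.asarray(self.frame_tag, dtype="U6")
        m = len(self.i)
        for arr in (self.j, self.r0, self.eps, self.frame_tag):
            if len(arr) != m:
                raise ConfigurationError("contact map arrays must align")
        if m:
            if np.any(self.j <= self.i):
                raise ConfigurationError("contacts require j > i")
            if np.any(self.r0 <= 0) or np.any(self.eps < 0):
                raise ConfigurationError("require r0 > 0 and eps >= 0")
            if len({(a, b) for a, b in zip(self.i, self.j)}) != m:
                raise ConfigurationError("duplicate contact pairs")

    def __len__(self) -> int:
        return len(self.i)

    def involving(self, residue: int) -> np.ndarray:
        """Boolean mask of contacts involving ``residue``."""
        return (self.i == residue) | (self.j == residue)

    def degree(self, n_residues: int) -> np.ndarray:
        """Number of contacts per residue (index 0 holds residue 1)."""
        deg = np.zeros(n_residues, dtype=int)
        np.add.at(deg, self.i - 1, 1)
        np.add.at(deg, self.j - 1, 1)
        return deg

    def copy(self) -> "ContactMap":
        return ContactMap(self.i.copy(), self.j.copy(), self.r0.copy(),
                          self.eps.copy(), self.frame_tag.copy())


def compute_native_contacts(structure: BeadStructure, cutoff: float = 8.0,
                            min_separation: int = 3,
                            eps: float = 1.0) -> ContactMap:
    """Native contacts: pairs with |i - j| >= min_separation and Cα–Cα
    distance <= cutoff in the native structure.

    Well depths are set uniformly to ``eps`` pending calibration.
    """
    if cutoff <= 0:
        raise ConfigurationError("cutoff must be positive")
    xyz = structure.coords
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    n = structure.chain_length
    ii, jj = np.triu_indices(n, k=min_separation)
    keep = d[ii, jj] <= cutoff
    ii, jj = ii[keep], jj[keep]
    return ContactMap(i=ii + 1, j=jj + 1, r0=d[ii, jj],
                      eps=np.full(ii.shape, float(eps)),
                      frame_tag=np.full(ii.shape, TAG_N, dtype="U6"))


# ---------------------------------------------------------------------------
# Force-field parameters and bonded terms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForceFieldParams:
    """Bonded and excluded-volume constants, expressed relative to the
    uniform contact depth ε (the single calibration scalar).

    ``k_bond``/``k_angle``/``k_dihedral_*`` are multiplied by ε when a model
    is built, following the usual structure-based-model convention of
    scaling the whole surface with one energy unit.
    """

    k_bond: float = 100.0        # ε Å^-2
    k_angle: float = 20.0        # ε rad^-2
    k_dihedral_1: float = 1.0    # ε
    k_dihedral_3: float = 0.5    # ε
    ev_eps: float = 1.0          # ε
    ev_sigma: float = 4.0        # Å, excluded-volume diameter
    r_floor: float = 0.5         # Å, hard overlap floor (non-finite energy)


@dataclass
class BondedTerms:
    """Bond/angle/dihedral parameter lists (indices 0-based into beads)."""

    bond_idx: np.ndarray      # (nb, 2) int
    bond_r0: np.ndarray       # (nb,)
    bond_k: np.ndarray        # (nb,)
    angle_idx: np.ndarray     # (na, 3) int
    angle_theta0: np.ndarray  # (na,)
    angle_k: np.ndarray       # (na,)
    dih_idx: np.ndarray       # (nd, 4) int
    dih_phi0: np.ndarray      # (nd,)
    dih_k1: np.ndarray        # (nd,)
    dih_k3: np.ndarray        # (nd,)

    def copy(self) -> "BondedTerms":
        return BondedTerms(*(np.array(getattr(self, f)) for f in (
            "bond_idx", "bond_r0", "bond_k", "angle_idx", "angle_theta0",
            "angle_k", "dih_idx", "dih_phi0", "dih_k1", "dih_k3")))


def _dihedral_angle(x0, x1, x2, x3) -> float:
    b1 = x1 - x0
    b2 = x2 - x1
    b3 = x3 - x2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, n2)
    y = m1 @ b2 / np.linalg.norm(b2)
    x = n1 @ n2
    return float(np.arctan2(y, x))


def _bonded_from_reference(ref: np.ndarray, ff: ForceFieldParams,
                           eps: float) -> BondedTerms:
    """Bond/angle/dihedral native values measured on reference coordinates."""
    n = len(ref)
    bond_idx = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
    bond_r0 = np.linalg.norm(ref[1:] - ref[:-1], axis=1)
    angle_idx = np.stack([np.arange(n - 2), np.arange(1, n - 1),
                          np.arange(2, n)], axis=1)
    theta0 = np.empty(n - 2)
    for k in range(n - 2):
        u = ref[k] - ref[k + 1]
        v = ref[k + 2] - ref[k + 1]
        c = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
        theta0[k] = np.arccos(np.clip(c, -1.0, 1.0))
    dih_idx = np.stack([np.arange(n - 3), np.arange(1, n - 2),
                        np.arange(2, n - 1), np.arange(3, n)], axis=1)
    phi0 = np.array([_dihedral_angle(*ref[k:k + 4]) for k in range(n - 3)])
    return BondedTerms(
        bond_idx=bond_idx, bond_r0=bond_r0,
        bond_k=np.full(n - 1, ff.k_bond * eps),
        angle_idx=angle_idx, angle_theta0=theta0,
        angle_k=np.full(n - 2, ff.k_angle * eps),
        dih_idx=dih_idx, dih_phi0=phi0,
        dih_k1=np.full(n - 3, ff.k_dihedral_1 * eps),
        dih_k3=np.full(n - 3, ff.k_dihedral_3 * eps))


# ---------------------------------------------------------------------------
# AFF topology and model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AFFTopology:
    """Index bookkeeping of an AFF construct (all indices 1-based)."""

    wt_length: int
    duplicated_range: tuple | None      # inclusive (a, b) in WT numbering
    linker_length: int
    total_length: int
    frame_N_residues: np.ndarray        # construct indices of the N frame
    frame_Nprime_residues: np.ndarray   # construct indices of the N' frame
    shared_residues: np.ndarray         # construct indices shared by both

    def __post_init__(self):
        dup = 0 if self.duplicated_range is None else (
            self.duplicated_range[1] - self.duplicated_range[0] + 1)
        if self.total_length != self.wt_length + dup + self.linker_length:
            raise ConstructionError("construct length arithmetic violated")
        inter = np.intersect1d(self.frame_N_residues, self.frame_Nprime_residues)
        if not np.array_equal(inter, np.sort(self.shared_residues)):
            raise ConstructionError("frame intersection must equal shared set")

    @property
    def duplicate_length(self) -> int:
        if self.duplicated_range is None:
            return 0
        return self.duplicated_range[1] - self.duplicated_range[0] + 1

    @property
    def offset(self) -> int:
        """Construct index offset of the wild-type copy."""
        return self.duplicate_length + self.linker_length

    def wt_to_construct(self, wt_index: int) -> int:
        """Construct index of a wild-type residue (original copy)."""
        if not 1 <= wt_index <= self.wt_length:
            raise ConfigurationError(f"wild-type index {wt_index} out of range")
        return wt_index + self.offset

    def twin(self, construct_index: int) -> int | None:
        """Construct index of the duplicate copy of a residue, if any.

        Residues in the duplicated WT range and their N-terminal copies are
        twins; shared and linker residues have none.
        """
        if self.duplicated_range is None:
            return None
        a, b = self.duplicated_range
        if 1 <= construct_index <= self.duplicate_length:
            return construct_index + a - 1 + self.offset
        wt = construct_index - self.offset
        if a <= wt <= b:
            return wt - a + 1
        return None


@dataclass(frozen=True)
class MutationSpec:
    """An in-silico underpacking mutation: delete all attractive native
    interactions of the parent residue (excluded volume is retained)."""

    residue_index: int
    label: str = ""
    mode: str = "delete-attractive"

    def __post_init__(self):
        if self.mode != "delete-attractive":
            raise ConfigurationError(f"unsupported mutation mode {self.mode!r}")


@dataclass(frozen=True)
class LigandBias:
    """Ligand (e.g. Ca2+) binding modeled as uniform multiplicative
    strengthening of selected native contacts of the binding-competent
    frame; scale 1 reproduces the apo model exactly."""

    frame: str                       # "N" or "Nprime"
    strength_scale: float
    affected_pairs: tuple            # of (i, j) construct-index pairs

    def __post_init__(self):
        if self.frame not in (TAG_N, TAG_NPRIME):
            raise ConfigurationError("bias frame must be 'N' or 'Nprime'")
        if self.strength_scale < 1.0:
            raise ConfigurationError("strength_scale must be >= 1")


@dataclass
class AFFModel:
    """A dual-frame (or degenerate single-frame) Cα structure-based model."""

    topology: AFFTopology
    beads: BeadStructure                 # construct-length, reference coords
    contacts: ContactMap
    bonded: BondedTerms
    ff: ForceFieldParams
    eps: float                           # uniform contact depth ε
    ref_frame_N: np.ndarray              # folded reference of the N frame
    ref_frame_Nprime: np.ndarray | None  # folded reference of the N' frame
    native_coords_N: np.ndarray          # full construct, N folded
    native_coords_Nprime: np.ndarray | None
    mutations: tuple = ()
    ligand_bias: LigandBias | None = None
    _packed: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n = self.beads.chain_length
        if len(self.contacts) and (self.contacts.j.max() > n
                                   or self.contacts.i.min() < 1):
            raise ConstructionError("contact references an invalid bead index")
        shared = set(self.topology.shared_residues.tolist())
        mask = self.contacts.frame_tag == TAG_SHARED
        for a, b in zip(self.contacts.i[mask], self.contacts.j[mask]):
            if a not in shared or b not in shared:
                raise ConstructionError(
                    "shared-tagged contact outside the shared segment")
        if np.any(self.contacts.r0 < self.ff.r_floor):
            raise ConstructionError("native pair distance below overlap floor")

    @property
    def n_beads(self) -> int:
        return self.beads.chain_length

    @property
    def frame_N_index0(self) -> np.ndarray:
        return self.topology.frame_N_residues - 1

    @property
    def frame_Nprime_index0(self) -> np.ndarray:
        return self.topology.frame_Nprime_residues - 1

    @property
    def has_nprime(self) -> bool:
        return self.ref_frame_Nprime is not None and \
            len(self.topology.frame_Nprime_residues) > 0

    @property
    def progress_dim(self) -> int:
        return 2 if self.has_nprime else 1

    def effective_eps(self) -> np.ndarray:
        """Per-contact well depths after mutations and ligand bias."""
        eps = self.contacts.eps.copy()
        if self.ligand_bias is not None:
            pairs = {(a, b) for a, b in self.ligand_bias.affected_pairs}
            for k, (a, b) in enumerate(zip(self.contacts.i, self.contacts.j)):
                if (a, b) in pairs:
                    eps[k] *= self.ligand_bias.strength_scale
        return eps

    def packed(self) -> dict:
        """Arrays for the numba kernels (cached; rebuilt on modification)."""
        if self._packed is None:
            n = self.n_beads
            # pairs whose native well was deleted (mutations) fall back to
            # plain excluded volume
            eff = self.effective_eps()
            native = {(a, b) for a, b, e in zip(self.contacts.i - 1,
                                                self.contacts.j - 1, eff)
                      if e > 0}
            ev = [(a, b) for a in range(n) for b in range(a + 4, n)
                  if (a, b) not in native]
            ev_idx = (np.asarray(ev, dtype=np.int64).reshape(-1, 2)
                      if ev else np.empty((0, 2), dtype=np.int64))
            b = self.bonded
            self._packed = dict(
                bond_idx=b.bond_idx.astype(np.int64),
                bond_r0=b.bond_r0.astype(np.float64),
                bond_k=b.bond_k.astype(np.float64),
                angle_idx=b.angle_idx.astype(np.int64),
                angle_theta0=b.angle_theta0.astype(np.float64),
                angle_k=b.angle_k.astype(np.float64),
                dih_idx=b.dih_idx.astype(np.int64),
                dih_phi0=b.dih_phi0.astype(np.float64),
                dih_k1=b.dih_k1.astype(np.float64),
                dih_k3=b.dih_k3.astype(np.float64),
                con_i=(self.contacts.i - 1).astype(np.int64),
                con_j=(self.contacts.j - 1).astype(np.int64),
                con_r0=self.contacts.r0.astype(np.float64),
                con_eps=self.effective_eps().astype(np.float64),
                ev_idx=ev_idx,
                ev_eps=float(self.ff.ev_eps * self.eps),
                ev_sigma=float(self.ff.ev_sigma),
                r_floor=float(self.ff.r_floor),
            )
        return self._packed

    def replace(self, **kw) -> "AFFModel":
        kw.setdefault("_packed", None)
        kw.setdefault("contacts", self.contacts.copy())
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Construct assembly
# ---------------------------------------------------------------------------

def _extend_tail(anchor: np.ndarray, direction: np.ndarray, n: int,
                 spacing: float = 3.8) -> np.ndarray:
    """Place n beads in a gentle zigzag continuing from ``anchor``.

    Used for orphan segments and linkers whose geometry is not part of
    either folded reference; the zigzag avoids exactly collinear triples
    (which would leave angles/dihedrals undefined).
    """
    direction = direction / np.linalg.norm(direction)
    # any vector not parallel to direction
    probe = np.array([1.0, 0.0, 0.0])
    if abs(direction @ probe) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    perp = np.cross(direction, probe)
    perp /= np.linalg.norm(perp)
    wobble = 0.5
    axial = np.sqrt(spacing ** 2 - wobble ** 2)
    out = np.empty((n, 3))
    pos = anchor.astype(float).copy()
    for k in range(n):
        pos = pos + axial * direction + ((-1) ** k) * wobble * perp
        out[k] = pos
    return out


def build_aff_model(wt: BeadStructure, wt_contacts: ContactMap,
                    duplicated_range: tuple | None, linker_length: int,
                    ff: ForceFieldParams = ForceFieldParams(),
                    eps: float = 1.0) -> AFFModel:
    """Assemble the dual-frame AFF model from a wild-type bead structure.

    The N-frame contact set is the wild-type map on the original copy; the
    N'-frame set is the wild-type map remapped so that contacts involving
    the duplicated range use the N-terminal copy.  Contacts lying entirely
    inside the shared region appear once, tagged ``shared``, with identical
    parameters in both frames.
    """
    if linker_length < 0:
        raise ConfigurationError("linker_length must be >= 0")
    wt_n = wt.chain_length
    if duplicated_range is not None:
        a, b = duplicated_range
        if not (1 <= a <= b <= wt_n):
            raise ConstructionError(
                f"duplicated range {duplicated_range} outside 1..{wt_n}")
        dup = b - a + 1
    else:
        a = wt_n + 1
        dup = 0
        if linker_length:
            raise ConstructionError(
                "a linker without a duplicated segment is not a construct")
    off = dup + linker_length
    total = wt_n + off

    # --- index sets -------------------------------------------------------
    frame_N = np.arange(off + 1, off + wt_n + 1)
    shared = np.arange(off + 1, off + a)            # WT residues 1..a-1
    frame_Np = (np.concatenate([np.arange(1, dup + 1), shared])
                if dup else np.array([], dtype=int))
    topo = AFFTopology(wt_length=wt_n, duplicated_range=duplicated_range,
                       linker_length=linker_length, total_length=total,
                       frame_N_residues=frame_N,
                       frame_Nprime_residues=frame_Np,
                       shared_residues=shared if dup else np.array([], int))

    # --- contact remapping ------------------------------------------------
    ci, cj, cr0, ceps, ctag = [], [], [], [], []
    for i, j, r0, e in zip(wt_contacts.i, wt_contacts.j,
                           wt_contacts.r0, wt_contacts.eps):
        if j < a:        # entirely inside the shared region: counted once
            ci.append(i + off); cj.append(j + off); cr0.append(r0)
            ceps.append(e); ctag.append(TAG_SHARED if dup else TAG_N)
        else:
            ci.append(i + off); cj.append(j + off); cr0.append(r0)
            ceps.append(e); ctag.append(TAG_N)
    if dup:
        remap = lambda r: r - a + 1 if r >= a else r + off
        for i, j, r0, e in zip(wt_contacts.i, wt_contacts.j,
                               wt_contacts.r0, wt_contacts.eps):
            if j < a:
                continue                      # shared pair, already present
            p, q = sorted((remap(int(i)), remap(int(j))))
            ci.append(p); cj.append(q); cr0.append(r0)
            ceps.append(e); ctag.append(TAG_NPRIME)
    pair_list = list(zip(ci, cj))
    if len(set(pair_list)) != len(pair_list):
        raise ConstructionError("remapped contact indices overlap")
    contacts = ContactMap(i=np.array(ci, int), j=np.array(cj, int),
                          r0=np.array(cr0), eps=np.array(ceps, float),
                          frame_tag=np.array(ctag, dtype="U6"))

    # --- reference geometries --------------------------------------------
    wt_xyz = wt.coords
    centroid = wt_xyz.mean(axis=0)

    # N-folded construct: WT copy native; duplicate+linker dangle from WT 1.
    coords_N = np.empty((total, 3))
    coords_N[off:] = wt_xyz
    if off:
        away = wt_xyz[0] - centroid
        if np.linalg.norm(away) < 1e-6:
            away = np.array([0.0, 0.0, 1.0])
        tail = _extend_tail(wt_xyz[0], away, off)
        coords_N[:off] = tail[::-1]           # chain runs dup -> linker -> WT1

    coords_Np = None
    if dup:
        # N'-folded construct: duplicate copy occupies the WT a..b positions,
        # shared segment native, WT a..b copy dangles from WT residue a-1.
        coords_Np = np.empty((total, 3))
        coords_Np[:dup] = wt_xyz[a - 1:b]
        coords_Np[off:off + a - 1] = wt_xyz[:a - 1]
        if linker_length:
            # linker bridges duplicate end (WT b position) and WT residue 1
            start = wt_xyz[b - 1]
            stop = wt_xyz[0]
            ts = np.linspace(0, 1, linker_length + 2)[1:-1]
            bridge = start[None, :] + ts[:, None] * (stop - start)[None, :]
            perp = np.cross(stop - start, np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(stop - start, np.array([0.0, 1.0, 0.0]))
            perp = perp / np.linalg.norm(perp)
            bulge = perp * 2.0
            coords_Np[dup:off] = bridge + bulge
        anchor = wt_xyz[a - 2] if a >= 2 else wt_xyz[0]
        away = anchor - centroid
        if np.linalg.norm(away) < 1e-6:
            away = np.array([0.0, 0.0, 1.0])
        coords_Np[off + a - 1:] = _extend_tail(anchor, away, wt_n - a + 1)

    # --- bonded terms from a hybrid reference ----------------------------
    # Terms entirely within duplicate+linker+shared take native values from
    # the N' fold (the circular-permutant geometry); all others from the N
    # fold.  Terms inside the shared segment are identical either way.
    ref_for_bonded = coords_N.copy()
    bonded = _bonded_from_reference(ref_for_bonded, ff, eps)
    if dup:
        cut = off + a - 1  # last construct index (1-based) of the CP region
        bonded_np = _bonded_from_reference(coords_Np, ff, eps)
        for idx_name, vals in (("bond_idx", ("bond_r0",)),
                               ("angle_idx", ("angle_theta0",)),
                               ("dih_idx", ("dih_phi0",))):
            idx = getattr(bonded, idx_name)
            inside = idx.max(axis=1) < cut     # 0-based strict: max idx <= cut-1
            for v in vals:
                getattr(bonded, v)[inside] = getattr(bonded_np, v)[inside]

    beads = BeadStructure(
        residue_index=np.arange(1, total + 1),
        residue_name=tuple(["GLY"] * off) + tuple(wt.residue_name),
        coords=coords_N)
    ref_N = wt_xyz.copy()
    ref_Np = coords_Np[frame_Np - 1].copy() if dup else None
    return AFFModel(topology=topo, beads=beads, contacts=contacts,
                    bonded=bonded, ff=ff, eps=eps,
                    ref_frame_N=ref_N, ref_frame_Nprime=ref_Np,
                    native_coords_N=coords_N, native_coords_Nprime=coords_Np)


def build_two_state_model(structure: BeadStructure, eps: float = 1.0,
                          cutoff: float = 8.0, min_separation: int = 3,
                          ff: ForceFieldParams = ForceFieldParams()) -> AFFModel:
    """A plain (single-frame) two-state folder: the degenerate AFF case."""
    contacts = compute_native_contacts(structure, cutoff=cutoff,
                                       min_separation=min_separation, eps=eps)
    return build_aff_model(structure, contacts, duplicated_range=None,
                           linker_length=0, ff=ff, eps=eps)


# ---------------------------------------------------------------------------
# In-silico mutations and ligand bias
# ---------------------------------------------------------------------------

def apply_mutation(model: AFFModel, spec: MutationSpec) -> AFFModel:
    """Delete all attractive native interactions of the parent residue.

    Returns a new model; applying the same spec twice is idempotent.
    """
    if not 1 <= spec.residue_index <= model.n_beads:
        raise ConfigurationError(
            f"residue {spec.residue_index} not in construct "
            f"(1..{model.n_beads})")
    contacts = model.contacts.copy()
    contacts.eps[contacts.involving(spec.residue_index)] = 0.0
    muts = model.mutations if spec in model.mutations \
        else model.mutations + (spec,)
    return model.replace(contacts=contacts, mutations=muts)


def apply_ligand_bias(model: AFFModel, bias: LigandBias) -> AFFModel:
    """Scale the well depths of the bias's affected pairs.

    Every affected pair must be a contact carrying the stated frame's tag.
    """
    tags = {(a, b): t for a, b, t in zip(model.contacts.i, model.contacts.j,
                                         model.contacts.frame_tag)}
    frame_pairs = [p for p, t in tags.items() if t == bias.frame]
    if not frame_pairs:
        raise ConfigurationError(f"frame {bias.frame!r} has no contacts")
    for a, b in bias.affected_pairs:
        if tags.get((a, b)) != bias.frame:
            raise ConfigurationError(
                f"pair ({a}, {b}) is not a {bias.frame}-frame contact")
    return model.replace(ligand_bias=bias)


def binding_loop_bias(model: AFFModel, frame: str,
                      loop_residues: Iterable[int],
                      strength_scale: float) -> LigandBias:
    """Build a LigandBias covering the frame-tagged contacts that involve
    any residue of the binding loop (construct indices)."""
    loop = set(int(r) for r in loop_residues)
    pairs = [(int(a), int(b)) for a, b, t in
             zip(model.contacts.i, model.contacts.j, model.contacts.frame_tag)
             if t == frame and (a in loop or b in loop)]
    if not pairs:
        raise ConfigurationError(
            f"no {frame}-frame contacts involve residues {sorted(loop)}")
    return LigandBias(frame=frame, strength_scale=strength_scale,
                      affected_pairs=tuple(pairs))
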