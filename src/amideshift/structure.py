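"""Protein structures with explicit hydrogens: parsing, geometry, hydrogen bonds.

The model here is deliberately minimal: a flat table of atoms with positions,
plus derived views (backbone amide groups, aromatic rings, hydrogen bonds)
that the chemical-shift terms consume.  Structures must already carry their
amide hydrogens — no protonation is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

from .geometry import bond_angle, dihedral, plane_normal, rotation_about_axis

logger = logging.getLogger(__name__)

# Names accepted for the backbone amide hydrogen.
_AMIDE_H_NAMES = ("H", "HN")


class AcceptorClass(str, Enum):
    """Chemical class of a hydrogen-bond acceptor oxygen."""

    BACKBONE_AMIDE = "BACKBONE_AMIDE"
    SIDECHAIN_AMIDE = "SIDECHAIN_AMIDE"
    CARBOXYLATE = "CARBOXYLATE"
    ALCOHOL = "ALCOHOL"
    NONE = "NONE"


class MissingHydrogenError(ValueError):
    """Raised when a structure lacks explicit backbone amide hydrogens."""


# acceptor oxygen -> (class, name of the covalently bonded carbon)
# keyed by (residue name or '*', atom name)
_ACCEPTOR_MAP = {
    ("*", "O"): (AcceptorClass.BACKBONE_AMIDE, "C"),
    ("*", "OXT"): (AcceptorClass.CARBOXYLATE, "C"),
    ("SER", "OG"): (AcceptorClass.ALCOHOL, "CB"),
    ("THR", "OG1"): (AcceptorClass.ALCOHOL, "CB"),
    ("TYR", "OH"): (AcceptorClass.ALCOHOL, "CZ"),
    ("ASP", "OD1"): (AcceptorClass.CARBOXYLATE, "CG"),
    ("ASP", "OD2"): (AcceptorClass.CARBOXYLATE, "CG"),
    ("GLU", "OE1"): (AcceptorClass.CARBOXYLATE, "CD"),
    ("GLU", "OE2"): (AcceptorClass.CARBOXYLATE, "CD"),
    ("ASN", "OD1"): (AcceptorClass.SIDECHAIN_AMIDE, "CG"),
    ("GLN", "OE1"): (AcceptorClass.SIDECHAIN_AMIDE, "CD"),
}

_RING_SPECS = {
    "PHE": [("PHE6", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"])],
    "TYR": [("TYR6", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"])],
    "HIS": [("HIS5", ["CG", "ND1", "CD2", "CE1", "NE2"])],
    "TRP": [
        ("TRP5", ["CG", "CD1", "NE1", "CE2", "CD2"]),
        ("TRP6", ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]),
    ],
}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"} | set(_AMIDE_H_NAMES)


@dataclass
class Structure:
    """One conformer: parallel arrays of atom metadata plus an (n, 3) coordinate block."""

    names: list
    elements: list
    res_indices: np.ndarray
    res_names: list
    chains: list
    coords: np.ndarray
    model_index: int = 0
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.res_indices = np.asarray(self.res_indices, dtype=int)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atom coordinates")
        if self._index is None:
            self._rebuild_index()

    def _rebuild_index(self):
        self._index = {
            (c, int(r), n): i
            for i, (c, r, n) in enumerate(zip(self.chains, self.res_indices, self.names))
        }

    # -- lookups ------------------------------------------------------------
    def atom_index(self, chain: str, res_index: int, name: str) -> Optional[int]:
        return self._index.get((chain, int(res_index), name))

    def has_atom(self, chain: str, res_index: int, name: str) -> bool:
        return (chain, int(res_index), name) in self._index

    def position(self, chain: str, res_index: int, name: str) -> np.ndarray:
        i = self.atom_index(chain, res_index, name)
        if i is None:
            raise KeyError(f"atom {name} of {chain}:{res_index} not present")
        return self.coords[i]

    def residues(self):
        """Ordered (chain, res_index, res_name) triples."""
        seen, out = set(), []
        for c, r, rn in zip(self.chains, self.res_indices, self.res_names):
            key = (c, int(r))
            if key not in seen:
                seen.add(key)
                out.append((c, int(r), rn))
        return out

    def chain_ids(self):
        out = []
        for c in self.chains:
            if c not in out:
                out.append(c)
        return out

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def copy(self) -> "Structure":
        return Structure(
            names=list(self.names),
            elements=list(self.elements),
            res_indices=self.res_indices.copy(),
            res_names=list(self.res_names),
            chains=list(self.chains),
            coords=self.coords.copy(),
            model_index=self.model_index,
            _index=self._index,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        out = self.copy()
        out.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return out


@dataclass(frozen=True)
class AmideGroup:
    """A backbone H-N amide with the carbonyl of its own peptide plane (residue i-1)."""

    chain: str
    res_index: int
    res_name: str
    h: np.ndarray
    n: np.ndarray
    c_carbonyl: np.ndarray
    o_carbonyl: np.ndarray

    def __post_init__(self):
        d = float(np.linalg.norm(self.n - self.h))
        if not (0.8 <= d <= 1.2):
            raise MissingHydrogenError(
                f"amide N-H distance {d:.2f} A at residue {self.chain}:{self.res_index} "
                "outside 0.8-1.2 A: structure lacks plausible explicit hydrogens"
            )


@dataclass(frozen=True)
class AromaticRing:
    res_index: int
    chain: str
    kind: str
    center: np.ndarray
    normal: np.ndarray
    intensity: float = 1.0


@dataclass(frozen=True)
class HydrogenBond:
    """One record per backbone amide proton; acceptor_class NONE means no acceptor."""

    donor: AmideGroup
    acceptor_chain: Optional[str]
    acceptor_res_index: Optional[int]
    acceptor_res_name: Optional[str]
    acceptor_atom: Optional[str]
    acceptor_class: AcceptorClass
    r_ho: float
    angle_hoc: float
    angle_nho: float
    dihedral_rho: float

    @property
    def bonded(self) -> bool:
        return self.acceptor_class is not AcceptorClass.NONE


# ---------------------------------------------------------------------------
# Parsing / writing
# ---------------------------------------------------------------------------

def _structure_from_gemmi_model(model, model_index: int) -> Structure:
    names, elements, res_idx, res_names, chains, coords = [], [], [], [], [], []
    for chain in model:
        for res in chain:
            if res.name == "HOH":
                continue
            for atom in res:
                if atom.altloc not in ("", "A", "\x00"):
                    continue
                names.append(atom.name)
                elements.append(atom.element.name)
                res_idx.append(res.seqid.num)
                res_names.append(res.name)
                chains.append(chain.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not names:
        raise ValueError("no atoms found in model")
    return Structure(
        names=names,
        elements=elements,
        res_indices=np.array(res_idx),
        res_names=res_names,
        chains=chains,
        coords=np.array(coords),
        model_index=model_index,
    )


def _validate_hydrogens(s: Structure) -> None:
    for chain in s.chain_ids():
        chain_res = [(r, rn) for c, r, rn in s.residues() if c == chain]
        for k, (r, rn) in enumerate(chain_res):
            if k == 0 or rn == "PRO":
                continue
            if not s.has_atom(chain, r, "N"):
                continue
            h = _find_amide_h(s, chain, r)
            if h is None:
                raise MissingHydrogenError(
                    f"no explicit hydrogens: backbone amide H missing at residue "
                    f"{chain}:{r} ({rn})"
                )
            d = float(np.linalg.norm(s.position(chain, r, "N") - s.coords[h]))
            if not (0.8 <= d <= 1.2):
                raise MissingHydrogenError(
                    f"no explicit hydrogens: N-H distance {d:.2f} A at residue "
                    f"{chain}:{r} ({rn})"
                )


def _find_amide_h(s: Structure, chain: str, res_index: int) -> Optional[int]:
    for name in _AMIDE_H_NAMES:
        i = s.atom_index(chain, res_index, name)
        if i is not None:
            return i
    return None


def parse_structure(path, model_index: int = 0, require_hydrogens: bool = True) -> Structure:
    """Read one conformer of a PDB file.

    ``model_index`` is the 0-based ordinal of the MODEL record to read
    (single-model files have exactly index 0).  Structures are validated to
    carry explicit backbone amide hydrogens unless ``require_hydrogens`` is
    False.
    """
    st = gemmi.read_structure(str(path))
    if model_index < 0 or model_index >= len(st):
        raise IndexError(f"model_index {model_index} out of range (file has {len(st)} models)")
    s = _structure_from_gemmi_model(st[model_index], model_index)
    if require_hydrogens:
        _validate_hydrogens(s)
    return s


def parse_ensemble(path, require_hydrogens: bool = True):
    """Read every MODEL of a (possibly multi-model) PDB file."""
    st = gemmi.read_structure(str(path))
    out = []
    for i in range(len(st)):
        s = _structure_from_gemmi_model(st[i], i)
        if require_hydrogens:
            _validate_hydrogens(s)
        out.append(s)
    return out


def _to_gemmi(structures: Sequence[Structure]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "amideshift"
    for mi, s in enumerate(structures):
        model = gemmi.Model(mi + 1)
        chain_map = {}
        for i in range(s.n_atoms):
            cid = s.chains[i]
            if cid not in chain_map:
                chain_map[cid] = gemmi.Chain(cid)
            chain = chain_map[cid]
            rnum = int(s.res_indices[i])
            if len(chain) == 0 or chain[-1].seqid.num != rnum:
                res = gemmi.Residue()
                res.name = s.res_names[i]
                res.seqid = gemmi.SeqId(rnum, " ")
                chain.add_residue(res)
            res = chain[-1]
            atom = gemmi.Atom()
            atom.name = s.names[i]
            atom.element = gemmi.Element(s.elements[i])
            atom.pos = gemmi.Position(*s.coords[i])
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
        for chain in chain_map.values():
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: Structure, path) -> None:
    _to_gemmi([structure]).write_pdb(str(path))


def write_ensemble(structures: Sequence[Structure], path) -> None:
    """Write conformers as a multi-model PDB file."""
    _to_gemmi(list(structures)).write_pdb(str(path))


# ---------------------------------------------------------------------------
# Geometry views
# ---------------------------------------------------------------------------

def backbone_torsions(s: Structure, res_index: int, chain: Optional[str] = None):
    """(phi, psi) of a residue in degrees; raises if defining atoms are absent."""
    chain = chain if chain is not None else s.chain_ids()[0]
    need = {
        "phi": [(res_index - 1, "C"), (res_index, "N"), (res_index, "CA"), (res_index, "C")],
        "psi": [(res_index, "N"), (res_index, "CA"), (res_index, "C"), (res_index + 1, "N")],
    }
    out = {}
    for key, spec in need.items():
        pts = []
        for r, name in spec:
            if not s.has_atom(chain, r, name):
                raise KeyError(f"{key} of residue {chain}:{res_index} undefined: missing {name} of residue {r}")
            pts.append(s.position(chain, r, name))
        out[key] = dihedral(*pts)
    return out["phi"], out["psi"]


def torsion_value(s: Structure, kind: str, res_index: int,
                  chain: Optional[str] = None) -> float:
    """One named torsion (phi, psi or chi1) in degrees."""
    chain = chain if chain is not None else s.chain_ids()[0]
    specs = {
        "phi": [(res_index - 1, "C"), (res_index, "N"), (res_index, "CA"), (res_index, "C")],
        "psi": [(res_index, "N"), (res_index, "CA"), (res_index, "C"), (res_index + 1, "N")],
        "chi1": [(res_index, "N"), (res_index, "CA"), (res_index, "CB"), (res_index, "CG")],
    }
    pts = []
    for r, name in specs[kind]:
        if not s.has_atom(chain, r, name):
            raise KeyError(f"{kind} of residue {chain}:{res_index} undefined: missing {name} of residue {r}")
        pts.append(s.position(chain, r, name))
    return dihedral(*pts)


def amide_groups(s: Structure):
    """Backbone amide groups eligible for prediction (non-PRO, non-N-terminal)."""
    out = []
    for chain in s.chain_ids():
        chain_res = [(r, rn) for c, r, rn in s.residues() if c == chain]
        for k, (r, rn) in enumerate(chain_res):
            if k == 0 or rn == "PRO":
                continue
            prev_r = chain_res[k - 1][0]
            h_idx = _find_amide_h(s, chain, r)
            if h_idx is None:
                raise MissingHydrogenError(
                    f"no explicit hydrogens: backbone amide H missing at residue {chain}:{r} ({rn})"
                )
            try:
                group = AmideGroup(
                    chain=chain,
                    res_index=r,
                    res_name=rn,
                    h=s.coords[h_idx],
                    n=s.position(chain, r, "N"),
                    c_carbonyl=s.position(chain, prev_r, "C"),
                    o_carbonyl=s.position(chain, prev_r, "O"),
                )
            except KeyError:
                continue
            out.append(group)
    return out


def find_rings(s: Structure, intensities: Optional[dict] = None):
    """Aromatic rings with centroid and SVD plane normal.

    Incomplete rings are skipped with a logged warning.  ``intensities``
    optionally maps ring kind to the dimensionless point-dipole intensity.
    """
    rings = []
    for chain, r, rn in s.residues():
        for kind, atom_names in _RING_SPECS.get(rn, []):
            try:
                pts = np.array([s.position(chain, r, a) for a in atom_names])
            except KeyError:
                logger.warning("skipping incomplete %s ring at %s:%d", kind, chain, r)
                continue
            center = pts.mean(axis=0)
            normal = plane_normal(pts)
            intensity = 1.0 if intensities is None else float(intensities.get(kind, 1.0))
            rings.append(AromaticRing(res_index=r, chain=chain, kind=kind,
                                      center=center, normal=normal, intensity=intensity))
    return rings


def _acceptor_candidates(s: Structure):
    """Every oxygen that can accept a hydrogen bond, with class and bonded carbon."""
    out = []
    for i in range(s.n_atoms):
        name = s.names[i]
        if s.elements[i] != "O":
            continue
        rn = s.res_names[i]
        entry = _ACCEPTOR_MAP.get((rn, name)) or _ACCEPTOR_MAP.get(("*", name))
        if entry is None:
            continue
        klass, carbon = entry
        chain, r = s.chains[i], int(s.res_indices[i])
        if not s.has_atom(chain, r, carbon):
            continue
        out.append((i, chain, r, rn, name, klass, carbon))
    return out


def detect_hydrogen_bonds(s: Structure, r_max: float = 2.5, angle_min: float = 120.0):
    """One HydrogenBond record per backbone amide proton.

    The acceptor is the oxygen with smallest H···O distance among candidates
    passing the geometric gate (r_HO <= ``r_max`` A and N-H···O angle >=
    ``angle_min`` deg); ties break toward the larger N-H···O angle.  The
    carbonyl oxygens of the donor's own peptide plane (residue i-1) and of
    the donor residue itself are never acceptor candidates.
    """
    candidates = _acceptor_candidates(s)
    bonds = []
    for donor in amide_groups(s):
        best = None
        best_key = None
        for (i, chain, r, rn, name, klass, carbon) in candidates:
            if chain == donor.chain and name == "O" and r in (donor.res_index - 1, donor.res_index):
                continue
            o = s.coords[i]
            r_ho = float(np.linalg.norm(donor.h - o))
            if r_ho > r_max or r_ho <= 0.0:
                continue
            nho = bond_angle(donor.n, donor.h, o)
            if nho < angle_min:
                continue
            key = (r_ho, -nho)
            if best_key is None or key < best_key:
                c_pos = s.position(chain, r, carbon)
                hoc = bond_angle(donor.h, o, c_pos)
                x_name = "CA" if s.has_atom(chain, r, "CA") else None
                if x_name is not None:
                    try:
                        rho = dihedral(donor.h, o, c_pos, s.position(chain, r, "CA"))
                    except ValueError:
                        rho = 0.0
                else:
                    rho = 0.0
                best = HydrogenBond(
                    donor=donor, acceptor_chain=chain, acceptor_res_index=r,
                    acceptor_res_name=rn, acceptor_atom=name, acceptor_class=klass,
                    r_ho=r_ho, angle_hoc=hoc, angle_nho=nho, dihedral_rho=rho,
                )
                best_key = key
        if best is None:
            best = HydrogenBond(
                donor=donor, acceptor_chain=None, acceptor_res_index=None,
                acceptor_res_name=None, acceptor_atom=None,
                acceptor_class=AcceptorClass.NONE,
                r_ho=float("inf"), angle_hoc=float("nan"),
                angle_nho=float("nan"), dihedral_rho=float("nan"),
            )
        bonds.append(best)
    return bonds


# ---------------------------------------------------------------------------
# Torsion moves (used by the refinement sampler)
# ---------------------------------------------------------------------------

def movable_torsions(s: Structure, chain: Optional[str] = None):
    """Rotatable (kind, res_index) torsions of one chain.

    ``phi`` for residues with a preceding C, ``psi`` for residues with a
    following N, and ``chi1`` for residues with side-chain atoms beyond CB.
    """
    chain = chain if chain is not None else s.chain_ids()[0]
    chain_res = [(r, rn) for c, r, rn in s.residues() if c == chain]
    torsions = []
    for k, (r, rn) in enumerate(chain_res):
        if k > 0 and rn != "PRO" and all(s.has_atom(chain, r, a) for a in ("N", "CA", "C")):
            torsions.append(("phi", r))
        if k + 1 < len(chain_res) and all(s.has_atom(chain, r, a) for a in ("N", "CA", "C")):
            torsions.append(("psi", r))
        if s.has_atom(chain, r, "CB"):
            downstream = _sidechain_downstream(s, chain, r)
            if downstream:
                torsions.append(("chi1", r))
    return torsions


def _sidechain_downstream(s: Structure, chain: str, res_index: int):
    """Atom indices of side-chain atoms beyond CB for one residue."""
    out = []
    for i in range(s.n_atoms):
        if s.chains[i] != chain or int(s.res_indices[i]) != res_index:
            continue
        if s.names[i] in _BACKBONE_NAMES or s.names[i] == "CB":
            continue
        out.append(i)
    return out


def _downstream_atoms(s: Structure, chain: str, kind: str, res_index: int):
    if kind == "chi1":
        return _sidechain_downstream(s, chain, res_index)
    out = []
    for i in range(s.n_atoms):
        if s.chains[i] != chain:
            continue
        r = int(s.res_indices[i])
        if r > res_index:
            out.append(i)
        elif r == res_index:
            name = s.names[i]
            if kind == "phi" and name not in ("N", "CA") and name not in _AMIDE_H_NAMES:
                out.append(i)
            elif kind == "psi" and name in ("O", "OXT"):
                out.append(i)
    return out


def rotate_torsion(s: Structure, kind: str, res_index: int, delta_deg: float,
                   chain: Optional[str] = None) -> Structure:
    """Return a copy of ``s`` with one torsion rotated by ``delta_deg``.

    Rotation is about the N-CA axis (phi), CA-C axis (psi) or CA-CB axis
    (chi1); all atoms downstream of the axis within the chain move rigidly.
    """
    chain = chain if chain is not None else s.chain_ids()[0]
    axes = {"phi": ("N", "CA"), "psi": ("CA", "C"), "chi1": ("CA", "CB")}
    a_name, b_name = axes[kind]
    p0 = s.position(chain, res_index, a_name)
    p1 = s.position(chain, res_index, b_name)
    rot = rotation_about_axis(p1 - p0, delta_deg)
    idx = _downstream_atoms(s, chain, kind, res_index)
    out = s.copy()
    out.coords[idx] = (out.coords[idx] - p0) @ rot.T + p0
    return out
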