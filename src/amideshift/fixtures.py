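"""Programmatic generation of every test input.

Ideal poly-alanine peptides at exact backbone torsions (with optional
aromatic / polar residues for ring-current and acceptor-class coverage),
two-amide hydrogen-bond geometry scans, and synthetic shift / coupling /
RDC tables with known ground truth.  All outputs are deterministic given
their parameters and seed.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import place_atom, unit
from .observables import AlignmentTensor, back_calc_rdc, couplings_for_structure
from .params import ParameterSet
from .predictor import ShiftTable, predict, predictions_frame
from .structure import Structure

# Ideal backbone internal coordinates (A, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.010, 1.521
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O, _A_C_N_H = 121.7, 111.2, 116.6, 120.8, 119.0
_A_N_CA_CB = 110.4
_T_N_C_CA_CB = -122.3  # improper fixing side-chain chirality

_ONE_TO_THREE = {
    "A": "ALA", "G": "GLY", "S": "SER", "D": "ASP", "N": "ASN",
    "F": "PHE", "Y": "TYR", "W": "TRP", "H": "HIS",
}


def _element_of(name: str) -> str:
    return name.lstrip("0123456789")[0]


def _hexagon_template() -> Dict[str, np.ndarray]:
    """Regular 1.39 A hexagon with CG at the origin, ring along +x."""
    center = np.array([1.39, 0.0])
    order = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    out = {}
    for k, name in enumerate(order):
        a = np.deg2rad(180.0 - 60.0 * k)
        out[name] = center + 1.39 * np.array([np.cos(a), np.sin(a)])
    return out


def _pentagon_template(order: Sequence[str]) -> Dict[str, np.ndarray]:
    """Regular 1.37 A pentagon with the first atom at the origin."""
    R = 1.37 / (2.0 * np.sin(np.deg2rad(36.0)))
    center = np.array([R, 0.0])
    out = {}
    for k, name in enumerate(order):
        a = np.deg2rad(180.0 - 72.0 * k)
        out[name] = center + R * np.array([np.cos(a), np.sin(a)])
    return out


def _trp_template() -> Dict[str, np.ndarray]:
    """Indole: pentagon fused with a hexagon on the CD2-CE2 edge."""
    out = _pentagon_template(["CG", "CD1", "NE1", "CE2", "CD2"])
    ce2, cd2 = out["CE2"], out["CD2"]
    side = float(np.linalg.norm(ce2 - cd2))
    mid = 0.5 * (ce2 + cd2)
    pent_center = np.array([1.37 / (2.0 * np.sin(np.deg2rad(36.0))), 0.0])
    u = unit(mid - pent_center)
    hex_center = mid + (side * np.sqrt(3.0) / 2.0) * u

    def rot(p, deg):
        t = np.deg2rad(deg)
        R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        return hex_center + R @ (p - hex_center)

    sign = 60.0 if np.linalg.norm(rot(ce2, 5 * 60.0) - cd2) < 1e-6 else -60.0
    for k, name in enumerate(["CZ2", "CH2", "CZ3", "CE3"], start=1):
        out[name] = rot(ce2, sign * k)
    return out


_RING_TEMPLATES = {
    "PHE": _hexagon_template(),
    "TYR": {**_hexagon_template(), "OH": np.array([2.78 + 1.37, 0.0])},
    "HIS": _pentagon_template(["CG", "ND1", "CE1", "NE2", "CD2"]),
    "TRP": _trp_template(),
}


def _place_ring(res_name: str, n: np.ndarray, ca: np.ndarray, cb: np.ndarray,
                chi1: float, chi2: float) -> List[Tuple[str, np.ndarray]]:
    cg = place_atom(n, ca, cb, 1.50, 114.1, chi1)
    xhat = unit(cg - cb)
    nhat = unit(np.cross(cb - ca, xhat))
    mhat = np.cross(nhat, xhat)
    yhat = np.cos(np.deg2rad(chi2)) * mhat + np.sin(np.deg2rad(chi2)) * nhat
    template = _RING_TEMPLATES[res_name]
    return [(name, cg + uv[0] * xhat + uv[1] * yhat) for name, uv in template.items()]


def _sidechain_atoms(res_name: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                     chi1: float, chi2: float) -> List[Tuple[str, np.ndarray]]:
    if res_name == "GLY":
        return []
    cb = place_atom(c, n, ca, _B_CA_CB, _A_N_CA_CB, _T_N_C_CA_CB)
    atoms = [("CB", cb)]
    if res_name == "ALA":
        return atoms
    if res_name == "SER":
        atoms.append(("OG", place_atom(n, ca, cb, 1.417, 110.8, chi1)))
        return atoms
    if res_name in ("ASP", "ASN"):
        cg = place_atom(n, ca, cb, 1.52, 113.0, chi1)
        atoms.append(("CG", cg))
        if res_name == "ASP":
            atoms.append(("OD1", place_atom(ca, cb, cg, 1.25, 118.5, chi2)))
            atoms.append(("OD2", place_atom(ca, cb, cg, 1.25, 118.5, chi2 + 180.0)))
        else:
            atoms.append(("OD1", place_atom(ca, cb, cg, 1.23, 120.8, chi2)))
            atoms.append(("ND2", place_atom(ca, cb, cg, 1.33, 116.4, chi2 + 180.0)))
        return atoms
    if res_name in _RING_TEMPLATES:
        atoms.extend(_place_ring(res_name, n, ca, cb, chi1, chi2))
        return atoms
    raise ValueError(f"unsupported fixture residue {res_name}")


def make_peptide(n: int, phi: float = -57.0, psi: float = -47.0,
                 sequence: Optional[str] = None, chain: str = "A",
                 chi1: float = -60.0, chi2: float = 90.0,
                 start_index: int = 1) -> Structure:
    """Ideal-geometry peptide at exact (phi, psi) with explicit amide hydrogens.

    ``sequence`` is a one-letter string (default poly-alanine) drawn from
    A, G, S, D, N, F, Y, W, H.  phi applies to residues 2..n and psi to the
    carbonyl orientation of every residue.  The first residue carries no
    amide hydrogen (N-terminus).
    """
    if n < 2:
        raise ValueError("need at least 2 residues")
    seq = sequence if sequence is not None else "A" * n
    if len(seq) != n:
        raise ValueError("sequence length must equal n")
    res_names = [_ONE_TO_THREE[ch] for ch in seq]

    names, elements, res_idx, rn_list, chains, coords = [], [], [], [], [], []

    def add(res_i: int, res_name: str, atom_name: str, pos: np.ndarray):
        names.append(atom_name)
        elements.append(_element_of(atom_name))
        res_idx.append(start_index + res_i)
        rn_list.append(res_name)
        chains.append(chain)
        coords.append(np.asarray(pos, dtype=float))

    prev = {}
    for i in range(n):
        if i == 0:
            N = np.zeros(3)
            CA = np.array([_B_N_CA, 0.0, 0.0])
            ang = np.deg2rad(_A_N_CA_C)
            C = CA + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
            H = None
        else:
            N = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
            CA = place_atom(prev["CA"], prev["C"], N, _B_N_CA, _A_C_N_CA, 180.0)
            C = place_atom(prev["C"], N, CA, _B_CA_C, _A_N_CA_C, phi)
            H = place_atom(prev["O"], prev["C"], N, _B_N_H, _A_C_N_H, 180.0)
        O = place_atom(N, CA, C, _B_C_O, _A_CA_C_O, psi + 180.0)
        add(i, res_names[i], "N", N)
        if H is not None:
            add(i, res_names[i], "H", H)
        add(i, res_names[i], "CA", CA)
        add(i, res_names[i], "C", C)
        add(i, res_names[i], "O", O)
        for atom_name, pos in _sidechain_atoms(res_names[i], N, CA, C, chi1, chi2):
            add(i, res_names[i], atom_name, pos)
        prev = {"N": N, "CA": CA, "C": C, "O": O}

    return Structure(names=names, elements=elements, res_indices=np.array(res_idx),
                     res_names=rn_list, chains=chains, coords=np.array(coords))


def make_dimer(r_ho: float, angle_hoc: float, angle_nho: float = 170.0) -> Structure:
    """Two dipeptides posed so the chain-B amide proton of residue 2 donates
    to the chain-A carbonyl oxygen of residue 1 at exactly (r_HO, H···O=C
    angle, N-H···O angle).  Emulates a formamide/N-methylacetamide dimer scan."""
    acceptor = make_peptide(2, phi=-139.0, psi=135.0, chain="A")
    donor = make_peptide(2, phi=-139.0, psi=135.0, chain="B")

    o = acceptor.position("A", 1, "O")
    c = acceptor.position("A", 1, "C")
    ca = acceptor.position("A", 1, "CA")
    chat = unit(c - o)
    nplane = unit(np.cross(chat, ca - o))
    ehat = np.cross(nplane, chat)
    th = np.deg2rad(angle_hoc)
    dhat = np.cos(th) * chat + np.sin(th) * ehat        # O -> H direction
    p_h = o + r_ho * dhat
    al = np.deg2rad(angle_nho)
    eprime = np.cross(nplane, dhat)
    n_dir = np.cos(al) * (-dhat) + np.sin(al) * eprime  # H -> N direction

    h_cur = donor.position("B", 2, "H")
    n_cur = donor.position("B", 2, "N")
    ca_cur = donor.position("B", 2, "CA")
    xc = unit(n_cur - h_cur)
    zc = unit(np.cross(xc, ca_cur - h_cur))
    yc = np.cross(zc, xc)
    xt, zt = unit(n_dir), nplane
    yt = np.cross(zt, xt)
    rot = np.column_stack([xt, yt, zt]) @ np.column_stack([xc, yc, zc]).T

    moved = donor.copy()
    moved.coords = (donor.coords - h_cur) @ rot.T + p_h

    return Structure(
        names=acceptor.names + moved.names,
        elements=acceptor.elements + moved.elements,
        res_indices=np.concatenate([acceptor.res_indices, moved.res_indices]),
        res_names=acceptor.res_names + moved.res_names,
        chains=acceptor.chains + moved.chains,
        coords=np.vstack([acceptor.coords, moved.coords]),
    )


def make_dimer_scan(r_values: Sequence[float], angle_values: Sequence[float],
                    angle_nho: float = 170.0) -> List[Structure]:
    """One dimer per (r_HO, angle_HOC) node, row-major over r then angle."""
    if len(r_values) == 0 or len(angle_values) == 0:
        raise ValueError("scan ranges must be nonempty")
    return [make_dimer(r, a, angle_nho) for r in r_values for a in angle_values]


# ---------------------------------------------------------------------------
# Synthetic observables
# ---------------------------------------------------------------------------

def synthetic_shift_table(s: Structure, noise_sigma: float = 0.0, seed: int = 0,
                          params: Optional[ParameterSet] = None) -> ShiftTable:
    """Forward-model shifts plus Gaussian noise, as an experimental-style table."""
    rng = np.random.default_rng(seed)
    preds = predict(s, params)
    frame = predictions_frame(preds)
    shifts = frame["total_ppm"].to_numpy() + rng.normal(0.0, noise_sigma, len(frame))
    return ShiftTable.from_records([
        (int(r), rn, float(v))
        for r, rn, v in zip(frame["res_index"], frame["res_name"], shifts)
    ])


def synthetic_couplings(s: Structure, noise_sigma: float = 0.0, seed: int = 0,
                        params: Optional[ParameterSet] = None) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    recs = couplings_for_structure(s, params)
    return pd.DataFrame([{
        "donor_res": r.donor_res, "acceptor_res": r.acceptor_res,
        "j_hz": r.j_hz + rng.normal(0.0, noise_sigma),
    } for r in recs])


def random_alignment_tensor(seed: int = 0, scale: float = 5.0) -> AlignmentTensor:
    rng = np.random.default_rng(seed)
    return AlignmentTensor(components=rng.normal(0.0, scale, 5))


def synthetic_rdcs(structures, residues: Sequence[int],
                   tensor: Optional[AlignmentTensor] = None,
                   noise_sigma: float = 0.0, seed: int = 0) -> Tuple[pd.DataFrame, AlignmentTensor]:
    """Back-calculated N-H RDCs from a (possibly random) alignment tensor."""
    if tensor is None:
        tensor = random_alignment_tensor(seed)
    rng = np.random.default_rng(seed + 1)
    if isinstance(structures, Structure):
        structures = [structures]
    d = back_calc_rdc(structures, residues, tensor)
    d = d + rng.normal(0.0, noise_sigma, len(d))
    frame = pd.DataFrame({"res_index": list(residues), "d_hz": d})
    return frame, tensor
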