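"""Trans-hydrogen-bond h3J(NC') couplings and N-H residual dipolar couplings.

Couplings use a Barfield-style closed form (exponential in the H···O
distance times angular factors); RDCs are back-calculated through a
5-parameter Saupe alignment tensor fitted by SVD least squares, with the
Q-factor as the agreement measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .params import ParameterSet
from .structure import AcceptorClass, HydrogenBond, Structure, detect_hydrogen_bonds


@dataclass(frozen=True)
class CouplingRecord:
    donor_res: int
    acceptor_res: int
    j_hz: float


@dataclass(frozen=True)
class AlignmentTensor:
    """Saupe alignment tensor as its five independent components.

    Components are (S_xx - S_zz is implied by tracelessness):
    (S_xx, S_yy, S_xy, S_xz, S_yz); the Hz scale of the dipolar constant is
    absorbed into the tensor, so back-calculated couplings are in Hz.
    """

    components: np.ndarray

    def matrix(self) -> np.ndarray:
        sxx, syy, sxy, sxz, syz = self.components
        return np.array([
            [sxx, sxy, sxz],
            [sxy, syy, syz],
            [sxz, syz, -sxx - syy],
        ])


def j_coupling(hb: HydrogenBond, params: Optional[ParameterSet] = None) -> float:
    """h3J(NC') across one amide-amide hydrogen bond, Hz.

    J = amplitude * exp(-decay * r_HO) * cos^2(theta1) * cos^2(theta2) with
    theta1 the N-H···O angle and theta2 the H···O=C angle; the amplitude is
    negative, so amide-amide couplings are <= 0 and decay to zero as the
    bond breaks.
    """
    params = params if params is not None else ParameterSet.default()
    if hb.acceptor_class is AcceptorClass.NONE:
        return 0.0
    if hb.acceptor_class is not AcceptorClass.BACKBONE_AMIDE:
        raise ValueError(
            "h3J(NC') is defined only across amide-amide hydrogen bonds "
            f"(got acceptor class {hb.acceptor_class.value})"
        )
    t1 = np.cos(np.deg2rad(hb.angle_nho)) ** 2
    t2 = np.cos(np.deg2rad(hb.angle_hoc)) ** 2
    return float(params.jc_amplitude * np.exp(-params.jc_decay * hb.r_ho) * t1 * t2)


def couplings_for_structure(s: Structure, params: Optional[ParameterSet] = None
                            ) -> List[CouplingRecord]:
    """All amide-amide trans-hydrogen-bond couplings of one conformer."""
    params = params if params is not None else ParameterSet.default()
    records = []
    for hb in detect_hydrogen_bonds(s, r_max=params.hb_gate_r_max,
                                    angle_min=params.hb_gate_angle_min):
        if hb.acceptor_class is AcceptorClass.BACKBONE_AMIDE:
            records.append(CouplingRecord(hb.donor.res_index, hb.acceptor_res_index,
                                          j_coupling(hb, params)))
    return records


def ensemble_j_stats(ensemble: Sequence[Structure],
                     experimental: Optional[pd.DataFrame] = None,
                     params: Optional[ParameterSet] = None):
    """Per-bond mean/SD of h3J over conformers and the RMSD of the means to
    experiment.

    The SD is the root-mean-square deviation from the per-bond mean
    (population convention).  ``experimental`` needs columns
    donor_res, acceptor_res, j_hz.  Bonds broken in a conformer contribute
    J = 0 for that conformer.
    """
    if len(ensemble) < 1:
        raise ValueError("need at least one conformer")
    params = params if params is not None else ParameterSet.default()
    per_conformer = [
        {(r.donor_res, r.acceptor_res): r.j_hz for r in couplings_for_structure(s, params)}
        for s in ensemble
    ]
    # stable bond set across the ensemble so broken bonds count as 0 Hz
    keys = sorted({k for seen in per_conformer for k in seen})
    if experimental is not None:
        keys = sorted(set(keys) | {(int(a), int(b)) for a, b in
                                   zip(experimental["donor_res"], experimental["acceptor_res"])})
    values = {k: [seen.get(k, 0.0) for seen in per_conformer] for k in keys}
    rows = []
    for (donor, acceptor) in keys:
        arr = np.array(values[(donor, acceptor)])
        rows.append({"donor_res": donor, "acceptor_res": acceptor,
                     "mean_hz": float(arr.mean()),
                     "sd_hz": float(np.sqrt(np.mean((arr - arr.mean()) ** 2)))})
    stats = pd.DataFrame(rows)
    rmsd = None
    if experimental is not None:
        merged = stats.merge(experimental, on=["donor_res", "acceptor_res"], how="inner")
        if len(merged):
            diff = merged["mean_hz"].to_numpy() - merged["j_hz"].to_numpy()
            rmsd = float(np.sqrt(np.mean(diff ** 2)))
    return stats, rmsd


# ---------------------------------------------------------------------------
# RDCs
# ---------------------------------------------------------------------------

def _nh_unit_vectors(s: Structure, residues: Sequence[int]) -> np.ndarray:
    chain = s.chain_ids()[0]
    out = []
    for r in residues:
        h_name = "H" if s.has_atom(chain, r, "H") else "HN"
        v = s.position(chain, r, h_name) - s.position(chain, r, "N")
        out.append(v / np.linalg.norm(v))
    return np.array(out)


def _design_row(u: np.ndarray) -> np.ndarray:
    x, y, z = u
    return np.array([x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z])


def back_calc_rdc(structures, residues: Sequence[int],
                  tensor: AlignmentTensor) -> np.ndarray:
    """D_i = u_i^T S u_i averaged over conformers (Hz, scale inside S)."""
    if isinstance(structures, Structure):
        structures = [structures]
    S = tensor.matrix()
    d = np.zeros(len(residues))
    for s in structures:
        units = _nh_unit_vectors(s, residues)
        d += np.einsum("ij,jk,ik->i", units, S, units)
    return d / len(structures)


def fit_alignment_tensor(structures, rdc: pd.DataFrame,
                         ensemble_mode: bool = False) -> AlignmentTensor:
    """Least-squares Saupe tensor from >= 5 N-H RDCs via SVD.

    ``rdc`` needs columns res_index and d_hz.  With ``ensemble_mode`` the
    design-matrix rows are averaged over all conformers so a single tensor
    fits the whole ensemble simultaneously; a single Structure (or a
    one-element list) reduces to the ordinary single-structure fit.
    """
    if isinstance(structures, Structure):
        structures = [structures]
    if not ensemble_mode:
        structures = structures[:1]
    residues = [int(r) for r in rdc["res_index"]]
    d_exp = rdc["d_hz"].to_numpy(dtype=float)
    if len(residues) < 5:
        raise ValueError(f"need at least 5 RDCs to fit an alignment tensor (got {len(residues)})")
    design = np.zeros((len(residues), 5))
    for s in structures:
        units = _nh_unit_vectors(s, residues)
        design += np.array([_design_row(u) for u in units])
    design /= len(structures)
    rank = np.linalg.matrix_rank(design, tol=1e-8)
    if rank < 5:
        raise ValueError(
            f"rank-deficient RDC design matrix (rank {rank} < 5): "
            "N-H vectors are too collinear to determine the alignment tensor"
        )
    components, *_ = np.linalg.lstsq(design, d_exp, rcond=None)
    return AlignmentTensor(components=components)


def q_factor(d_calc: np.ndarray, d_exp: np.ndarray) -> float:
    """Q = sqrt( sum (D_calc - D_exp)^2 / sum D_exp^2 )."""
    d_calc = np.asarray(d_calc, dtype=float)
    d_exp = np.asarray(d_exp, dtype=float)
    if d_exp.size < 1:
        raise ValueError("need at least one RDC")
    denom = float(np.sum(d_exp ** 2))
    if denom == 0.0:
        raise ValueError("all experimental RDCs are zero; Q-factor undefined")
    return float(np.sqrt(np.sum((d_calc - d_exp) ** 2) / denom))


def rdc_report(structures, rdc: pd.DataFrame, ensemble_mode: bool = False):
    """Fit a tensor, back-calculate, and return (tensor, frame-with-D_calc, Q)."""
    tensor = fit_alignment_tensor(structures, rdc, ensemble_mode=ensemble_mode)
    if isinstance(structures, Structure):
        structures = [structures]
    used = structures if ensemble_mode else structures[:1]
    residues = [int(r) for r in rdc["res_index"]]
    d_calc = back_calc_rdc(used, residues, tensor)
    out = rdc.copy()
    out["d_calc_hz"] = d_calc
    q = q_factor(d_calc, rdc["d_hz"].to_numpy())
    return tensor, out, q
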