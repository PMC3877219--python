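"""Assemble per-proton shift predictions, ensemble averages and scores."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .params import ParameterSet
from .structure import (AcceptorClass, HydrogenBond, Structure, backbone_torsions,
                        detect_hydrogen_bonds, find_rings)
from .terms import (BondNetwork, TermBreakdown, backbone_term, primary_hb_term,
                    ring_current_term, secondary_hb_term, tertiary_term)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShiftPrediction:
    chain: str
    res_index: int
    res_name: str
    breakdown: TermBreakdown
    acceptor_class: AcceptorClass

    @property
    def total(self) -> float:
        return self.breakdown.total


class ShiftTable:
    """Experimental (or synthetic) amide proton shifts: residue -> ppm."""

    COLUMNS = ["res_index", "res_name", "shift_ppm"]

    def __init__(self, frame: pd.DataFrame):
        frame = frame[self.COLUMNS].copy()
        frame["res_index"] = frame["res_index"].astype(int)
        if frame["res_index"].duplicated().any():
            raise ValueError("duplicate residue indices in shift table")
        bad = frame[(frame["shift_ppm"] < 3.0) | (frame["shift_ppm"] > 13.0)]
        if len(bad):
            logger.warning("%d shifts outside the physical 3-13 ppm window", len(bad))
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "ShiftTable":
        return cls(pd.DataFrame(records, columns=cls.COLUMNS))

    @classmethod
    def from_csv(cls, path) -> "ShiftTable":
        df = pd.read_csv(path, sep=None, engine="python")
        df.columns = [c.strip().lower() for c in df.columns]
        rename = {"residue": "res_index", "resid": "res_index", "res": "res_index",
                  "name": "res_name", "resname": "res_name",
                  "shift": "shift_ppm", "ppm": "shift_ppm"}
        df = df.rename(columns=rename)
        return cls(df)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def shift_for(self, res_index: int) -> Optional[float]:
        rows = self.frame[self.frame["res_index"] == res_index]
        return None if rows.empty else float(rows["shift_ppm"].iloc[0])

    def __len__(self) -> int:
        return len(self.frame)


def _bond_accepted_by(bonds: Sequence[HydrogenBond], chain: str, res_index: int,
                      atom: str = "O") -> Optional[HydrogenBond]:
    """The hydrogen bond (smallest r_HO) accepted by a specific oxygen, if any."""
    hits = [b for b in bonds
            if b.bonded and b.acceptor_chain == chain
            and b.acceptor_res_index == res_index and b.acceptor_atom == atom]
    return min(hits, key=lambda b: b.r_ho) if hits else None


def _bond_network(hb: HydrogenBond, secondary: Optional[HydrogenBond],
                  bonds: Sequence[HydrogenBond]) -> BondNetwork:
    by_donor = {(b.donor.chain, b.donor.res_index): b for b in bonds}
    primary_partner_bonded = False
    if hb.bonded and hb.acceptor_class is AcceptorClass.BACKBONE_AMIDE and hb.acceptor_atom == "O":
        # the acceptor carbonyl C(j)=O(j) belongs to the amide group of residue j+1
        partner = by_donor.get((hb.acceptor_chain, hb.acceptor_res_index + 1))
        primary_partner_bonded = partner is not None and partner.bonded
    secondary_partner_bonded = False
    if secondary is not None and secondary.bonded:
        donor = secondary.donor
        chained = _bond_accepted_by(bonds, donor.chain, donor.res_index - 1)
        secondary_partner_bonded = chained is not None
    return BondNetwork(primary_partner_bonded, secondary_partner_bonded)


def predict(s: Structure, params: Optional[ParameterSet] = None) -> List[ShiftPrediction]:
    """One prediction per eligible amide proton (phi and psi both defined).

    Prolines, the N-terminal residue and the C-terminal residue (whose psi is
    undefined) carry no prediction.
    """
    params = params if params is not None else ParameterSet.default()
    bonds = detect_hydrogen_bonds(s, r_max=params.hb_gate_r_max,
                                  angle_min=params.hb_gate_angle_min)
    rings = find_rings(s, intensities=params.ring_intensities)
    out = []
    for hb in bonds:
        donor = hb.donor
        try:
            phi, psi = backbone_torsions(s, donor.res_index, chain=donor.chain)
        except KeyError:
            continue  # chain terminus: backbone term undefined
        bb = backbone_term(phi, psi, params.backbone_scale, params.backbone_series)
        primary = primary_hb_term(hb, params)
        secondary_bond = _bond_accepted_by(bonds, donor.chain, donor.res_index - 1)
        secondary = secondary_hb_term(secondary_bond, params)
        tert = tertiary_term(_bond_network(hb, secondary_bond, bonds), params)
        ring = ring_current_term(donor.h, rings, B=params.ring_B)
        out.append(ShiftPrediction(
            chain=donor.chain, res_index=donor.res_index, res_name=donor.res_name,
            breakdown=TermBreakdown(bb, primary, secondary, tert, ring),
            acceptor_class=hb.acceptor_class,
        ))
    return out


def predictions_frame(predictions: Sequence[ShiftPrediction]) -> pd.DataFrame:
    rows = [{
        "chain": p.chain, "res_index": p.res_index, "res_name": p.res_name,
        "total_ppm": p.total, "backbone": p.breakdown.backbone,
        "primary_hb": p.breakdown.primary_hb, "secondary_hb": p.breakdown.secondary_hb,
        "tertiary": p.breakdown.tertiary, "ring_current": p.breakdown.ring_current,
        "acceptor_class": p.acceptor_class.value,
    } for p in predictions]
    return pd.DataFrame(rows)


def ensemble_average(per_conformer: Sequence[Sequence[ShiftPrediction]]) -> pd.DataFrame:
    """Uniform-weight mean and population SD of the total shift per residue,
    plus the mean of each additive term (means commute with the decomposition)."""
    if len(per_conformer) < 1:
        raise ValueError("need at least one conformer")
    frames = []
    for m, preds in enumerate(per_conformer):
        f = predictions_frame(preds)
        f["conformer"] = m
        frames.append(f)
    allf = pd.concat(frames, ignore_index=True)
    grouped = allf.groupby("res_index")
    out = grouped.agg(
        res_name=("res_name", "first"),
        mean_ppm=("total_ppm", "mean"),
        sd_ppm=("total_ppm", lambda x: float(np.std(x, ddof=0))),
        backbone=("backbone", "mean"),
        primary_hb=("primary_hb", "mean"),
        secondary_hb=("secondary_hb", "mean"),
        tertiary=("tertiary", "mean"),
        ring_current=("ring_current", "mean"),
        n_conformers=("conformer", "nunique"),
    ).reset_index()
    return out


@dataclass(frozen=True)
class ScoreResult:
    rmsd: float
    pearson_r: float
    n_matched: int
    unmatched: tuple
    per_class_rmsd: dict

    def __str__(self) -> str:
        lines = [f"matched residues : {self.n_matched}",
                 f"RMSD             : {self.rmsd:.3f} ppm",
                 f"Pearson r        : {self.pearson_r:.3f}"]
        for klass, value in sorted(self.per_class_rmsd.items()):
            lines.append(f"RMSD [{klass:>16s}] : {value:.3f} ppm")
        if self.unmatched:
            lines.append(f"unmatched        : {list(self.unmatched)}")
        return "\n".join(lines)


def score(predictions, experimental: ShiftTable) -> ScoreResult:
    """RMSD and Pearson r between predicted and experimental shifts.

    Rows are matched by residue index (a residue-name mismatch warns); the
    per-acceptor-class RMSD breakdown is reported alongside.
    """
    if isinstance(predictions, pd.DataFrame):
        pred_df = predictions
    else:
        pred_df = predictions_frame(list(predictions))
    merged = pred_df.merge(experimental.frame, on="res_index", how="inner",
                           suffixes=("_pred", "_exp"))
    if "res_name_pred" in merged and "res_name_exp" in merged:
        bad = merged[merged["res_name_pred"] != merged["res_name_exp"]]
        if len(bad):
            logger.warning("residue-name mismatch at indices %s",
                           bad["res_index"].tolist())
    if len(merged) < 2:
        raise ValueError("need at least 2 matched residues to score")
    pred_col = "total_ppm" if "total_ppm" in merged else "mean_ppm"
    diff = merged[pred_col].to_numpy() - merged["shift_ppm"].to_numpy()
    rmsd = float(np.sqrt(np.mean(diff ** 2)))
    r = float(np.corrcoef(merged[pred_col], merged["shift_ppm"])[0, 1])
    unmatched = tuple(sorted(set(experimental.frame["res_index"])
                             - set(pred_df["res_index"])))
    per_class = {}
    if "acceptor_class" in merged:
        for klass, sub in merged.groupby("acceptor_class"):
            d = sub[pred_col].to_numpy() - sub["shift_ppm"].to_numpy()
            per_class[klass] = float(np.sqrt(np.mean(d ** 2)))
    return ScoreResult(rmsd=rmsd, pearson_r=r, n_matched=len(merged),
                       unmatched=unmatched, per_class_rmsd=per_class)
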