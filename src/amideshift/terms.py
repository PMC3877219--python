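"""The five additive contributions to a backbone amide proton chemical shift.

total = backbone(phi, psi) + primary H-bond + secondary H-bond
        + tertiary polarization + ring current

Each term is a pure function of geometry plus a coefficient set, so the
algorithm can be exercised against any parameterization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .params import ParameterSet
from .structure import AcceptorClass, AromaticRing, HydrogenBond

logger = logging.getLogger(__name__)

_BASIS = {
    "cc": lambda a, b: np.cos(a) * np.cos(b),
    "cs": lambda a, b: np.cos(a) * np.sin(b),
    "sc": lambda a, b: np.sin(a) * np.cos(b),
    "ss": lambda a, b: np.sin(a) * np.sin(b),
}


@dataclass(frozen=True)
class TermBreakdown:
    """Per-proton decomposition of the additive shift model (all ppm)."""

    backbone: float
    primary_hb: float
    secondary_hb: float
    tertiary: float
    ring_current: float

    @property
    def total(self) -> float:
        return self.backbone + self.primary_hb + self.secondary_hb + self.tertiary + self.ring_current


class GridSurface:
    """Bilinear lookup surface over (r_HO, angle_HOC) nodes.

    Out-of-range geometries clamp to the boundary (with a logged warning)
    rather than extrapolate.
    """

    def __init__(self, kind: AcceptorClass, r_nodes, angle_nodes, values):
        self.kind = kind
        self.r_nodes = np.asarray(r_nodes, dtype=float)
        self.angle_nodes = np.asarray(angle_nodes, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self._interp = RegularGridInterpolator(
            (self.r_nodes, self.angle_nodes), self.values, method="linear",
            bounds_error=False, fill_value=None,
        )

    def __call__(self, r_ho: float, angle_deg: float) -> float:
        r_clamped = float(np.clip(r_ho, self.r_nodes[0], self.r_nodes[-1]))
        a_clamped = float(np.clip(angle_deg, self.angle_nodes[0], self.angle_nodes[-1]))
        if r_clamped != r_ho or a_clamped != angle_deg:
            logger.warning(
                "geometry (r=%.2f A, angle=%.1f deg) outside the %s grid; clamped",
                r_ho, angle_deg, self.kind.value,
            )
        return float(self._interp((r_clamped, a_clamped)))


def backbone_term(phi: float, psi: float, scale: Tuple[float, float],
                  series: Sequence[Tuple[int, int, str, float]]) -> float:
    """Evaluate the truncated 2-D trigonometric series at (phi, psi), then
    apply the affine scaling a*x + b (accounts for the basis-set/geometry
    dependence of the underlying quantum-chemical surface)."""
    a, b = scale
    return a * evaluate_series(phi, psi, series) + b


def evaluate_series(phi: float, psi: float,
                    series: Sequence[Tuple[int, int, str, float]]) -> float:
    p, q = np.deg2rad(phi), np.deg2rad(psi)
    return float(sum(c * _BASIS[basis](m * p, n * q) for m, n, basis, c in series))


def ring_current_term(h_pos: np.ndarray, rings: Iterable[AromaticRing],
                      B: float = 30.42,
                      intensities: Optional[Dict[str, float]] = None) -> float:
    """Point-dipole ring-current shift: sum_rings i * B * (1 - 3 cos^2 theta) / r^3.

    theta is the angle between the ring normal and the vector from the ring
    center to the proton; protons on the ring axis are shielded (negative
    contribution).  B is in ppm A^3.
    """
    total = 0.0
    for ring in rings:
        r_vec = np.asarray(h_pos, dtype=float) - ring.center
        r = float(np.linalg.norm(r_vec))
        if r <= 1e-9:
            raise ValueError(f"proton coincides with the {ring.kind} ring center")
        intensity = ring.intensity if intensities is None else intensities.get(ring.kind, ring.intensity)
        cos_t = float(np.dot(r_vec, ring.normal)) / r
        total += intensity * B * (1.0 - 3.0 * cos_t ** 2) / r ** 3
    return total


def primary_hb_term(hb: HydrogenBond, params: ParameterSet) -> float:
    """Primary hydrogen-bond contribution for one amide proton.

    Amide acceptors use the closed-form exponential surface; carboxylate and
    alcohol acceptors interpolate on their lookup grids; a proton with no
    acceptor gets the constant water-model value.
    """
    klass = hb.acceptor_class
    if klass is AcceptorClass.NONE:
        return params.water_term
    if klass in (AcceptorClass.BACKBONE_AMIDE, AcceptorClass.SIDECHAIN_AMIDE):
        return params.hb_primary_amide(hb.r_ho, hb.angle_hoc)
    surface = params.surfaces.get(klass)
    if surface is None:
        raise KeyError(f"no bond surface for acceptor class {klass.value}")
    return surface(hb.r_ho, hb.angle_hoc)


def secondary_hb_term(hb_to_own_carbonyl: Optional[HydrogenBond],
                      params: ParameterSet) -> float:
    """Contribution from a hydrogen bond accepted by the amide's own carbonyl
    oxygen; zero when that oxygen accepts none."""
    if hb_to_own_carbonyl is None or not hb_to_own_carbonyl.bonded:
        return 0.0
    return params.hb_secondary(hb_to_own_carbonyl.r_ho, hb_to_own_carbonyl.angle_hoc)


@dataclass(frozen=True)
class BondNetwork:
    """Chained-bond context of one amide proton, for the tertiary term."""

    primary_partner_bonded: bool = False
    secondary_partner_bonded: bool = False


def tertiary_term(network: BondNetwork, params: ParameterSet) -> float:
    """Small polarization correction when a bonding partner is itself bonded."""
    out = 0.0
    if network.primary_partner_bonded:
        out += params.tertiary_increments.get("primary_partner_bonded", 0.0)
    if network.secondary_partner_bonded:
        out += params.tertiary_increments.get("secondary_partner_bonded", 0.0)
    return out
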