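"""Loading of the bundled coefficient files and the run-time configuration.

All parameterization lives in plain-text files under ``amideshift/data`` so
the algorithm code is testable against any coefficient set; a user YAML file
can override the configuration keys in ``defaults.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .structure import AcceptorClass


class ConfigurationError(RuntimeError):
    """A coefficient or configuration file is missing or malformed."""


def _data_path(name: str) -> Path:
    p = resources.files("amideshift").joinpath("data", name)
    if not p.is_file():
        raise ConfigurationError(f"bundled data file {name!r} not found")
    return Path(str(p))


def _read_keyed_file(path: Path) -> Dict[str, float]:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split()
        out[key] = float(value)
    return out


def read_series_file(path) -> List[Tuple[int, int, str, float]]:
    """Parse a cosine/sine series coefficient table: columns m n basis coeff."""
    terms = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m, n, basis, coeff = line.split()
        if basis not in ("cc", "cs", "sc", "ss"):
            raise ConfigurationError(f"unknown basis code {basis!r} in {path}")
        terms.append((int(m), int(n), basis, float(coeff)))
    if not terms:
        raise ConfigurationError(f"empty series file {path}")
    return terms


def read_surface_file(path):
    """Parse a 2-D grid file; returns (kind, r_nodes, angle_nodes, values)."""
    kind = None
    r_nodes = angle_nodes = None
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "kind:" in line:
                kind = line.split("kind:")[1].strip()
            continue
        head, *rest = line.split()
        if head == "r_HO":
            r_nodes = np.array([float(x) for x in rest])
        elif head == "angle_HOC":
            angle_nodes = np.array([float(x) for x in rest])
        else:
            rows.append([float(x) for x in line.split()])
    values = np.array(rows)
    if r_nodes is None or angle_nodes is None or values.shape != (len(r_nodes), len(angle_nodes)):
        raise ConfigurationError(f"malformed surface file {path}")
    if not np.all(np.isfinite(values)):
        raise ConfigurationError(f"non-finite grid values in {path}")
    return kind, r_nodes, angle_nodes, values


@dataclass
class ExponentialSurface:
    """Closed-form bond surface: amplitude * exp(-decay*r) * cos^2(theta)."""

    amplitude: float
    decay: float

    def __call__(self, r_ho: float, angle_deg: float) -> float:
        return float(self.amplitude * np.exp(-self.decay * r_ho)
                     * np.cos(np.deg2rad(angle_deg)) ** 2)


@dataclass
class ParameterSet:
    """Everything the shift terms, couplings and likelihood need."""

    backbone_series: List[Tuple[int, int, str, float]]
    backbone_scale: Tuple[float, float]
    ring_B: float
    ring_intensities: Dict[str, float]
    hb_primary_amide: ExponentialSurface
    hb_secondary: ExponentialSurface
    tertiary_increments: Dict[str, float]
    surfaces: Dict[AcceptorClass, "object"]  # GridSurface, set in terms
    water_term: float
    jc_amplitude: float
    jc_decay: float
    sigma: Dict[AcceptorClass, float]
    hb_gate_r_max: float
    hb_gate_angle_min: float
    temperature: float = 300.0

    @classmethod
    def default(cls, config_path: Optional[str] = None) -> "ParameterSet":
        """Load the bundled parameterization, optionally overridden by a YAML file."""
        from .terms import GridSurface  # deferred: terms imports this module

        cfg = yaml.safe_load(_data_path("defaults.yaml").read_text())
        if config_path is not None:
            user = yaml.safe_load(Path(config_path).read_text()) or {}
            for key, value in user.items():
                if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                    cfg[key].update(value)
                else:
                    cfg[key] = value

        ring = _read_keyed_file(_data_path("ring_current.txt"))
        ring_B = ring.pop("B")
        prim = _read_keyed_file(_data_path("hbond_primary_amide.txt"))
        sec = _read_keyed_file(_data_path("hbond_secondary.txt"))
        tert = _read_keyed_file(_data_path("tertiary_increments.txt"))
        jc = _read_keyed_file(_data_path("jcoupling.txt"))

        surfaces = {}
        for fname, klass in (("surface_carboxylate.txt", AcceptorClass.CARBOXYLATE),
                             ("surface_alcohol.txt", AcceptorClass.ALCOHOL)):
            _, r_nodes, angle_nodes, values = read_surface_file(_data_path(fname))
            surfaces[klass] = GridSurface(klass, r_nodes, angle_nodes, values)

        sigma = {AcceptorClass[k]: float(v) for k, v in cfg["sigma_ppm"].items()}
        return cls(
            backbone_series=read_series_file(_data_path("backbone_series.txt")),
            backbone_scale=(float(cfg["backbone_scale"]["a"]), float(cfg["backbone_scale"]["b"])),
            ring_B=ring_B,
            ring_intensities=ring,
            hb_primary_amide=ExponentialSurface(prim["amplitude_ppm"], prim["decay_inv_angstrom"]),
            hb_secondary=ExponentialSurface(sec["amplitude_ppm"], sec["decay_inv_angstrom"]),
            tertiary_increments=tert,
            surfaces=surfaces,
            water_term=float(cfg["water_term_ppm"]),
            jc_amplitude=jc["amplitude_hz"],
            jc_decay=jc["decay_inv_angstrom"],
            sigma=sigma,
            hb_gate_r_max=float(cfg["hydrogen_bond_gate"]["r_max_angstrom"]),
            hb_gate_angle_min=float(cfg["hydrogen_bond_gate"]["angle_min_deg"]),
            temperature=float(cfg.get("temperature_kelvin", 300.0)),
        )
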