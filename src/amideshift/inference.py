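"""Bayesian ensemble refinement against amide proton chemical shifts.

The posterior over conformations X given a shift table D is

    p(X | D) ∝ exp(-E(X) / kT) * L(D | X)

where E is a pluggable prior energy (kcal/mol) and L is a Gaussian
likelihood in the per-residue shift deviations, with a standard deviation
per primary hydrogen-bond acceptor class (the prediction model is much
cruder for solvent-exposed protons than for amide-amide bonds).  Sampling
is Metropolis-Hastings at 300 K with symmetric Gaussian torsion moves.

`RefinementModel` / `RefinementResults` follow the model-object idiom:
build the model from a starting structure and data, call ``fit`` to sample,
inspect the results object for the ensemble, the trace and a summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .params import ParameterSet
from .predictor import ShiftPrediction, ShiftTable, ensemble_average, predict, score
from .structure import (AcceptorClass, Structure, detect_hydrogen_bonds,
                        movable_torsions, rotate_torsion, torsion_value,
                        write_ensemble)

logger = logging.getLogger(__name__)

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal/(mol K)


@dataclass(frozen=True)
class SigmaModel:
    """Likelihood standard deviation (ppm) per primary-bond acceptor class."""

    sigma: Dict[AcceptorClass, float]

    def __post_init__(self):
        for klass, s in self.sigma.items():
            if s <= 0:
                raise ValueError(f"sigma for {klass} must be positive")

    @classmethod
    def default(cls, params: Optional[ParameterSet] = None) -> "SigmaModel":
        params = params if params is not None else ParameterSet.default()
        return cls(sigma=dict(params.sigma))

    def for_class(self, klass: AcceptorClass) -> float:
        return self.sigma.get(klass, self.sigma[AcceptorClass.NONE])


def log_likelihood(predictions: Sequence[ShiftPrediction], experimental: ShiftTable,
                   sigma: SigmaModel) -> float:
    """Sum over matched residues of log N(delta_i | 0, sigma_i^2)."""
    total = 0.0
    matched = 0
    for p in predictions:
        obs = experimental.shift_for(p.res_index)
        if obs is None:
            continue
        s = sigma.for_class(p.acceptor_class)
        d = p.total - obs
        total += -d * d / (2.0 * s * s) - np.log(s * np.sqrt(2.0 * np.pi))
        matched += 1
    if matched < 1:
        raise ValueError("no residues matched between predictions and shift table")
    return float(total)


def _shift_rmsd(predictions: Sequence[ShiftPrediction], table: ShiftTable) -> float:
    diffs = [p.total - table.shift_for(p.res_index) for p in predictions
             if table.shift_for(p.res_index) is not None]
    return float(np.sqrt(np.mean(np.square(diffs)))) if diffs else float("nan")


def log_posterior(energy: float, loglik: float, temperature: float = 300.0) -> float:
    """-E/(k_B T) + log-likelihood, energy in kcal/mol."""
    if not np.isfinite(energy):
        return -np.inf
    return -energy / (KB_KCAL * temperature) + loglik


# ---------------------------------------------------------------------------
# Energy models (the prior)
# ---------------------------------------------------------------------------
# Contract: a callable Structure -> float (kcal/mol), deterministic, finite
# for any structure free of hard atomic overlap.

class ZeroEnergy:
    """Flat prior."""

    def __call__(self, s: Structure) -> float:
        return 0.0


class HarmonicTorsionEnergy:
    """k/2 * sum (theta - theta_ref)^2 over movable backbone torsions.

    ``k`` is in kcal/(mol deg^2); deviations are wrapped to (-180, 180].
    """

    def __init__(self, reference: Structure, k: float = 0.02):
        self.k = k
        self.reference = {t: self._value(reference, t) for t in movable_torsions(reference)
                          if t[0] in ("phi", "psi")}

    @staticmethod
    def _value(s: Structure, torsion) -> float:
        kind, res = torsion
        return torsion_value(s, kind, res)

    def __call__(self, s: Structure) -> float:
        e = 0.0
        for torsion, ref in self.reference.items():
            try:
                v = self._value(s, torsion)
            except (KeyError, ValueError):
                return np.inf
            d = (v - ref + 180.0) % 360.0 - 180.0
            e += 0.5 * self.k * d * d
        return e


class DefaultEnergy:
    """Coarse desk-scale prior: soft-sphere sterics, a flat-bottomed
    hydrogen-bond well, and a harmonic torsion restraint to the start
    structure (default k = 0.15 kcal/(mol deg^2), about a 2 degree SD per
    torsion at 300 K - a stand-in for the conformational basin a force
    field would define around a refinement start).

    Not a force field - just enough regularization to keep the sampler in
    physically sensible territory while the shift likelihood does the work.
    """

    def __init__(self, reference: Structure, k_torsion: float = 0.15,
                 clash_radius: float = 2.4, k_clash: float = 10.0,
                 hbond_depth: float = 3.0, hbond_r_lo: float = 1.75,
                 hbond_r_hi: float = 2.35, hbond_width: float = 0.15):
        self.restraint = HarmonicTorsionEnergy(reference, k=k_torsion)
        self.clash_radius = clash_radius
        self.k_clash = k_clash
        self.hbond_depth = hbond_depth
        # flat-bottomed well: rewards an intact bond anywhere in the typical
        # amide range without preferring a particular length inside it
        self.hbond_r_lo = hbond_r_lo
        self.hbond_r_hi = hbond_r_hi
        self.hbond_width = hbond_width

    def _sterics(self, s: Structure) -> float:
        heavy = np.array([i for i in range(s.n_atoms) if s.elements[i] != "H"])
        coords = s.coords[heavy]
        res = s.res_indices[heavy]
        is_no = np.array([s.elements[i] in ("N", "O") for i in heavy])
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        iu = np.triu_indices(len(heavy), k=1)
        sep = np.abs(res[:, None] - res[None, :])[iu]
        # hydrogen-bond partner elements (N/O with N/O) may approach freely
        excluded = (is_no[:, None] & is_no[None, :])[iu]
        dist = d[iu]
        mask = (sep >= 2) & ~excluded & (dist < self.clash_radius)
        return float(self.k_clash * np.sum((self.clash_radius - dist[mask]) ** 2))

    def _hbond_wells(self, s: Structure) -> float:
        e = 0.0
        for hb in detect_hydrogen_bonds(s):
            if hb.bonded:
                r = hb.r_ho
                edge = np.clip(r, self.hbond_r_lo, self.hbond_r_hi)
                z = (r - edge) / self.hbond_width
                e -= self.hbond_depth * np.exp(-0.5 * z * z)
        return e

    def __call__(self, s: Structure) -> float:
        return self._sterics(s) + self._hbond_wells(s) + self.restraint(s)


# ---------------------------------------------------------------------------
# Metropolis-Hastings machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PosteriorState:
    """One point of the chain: structure, prior energy, likelihood, posterior."""

    structure: Structure
    energy: float
    loglik: float
    log_posterior: float
    predictions: tuple = ()


def mh_step(state, proposal: Callable, rng: np.random.Generator):
    """One Metropolis step with a symmetric proposal.

    ``proposal(state, rng)`` must return a candidate state carrying a
    ``log_posterior`` attribute.  Returns ``(state, accepted)``; on
    rejection the input state object itself is returned, so the previous
    state is restored bit-exactly.
    """
    candidate = proposal(state, rng)
    delta = candidate.log_posterior - state.log_posterior
    if delta >= 0.0 or rng.random() < np.exp(delta):
        return candidate, True
    return state, False


class TorsionMoveGenerator:
    """Symmetric Gaussian perturbation of one randomly chosen torsion.

    Backbone (phi/psi) moves are drawn with probability
    ``backbone_fraction``; the rest are side-chain chi1 moves.  Chains with
    no rotatable side-chain torsion fall back to backbone moves.
    """

    def __init__(self, structure: Structure, backbone_sigma: float = 2.0,
                 sidechain_sigma: float = 10.0, backbone_fraction: float = 0.25):
        torsions = movable_torsions(structure)
        self.backbone = [t for t in torsions if t[0] in ("phi", "psi")]
        self.sidechain = [t for t in torsions if t[0] == "chi1"]
        if not self.backbone and not self.sidechain:
            raise ValueError("structure has no movable torsions")
        self.backbone_sigma = backbone_sigma
        self.sidechain_sigma = sidechain_sigma
        self.backbone_fraction = backbone_fraction

    def __call__(self, s: Structure, rng: np.random.Generator) -> Structure:
        use_backbone = bool(self.backbone) and (
            not self.sidechain or rng.random() < self.backbone_fraction)
        pool = self.backbone if use_backbone else self.sidechain
        sigma = self.backbone_sigma if use_backbone else self.sidechain_sigma
        kind, res = pool[rng.integers(len(pool))]
        return rotate_torsion(s, kind, res, rng.normal(0.0, sigma))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class RefinementModel:
    """Posterior sampler for one chain against an amide proton shift table.

    Parameters
    ----------
    start : Structure
        Starting conformer with explicit amide hydrogens.
    shifts : ShiftTable or None
        Experimental shifts; ``None`` samples the prior alone.
    energy : callable, optional
        Prior energy model (Structure -> kcal/mol).  Defaults to
        :class:`DefaultEnergy` restrained to ``start``.
    sigma : SigmaModel, optional
        Per-acceptor-class likelihood widths; defaults from the bundled
        configuration (0.3 / 0.5 / 0.8 / 1.2 ppm).
    temperature : float
        Sampling temperature in kelvin (default 300).
    """

    def __init__(self, start: Structure, shifts: Optional[ShiftTable] = None,
                 params: Optional[ParameterSet] = None,
                 energy: Optional[Callable] = None,
                 sigma: Optional[SigmaModel] = None,
                 temperature: Optional[float] = None,
                 move_generator: Optional[TorsionMoveGenerator] = None):
        self.params = params if params is not None else ParameterSet.default()
        self.start = start
        self.shifts = shifts
        self.energy = energy if energy is not None else DefaultEnergy(start)
        self.sigma = sigma if sigma is not None else SigmaModel.default(self.params)
        self.temperature = temperature if temperature is not None else self.params.temperature
        self.moves = move_generator if move_generator is not None else TorsionMoveGenerator(start)

    def _evaluate(self, s: Structure) -> PosteriorState:
        e = float(self.energy(s))
        if self.shifts is not None:
            preds = tuple(predict(s, self.params))
            ll = log_likelihood(preds, self.shifts, self.sigma)
        else:
            preds, ll = (), 0.0
        return PosteriorState(structure=s, energy=e, loglik=ll,
                              log_posterior=log_posterior(e, ll, self.temperature),
                              predictions=preds)

    def _proposal(self, state: PosteriorState, rng: np.random.Generator) -> PosteriorState:
        return self._evaluate(self.moves(state.structure, rng))

    def fit(self, n_steps: int, seed: int = 0, save_interval: int = 10_000,
            trace_interval: int = 100, burn_in: int = 0,
            frozen_window: int = 1_000) -> "RefinementResults":
        """Run the chain; conformers are saved every ``save_interval`` steps
        (after ``burn_in``) and the trace is recorded every ``trace_interval``."""
        rng = np.random.default_rng(seed)
        state = self._evaluate(self.start)
        samples: List[Structure] = []
        trace_rows = []
        n_accept = 0
        since_accept = 0
        for step in range(1, n_steps + 1):
            state, accepted = mh_step(state, self._proposal, rng)
            if accepted:
                n_accept += 1
                since_accept = 0
            else:
                since_accept += 1
                if since_accept == frozen_window:
                    logger.warning("no accepted move in the last %d steps: "
                                   "chain may be frozen", frozen_window)
            if step % trace_interval == 0:
                row = {"step": step, "energy_kcal": state.energy,
                       "log_likelihood": state.loglik,
                       "log_posterior": state.log_posterior,
                       "acceptance_rate": n_accept / step}
                if self.shifts is not None and state.predictions:
                    row["shift_rmsd_ppm"] = _shift_rmsd(state.predictions, self.shifts)
                trace_rows.append(row)
            if step > burn_in and step % save_interval == 0:
                samples.append(state.structure)
        if not samples:
            samples.append(state.structure)
        trace = pd.DataFrame(trace_rows)
        return RefinementResults(model=self, samples=samples, trace=trace, seed=seed,
                                 n_steps=n_steps, acceptance_rate=n_accept / max(n_steps, 1))


@dataclass
class RefinementResults:
    """Sampled ensemble plus diagnostics from one refinement run."""

    model: RefinementModel
    samples: List[Structure]
    trace: pd.DataFrame
    seed: int
    n_steps: int
    acceptance_rate: float

    @property
    def ensemble(self) -> List[Structure]:
        return self.samples

    def ensemble_shifts(self) -> pd.DataFrame:
        preds = [predict(s, self.model.params) for s in self.samples]
        return ensemble_average(preds)

    def shift_score(self):
        if self.model.shifts is None:
            raise ValueError("model was fit without a shift table")
        avg = self.ensemble_shifts()
        return score(avg, self.model.shifts)

    def hbond_length_means(self) -> pd.DataFrame:
        """Ensemble mean/SD of r_HO per donor residue (NaN when never bonded)."""
        rows: Dict[int, List[float]] = {}
        for s in self.samples:
            for hb in detect_hydrogen_bonds(s, r_max=self.model.params.hb_gate_r_max,
                                            angle_min=self.model.params.hb_gate_angle_min):
                rows.setdefault(hb.donor.res_index, []).append(
                    hb.r_ho if hb.bonded else np.nan)
        out = []
        for res, values in sorted(rows.items()):
            arr = np.array(values, dtype=float)
            ok = arr[np.isfinite(arr)]
            out.append({"res_index": res,
                        "mean_r_ho": float(ok.mean()) if len(ok) else np.nan,
                        "sd_r_ho": float(ok.std()) if len(ok) else np.nan,
                        "n_bonded": int(len(ok)), "n_samples": len(arr)})
        return pd.DataFrame(out)

    def to_pdb(self, path) -> None:
        write_ensemble(self.samples, path)

    def write_trace(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# amideshift refinement trace (seed={self.seed}, "
                     f"n_steps={self.n_steps}, T={self.model.temperature} K)\n")
            self.trace.to_csv(fh, index=False)

    def summary(self) -> str:
        lines = [
            "Refinement results",
            "==================",
            f"steps            : {self.n_steps}",
            f"seed             : {self.seed}",
            f"temperature      : {self.model.temperature:.1f} K",
            f"saved conformers : {len(self.samples)}",
            f"acceptance rate  : {self.acceptance_rate:.3f}",
            f"final energy     : {self.trace['energy_kcal'].iloc[-1]:.3f} kcal/mol"
            if len(self.trace) else "final energy     : n/a",
        ]
        if self.model.shifts is not None:
            sc = self.shift_score()
            lines.append(f"ensemble shift RMSD : {sc.rmsd:.3f} ppm (r = {sc.pearson_r:.3f})")
            for klass, s in sorted(self.model.sigma.sigma.items(), key=lambda kv: kv[0].value):
                lines.append(f"  sigma[{klass.value:>16s}] = {s:.2f} ppm")
        return "\n".join(lines)

    def plot_trace(self, path=None):
        """Energy / shift-RMSD trace plot (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        cols = [c for c in ("energy_kcal", "log_posterior", "shift_rmsd_ppm")
                if c in self.trace]
        fig, axes = plt.subplots(len(cols), 1, sharex=True, figsize=(7, 2.2 * len(cols)))
        axes = np.atleast_1d(axes)
        for ax, col in zip(axes, cols):
            ax.plot(self.trace["step"], self.trace[col], lw=0.8)
            ax.set_ylabel(col)
        axes[-1].set_xlabel("MC step")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def run_refinement(start: Structure, shifts: Optional[ShiftTable], n_steps: int,
                   seed: int = 0, save_interval: int = 10_000,
                   **model_kwargs) -> RefinementResults:
    """Convenience wrapper: build a RefinementModel and fit it."""
    model = RefinementModel(start, shifts, **model_kwargs)
    return model.fit(n_steps=n_steps, seed=seed, save_interval=save_interval)
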