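"""Likelihood, posterior and Metropolis-Hastings sampling."""

import math
from dataclasses import dataclass

import numpy as np
import pytest

from amideshift.fixtures import make_peptide, synthetic_shift_table
from amideshift.inference import (KB_KCAL, HarmonicTorsionEnergy, RefinementModel,
                                  SigmaModel, TorsionMoveGenerator, ZeroEnergy,
                                  log_likelihood, log_posterior, mh_step)
from amideshift.predictor import ShiftPrediction, ShiftTable
from amideshift.structure import AcceptorClass, torsion_value
from amideshift.terms import TermBreakdown


def _pred(res, total, klass=AcceptorClass.BACKBONE_AMIDE):
    return ShiftPrediction(chain="A", res_index=res, res_name="ALA",
                           breakdown=TermBreakdown(total, 0.0, 0.0, 0.0, 0.0),
                           acceptor_class=klass)


def _table(pairs):
    return ShiftTable.from_records([(r, "ALA", v) for r, v in pairs])


class TestLogLikelihood:
    def test_sigma_class_assignment(self, params):
        sig = SigmaModel.default(params)
        assert sig.for_class(AcceptorClass.BACKBONE_AMIDE) == 0.3
        assert sig.for_class(AcceptorClass.SIDECHAIN_AMIDE) == 0.5
        assert sig.for_class(AcceptorClass.ALCOHOL) == 0.8
        assert sig.for_class(AcceptorClass.CARBOXYLATE) == 0.8
        assert sig.for_class(AcceptorClass.NONE) == 1.2

    def test_maximum_at_zero_deviation(self, params):
        sig = SigmaModel.default(params)
        at_zero = log_likelihood([_pred(2, 8.0)], _table([(2, 8.0)]), sig)
        at_sigma = log_likelihood([_pred(2, 8.3)], _table([(2, 8.0)]), sig)
        # Gaussian algebra: one sigma of deviation costs exactly 1/2
        assert at_zero - at_sigma == pytest.approx(0.5, abs=1e-10)

    def test_backbone_sigma_used(self, params):
        sig = SigmaModel.default(params)
        got = log_likelihood([_pred(2, 8.5)], _table([(2, 8.0)]), sig)
        s = 0.3
        expected = -0.25 / (2 * s * s) - math.log(s * math.sqrt(2 * math.pi))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_ten_residue_brute_force(self, params):
        sig = SigmaModel.default(params)
        rng = np.random.default_rng(17)
        classes = [AcceptorClass.BACKBONE_AMIDE, AcceptorClass.NONE,
                   AcceptorClass.ALCOHOL, AcceptorClass.SIDECHAIN_AMIDE]
        preds, rows, expected = [], [], 0.0
        for i in range(10):
            klass = classes[i % 4]
            total = 8.0 + rng.normal(0, 0.5)
            obs = 8.0 + rng.normal(0, 0.5)
            preds.append(_pred(i + 2, total, klass))
            rows.append((i + 2, obs))
            s = sig.for_class(klass)
            expected += -(total - obs) ** 2 / (2 * s * s) - math.log(s * math.sqrt(2 * math.pi))
        assert log_likelihood(preds, _table(rows), sig) == pytest.approx(expected, abs=1e-10)

    def test_no_matches_raise(self, params):
        with pytest.raises(ValueError, match="matched"):
            log_likelihood([_pred(2, 8.0)], _table([(9, 8.0)]), SigmaModel.default(params))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SigmaModel({AcceptorClass.NONE: 0.0})


class TestLogPosterior:
    def test_no_data_reduces_to_prior(self):
        assert log_posterior(1.0, 0.0, 300.0) == pytest.approx(-1.0 / (KB_KCAL * 300.0))

    def test_doubling_temperature_halves_prior_weight(self):
        e, ll = 2.0, -3.0
        lp_300 = log_posterior(e, ll, 300.0)
        lp_600 = log_posterior(e, ll, 600.0)
        assert lp_300 - ll == pytest.approx(2.0 * (lp_600 - ll), rel=1e-12)

    def test_two_state_ratio_is_boltzmann_times_likelihood(self):
        e1, e2, ll1, ll2, T = 0.5, 1.3, -2.0, -0.7, 300.0
        log_ratio = log_posterior(e2, ll2, T) - log_posterior(e1, ll1, T)
        analytic = -(e2 - e1) / (KB_KCAL * T) + (ll2 - ll1)
        assert log_ratio == pytest.approx(analytic, abs=1e-12)


@dataclass(frozen=True)
class ToyState:
    label: int
    log_posterior: float


class TestMHStep:
    def test_equal_posterior_always_accepted(self):
        rng = np.random.default_rng(0)
        a = ToyState(0, -1.0)
        for _ in range(50):
            new, accepted = mh_step(a, lambda s, r: ToyState(1, -1.0), rng)
            assert accepted and new.label == 1

    def test_infinite_energy_always_rejected(self):
        rng = np.random.default_rng(0)
        a = ToyState(0, -1.0)
        for _ in range(50):
            new, accepted = mh_step(a, lambda s, r: ToyState(1, -np.inf), rng)
            assert not accepted
            assert new is a  # previous state restored bit-exactly

    def test_two_state_occupancy_matches_boltzmann(self):
        # stationary distribution of a symmetric-proposal chain on two states
        delta = 1.0  # log-posterior gap
        states = {0: ToyState(0, 0.0), 1: ToyState(1, -delta)}
        rng = np.random.default_rng(123)
        state = states[0]
        n_steps = 100_000
        occ = 0
        for _ in range(n_steps):
            state, _ = mh_step(state, lambda s, r: states[1 - s.label], rng)
            occ += state.label
        p1 = math.exp(-delta) / (1.0 + math.exp(-delta))
        # the flip proposal anticorrelates successive states, so the iid
        # standard error is conservative here
        se = math.sqrt(p1 * (1 - p1) / n_steps)
        assert abs(occ / n_steps - p1) < 3 * se


class TestSampler:
    def test_fixed_seed_determinism(self, params):
        start = make_peptide(4, -57, -47)
        table = synthetic_shift_table(start, params=params)
        runs = []
        for _ in range(2):
            model = RefinementModel(start, table, params=params, energy=ZeroEnergy())
            res = model.fit(n_steps=500, seed=7, save_interval=100, trace_interval=50)
            runs.append(res)
        assert runs[0].trace.equals(runs[1].trace)
        for a, b in zip(runs[0].samples, runs[1].samples):
            assert np.array_equal(a.coords, b.coords)

    def test_harmonic_prior_torsion_variance(self, params):
        # likelihood-free chain with a harmonic torsion prior: the sampled
        # variance of each torsion must match kT/k
        start = make_peptide(3, -57, -47)
        k = 0.05  # kcal/(mol deg^2)
        model = RefinementModel(
            start, shifts=None, params=params,
            energy=HarmonicTorsionEnergy(start, k=k),
            move_generator=TorsionMoveGenerator(start, backbone_sigma=2.5),
        )
        res = model.fit(n_steps=60_000, seed=3, save_interval=25, burn_in=2_000)
        values = [torsion_value(s, "phi", 2) for s in res.samples]
        target = KB_KCAL * 300.0 / k
        assert np.var(values) == pytest.approx(target, rel=0.10)

    def test_frozen_chain_warns(self, params, caplog):
        start = make_peptide(3, -57, -47)
        ref = start.coords.copy()

        class Wall:
            """Zero at the exact start coordinates, impassable elsewhere."""

            def __call__(self, s):
                return 0.0 if np.array_equal(s.coords, ref) else np.inf

        model = RefinementModel(start, shifts=None, params=params, energy=Wall())
        with caplog.at_level("WARNING", logger="amideshift.inference"):
            res = model.fit(n_steps=250, seed=0, save_interval=100, frozen_window=200)
        assert res.acceptance_rate == 0.0
        assert any("frozen" in rec.message for rec in caplog.records)

    def test_sampled_posterior_state_consistency(self, params):
        start = make_peptide(4, -57, -47)
        table = synthetic_shift_table(start, params=params)
        model = RefinementModel(start, table, params=params, energy=ZeroEnergy())
        state = model._evaluate(start)
        assert state.log_posterior == pytest.approx(
            -state.energy / (KB_KCAL * model.temperature) + state.loglik, abs=1e-10)
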