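"""Mushroom-body circuit models: steady states, learning, novelty rule."""

import numpy as np
import pytest

from mbpredict.circuits import (CircuitParams, dan_valence_activity,
                                mbon_activity, simulate_error_driven,
                                simulate_target_driven,
                                target_driven_test_gain, update_novelty_rule,
                                valence_targets)
from mbpredict.encoding import shock_to_internal
from mbpredict.plasticity import FIG6B_RATE, integrate, paper_fit
from mbpredict.protocols import (StimulusProtocol, build_continuous_protocol,
                                 build_sequence_protocol)

DT = 0.001


@pytest.fixture(scope="module")
def circuit_rule():
    """Predictive rule with the faster circuit-simulation rate process."""
    return paper_fit("predictive").replace(**FIG6B_RATE)


def pairing_then_test_protocol(pair_dur=30.0, gap=10.0, test_dur=20.0,
                               voltage=50.0, dt=DT):
    """Odor-shock pairing, a pause, then the odor alone (the memory test)."""
    total = pair_dur + gap + test_dur
    n = int(round(total / dt)) + 1
    t = np.arange(n) * dt
    odor = np.zeros(n)
    volt = np.zeros(n)
    odor[: int(pair_dur / dt)] = 1.0
    volt[: int(pair_dur / dt)] = voltage
    odor[int((pair_dur + gap) / dt): int(total / dt)] = 1.0
    return StimulusProtocol("pairing_then_test", dt, t, odor, volt, total,
                            {"family": "custom"})


class TestErrorDriven:
    def test_frozen_weights_steady_state(self, circuit_rule):
        """With frozen weights the rates settle at v = w*o, e = s - v."""
        proto = build_continuous_protocol(30.0, 50.0, DT, enforce_allowed=False)
        cp = CircuitParams(w_MK=0.5)
        trace = simulate_error_driven(proto, cp, circuit_rule,
                                      freeze_weights=True)
        i = int(round(119.0 / DT))          # deep inside the pairing window
        s_val = shock_to_internal(50.0, circuit_rule.encoding)
        assert trace.v[i] == pytest.approx(0.5, abs=1e-6)
        assert trace.dan[i] == pytest.approx(s_val - 0.5, abs=1e-6)

    def test_learning_drives_error_to_zero(self, circuit_rule):
        proto = pairing_then_test_protocol()
        trace = simulate_error_driven(proto, CircuitParams(), circuit_rule)
        i_end_pair = int(round(29.9 / DT))
        s_val = shock_to_internal(50.0, circuit_rule.encoding)
        assert trace.v[i_end_pair] == pytest.approx(s_val, rel=0.01)
        assert abs(trace.dan[i_end_pair]) < 1e-2 * s_val

    def test_negative_prediction_error_at_odor_alone_test(self, circuit_rule):
        proto = pairing_then_test_protocol()
        trace = simulate_error_driven(proto, CircuitParams(), circuit_rule)
        i_test = int(round(45.0 / DT))      # 5 s into the odor-alone test
        assert trace.dan[i_test] < 0.0
        assert trace.dan[i_test] == pytest.approx(-trace.v[i_test], rel=0.05)

    def test_instability_rejected(self, circuit_rule):
        proto = build_continuous_protocol(10.0, 25.0, 0.01)
        with pytest.raises(ValueError):
            simulate_error_driven(proto, CircuitParams(tau=0.01), circuit_rule)

    def test_matches_phenomenological_rule_on_behavioral_timescale(self):
        """With tau = 10 ms << protocol timescales, the circuit's learned
        weight reproduces the phenomenological predictive-rule weight < 2%."""
        pp = paper_fit("predictive")
        for proto_fn in (lambda dt: build_sequence_protocol(4, 25.0, "end", dt),
                         lambda dt: build_continuous_protocol(30.0, 50.0, dt)):
            circuit_w = simulate_error_driven(proto_fn(DT), CircuitParams(),
                                              pp).w_MK[-1]
            pheno_w = integrate(proto_fn(0.01), pp).learned_weight
            assert circuit_w == pytest.approx(pheno_w, rel=0.02)


class TestTargetDriven:
    def test_pairing_converges_to_shock_representation(self, circuit_rule):
        proto = pairing_then_test_protocol(pair_dur=60.0)
        trace = simulate_target_driven(proto, CircuitParams(), circuit_rule)
        i = int(round(59.9 / DT))
        s_val = shock_to_internal(50.0, circuit_rule.encoding)
        assert trace.v[i] == pytest.approx(s_val, rel=0.01)
        assert trace.dan[i] == pytest.approx(s_val, rel=0.01)

    @pytest.mark.parametrize("lam", [0.05, 0.1, 0.2])
    def test_odor_alone_steady_state_matches_closed_form(self, lam, circuit_rule):
        """Fully learned loop sustains v = (1-lam)/(1-lam(1-lam)) * s0."""
        s0 = 1.5646
        n = int(round(2.0 / DT)) + 1
        t = np.arange(n) * DT
        proto = StimulusProtocol("odor_alone", DT, t, np.ones(n), np.zeros(n),
                                 t[-1], {"family": "custom"})
        cp = CircuitParams(lambda_nudge=lam, w_MK=s0, w_DM=1.0)
        trace = simulate_target_driven(proto, cp, circuit_rule,
                                       freeze_weights=True)
        assert trace.v[-1] / s0 == pytest.approx(target_driven_test_gain(lam),
                                                 abs=1e-6)

    def test_lambda_zero_decouples(self, circuit_rule):
        n = int(round(1.0 / DT)) + 1
        t = np.arange(n) * DT
        proto = StimulusProtocol("odor_alone", DT, t, np.ones(n), np.zeros(n),
                                 t[-1], {"family": "custom"})
        cp = CircuitParams(lambda_nudge=0.0, w_MK=0.8, w_DM=1.0)
        trace = simulate_target_driven(proto, cp, circuit_rule,
                                       freeze_weights=True)
        assert trace.v[-1] == pytest.approx(0.8, abs=1e-6)


class TestValenceDans:
    def test_zero_inputs(self):
        assert dan_valence_activity(0, 0, 0, 0, 0, CircuitParams()) == (0.0, 0.0)

    def test_saturation(self):
        d_plus, _ = dan_valence_activity(0, 0, 100.0, 0, 0, CircuitParams())
        assert d_plus == 1.0

    def test_mismatched_valence_target_drives_depression(self):
        """Active aversive DAN silences the appetitive target, so a
        previously appetitive synapse sees a negative error."""
        target_plus, _ = valence_targets(d_plus=0.0, d_minus=1.0)
        assert target_plus == 0.0
        w_mk_o = 0.8                         # appetitively trained, odor on
        assert target_plus - w_mk_o < 0.0


class TestNoveltyRule:
    def setup_method(self):
        self.cp = CircuitParams(n_K=100, o_spont=0.05, d_spont=0.05, eta0=1.0)
        self.active = np.zeros(100, bool)
        self.active[:10] = True
        self.o_odor = np.where(self.active, 1.0, self.cp.o_spont)

    def test_zero_error_freezes_weights(self):
        w = np.full(100, 0.4)
        d = mbon_activity(w, self.o_odor)    # d == v exactly
        w2 = update_novelty_rule(w, self.o_odor, d, self.cp, 0.01)
        np.testing.assert_allclose(w2, w, atol=1e-15)

    def test_repetition_suppression_and_heterosynaptic_potentiation(self):
        """Weak DAN drive during an odor (d < v) depresses the active
        synapses while potentiating the non-activated ones."""
        w = np.full(100, 1.0)
        v = mbon_activity(w, self.o_odor)
        d = 0.5 * v
        w2 = update_novelty_rule(w, self.o_odor, d, self.cp, 0.01)
        dw = w2 - w
        assert np.all(dw[self.active] < 0)
        assert np.all(dw[~self.active] > 0)

    def test_passive_recovery_to_spontaneous_equilibrium(self):
        """Depressed weights recover under spontaneous activity until the
        spontaneous MBON drive matches the spontaneous DAN rate."""
        cp = CircuitParams(n_K=100, o_spont=0.05, d_spont=0.05, eta0=500.0)
        w = np.full(100, 0.5)                # depressed: w*o_spont < d_spont
        o_sp = np.full(100, cp.o_spont)
        for _ in range(4000):
            w = update_novelty_rule(w, o_sp, cp.d_spont, cp, dt=0.1)
        assert mbon_activity(w, o_sp) == pytest.approx(cp.d_spont, rel=1e-3)

    def test_dan_alone_activation_potentiates_all_synapses(self):
        w = np.full(100, 0.2)
        o_sp = np.full(100, self.cp.o_spont)
        d = 0.8                              # optogenetic DAN drive, d > v
        w2 = update_novelty_rule(w, o_sp, d, self.cp, 0.01)
        assert np.all(w2 > w)

    def test_matches_per_synapse_oracle_on_random_instances(self, rng):
        """Vector update equals an explicit per-synapse loop."""
        for _ in range(10):
            w = rng.uniform(0, 2, size=100)
            ot = self.cp.o_spont + rng.uniform(0, 1, size=100)
            d = rng.uniform(0, 1)
            got = update_novelty_rule(w, ot, d, self.cp, 0.01)
            v = np.mean(w * ot)
            obar = np.mean(ot) - self.cp.o_spont
            expected = [w[i] + 0.01 * d * self.cp.eta0 * (d - v) * (ot[i] - obar)
                        for i in range(100)]
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_signed_balance_of_redistribution(self, rng):
        """With a negative error, the summed potentiation of non-activated
        synapses is positive while activated synapses depress."""
        w = rng.uniform(0.5, 1.5, size=100)
        d = 0.2 * mbon_activity(w, self.o_odor)
        dw = update_novelty_rule(w, self.o_odor, d, self.cp, 0.01) - w
        assert dw[~self.active].sum() > 0
        assert np.all(dw[self.active] < 0)


def test_invalid_circuit_params():
    with pytest.raises(ValueError):
        CircuitParams(tau=-0.01)
    with pytest.raises(ValueError):
        CircuitParams(lambda_nudge=1.5)
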