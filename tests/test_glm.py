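import numpy as np
import pytest

from scrglm import glm
from scrglm.basis import canonical_scrf, make_basis
from scrglm.core_io import Condition, EventModel, SCTimeSeries
from scrglm.preprocess import FilterSpec

SR = 10.0


def _simulate(events, waveform, amps, n):
    """Brute-force forward data: amplitude-scaled shifted copies, summed."""
    y = np.zeros(n)
    for cond, amp in amps.items():
        for onset in events.condition(cond).onsets:
            i0 = int(np.round(onset * SR))
            seg = waveform[: n - i0]
            y[i0:i0 + seg.size] += amp * seg
    return y


class TestDeltaTrainAndDesign:
    def test_single_event_regressor_equals_basis_column(self):
        ev = EventModel((Condition("a", [0.0]),))
        b = make_basis("scrf")
        d = glm.build_design(ev, b, 400, SR, None)
        col = d.X[:, d.column_indices("cond", "a")[0]]
        np.testing.assert_allclose(col[:300], b.columns[:, 0])
        np.testing.assert_allclose(col[300:], 0.0)

    def test_disjoint_events_superpose(self):
        ev = EventModel((Condition("a", [0.0, 40.0]),))
        b = make_basis("scrf")
        d = glm.build_design(ev, b, 800, SR, None)
        col = d.X[:, d.column_indices("cond", "a")[0]]
        np.testing.assert_allclose(col[0:300], b.columns[:, 0])
        np.testing.assert_allclose(col[400:700], b.columns[:, 0])

    def test_overlapping_events_match_shift_sum_oracle(self):
        onsets = [5.0, 9.4, 13.8]
        ev = EventModel((Condition("a", onsets),))
        b = make_basis("scrf")
        n = 400
        d = glm.build_design(ev, b, n, SR, None)
        col = d.X[:, d.column_indices("cond", "a")[0]]
        oracle = np.zeros(n)
        for onset in onsets:
            i0 = int(np.round(onset * SR))
            seg = b.columns[: n - i0, 0]
            oracle[i0:i0 + seg.size] += seg
        np.testing.assert_allclose(col, oracle, atol=1e-12)

    def test_onset_beyond_recording_lists_trials(self):
        ev = EventModel((Condition("a", [1.0, 999.0]),))
        with pytest.raises(ValueError, match=r"\[1\]"):
            glm.build_design(ev, make_basis("scrf"), 100, SR, None)

    def test_column_count_bookkeeping(self, jittered_events, recording_length):
        b = make_basis("scrf-tdd")
        d = glm.build_design(jittered_events, b, recording_length, SR, None)
        assert d.X.shape[1] == 2 * 3 + 1  # j*bf + constant
        assert d.k == 6


class TestFit:
    def test_noise_free_amplitude_recovery(self, jittered_events, recording_length):
        b = make_basis("scrf")
        amps = {"a": 2.0, "b": 1.0}
        y = _simulate(jittered_events, b.columns[:, 0], amps, recording_length)
        d = glm.build_design(jittered_events, b, recording_length, SR, None)
        f = glm.fit(SCTimeSeries(y, SR), d)
        for cond, amp in amps.items():
            beta = f.betas[d.column_indices("cond", cond)[0]]
            assert beta == pytest.approx(amp, rel=1e-6)

    def test_data_orthogonal_to_design_gives_zero_betas(self, rng,
                                                        jittered_events,
                                                        recording_length):
        b = make_basis("scrf")
        d = glm.build_design(jittered_events, b, recording_length, SR, None)
        noise = rng.normal(0, 1, recording_length)
        proj, _, _, _ = np.linalg.lstsq(d.X, noise, rcond=None)
        resid = noise - d.X @ proj  # residualized: orthogonal to the design
        f = glm.fit(SCTimeSeries(resid, SR), d)
        np.testing.assert_allclose(f.betas[:-1], 0.0, atol=1e-9)

    def test_fitted_plus_residual_reconstructs_rss(self, rng, jittered_events,
                                                   recording_length):
        b = make_basis("scrf-td")
        d = glm.build_design(jittered_events, b, recording_length, SR, None)
        y = rng.normal(0, 1, recording_length)
        f = glm.fit(SCTimeSeries(y, SR), d)
        resid = y - d.X @ f.betas
        assert f.rss == pytest.approx(float(resid @ resid))
        assert f.rss >= 0

    def test_duplicated_column_warns_rank_deficient(self):
        ev = EventModel((Condition("a", [1.0]), Condition("b", [1.0])))
        b = make_basis("scrf")
        d = glm.build_design(ev, b, 200, SR, None)
        with pytest.warns(UserWarning, match="rank deficient"):
            glm.fit(SCTimeSeries(np.random.default_rng(0).normal(0, 1, 200), SR), d)

    def test_rss_non_increasing_in_nested_family(self, rng, jittered_events,
                                                 recording_length):
        y = SCTimeSeries(rng.normal(0, 1, recording_length), SR)
        rss = []
        for name in ("scrf", "scrf-td", "scrf-tdd"):
            b = make_basis(name)
            d = glm.build_design(jittered_events, b, recording_length, SR, None)
            rss.append(glm.fit(y, d).rss)
        assert rss[0] >= rss[1] >= rss[2]


class TestOrthogonalizationInvariance:
    @pytest.mark.parametrize("richer", ["scrf-td", "scrf-tdd"])
    def test_scrf_beta_unchanged_by_derivative_regressors(
        self, rng, jittered_events, recording_length, richer
    ):
        """Adding orthogonalized derivative regressors must not move the
        canonical-SCRF coefficient: that invariance is what licenses the
        coefficient as an SNA amplitude estimate."""
        hp = FilterSpec("highpass", 0.05, "unidirectional")
        b1 = make_basis("scrf")
        b2 = make_basis(richer)
        d1 = glm.build_design(jittered_events, b1, recording_length, SR, hp)
        d2 = glm.build_design(jittered_events, b2, recording_length, SR, hp)
        for _ in range(5):
            y = SCTimeSeries(rng.normal(0, 1, recording_length), SR)
            f1 = glm.fit(y, d1)
            f2 = glm.fit(y, d2)
            for cond in ("a", "b"):
                bA = f1.betas[d1.column_indices("cond", cond)[0]]
                bB = f2.betas[d2.column_indices("cond", cond)[0]]
                assert bB == pytest.approx(bA, rel=1e-8)


class TestReconstructionAndAmplitude:
    def test_single_column_amplitude_equals_beta(self, jittered_events,
                                                 recording_length):
        b = make_basis("scrf")
        y = _simulate(jittered_events, b.columns[:, 0], {"a": 2.0, "b": 1.0},
                      recording_length)
        d = glm.build_design(jittered_events, b, recording_length, SR, None)
        f = glm.fit(SCTimeSeries(y, SR), d)
        assert glm.sna_amplitude(f, "a", b) == pytest.approx(2.0, rel=1e-6)

    def test_largest_modulus_keeps_sign(self, jittered_events, recording_length):
        b = make_basis("scrf")
        y = _simulate(jittered_events, b.columns[:, 0], {"a": -0.5, "b": 0.3},
                      recording_length)
        d = glm.build_design(jittered_events, b, recording_length, SR, None)
        f = glm.fit(SCTimeSeries(y, SR), d)
        assert glm.sna_amplitude(f, "a", b) == pytest.approx(-0.5, rel=1e-6)

    def test_weighted_sum_reconstruction(self, jittered_events, recording_length):
        b = make_basis("scrf-td")
        coefs = np.array([1.5, 0.4])
        w = b.columns @ coefs
        y = _simulate(jittered_events, w, {"a": 1.0, "b": 1.0}, recording_length)
        d = glm.build_design(jittered_events, b, recording_length, SR, None)
        f = glm.fit(SCTimeSeries(y, SR), d)
        np.testing.assert_allclose(
            glm.reconstruct_response(f, "a", b), w, atol=1e-8
        )

    def test_unknown_condition_rejected(self, jittered_events, recording_length):
        b = make_basis("scrf")
        d = glm.build_design(jittered_events, b, recording_length, SR, None)
        f = glm.fit(SCTimeSeries(np.zeros(recording_length) + 1e-3, SR), d)
        with pytest.raises(KeyError):
            glm.sna_amplitude(f, "zz", b)

    def test_latency_shift_better_tracked_with_time_derivative(self):
        """A latency-shifted response biases the SCRF-only beta; the
        SCRF+TD reconstructed peak comes closer to the true amplitude."""
        rng = np.random.default_rng(3)
        onsets = np.cumsum(rng.choice([8.65, 10.0, 11.35], 20)) + 2
        ev = EventModel((Condition("a", onsets),))
        n = int((onsets[-1] + 40) * SR)
        true_amp = 1.0
        from scrglm.basis import SCRFParams
        shifted = canonical_scrf(SCRFParams(peak_time=4.0), SR).columns[:, 0]
        y = _simulate(ev, shifted, {"a": true_amp}, n)
        errs = {}
        for name in ("scrf", "scrf-td"):
            b = make_basis(name)
            d = glm.build_design(ev, b, n, SR, None)
            f = glm.fit(SCTimeSeries(y, SR), d)
            errs[name] = abs(glm.sna_amplitude(f, "a", b) - true_amp)
        assert errs["scrf-td"] < errs["scrf"]


class TestParametricModulators:
    def _events_with_pmod(self, rng, pmod_vals=None):
        onsets = np.cumsum(rng.choice([8.65, 10.0, 11.35], 30)) + 2
        n_trials = onsets.size
        vals = pmod_vals if pmod_vals is not None else np.arange(1, n_trials + 1)
        return EventModel((Condition("stim", onsets, {"habituation": vals}),))

    def test_habituation_pmod_design_shape(self, rng):
        ev = self._events_with_pmod(rng)
        n = int((ev.condition("stim").onsets[-1] + 40) * SR)
        b = make_basis("scrf")
        d = glm.add_parametric_modulators(ev, b, n, SR, None)
        assert len(d.column_indices("pmod", "stim", "habituation")) == 1
        assert d.k == 2

    def test_constant_pmod_rejected(self, rng):
        ev = self._events_with_pmod(rng, pmod_vals=np.full(30, 3.0))
        n = int((ev.condition("stim").onsets[-1] + 40) * SR)
        with pytest.raises(ValueError, match="constant"):
            glm.add_parametric_modulators(ev, make_basis("scrf"), n, SR, None)

    def test_binary_pmod_reparametrizes_two_condition_design(self, rng):
        """A ±0.5 modulator on one condition spans the same space as a
        two-condition design: fitted values must agree."""
        onsets = np.cumsum(rng.choice([8.65, 10.0, 11.35], 30)) + 2
        codes = rng.choice([-0.5, 0.5], 30)
        ev_pmod = EventModel((Condition("stim", onsets, {"type": codes}),))
        ev_two = EventModel((
            Condition("lo", onsets[codes < 0]),
            Condition("hi", onsets[codes > 0]),
        ))
        n = int((onsets[-1] + 40) * SR)
        b = make_basis("scrf")
        y = SCTimeSeries(rng.normal(0, 1, n), SR)
        d1 = glm.add_parametric_modulators(ev_pmod, b, n, SR, None)
        d2 = glm.build_design(ev_two, b, n, SR, None)
        f1 = glm.fit(y, d1)
        f2 = glm.fit(y, d2)
        np.testing.assert_allclose(
            d1.X @ f1.betas, d2.X @ f2.betas, atol=1e-8
        )


class TestSingleTrial:
    def test_one_regressor_set_per_trial(self, jittered_events, recording_length):
        b = make_basis("scrf")
        d = glm.single_trial_design(jittered_events, b, recording_length, SR, None)
        assert d.k == jittered_events.n_trials

    def test_trialwise_recovery_with_overlap(self):
        rng = np.random.default_rng(11)
        onsets = np.cumsum(np.full(12, 4.4)) + 2 + rng.uniform(-0.4, 0.4, 12)
        onsets.sort()
        ev = EventModel((Condition("stim", onsets),))
        n = int((onsets[-1] + 40) * SR)
        b = make_basis("scrf")
        true = rng.uniform(0.3, 1.5, onsets.size)
        y = np.zeros(n)
        for onset, amp in zip(onsets, true):
            i0 = int(np.round(onset * SR))
            seg = b.columns[: n - i0, 0]
            y[i0:i0 + seg.size] += amp * seg
        d = glm.single_trial_design(ev, b, n, SR, None)
        f = glm.fit(SCTimeSeries(y, SR), d)
        for i, amp in enumerate(true):
            est = glm.sna_amplitude(f, f"stim#{i}", b)
            assert est == pytest.approx(amp, rel=0.01)
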