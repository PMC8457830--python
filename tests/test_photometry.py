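"""Isosbestic correction and behavior-locked photometry summaries."""

import numpy as np
import pytest

import escapekit as ek
from escapekit.core import BehaviorEpoch
from escapekit.errors import (DegenerateInputError, FormatError,
                              InsufficientDataError, ParameterError)
from escapekit.photometry import CorrectedSignal


def _recording(n=2000, seed=0, signal_fn=None):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / 20.0
    channel = np.where(np.arange(n) % 2 == 0, 405, 470)
    ref = 1.0 + 0.3 * np.exp(-t / 300.0) + 0.01 * rng.standard_normal(n)
    values = np.where(channel == 405, ref,
                      signal_fn(t, ref) if signal_fn else 2.0 * ref)
    return ek.PhotometryRecording(times=t, values=values, channel=channel)


class TestCorrection:
    def test_pure_shared_artifact_corrects_to_zero(self):
        rec = _recording(signal_fn=lambda t, ref: 2.0 * ref, seed=1)
        sig = ek.correct_reference_artifacts(rec)
        assert np.max(np.abs(sig.dff)) < 0.05

    def test_output_is_zscored(self, escape_session):
        traj, truth, _, _ = escape_session
        rec, _ = ek.generate_photometry(traj, ek.TuningSpec.photometry(),
                                        seed=2, epochs=truth)
        sig = ek.correct_reference_artifacts(rec)
        assert sig.z.mean() == pytest.approx(0.0, abs=1e-9)
        assert sig.z.std() == pytest.approx(1.0, abs=1e-9)

    def test_constant_reference_degenerate(self):
        n = 400
        t = np.arange(n) / 20.0
        channel = np.where(np.arange(n) % 2 == 0, 405, 470)
        values = np.where(channel == 405, 1.0, 2.0 + 0.1 * np.sin(t))
        rec = ek.PhotometryRecording(times=t, values=values, channel=channel)
        with pytest.raises(DegenerateInputError):
            ek.correct_reference_artifacts(rec)

    def test_too_few_samples(self):
        rec = _recording(n=100)
        with pytest.raises(InsufficientDataError):
            ek.correct_reference_artifacts(rec)

    def test_channel_flags_validated(self):
        with pytest.raises(FormatError):
            ek.PhotometryRecording(times=np.arange(4.0),
                                   values=np.ones(4),
                                   channel=np.array([405, 470, 500, 405]))

    def test_planted_transients_recovered(self, escape_session):
        """Corrected df/F tracks the planted clean trace at r > 0.9."""
        traj, truth, _, _ = escape_session
        rec, clean = ek.generate_photometry(traj, ek.TuningSpec.photometry(),
                                            seed=3, epochs=truth)
        sig = ek.correct_reference_artifacts(rec)
        r = np.corrcoef(sig.z, clean["clean"])[0, 1]
        assert r > 0.9

    def test_affine_reference_invariance(self, escape_session):
        """Adding an affine transform of the reference to the signal leaves
        the corrected output unchanged to tolerance."""
        traj, truth, _, _ = escape_session
        rec, _ = ek.generate_photometry(traj, ek.TuningSpec.photometry(),
                                        seed=4, epochs=truth)
        sig = ek.correct_reference_artifacts(rec)
        t_ref, ref, _, _ = rec.split()
        ref_full = np.interp(rec.times, t_ref, ref)
        perturbed = np.where(rec.channel == 470,
                             rec.values + 0.5 * ref_full + 0.2, rec.values)
        rec2 = ek.PhotometryRecording(times=rec.times, values=perturbed,
                                      channel=rec.channel,
                                      rate_hz=rec.rate_hz)
        sig2 = ek.correct_reference_artifacts(rec2)
        assert np.corrcoef(sig.z, sig2.z)[0, 1] > 0.98


def _flat_signal(duration_s=300.0, value=0.0, rate=10.0):
    t = np.arange(0, duration_s, 1 / rate)
    z = np.full(len(t), value)
    return CorrectedSignal(times=t, z=z, dff=z.copy())


class TestTriggeredAverage:
    def test_two_instances_excluded(self):
        sig = _flat_signal()
        eps = [BehaviorEpoch("escape", 900, 1050, 5.0),
               BehaviorEpoch("escape", 2700, 2850, 5.0)]
        res = ek.behavior_triggered_average(sig, eps, "escape")
        assert res.excluded and res.n == 2
        assert res.mean is None

    def test_constant_signal_constant_average(self):
        sig = _flat_signal(value=3.14)
        eps = [BehaviorEpoch("escape", f, f + 60, 2.0)
               for f in (900, 2700, 4500, 6300)]
        res = ek.behavior_triggered_average(sig, eps, "escape")
        assert not res.excluded
        assert np.allclose(res.mean, 3.14)
        assert res.pre_onset_mean == pytest.approx(3.14)

    def test_nonisolated_instances_dropped(self):
        sig = _flat_signal()
        iso = [BehaviorEpoch("escape", f, f + 60, 2.0)
               for f in (900, 2700, 4500)]
        # a freeze 2 s after the first escape breaks its isolation
        eps = iso + [BehaviorEpoch("freeze", 1020, 1080, 2.0)]
        res = ek.behavior_triggered_average(sig, eps, "escape",
                                            min_instances=1)
        assert res.n == 2

    def test_shrinking_isolation_never_drops_epochs(self):
        sig = _flat_signal()
        eps = [BehaviorEpoch("escape", f, f + 60, 2.0)
               for f in (900, 1200, 2700, 4500)]
        counts = [ek.behavior_triggered_average(
            sig, eps, "escape", min_instances=1, isolation_s=s).n
            for s in (10.0, 5.0, 2.0, 0.5)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_planted_transients_peak_after_onset(self, escape_session):
        traj, truth, _, epochs = escape_session
        spec = ek.TuningSpec.photometry("escape")
        rec, _ = ek.generate_photometry(traj, spec, seed=5, epochs=truth)
        sig = ek.correct_reference_artifacts(rec)
        res = ek.behavior_triggered_average(sig, epochs, "escape")
        assert not res.excluded
        t_peak = res.offsets_s[np.argmax(res.mean)]
        assert 0.0 <= t_peak <= 2 * spec.kernel_tau_s


class TestSpeedMatched:
    def test_no_samples_in_range(self, arena):
        from conftest import make_kin
        kin = make_kin(arena, speed=np.full(100, 1.0))
        sig = _flat_signal(duration_s=100 / 30.0, rate=10.0)
        mean, n = ek.speed_matched_activity(sig, kin)
        assert n == 0 and np.isnan(mean)

    def test_higher_gain_regime_higher_matched_mean(self, escape_session):
        """With equal speed occupancy, the regime with stronger
        speed-locked activity has the higher speed-matched mean."""
        traj, truth, kin, _ = escape_session
        means = []
        for gain in (0.5, 3.0):
            spec = ek.TuningSpec(tunings=[ek.CellTuning("speed", gain)],
                                 noise_sd=0.005)
            rec, _ = ek.generate_photometry(traj, spec, seed=6, epochs=truth)
            sig = ek.correct_reference_artifacts(rec)
            m, n = ek.speed_matched_activity(sig, kin)
            assert n > 0
            means.append(m)
        assert means[1] > means[0]


class TestSpatialMap:
    def test_uniform_signal_flat_map(self, escape_session):
        traj, *_ = escape_session
        n = int(traj.duration_s * 10)
        sig = CorrectedSignal(times=np.arange(n) / 10.0,
                              z=np.full(n, 2.0), dff=np.full(n, 2.0))
        m = ek.spatial_activity_map(sig, traj, ek.ArenaSpec(), bin_cm=10.0)
        visited = ~np.isnan(m)
        assert visited.any()
        assert np.allclose(m[visited], 2.0)

    def test_unvisited_bins_marked_empty(self, escape_session):
        traj, *_ = escape_session
        n = int(traj.duration_s * 10)
        sig = CorrectedSignal(times=np.arange(n) / 10.0, z=np.zeros(n),
                              dff=np.zeros(n))
        m = ek.spatial_activity_map(sig, traj, ek.ArenaSpec(), bin_cm=5.0)
        assert np.isnan(m).any()

    def test_oversized_bin_rejected(self, escape_session):
        traj, *_ = escape_session
        sig = _flat_signal()
        with pytest.raises(ParameterError):
            ek.spatial_activity_map(sig, traj, ek.ArenaSpec(), bin_cm=30.0)

    def test_proximity_tuned_signal_increases_toward_threat(
            self, escape_session):
        traj, truth, _, _ = escape_session
        spec = ek.TuningSpec.photometry("position", gain=3.0)
        rec, _ = ek.generate_photometry(traj, spec, seed=7, epochs=truth)
        sig = ek.correct_reference_artifacts(rec)
        m = ek.spatial_activity_map(sig, traj, ek.ArenaSpec(), bin_cm=10.0)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_means = np.nanmean(m, axis=1)
        xs = np.arange(len(col_means)) + 0.5
        ok = np.isfinite(col_means)
        slope = np.polyfit(xs[ok], col_means[ok], 1)[0]
        assert slope > 0  # activity grows toward the threat wall (x max)
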