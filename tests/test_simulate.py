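import dataclasses
import json

import numpy as np
import pytest

from ieegnet.io import ContactTable
from ieegnet.spatial import pairwise_distances
from ieegnet.simulate import (
    SynthConfig,
    amplitude_profile,
    make_cohort,
    make_layout,
    make_patient,
    make_target_correlation,
    sample_recording,
)


def fixed_cfg(**kwargs):
    base = dict(
        grid_rows_range=None,
        grid_cols_range=None,
        pitch_range_mm=None,
        n_resected_range=None,
        fs=256.0,
    )
    base.update(kwargs)
    return SynthConfig(**base)


class TestLayout:
    def test_grid_span(self):
        cfg = fixed_cfg(grid_shape=(8, 8), pitch_mm=10.0)
        coords = make_layout(cfg)
        assert coords.shape == (64, 3)
        d = pairwise_distances(
            ContactTable([str(i) for i in range(64)], coords, np.zeros(64, bool), np.zeros(64, bool))
        )
        assert d.values.max() == pytest.approx(np.sqrt(2) * 70.0)

    def test_strip_distances(self):
        cfg = fixed_cfg(grid_shape=(1, 6), pitch_mm=5.0)
        coords = make_layout(cfg)
        gaps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        np.testing.assert_allclose(gaps, 5.0)
        assert np.linalg.norm(coords[-1] - coords[0]) == pytest.approx(25.0)

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            make_layout(fixed_cfg(grid_shape=(0, 5)))


class TestTargetCorrelation:
    def _dist(self, cfg):
        coords = make_layout(cfg)
        n = len(coords)
        tab = ContactTable([str(i) for i in range(n)], coords, np.zeros(n, bool), np.zeros(n, bool))
        return pairwise_distances(tab).values

    def test_zero_effect_matches_decay(self):
        cfg = fixed_cfg(epi_effect=0.0)
        d = self._dist(cfg)
        c, repair = make_target_correlation(d, np.zeros(len(d), bool), cfg)
        assert repair < 1e-6
        off = ~np.eye(len(d), dtype=bool)
        np.testing.assert_allclose(c[off], cfg.f_true(d[off]), atol=1e-6)

    def test_epi_pairs_elevated_by_delta(self):
        cfg = fixed_cfg()
        d = self._dist(cfg)
        epi = np.zeros(len(d), bool)
        epi[:4] = True
        c, _ = make_target_correlation(d, epi, cfg)
        base = cfg.f_true(d)
        bump = c[np.ix_(epi, epi)] - base[np.ix_(epi, epi)]
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(bump[off], cfg.epi_effect, atol=0.01)

    def test_output_is_valid_correlation_matrix(self):
        cfg = fixed_cfg()
        d = self._dist(cfg)
        epi = np.zeros(len(d), bool)
        epi[::7] = True
        c, _ = make_target_correlation(d, epi, cfg)
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)
        assert np.linalg.eigvalsh(c).min() >= -1e-10

    def test_infeasible_effect_rejected(self):
        cfg = fixed_cfg(epi_effect=1.5, max_psd_repair=0.05)
        d = self._dist(cfg)
        epi = np.zeros(len(d), bool)
        epi[:10] = True
        with pytest.raises(ValueError):
            make_target_correlation(d, epi, cfg)


class TestSampleRecording:
    def test_identity_correlations_small(self):
        cfg = fixed_cfg(fs=1000.0)
        rng = np.random.default_rng(3)
        rec = sample_recording(np.eye(3), cfg, rng, "p", ["a", "b", "c"], duration_s=100.0)
        c = np.corrcoef(rec.data)
        off = ~np.eye(3, dtype=bool)
        assert np.abs(c[off]).max() < 0.05

    def test_strong_pair_recovered(self):
        cfg = fixed_cfg(fs=1000.0)
        target = np.array([[1.0, 0.9], [0.9, 1.0]])
        rng = np.random.default_rng(4)
        rec = sample_recording(target, cfg, rng, "p", ["a", "b"], duration_s=100.0)
        assert np.corrcoef(rec.data)[0, 1] == pytest.approx(0.9, abs=0.02)

    def test_same_seed_identical(self):
        cfg = fixed_cfg()
        a = sample_recording(np.eye(2), cfg, np.random.default_rng(9), "p", ["a", "b"], 2.0)
        b = sample_recording(np.eye(2), cfg, np.random.default_rng(9), "p", ["a", "b"], 2.0)
        np.testing.assert_array_equal(a.data, b.data)

    def test_non_psd_rejected(self):
        cfg = fixed_cfg()
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            sample_recording(bad, cfg, np.random.default_rng(0), "p", ["a", "b"], 2.0)

    def test_line_noise_adds_50hz_peak(self):
        from scipy.signal import periodogram

        cfg = fixed_cfg(line_noise_amp=3.0, fs=256.0)
        rng = np.random.default_rng(6)
        rec = sample_recording(np.eye(2), cfg, rng, "p", ["a", "b"], duration_s=20.0)
        f, p = periodogram(rec.data[0], fs=256.0)
        peak = f[np.argmax(p)]
        assert peak == pytest.approx(50.0, abs=0.5)


class TestAmplitudeProfile:
    def test_hypersynchronous_contacts_run_low(self):
        cfg = fixed_cfg(gain_sd=0.0)
        n = 20
        c = np.full((n, n), 0.1)
        np.fill_diagonal(c, 1.0)
        c[:5, :5] += 0.3  # strongly coherent block
        np.fill_diagonal(c, 1.0)
        amps = amplitude_profile(c, cfg, np.random.default_rng(0))
        assert amps[:5].mean() < amps[5:].mean()


class TestMakePatient:
    def test_good_outcome_epi_fully_resected(self, tiny_cfg):
        p = make_patient(tiny_cfg, "good", np.random.default_rng(1), duration_s=4.0)
        epi_removed = [
            p.contacts.removed[p.contacts.contact_ids.index(c)] for c in p.epi_contact_ids
        ]
        assert all(epi_removed)
        assert p.ilae_class == 1 and p.resection_overlap == 1.0

    def test_poor_outcome_epi_fully_spared(self, tiny_cfg):
        p = make_patient(tiny_cfg, "poor", np.random.default_rng(2), duration_s=4.0)
        epi_removed = [
            p.contacts.removed[p.contacts.contact_ids.index(c)] for c in p.epi_contact_ids
        ]
        assert not any(epi_removed)
        assert p.ilae_class == 3 and p.resection_overlap == 0.0

    def test_infeasible_sizes_rejected(self):
        cfg = fixed_cfg(grid_shape=(3, 3), n_resected=4, epi_set_size=6)
        with pytest.raises(ValueError):
            make_patient(cfg, "good", np.random.default_rng(0), duration_s=2.0)


class TestMakeCohort:
    def test_bookkeeping_on_disk(self, tmp_path, tiny_cfg):
        out = tmp_path / "cohort"
        patients, manifest = make_cohort(2, 2, tiny_cfg, seed=11, out_dir=out, duration_s=4.0)
        assert len(list(out.glob("*.edf"))) == 4
        assert len(list(out.glob("*_contacts.csv"))) == 4
        classes = [e.ilae_class for e in manifest.patients]
        assert classes.count(1) == 2
        truth = json.loads((out / "ground_truth.json").read_text())
        assert set(truth) == {e.patient_id for e in manifest.patients}

    def test_reruns_are_byte_identical(self, tmp_path, tiny_cfg):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        make_cohort(1, 1, tiny_cfg, seed=5, out_dir=out1, duration_s=4.0)
        make_cohort(1, 1, tiny_cfg, seed=5, out_dir=out2, duration_s=4.0)
        for name in ("manifest.json", "ground_truth.json", "P000_contacts.csv", "P000_seg0.edf"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_extra_segments_share_ground_truth(self, tiny_cfg):
        patients, _ = make_cohort(1, 1, tiny_cfg, seed=8, duration_s=4.0, segments_per_patient=2)
        p = patients[0]
        assert len(p.extra_segments) == 1
        assert p.extra_segments[0].channel_ids == p.recording.channel_ids
        assert not np.array_equal(p.extra_segments[0].data, p.recording.data)

    def test_generator_fidelity_to_target(self, tiny_cfg):
        # empirical windowed-correlation network converges entrywise to the
        # target matrix (no rereferencing/filtering in this check)
        from ieegnet.network import temporal_average_network

        cfg = dataclasses.replace(tiny_cfg, fs=64.0, gain_sd=0.0)
        p = make_patient(cfg, "good", np.random.default_rng(3), duration_s=3600.0)
        conn = temporal_average_network(p.recording)  # 1800 windows
        assert np.abs(conn.values - p.target_correlation).max() < 0.05
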