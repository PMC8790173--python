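import numpy as np
import pytest
from scipy import linalg

import stimdecode as sd
from stimdecode import ConfigurationError
from stimdecode.source import (ROI_SEEDS, build_forward, lcmv_filters,
                               roi_average, source_band_power,
                               source_power_map)
from stimdecode.spectral import BANDS


@pytest.fixture(scope="module")
def model16():
    return build_forward(sd.make_montage(16), grid_spacing=0.02)


class TestForwardModel:
    def test_grid_inside_head_and_rois_non_empty(self, model16):
        r = np.linalg.norm(model16.grid - model16.origin, axis=1)
        assert np.all(r <= 0.85 * model16.head_radius + 1e-9)
        present = [roi for roi, ch in ROI_SEEDS.items()
                   if ch in model16.channel_names]
        for roi in present:
            assert len(model16.roi_points(roi)) > 0
        assert np.isfinite(model16.leadfield).all()

    def test_leadfield_linearity(self, model16):
        lf = model16.leadfield[0]
        u = np.array([0.3, 0.5, 0.8])
        assert np.allclose(lf @ (2 * u), 2 * (lf @ u))

    def test_radial_dipole_under_electrode_peaks_there(self, model16):
        m = sd.make_montage(16)
        direction = m.positions[m.index("C3")]
        pos = model16.origin + 0.75 * model16.head_radius * direction
        gi = int(np.argmin(np.linalg.norm(model16.grid - pos, axis=1)))
        signal = model16.leadfield_for(m.scalp_names, "common_average")[gi] @ direction
        peak = m.scalp_names[int(np.argmax(np.abs(signal)))]
        # the maximum pick-up lies at the overhead electrode or a neighbour
        c3 = m.scalp_names.index("C3")
        neighbours = {m.scalp_names[j]
                      for j in np.flatnonzero(m.adjacency[c3])} | {"C3"}
        assert peak in neighbours

    def test_deep_source_attenuated_relative_to_superficial(self, model16):
        rel = model16.grid - model16.origin
        r = np.linalg.norm(rel, axis=1)
        deep = int(np.argmin(r))
        superficial = int(np.argmax(rel[:, 2]))
        n_deep = np.linalg.norm(model16.leadfield[deep])
        n_sup = np.linalg.norm(model16.leadfield[superficial])
        assert n_deep < n_sup

    def test_roi_average_single_point_identity(self, model16):
        vals = np.arange(model16.grid.shape[0], dtype=float)
        roi = next(r for r in ROI_SEEDS if (model16.roi_labels == r).any())
        pts = model16.roi_points(roi)
        avg = roi_average(vals, model16)[roi]
        assert avg == pytest.approx(vals[pts].mean())


class TestLCMV:
    def test_unit_gain_constraint(self, model16, rng):
        lf = model16.leadfield_for(model16.channel_names, "raw")
        cov = np.cov(rng.standard_normal((len(model16.channel_names), 4000)))
        f = lcmv_filters(cov, lf, reg=0.05)
        scalar_lf = np.einsum("pcd,pd->pc", lf, f.orientation)
        gain = np.einsum("pc,pc->p", f.weights, scalar_lf)
        assert np.abs(gain - 1).max() < 1e-6
        assert np.allclose(np.linalg.norm(f.orientation, axis=1), 1.0)

    def test_singular_covariance_instructs_regularization(self, model16):
        n = len(model16.channel_names)
        cov = np.zeros((n, n))
        lf = model16.leadfield_for(model16.channel_names, "raw")
        with pytest.raises(linalg.LinAlgError, match="regulariz"):
            lcmv_filters(cov, lf, reg=0.0)

    def test_asymmetric_covariance_rejected(self, model16, rng):
        n = len(model16.channel_names)
        cov = rng.standard_normal((n, n))
        lf = model16.leadfield_for(model16.channel_names, "raw")
        with pytest.raises(ConfigurationError):
            lcmv_filters(cov, lf)

    def test_noise_only_power_map_tracks_noise_gain(self, model16, rng):
        """With white-noise data the raw output power map is proportional
        to the filter noise-gain map; no localized peak appears."""
        n = len(model16.channel_names)
        noise = rng.standard_normal((20, n, 256))
        cov = np.cov(noise.transpose(1, 0, 2).reshape(n, -1))
        lf = model16.leadfield_for(model16.channel_names, "raw")
        f = lcmv_filters(cov, lf, reg=0.05)
        pm_raw = source_power_map(noise, f, normalize=None)
        wnorm = (f.weights ** 2).sum(axis=1)
        assert np.corrcoef(pm_raw, wnorm)[0, 1] > 0.99
        pm = source_power_map(noise, f)  # noise-gain normalized
        assert pm.max() <= 2.5 * np.median(pm)

    def test_single_dipole_localized_within_one_spacing(self, model16, rng):
        lf = model16.leadfield_for(model16.channel_names, "raw")
        rel = model16.grid - model16.origin
        candidates = np.flatnonzero(
            np.linalg.norm(rel, axis=1) > 0.6 * model16.head_radius)
        true = int(rng.choice(candidates))
        u = rel[true] / np.linalg.norm(rel[true])
        t = np.arange(2048) / 128.0
        s = np.sin(2 * np.pi * 10 * t)
        data = (np.outer(lf[true] @ u, s)
                + 0.01 * rng.standard_normal((lf.shape[1], len(t))))
        cov = np.cov(data)
        f = lcmv_filters(cov, lf, reg=0.05)
        pm = source_power_map(data[None], f)
        best = int(np.argmax(pm))
        err = np.linalg.norm(model16.grid[best] - model16.grid[true])
        assert err <= model16.grid_spacing + 1e-9

    def test_two_sources_low_cross_talk(self, model16, rng):
        """Two independent dipoles ~4 cm apart are each recovered at their
        own location with limited leakage."""
        lf = model16.leadfield_for(model16.channel_names, "raw")
        rel = model16.grid - model16.origin
        cand = np.flatnonzero(np.linalg.norm(rel, axis=1)
                              > 0.6 * model16.head_radius)
        a = cand[0]
        dists = np.linalg.norm(model16.grid[cand] - model16.grid[a], axis=1)
        b = int(cand[np.argmin(np.abs(dists - 0.04))])
        ua = rel[a] / np.linalg.norm(rel[a])
        ub = rel[b] / np.linalg.norm(rel[b])
        t = np.arange(4096) / 128.0
        s1 = np.sin(2 * np.pi * 10 * t + rng.uniform(0, 6.28))
        s2 = np.sin(2 * np.pi * 11 * t + rng.uniform(0, 6.28))
        data = (np.outer(lf[a] @ ua, s1) + np.outer(lf[b] @ ub, s2)
                + 0.01 * rng.standard_normal((lf.shape[1], len(t))))
        f = lcmv_filters(np.cov(data), lf, reg=0.05)
        # project data from source 1 only; power should sit at a, not b
        d1 = np.outer(lf[a] @ ua, s1)[None]
        pm = source_power_map(d1, f, normalize=None)
        assert pm[b] < 0.2 * pm[a]


class TestSourceBandPower:
    def test_zero_data_zero_power(self, model16):
        n = len(model16.channel_names)
        lf = model16.leadfield_for(model16.channel_names, "raw")
        cov = np.eye(n)
        f = lcmv_filters(cov, lf, reg=0.05)
        sp = source_band_power(np.zeros((3, n, 512)), 128.0, f,
                               BANDS["alpha"])
        assert np.all(sp == 0)

    def test_planted_alpha_source_dominates_its_location(self, model16, rng):
        lf = model16.leadfield_for(model16.channel_names, "raw")
        rel = model16.grid - model16.origin
        cand = np.flatnonzero(np.linalg.norm(rel, axis=1)
                              > 0.6 * model16.head_radius)
        true = int(cand[3])
        u = rel[true] / np.linalg.norm(rel[true])
        t = np.arange(512) / 128.0
        epochs = np.stack([
            np.outer(lf[true] @ u, np.sin(2 * np.pi * 10 * t + ph))
            + 0.01 * rng.standard_normal((lf.shape[1], len(t)))
            for ph in rng.uniform(0, 6.28, 10)])
        flat = epochs.transpose(1, 0, 2).reshape(lf.shape[1], -1)
        f = lcmv_filters(np.cov(flat), lf, reg=0.05)
        sp = source_band_power(epochs, 128.0, f, BANDS["alpha"])
        norm = sp.mean(axis=0) / (f.weights ** 2).sum(axis=1)
        far = np.linalg.norm(model16.grid - model16.grid[true],
                             axis=1) > 0.05
        assert norm[true] >= 5 * np.median(norm[far])

    def test_segmented_output_shape(self, model16):
        n = len(model16.channel_names)
        f = lcmv_filters(np.eye(n), model16.leadfield_for(
            model16.channel_names, "raw"), reg=0.05)
        sp = source_band_power(np.random.default_rng(0).standard_normal(
            (4, n, 512)), 128.0, f, BANDS["alpha"], window=(1.0, 1.4),
            segments=8)
        assert sp.shape == (4, model16.grid.shape[0], 8)
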