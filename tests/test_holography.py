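"""Forward rendering, angular-spectrum propagation, autofocus,
reconstruction and ROI phase unwrapping."""

import math

import numpy as np
import pytest

from aerovol import (
    ComplexFrame,
    ScenarioConfig,
    autofocus,
    droplet_phase_map,
    propagate_angular_spectrum,
    reconstruct_frame,
    render_hologram_frame,
    unwrap_phase_roi,
)
from aerovol.holography import propagate_with_unit_background
from aerovol.scene import ParticleTruth


def _droplet(x=100.0, y=110.0, v0=8.0, contact_angle=60.0):
    return ParticleTruth(0, x, y, 0, v0, 0.3, 0.0, "volatile", contact_angle)


class TestDropletPhaseMap:
    def test_zero_volume_gives_zero_phase(self, validation_config):
        phi = droplet_phase_map(_droplet(), 0.0, validation_config)
        assert not phi.any()

    def test_phase_integral_inverts_to_volume(self, validation_config):
        """Summing phi and applying the phase-volume conversion must
        recover the requested volume (the map is normalized exactly)."""
        cfg = validation_config
        for v in (0.5, 3.0, 12.0):
            phi = droplet_phase_map(_droplet(v0=12.0), v, cfg)
            recovered = (cfg.wavelength_um / (2 * math.pi * cfg.delta_n)
                         * cfg.pixel_area_um2 * phi.sum())
            assert recovered == pytest.approx(v, rel=1e-9)

    def test_linearity_in_delta_n(self):
        lo = ScenarioConfig(delta_n=0.2, rng_seed=0)
        hi = ScenarioConfig(delta_n=0.4, rng_seed=0)
        phi_lo = droplet_phase_map(_droplet(), 5.0, lo)
        phi_hi = droplet_phase_map(_droplet(), 5.0, hi)
        assert np.allclose(phi_hi, 2.0 * phi_lo)

    def test_footprint_outside_field_rejected(self, validation_config):
        with pytest.raises(ValueError, match="footprint"):
            droplet_phase_map(_droplet(x=1.0, y=1.0), 8.0, validation_config)


class TestPropagation:
    wavelength = 0.85
    pitch = 1.12

    def _gaussian(self, n=256, sigma=15.0):
        yy, xx = np.mgrid[:n, :n]
        return np.exp(-(((xx - n / 2) ** 2 + (yy - n / 2) ** 2)
                        / (2 * sigma ** 2))).astype(complex)

    def test_zero_distance_is_identity(self):
        g = self._gaussian()
        out = propagate_angular_spectrum(g, 0.0, self.wavelength, self.pitch)
        assert np.abs(out - g).max() < 1e-10

    def test_round_trip_recovers_field(self):
        g = self._gaussian()
        fwd = propagate_angular_spectrum(g, 300.0, self.wavelength, self.pitch,
                                         pad=False)
        back = propagate_angular_spectrum(fwd, -300.0, self.wavelength,
                                          self.pitch, pad=False)
        assert np.abs(back - g).max() < 1e-10

    def test_power_conservation(self):
        """Unit-modulus transfer function conserves the total power of a
        band-limited (smooth) field."""
        g = self._gaussian()
        out = propagate_angular_spectrum(g, 500.0, self.wavelength, self.pitch,
                                         pad=False)
        p_in = (np.abs(g) ** 2).sum()
        p_out = (np.abs(out) ** 2).sum()
        assert abs(p_out - p_in) / p_in < 1e-10

    def test_non_finite_input_rejected(self):
        g = self._gaussian()
        g[0, 0] = np.nan
        with pytest.raises(ValueError):
            propagate_angular_spectrum(g, 100.0, self.wavelength, self.pitch)


class TestRenderHologram:
    def test_flat_field_without_particles(self, validation_config):
        frame = render_hologram_frame([], validation_config, None)
        assert frame.dtype == np.uint16
        assert np.all(frame == validation_config.mean_counts)

    def test_single_particle_conserves_mean_intensity(self, validation_config):
        p = _droplet(x=140.0, y=150.0, v0=8.0)
        frame = render_hologram_frame([(p, 8.0)], validation_config, None)
        assert frame.std() > 0  # interference fringes present
        assert frame.mean() == pytest.approx(validation_config.mean_counts,
                                             rel=0.01)

    def test_noise_is_reproducible(self, default_config):
        p = _droplet(x=140.0, y=150.0)
        a = render_hologram_frame([(p, 8.0)], default_config,
                                  np.random.default_rng(5))
        b = render_hologram_frame([(p, 8.0)], default_config,
                                  np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestAutofocus:
    def test_recovers_known_distance(self, validation_config):
        p = _droplet(x=140.0, y=150.0, v0=10.0)
        frame = render_hologram_frame([(p, 10.0)], validation_config, None)
        res = autofocus(frame, (100.0, 300.0), 10.0, validation_config)
        assert res.focusable
        assert res.z_um == pytest.approx(validation_config.z_distance_um, abs=2.0)

    def test_flat_field_flagged_unfocusable(self, validation_config):
        frame = np.full((256, 256), 10000.0)
        res = autofocus(frame, (100.0, 300.0), 20.0, validation_config)
        assert not res.focusable

    def test_invariant_to_intensity_scaling(self, validation_config):
        p = _droplet(x=140.0, y=150.0, v0=10.0)
        frame = render_hologram_frame([(p, 10.0)], validation_config, None)
        res1 = autofocus(frame, (150.0, 250.0), 10.0, validation_config)
        res2 = autofocus(frame.astype(float) * 7.5, (150.0, 250.0), 10.0,
                         validation_config)
        assert res1.z_um == pytest.approx(res2.z_um, abs=1e-9)
        assert np.allclose(res1.criterion, res2.criterion)

    def test_empty_search_range_rejected(self, validation_config):
        frame = np.full((64, 64), 100.0)
        with pytest.raises(ValueError):
            autofocus(frame, (300.0, 100.0), 10.0, validation_config)


class TestReconstruction:
    def test_flat_field_reconstructs_to_unit_transmission(self, validation_config):
        frame = np.full((256, 256), 10000.0)
        rec = reconstruct_frame(frame, 200.0, validation_config)
        assert np.abs(1.0 - rec.amplitude).max() < 0.01
        assert np.abs(rec.phase).max() < 0.05

    def test_weak_phase_volume_recovery(self, validation_config):
        """Phase integral over the droplet neighbourhood recovers the
        ground-truth volume from a rendered hologram."""
        cfg = validation_config
        v0 = 10.0
        p = _droplet(x=140.0, y=150.0, v0=v0)
        frame = render_hologram_frame([(p, v0)], cfg, None)
        phi_true = droplet_phase_map(p, v0, cfg)
        support = phi_true > 0
        rec = reconstruct_frame(frame, cfg.z_distance_um, cfg, refine=True)
        factor = (cfg.wavelength_um / (2 * math.pi * cfg.delta_n)
                  * cfg.pixel_area_um2)
        v_rec = factor * np.clip(rec.phase[support], 0, None).sum()
        assert v_rec == pytest.approx(v0, rel=0.10)

    def test_refinement_reduces_twin_image_error(self, validation_config):
        cfg = validation_config
        v0 = 8.0
        p = _droplet(x=120.0, y=130.0, v0=v0)
        frame = render_hologram_frame([(p, v0)], cfg, None)
        support = droplet_phase_map(p, v0, cfg) > 0
        raw = reconstruct_frame(frame, cfg.z_distance_um, cfg, refine=False)
        ref = reconstruct_frame(frame, cfg.z_distance_um, cfg, refine=True)
        factor = (cfg.wavelength_um / (2 * math.pi * cfg.delta_n)
                  * cfg.pixel_area_um2)
        err_raw = abs(factor * raw.phase[support].sum() - v0)
        err_ref = abs(factor * ref.phase[support].sum() - v0)
        assert err_ref <= err_raw

    def test_non_positive_z_rejected(self, validation_config):
        with pytest.raises(ValueError):
            reconstruct_frame(np.full((64, 64), 100.0), 0.0, validation_config)


class TestUnitBackgroundPropagation:
    def test_plane_wave_maps_to_plane_wave(self):
        u = np.ones((128, 128), dtype=complex)
        out = propagate_with_unit_background(u, 250.0, 0.85, 1.12)
        expected = np.exp(2j * math.pi * 250.0 / 0.85)
        assert np.abs(out - expected).max() < 1e-12


class TestUnwrapPhaseROI:
    def _radial_bump(self, peak, n=41):
        yy, xx = np.mgrid[:n, :n]
        r = np.hypot(xx - n // 2, yy - n // 2)
        mask = r <= n // 2 - 2
        phase = np.where(mask, peak * np.clip(1 - r / (n // 2 - 2), 0, 1), 0.0)
        return phase, mask

    def test_wrap_then_unwrap_recovers_ramp(self):
        """A smooth radial ramp 0 -> 3 pi, zero at the ROI boundary,
        survives a wrap/unwrap round trip."""
        truth, mask = self._radial_bump(3 * math.pi)
        wrapped = np.angle(np.exp(1j * truth))
        unwrapped = unwrap_phase_roi(wrapped, mask)
        assert np.abs(unwrapped[mask] - truth[mask]).max() < 1e-6

    def test_identity_on_already_unwrapped_input(self):
        truth, mask = self._radial_bump(2.0)  # within (-pi, pi]
        out = unwrap_phase_roi(truth, mask)
        assert np.allclose(out, truth, atol=1e-9)

    def test_gauge_invariance_of_differences(self):
        truth, mask = self._radial_bump(3 * math.pi)
        wrapped = np.angle(np.exp(1j * truth))
        u1 = unwrap_phase_roi(wrapped, mask)
        u2 = unwrap_phase_roi(wrapped + 2 * math.pi, mask)
        d1 = np.diff(u1[mask])
        d2 = np.diff(u2[mask])
        assert np.abs(d1 - d2).max() < 1e-9

    def test_disconnected_roi_warns_and_processes(self):
        phase = np.zeros((20, 20))
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:6, 2:6] = True
        mask[12:16, 12:16] = True
        phase[mask] = 0.5
        with pytest.warns(UserWarning, match="connected components"):
            out = unwrap_phase_roi(phase, mask)
        assert np.allclose(out[mask], 0.5)
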